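"""Time-anchored feature extraction from rise/decay curves.

Each channel of a measurement yields five features: the signal at fixed
offsets after the detected onset, baseline-subtracted at the onset sample.
The default anchors (2, 10, 120, 122, 130 s) place the first three on the
rising curve of a 2-minute sampling window and the last two on the decay
just after the purge starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import Measurement, ResponseCurve
from .exceptions import DegenerateInputError, NoRiseError

__all__ = [
    "DEFAULT_OFFSETS",
    "FeatureVector",
    "FeatureMatrix",
    "detect_onset",
    "extract_features",
    "assemble_feature_matrix",
    "replicate_relative_deviation",
    "DeviationReport",
]

DEFAULT_OFFSETS = (2.0, 10.0, 120.0, 122.0, 130.0)
METADATA_COLUMNS = ["sample_id", "group", "replicate"]


@dataclass(frozen=True)
class FeatureVector:
    channel_label: str
    t0_used: float
    offsets: tuple[float, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "offsets", tuple(float(o) for o in self.offsets))
        if len(self.offsets) != values.size:
            raise ValueError("offsets and values must have equal length")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("offsets must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")


@dataclass(frozen=True)
class FeatureMatrix:
    """Measurements x (channel-major) feature table with study metadata."""

    frame: pd.DataFrame
    channels: tuple[str, ...]
    offsets: tuple[float, ...]

    @property
    def feature_columns(self) -> list[str]:
        return [
            f"{ch}_S{i + 1}"
            for ch in self.channels
            for i in range(len(self.offsets))
        ]

    @property
    def values(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    @property
    def labels(self) -> pd.Series:
        return self.frame["group"]

    def __len__(self) -> int:
        return len(self.frame)


def _trailing_mean(values: np.ndarray, width: int) -> np.ndarray:
    """Causal boxcar mean; avoids pre-onset leakage of the rise."""
    if width <= 1:
        return values.astype(float)
    c = np.cumsum(np.concatenate([[0.0], values]))
    out = np.empty_like(values, dtype=float)
    idx = np.arange(values.size)
    start = np.maximum(idx - width + 1, 0)
    out = (c[idx + 1] - c[start]) / (idx + 1 - start)
    return out


def detect_onset(
    curve: ResponseCurve,
    method: str = "derivative",
    nominal_valve_time: float | None = None,
    k: float = 5.0,
    m: int = 5,
    smooth_samples: int | None = None,
) -> float:
    """Time when the signal starts to rise.

    ``method="nominal"`` returns the supplied valve time unchanged.  The
    default derivative method smooths causally, estimates the baseline
    derivative noise, and returns the first time where ``|dy/dt|`` exceeds
    ``k`` baseline standard deviations for ``m`` consecutive samples.  With a
    nominal valve time the search is restricted to +-2 s around it.
    """
    if method == "nominal":
        if nominal_valve_time is None:
            raise ValueError("method 'nominal' requires nominal_valve_time")
        return float(nominal_valve_time)
    if method != "derivative":
        raise ValueError(f"unknown onset method {method!r}")

    t = curve.times
    v = curve.values
    if smooth_samples is None:
        # ~0.25 s window (>= 5 samples) so the derivative noise floor does
        # not swamp slow rises at high sampling rates
        smooth_samples = max(5, int(round(0.25 * curve.sampling_rate)))
    baseline_end = nominal_valve_time - 2.0 if nominal_valve_time is not None else t[0] + 1.0
    base_mask = t < baseline_end
    if base_mask.sum() < 2 or baseline_end - t[0] < 1.0 - 1e-9:
        raise DegenerateInputError(
            "need >= 1 s of pre-injection baseline for onset detection"
        )
    smoothed = _trailing_mean(v, smooth_samples)
    deriv = np.gradient(smoothed, t)
    sd = float(np.std(deriv[base_mask]))
    threshold = k * sd + 1e-12 * max(float(np.max(np.abs(v))), 1.0)

    search = ~base_mask
    if nominal_valve_time is not None:
        search &= (t >= nominal_valve_time - 2.0) & (t <= nominal_valve_time + 2.0)
    idx = np.nonzero(search)[0]
    if idx.size < m:
        raise NoRiseError("search window too short for onset detection")
    above = np.abs(deriv[idx]) > threshold
    # first run of m consecutive exceedances
    run = 0
    t_thr = None
    for j, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= m:
            t_thr = float(t[idx[j - m + 1]])
            break
    if t_thr is None:
        raise NoRiseError("no signal rise detected")
    return _refine_onset(curve, t_thr, baseline_end)


def _refine_onset(curve: ResponseCurve, t_thr: float, baseline_end: float) -> float:
    """Sub-sample onset: intersect a line fit of the early rise with a line
    fit of the (possibly drifting) baseline.  Falls back to the threshold
    time when the geometry is degenerate."""
    t, v = curve.times, curve.values
    rise = (t >= t_thr) & (t <= t_thr + 0.5)
    base = (t < min(t_thr - 0.05, baseline_end)) & (t >= t_thr - 6.0)
    if rise.sum() < 2 or base.sum() < 2:
        return t_thr
    br, ar = np.polyfit(t[rise], v[rise], 1)
    bb, ab = np.polyfit(t[base], v[base], 1)
    if abs(br - bb) < 1e-30:
        return t_thr
    t_star = (ab - ar) / (br - bb)
    if t_thr - 1.0 <= t_star <= t_thr + 0.5:
        return float(t_star)
    return t_thr


def extract_features(
    curve: ResponseCurve,
    t0: float,
    offsets: tuple[float, ...] = DEFAULT_OFFSETS,
    baseline: str = "sample",
) -> FeatureVector:
    """Baseline-subtracted signal values at ``t0 + offset_i``.

    Anchors use nearest-sample lookup.  ``baseline`` is the single nearest
    sample at ``t0`` by default, or the mean of the preceding second with
    ``baseline="mean1s"``.
    """
    half_step = 0.5 / curve.sampling_rate
    for i, off in enumerate(offsets):
        if t0 + off > curve.times[-1] + half_step:
            raise ValueError(
                f"curve too short for anchor S{i + 1} at t0+{off:g} s "
                f"(curve ends at {curve.times[-1]:g} s)"
            )
    if baseline == "sample":
        base = curve.value_at(t0)
    elif baseline == "mean1s":
        mask = (curve.times >= t0 - 1.0) & (curve.times <= t0)
        if not mask.any():
            raise ValueError("no samples in the second preceding t0")
        base = float(np.mean(curve.values[mask]))
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    vals = np.array([curve.value_at(t0 + off) - base for off in offsets])
    return FeatureVector(
        channel_label=curve.channel_label, t0_used=float(t0),
        offsets=tuple(offsets), values=vals,
    )


def assemble_feature_matrix(
    measurements: list[Measurement],
    onset_method: str = "derivative",
    offsets: tuple[float, ...] = DEFAULT_OFFSETS,
    shared_t0: bool = True,
    baseline: str = "sample",
) -> FeatureMatrix:
    """One row per measurement, 5 features per channel, channel-major columns.

    With ``shared_t0`` (default) a single onset per measurement is used: the
    nominal valve time when the measurement carries one, otherwise the median
    of the per-channel detections.
    """
    if not measurements:
        empty = pd.DataFrame(columns=METADATA_COLUMNS)
        return FeatureMatrix(frame=empty, channels=(), offsets=tuple(offsets))

    channels = tuple(measurements[0].channels)
    rows = []
    for meas in measurements:
        if tuple(meas.channels) != channels:
            raise ValueError(
                f"measurement {meas.measurement_id!r} channels {meas.channels} "
                f"differ from {list(channels)}"
            )
        onsets: dict[str, float] = {}
        if shared_t0:
            if onset_method == "nominal":
                t0 = detect_onset(
                    meas.curves[channels[0]], "nominal", meas.nominal_valve_time
                )
            else:
                per_channel = [
                    detect_onset(
                        meas.curves[ch], onset_method, meas.nominal_valve_time
                    )
                    for ch in channels
                ]
                t0 = float(np.median(per_channel))
            onsets = {ch: t0 for ch in channels}
        else:
            onsets = {
                ch: detect_onset(meas.curves[ch], onset_method, meas.nominal_valve_time)
                for ch in channels
            }
        row: dict = {
            "sample_id": meas.sample_id,
            "group": meas.group,
            "replicate": meas.replicate,
        }
        for ch in channels:
            fv = extract_features(meas.curves[ch], onsets[ch], offsets, baseline)
            for i, val in enumerate(fv.values):
                row[f"{ch}_S{i + 1}"] = val
        rows.append(row)
    frame = pd.DataFrame(rows)
    return FeatureMatrix(frame=frame, channels=channels, offsets=tuple(offsets))


@dataclass(frozen=True)
class DeviationReport:
    table: pd.DataFrame  # sample_id x feature column, fractional deviations
    max_deviation: float
    flagged: list[tuple[str, str]]  # (sample_id, column) cells with zero S3


def replicate_relative_deviation(
    matrix: FeatureMatrix, intensity_anchor: int = 3
) -> DeviationReport:
    """Replicate spread of every feature relative to the signal intensity.

    For each sample and feature column: (max - min across replicates) divided
    by |mean S_<intensity_anchor>| of that channel within the sample, as a
    fraction.  Zero-intensity denominators are flagged and excluded from the
    summary maximum.
    """
    cols = matrix.feature_columns
    frame = matrix.frame
    counts = frame.groupby("sample_id").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"samples with fewer than 2 replicates: {bad}")

    flagged: list[tuple[str, str]] = []
    records = {}
    for sample_id, grp in frame.groupby("sample_id", sort=True):
        rec = {}
        for ch in matrix.channels:
            denom = abs(float(grp[f"{ch}_S{intensity_anchor}"].mean()))
            for i in range(len(matrix.offsets)):
                col = f"{ch}_S{i + 1}"
                spread = float(grp[col].max() - grp[col].min())
                if denom == 0.0:
                    rec[col] = np.nan
                    flagged.append((str(sample_id), col))
                else:
                    rec[col] = spread / denom
        records[sample_id] = rec
    table = pd.DataFrame.from_dict(records, orient="index")[cols]
    finite = table.to_numpy(dtype=float)
    finite = finite[np.isfinite(finite)]
    max_dev = float(np.max(finite)) if finite.size else float("nan")
    return DeviationReport(table=table, max_deviation=max_dev, flagged=flagged)
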