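"""File formats: the response-curve CSV dialect, labels, configs, results.

Curve files are plain UTF-8 CSV with LF line endings and '.' decimals:

    # sampling_rate_hz=100.0
    # channels=PS,PMMA,Tenax
    # valve_time_s=30.0
    time_s,PS,PMMA,Tenax
    0.0,0.0,0.0,0.0
    ...

Unknown ``# key=value`` headers are preserved as metadata.  Floats are
written with ``repr`` so a write/read round trip is exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import Measurement, ResponseCurve
from .exceptions import CurveFormatError
from .features import FeatureMatrix, METADATA_COLUMNS

__all__ = [
    "write_measurement_csv",
    "read_measurement_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_feature_matrix_csv",
    "read_feature_matrix_csv",
    "write_json",
    "read_json",
]


def write_measurement_csv(path, measurement: Measurement) -> None:
    path = Path(path)
    channels = measurement.channels
    if not channels:
        raise ValueError("measurement has no channels")
    first = measurement.curves[channels[0]]
    for ch in channels[1:]:
        c = measurement.curves[ch]
        if c.times.size != first.times.size or abs(c.times[0] - first.times[0]) > 1e-9:
            raise ValueError("all channels must share the same time base")
    lines = [
        f"# sampling_rate_hz={first.sampling_rate!r}",
        f"# channels={','.join(channels)}",
    ]
    if measurement.nominal_valve_time is not None:
        lines.append(f"# valve_time_s={measurement.nominal_valve_time!r}")
    lines.append("time_s," + ",".join(channels))
    cols = [first.times] + [measurement.curves[ch].values for ch in channels]
    for row in zip(*cols):
        lines.append(",".join(repr(float(x)) for x in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_measurement_csv(
    path,
    measurement_id: str = "",
    sample_id: str = "",
    group: str = "",
    replicate: int = 1,
) -> Measurement:
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise CurveFormatError(f"malformed header {line!r}", lineno)
            key, val = body.split("=", 1)
            meta[key.strip()] = val.strip()
            continue
        if header is None:
            header = [h.strip() for h in line.split(",")]
            if not header or header[0] != "time_s":
                raise CurveFormatError(
                    f"first data column must be 'time_s', got {header}", lineno
                )
            continue
        parts = line.split(",")
        if len(parts) != len(header):
            raise CurveFormatError(
                f"expected {len(header)} fields, got {len(parts)}", lineno
            )
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise CurveFormatError(f"non-numeric value: {exc}", lineno) from None
        if not all(np.isfinite(vals)):
            raise CurveFormatError("non-finite value in data row", lineno)
        rows.append(vals)
    if header is None or not rows:
        raise CurveFormatError(f"{path} contains no data rows")
    if "sampling_rate_hz" not in meta:
        raise CurveFormatError("missing '# sampling_rate_hz=' header")
    rate = float(meta["sampling_rate_hz"])
    data = np.asarray(rows, dtype=float)
    channels = header[1:]
    if "channels" in meta:
        declared = meta["channels"].split(",")
        if declared != channels:
            raise CurveFormatError(
                f"declared channels {declared} do not match columns {channels}"
            )
    curves = {
        ch: ResponseCurve(
            times=data[:, 0], values=data[:, j + 1], sampling_rate=rate,
            channel_label=ch,
        )
        for j, ch in enumerate(channels)
    }
    valve = float(meta["valve_time_s"]) if "valve_time_s" in meta else None
    return Measurement(
        measurement_id=measurement_id or path.stem,
        sample_id=sample_id,
        group=group,
        replicate=replicate,
        curves=curves,
        nominal_valve_time=valve,
    )


def write_labels_csv(path, measurements: list[Measurement], paths: list[str]) -> None:
    frame = pd.DataFrame(
        {
            "measurement_id": [m.measurement_id for m in measurements],
            "sample_id": [m.sample_id for m in measurements],
            "group": [m.group for m in measurements],
            "replicate": [m.replicate for m in measurements],
            "path": paths,
        }
    )
    frame.to_csv(path, index=False, lineterminator="\n")


def read_labels_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"measurement_id", "sample_id", "group", "replicate", "path"}
    missing = required - set(frame.columns)
    if missing:
        raise CurveFormatError(f"labels file missing columns {sorted(missing)}")
    return frame


def write_feature_matrix_csv(path, matrix: FeatureMatrix) -> None:
    matrix.frame.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_feature_matrix_csv(path) -> FeatureMatrix:
    frame = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise CurveFormatError(f"feature matrix missing columns {missing}")
    feature_cols = [c for c in frame.columns if c not in METADATA_COLUMNS]
    channels: list[str] = []
    n_anchor = 0
    for col in feature_cols:
        ch, _, s = col.rpartition("_S")
        if not ch or not s.isdigit():
            raise CurveFormatError(f"unrecognized feature column {col!r}")
        if ch not in channels:
            channels.append(ch)
        n_anchor = max(n_anchor, int(s))
    offsets = tuple(float(i) for i in range(1, n_anchor + 1))  # placeholder anchors
    return FeatureMatrix(frame=frame, channels=tuple(channels), offsets=offsets)


def write_json(path, obj) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
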