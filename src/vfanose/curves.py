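"""Sampled sensor response containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ResponseCurve", "Measurement"]


@dataclass(frozen=True)
class ResponseCurve:
    """One channel of a uniformly sampled sensor signal.

    ``times`` must be strictly increasing and uniform to within 1e-9 s, and
    consistent with ``sampling_rate``; ``values`` must be finite.
    """

    times: np.ndarray
    values: np.ndarray
    sampling_rate: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size < 2:
            raise ValueError("a curve needs at least two samples")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
            raise ValueError("times and values must be finite")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > 1e-9:
            raise ValueError("times must be uniform within 1e-9 s")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if abs(1.0 / steps[0] - self.sampling_rate) > 1e-6 * self.sampling_rate:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz inconsistent with "
                f"time step {steps[0]} s"
            )

    @classmethod
    def from_values(
        cls,
        values,
        sampling_rate: float,
        t_start: float = 0.0,
        channel_label: str = "",
    ) -> "ResponseCurve":
        values = np.asarray(values, dtype=float)
        times = t_start + np.arange(values.size) / sampling_rate
        return cls(times, values, sampling_rate, channel_label)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def nearest_index(self, t: float) -> int:
        """Index of the sample closest to time ``t``."""
        i = int(round((t - self.times[0]) * self.sampling_rate))
        return min(max(i, 0), self.times.size - 1)

    def value_at(self, t: float) -> float:
        """Value of the nearest sample to time ``t``."""
        return float(self.values[self.nearest_index(t)])


@dataclass(frozen=True)
class Measurement:
    """A multi-channel measurement with its study metadata."""

    measurement_id: str
    sample_id: str
    group: str
    replicate: int
    curves: dict[str, ResponseCurve] = field(default_factory=dict)
    nominal_valve_time: float | None = None

    @property
    def channels(self) -> list[str]:
        return list(self.curves.keys())
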