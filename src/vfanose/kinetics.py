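"""Closed-form response models for cyclic vapor injection/purge sensing.

The sensor signal is modeled as the stress output of a receptor film that
absorbs/desorbs an analyte with first-order kinetics (diffusion time constant
``tau_s``) while relaxing viscoelastically (relaxation time constant
``tau_r``).  A single valve switch produces a two-exponential basis response;
an arbitrary alternating injection/purge schedule is the signed superposition
of that basis at every switch time.  For equal-duration cycles the
superposition collapses to a closed form evaluated here entirely with
time-shifted exponents (all exponents <= 0 inside a branch), which is the
numerically stable and switch-continuous evaluation.

An independent numerical oracle (:func:`ode_convolution_oracle`) integrates
the underlying sorption ODE and the viscoelastic hereditary integral; it is
used by the tests to validate the closed forms and the mapping between the
mixing weight ``alpha`` and the modulus ratio ``E_U/E_R``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .exceptions import ScheduleError

__all__ = [
    "SorptionParams",
    "SwitchingSchedule",
    "ConcentrationModelParams",
    "ViscoelasticParams",
    "single_switch_response",
    "multi_cycle_response",
    "superposition_response",
    "concentration_profile",
    "symmetry_index",
    "cycle_peaks",
    "ode_convolution_oracle",
    "alpha_from_moduli",
    "moduli_ratio_from_alpha",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SorptionParams:
    """Kinetic/viscoelastic parameter set of the two-exponential response.

    Parameters
    ----------
    sigma_sat : float
        Saturation amplitude of the signal (sensor output units), >= 0.
    alpha : float
        Dimensionless mixing weight between the sorption exponential and the
        relaxation exponential.  May exceed 1 (viscoelastic overshoot).
    tau_s : float
        Sorption/desorption (diffusion) time constant in seconds, > 0.
    tau_r : float
        Stress-relaxation time constant in seconds, > 0.
    t0 : float
        Response onset time in seconds.
    sign : int
        Response polarity, +1 (positive-going rise, default) or -1.
    """

    sigma_sat: float
    alpha: float
    tau_s: float
    tau_r: float
    t0: float = 0.0
    sign: int = 1

    def __post_init__(self) -> None:
        vals = [self.sigma_sat, self.alpha, self.tau_s, self.tau_r, self.t0]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"SorptionParams must be finite, got {vals}")
        if self.tau_s <= 0:
            raise ValueError(f"tau_s must be > 0, got {self.tau_s}")
        if self.tau_r <= 0:
            raise ValueError(f"tau_r must be > 0, got {self.tau_r}")
        if self.sigma_sat < 0:
            raise ValueError(f"sigma_sat must be >= 0, got {self.sigma_sat}")
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")

    def to_dict(self) -> dict:
        return {
            "sigma_sat": self.sigma_sat,
            "alpha": self.alpha,
            "tau_s": self.tau_s,
            "tau_r": self.tau_r,
            "t0": self.t0,
            "sign": self.sign,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SorptionParams":
        return cls(**d)


_INJECT = "inject"
_PURGE = "purge"


@dataclass(frozen=True)
class SwitchingSchedule:
    """Valve switching schedule: equal-period cycles or an explicit list.

    Either give ``half_period_T`` and ``n_cycles`` (each injection and each
    purge lasts ``half_period_T`` seconds, first injection at ``t0``), or an
    explicit ``switch_times`` list of ``(time, state)`` pairs with strictly
    increasing times and strictly alternating states starting with
    ``"inject"`` (e.g. the 120 s inject / 480 s purge protocol).
    """

    t0: float = 0.0
    half_period_T: float | None = None
    n_cycles: int | None = None
    switch_times: tuple[tuple[float, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.switch_times is not None:
            sw = tuple((float(t), str(s)) for t, s in self.switch_times)
            object.__setattr__(self, "switch_times", sw)
            if len(sw) == 0:
                raise ScheduleError("switch_times must not be empty")
            times = [t for t, _ in sw]
            if not np.all(np.isfinite(times)):
                raise ScheduleError("switch times must be finite")
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ScheduleError("switch times must be strictly increasing")
            expected = [_INJECT if i % 2 == 0 else _PURGE for i in range(len(sw))]
            got = [s for _, s in sw]
            if got != expected:
                raise ScheduleError(
                    "states must strictly alternate starting with 'inject', "
                    f"got {got}"
                )
            object.__setattr__(self, "t0", times[0])
        else:
            if self.half_period_T is None or self.n_cycles is None:
                raise ScheduleError(
                    "give either (half_period_T, n_cycles) or switch_times"
                )
            if not (np.isfinite(self.t0) and np.isfinite(self.half_period_T)):
                raise ScheduleError("t0 and half_period_T must be finite")
            if self.half_period_T <= 0:
                raise ScheduleError(
                    f"half_period_T must be > 0, got {self.half_period_T}"
                )
            if int(self.n_cycles) != self.n_cycles or self.n_cycles < 1:
                raise ScheduleError(f"n_cycles must be >= 1, got {self.n_cycles}")

    @property
    def is_equal_period(self) -> bool:
        return self.switch_times is None

    def events(self) -> list[tuple[float, str]]:
        """All switch events as ``(time, state)`` pairs."""
        if self.switch_times is not None:
            return list(self.switch_times)
        T, n = self.half_period_T, int(self.n_cycles)
        return [
            (self.t0 + i * T, _INJECT if i % 2 == 0 else _PURGE)
            for i in range(2 * n)
        ]

    def end_time(self) -> float:
        """Time of the last switch (start of the final purge for equal-T)."""
        return self.events()[-1][0]

    def first_injection_duration(self) -> float:
        ev = self.events()
        if len(ev) >= 2:
            return ev[1][0] - ev[0][0]
        if self.half_period_T is not None:
            return self.half_period_T
        raise ScheduleError("single-switch schedule has no injection duration")

    def shifted(self, new_t0: float) -> "SwitchingSchedule":
        """Return a copy with every switch time translated so onset is new_t0."""
        delta = new_t0 - self.t0
        if self.switch_times is not None:
            return SwitchingSchedule(
                switch_times=tuple((t + delta, s) for t, s in self.switch_times)
            )
        return replace(self, t0=new_t0)


@dataclass(frozen=True)
class ConcentrationModelParams:
    """Parameters of the single-cycle receptor-layer concentration model."""

    kp: float
    cg: float
    tau_s: float
    t0: float
    t3: float

    def __post_init__(self) -> None:
        if self.t3 <= self.t0:
            raise ValueError(f"t3 must exceed t0, got t0={self.t0}, t3={self.t3}")
        if self.kp < 0 or self.cg < 0:
            raise ValueError("kp and cg must be >= 0")
        if self.tau_s <= 0:
            raise ValueError(f"tau_s must be > 0, got {self.tau_s}")

    @property
    def duration(self) -> float:
        return self.t3 - self.t0


@dataclass(frozen=True)
class ViscoelasticParams:
    """Standard-linear-solid relaxation parameters used by the ODE oracle."""

    e_u: float
    e_r: float
    tau_r: float
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not (self.e_u >= self.e_r > 0):
            raise ValueError(f"need e_u >= e_r > 0, got e_u={self.e_u}, e_r={self.e_r}")
        if self.tau_r <= 0:
            raise ValueError(f"tau_r must be > 0, got {self.tau_r}")
        if self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")


# ---------------------------------------------------------------------------
# closed-form responses
# ---------------------------------------------------------------------------


def _basis(params: SorptionParams, x: np.ndarray) -> np.ndarray:
    """Two-exponential step response at nonnegative lag x (sign applied)."""
    return (
        params.sign
        * params.sigma_sat
        * (
            1.0
            - params.alpha * np.exp(-x / params.tau_s)
            - (1.0 - params.alpha) * np.exp(-x / params.tau_r)
        )
    )


def single_switch_response(params: SorptionParams, dt):
    """Response ``dt`` seconds after a single inject switch.

    ``sign * sigma_sat * (1 - alpha*exp(-dt/tau_s) - (1-alpha)*exp(-dt/tau_r))``;
    zero at ``dt = 0`` and tending to ``sign * sigma_sat`` as ``dt -> inf``.
    """
    dt_arr = np.asarray(dt, dtype=float)
    if np.any(dt_arr < 0):
        raise ValueError("dt must be >= 0")
    out = _basis(params, dt_arr)
    return float(out) if np.isscalar(dt) or dt_arr.ndim == 0 else out


def multi_cycle_response(params: SorptionParams, schedule: SwitchingSchedule, t):
    """Equal-period multi-cycle closed form.

    Evaluates, per time point, the partial superposition sum
    ``C*sigma_sat - sum_{i=0}^{m} (-1)^i sigma_sat [alpha e^{-(t-t0-iT)/tau_s}
    + (1-alpha) e^{-(t-t0-iT)/tau_r}]`` where ``m`` is the index of the last
    switch at or before ``t`` and ``C`` is 1 inside injection windows and 0
    inside purge windows.  All exponents are <= 0, so the evaluation is stable
    for any ``T/tau`` ratio, and the value is continuous at every switch.
    Times before ``t0`` give 0; times past the last cycle continue the final
    purge decay.
    """
    if not schedule.is_equal_period:
        raise ScheduleError(
            "multi_cycle_response requires an equal-period schedule; "
            "use superposition_response for explicit switch lists"
        )
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    T = float(schedule.half_period_T)
    n_switches = 2 * int(schedule.n_cycles)
    dt = t_arr - schedule.t0
    m = np.full(t_arr.shape, -1, dtype=int)
    pos = dt >= 0
    m[pos] = np.minimum(np.floor(dt[pos] / T).astype(int), n_switches - 1)

    # constant term: sigma_sat inside injection windows (odd number of
    # switches applied); note (-1) % 2 == 1 so pre-onset points get 0.
    out = np.where(m % 2 == 0, params.sigma_sat, 0.0)
    for i in range(n_switches):
        mask = m >= i
        if not mask.any():
            break
        x = dt[mask] - i * T
        term = params.sigma_sat * (
            params.alpha * np.exp(-x / params.tau_s)
            + (1.0 - params.alpha) * np.exp(-x / params.tau_r)
        )
        out[mask] -= (-1) ** i * term
    out *= params.sign
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


def superposition_response(params: SorptionParams, schedule: SwitchingSchedule, t):
    """General alternating-schedule response as a signed superposition.

    ``sum_k s_k f(t - tau_k)`` over all switch times ``tau_k <= t`` with
    ``s_k = +1`` for inject and ``-1`` for purge switches and ``f`` the
    single-switch basis.  Identical to :func:`multi_cycle_response` on
    equal-period schedules.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    out = np.zeros(t_arr.shape)
    for tk, state in schedule.events():
        s = 1.0 if state == _INJECT else -1.0
        mask = t_arr >= tk
        if mask.any():
            out[mask] += s * _basis(params, t_arr[mask] - tk)
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


def concentration_profile(p: ConcentrationModelParams, t):
    """Single-cycle receptor-layer concentration.

    0 before ``t0``; first-order rise toward ``kp*cg`` during the injection
    ``[t0, t3)``; exponential decay from the reached level afterwards.
    Continuous at ``t3``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros(t_arr.shape)
    sat = p.kp * p.cg
    rise = (t_arr >= p.t0) & (t_arr < p.t3)
    out[rise] = sat * (1.0 - np.exp(-(t_arr[rise] - p.t0) / p.tau_s))
    decay = t_arr >= p.t3
    top = sat * (1.0 - np.exp(-p.duration / p.tau_s))
    out[decay] = top * np.exp(-(t_arr[decay] - p.t3) / p.tau_s)
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


def symmetry_index(params: SorptionParams, schedule: SwitchingSchedule) -> float:
    """Carry-over score ``exp(-T/tau_s)`` in [0, 1].

    Near 0: sorption equilibrates within one injection, so rise and decay
    mirror each other.  Near 1: sorbed analyte survives the purge and cycles
    accumulate (asymmetric rise/decay, growing per-cycle peaks).
    """
    T = schedule.first_injection_duration()
    return float(math.exp(-T / params.tau_s))


def cycle_peaks(
    params: SorptionParams,
    schedule: SwitchingSchedule,
    grid_points: int = 2001,
) -> np.ndarray:
    """Maximum (in the positive-rise orientation) over each injection window.

    Located on a dense grid and refined with bounded scalar minimization, so
    interior maxima from viscoelastic overshoot (alpha > 1) are also found.
    """
    if not schedule.is_equal_period:
        raise ScheduleError("cycle_peaks requires an equal-period schedule")
    if schedule.n_cycles < 2:
        raise ScheduleError("cycle_peaks needs n_cycles >= 2")
    T = float(schedule.half_period_T)

    def y(tt):
        return params.sign * multi_cycle_response(params, schedule, tt)

    peaks = []
    for k in range(int(schedule.n_cycles)):
        ts = schedule.t0 + 2 * k * T
        te = ts + T
        grid = np.linspace(ts, te, grid_points)
        vals = y(grid)
        j = int(np.argmax(vals))
        best = float(vals[j])
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, grid_points - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda tt: -y(float(tt)), bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10 * T},
            )
            best = max(best, float(-res.fun))
        peaks.append(best)
    return np.asarray(peaks)


# ---------------------------------------------------------------------------
# alpha <-> modulus-ratio mapping (re-derived; verified against the oracle)
# ---------------------------------------------------------------------------


def alpha_from_moduli(e_ratio: float, tau_s: float, tau_r: float) -> float:
    """Mixing weight implied by modulus ratio ``e_ratio = E_U/E_R``.

    ``alpha = 1 + (E_U/E_R - 1) * tau_r / (tau_r - tau_s)``; requires
    ``tau_r != tau_s`` (confluent case has no two-exponential form).
    """
    if abs(tau_r - tau_s) <= 1e-12 * max(tau_r, tau_s):
        raise ValueError("tau_r == tau_s: two-exponential mapping is degenerate")
    return 1.0 + (e_ratio - 1.0) * tau_r / (tau_r - tau_s)


def moduli_ratio_from_alpha(alpha: float, tau_s: float, tau_r: float) -> float:
    """Inverse of :func:`alpha_from_moduli`."""
    if abs(tau_r - tau_s) <= 1e-12 * max(tau_r, tau_s):
        raise ValueError("tau_r == tau_s: two-exponential mapping is degenerate")
    return 1.0 + (alpha - 1.0) * (tau_r - tau_s) / tau_r


# ---------------------------------------------------------------------------
# numerical oracle
# ---------------------------------------------------------------------------


def ode_convolution_oracle(
    kp_cg: float,
    tau_s: float,
    visco: ViscoelasticParams,
    schedule: SwitchingSchedule,
    dt: float,
    t_end: float | None = None,
):
    """Ground-truth response by direct numerical integration.

    Integrates the sorption ODE ``dC/dt = (kp_cg * u(t) - C)/tau_s`` (``u``
    the on/off valve state) together with the auxiliary hereditary state
    ``dQ/dt = gain * dC/dt - Q/tau_r`` so that the stress

    ``sigma(t) = e_r * gain * C(t) + (e_u - e_r) * Q(t)``

    equals the convolution of the relaxation modulus
    ``E(t) = e_r + (e_u - e_r) exp(-t/tau_r)`` with the strain rate.  Sampled
    on a uniform grid of step ``dt`` from the first switch to ``t_end``.

    This never touches the closed forms above; the tests use it to check
    the multi-cycle algebra and the sigma_sat/alpha mapping
    (``sigma_sat = gain * kp_cg * e_r``, ``alpha`` per
    :func:`alpha_from_moduli`).  ``tau_r == tau_s`` integrates fine (the
    confluent case is only degenerate for the two-exponential closed form).

    Returns a :class:`~vfanose.curves.ResponseCurve` labelled ``"oracle"``.
    """
    from .curves import ResponseCurve  # local import avoids a cycle

    if tau_s <= 0:
        raise ValueError(f"tau_s must be > 0, got {tau_s}")
    if kp_cg < 0:
        raise ValueError("kp_cg must be >= 0")
    if dt <= 0 or dt > tau_s / 50.0 or dt > visco.tau_r / 50.0:
        raise ValueError(
            f"step dt={dt} too coarse: need dt <= min(tau_s, tau_r)/50"
        )
    events = schedule.events()
    t_start = events[0][0]
    if t_end is None:
        t_end = events[-1][0] + 5.0 * max(tau_s, visco.tau_r)
    if t_end <= t_start:
        raise ValueError("t_end must exceed the first switch time")

    n = int(math.floor((t_end - t_start) / dt + 0.5)) + 1
    times = t_start + dt * np.arange(n)

    # segment boundaries: switch times plus the grid end
    bounds = [tk for tk, _ in events] + [times[-1] + dt]
    states = [1.0 if s == _INJECT else 0.0 for _, s in events]

    de = visco.e_u - visco.e_r
    scale = max(kp_cg * visco.gain, 1e-30)
    sol_c = np.zeros(n)
    sol_q = np.zeros(n)
    y = np.array([0.0, 0.0])  # (C, Q)
    for seg in range(len(states)):
        a, b = bounds[seg], bounds[seg + 1]
        if b <= a:
            continue
        u = states[seg]

        def rhs(_t, yy, u=u):
            c, q = yy
            cdot = (kp_cg * u - c) / tau_s
            return [cdot, visco.gain * cdot - q / visco.tau_r]

        mask = (times >= a - 1e-12 * dt) & (times < b - 1e-12 * dt)
        interior = times[mask]
        # evaluate at interior grid points and at b (segment handoff state)
        t_eval = np.append(interior, b)
        res = solve_ivp(
            rhs,
            (a, b),
            y,
            t_eval=t_eval,
            rtol=1e-11,
            atol=1e-13 * scale,
            method="LSODA",
        )
        if not res.success:
            raise RuntimeError(f"oracle integration failed: {res.message}")
        if interior.size:
            sol_c[mask] = res.y[0, :-1]
            sol_q[mask] = res.y[1, :-1]
        y = res.y[:, -1]

    sigma = visco.e_r * visco.gain * sol_c + de * sol_q
    return ResponseCurve(
        times=times,
        values=sigma,
        sampling_rate=1.0 / dt,
        channel_label="oracle",
    )
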