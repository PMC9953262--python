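import numpy as np
import pytest

from vfanose import (
    GeneratorConfig,
    ResponseCurve,
    SorptionParams,
    SwitchingSchedule,
    multi_cycle_response,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_cycle_schedule():
    """Four 10 s on/off cycles starting at t0 = 5 s (pure-vapor protocol)."""
    return SwitchingSchedule(t0=5.0, half_period_T=10.0, n_cycles=4)


@pytest.fixture
def reference_params():
    return SorptionParams(sigma_sat=1.0, alpha=1.3, tau_s=8.0, tau_r=60.0, t0=5.0)


@pytest.fixture
def reference_curve(reference_params, short_cycle_schedule):
    """Noiseless 20 Hz closed-form curve covering all four cycles plus tail."""
    t = np.arange(0.0, 130.0, 0.05)
    y = multi_cycle_response(reference_params, short_cycle_schedule, t)
    return ResponseCurve(t, y, 20.0, channel_label="PS")


@pytest.fixture
def fast_silage_config():
    """Silage protocol downsampled to 5 Hz to keep unit tests quick."""
    return GeneratorConfig(protocol="silage", seed=7, sampling_rate_hz=5.0)


def random_sorption_params(rng, alpha_range=(0.0, 1.0)) -> SorptionParams:
    return SorptionParams(
        sigma_sat=float(rng.uniform(0.1, 10.0)),
        alpha=float(rng.uniform(*alpha_range)),
        tau_s=float(rng.uniform(0.5, 50.0)),
        tau_r=float(rng.uniform(0.5, 500.0)),
        t0=float(rng.uniform(-5.0, 5.0)),
    )
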