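import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfanose import (
    ConcentrationModelParams,
    SorptionParams,
    SwitchingSchedule,
    ViscoelasticParams,
    concentration_profile,
    cycle_peaks,
    multi_cycle_response,
    ode_convolution_oracle,
    single_switch_response,
    superposition_response,
    symmetry_index,
)
from vfanose.exceptions import ScheduleError
from vfanose.kinetics import alpha_from_moduli, moduli_ratio_from_alpha

from conftest import random_sorption_params


# ---------------------------------------------------------------------------
# single_switch_response
# ---------------------------------------------------------------------------


class TestSingleSwitch:
    def test_zero_at_onset(self):
        p = SorptionParams(1.0, 1.0, 5.0, 37.0)
        assert single_switch_response(p, 0.0) == 0.0

    def test_asymptote(self):
        p = SorptionParams(2.0, 0.5, 5.0, 50.0)
        assert single_switch_response(p, 1e6) == pytest.approx(2.0, abs=1e-9)

    def test_closed_form_value(self):
        p = SorptionParams(1.0, 1.0, 5.0, 99.0)
        assert single_switch_response(p, 5.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_negative_dt_rejected(self):
        p = SorptionParams(1.0, 1.0, 5.0, 50.0)
        with pytest.raises(ValueError):
            single_switch_response(p, -0.1)

    @pytest.mark.parametrize("tau_s,tau_r", [(-1.0, 5.0), (5.0, 0.0)])
    def test_nonpositive_time_constants_rejected(self, tau_s, tau_r):
        with pytest.raises(ValueError):
            SorptionParams(1.0, 1.0, tau_s, tau_r)

    def test_sign_flag(self):
        p = SorptionParams(1.0, 1.0, 5.0, 50.0, sign=-1)
        assert single_switch_response(p, 1e6) == pytest.approx(-1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


class TestSwitchingSchedule:
    def test_equal_period_events(self):
        sch = SwitchingSchedule(t0=2.0, half_period_T=10.0, n_cycles=2)
        assert sch.events() == [
            (2.0, "inject"), (12.0, "purge"), (22.0, "inject"), (32.0, "purge"),
        ]

    def test_explicit_schedule_alternation_enforced(self):
        with pytest.raises(ScheduleError):
            SwitchingSchedule(switch_times=((0.0, "purge"), (10.0, "inject")))
        with pytest.raises(ScheduleError):
            SwitchingSchedule(switch_times=((0.0, "inject"), (10.0, "inject")))

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ScheduleError):
            SwitchingSchedule(switch_times=((5.0, "inject"), (5.0, "purge")))

    def test_invalid_cycle_count(self):
        with pytest.raises(ScheduleError):
            SwitchingSchedule(t0=0.0, half_period_T=10.0, n_cycles=0)

    def test_silage_schedule(self):
        sch = SwitchingSchedule(switch_times=((30.0, "inject"), (150.0, "purge")))
        assert sch.first_injection_duration() == 120.0
        assert sch.t0 == 30.0


# ---------------------------------------------------------------------------
# multi_cycle_response
# ---------------------------------------------------------------------------


class TestMultiCycle:
    def test_zero_at_t0(self, short_cycle_schedule):
        p = SorptionParams(3.0, 1.2, 4.0, 30.0, t0=5.0)
        assert multi_cycle_response(p, short_cycle_schedule, 5.0) == 0.0

    def test_zero_before_t0(self, short_cycle_schedule):
        p = SorptionParams(3.0, 1.2, 4.0, 30.0, t0=5.0)
        assert multi_cycle_response(p, short_cycle_schedule, 1.0) == 0.0

    def test_single_cycle_purge_collapse(self):
        # alpha = 1, n = 1: decay is sigma*(1-e^{-T/tau})*e^{-delta/tau}
        sigma, tau, T, delta = 2.0, 6.0, 10.0, 3.5
        p = SorptionParams(sigma, 1.0, tau, 70.0, t0=0.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=T, n_cycles=1)
        got = multi_cycle_response(p, sch, T + delta)
        want = sigma * (1 - math.exp(-T / tau)) * math.exp(-delta / tau)
        assert got == pytest.approx(want, rel=1e-12)

    def test_matches_concentration_model_scaling(self):
        # same collapse expressed through Eq-3-style concentration profile
        cp = ConcentrationModelParams(kp=2.0, cg=3.0, tau_s=6.0, t0=1.0, t3=11.0)
        p = SorptionParams(6.0, 1.0, 6.0, 80.0, t0=1.0)
        sch = SwitchingSchedule(t0=1.0, half_period_T=10.0, n_cycles=1)
        t = np.linspace(1.0, 40.0, 200)
        np.testing.assert_allclose(
            multi_cycle_response(p, sch, t),
            concentration_profile(cp, t),
            rtol=1e-10, atol=1e-12,
        )

    def test_no_overflow_for_large_T_over_tau(self):
        # the time-shifted evaluation must survive T >> tau_s
        p = SorptionParams(1.0, 1.0, 0.01, 100.0, t0=0.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=100.0, n_cycles=4)
        vals = multi_cycle_response(p, sch, np.linspace(0, 900, 500))
        assert np.all(np.isfinite(vals))
        assert np.max(np.abs(vals)) <= 1.0 + 1e-9

    def test_explicit_schedule_rejected(self):
        p = SorptionParams(1.0, 1.0, 5.0, 50.0)
        sch = SwitchingSchedule(switch_times=((0.0, "inject"), (120.0, "purge")))
        with pytest.raises(ScheduleError):
            multi_cycle_response(p, sch, 10.0)


# ---------------------------------------------------------------------------
# superposition_response
# ---------------------------------------------------------------------------


class TestSuperposition:
    def test_identity_with_closed_form(self, rng):
        for _ in range(10):
            p = random_sorption_params(rng, alpha_range=(0.0, 3.0))
            T = float(rng.uniform(1.0, 30.0))
            n = int(rng.integers(1, 5))
            sch = SwitchingSchedule(t0=p.t0, half_period_T=T, n_cycles=n)
            t = np.sort(rng.uniform(p.t0 - 5.0, p.t0 + 2 * n * T + 50.0, 100))
            a = multi_cycle_response(p, sch, t)
            b = superposition_response(p, sch, t)
            np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-12 * p.sigma_sat)

    def test_silage_schedule_zero_at_onset(self):
        p = SorptionParams(1.0, 1.2, 20.0, 60.0)
        sch = SwitchingSchedule(switch_times=((30.0, "inject"), (150.0, "purge")))
        assert superposition_response(p, sch, 30.0) == 0.0

    def test_single_switch_equals_basis(self):
        p = SorptionParams(1.5, 0.7, 5.0, 50.0)
        sch = SwitchingSchedule(switch_times=((2.0, "inject"),))
        for dt in (0.0, 1.0, 10.0, 100.0):
            assert superposition_response(p, sch, 2.0 + dt) == pytest.approx(
                single_switch_response(p, dt), rel=1e-12, abs=1e-15
            )


# ---------------------------------------------------------------------------
# concentration_profile / symmetry_index
# ---------------------------------------------------------------------------


class TestConcentrationProfile:
    def test_zero_at_onset(self):
        cp = ConcentrationModelParams(1.0, 2.0, 5.0, t0=3.0, t3=13.0)
        assert concentration_profile(cp, 3.0) == 0.0

    def test_end_of_long_injection(self):
        cp = ConcentrationModelParams(1.0, 1.0, 1.0, t0=0.0, t3=10.0)
        # left limit at t3 after 10 time constants
        val = concentration_profile(cp, 10.0 - 1e-9)
        assert val == pytest.approx(1 - math.exp(-10), rel=1e-6)

    def test_continuity_at_t3(self):
        cp = ConcentrationModelParams(2.0, 3.0, 4.0, t0=1.0, t3=9.0)
        left = concentration_profile(cp, 9.0 - 1e-10)
        right = concentration_profile(cp, 9.0)
        assert left == pytest.approx(right, abs=1e-8)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationModelParams(1.0, 1.0, 1.0, t0=5.0, t3=5.0)


class TestSymmetryIndex:
    def test_symmetric_regime(self):
        p = SorptionParams(1.0, 1.0, 1.0, 50.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=10.0, n_cycles=1)
        assert symmetry_index(p, sch) == pytest.approx(math.exp(-10), rel=1e-12)

    def test_asymmetric_regime(self):
        p = SorptionParams(1.0, 1.0, 10.0, 50.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=10.0, n_cycles=1)
        assert symmetry_index(p, sch) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_infinite_tau_limit(self):
        p = SorptionParams(1.0, 1.0, 1e12, 50.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=10.0, n_cycles=1)
        assert symmetry_index(p, sch) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# cycle_peaks
# ---------------------------------------------------------------------------


class TestCyclePeaks:
    def test_carry_over_increases_peaks(self):
        p = SorptionParams(1.0, 1.0, 50.0, 500.0, t0=0.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=10.0, n_cycles=4)
        peaks = cycle_peaks(p, sch)
        assert np.all(np.diff(peaks) > 0)

    def test_no_carry_over_equal_peaks(self):
        p = SorptionParams(1.0, 1.0, 0.3, 500.0, t0=0.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=10.0, n_cycles=4)
        peaks = cycle_peaks(p, sch)
        assert np.max(peaks) - np.min(peaks) < 1e-9

    def test_against_brute_force_maximization(self):
        # independent oracle: dense sampling of the superposition construction
        p = SorptionParams(1.0, 1.0, 10.0, 200.0, t0=0.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=10.0, n_cycles=4)
        peaks = cycle_peaks(p, sch)
        for k in range(4):
            grid = np.linspace(20.0 * k, 20.0 * k + 10.0, 200001)
            brute = np.max(superposition_response(p, sch, grid))
            assert peaks[k] == pytest.approx(brute, abs=1e-9)

    def test_needs_two_cycles(self):
        p = SorptionParams(1.0, 1.0, 5.0, 50.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=10.0, n_cycles=1)
        with pytest.raises(ScheduleError):
            cycle_peaks(p, sch)


# ---------------------------------------------------------------------------
# ODE / hereditary-integral oracle
# ---------------------------------------------------------------------------


class TestOdeOracle:
    def test_no_relaxation_matches_pure_sorption(self):
        visco = ViscoelasticParams(e_u=1.0, e_r=1.0, tau_r=40.0, gain=1.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=20.0, n_cycles=1)
        oc = ode_convolution_oracle(1.0, 5.0, visco, sch, dt=0.1, t_end=60.0)
        p = SorptionParams(1.0, 1.0, 5.0, 40.0, t0=0.0)
        want = superposition_response(p, sch, oc.times)
        assert np.max(np.abs(oc.values - want)) < 1e-7

    def test_zero_drive_zero_output(self):
        visco = ViscoelasticParams(e_u=3.0, e_r=1.0, tau_r=40.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=20.0, n_cycles=1)
        oc = ode_convolution_oracle(0.0, 5.0, visco, sch, dt=0.1, t_end=60.0)
        assert np.max(np.abs(oc.values)) == 0.0

    def test_single_injection_matches_mapped_closed_form(self):
        # derived mapping: sigma_sat = gain*Kp*Cg*E_R, alpha from the moduli
        tau_s, tau_r = 5.0, 60.0
        visco = ViscoelasticParams(e_u=3.0, e_r=1.0, tau_r=tau_r, gain=1.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=50.0, n_cycles=1)
        oc = ode_convolution_oracle(1.0, tau_s, visco, sch, dt=0.05, t_end=120.0)
        alpha = alpha_from_moduli(3.0, tau_s, tau_r)
        p = SorptionParams(1.0, alpha, tau_s, tau_r, t0=0.0)
        want = superposition_response(p, sch, oc.times)
        scale = np.max(np.abs(oc.values))
        assert np.max(np.abs(oc.values - want)) / scale < 1e-5

    def test_multi_cycle_oracle_equivalence_example(self):
        # (sigma=1, alpha=1.4, tau_s=6, tau_r=80, T=10, n=4) at 20 Hz
        tau_s, tau_r, alpha = 6.0, 80.0, 1.4
        r = moduli_ratio_from_alpha(alpha, tau_s, tau_r)
        visco = ViscoelasticParams(e_u=r, e_r=1.0, tau_r=tau_r, gain=1.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=10.0, n_cycles=4)
        oc = ode_convolution_oracle(1.0, tau_s, visco, sch, dt=0.05, t_end=120.0)
        p = SorptionParams(1.0, alpha, tau_s, tau_r, t0=0.0)
        want = multi_cycle_response(p, sch, oc.times)
        scale = np.max(np.abs(oc.values))
        assert np.max(np.abs(oc.values - want)) / scale < 1e-6

    def test_coarse_step_rejected(self):
        visco = ViscoelasticParams(e_u=2.0, e_r=1.0, tau_r=40.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=10.0, n_cycles=1)
        with pytest.raises(ValueError):
            ode_convolution_oracle(1.0, 5.0, visco, sch, dt=1.0)

    def test_confluent_time_constants_integrate(self):
        visco = ViscoelasticParams(e_u=2.0, e_r=1.0, tau_r=5.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=10.0, n_cycles=1)
        oc = ode_convolution_oracle(1.0, 5.0, visco, sch, dt=0.05, t_end=30.0)
        assert np.all(np.isfinite(oc.values))
        assert np.max(oc.values) > 0


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


class TestInvariants:
    def test_onset_zero_randomized(self, rng):
        for _ in range(50):
            p = random_sorption_params(rng, alpha_range=(0.0, 5.0))
            sch = SwitchingSchedule(
                t0=p.t0, half_period_T=float(rng.uniform(0.5, 50.0)),
                n_cycles=int(rng.integers(1, 6)),
            )
            assert multi_cycle_response(p, sch, p.t0) == 0.0

    def test_continuity_at_switches_randomized(self, rng):
        # left limit from the truncated-event superposition must equal the
        # next branch's value at the switch; this discriminates the adopted
        # (time-shifted, continuous) algebra from a sign-flipped variant.
        for _ in range(30):
            p = random_sorption_params(rng, alpha_range=(0.0, 5.0))
            T = float(rng.uniform(0.5, 50.0))
            n = int(rng.integers(1, 5))
            sch = SwitchingSchedule(t0=p.t0, half_period_T=T, n_cycles=n)
            events = sch.events()
            for i in range(1, len(events)):
                tk = events[i][0]
                left = superposition_response(
                    p, SwitchingSchedule(switch_times=tuple(events[:i])), tk
                )
                right = multi_cycle_response(p, sch, tk)
                assert abs(left - right) < 1e-9 * max(p.sigma_sat, 1e-12)

    @settings(max_examples=40, deadline=None)
    @given(
        alpha=st.floats(0.0, 1.0),
        tau_s=st.floats(0.5, 50.0),
        tau_r=st.floats(0.5, 200.0),
        T=st.floats(1.0, 40.0),
        n=st.integers(1, 4),
    )
    def test_bounded_for_alpha_in_unit_interval(self, alpha, tau_s, tau_r, T, n):
        p = SorptionParams(2.0, alpha, tau_s, tau_r, t0=0.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=T, n_cycles=n)
        t = np.linspace(-1.0, 2 * n * T + 100.0, 500)
        y = multi_cycle_response(p, sch, t)
        assert np.all(y >= -1e-9 * p.sigma_sat)
        assert np.all(y <= p.sigma_sat * (1 + 1e-9))

    def test_symmetric_limit_mirror(self):
        # e^{-T/tau_s} < 1e-6 and alpha = 1: decay mirrors the rise
        sigma, tau, T = 1.0, 1.0, 20.0
        p = SorptionParams(sigma, 1.0, tau, 300.0, t0=0.0)
        sch = SwitchingSchedule(t0=0.0, half_period_T=T, n_cycles=1)
        assert symmetry_index(p, sch) < 1e-6
        for delta in np.linspace(0.0, 10.0, 50):
            rise = multi_cycle_response(p, sch, delta)
            decay = multi_cycle_response(p, sch, T + delta)
            assert abs(rise + decay - sigma) < 1e-5 * sigma

    def test_moduli_alpha_mapping_round_trip(self, rng):
        for _ in range(20):
            tau_s = float(rng.uniform(0.5, 30.0))
            tau_r = tau_s * float(rng.uniform(1.5, 5.0))
            r = float(rng.uniform(1.0, 5.0))
            alpha = alpha_from_moduli(r, tau_s, tau_r)
            assert moduli_ratio_from_alpha(alpha, tau_s, tau_r) == pytest.approx(r, rel=1e-12)
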