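"""Dopamine terminal dynamics: release, reuptake, autoreceptors, receptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import bisect

from bglearn import (DAParams, DAState, RPEEvent, da_ratio,
                     phasic_release_rate, phasic_transient,
                     punishment_decay_time, receptor_occupancy, steady_state,
                     step, tonic_release_rate)


class TestReleaseRates:
    def test_tonic_rate_matches_direct_arithmetic(self, control_params):
        p = control_params
        expected = (p.rho * p.Pr_tonic * p.n0 / (p.alpha_vf * p.NA)
                    * p.nu_tonic * 1e6)
        assert tonic_release_rate(p) == pytest.approx(expected)
        assert tonic_release_rate(p) == pytest.approx(0.1423, rel=1e-3)

    def test_tonic_rate_zero_firing_and_linearity(self, control_params):
        assert tonic_release_rate(control_params.with_(nu_tonic=0.0)) == 0.0
        doubled = control_params.with_(rho=2 * control_params.rho)
        assert tonic_release_rate(doubled) == pytest.approx(
            2 * tonic_release_rate(control_params))

    def test_phasic_rate_at_reference_occupancy_is_burst_scaled_tonic(
            self, control_params):
        # at AR = AR_norm the occupancy scalings cancel and the burst rate
        # is the tonic rate scaled by the firing-rate ratio (40/4 = 10)
        p = control_params
        rate = phasic_release_rate(p, AR=p.AR_norm, rpe=1.0)
        assert rate == pytest.approx(10 * tonic_release_rate(p), rel=1e-12)

    def test_phasic_rate_zero_rpe_and_inverse_square_occupancy(
            self, control_params):
        p = control_params
        assert phasic_release_rate(p, AR=0.3, rpe=0.0) == 0.0
        assert phasic_release_rate(p, AR=0.15, rpe=1.0) == pytest.approx(
            4 * phasic_release_rate(p, AR=0.3, rpe=1.0))

    def test_phasic_rate_rejects_zero_occupancy(self, control_params):
        with pytest.raises(ValueError):
            phasic_release_rate(control_params, AR=0.0, rpe=1.0)


class TestSteadyState:
    def test_control_tonic_concentration_and_occupancy(self, control_params):
        C, AR = steady_state(control_params)
        assert C == pytest.approx(0.02, rel=0.02)
        assert AR == pytest.approx(0.334, rel=0.01)
        # closed form of the occupancy equilibrium
        p = control_params
        assert AR == pytest.approx(p.kon * C / (p.kon * C + p.koff), rel=1e-9)

    def test_imbalance_tonic_concentration_bisection_oracle(
            self, imbalance_params):
        p = imbalance_params
        it = tonic_release_rate(p)
        C_oracle = bisect(
            lambda C: it - p.Vmax * C / (p.km + C) - p.krem * C, 1e-12, 1.0,
            xtol=1e-14)
        C, _ = steady_state(p)
        assert C == pytest.approx(C_oracle, rel=1e-8)
        assert C == pytest.approx(0.0128, rel=0.01)

    def test_steady_state_agrees_with_long_integration(self, control_params):
        C0, AR0 = steady_state(control_params)
        s = DAState(C_DA=0.5 * C0, AR=0.5 * AR0)
        for _ in range(20000):  # 20 s
            s = step(s, control_params, dt=1e-3)
        assert s.C_DA == pytest.approx(C0, rel=1e-4)
        assert s.AR == pytest.approx(AR0, rel=1e-4)

    def test_tonic_level_decreases_with_reuptake_rate(self, control_params):
        cs = [steady_state(control_params.with_(Vmax=v))[0]
              for v in (0.8, 1.2, 1.8, 2.4)]
        assert all(a > b for a, b in zip(cs, cs[1:]))


class TestStep:
    def test_equilibrium_is_fixed_point(self, control_params):
        C0, AR0 = steady_state(control_params)
        s = step(DAState(C_DA=C0, AR=AR0), control_params, dt=1e-3)
        assert s.C_DA == pytest.approx(C0, rel=1e-6)
        assert s.AR == pytest.approx(AR0, rel=1e-6)

    def test_punishment_window_clamps_concentration_to_zero(
            self, control_params):
        C0, AR0 = steady_state(control_params)
        ev = RPEEvent(kind="punishment", onset=0.0)
        s = DAState(C_DA=C0, AR=AR0, t=0.11)  # inside [0.1, 0.15]
        out = step(s, control_params, events=[ev], dt=1e-3)
        assert out.C_DA == 0.0
        # AR keeps unbinding while the concentration is clamped
        assert out.AR < AR0

    def test_linear_removal_equilibrium_without_reuptake(self):
        p = DAParams(Vmax=0.0, krem=0.04)
        C_expected = tonic_release_rate(p) / p.krem
        s = DAState(C_DA=C_expected, AR=0.5)
        for _ in range(5000):
            s = step(s, p, dt=1e-3)
        assert s.C_DA == pytest.approx(C_expected, rel=1e-6)

    def test_step_rejects_bad_dt(self, control_params):
        s = DAState(C_DA=0.02, AR=0.3)
        with pytest.raises(ValueError):
            step(s, control_params, dt=-1e-3)
        with pytest.raises(ValueError):
            step(s, control_params, dt=5e-3)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(c=st.floats(0.0, 0.5), ar=st.floats(0.0, 1.0),
           rpe=st.floats(0.0, 2.0))
    def test_trajectories_stay_nonnegative_and_bounded(self, c, ar, rpe):
        p = DAParams.imbalance()
        ev = RPEEvent(kind="reward", magnitude=rpe, onset=0.0)
        s = DAState(C_DA=c, AR=max(ar, 1e-6))
        for _ in range(300):
            s = step(s, p, events=[ev], dt=1e-3)
            assert s.C_DA >= 0.0
            assert 0.0 <= s.AR <= 1.0


class TestPhasicTransient:
    def test_zero_rpe_gives_flat_trace(self, control_params):
        trace, peak = phasic_transient(control_params, rpe=0.0)
        C0, _ = steady_state(control_params)
        assert peak == pytest.approx(C0, rel=1e-6)
        assert np.allclose(trace[:, 1], C0, rtol=1e-5)

    def test_da_ratio_control_and_imbalance(self, control_params,
                                            imbalance_params):
        assert da_ratio(control_params) == pytest.approx(3.0, rel=0.15)
        assert da_ratio(imbalance_params) == pytest.approx(8.3, rel=0.15)

    def test_da_ratio_increases_with_reuptake(self, control_params):
        ratios = [da_ratio(control_params.with_(Vmax=v))
                  for v in (1.2, 1.5, 1.8)]
        assert ratios[0] < ratios[1] < ratios[2]


class TestReceptorOccupancy:
    def test_zero_and_half_saturation(self, control_params):
        occ0 = receptor_occupancy(0.0, control_params)
        assert occ0.D1 == 0.0 and occ0.D2 == 0.0
        occ = receptor_occupancy(control_params.kD_D1, control_params)
        assert occ.D1 == pytest.approx(control_params.Bmax_D1 / 2)

    def test_tonic_occupancies_match_direct_arithmetic(self, control_params):
        occ = receptor_occupancy(0.02, control_params)
        assert occ.D1 == pytest.approx(1.6 * 0.02 / 1.02, rel=1e-9)
        assert occ.D2 == pytest.approx(0.08 * 0.02 / 0.03, rel=1e-9)
        assert occ.D1 == pytest.approx(0.0314, abs=5e-4)
        assert occ.D2 == pytest.approx(0.0533, abs=5e-4)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    def test_occupancy_monotone_and_bounded(self, c1, c2):
        p = DAParams.control()
        lo, hi = sorted((c1, c2))
        a, b = receptor_occupancy(lo, p), receptor_occupancy(hi, p)
        assert a.D1 <= b.D1 <= p.Bmax_D1
        assert a.D2 <= b.D2 <= p.Bmax_D2


class TestPunishmentDecay:
    def test_decay_to_one_percent_takes_about_half_a_second(
            self, control_params):
        t = punishment_decay_time(control_params, threshold_frac=0.01)
        assert t == pytest.approx(0.5, rel=0.30)

    def test_decay_time_vanishes_as_threshold_approaches_one(
            self, control_params):
        assert punishment_decay_time(control_params, 0.999) < 0.005

    def test_small_concentration_limit_is_exponential(self, control_params):
        # starting far below km the dynamics are nearly linear with rate
        # Vmax/km + krem; compare against the closed-form half time
        p = control_params.with_(rho=control_params.rho * 1e-3)
        rate = p.Vmax / p.km + p.krem
        t_half = punishment_decay_time(p, threshold_frac=0.5)
        assert t_half == pytest.approx(np.log(2) / rate, rel=0.02)

    def test_invalid_threshold_rejected(self, control_params):
        with pytest.raises(ValueError):
            punishment_decay_time(control_params, 1.5)
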