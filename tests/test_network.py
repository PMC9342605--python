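"""Action-selection network: boundedness, symmetry, WTA, trial semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bglearn import (NetworkParams, NetworkState, PlasticWeights,
                     canonical_stimuli, receptor_occupancy, resting_state,
                     run_trial, steady_state, step_network)


def _tonic_occ(da):
    C0, _ = steady_state(da)
    return receptor_occupancy(C0, da)


class TestStepNetwork:
    def test_permutation_symmetry_with_equal_input(self, control_params,
                                                   net_params, naive_weights):
        occ = _tonic_occ(control_params)
        S = np.full(4, 0.5)
        state = NetworkState()
        for _ in range(300):
            state = step_network(state, S, naive_weights, occ.D1, occ.D2,
                                 np.zeros(4), net_params)
        for region in ("cortex", "go", "nogo", "gpe", "gpi", "thalamus"):
            y = state.output(region)
            assert np.ptp(y) < 1e-12, region

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_outputs_bounded_for_random_inputs_and_weights(self, seed):
        rng = np.random.default_rng(seed)
        W = PlasticWeights(wGS=rng.random((4, 4)), wNS=rng.random((4, 4)),
                           wGC=np.diag(rng.random(4)),
                           wNC=np.diag(rng.random(4)))
        npar = NetworkParams()
        state = NetworkState(u=rng.normal(0, 2, 26))
        S = rng.random(4)
        for _ in range(50):
            noise = rng.uniform(0, 0.2, 4)
            state = step_network(state, S, W, 0.1, 0.05, noise, npar)
            assert np.all(state.y >= 0.0) and np.all(state.y <= 1.0)

    def test_relaxes_to_rest_without_input(self, control_params, net_params,
                                           naive_weights):
        rest = resting_state(net_params, naive_weights, control_params)
        # one more settling second does not move the state
        occ = _tonic_occ(control_params)
        state = rest.copy()
        for _ in range(1000):
            state = step_network(state, np.zeros(4), naive_weights, occ.D1,
                                 occ.D2, np.zeros(4), net_params)
        assert np.allclose(state.y, rest.y, atol=1e-6)
        # cortex rests far below the response criterion
        assert state.output("cortex").max() < 0.5

    def test_dopamine_gain_direction_on_striatum(self, control_params,
                                                 net_params, naive_weights):
        # more D1 never decreases Go drive; more D2 never increases NoGo
        S = canonical_stimuli()[0]
        state0 = NetworkState(u=np.full(26, 0.3))

        def after(d1, d2):
            s = state0.copy()
            for _ in range(100):
                s = step_network(s, S, naive_weights, d1, d2, np.zeros(4),
                                 net_params)
            return s

        lo, hi = after(0.01, 0.05), after(0.10, 0.05)
        assert np.all(hi.output("go") >= lo.output("go") - 1e-12)
        lo2, hi2 = after(0.03, 0.01), after(0.03, 0.07)
        assert np.all(hi2.output("nogo") <= lo2.output("nogo") + 1e-12)


class TestRunTrial:
    def test_no_stimulus_no_noise_gives_no_response(self, control_params,
                                                    naive_weights):
        npar = NetworkParams(noise_high=0.0)
        rng = np.random.default_rng(0)
        out = run_trial(np.zeros(4), naive_weights, control_params, npar,
                        rng, duration=0.8, learning=False)
        assert out.chosen is None
        assert np.isnan(out.rt)
        assert not out.responded

    def test_trained_subject_selects_target_with_wta_exclusivity(
            self, control_params, net_params, strong_weights):
        rest = resting_state(net_params, strong_weights, control_params)
        stim = canonical_stimuli()
        for si in range(4):
            rng = np.random.default_rng(100 + si)
            out = run_trial(stim[si], strong_weights, control_params,
                            net_params, rng, duration=1.8, learning=False,
                            init=rest, keep_trace=True)
            tgt = int(np.argmax(stim[si]))
            assert out.chosen == tgt
            assert 0.0 < out.rt < 0.5
            final = out.yC_trace[-1]
            assert final[tgt] > 0.9
            assert np.delete(final, tgt).sum() < 0.1

    def test_symmetric_race_resolves_by_lowest_index_without_noise(
            self, control_params, strong_weights):
        # two identical channels, zero noise: a deterministic tie broken by
        # channel order
        npar = NetworkParams(noise_high=0.0)
        W = strong_weights.copy()
        W.wGS[1] = W.wGS[0] = np.array([1.0, 1.0, 0.2, 0.2])
        rest = resting_state(npar, W, control_params)
        S = np.array([1.0, 1.0, 0.1, 0.1])
        rng = np.random.default_rng(0)
        out = run_trial(S, W, control_params, npar, rng, duration=1.8,
                        learning=False, init=rest)
        if out.responded:
            assert out.chosen == 0

    def test_learning_trial_reports_window_averages(self, control_params,
                                                    net_params,
                                                    naive_weights):
        rest = resting_state(net_params, naive_weights, control_params)
        S = canonical_stimuli()[0]
        rng = np.random.default_rng(3)
        out = run_trial(S, naive_weights, control_params, net_params, rng,
                        learning=True,
                        rpe_by_channel=np.array([1.0, 0.1, -1.0, -1.0]),
                        init=rest)
        assert out.responded
        for arr in (out.window_yC, out.window_yG, out.window_yN):
            assert arr.shape == (4,)
            assert np.all(arr >= 0) and np.all(arr <= 1)
        # the selected channel dominates its cortical window average
        assert out.window_yC[out.chosen] > 0.8

    def test_naive_choice_is_noise_driven_and_roughly_uniform(
            self, control_params, net_params, naive_weights):
        rest = resting_state(net_params, naive_weights, control_params)
        S = canonical_stimuli()[0]
        counts = np.zeros(4)
        for k in range(80):
            rng = np.random.default_rng(500 + k)
            out = run_trial(S, naive_weights, control_params, net_params,
                            rng, learning=False, init=rest)
            if out.chosen is not None:
                counts[out.chosen] += 1
        assert counts.sum() >= 70          # naive subjects do respond
        assert counts.max() <= 0.5 * counts.sum()   # no channel dominates

    def test_invalid_arguments_rejected(self, control_params, net_params,
                                        naive_weights):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            run_trial(np.zeros(3), naive_weights, control_params, net_params,
                      rng, learning=False)
        with pytest.raises(ValueError):
            run_trial(np.zeros(4), naive_weights, control_params, net_params,
                      rng, duration=-1, learning=False)
        with pytest.raises(ValueError):
            run_trial(np.zeros(4), naive_weights, control_params, net_params,
                      rng, learning=True)  # missing rpe_by_channel
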