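"""Observer model: conjugate limits, grid accuracy, and belief dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sst_osc.observer import (
    BeliefState,
    ObserverParams,
    exponential_filter_pstop,
    init_prior,
    predict_step,
    pstop_readout,
    run_sequence,
    run_sequence_batch,
    update_step,
)


def beta_params(pm, sc):
    return pm * sc, (1 - pm) * sc


class TestPrior:
    @pytest.mark.parametrize(
        "pm,sc,expected_mean",
        [(0.25, 10.0, 0.25), (0.14, 10.0, 0.14), (0.5, 2.0, 0.5)],
    )
    def test_prior_mean_matches_beta_mean(self, pm, sc, expected_mean):
        state = init_prior(ObserverParams(alpha=0.5, pm=pm, sc=sc, grid_size=2000))
        assert state.mean == pytest.approx(expected_mean, abs=1e-3)

    def test_flat_prior_is_uniform(self):
        state = init_prior(ObserverParams(alpha=0.5, pm=0.5, sc=2.0))
        assert np.allclose(state.mass, state.mass[0])

    @pytest.mark.parametrize("bad", [dict(pm=0.0), dict(pm=1.0), dict(sc=0.0), dict(sc=-1.0)])
    def test_degenerate_prior_rejected(self, bad):
        kwargs = dict(alpha=0.5, pm=0.25, sc=10.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            init_prior(ObserverParams(**kwargs))


class TestUpdate:
    """Bayes updates must reproduce conjugate beta-Bernoulli arithmetic."""

    @pytest.mark.parametrize(
        "s,expected_mean",
        [(1, 3.5 / 11.0), (0, 2.5 / 11.0)],
    )
    def test_conjugate_posterior_mean(self, s, expected_mean):
        params = ObserverParams(alpha=1.0, pm=0.25, sc=10.0, grid_size=4000)
        post = update_step(init_prior(params), s)
        assert post.mean == pytest.approx(expected_mean, abs=1e-4)

    def test_laplace_rule_of_succession(self):
        params = ObserverParams(alpha=1.0, pm=0.5, sc=2.0, grid_size=4000)
        post = update_step(init_prior(params), 1)
        assert post.mean == pytest.approx(2.0 / 3.0, abs=1e-4)

    def test_update_rejects_bad_outcome(self):
        params = ObserverParams(alpha=1.0, pm=0.25, sc=10.0)
        with pytest.raises(ValueError):
            update_step(init_prior(params), 2)


class TestPredictStep:
    def test_alpha_one_is_identity(self):
        params = ObserverParams(alpha=1.0, pm=0.25, sc=10.0)
        post = update_step(init_prior(params), 1)
        out = predict_step(post, params)
        assert np.allclose(out.mass, post.mass)

    def test_alpha_zero_resets_to_prior(self):
        params = ObserverParams(alpha=0.0, pm=0.25, sc=10.0)
        post = update_step(init_prior(params), 1)
        out = predict_step(post, params)
        assert np.allclose(out.mass, init_prior(params).mass)

    def test_mixture_mean_is_linear(self):
        params = ObserverParams(alpha=0.5, pm=0.25, sc=10.0)
        post = update_step(update_step(init_prior(params), 1), 1)
        out = predict_step(post, params)
        expected = 0.5 * post.mean + 0.5 * init_prior(params).mean
        assert out.mean == pytest.approx(expected, abs=1e-12)


class TestReadout:
    def test_mean_readout(self):
        params = ObserverParams(alpha=1.0, pm=0.35 / 1.1, sc=11.0, grid_size=4000)
        state = init_prior(params)  # beta(3.5, 7.5)
        assert pstop_readout(state, "mean") == pytest.approx(3.5 / 11.0, abs=1e-4)

    @pytest.mark.parametrize(
        "a,b,mode",
        [(3.5, 7.5, 2.5 / 9.0), (1.4, 8.6, 0.05)],
    )
    def test_map_readout_is_beta_mode(self, a, b, mode):
        params = ObserverParams(
            alpha=1.0, pm=a / (a + b), sc=a + b, grid_size=2000
        )
        assert pstop_readout(init_prior(params), "map") == pytest.approx(mode, abs=1e-3)


class TestRunSequence:
    def test_all_go_monotone_decreasing(self):
        params = ObserverParams(alpha=1.0, pm=0.25, sc=10.0, readout="mean")
        trace = run_sequence(np.zeros(30, dtype=int), params)
        assert np.all(np.diff(trace.pstop) < 0)

    def test_first_trial_is_prior_predictive(self):
        params = ObserverParams(alpha=0.7, pm=0.25, sc=10.0, readout="mean")
        trace = run_sequence([1], params)
        assert trace.pstop[0] == pytest.approx(0.25, abs=1e-3)
        assert trace.pe[0] == pytest.approx(0.75, abs=1e-3)

    def test_conjugate_closed_form_at_alpha_one(self):
        """alpha=1 + mean readout equals the beta-Bernoulli predictive."""
        rng = np.random.default_rng(0)
        s = (rng.random(200) < 0.25).astype(int)
        params = ObserverParams(alpha=1.0, pm=0.14, sc=10.0, readout="mean")
        trace = run_sequence(s, params)
        k = np.arange(200)
        closed = (params.a + np.concatenate([[0], np.cumsum(s)[:-1]])) / (params.sc + k)
        assert np.max(np.abs(trace.pstop - closed)) < 1e-3

    def test_fine_grid_oracle_equivalence_mean(self):
        """grid_size=200 agrees with a 4000-cell oracle to < 1e-3 (mean readout)."""
        rng = np.random.default_rng(1)
        s = (rng.random(1000) < 0.25).astype(int)
        coarse = run_sequence(s, ObserverParams(0.78, 0.14, 10.0, "mean", 200))
        fine = run_sequence(s, ObserverParams(0.78, 0.14, 10.0, "mean", 4000))
        assert np.max(np.abs(coarse.pstop - fine.pstop)) < 1e-3

    def test_fine_grid_oracle_equivalence_map(self):
        """MAP readout: grid agreement within half a coarse cell on >= 97% of
        trials; the rest are genuine argmax flips of a bimodal predictive."""
        rng = np.random.default_rng(1)
        s = (rng.random(1000) < 0.25).astype(int)
        coarse = run_sequence(s, ObserverParams(0.78, 0.14, 10.0, "map", 200))
        fine = run_sequence(s, ObserverParams(0.78, 0.14, 10.0, "map", 4000))
        d = np.abs(coarse.pstop - fine.pstop)
        assert (d <= 0.5 / 200 + 1e-12).mean() >= 0.97

    def test_alternating_blocks_match_oracle(self):
        s = np.tile([1] * 5 + [0] * 5, 4)
        coarse = run_sequence(s, ObserverParams(0.78, 0.14, 10.0, "mean", 200))
        fine = run_sequence(s, ObserverParams(0.78, 0.14, 10.0, "mean", 4000))
        assert np.max(np.abs(coarse.pstop - fine.pstop)) < 1e-3

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        s=st.lists(st.integers(0, 1), min_size=3, max_size=40),
        flip=st.integers(0, 38),
        alpha=st.floats(0.0, 1.0),
    )
    def test_observing_a_stop_never_lowers_next_pstop(self, s, flip, alpha):
        """Monotone response: s_k 0 -> 1 cannot decrease pstop_{k+1}."""
        flip = flip % (len(s) - 1)
        s0, s1 = list(s), list(s)
        s0[flip], s1[flip] = 0, 1
        params = ObserverParams(alpha=alpha, pm=0.2, sc=10.0, readout="mean")
        t0 = run_sequence(s0, params)
        t1 = run_sequence(s1, params)
        assert t1.pstop[flip + 1] >= t0.pstop[flip + 1] - 1e-12

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        seed=st.integers(0, 1000),
        alpha=st.floats(0.0, 1.0),
        readout=st.sampled_from(["map", "mean"]),
    )
    def test_range_and_pe_identity(self, seed, alpha, readout):
        rng = np.random.default_rng(seed)
        s = (rng.random(50) < 0.3).astype(int)
        trace = run_sequence(s, ObserverParams(alpha, 0.14, 10.0, readout))
        assert np.all((trace.pstop > 0) & (trace.pstop < 1))
        on_stop = s == 1
        assert np.allclose(trace.pe[on_stop], 1 - trace.pstop[on_stop])
        assert np.all(np.isnan(trace.pe[~on_stop]))

    def test_batch_matches_scalar_path(self):
        rng = np.random.default_rng(2)
        s = (rng.random(120) < 0.25).astype(int)
        alphas, pms = np.array([0.3, 0.78]), np.array([0.14, 0.3])
        batch = run_sequence_batch(s, alphas, pms, readout="map")
        for i, a in enumerate(alphas):
            for j, pm in enumerate(pms):
                ref = run_sequence(s, ObserverParams(a, pm, 10.0, "map"))
                assert np.allclose(batch[i, j], ref.pstop)


class TestBeliefInvariants:
    def test_mass_normalized_after_each_step(self):
        params = ObserverParams(alpha=0.6, pm=0.2, sc=10.0)
        state = init_prior(params)
        rng = np.random.default_rng(3)
        for s_k in (rng.random(50) < 0.3).astype(int):
            state = update_step(predict_step(state, params), s_k)
            assert abs(state.mass.sum() - 1.0) < 1e-12

    def test_invalid_belief_rejected(self):
        with pytest.raises(ValueError):
            BeliefState(r_grid=np.array([0.2, 0.1]), mass=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            BeliefState(r_grid=np.array([0.1, 0.2]), mass=np.array([0.5, 0.6]))


class TestExponentialFilter:
    def test_all_stop_converges_to_one(self):
        p = exponential_filter_pstop(np.ones(300, dtype=int), decay=0.8)
        assert p[-1] > 0.99

    def test_all_go_decays_geometrically(self):
        p = exponential_filter_pstop(np.zeros(10, dtype=int), decay=0.5, init=0.25)
        assert np.allclose(p, 0.25 * 0.5 ** np.arange(10))

    def test_filter_tracks_dynamic_observer(self):
        """Best-decay filter correlates > 0.95 with the observer's mean trace."""
        rng = np.random.default_rng(4)
        s = (rng.random(400) < 0.25).astype(int)
        trace = run_sequence(s, ObserverParams(0.78, 0.14, 10.0, "mean"))
        best = max(
            np.corrcoef(exponential_filter_pstop(s, d, 0.14), trace.pstop)[0, 1]
            for d in np.linspace(0.4, 0.95, 12)
        )
        assert best > 0.95
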