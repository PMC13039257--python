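"""Ensemble HMM: binning, forward-backward exactness, EM, BIC, state rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from histbias import (
    BernoulliSpikeHMM,
    assign_states,
    baum_welch,
    bic_score,
    bin_spikes,
    detect_coding_states,
    forward_backward,
    init_hmm,
    select_n_states,
    state_occupancy,
)
from histbias.hmm import sample_hmm, EMISSION_FLOOR
from histbias.task import SessionEnsemble, TrialRecord


def brute_force_ll(obs, trans, emis, init):
    """Exhaustive path-sum likelihood (oracle for small M**T instances)."""
    M = trans.shape[0]
    _, T, N = obs.shape
    total = 0.0
    for path in itertools.product(range(M), repeat=T):
        p = init[path[0]]
        for t in range(1, T):
            p *= trans[path[t - 1], path[t]]
        for t in range(T):
            for j in range(N):
                p *= emis[path[t], j] if obs[0, t, j] else 1 - emis[path[t], j]
        total += p
    return np.log(total)


def random_model(M, N, rng):
    trans = rng.dirichlet(np.ones(M), M)
    emis = rng.uniform(0.05, 0.6, (M, N))
    init = rng.dirichlet(np.ones(M))
    return trans, emis, init


class TestBinSpikes:
    @pytest.fixture()
    def session(self):
        trials = [
            TrialRecord("s", i, 16, 24, "blue", "above", 400, 400, 0, "S2", True)
            for i in range(4)
        ]
        spikes = {
            "n0": {0: np.array([2.0, 3.0, 999.0]), 1: np.array([]), 2: np.array([500.0]), 3: np.array([])},
            "n1": {i: np.array([]) for i in range(4)},
        }
        return SessionEnsemble("s", ["n0", "n1"], spikes, trials)

    def test_span_of_1000ms_gives_200_bins(self, session):
        obs, clipped, idx = bin_spikes(session, span=(0.0, 1000.0), trial_indices=[0, 1, 2, 3])
        assert obs.shape == (4, 200, 2)

    def test_multi_spike_bin_clipped_and_counted(self, session):
        obs, clipped, _ = bin_spikes(session, span=(0.0, 1000.0), trial_indices=[0])
        assert obs[0, 0, 0] == 1  # spikes at 2.0 and 3.0 ms share bin [0, 5)
        assert clipped == 1

    def test_empty_trial_is_all_zero(self, session):
        obs, _, _ = bin_spikes(session, span=(0.0, 1000.0), trial_indices=[1])
        assert obs[0].sum() == 0

    def test_default_trial_selection_requires_complete_predecessor(self, session):
        obs, _, idx = bin_spikes(session, span=(0.0, 1000.0))
        assert idx == [1, 2, 3]  # first trial has no predecessor


class TestInit:
    def test_zero_noise_gives_identity_transition(self):
        trans, emis = init_hmm(3, 4, np.full(4, 0.1), np.random.default_rng(0), noise_std=0.0)
        np.testing.assert_array_equal(trans, np.eye(3))

    def test_emission_entries_clipped_into_open_interval(self):
        trans, emis = init_hmm(4, 6, np.array([0.0, 0.001, 0.5, 0.999, 1.0, 0.02]),
                               np.random.default_rng(1))
        assert emis.min() >= EMISSION_FLOOR and emis.max() <= 1 - EMISSION_FLOOR
        np.testing.assert_allclose(trans.sum(axis=1), 1.0, atol=1e-12)

    def test_fixed_seed_reproducible(self):
        a = init_hmm(3, 5, np.full(5, 0.1), np.random.default_rng(42))
        b = init_hmm(3, 5, np.full(5, 0.1), np.random.default_rng(42))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestForwardBackward:
    def test_single_state_posterior_is_one_and_ll_is_bernoulli(self):
        rng = np.random.default_rng(2)
        emis = np.array([[0.2, 0.4]])
        obs = (rng.random((3, 10, 2)) < 0.3).astype(np.int8)
        ll, gamma, _, _ = forward_backward(obs, np.ones((1, 1)), emis)
        np.testing.assert_allclose(gamma, 1.0)
        expect = np.sum(obs * np.log(emis) + (1 - obs) * np.log(1 - emis))
        assert ll == pytest.approx(expect, abs=1e-8)

    @pytest.mark.parametrize("M,T", [(2, 3), (2, 6), (2, 8), (3, 4), (3, 5), (4, 4)])
    def test_equals_brute_force_enumeration(self, M, T):
        # exhaustive over all instances with M * T <= 16, three random draws
        rng = np.random.default_rng(100 * M + T)
        for _ in range(3):
            trans, emis, init = random_model(M, 3, rng)
            obs = (rng.random((1, T, 3)) < 0.4).astype(np.int8)
            ll, gamma, _, _ = forward_backward(obs, trans, emis, init)
            assert abs(ll - brute_force_ll(obs, trans, emis, init)) < 1e-8
            np.testing.assert_allclose(gamma.sum(axis=2), 1.0, atol=1e-10)

    def test_agrees_with_hmmlearn_on_categorical_embedding(self):
        from hmmlearn.hmm import CategoricalHMM

        rng = np.random.default_rng(3)
        M, T, N = 3, 40, 3
        trans, emis, init = random_model(M, N, rng)
        obs = (rng.random((1, T, N)) < 0.35).astype(np.int8)
        ll, _, _, _ = forward_backward(obs, trans, emis, init)
        symbols = (obs[0] @ (2 ** np.arange(N))).astype(int)
        ep = np.empty((M, 2**N))
        for s in range(2**N):
            bits = np.array([(s >> j) & 1 for j in range(N)])
            ep[:, s] = np.prod(np.where(bits, emis, 1 - emis), axis=1)
        ref = CategoricalHMM(n_components=M)
        ref.startprob_, ref.transmat_, ref.emissionprob_ = init, trans, ep
        ref.n_features = 2**N
        assert ll == pytest.approx(ref.score(symbols.reshape(-1, 1)), abs=1e-8)

    def test_uniform_emission_makes_posteriors_observation_free(self):
        rng = np.random.default_rng(4)
        trans = rng.dirichlet(np.ones(2), 2)
        emis = np.tile([[0.3, 0.3]], (2, 1))  # identical rows
        obs_a = (rng.random((1, 12, 2)) < 0.3).astype(np.int8)
        obs_b = (rng.random((1, 12, 2)) < 0.3).astype(np.int8)
        _, ga, _, _ = forward_backward(obs_a, trans, emis)
        _, gb, _, _ = forward_backward(obs_b, trans, emis)
        np.testing.assert_allclose(ga, gb, atol=1e-12)


class TestBaumWelch:
    def test_training_ll_monotone_every_restart(self):
        trans = np.array([[0.95, 0.05], [0.1, 0.9]])
        emis = np.array([[0.02, 0.2, 0.05], [0.15, 0.02, 0.1]])
        obs, _ = sample_hmm(trans, emis, 20, 100, rng=5)
        for seed in range(3):
            m = BernoulliSpikeHMM(2, restarts=1, cv_folds=1, max_iter=50,
                                  random_state=seed).fit(obs)
            diffs = np.diff(m.history_)
            assert np.all(diffs > -1e-7)

    def test_single_state_degenerates_to_bernoulli_fit(self):
        rng = np.random.default_rng(6)
        obs = (rng.random((10, 50, 4)) < 0.25).astype(np.int8)
        m = baum_welch(obs, 1, rng=7, restarts=1, cv_folds=1, max_iter=20)
        np.testing.assert_allclose(
            m.emission_[0], obs.reshape(-1, 4).mean(axis=0), atol=1e-6
        )

    def test_three_state_recovery_by_bin_agreement(self):
        rng = np.random.default_rng(8)
        trans = np.full((3, 3), 0.01)
        np.fill_diagonal(trans, 0.98)
        emis = rng.uniform(0.01, 0.02, (3, 6))
        for m in range(3):
            emis[m, rng.choice(6, 3, replace=False)] = rng.uniform(0.08, 0.2, 3)
        obs, states = sample_hmm(trans, emis, 60, 300, rng=9)
        model = baum_welch(obs, 3, rng=10, restarts=3, cv_folds=2, max_iter=150)
        decoded = model.predict_posteriors(obs).argmax(axis=2)
        agreement = max(
            np.mean(np.asarray(perm)[decoded] == states)
            for perm in itertools.permutations(range(3))
        )
        assert agreement >= 0.8

    def test_transition_rows_stochastic_after_fit(self):
        obs, _ = sample_hmm(
            np.array([[0.9, 0.1], [0.2, 0.8]]),
            np.array([[0.02, 0.15], [0.2, 0.01]]),
            15, 80, rng=11,
        )
        m = baum_welch(obs, 2, rng=12, restarts=2, cv_folds=2, max_iter=60)
        np.testing.assert_allclose(m.transition_.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(m.initial_.sum(), 1.0, atol=1e-10)
        assert m.emission_.min() >= EMISSION_FLOOR

    def test_estimator_params_roundtrip(self):
        m = BernoulliSpikeHMM(4, restarts=2)
        assert m.get_params()["n_states"] == 4
        m.set_params(n_states=3)
        assert m.n_states == 3
        with pytest.raises(ValueError, match="unknown"):
            m.set_params(bogus=1)


class TestModelSelection:
    def test_bic_formula_worked_example(self):
        # LL = 0, M = 2, N = 4, T = 1000: (2*1 + 2*4) ln 1000 = 10 ln 1000
        assert bic_score(0.0, 2, 4, 1000) == pytest.approx(10 * np.log(1000), abs=1e-9)
        assert bic_score(0.0, 2, 4, 1000) == pytest.approx(69.07755278982137, abs=1e-9)

    def test_trace_covers_2_to_nminus1(self):
        rng = np.random.default_rng(13)
        obs = (rng.random((12, 60, 5)) < 0.1).astype(np.int8)
        model, trace = select_n_states(obs, rng=14, restarts=1, cv_folds=1, max_iter=20)
        assert list(trace["n_states"]) == [2, 3, 4]
        assert len(trace) == 5 - 2

    def test_too_few_neurons_rejected(self):
        obs = np.zeros((5, 10, 3), dtype=np.int8)
        with pytest.raises(ValueError, match="4 neurons"):
            select_n_states(obs, rng=15)

    def test_bic_matches_fitted_attributes(self):
        rng = np.random.default_rng(16)
        obs = (rng.random((8, 40, 4)) < 0.15).astype(np.int8)
        m = baum_welch(obs, 2, rng=17, restarts=1, cv_folds=1, max_iter=15)
        assert m.bic_ == pytest.approx(
            bic_score(m.log_likelihood_, 2, 4, 8 * 40), abs=1e-9
        )


class TestStateAssignment:
    def _post(self, spec, M=2):
        """Posterior matrix from a list of (value, n_bins) for state 0."""
        p0 = np.concatenate([np.full(n, v) for v, n in spec])
        return np.stack([p0, 1 - p0], axis=1)[None]

    def test_sustained_high_posterior_assigned(self):
        post = self._post([(0.5, 10), (0.9, 12), (0.5, 10)])
        ivals = assign_states(post, span_start_ms=0.0)
        assert [(iv.state, iv.start_ms, iv.end_ms) for iv in ivals] == [(0, 50.0, 110.0)]

    def test_short_run_not_assigned(self):
        post = self._post([(0.5, 10), (0.9, 8), (0.5, 10)])  # 40 ms < 50 ms
        assert assign_states(post, span_start_ms=0.0) == []

    def test_subthreshold_posterior_not_assigned(self):
        post = self._post([(0.7, 100)])  # 500 ms at 0.7 <= 0.8
        assert assign_states(post, span_start_ms=0.0) == []

    def test_exact_boundary_values(self):
        # exactly 0.8 fails the strictly-greater rule; exactly 50 ms passes
        post = self._post([(0.8, 100)])
        assert assign_states(post, span_start_ms=0.0) == []
        post = self._post([(0.5, 4), (0.81, 10), (0.5, 4)])
        ivals = assign_states(post, span_start_ms=0.0)
        assert len(ivals) == 1 and ivals[0].end_ms - ivals[0].start_ms == 50.0

    def test_occupancy_bounded_by_window(self):
        post = self._post([(0.9, 200)])
        ivals = assign_states(post, span_start_ms=0.0, trial_indices=[7])
        occ = state_occupancy(ivals, [7], 2, window=(100.0, 400.0))
        by_state = occ.set_index("state")["occupancy_ms"]
        assert by_state.loc[0] == 300.0
        assert by_state.loc[1] == 0.0
        assert occ.groupby("trial_index")["occupancy_ms"].sum().max() <= 300.0


class TestCodingStates:
    def _occupancy_frame(self, occ_by_state_group):
        rows = []
        trial = 0
        groups = {}
        for g, per_state in occ_by_state_group.items():
            n = len(next(iter(per_state.values())))
            for i in range(n):
                for state, vals in per_state.items():
                    rows.append(
                        {"trial_index": trial, "state": state, "occupancy_ms": vals[i]}
                    )
                groups[trial] = g
                trial += 1
        return pd.DataFrame(rows), groups

    def test_strongly_gated_state_detected(self):
        rng = np.random.default_rng(18)
        occ, groups = self._occupancy_frame(
            {
                "blue": {0: rng.normal(300, 40, 30), 1: rng.normal(100, 40, 30)},
                "red": {0: rng.normal(50, 40, 30), 1: rng.normal(100, 40, 30)},
            }
        )
        res = detect_coding_states(occ, groups)
        assert bool(res.loc[res.state == 0, "coding"].iloc[0])
        assert not bool(res.loc[res.state == 1, "coding"].iloc[0])
        assert res.loc[res.state == 0, "p_fdr"].iloc[0] < 0.05

    def test_null_occupancies_rarely_flagged(self):
        rng = np.random.default_rng(19)
        n_flagged = 0
        n_rep = 100
        for _ in range(n_rep):
            occ, groups = self._occupancy_frame(
                {
                    "blue": {s: rng.normal(150, 50, 20) for s in range(3)},
                    "red": {s: rng.normal(150, 50, 20) for s in range(3)},
                }
            )
            res = detect_coding_states(occ, groups)
            n_flagged += int(res["coding"].any())
        # BH at alpha=0.05 across 3 states: session-level false positives ~5%
        assert n_flagged / n_rep <= 0.1

    def test_small_group_skipped_with_warning(self):
        occ, groups = self._occupancy_frame(
            {"blue": {0: [100.0, 110.0]}, "red": {0: [90.0, 95.0, 100.0]}}
        )
        with pytest.warns(UserWarning, match="fewer than"):
            res = detect_coding_states(occ, groups)
        assert res.empty

    def test_session_summary_reproducible_under_fixed_seed(self):
        from histbias import (
            BehaviourParams,
            NeuralParams,
            generate_neural_dataset,
        )

        def run():
            sessions, _ = generate_neural_dataset(
                2, 60, BehaviourParams(),
                NeuralParams(n_neurons=4, colour_state_bias=0.9,
                             transition_stickiness=0.995,
                             span_ms=(-400.0, 1000.0)),
                seed=505,
            )
            counts = []
            for s in sessions:
                obs, _, idx = bin_spikes(s, span=(-400.0, 1000.0))
                m = baum_welch(obs, 2, rng=20, restarts=1, cv_folds=1, max_iter=30)
                post = m.predict_posteriors(obs)
                ivals = assign_states(post, span_start_ms=-400.0, trial_indices=idx)
                occ = state_occupancy(ivals, idx, 2, window=(0.0, 1000.0))
                groups = {
                    t.trial_index: t.s1_colour for t in s.trials if t.trial_index in idx
                }
                res = detect_coding_states(occ, groups)
                counts.append(int(res["coding"].sum()) if not res.empty else 0)
            return counts

        assert run() == run()
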