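"""Pseudo-population decoding: windows, assembly, SVM, nulls, conditioning."""

import numpy as np
import pytest
from scipy.stats import norm

from histbias import (
    NeuralParams,
    BehaviourParams,
    WindowGrid,
    build_pseudopopulation,
    conditional_decode,
    cross_temporal,
    decode_feature,
    decode_window,
    generate_neural_dataset,
    permutation_null,
    sliding_curve,
)
from histbias.decoding import label_s1_class, label_prev_s2_class, label_s1_colour
from histbias.task import SessionEnsemble, TrialRecord
from histbias.decoding import window_rates


def regular_session():
    trials = [
        TrialRecord("s", i, 16, 24, "blue", "above", 400, 400, 0, "S2", True)
        for i in range(3)
    ]
    spikes = {"n0": {0: np.array([10.0, 50.0, 150.0]), 1: np.array([]), 2: np.array([200.0])}}
    return SessionEnsemble("s", ["n0"], spikes, trials)


class TestWindowRates:
    def test_three_spikes_in_window_is_15_spk_per_s(self):
        s = regular_session()
        rates = window_rates(s, 100.0, [0, 1, 2])
        assert rates[0, 0] == pytest.approx(15.0)  # 3 spikes / 0.2 s

    def test_empty_window_is_zero(self):
        s = regular_session()
        assert window_rates(s, 100.0, [1])[0, 0] == 0.0

    def test_right_edge_spike_excluded_half_open(self):
        s = regular_session()
        # trial 2 has a single spike at exactly 200.0 ms
        # window [100, 300) includes it ...
        assert window_rates(s, 200.0, [2])[0, 0] == pytest.approx(5.0)
        # ... but the half-open window [0, 200) does not
        assert window_rates(s, 100.0, [2])[0, 0] == 0.0
        # and the left edge is inclusive: [200, 400) includes it
        assert window_rates(s, 300.0, [2])[0, 0] == pytest.approx(5.0)


class TestGrid:
    def test_default_grid_has_69_centers(self):
        grid = WindowGrid()
        assert len(grid) == 69
        assert grid.centers[0] == -300.0 and grid.centers[-1] == 1400.0

    def test_early_late_window_sets(self):
        grid = WindowGrid()
        early = grid.window_indices(grid.early_s1)
        late = grid.window_indices(grid.late_s1)
        assert grid.centers[early].min() == 0.0 and grid.centers[early].max() == 475.0
        assert grid.centers[late].min() == 500.0 and grid.centers[late].max() == 975.0


class TestPseudoPopulation:
    def test_split_and_zscoring(self, tuned_sessions):
        pop = build_pseudopopulation(
            tuned_sessions, label_s1_class, window_center_ms=500.0, rng=3
        )
        # z-scored train matrix has column means ~0 and sd ~1
        keep = pop.X_train.std(axis=0) > 0
        np.testing.assert_allclose(pop.X_train.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(pop.X_train[:, keep].std(axis=0), 1.0, atol=1e-10)
        # stratified 75/25: train rows ~3x test rows per class
        for c in range(len(pop.classes)):
            n_tr = (pop.y_train == c).sum()
            n_te = (pop.y_test == c).sum()
            assert n_tr >= 2 * n_te  # 75/25 with per-neuron flooring
        # disjoint labels arrays consistent
        assert set(np.unique(pop.y_train)) == set(range(len(pop.classes)))

    def test_assembly_deterministic_under_seed(self, tuned_sessions):
        a = build_pseudopopulation(tuned_sessions, label_s1_class, 500.0, rng=11)
        b = build_pseudopopulation(tuned_sessions, label_s1_class, 500.0, rng=11)
        np.testing.assert_array_equal(a.X_train, b.X_train)
        np.testing.assert_array_equal(a.X_test, b.X_test)


class TestDecodeWindow:
    def test_separable_toy_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        X0 = rng.normal(-3, 0.1, (20, 2))
        X1 = rng.normal(3, 0.1, (20, 2))
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(20), np.ones(20)]
        acc, _ = decode_window(X, y, X, y)
        assert acc == 1.0

    def test_shuffled_labels_decode_at_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(100):
            X = rng.normal(size=(60, 5))
            y = rng.permutation(np.repeat([0, 1, 2], 20))
            acc, _ = decode_window(X[:40], y[:40], X[40:], y[40:])
            accs.append(acc)
        # mean over 100 repeats of 20-trial tests: SE = sqrt(p(1-p)/2000)
        se = np.sqrt((1 / 3) * (2 / 3) / (100 * 20))
        assert abs(np.mean(accs) - 1 / 3) < 3 * se

    def test_single_class_train_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="single class"):
            decode_window(X, np.zeros(10), X, np.zeros(10))

    def test_accuracy_matches_bayes_on_gaussian_toy(self):
        # two isotropic Gaussians: Bayes accuracy = Phi(d/2), d = |mu1-mu0|/sigma
        rng = np.random.default_rng(2)
        mu, sigma = np.array([1.0, 1.0]), 1.0
        d = np.linalg.norm(2 * mu) / sigma
        bayes = norm.cdf(d / 2)
        Xtr = np.vstack([rng.normal(-mu, sigma, (500, 2)), rng.normal(mu, sigma, (500, 2))])
        ytr = np.r_[np.zeros(500), np.ones(500)]
        Xte = np.vstack([rng.normal(-mu, sigma, (2000, 2)), rng.normal(mu, sigma, (2000, 2))])
        yte = np.r_[np.zeros(2000), np.ones(2000)]
        acc, _ = decode_window(Xtr, ytr, Xte, yte)
        se = np.sqrt(bayes * (1 - bayes) / 4000)
        assert abs(acc - bayes) < 3 * se

    def test_duplicating_every_trial_leaves_accuracy_close(self):
        rng = np.random.default_rng(3)
        Xtr = np.vstack([rng.normal(-1, 1, (100, 4)), rng.normal(1, 1, (100, 4))])
        ytr = np.r_[np.zeros(100), np.ones(100)]
        Xte = np.vstack([rng.normal(-1, 1, (500, 4)), rng.normal(1, 1, (500, 4))])
        yte = np.r_[np.zeros(500), np.ones(500)]
        acc1, _ = decode_window(Xtr, ytr, Xte, yte)
        acc2, _ = decode_window(
            np.repeat(Xtr, 2, axis=0), np.repeat(ytr, 2), Xte, yte
        )
        assert abs(acc1 - acc2) < 0.02


class TestCurves:
    def test_s1_class_decodable_during_presentation_only(self, tuned_sessions):
        grid = WindowGrid(step_ms=200.0)
        res = sliding_curve(tuned_sessions, label_s1_class, grid, repeats=5, rng=4)
        pre = res.mean_accuracy[grid.centers < -100]
        during = res.mean_accuracy[(grid.centers >= 100) & (grid.centers < 900)]
        assert during.mean() > 0.55
        assert abs(pre.mean() - 1 / 3) < 0.1
        assert np.all(res.accuracy >= 0) and np.all(res.accuracy <= 1)

    def test_fixed_seed_bit_identical(self, tuned_sessions):
        grid = WindowGrid(step_ms=400.0)
        a = sliding_curve(tuned_sessions, label_s1_class, grid, repeats=3, rng=7)
        b = sliding_curve(tuned_sessions, label_s1_class, grid, repeats=3, rng=7)
        np.testing.assert_array_equal(a.accuracy, b.accuracy)

    def test_cross_temporal_diagonal_equals_curve(self, tuned_sessions):
        grid = WindowGrid(step_ms=200.0)
        curve = sliding_curve(tuned_sessions, label_s1_class, grid, repeats=2, rng=9)
        mat = cross_temporal(tuned_sessions, label_s1_class, grid, repeats=2, rng=9)
        assert mat.accuracy.shape == (2, len(grid), len(grid))
        np.testing.assert_allclose(
            np.diagonal(mat.accuracy, axis1=1, axis2=2), curve.accuracy, atol=1e-12
        )

    def test_dynamic_code_off_diagonal_below_diagonal(self, tuned_sessions):
        grid = WindowGrid(start_ms=100.0, stop_ms=900.0, step_ms=200.0)
        mat = cross_temporal(tuned_sessions, label_prev_s2_class, grid, repeats=3, rng=10)
        m = mat.mean_accuracy
        diag = np.diagonal(m).mean()
        off = m[~np.eye(len(grid), dtype=bool)].mean()
        assert diag > off


class TestPermutationNull:
    def test_null_centred_at_chance_and_mask(self, tuned_sessions):
        grid = WindowGrid(start_ms=-300.0, stop_ms=900.0, step_ms=300.0)
        null = permutation_null(
            tuned_sessions, label_s1_class, grid, n_perm=100, rng=12
        )
        assert null.shape == (100, len(grid))
        se = null.std(axis=0).mean() / 10  # SE of the null mean over 100 perms
        assert abs(null.mean() - 1 / 3) < 4 * se
        res = sliding_curve(tuned_sessions, label_s1_class, grid, repeats=5, rng=13)
        res.null = null
        sig = res.significant
        in_s1 = (grid.centers >= 100) & (grid.centers <= 900)
        assert sig[in_s1].all()
        assert res.p_values[in_s1].max() <= 0.05

    def test_too_few_permutations_rejected(self, tuned_sessions):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(tuned_sessions, label_s1_class, WindowGrid(), n_perm=10)


@pytest.fixture(scope="module")
def adaptive_sessions():
    sessions, _ = generate_neural_dataset(
        8,
        300,
        BehaviourParams(),
        NeuralParams(n_neurons=8, history_shift_eta=-0.35),
        seed=303,
    )
    return sessions


@pytest.fixture(scope="module")
def result(adaptive_sessions):
    return conditional_decode(
        adaptive_sessions, grid=WindowGrid(step_ms=100.0), repeats=4, rng=14
    )


class TestConditionalDecode:
    def test_history_gap_orders_accuracy_tiers(self, result):
        f, p, tukey = result.tier_anova("early_s1")
        samples = result.tier_samples("early_s1")
        assert (
            samples["within"].mean()
            > samples["low_delta"].mean()
            > samples["high_delta"].mean()
        )
        assert p < 0.05
        wh = tukey[
            ((tukey.group1 == "within") & (tukey.group2 == "high_delta"))
            | ((tukey.group1 == "high_delta") & (tukey.group2 == "within"))
        ]
        assert float(wh["p-adj"].iloc[0]) < 0.05

    def test_marginals_sum_to_one(self, result):
        np.testing.assert_allclose(result.marginals.sum(axis=-1), 1.0, atol=1e-12)

    def test_predictions_biased_toward_training_history(self, result):
        d_early = result.marginal_deltas("early_s1")
        i_low = result.conditions.index("low")
        i_high = result.conditions.index("high")
        k_low = result.classes.index("low")
        k_high = result.classes.index("high")
        # decoder trained on low previous-S2, tested on high-history trials:
        # the low S1 class is over-assigned relative to the within reference
        assert d_early[i_low, i_high, k_low] > 0
        # and symmetrically for the high-trained decoder on low-history trials
        assert d_early[i_high, i_low, k_high] > 0

    def test_no_tier_effect_without_history_shift(self):
        sessions, _ = generate_neural_dataset(
            8,
            300,
            BehaviourParams(),
            NeuralParams(n_neurons=8, history_shift_eta=0.0, prev_s2_gain=1.0),
            seed=304,
        )
        res = conditional_decode(
            sessions, grid=WindowGrid(step_ms=100.0), repeats=4, rng=15
        )
        samples = res.tier_samples("early_s1")
        gap = samples["within"].mean() - samples["high_delta"].mean()
        assert abs(gap) < 0.05

    def test_empty_condition_class_cell_rejected(self, adaptive_sessions):
        def broken_target(p):
            # class never observed together with high previous S2
            if label_prev_s2_class(p) == "high":
                return None if label_s1_class(p) == "low" else label_s1_class(p)
            return label_s1_class(p)

        with pytest.raises(ValueError, match="cell"):
            conditional_decode(
                adaptive_sessions,
                target_fn=broken_target,
                grid=WindowGrid(step_ms=200.0),
                repeats=1,
                rng=16,
            )


class TestFeatureDecoding:
    def test_colour_decodable_during_s1(self, tuned_sessions):
        grid = WindowGrid(start_ms=-300.0, stop_ms=900.0, step_ms=300.0)
        res = decode_feature(tuned_sessions, grid, repeats=4, rng=17)["all"]
        assert res.chance == 0.5
        in_s1 = (grid.centers >= 100) & (grid.centers <= 900)
        assert res.mean_accuracy[in_s1].mean() > 0.7
        assert abs(res.mean_accuracy[grid.centers < -100].mean() - 0.5) < 0.12

    def test_match_mismatch_partitions_returned(self, tuned_sessions):
        grid = WindowGrid(start_ms=300.0, stop_ms=700.0, step_ms=200.0)
        parts = decode_feature(tuned_sessions, grid, repeats=2, rng=18, split_by_match=True)
        assert set(parts) == {"match", "mismatch"}
        for res in parts.values():
            assert res.accuracy.shape == (2, len(grid))
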