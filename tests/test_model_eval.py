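"""Metrics, cross-validation contracts, permutation and corrected t-tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ttest_rel

from feedcsp import model_eval as me
from feedcsp import synthetic_data as sd


class TestBalancedAccuracy:
    def test_perfect_classification(self):
        assert me.balanced_accuracy_from_counts(5, 0, 5, 0) == 1.0

    def test_manual_arithmetic_case(self):
        # sens 3/4, spec 2/4 -> 0.625
        assert me.balanced_accuracy_from_counts(3, 1, 2, 2) == \
            pytest.approx(0.625)

    def test_absent_truth_class_rejected(self):
        with pytest.raises(ValueError, match="both truth classes"):
            me.balanced_accuracy_from_counts(3, 1, 0, 0)

    def test_agrees_with_sklearn_on_all_small_tables(self):
        """Exhaustive agreement with the reference implementation over all
        2x2 confusion tables with entries <= 6."""
        from sklearn.metrics import balanced_accuracy_score

        for tp, fn, tn, fp in itertools.product(range(7), repeat=4):
            if tp + fn == 0 or tn + fp == 0:
                continue
            y_true = [1] * (tp + fn) + [0] * (tn + fp)
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            assert me.balanced_accuracy_from_counts(tp, fn, tn, fp) == \
                pytest.approx(balanced_accuracy_score(y_true, y_pred))


class TestRocAuc:
    def test_perfect_and_reversed_ordering(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        assert me.roc_auc(scores, [0, 0, 1, 1]) == 1.0
        assert me.roc_auc(scores, [1, 1, 0, 0]) == 0.0

    def test_tie_case_matches_pairwise_count(self):
        scores = np.array([0.5, 0.5, 0.7, 0.3])
        labels = np.array([1, 0, 1, 0])
        # brute force: mean over (pos, neg) pairs of 1[s+ > s-] + 0.5 ties
        total = 0.0
        for sp in scores[labels == 1]:
            for sn in scores[labels == 0]:
                total += 1.0 if sp > sn else 0.5 if sp == sn else 0.0
        assert me.roc_auc(scores, labels) == pytest.approx(total / 4.0)

    def test_random_scores_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            scores = rng.integers(0, 4, n).astype(float)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            brute = np.mean([
                1.0 if sp > sn else 0.5 if sp == sn else 0.0
                for sp in scores[labels == 1] for sn in scores[labels == 0]])
            assert me.roc_auc(scores, labels) == pytest.approx(brute)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            me.roc_auc(np.array([0.1, 0.9]), [1, 1])


class TestPrecisionRecall:
    def test_precision_zero_when_no_positive_predictions(self):
        assert me.precision_score(0, 3, 4, 0) == 0.0

    def test_values_from_counts(self):
        assert me.precision_score(3, 1, 2, 2) == pytest.approx(0.6)
        assert me.recall_score(3, 1, 2, 2) == pytest.approx(0.75)


class TestCorrectedPairedTTest:
    def test_identical_vectors(self):
        a = np.linspace(0.4, 0.8, 100)
        res = me.corrected_paired_ttest(a, a.copy(), k=10, r=10)
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_evaluated_formula(self):
        """Fixed 100-element difference vector, rho = 1/9, df = 99."""
        rng = np.random.default_rng(1234)
        a = 0.6 + 0.05 * rng.standard_normal(100)
        b = 0.55 + 0.05 * rng.standard_normal(100)
        res = me.corrected_paired_ttest(a, b, k=10, r=10)
        d = a - b
        t_hand = d.mean() / np.sqrt((1 / 100 + 1 / 9) * d.var(ddof=1))
        assert res.t == pytest.approx(t_hand, abs=1e-12)
        assert res.df == 99
        assert res.rho == pytest.approx(1.0 / 9.0)
        from scipy.stats import t as t_dist
        assert res.p == pytest.approx(2 * t_dist.sf(abs(t_hand), 99),
                                      abs=1e-12)

    def test_rho_zero_recovers_classical_paired_t(self):
        rng = np.random.default_rng(2)
        a = rng.random(30)
        b = rng.random(30)
        res = me.corrected_paired_ttest(a, b, k=30, r=1, train_frac=1.0)
        classic = ttest_rel(a, b)
        assert res.t == pytest.approx(classic.statistic)
        assert res.p == pytest.approx(classic.pvalue)

    def test_zero_variance_nonzero_mean_flagged(self):
        a = np.full(10, 0.7)
        b = np.full(10, 0.6)
        res = me.corrected_paired_ttest(a, b, k=5, r=2)
        assert np.isinf(res.t) and res.p == 0.0 and res.flag

    def test_length_mismatch_with_rk(self):
        with pytest.raises(ValueError, match="r\\*k"):
            me.corrected_paired_ttest(np.ones(10), np.ones(10), k=3, r=3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_correction_is_conservative(self, seed):
        """|t_corrected| <= |t_classical| whenever rho > 0, var > 0."""
        rng = np.random.default_rng(seed)
        a, b = rng.random(20), rng.random(20)
        if np.var(a - b, ddof=1) == 0:
            return
        res = me.corrected_paired_ttest(a, b, k=10, r=2)
        classic = ttest_rel(a, b).statistic
        assert abs(res.t) <= abs(classic) + 1e-12


class TestHyperGrid:
    def test_grid_values_within_printed_ranges(self):
        g = me.HyperGrid()
        assert set(g.csp_components) == {1, 2, 3, 4}
        assert min(g.csp_lambda) >= 1e-3 and max(g.csp_lambda) <= 1e-1
        assert min(g.C) >= 1e-5 and max(g.C) <= 1e1
        assert set(g.kernel) == {"linear", "rbf"}

    def test_point_order_encodes_tie_break(self):
        pts = me.HyperGrid().points("csp")
        assert pts[0]["m"] == 1 and pts[0]["kernel"] == "linear"
        assert pts[0]["C"] == min(me.HyperGrid().C)
        ms = [p["m"] for p in pts]
        assert ms == sorted(ms)

    def test_direct_points_skip_csp_axes(self):
        pts = me.HyperGrid().points("direct")
        assert all("m" not in p for p in pts)

    def test_unstable_lambda_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            me.HyperGrid(csp_lambda=(1e-6,))


def _feature_data(rng, n=24, separation=0.0):
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X = rng.standard_normal((n, 2))
    X[:, 0] += separation * y
    return me.ModelData(X, "direct"), y


class TestFitSelect:
    def test_separable_features_reach_perfect_accuracy(self):
        rng = np.random.default_rng(3)
        data, y = _feature_data(rng, separation=20.0)
        params, report = me.fit_select(data, y, me.HyperGrid(), k=3, seed=0)
        assert report.mean("balanced_accuracy") == 1.0

    def test_chance_level_on_null_features(self):
        rng = np.random.default_rng(4)
        accs = []
        for seed in range(10):
            data, y = _feature_data(np.random.default_rng(seed), n=30)
            _, report = me.fit_select(data, y, me.SMALL_GRID, k=3, seed=seed)
            accs.append(report.mean("balanced_accuracy"))
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_tie_break_prefers_simpler_model(self):
        rng = np.random.default_rng(5)
        data, y = _feature_data(rng, separation=20.0)  # everything wins
        params, _ = me.fit_select(data, y, me.HyperGrid(), k=3, seed=0)
        assert params["kernel"] == "linear"
        assert params["C"] == min(me.HyperGrid().C)


class TestRepeatedCV:
    def test_score_counts_and_reproducibility(self):
        rng = np.random.default_rng(6)
        data, y = _feature_data(rng, n=30, separation=1.0)
        p = {"kind": "direct", "kernel": "linear", "C": 1.0}
        rep1 = me.repeated_cv_score(data, y, p, r=10, k=10, seed=9)
        rep2 = me.repeated_cv_score(data, y, p, r=10, k=10, seed=9)
        for metric in ("balanced_accuracy", "roc_auc", "precision",
                       "recall"):
            assert rep1.scores[metric].shape == (100,)
            assert np.array_equal(rep1.scores[metric],
                                  rep2.scores[metric])
        assert np.all((rep1.scores["balanced_accuracy"] >= 0)
                      & (rep1.scores["balanced_accuracy"] <= 1))
        assert rep1.train_acc is not None

    def test_k_reduced_when_class_small(self):
        rng = np.random.default_rng(7)
        data, y = _feature_data(rng, n=12)  # 6 per class < k=10
        p = {"kind": "direct", "kernel": "linear", "C": 1.0}
        rep = me.repeated_cv_score(data, y, p, r=2, k=10, seed=0)
        assert rep.k == 6
        assert any("reduced" in n for n in rep.notes)

    def test_all_identical_features_stay_near_chance(self):
        data = me.ModelData(np.ones((20, 2)), "direct")
        y = np.array([1] * 10 + [0] * 10)
        p = {"kind": "direct", "kernel": "linear", "C": 1.0}
        rep = me.repeated_cv_score(data, y, p, r=5, k=5, seed=1)
        assert abs(rep.mean("balanced_accuracy") - 0.5) <= 0.05


class TestPermutationTest:
    def test_p_formula_boundary(self):
        # observed score below every permutation -> p = (1+B)/(B+1) = 1
        rng = np.random.default_rng(8)
        data, y = _feature_data(rng, n=20)
        p = {"kind": "direct", "kernel": "linear", "C": 1.0}
        res = me.permutation_test(data, y, params=p, B=99, seed=0)
        assert res.p == (1 + np.sum(res.perm_scores >= res.observed)) / 100.0
        assert 0 < res.p <= 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        data, y = _feature_data(rng, n=20, separation=1.0)
        p = {"kind": "direct", "kernel": "linear", "C": 1.0}
        r1 = me.permutation_test(data, y, params=p, B=99, seed=5)
        r2 = me.permutation_test(data, y, params=p, B=99, seed=5)
        assert r1.p == r2.p
        assert np.array_equal(r1.perm_scores, r2.perm_scores)

    def test_high_snr_effect_detected(self):
        rng = np.random.default_rng(10)
        data, y = _feature_data(rng, n=30, separation=5.0)
        p = {"kind": "direct", "kernel": "linear", "C": 1.0}
        res = me.permutation_test(data, y, params=p, B=199, seed=3)
        assert res.p <= 0.01

    def test_small_b_rejected(self):
        rng = np.random.default_rng(11)
        data, y = _feature_data(rng, n=20)
        with pytest.raises(ValueError, match="B >= 99"):
            me.permutation_test(data, y,
                                params={"kind": "direct",
                                        "kernel": "linear", "C": 1.0},
                                B=10, seed=0)


class TestRunModel:
    def test_twelve_configurations(self):
        assert len(me.enumerate_configs()) == 12
        assert len(me.enumerate_configs(components=("theta",),
                                        valences=("positive",))) == 2

    def test_run_model_emits_table_row(self, small_dataset):
        (epochs, metas), _ = small_dataset
        res = me.run_model(epochs, metas, "theta", "positive", "depression",
                           grid=me.SMALL_GRID, r=2, k=3, B=99, seed=0)
        row = res.table_row()
        assert set(row) >= {"component", "valence", "contrast", "train_acc",
                            "acc", "p_acc", "roc_auc", "recall", "precision"}
        assert 0 <= row["acc"] <= 1 and 0 < row["p_acc"] <= 1
        assert res.csp_model is not None
        assert res.csp_model.meta["component"] == "theta"

    def test_erp_component_uses_single_feature(self, small_dataset):
        (epochs, metas), _ = small_dataset
        data, y, kept, _ = me.prepare_model_data(
            epochs, metas, "erp", "positive", "depression",
            erp_channel=epochs[0].montage.labels[0])
        assert data.kind == "direct" and data.X.shape[1] == 1

    def test_insufficient_trials_subject_excluded(self, montage8):
        from .conftest import make_epochs
        from feedcsp import SubjectMeta
        epochs = [make_epochs(montage8, n_pos=6, n_neg=6, seed=i,
                              subject_id=f"S{i:03d}") for i in range(8)]
        # subject S000 has too few positive trials
        epochs[0] = make_epochs(montage8, n_pos=3, n_neg=6, seed=0,
                                subject_id="S000")
        metas = [SubjectMeta(f"S{i:03d}", bdi=25, stai=55) for i in range(4)] \
            + [SubjectMeta(f"S{i:03d}", bdi=4, stai=50) for i in range(4, 8)]
        data, y, kept, excluded = me.prepare_model_data(
            epochs, metas, "theta", "positive", "depression")
        assert "S000" in excluded and len(kept) == 7

    def test_compare_models_requires_identical_splits(self, small_dataset):
        (epochs, metas), _ = small_dataset
        kwargs = dict(grid=me.SMALL_GRID, r=2, k=3, B=99)
        a = me.run_model(epochs, metas, "theta", "positive", "depression",
                         seed=0, **kwargs)
        b = me.run_model(epochs, metas, "delta", "positive", "depression",
                         seed=0, **kwargs)
        res = me.compare_models(a, b)
        assert res.df == 2 * 3 - 1
        c = me.run_model(epochs, metas, "delta", "positive", "depression",
                         seed=1, **kwargs)
        with pytest.raises(ValueError, match="identical splits"):
            me.compare_models(a, c)
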