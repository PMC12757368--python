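"""Split, network training, scoring and the statistics toolbox."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from cflmd.classifier import (
    NetSpec,
    bh_adjust,
    fisher_exact,
    mann_whitney,
    roc_auc,
    score,
    scores_frame,
    spearman,
    split_train_val,
    train_nn,
)
from cflmd.feature_integration import FeatureMatrix
from cflmd.io_formats import CASE, CONTROL


def _fm(n_ctrl, n_case, n_feat=4, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    n = n_ctrl + n_case
    X = rng.uniform(0.2, 0.6, size=(n, n_feat))
    X[n_ctrl:] = np.clip(X[n_ctrl:] + shift, 0, 1)
    idx = [f"s{i}" for i in range(n)]
    groups = pd.Series([CONTROL] * n_ctrl + [CASE] * n_case, index=idx)
    return FeatureMatrix(
        values=pd.DataFrame(X, index=idx, columns=[f"r{j}" for j in range(n_feat)]),
        groups=groups,
        activity=pd.Series(rng.uniform(0, 10, size=n), index=idx),
    )


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

class TestSplit:
    def test_canonical_study_counts(self):
        fm = _fm(21, 60)
        train, val = split_train_val(fm, seed=0)
        tg, vg = train.groups, val.groups
        assert (len(train.values), len(val.values)) == (54, 27)
        assert (tg == CONTROL).sum() == 14 and (tg == CASE).sum() == 40
        assert (vg == CONTROL).sum() == 7 and (vg == CASE).sum() == 20

    def test_disjoint_and_exhaustive(self):
        fm = _fm(9, 11)
        train, val = split_train_val(fm, seed=3)
        ti, vi = set(train.values.index), set(val.values.index)
        assert not ti & vi
        assert ti | vi == set(fm.values.index)

    def test_deterministic_under_seed(self):
        fm = _fm(10, 10)
        a = split_train_val(fm, seed=4)[0].values.index
        b = split_train_val(fm, seed=4)[0].values.index
        assert list(a) == list(b)

    def test_empty_validation_rejected(self):
        fm = _fm(2, 2)
        with pytest.raises(ValueError):
            split_train_val(fm, fraction=1.0)

    def test_tiny_class_rejected(self):
        fm = _fm(1, 10)
        with pytest.raises(ValueError):
            split_train_val(fm)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class TestNetwork:
    def test_separable_problem_reaches_auc_one(self):
        fm = _fm(15, 15, seed=1, shift=0.35)
        train, val = split_train_val(fm, seed=1)
        model = train_nn(train, NetSpec(seed=1, max_epochs=800))
        sf = scores_frame(score(model, val))
        assert roc_auc(sf["score"], sf["group"] == CASE) == 1.0

    def test_loss_decreases_overall(self):
        fm = _fm(12, 12, seed=2, shift=0.2)
        model = train_nn(fm, NetSpec(seed=2, max_epochs=300))
        loss = model.loss_history
        assert loss[-1] < loss[0]

    def test_scores_within_unit_interval(self):
        fm = _fm(10, 10, seed=3, shift=0.1)
        model = train_nn(fm, NetSpec(seed=3, max_epochs=100))
        s = [m.score for m in score(model, fm)]
        assert all(0.0 <= v <= 1.0 for v in s)

    def test_score_invariant_to_column_permutation(self):
        fm = _fm(10, 10, seed=4, shift=0.2)
        model = train_nn(fm, NetSpec(seed=4, max_epochs=200))
        base = [m.score for m in score(model, fm)]
        perm = FeatureMatrix(
            values=fm.values[list(fm.values.columns[::-1])],
            groups=fm.groups, activity=fm.activity,
        )
        np.testing.assert_allclose([m.score for m in score(model, perm)], base)

    def test_training_deterministic(self):
        fm = _fm(8, 8, seed=5, shift=0.2)
        m1 = train_nn(fm, NetSpec(seed=9, max_epochs=150))
        m2 = train_nn(fm, NetSpec(seed=9, max_epochs=150))
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)

    def test_missing_model_region_rejected(self):
        fm = _fm(8, 8, seed=6)
        model = train_nn(fm, NetSpec(seed=0, max_epochs=10))
        smaller = FeatureMatrix(values=fm.values.drop(columns=["r0"]),
                                groups=fm.groups)
        with pytest.raises(ValueError, match="r0"):
            score(model, smaller)

    def test_two_hidden_layer_spec_rejected(self):
        with pytest.raises(ValueError):
            NetSpec(hidden_sizes=(8, 4))


# ---------------------------------------------------------------------------
# ROC AUC
# ---------------------------------------------------------------------------

class TestRocAuc:
    def test_hand_example(self):
        # positives {0.9, 0.8}, negatives {0.1, 0.7}: all 4 pairs won -> 1.0
        assert roc_auc([0.9, 0.8, 0.1, 0.7], [1, 1, 0, 0]) == 1.0

    def test_tie_counts_half(self):
        assert roc_auc([0.5, 0.5], [1, 0]) == 0.5

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=200)
        y = rng.integers(0, 2, size=200)
        y[0], y[1] = 0, 1  # guarantee both classes
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0.1, 0.9, size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        assert roc_auc(s, y) == pytest.approx(roc_auc(np.log(s), y))

    def test_label_flip_complements(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        assert roc_auc(s, y) + roc_auc(s, 1 - y) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


# ---------------------------------------------------------------------------
# Mann-Whitney / Spearman / BH / Fisher
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_complete_separation_3v3(self):
        _, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            u, p = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.3, 1, size=40)
        b = rng.normal(0.0, 1, size=35)
        _, p = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 100, 1000, 10000])
        assert rho == pytest.approx(1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=2.0, size=30)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_nan(self):
        rho, p = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(p)


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03, 0.005]),
            [0.02, 0.04, 0.04, 0.02],
        )

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0


class TestFisherExact:
    def test_matches_scipy(self):
        for table in ([[8, 2], [1, 5]], [[0, 10], [10, 0]], [[3, 3], [3, 3]]):
            ref = sps.fisher_exact(table)[1]
            assert fisher_exact(table) == pytest.approx(ref, abs=1e-12)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])
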