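"""Imputation, moderated t, screening rules and cross-dataset consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cflmd.diff_consensus import (
    consensus_features,
    impute_missing,
    map_probes_to_genes,
    moderated_t_test,
    select_degs,
    select_dmps,
)
from cflmd.io_formats import CASE, CONTROL, BetaMatrix
from cflmd.synthetic_data import SimConfig, simulate_array_cohort


def _beta(values, groups=None, index=None, columns=None):
    df = pd.DataFrame(values, index=index, columns=columns)
    g = None
    if groups is not None:
        g = pd.Series(groups, index=df.columns)
    return BetaMatrix(values=df, groups=g)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

class TestImputeMissing:
    def test_identity_without_missing(self, tiny_beta):
        out = impute_missing(tiny_beta, k=1)
        pd.testing.assert_frame_equal(out.values, tiny_beta.values)

    def test_single_cell_copied_from_nearest_probe(self):
        """Brute-force nearest neighbour over shared observed samples."""
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.2, 0.8, size=(6, 5))
        vals[0, 2] = np.nan
        m = _beta(vals.copy(), index=[f"p{i}" for i in range(6)],
                  columns=[f"s{j}" for j in range(5)])
        out = impute_missing(m, k=1)
        shared = [0, 1, 3, 4]
        dists = [np.sqrt(np.mean((vals[i, shared] - vals[0, shared]) ** 2))
                 for i in range(1, 6)]
        nearest = 1 + int(np.argmin(dists))
        assert out.values.iloc[0, 2] == pytest.approx(vals[nearest, 2])

    def test_k_mean_of_nearest_donors(self):
        vals = np.array([[0.5, np.nan], [0.5, 0.2], [0.5, 0.4], [0.9, 0.9]])
        m = _beta(vals, index=list("abcd"), columns=["s1", "s2"])
        out = impute_missing(m, k=2)
        # probes b and c are equidistant (identical on s1) and nearest
        assert out.values.loc["a", "s2"] == pytest.approx(0.3)

    def test_all_missing_probe_dropped(self, caplog):
        vals = np.array([[np.nan, np.nan], [0.1, 0.2]])
        m = _beta(vals, index=["gone", "kept"], columns=["s1", "s2"])
        with caplog.at_level("WARNING"):
            out = impute_missing(m, k=1)
        assert list(out.values.index) == ["kept"]
        assert "1 probe" in caplog.text

    def test_k_too_large_for_complete_probes(self):
        vals = np.array([[np.nan, 0.5], [0.1, 0.2]])
        m = _beta(vals, index=["a", "b"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="complete probes"):
            impute_missing(m, k=5)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

class TestModeratedT:
    def _cohort(self, seed=0, n=40, per_group=5):
        rng = np.random.default_rng(seed)
        vals = np.clip(rng.normal(0.5, 0.08, size=(n, 2 * per_group)), 0, 1)
        groups = [CONTROL] * per_group + [CASE] * per_group
        return _beta(vals, groups=groups,
                     index=[f"f{i}" for i in range(n)],
                     columns=[f"s{j}" for j in range(2 * per_group)])

    def test_zero_prior_limit_equals_classical_pooled_t(self):
        m = self._cohort(seed=1)
        stats = moderated_t_test(m, prior_df=0)
        case = m.values[m.groups.index[m.groups == CASE]]
        ctrl = m.values[m.groups.index[m.groups == CONTROL]]
        t_ref, p_ref = sps.ttest_ind(case, ctrl, axis=1, equal_var=True)
        np.testing.assert_allclose(stats["t_stat"], t_ref, atol=1e-8)
        np.testing.assert_allclose(stats["p_value"], p_ref, atol=1e-8)

    def test_group_swap_negates_t_keeps_p(self):
        m = self._cohort(seed=2)
        a = moderated_t_test(m)
        b = moderated_t_test(m, case_label=CONTROL, control_label=CASE)
        np.testing.assert_allclose(a["t_stat"], -b["t_stat"], atol=1e-12)
        np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-12)

    def test_null_gaussian_keeps_nominal_rate(self):
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = np.clip(rng.normal(0.5, 0.05, size=(200, 10)), 0, 1)
            m = _beta(vals, groups=[CONTROL] * 5 + [CASE] * 5,
                      index=[f"f{i}" for i in range(200)],
                      columns=[f"s{j}" for j in range(10)])
            rates.append((moderated_t_test(m)["p_value"] < 0.05).mean())
        assert abs(np.mean(rates) - 0.05) < 0.03

    def test_constant_feature_flagged_p_one(self):
        vals = np.array([[0.5] * 6, [0.2, 0.3, 0.25, 0.6, 0.7, 0.65]])
        m = _beta(vals, groups=[CONTROL] * 3 + [CASE] * 3,
                  index=["flat", "real"], columns=list("abcdef"))
        stats = moderated_t_test(m)
        assert stats.loc["flat", "p_value"] == 1.0
        assert bool(stats.loc["flat", "constant"])

    def test_requires_two_samples_per_group(self):
        vals = np.array([[0.1, 0.2, 0.3]])
        m = _beta(vals, groups=[CONTROL, CASE, CASE], index=["f"], columns=list("abc"))
        with pytest.raises(ValueError):
            moderated_t_test(m)


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------

def _stats(rows):
    df = pd.DataFrame(
        rows,
        columns=["feature_id", "mean_case", "mean_control", "sd_case",
                 "sd_control", "t_stat", "p_value"],
    ).set_index("feature_id")
    df["delta"] = df["mean_case"] - df["mean_control"]
    df["direction"] = np.where(df["delta"] >= 0, "up", "down")
    return df


class TestSelectDegs:
    def test_fewer_than_cap_all_returned(self):
        st = _stats([("a", 1, 0, 1, 1, 3.0, 0.01),
                     ("b", 1, 0, 1, 1, 2.5, 0.02),
                     ("c", 0, 1, 1, 1, -2.0, 0.03)])
        up, down = select_degs(st, top_n=1000)
        assert up == {"a", "b"} and down == {"c"}

    def test_ties_broken_by_abs_t_then_id(self):
        st = _stats([("b", 1, 0, 1, 1, 2.0, 0.02),
                     ("a", 1, 0, 1, 1, 2.0, 0.02),
                     ("c", 1, 0, 1, 1, 5.0, 0.02)])
        up, _ = select_degs(st, top_n=2)
        assert up == {"c", "a"}  # larger |t| first, then id

    def test_nothing_significant_empty(self):
        st = _stats([("a", 1, 0, 1, 1, 1.0, 0.5)])
        assert select_degs(st) == (set(), set())


class TestSelectDmps:
    def test_threshold_criteria(self):
        st = _stats([
            ("keep", 0.55, 0.40, 0.20, 0.10, 2, 0.01),   # passes all
            ("small_delta", 0.45, 0.40, 0.1, 0.1, 2, 0.01),  # |d|=0.05
            ("noisy_ctrl", 0.70, 0.40, 0.1, 0.25, 2, 0.01),  # ctrl sd >= 0.2
            ("noisy_case", 0.70, 0.40, 0.35, 0.1, 2, 0.01),  # case sd >= 0.3
        ])
        hyper, hypo = select_dmps(st)
        assert hyper == {"keep"} and hypo == set()

    def test_ranked_by_abs_delta_and_capped(self):
        st = _stats([("a", 0.6, 0.4, 0.1, 0.1, 2, 0.01),
                     ("b", 0.8, 0.4, 0.1, 0.1, 2, 0.01),
                     ("c", 0.7, 0.4, 0.1, 0.1, 2, 0.01)])
        hyper, _ = select_dmps(st, top_n=2)
        assert hyper == {"b", "c"}

    def test_invariant_to_sample_column_order(self):
        cfg = SimConfig(seed=4, n_probes=100, n_true_hypo=10, n_true_hyper=5)
        beta, _, _ = simulate_array_cohort(cfg)
        stats1 = moderated_t_test(beta)
        rng = np.random.default_rng(0)
        perm = rng.permutation(beta.values.columns)
        shuffled = BetaMatrix(values=beta.values[perm], groups=beta.groups[perm])
        stats2 = moderated_t_test(shuffled)
        assert select_dmps(stats1) == select_dmps(stats2)


class TestConsensus:
    def test_three_of_five_same_direction_selected(self):
        sels = [({"f"}, set())] * 3 + [(set(), set())] * 2
        res = consensus_features(sels, min_datasets=3)
        assert res.selected_up == {"f"}

    def test_conflicting_directions_never_selected(self):
        sels = [({"f"}, set())] * 2 + [(set(), {"f"})] * 2
        res = consensus_features(sels, min_datasets=3)
        assert "f" in res.conflicting and not res.selected

    def test_single_dataset_identity(self):
        res = consensus_features([({"a"}, {"b"})], min_datasets=1)
        assert res.selected_up == {"a"} and res.selected_down == {"b"}

    def test_min_datasets_exceeding_inputs_rejected(self):
        with pytest.raises(ValueError):
            consensus_features([({"a"}, set())], min_datasets=3)

    def test_invariant_to_dataset_order(self):
        sels = [({"a", "b"}, set()), ({"a"}, {"c"}), ({"a", "b"}, {"c"}),
                (set(), {"c"})]
        r1 = consensus_features(sels, min_datasets=3)
        r2 = consensus_features(sels[::-1], min_datasets=3)
        assert r1.selected == r2.selected


class TestMapProbesToGenes:
    def test_shared_gene_deduplicated(self, simple_annotation):
        assert map_probes_to_genes({"p1", "p2"}, simple_annotation) == {"GENEA"}

    def test_unannotated_probe_dropped(self, simple_annotation):
        assert map_probes_to_genes({"p4"}, simple_annotation) == set()

    def test_disjoint_genes_preserved(self, simple_annotation):
        assert map_probes_to_genes({"p1", "p3"}, simple_annotation) == {"GENEA", "GENEB"}
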