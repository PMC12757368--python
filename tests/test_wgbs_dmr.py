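"""Smoothing, beta-binomial Wald testing, DMR merging and augmentation."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportions_ztest

from cflmd.io_formats import CASE, CONTROL
from cflmd.synthetic_data import SimConfig, simulate_wgbs_cohort
from cflmd.wgbs_dmr import (
    HYPER,
    HYPO,
    augment_subsamples,
    bb_wald_test,
    call_dmps,
    call_dmrs,
    smooth_methylation,
)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

class TestSmoothing:
    def test_window_zero_returns_raw_fractions(self, count_table_factory):
        t = count_table_factory([("chr1", 100, 10, 3), ("chr1", 110, 20, 10)])
        np.testing.assert_allclose(smooth_methylation(t, window_bp=0), [0.3, 0.5])

    def test_neighbours_pool_coverage_weighted(self, count_table_factory):
        # both sites inside each other's 500bp window: pooled ratio 13/30
        t = count_table_factory([("chr1", 100, 10, 3), ("chr1", 200, 20, 10)])
        np.testing.assert_allclose(smooth_methylation(t), [13 / 30, 13 / 30])

    def test_distant_sites_stay_independent(self, count_table_factory):
        t = count_table_factory([("chr1", 100, 10, 3), ("chr1", 5000, 20, 10)])
        np.testing.assert_allclose(smooth_methylation(t), [0.3, 0.5])

    def test_chromosomes_never_mix(self, count_table_factory):
        t = count_table_factory([("chr1", 100, 10, 0), ("chr2", 100, 10, 10)])
        np.testing.assert_allclose(smooth_methylation(t), [0.0, 1.0])


# ---------------------------------------------------------------------------
# beta-binomial Wald test
# ---------------------------------------------------------------------------

class TestBbWald:
    def test_identical_groups_give_zero_delta_p_one(self, count_table_factory):
        rows = [("chr1", 100 * i, 30, 10) for i in range(1, 20)]
        case = count_table_factory(rows, sample_id="c1", group=CASE)
        ctrl = count_table_factory(rows, sample_id="n1", group=CONTROL)
        res = bb_wald_test([case], [ctrl])
        np.testing.assert_allclose(res["delta"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p_value"], 1.0)

    def test_single_samples_match_pooled_two_proportion_z(self, count_table_factory):
        """Independent oracle: with one sample per group and isolated sites the
        Wald statistic must equal the classical pooled two-proportion z."""
        rng = np.random.default_rng(0)
        rows_case, rows_ctrl = [], []
        for i in range(30):
            pos = 10_000 * (i + 1)  # far apart: smoothing is a no-op
            n1, n0 = 200, 150
            k1 = int(rng.binomial(n1, 0.5))
            k0 = int(rng.binomial(n0, 0.35))
            rows_case.append(("chr1", pos, n1, k1))
            rows_ctrl.append(("chr1", pos, n0, k0))
        case = count_table_factory(rows_case, sample_id="c1", group=CASE)
        ctrl = count_table_factory(rows_ctrl, sample_id="n1", group=CONTROL)
        res = bb_wald_test([case], [ctrl], shrinkage_m=0)
        for i in range(30):
            k1, n1 = rows_case[i][3], rows_case[i][2]
            k0, n0 = rows_ctrl[i][3], rows_ctrl[i][2]
            z_ref, p_ref = proportions_ztest([k1, k0], [n1, n0])
            assert res["wald_stat"].iloc[i] == pytest.approx(z_ref, abs=1e-3)
            assert res["p_value"].iloc[i] == pytest.approx(p_ref, abs=1e-3)

    def test_null_false_positive_rate_at_most_nominal(self):
        """Dispersion-aware test must not exceed the nominal rate under the
        null (it is conservative by construction)."""
        rates = []
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_control=3, n_case=3, n_cpgs=300,
                            effect_size=0.0, n_true_hypo=0, n_true_hyper=0)
            tables, _ = simulate_wgbs_cohort(cfg)
            cases = [t for t in tables if t.group == CASE]
            ctrls = [t for t in tables if t.group == CONTROL]
            res = bb_wald_test(cases, ctrls)
            rates.append((res["p_value"] < 0.01).mean())
        assert np.mean(rates) <= 0.02

    def test_table_order_within_group_is_irrelevant(self):
        cfg = SimConfig(seed=9, n_control=3, n_case=3, n_cpgs=150)
        tables, _ = simulate_wgbs_cohort(cfg)
        cases = [t for t in tables if t.group == CASE]
        ctrls = [t for t in tables if t.group == CONTROL]
        r1 = bb_wald_test(cases, ctrls)
        r2 = bb_wald_test(cases[::-1], ctrls[::-1])
        pd.testing.assert_frame_equal(r1, r2)

    def test_empty_group_rejected(self, count_table_factory):
        t = count_table_factory([("chr1", 100, 10, 5)])
        with pytest.raises(ValueError):
            bb_wald_test([t], [])


# ---------------------------------------------------------------------------
# DMP / DMR calling
# ---------------------------------------------------------------------------

def _dmp_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "delta", "p_value"]).assign(
        pi_case=0.5, pi_control=0.5, wald_stat=0.0
    )


class TestCallDmps:
    def test_thresholds_are_strict(self):
        rec = _dmp_frame([
            ("chr1", 100, 0.25, 0.005),   # in
            ("chr1", 200, 0.20, 0.005),   # |delta| not > 0.2
            ("chr1", 300, 0.25, 0.010),   # p not < 0.01
        ])
        out = call_dmps(rec)
        assert list(out["pos"]) == [100]

    def test_sign_irrelevant(self):
        rec = _dmp_frame([("chr1", 100, -0.4, 1e-4), ("chr1", 200, 0.4, 1e-4)])
        assert len(call_dmps(rec)) == 2

    def test_empty_input_empty_output(self):
        assert call_dmps(_dmp_frame([])).empty


class TestCallDmrs:
    def _run(self, n, start=1000, gap=100, delta=-0.3, p=1e-6, chrom="chr1"):
        return [(chrom, start + i * gap, delta, p) for i in range(n)]

    def test_six_dmp_run_becomes_region(self):
        regions = call_dmrs(_dmp_frame(self._run(6)))
        assert len(regions) == 1
        r = regions[0]
        assert (r.chrom, r.start, r.end, r.n_dmps) == ("chr1", 1000, 1500, 6)
        assert r.direction == HYPO and r.region_p < 0.05

    def test_five_dmp_run_too_small(self):
        assert call_dmrs(_dmp_frame(self._run(5))) == []

    def test_large_gap_splits_run(self):
        rows = self._run(6) + self._run(6, start=1500 + 50_000)
        regions = call_dmrs(_dmp_frame(rows))
        assert len(regions) == 2

    def test_direction_change_splits_run(self):
        rows = self._run(6) + self._run(6, start=1600, delta=+0.3)
        regions = call_dmrs(_dmp_frame(rows))
        assert {r.direction for r in regions} == {HYPO, HYPER}
        assert all(r.n_dmps == 6 for r in regions)

    def test_weak_member_p_values_fail_region_filter(self):
        regions = call_dmrs(_dmp_frame(self._run(6, p=0.6)))
        assert regions == []

    def test_chromosomes_do_not_merge(self):
        rows = self._run(3) + self._run(3, chrom="chr2")
        assert call_dmrs(_dmp_frame(rows)) == []


# ---------------------------------------------------------------------------
# subsample augmentation
# ---------------------------------------------------------------------------

class TestAugment:
    def _parents(self, count_table_factory):
        rows = [("chr1", 100 * i, 30, 12) for i in range(1, 50)]
        ctrls = [count_table_factory(rows, sample_id=f"n{i}", group=CONTROL)
                 for i in range(3)]
        cases = [count_table_factory(rows, sample_id=f"c{i}", group=CASE)
                 for i in range(3)]
        return ctrls + cases

    def test_canonical_21_plus_60(self, count_table_factory):
        subs = augment_subsamples(self._parents(count_table_factory), seed=1)
        groups = [t.group for t in subs]
        assert groups.count(CONTROL) == 21 and groups.count(CASE) == 60

    def test_thin_fraction_one_is_identity(self, count_table_factory):
        parent = count_table_factory([("chr1", 100, 30, 12)], group=CASE)
        subs = augment_subsamples([parent], reps_case=2, thin_fraction=1.0, seed=0)
        for s in subs:
            pd.testing.assert_frame_equal(s.records, parent.records)

    def test_deterministic_under_seed(self, count_table_factory):
        parents = self._parents(count_table_factory)
        a = augment_subsamples(parents, seed=5)
        b = augment_subsamples(parents, seed=5)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.records, y.records)
            assert x.sample_id == y.sample_id

    def test_mean_coverage_close_to_thinned_parent(self, count_table_factory):
        parents = self._parents(count_table_factory)
        subs = augment_subsamples(parents, thin_fraction=0.5, seed=2)
        mean_cov = np.mean([s.records["n_total"].mean() for s in subs])
        assert mean_cov == pytest.approx(15.0, rel=0.05)

    def test_bad_thin_fraction_rejected(self, count_table_factory):
        parent = count_table_factory([("chr1", 100, 10, 5)])
        with pytest.raises(ValueError):
            augment_subsamples([parent], thin_fraction=0.0)
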