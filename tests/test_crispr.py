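"""Adjacent-cluster Welch tests, scans and q-value adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import multisep as ms
from multisep.clustering import ClusterModel
from multisep.errors import ConfigError, NotTestableError, TissueTooSmallError
from multisep.stats import bh_qvalues, storey_qvalues, welch_from_samples


def _model(assignments: dict[str, int], gene="G") -> ClusterModel:
    s = pd.Series(assignments, dtype=int)
    k = int(s.max())
    return ClusterModel(
        gene=gene, k=k, means=np.arange(k, dtype=float),
        variances=np.ones(k), weights=np.full(k, 1.0 / k),
        assignments=s, bic_by_k={}, n_cells=len(s),
    )


class TestTestPair:
    def test_identical_groups_not_significant(self, rng):
        model = _model({f"c{i}": 1 + i // 4 for i in range(8)})
        scores = pd.Series(
            -0.5 + rng.normal(0, 1e-6, 8), index=[f"c{i}" for i in range(8)]
        )
        res = ms.test_pair(model, scores)
        assert abs(res.effect) < 1e-3
        assert res.p > 0.9

    def test_strong_shift_detected_with_welch_oracle(self, rng):
        model = _model({f"c{i}": 1 if i < 10 else 2 for i in range(20)})
        lo = -1.0 + rng.normal(0, 0.05, 10)
        hi = 0.0 + rng.normal(0, 0.05, 10)
        scores = pd.Series(np.r_[lo, hi], index=[f"c{i}" for i in range(20)])
        res = ms.test_pair(model, scores)
        assert res.effect == pytest.approx(hi.mean() - lo.mean(), abs=1e-12)
        assert res.effect == pytest.approx(1.0, abs=0.1)
        assert res.p < 1e-10
        t_ref, p_ref = sps.ttest_ind(lo, hi, equal_var=False)
        assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_three_clusters_reports_differing_adjacent_pair(self, rng):
        labels = {f"c{i}": 1 + i // 10 for i in range(30)}
        model = _model(labels)
        vals = np.r_[rng.normal(0, 0.05, 10), rng.normal(0, 0.05, 10),
                     rng.normal(2, 0.05, 10)]
        scores = pd.Series(vals, index=list(labels))
        res = ms.test_pair(model, scores)
        assert (res.cluster_lo, res.cluster_hi) == (2, 3)
        # brute force over adjacent pairs confirms the selection
        ps = {}
        for lo in (1, 2):
            a = vals[(lo - 1) * 10: lo * 10]
            b = vals[lo * 10: (lo + 1) * 10]
            ps[lo] = sps.ttest_ind(a, b, equal_var=False).pvalue
        assert min(ps, key=ps.get) == 2

    def test_small_groups_not_testable(self):
        model = _model({"a": 1, "b": 1, "c": 2, "d": 2})
        scores = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("abcd"))
        with pytest.raises(NotTestableError):
            ms.test_pair(model, scores, min_group=3)

    def test_antisymmetry_of_effect(self, rng):
        lo = rng.normal(-1, 0.2, 12)
        hi = rng.normal(0, 0.2, 12)
        idx = [f"c{i}" for i in range(24)]
        fwd = _model({c: 1 if i < 12 else 2 for i, c in enumerate(idx)})
        rev = _model({c: 2 if i < 12 else 1 for i, c in enumerate(idx)})
        scores = pd.Series(np.r_[lo, hi], index=idx)
        r1 = ms.test_pair(fwd, scores)
        r2 = ms.test_pair(rev, scores)
        assert r1.effect == pytest.approx(-r2.effect, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)


class TestWelchOracle:
    def test_matches_textbook_formula_on_random_instances(self, rng):
        for _ in range(20):
            x = rng.normal(rng.normal(), rng.uniform(0.5, 2), rng.integers(4, 30))
            y = rng.normal(rng.normal(), rng.uniform(0.5, 2), rng.integers(4, 30))
            t, df, p = welch_from_samples(x, y)
            ref = sps.ttest_ind(y, x, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestQValues:
    def test_all_ones(self):
        np.testing.assert_array_equal(ms.compute_qvalues([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_bh_hand_computed_step_up(self):
        q = ms.compute_qvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_bh_matches_statsmodels(self, rng):
        p = rng.uniform(size=200)
        q = bh_qvalues(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_qvalues(p)[perm], bh_qvalues(p[perm]), atol=1e-12)
        np.testing.assert_allclose(
            storey_qvalues(p)[perm], storey_qvalues(p[perm]), atol=1e-12
        )

    def test_storey_no_larger_than_bh(self, rng):
        p = np.r_[rng.uniform(0, 0.001, 20), rng.uniform(size=480)]
        assert (storey_qvalues(p) <= bh_qvalues(p) + 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ms.compute_qvalues([0.5, 1.5])

    def test_q_at_least_p_under_bh(self, rng):
        p = rng.uniform(size=100)
        assert (bh_qvalues(p) >= p - 1e-12).all()


class TestScan:
    def test_planted_pairs_pass_thresholds_and_rank_high(self, bench_data):
        ds, truth, models = bench_data
        tbl = ms.scan_crispr(ds, models=models)
        found = set(zip(tbl["mRNA_gene"], tbl["crispr_gene"]))
        planted = {(a, b) for a, b, _ in truth.planted_crispr_pairs}
        assert planted <= found
        full = ms.scan_crispr(ds, models=models, include_unfiltered=True)
        ranked = full.sort_values("q_value")
        top = int(np.ceil(0.01 * len(ranked)))
        top_pairs = set(zip(ranked["mRNA_gene"].head(top), ranked["crispr_gene"].head(top)))
        assert planted <= top_pairs

    def test_effect_min_infinity_empties_table(self, bench_data):
        ds, _, models = bench_data
        tbl = ms.scan_crispr(ds, models=models, effect_min=np.inf)
        assert len(tbl) == 0

    def test_tiny_tissue_rejected(self, bench_data):
        ds, _, _ = bench_data
        tissues = ds.tissues.copy()
        tissues.iloc[:] = "bulk"
        tissues.iloc[:2] = "tiny"
        ds2 = ms.Dataset(expression=ds.expression, tissues=tissues, crispr=ds.crispr)
        with pytest.raises(TissueTooSmallError):
            ms.scan_crispr(ds2, tissue="tiny")

    def test_missing_crispr_matrix(self, bench_data):
        ds, _, _ = bench_data
        ds2 = ms.Dataset(expression=ds.expression, tissues=ds.tissues)
        with pytest.raises(ConfigError):
            ms.scan_crispr(ds2)

    def test_q_computed_before_filtering(self, bench_data):
        """Filtered table q-values equal those from the full tested table."""
        ds, _, models = bench_data
        filtered = ms.scan_crispr(ds, models=models)
        full = ms.scan_crispr(ds, models=models, include_unfiltered=True)
        merged = filtered.merge(
            full, on=["mRNA_gene", "crispr_gene"], suffixes=("", "_full")
        )
        np.testing.assert_allclose(merged["q_value"], merged["q_value_full"], atol=1e-12)
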