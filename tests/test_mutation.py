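"""Chi-squared mutation enrichment across expression clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import multisep as ms
from multisep.clustering import ClusterModel
from multisep.errors import ConfigError, NotTestableError
from multisep.mutation import chi2_independence, collapse_statuses


def _model(assignments: dict[str, int], gene="G") -> ClusterModel:
    s = pd.Series(assignments, dtype=int)
    k = int(s.max())
    return ClusterModel(
        gene=gene, k=k, means=np.arange(k, dtype=float),
        variances=np.ones(k), weights=np.full(k, 1.0 / k),
        assignments=s, bic_by_k={}, n_cells=len(s),
    )


def _statuses(model, mutated_lines):
    return pd.Series(
        ["missense" if c in mutated_lines else "wild-type" for c in model.assignments.index],
        index=model.assignments.index,
    )


def _chi2_oracle(table):
    """Explicit (o-e)^2/e summation + upper-tail chi-squared CDF."""
    table = np.asarray(table, dtype=float)
    row = table.sum(1, keepdims=True)
    col = table.sum(0, keepdims=True)
    expected = row @ col / table.sum()
    chi2 = ((table - expected) ** 2 / expected).sum()
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, dof, sps.chi2.sf(chi2, dof)


class TestTestMutationPair:
    def test_balanced_mutants_give_zero_statistic(self):
        model = _model({f"c{i}": 1 if i < 10 else 2 for i in range(20)})
        mutated = {f"c{i}" for i in list(range(5)) + list(range(10, 15))}
        res = ms.test_mutation_pair(model, _statuses(model, mutated))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_nine_vs_one_hand_computed(self):
        # 2 clusters of 10; 9 mutants in cluster 1, 1 in cluster 2:
        # all expected counts are 5, chi2 = sum (o-5)^2/5 = 12.8
        model = _model({f"c{i}": 1 if i < 10 else 2 for i in range(20)})
        mutated = {f"c{i}" for i in list(range(9)) + [10]}
        res = ms.test_mutation_pair(model, _statuses(model, mutated))
        assert res.chi2 == pytest.approx(12.8, abs=1e-9)
        assert res.p == pytest.approx(sps.chi2.sf(12.8, 1), abs=1e-9)
        assert res.p == pytest.approx(3.5e-4, rel=0.02)

    def test_fewer_than_five_mutations_not_testable(self):
        model = _model({f"c{i}": 1 if i < 10 else 2 for i in range(20)})
        with pytest.raises(NotTestableError):
            ms.test_mutation_pair(model, _statuses(model, {"c0", "c1", "c2", "c3"}))

    def test_all_mutated_not_testable(self):
        model = _model({f"c{i}": 1 if i < 10 else 2 for i in range(20)})
        everyone = {f"c{i}" for i in range(20)}
        with pytest.raises(NotTestableError):
            ms.test_mutation_pair(model, _statuses(model, everyone))

    def test_cluster_label_permutation_invariance(self):
        fwd = _model({f"c{i}": 1 + i // 10 for i in range(30)})
        rev = _model({f"c{i}": 3 - i // 10 for i in range(30)})
        mutated = {f"c{i}" for i in range(8)}
        a = ms.test_mutation_pair(fwd, _statuses(fwd, mutated))
        b = ms.test_mutation_pair(rev, _statuses(rev, mutated))
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_binary_two_clusters_equals_squared_z(self):
        model = _model({f"c{i}": 1 if i < 12 else 2 for i in range(30)})
        mutated = {f"c{i}" for i in list(range(7)) + [14, 15]}
        res = ms.test_mutation_pair(model, _statuses(model, mutated))
        x1, n1 = 7, 12
        x2, n2 = 2, 18
        p_pool = (x1 + x2) / (n1 + n2)
        z = (x1 / n1 - x2 / n2) / np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        assert res.chi2 == pytest.approx(z**2, abs=1e-8)

    def test_by_class_mode_builds_class_table(self):
        model = _model({f"c{i}": 1 if i < 10 else 2 for i in range(20)})
        statuses = _statuses(model, set())
        statuses.iloc[:4] = "missense"
        statuses.iloc[10:13] = "nonsense"
        res = ms.test_mutation_pair(model, statuses, mode="by_class")
        assert res.n_mutations == 7
        assert "wild-type" in res.counts.columns


class TestChi2Oracle:
    def test_matches_explicit_summation_on_random_tables(self, rng):
        for _ in range(20):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 4)))
            table = rng.integers(1, 40, size=shape)
            chi2, dof, p, _ = chi2_independence(table, warn_low_expected=False)
            c_ref, d_ref, p_ref = _chi2_oracle(table)
            assert chi2 == pytest.approx(c_ref, abs=1e-8)
            assert dof == d_ref
            assert p == pytest.approx(p_ref, abs=1e-8)


class TestCollapse:
    def test_multiple_records_count_once_with_most_deleterious(self):
        mutations = pd.DataFrame({
            "cell_line": ["A", "A", "B"],
            "gene": ["X", "X", "X"],
            "mutation_class": ["missense", "nonsense", "splice_site"],
        })
        status = collapse_statuses(mutations, "X", pd.Index(["A", "B", "C"]))
        assert status["A"] == "nonsense"
        assert status["B"] == "splice_site"
        assert status["C"] == "wild-type"


class TestScan:
    def test_planted_exclusivity_recovered_in_top_ranks(self, bench_data):
        ds, truth, models = bench_data
        genes = [m for _, m, _ in truth.planted_mutation_pairs]
        tbl = ms.scan_mutations(ds, mutation_genes=genes, models=models)
        found = set(zip(tbl["mRNA_gene"], tbl["mutation_gene"]))
        planted = {(a, m) for a, m, _ in truth.planted_mutation_pairs}
        assert planted <= found
        full = ms.scan_mutations(
            ds, mutation_genes=genes, models=models, include_unfiltered=True
        )
        ranked = full.sort_values("q_value")
        top = int(np.ceil(0.01 * len(ranked))) + len(planted)
        top_pairs = set(zip(ranked["mRNA_gene"].head(top), ranked["mutation_gene"].head(top)))
        assert planted <= top_pairs

    def test_retained_rows_satisfy_thresholds(self, bench_data):
        ds, truth, models = bench_data
        genes = [m for _, m, _ in truth.planted_mutation_pairs]
        tbl = ms.scan_mutations(ds, mutation_genes=genes, models=models)
        assert (tbl["p_value"] < 0.05).all()
        assert (tbl["n_mutations"] >= 5).all()

    def test_unknown_gene_skipped_with_warning(self, bench_data, caplog):
        ds, truth, models = bench_data
        genes = [truth.planted_mutation_pairs[0][1], "NOT_A_GENE"]
        with caplog.at_level("WARNING"):
            tbl = ms.scan_mutations(ds, mutation_genes=genes, models=models)
        assert "NOT_A_GENE" in caplog.text
        assert set(tbl["mutation_gene"]) <= {genes[0]}

    def test_empty_gene_list_rejected(self, bench_data):
        ds, _, _ = bench_data
        with pytest.raises(ConfigError):
            ms.scan_mutations(ds, mutation_genes=[])
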