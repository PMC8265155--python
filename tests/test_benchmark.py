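"""Gold standards, AUROC / DeLong machinery and FDR estimation."""

import numpy as np
import pandas as pd
import pytest

import multisep as ms
from multisep.benchmark import GoldStandardSet
from multisep.errors import EmptyGoldStandardError
from multisep.stats import auroc, bootstrap_auroc_test, delong_test, roc_points


def _auroc_oracle(scores, labels):
    """Exhaustive concordant-pair fraction with ties at half weight."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _gold(pairs):
    return GoldStandardSet(
        pairs=pd.DataFrame(pairs, columns=["gene_a", "gene_b", "label"]),
        positive_threshold=0.7, seed=0, balance=1.0,
    )


class TestBuildGoldStandard:
    def _db(self):
        return pd.DataFrame({
            "gene_a": ["A", "C"], "gene_b": ["B", "D"], "score": [0.8, 0.6],
        })

    def _predictions(self, genes=("A", "B", "C", "D", "E", "F", "G", "H")):
        return {frozenset(p): 1.0 for p in
                [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]}

    def test_threshold_selects_positives(self):
        gold = ms.build_gold_standard(self._db(), 0.7, self._predictions(), seed=1)
        pos = gold.pairs[gold.pairs["label"] == "positive"]
        assert set(map(tuple, pos[["gene_a", "gene_b"]].to_numpy())) == {("A", "B")}

    def test_balanced_counts_equal(self):
        db = pd.DataFrame({
            "gene_a": list("ABCDE"), "gene_b": list("FGHIJ"), "score": [0.9] * 5,
        })
        preds = self._predictions(tuple("ABCDEFGHIJKL"))
        gold = ms.build_gold_standard(db, 0.7, preds, balanced=True, seed=2)
        counts = gold.pairs["label"].value_counts()
        assert counts["positive"] == counts["negative"] == 5

    def test_negatives_absent_from_database_at_any_score(self):
        gold = ms.build_gold_standard(self._db(), 0.7, self._predictions(), seed=3)
        db_pairs = {frozenset(("A", "B")), frozenset(("C", "D"))}
        for row in gold.pairs[gold.pairs["label"] == "negative"].itertuples():
            assert frozenset((row.gene_a, row.gene_b)) not in db_pairs

    def test_same_seed_same_negatives(self):
        g1 = ms.build_gold_standard(self._db(), 0.7, self._predictions(), seed=7)
        g2 = ms.build_gold_standard(self._db(), 0.7, self._predictions(), seed=7)
        pd.testing.assert_frame_equal(g1.pairs, g2.pairs)

    def test_no_positive_after_intersection_raises(self):
        with pytest.raises(EmptyGoldStandardError):
            ms.build_gold_standard(self._db(), 0.95, self._predictions(), seed=1)


class TestAuroc:
    def test_perfect_separation(self):
        scores = np.r_[np.ones(5), np.zeros(5)]
        labels = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        assert auroc(scores, labels) == 1.0

    def test_label_independent_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert auroc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_hand_chosen_scores_with_tie(self):
        scores = np.array([0.9, 0.8, 0.8, 0.4, 0.3, 0.1])
        labels = np.array([True, True, False, False, True, False])
        assert auroc(scores, labels) == pytest.approx(_auroc_oracle(scores, labels), abs=1e-12)

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 100))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert auroc(scores, labels) == pytest.approx(
                _auroc_oracle(scores, labels), abs=1e-12
            )

    def test_roc_points_monotone(self, rng):
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.3
        pts = roc_points(scores, labels)
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.5
        _, _, p = delong_test(scores, scores, labels)
        assert p == 1.0

    def test_perfect_vs_random_significant(self, rng):
        labels = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        perfect = labels.astype(float) + rng.normal(0, 0.01, 200)
        random_scores = rng.normal(size=200)
        _, _, p = delong_test(perfect, random_scores, labels)
        assert p < 0.01

    def test_agrees_with_bootstrap_on_mid_effect(self, rng):
        labels = rng.random(300) < 0.5
        signal = labels.astype(float)
        a = signal + rng.normal(0, 1.2, 300)
        b = rng.normal(size=300)
        _, _, p_delong = delong_test(a, b, labels)
        p_boot = bootstrap_auroc_test(a, b, labels, n_boot=2000, seed=4)
        assert p_delong == pytest.approx(p_boot, abs=0.02)

    def test_placement_values_match_brute_force(self, rng):
        """DeLong V10/V01 placements equal their defining pair fractions."""
        from multisep.stats import _midrank_structure

        for _ in range(20):
            pos = rng.normal(1, 1, int(rng.integers(4, 15)))
            neg = rng.normal(0, 1, int(rng.integers(4, 15)))
            v10, v01, auc = _midrank_structure(pos, neg)
            for i, x in enumerate(pos):
                frac = np.mean([1.0 if x > y else 0.5 if x == y else 0.0 for y in neg])
                assert v10[i] == pytest.approx(frac, abs=1e-10)
            for j, y in enumerate(neg):
                frac = np.mean([1.0 if x > y else 0.5 if x == y else 0.0 for x in pos])
                assert v01[j] == pytest.approx(frac, abs=1e-10)
            assert auc == pytest.approx(_auroc_oracle(
                np.r_[pos, neg], np.r_[np.ones(len(pos), bool), np.zeros(len(neg), bool)]
            ), abs=1e-10)


class TestFdr:
    def _scored_gold(self, rng, n=400, informative=True):
        labels = rng.random(n) < 0.5
        scores = labels * 2.0 + rng.normal(0, 1, n) if informative else rng.normal(0, 1, n)
        pairs = [(f"a{i}", f"b{i}", "positive" if l else "negative")
                 for i, l in enumerate(labels)]
        gold = _gold(pairs)
        lookup = {frozenset((f"a{i}", f"b{i}")): float(s) for i, s in enumerate(scores)}
        return lookup, gold

    def test_only_true_positives_above_threshold(self, rng):
        lookup, gold = self._scored_gold(rng)
        # push positives far above everything else
        for k in list(lookup):
            pass
        labels = gold.labels
        for i, row in gold.pairs.iterrows():
            key = frozenset((row["gene_a"], row["gene_b"]))
            lookup[key] = 10.0 if row["label"] == "positive" else 0.0
        assert ms.estimate_fdr(lookup, gold, 5.0, prevalence=0.0375) == 0.0

    def test_label_independence_gives_prevalence_complement(self, rng):
        lookup, gold = self._scored_gold(rng, n=2000, informative=False)
        fdr = ms.estimate_fdr(lookup, gold, 0.0, prevalence=0.0375)
        assert fdr == pytest.approx(0.9625, abs=0.02)

    def test_monotone_in_threshold_on_planted_signal(self, rng):
        lookup, gold = self._scored_gold(rng)
        grid = [-1.0, 0.0, 0.5, 1.0, 1.5, 2.0]
        fdrs = [ms.estimate_fdr(lookup, gold, t, prevalence=0.0375) for t in grid]
        fdrs = [f for f in fdrs if not np.isnan(f)]
        assert all(a >= b - 1e-12 for a, b in zip(fdrs, fdrs[1:]))

    def test_resample_mode_close_to_reweight(self, rng):
        lookup, gold = self._scored_gold(rng, n=2000)
        a = ms.estimate_fdr(lookup, gold, 1.0, prevalence=0.0375, mode="reweight")
        b = ms.estimate_fdr(lookup, gold, 1.0, prevalence=0.0375, mode="resample", seed=3)
        assert b == pytest.approx(a, abs=0.1)

    def test_nothing_above_threshold_is_nan(self, rng):
        lookup, gold = self._scored_gold(rng, n=50)
        assert np.isnan(ms.estimate_fdr(lookup, gold, 1e9, prevalence=0.0375))


class TestCompareAurocs:
    def test_equal_scores_p_one(self, rng):
        lookup = {frozenset((f"a{i}", f"b{i}")): float(rng.normal()) for i in range(50)}
        pairs = [(f"a{i}", f"b{i}", "positive" if i % 2 else "negative") for i in range(50)]
        assert ms.compare_aurocs(lookup, lookup, _gold(pairs)) == 1.0

    def test_missing_scores_listed(self):
        pairs = [("A", "B", "positive"), ("C", "D", "negative")]
        gold = _gold(pairs)
        with pytest.raises(ValueError, match="no score"):
            ms.compute_roc({frozenset(("A", "B")): 1.0}, gold)
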