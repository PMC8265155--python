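"""Gold-standard construction, AUROC evaluation and FDR estimation.

Positives come from a SynLethDB-format score table: pairs scoring above a
confidence threshold (0.7 for high confidence, 0.1 for low) that also have
a prediction from the method under evaluation. Negatives are *resampled*:
gene pairs drawn uniformly from the prediction universe that never appear
in the database at any score. Resampled negatives may contain unannotated
true dependencies, but true pairs are rare so the contamination is a tiny
fraction; on synthetic data the generator's truth ledger quantifies it
exactly.

Method scores are compared by AUROC — the probability a random positive
outranks a random negative, computed as the normalised Mann-Whitney U —
with DeLong's paired test for AUROC differences (a paired bootstrap is
available as a cross-check). FDR is estimated on the thresholded prediction
set after re-weighting (default, deterministic) or re-sampling the classes
to a chosen prevalence; the "real-world" prevalence default is 0.0375,
matching the frequency of negative genetic dependencies in large-scale
yeast interaction screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyGoldStandardError
from .stats import auroc, bootstrap_auroc_test, delong_test, roc_points

logger = logging.getLogger(__name__)

REAL_WORLD_PREVALENCE = 0.0375


def _key(a: str, b: str) -> frozenset:
    return frozenset((a, b))


@dataclass
class GoldStandardSet:
    """Labelled unordered gene pairs for benchmarking.

    ``pairs`` rows are (gene_a, gene_b, label) with label in
    {"positive", "negative"}; negatives are always resampled pairs absent
    from the source database at any score.
    """

    pairs: pd.DataFrame
    positive_threshold: float
    seed: int
    balance: float  # positives / negatives ratio
    negative_source: str = "resampled"

    @property
    def labels(self) -> np.ndarray:
        return (self.pairs["label"] == "positive").to_numpy()

    def scores_for(self, scored: dict[frozenset, float]) -> np.ndarray:
        """Look up a score per gold pair; missing pairs raise with a listing."""
        vals, missing = [], []
        for a, b in zip(self.pairs["gene_a"], self.pairs["gene_b"]):
            k = _key(a, b)
            if k in scored:
                vals.append(scored[k])
            else:
                missing.append((a, b))
        if missing:
            raise ValueError(f"no score for {len(missing)} gold pairs, e.g. {missing[:5]}")
        return np.asarray(vals, dtype=float)


@dataclass
class BenchmarkResult:
    method: str
    n_pairs: int
    auroc: float
    roc_points: np.ndarray
    auroc_comparison_p: float | None = None
    fdr_at_threshold: dict = field(default_factory=dict)
    prevalence: float | None = None


def scores_to_dict(table: pd.DataFrame, score_col: str = "score") -> dict[frozenset, float]:
    """Convert a (gene_a, gene_b, score) table to a symmetric-pair lookup.

    Duplicated unordered pairs keep their maximum score.
    """
    out: dict[frozenset, float] = {}
    cols = list(table.columns)
    a_col = "gene_a" if "gene_a" in cols else cols[0]
    b_col = "gene_b" if "gene_b" in cols else cols[1]
    for a, b, s in zip(table[a_col], table[b_col], table[score_col]):
        k = _key(str(a), str(b))
        out[k] = max(out.get(k, -np.inf), float(s))
    return out


def multisep_scores(
    dataset,
    models: dict | None = None,
    mutation_genes: list[str] | None = None,
    seed: int = 0,
) -> dict[frozenset, float]:
    """Pairwise -log10 p prediction scores from the clustering-based tests.

    Every (mRNA gene, CRISPR gene) pair tested by the CRISPR scan receives
    its -log10 p; when ``mutation_genes`` is given, mutation-enrichment
    -log10 p scores are added and an unordered pair covered by both tests
    keeps the larger score.
    """
    from .crispr import scan_crispr
    from .mutation import scan_mutations

    tbl = scan_crispr(dataset, models=models, seed=seed, include_unfiltered=True)
    tbl = tbl.assign(score=-np.log10(tbl["p_value"].clip(lower=1e-300)))
    scores = scores_to_dict(
        tbl.rename(columns={"mRNA_gene": "gene_a", "crispr_gene": "gene_b"})
    )
    if mutation_genes:
        mtbl = scan_mutations(
            dataset, mutation_genes=mutation_genes, models=models,
            seed=seed, include_unfiltered=True,
        )
        if len(mtbl):
            mtbl = mtbl.assign(score=-np.log10(mtbl["p_value"].clip(lower=1e-300)))
            for k, v in scores_to_dict(
                mtbl.rename(columns={"mutation_gene": "gene_a", "mRNA_gene": "gene_b"})
            ).items():
                scores[k] = max(scores.get(k, -np.inf), v)
    return scores


def build_gold_standard(
    db: pd.DataFrame,
    threshold: float,
    predictions: dict[frozenset, float],
    balanced: bool = True,
    negative_ratio: float = 1.0,
    seed: int = 0,
) -> GoldStandardSet:
    """Intersect database positives with predictions and resample negatives.

    Positives: db pairs with score > ``threshold`` that have a prediction.
    Negatives: pairs of genes drawn from the prediction universe, excluded
    if they appear in the db at *any* score or lack a prediction;
    ``negative_ratio`` negatives per positive (1.0 when ``balanced``).
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    db_keys_all = {_key(str(a), str(b)) for a, b in zip(db["gene_a"], db["gene_b"])}
    positives = []
    seen = set()
    for a, b, s in zip(db["gene_a"], db["gene_b"], db["score"]):
        k = _key(str(a), str(b))
        if s > threshold and k in predictions and k not in seen:
            positives.append(tuple(sorted((str(a), str(b)))))
            seen.add(k)
    if not positives:
        raise EmptyGoldStandardError(
            f"no database pair above {threshold} has a prediction"
        )
    n_neg = int(round(len(positives) * (1.0 if balanced else negative_ratio)))
    universe = sorted({g for k in predictions for g in k})
    negatives = []
    neg_seen = set()
    max_tries = 1000 * max(n_neg, 1)
    tries = 0
    while len(negatives) < n_neg and tries < max_tries:
        tries += 1
        a, b = rng.choice(universe, size=2, replace=False)
        k = _key(str(a), str(b))
        if k in db_keys_all or k in neg_seen or k not in predictions:
            continue
        neg_seen.add(k)
        negatives.append(tuple(sorted((str(a), str(b)))))
    if len(negatives) < n_neg:
        logger.warning(
            "only %d/%d resampled negatives available in the prediction universe",
            len(negatives), n_neg,
        )
    rows = [(a, b, "positive") for a, b in positives] + [
        (a, b, "negative") for a, b in negatives
    ]
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"])
    return GoldStandardSet(
        pairs=pairs,
        positive_threshold=threshold,
        seed=seed,
        balance=len(positives) / max(len(negatives), 1),
    )


def compute_roc(
    scores: dict[frozenset, float], gold: GoldStandardSet, method: str = ""
) -> BenchmarkResult:
    """AUROC (normalised Mann-Whitney U, ties at half weight) plus ROC points."""
    vals = gold.scores_for(scores)
    labels = gold.labels
    return BenchmarkResult(
        method=method,
        n_pairs=len(vals),
        auroc=auroc(vals, labels),
        roc_points=roc_points(vals, labels),
    )


def compare_aurocs(
    scores_a: dict[frozenset, float],
    scores_b: dict[frozenset, float],
    gold: GoldStandardSet,
    method: str = "delong",
    seed: int = 0,
) -> float:
    """Two-tailed p-value for the paired AUROC difference on shared gold pairs."""
    va = gold.scores_for(scores_a)
    vb = gold.scores_for(scores_b)
    labels = gold.labels
    if method == "delong":
        _, _, p = delong_test(va, vb, labels)
        return p
    if method == "bootstrap":
        return bootstrap_auroc_test(va, vb, labels, seed=seed)
    raise ValueError(f"unknown comparison method {method!r}")


def estimate_fdr(
    scores: dict[frozenset, float],
    gold: GoldStandardSet,
    score_threshold: float,
    prevalence: float = REAL_WORLD_PREVALENCE,
    mode: str = "reweight",
    seed: int = 0,
) -> float:
    """Estimated FDR among predictions scoring above ``score_threshold``.

    Classes are re-weighted (default; deterministic) or re-sampled
    (``mode="resample"``, seed-controlled) so positives make up
    ``prevalence`` of the evaluation set, then
    FDR = expected false positives / all calls above the threshold.
    Returns NaN (with a warning) when nothing scores above the threshold.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    vals = gold.scores_for(scores)
    labels = gold.labels
    if mode == "resample":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(labels)
        neg_idx = np.flatnonzero(~labels)
        n_total = len(vals)
        n_pos = max(int(round(prevalence * n_total)), 1)
        n_neg = n_total - n_pos
        idx = np.r_[
            rng.choice(pos_idx, n_pos, replace=True),
            rng.choice(neg_idx, n_neg, replace=True),
        ]
        vals, labels = vals[idx], labels[idx]
        tp = float(((vals > score_threshold) & labels).sum())
        fp = float(((vals > score_threshold) & ~labels).sum())
    elif mode == "reweight":
        n_pos = labels.sum()
        n_neg = (~labels).sum()
        w_pos = prevalence / n_pos
        w_neg = (1.0 - prevalence) / n_neg
        tp = float(w_pos * ((vals > score_threshold) & labels).sum())
        fp = float(w_neg * ((vals > score_threshold) & ~labels).sum())
    else:
        raise ValueError(f"unknown FDR mode {mode!r}")
    if tp + fp == 0:
        logger.warning("no pair scores above %.3g; FDR undefined", score_threshold)
        return float("nan")
    return fp / (tp + fp)
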