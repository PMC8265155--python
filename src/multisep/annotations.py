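"""Orthogonal functional-similarity annotation of result tables.

Dependency candidates gain three columns of evidence that the two genes are
functionally related: the number of shared GO terms, whether a physical
protein-protein interaction links them, and whether they are paralogues.
Annotation is pure — it never reorders, drops, or re-tests rows — and genes
absent from an annotation source count as unannotated (zero / False), with
per-source missing-gene counts logged. Shared-GO counting uses the
annotation table as given, without ancestor propagation over the ontology
graph: high-level terms already make this filter permissive, and
propagation would only dilute it further.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .clustering import ClusterModel
from .errors import NotTestableError
from .io import AnnotationSets

logger = logging.getLogger(__name__)


def _pair_columns(results: pd.DataFrame) -> tuple[str, str]:
    for a, b in (("mRNA_gene", "crispr_gene"), ("mutation_gene", "mRNA_gene"),
                 ("gene_a", "gene_b")):
        if a in results.columns and b in results.columns:
            return a, b
    raise ValueError("result table has no recognisable gene-pair columns")


def annotate_pairs(
    results: pd.DataFrame,
    ann: AnnotationSets,
    require_go: bool = False,
    require_ppi: bool = False,
    require_paralogue: bool = False,
) -> pd.DataFrame:
    """Append shared_go_count / has_ppi / is_paralogue columns; optionally filter.

    Pair lookups are symmetric: a PPI edge stored as (B, A) annotates the
    row (A, B). Filter flags subset rows only after all three columns are
    computed, and the counts passing each filter are logged.
    """
    col_a, col_b = _pair_columns(results)
    empty = frozenset()
    shared_go, has_ppi, is_par = [], [], []
    missing_go = set()
    for a, b in zip(results[col_a], results[col_b]):
        ga = ann.go_terms.get(a)
        gb = ann.go_terms.get(b)
        for g, t in ((a, ga), (b, gb)):
            if t is None:
                missing_go.add(g)
        shared_go.append(len((ga or empty) & (gb or empty)))
        key = frozenset((a, b))
        has_ppi.append(key in ann.ppi_edges)
        is_par.append(key in ann.paralogue_pairs)
    out = results.copy()
    out["shared_go_count"] = np.asarray(shared_go, dtype=int)
    out["has_ppi"] = np.asarray(has_ppi, dtype=bool)
    out["is_paralogue"] = np.asarray(is_par, dtype=bool)
    if missing_go:
        logger.info("%d genes missing from the GO annotation source", len(missing_go))
    logger.info(
        "annotation filters: %d/%d shared-GO, %d PPI, %d paralogue of %d rows",
        int((out["shared_go_count"] > 0).sum()), len(out),
        int(out["has_ppi"].sum()), int(out["is_paralogue"].sum()), len(out),
    )
    if require_go:
        out = out[out["shared_go_count"] > 0]
    if require_ppi:
        out = out[out["has_ppi"]]
    if require_paralogue:
        out = out[out["is_paralogue"]]
    return out.reset_index(drop=True) if (require_go or require_ppi or require_paralogue) else out


def protein_by_cluster(
    model: ClusterModel, protein_values: pd.Series, min_n: int = 3
) -> pd.DataFrame:
    """Summarise protein concentrations within each expression cluster.

    Returns one row per cluster with n, median and quartiles of the protein
    measurements available for that cluster's cell lines; clusters without
    enough coverage are kept with ``covered = False`` rather than dropped.
    Raises ``NotTestableError`` if no cluster reaches ``min_n`` covered lines.
    """
    rows = []
    any_covered = False
    for c in range(1, model.k + 1):
        vals = protein_values.reindex(model.cluster_members(c)).dropna()
        covered = len(vals) >= min_n
        any_covered = any_covered or covered
        rows.append({
            "cluster": c,
            "n": int(len(vals)),
            "covered": covered,
            "median": float(vals.median()) if len(vals) else np.nan,
            "q1": float(vals.quantile(0.25)) if len(vals) else np.nan,
            "q3": float(vals.quantile(0.75)) if len(vals) else np.nan,
            "mrna_cluster_mean": float(model.means[c - 1]),
        })
    if not any_covered:
        raise NotTestableError(
            "no expression cluster has enough protein measurements"
        )
    return pd.DataFrame(rows)


def venn_counts(annotated: pd.DataFrame) -> dict[str, int]:
    """Partition annotated rows by their evidence-flag combination.

    The returned counts always sum to the number of rows, mirroring a
    three-set Venn decomposition over GO / PPI / paralogy.
    """
    go = annotated["shared_go_count"] > 0
    ppi = annotated["has_ppi"]
    par = annotated["is_paralogue"]
    out = {}
    for g in (False, True):
        for p in (False, True):
            for r in (False, True):
                key = "+".join(
                    n for n, flag in (("go", g), ("ppi", p), ("paralogue", r)) if flag
                ) or "none"
                out[key] = int(((go == g) & (ppi == p) & (par == r)).sum())
    return out
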