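"""Synthetic DepMap-shaped datasets with a machine-readable truth ledger.

The generator emulates the statistical structure the dependency tests
assume, at desk scale:

* per-gene expression drawn from a Gaussian mixture with a planted
  component count (2-4) and configurable component separation (in sd units);
* CERES-like CRISPR scores around per-gene baselines (essential genes near
  -1, non-essential near 0, noise sd 0.2); for each planted dependency pair
  the partner gene's knockout is *more* damaging (score shifted down by the
  effect size) in the mRNA gene's lowest-expression cluster;
* somatic mutations with a configurable marginal rate; for planted
  exclusivity pairs the mutation gene's per-line mutation odds are depressed
  in the partner's lowest-expression cluster through a logistic model;
* tissue labels over a configurable number of groups, including one
  fixed-size tissue for tissue-subset tests; tissue-specific planted pairs
  confine the CRISPR shift to that tissue's cell lines;
* per-gene copy-number values with deletions placed in low-expression lines
  for a subset of genes only, so a DAISY-style caller covers some genes and
  not others;
* a protein matrix correlated with expression at a configurable level.

Everything is deterministic per seed, and every planted signal is recorded
in a ``SyntheticTruth`` ledger so recovery, type-I-error and benchmarking
tests are closed-loop. What the generator does *not* emulate: gene-gene
correlation beyond the planted pairs, copy-number segment structure, or
germline variation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmark import GoldStandardSet
from .errors import ConfigError
from .io import MUTATION_CLASSES, AnnotationSets, Dataset, align_dataset

_CLASS_PROBS = np.array([0.55, 0.10, 0.07, 0.08, 0.03, 0.04, 0.08, 0.02, 0.03])


@dataclass
class GeneratorParams:
    """Study conditions for the synthetic cohort.

    Defaults describe a 400-line, 200-gene cohort over 10 tissues with five
    planted CRISPR dependencies (CERES shift 1.0) and five planted
    mutation-exclusivity pairs — large enough for the dependency scans to be
    well powered, small enough to run in seconds.
    """

    n_lines: int = 400
    n_genes: int = 200
    n_tissues: int = 10
    fixed_tissue_size: int = 40  # first tissue has exactly this many lines
    k_choices: tuple[int, ...] = (2, 3, 4)
    k_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    separation: float = 6.0  # component-mean separation in sd units
    weak_fraction: float = 0.3  # null genes with near-unimodal expression
    weak_separation: float = 1.0  # separation (sd units) for those genes
    expr_sd: float = 1.0
    expr_base_range: tuple[float, float] = (2.0, 8.0)
    min_weight: float = 0.15  # smallest mixture weight per component
    n_crispr_pairs: int = 5
    crispr_effect: float = 1.0
    n_mutation_pairs: int = 5
    mutation_exclusivity: float = 3.0  # log-odds depletion in the low cluster
    essential_fraction: float = 0.2
    ceres_sd: float = 0.2
    mutation_rate: float = 0.15
    cn_sd: float = 0.1
    cn_loss_value: float = -0.8
    cn_loss_fraction: float = 0.05  # lines deleted, for genes that have losses
    cn_gene_fraction: float = 0.5  # genes with any copy-number losses
    protein_correlation: float = 0.8
    tissue_specific_pairs: int = 0  # CRISPR pairs confined to the fixed tissue

    def validate(self) -> None:
        if self.n_lines < 20 or self.n_genes < 10 or self.n_tissues < 1:
            raise ConfigError("need n_lines >= 20, n_genes >= 10, n_tissues >= 1")
        if not 0 < self.min_weight <= 1.0 / max(self.k_choices):
            raise ConfigError("min_weight infeasible for the largest planted k")
        if self.fixed_tissue_size > self.n_lines:
            raise ConfigError("fixed_tissue_size exceeds n_lines")


@dataclass
class SyntheticTruth:
    """Ledger of every signal planted by the generator."""

    planted_k: dict[str, int]
    planted_crispr_pairs: list[tuple[str, str, float]]
    planted_mutation_pairs: list[tuple[str, str, float]]
    tissue_specific_pairs: list[tuple[str, str, float, str]]
    null_genes: list[str]
    weak_genes: list[str]  # near-unimodal expression (weak separation)
    low_cluster_lines: dict[str, list[str]]
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_dataset(
    params: GeneratorParams | None = None, seed: int = 0
) -> tuple[Dataset, SyntheticTruth]:
    """Generate an aligned synthetic dataset plus its truth ledger."""
    p = params or GeneratorParams()
    p.validate()
    ss = np.random.SeedSequence(seed)
    (r_expr, r_tissue, r_crispr, r_mut, r_cn, r_prot, r_pairs) = [
        np.random.default_rng(s) for s in ss.spawn(7)
    ]

    lines = [f"CL{i:04d}" for i in range(p.n_lines)]
    genes = [f"G{j:03d}" for j in range(p.n_genes)]

    # tissue labels: first tissue gets a fixed size, the rest spread evenly
    tissue_labels = np.empty(p.n_lines, dtype=object)
    tissue_labels[: p.fixed_tissue_size] = "tissue_00"
    rest = np.arange(p.fixed_tissue_size, p.n_lines)
    if p.n_tissues > 1:
        tissue_labels[rest] = [
            f"tissue_{1 + (i % (p.n_tissues - 1)):02d}" for i in range(len(rest))
        ]
    else:
        tissue_labels[rest] = "tissue_00"
    perm = r_tissue.permutation(p.n_lines)
    tissues = pd.Series(tissue_labels[perm], index=lines, name="tissue")

    # planted dependency pairs over disjoint gene roles
    pool = r_pairs.permutation(p.n_genes)
    n_cp, n_mp, n_tp = p.n_crispr_pairs, p.n_mutation_pairs, p.tissue_specific_pairs
    need = 2 * (n_cp + n_mp + n_tp)
    if need > p.n_genes:
        raise ConfigError("not enough genes for the requested planted pairs")
    cursor = 0

    def _take(n):
        nonlocal cursor
        sel = pool[cursor : cursor + n]
        cursor += n
        return [genes[i] for i in sel]

    crispr_mrna, crispr_partner = _take(n_cp), _take(n_cp)
    mut_mrna, mut_partner = _take(n_mp), _take(n_mp)
    ts_mrna, ts_partner = _take(n_tp), _take(n_tp)
    null_genes = [genes[i] for i in pool[cursor:]]
    # weakly separated (near-unimodal) genes come from the null pool only,
    # so every planted pair keeps a cleanly clusterable mRNA gene
    weak_genes = set(null_genes[: int(round(p.weak_fraction * p.n_genes))])

    # expression: per-gene Gaussian mixture with planted k
    planted_k: dict[str, int] = {}
    expr = np.empty((p.n_lines, p.n_genes))
    memberships = np.empty((p.n_lines, p.n_genes), dtype=int)
    for j, gene in enumerate(genes):
        k = int(r_expr.choice(p.k_choices, p=p.k_probs))
        planted_k[gene] = k
        w = r_expr.dirichlet(np.ones(k))
        w = p.min_weight + (1.0 - k * p.min_weight) * w  # floor the weights
        base = r_expr.uniform(*p.expr_base_range)
        sep = p.weak_separation if gene in weak_genes else p.separation
        means = base + np.arange(k) * sep * p.expr_sd
        comp = r_expr.choice(k, size=p.n_lines, p=w)
        expr[:, j] = r_expr.normal(means[comp], p.expr_sd)
        memberships[:, j] = comp
    expression = pd.DataFrame(expr, index=lines, columns=genes)

    low_cluster_lines = {
        g: list(expression.index[memberships[:, genes.index(g)] == 0])
        for g in crispr_mrna + mut_mrna + ts_mrna
    }

    # CRISPR: gene baselines near -1 (essential) or 0, noise sd ceres_sd
    essential = r_crispr.random(p.n_genes) < p.essential_fraction
    baselines = np.where(essential, -1.0, 0.0) + r_crispr.normal(0, 0.05, p.n_genes)
    ceres = r_crispr.normal(baselines[None, :], p.ceres_sd, size=(p.n_lines, p.n_genes))
    crispr = pd.DataFrame(ceres, index=lines, columns=genes)
    planted_crispr = []
    for a, b in zip(crispr_mrna, crispr_partner):
        mask = crispr.index.isin(low_cluster_lines[a])
        crispr.loc[mask, b] -= p.crispr_effect  # knockout more damaging
        planted_crispr.append((a, b, p.crispr_effect))
    tissue_pairs = []
    for a, b in zip(ts_mrna, ts_partner):
        mask = crispr.index.isin(low_cluster_lines[a]) & (tissues == "tissue_00").to_numpy()
        crispr.loc[mask, b] -= p.crispr_effect
        tissue_pairs.append((a, b, p.crispr_effect, "tissue_00"))

    # mutations: Bernoulli per (line, gene); planted pairs get depleted odds
    base_logit = np.log(p.mutation_rate / (1.0 - p.mutation_rate))
    logits = np.full((p.n_lines, p.n_genes), base_logit)
    planted_mut = []
    for a, m in zip(mut_mrna, mut_partner):
        jm = genes.index(m)
        mask = expression.index.isin(low_cluster_lines[a])
        logits[mask, jm] -= p.mutation_exclusivity
        planted_mut.append((a, m, p.mutation_exclusivity))
    mutated = r_mut.random((p.n_lines, p.n_genes)) < _sigmoid(logits)
    rec_lines, rec_genes = np.nonzero(mutated)
    classes = r_mut.choice(MUTATION_CLASSES, size=len(rec_lines), p=_CLASS_PROBS)
    mutations = pd.DataFrame({
        "cell_line": [lines[i] for i in rec_lines],
        "gene": [genes[j] for j in rec_genes],
        "mutation_class": classes,
    })

    # copy number: losses only for a subset of genes, placed in low-expression lines
    cn = r_cn.normal(0.0, p.cn_sd, size=(p.n_lines, p.n_genes))
    has_loss = r_cn.random(p.n_genes) < p.cn_gene_fraction
    n_loss = max(int(round(p.cn_loss_fraction * p.n_lines)), 2)
    for j in np.flatnonzero(has_loss):
        low_idx = np.argsort(expr[:, j])[:n_loss]
        cn[low_idx, j] = p.cn_loss_value + r_cn.normal(0, 0.05, n_loss)
    copy_number = pd.DataFrame(cn, index=lines, columns=genes)

    # protein: linear in expression with attenuating noise
    rho = p.protein_correlation
    noise_sd = p.expr_sd * np.sqrt(max(1.0 / rho**2 - 1.0, 1e-12)) if rho > 0 else 1e6
    protein = expression + r_prot.normal(0, noise_sd, size=expression.shape)

    # annotations: planted pairs get shared GO terms / PPI / paralogy evidence
    go_terms = {g: frozenset({f"GO:{1000 + i}" for i in r_pairs.integers(0, 50, 3)})
                for g in genes}
    ppi = {frozenset((a, b)) for a, b, _ in planted_crispr}
    paralogues = {frozenset(planted_crispr[0][:2])} if planted_crispr else set()
    ann = AnnotationSets(go_terms=go_terms, ppi_edges=ppi, paralogue_pairs=paralogues)

    ds = align_dataset(Dataset(
        expression=expression, tissues=tissues, crispr=crispr,
        mutations=mutations, annotations=ann, protein=protein,
        copy_number=copy_number,
    ))
    truth = SyntheticTruth(
        planted_k=planted_k,
        planted_crispr_pairs=planted_crispr,
        planted_mutation_pairs=planted_mut,
        tissue_specific_pairs=tissue_pairs,
        null_genes=null_genes,
        weak_genes=sorted(weak_genes),
        low_cluster_lines={k: list(v) for k, v in low_cluster_lines.items()},
        seed=seed,
    )
    return ds, truth


def truth_to_gold_standard(
    truth: SyntheticTruth, prevalence: float = 0.5, seed: int = 0,
    gene_universe: list[str] | None = None,
) -> tuple[GoldStandardSet, pd.DataFrame]:
    """Turn planted pairs into a database + labelled gold standard.

    Planted pairs become database positives with scores above 0.7; filler
    negative pairs (never planted) are resampled so that positives make up
    ``prevalence`` of the emitted gold-standard pairs. Returns the labelled
    ``GoldStandardSet`` and a SynLethDB-format three-column score table of
    the positives.
    """
    planted = [(a, b) for a, b, *_ in truth.planted_crispr_pairs]
    planted += [(a, b) for a, b, *_ in truth.planted_mutation_pairs]
    planted += [(a, b) for a, b, _, _ in truth.tissue_specific_pairs]
    if not planted:
        raise ConfigError("truth ledger has no planted pairs")
    if not (0 < prevalence < 1):
        raise ConfigError("prevalence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_pos = len(planted)
    n_neg = int(round(n_pos * (1.0 - prevalence) / prevalence))
    if gene_universe is None:
        gene_universe = sorted(
            set(truth.null_genes) | {g for pair in planted for g in pair}
        )
    if n_neg > 0 and len(gene_universe) < 3:
        raise ConfigError("gene universe too small to resample negatives")
    planted_keys = {frozenset(p) for p in planted}
    negatives: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    tries = 0
    while len(negatives) < n_neg:
        tries += 1
        if tries > 10000 * max(n_neg, 1):
            raise ConfigError("cannot reach requested prevalence with this gene universe")
        a, b = rng.choice(gene_universe, size=2, replace=False)
        key = frozenset((str(a), str(b)))
        if key in planted_keys or key in seen:
            continue
        seen.add(key)
        negatives.append((str(a), str(b)))
    db = pd.DataFrame({
        "gene_a": [a for a, _ in planted],
        "gene_b": [b for _, b in planted],
        "score": np.round(rng.uniform(0.75, 0.99, n_pos), 4),
    })
    rows = [(a, b, "positive") for a, b in planted] + [
        (a, b, "negative") for a, b in negatives
    ]
    gold = GoldStandardSet(
        pairs=pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"]),
        positive_threshold=0.7,
        seed=seed,
        balance=n_pos / max(n_neg, 1),
    )
    return gold, db


def write_dataset(ds: Dataset, truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write every component as delimited text plus truth.json; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _w(name, writer):
        path = outdir / name
        writer(path)
        paths[name] = path

    _w("expression.csv", lambda f: ds.expression.to_csv(f))
    _w("tissues.csv", lambda f: ds.tissues.rename("tissue").to_csv(f))
    if ds.crispr is not None:
        _w("crispr.csv", lambda f: ds.crispr.to_csv(f))
    if ds.mutations is not None:
        _w("mutations.csv", lambda f: ds.mutations.to_csv(f, index=False))
    if ds.protein is not None:
        _w("protein.csv", lambda f: ds.protein.to_csv(f))
    if ds.copy_number is not None:
        _w("copy_number.csv", lambda f: ds.copy_number.to_csv(f))
    if ds.annotations is not None:
        ann = ds.annotations
        go_rows = [(g, t) for g, ts in sorted(ann.go_terms.items()) for t in sorted(ts)]
        _w("go.csv", lambda f: pd.DataFrame(go_rows, columns=["gene", "go_term"]).to_csv(f, index=False))
        for name, pairs in (("ppi.csv", ann.ppi_edges), ("paralogues.csv", ann.paralogue_pairs)):
            rows = sorted(tuple(sorted(pr)) for pr in pairs)
            _w(name, lambda f, rows=rows: pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(f, index=False))
    truth.to_json(outdir / "truth.json")
    paths["truth.json"] = outdir / "truth.json"
    config = {
        "expression": "expression.csv", "tissues": "tissues.csv",
        **({"crispr": "crispr.csv"} if ds.crispr is not None else {}),
        **({"mutations": "mutations.csv"} if ds.mutations is not None else {}),
        **({"protein": "protein.csv"} if ds.protein is not None else {}),
        **({"copy_number": "copy_number.csv"} if ds.copy_number is not None else {}),
        **({"go": "go.csv", "ppi": "ppi.csv", "paralogues": "paralogues.csv"}
           if ds.annotations is not None else {}),
    }
    import yaml
    with open(outdir / "dataset.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    paths["dataset.yaml"] = outdir / "dataset.yaml"
    return paths


PRESETS = {
    "default": GeneratorParams(),
    "null": GeneratorParams(n_crispr_pairs=0, n_mutation_pairs=0),
    "tissue-specific": GeneratorParams(tissue_specific_pairs=3),
}
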