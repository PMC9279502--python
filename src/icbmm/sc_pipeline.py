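"""Single-cell QC, normalization, T-compartment gating, DE, and signatures.

Cells live in an :class:`anndata.AnnData`: raw RNA counts in ``X``, surface
protein counts in ``obsm["protein"]``, a per-gene mitochondrial flag in
``var["mito"]``, and the sorted fraction (CD45pos immune / CD45neg tumor) in
``obs["fraction"]``. The mitochondrial QC cutoff depends on the fraction: 6%
for immune cells, 20% for tumor cells.

Differential expression is a two-sided Wilcoxon rank-sum of one cluster
against all remaining cells, per gene, using the normal approximation with
tie correction (an exact null distribution when both sides have <= 10 cells
and no ties), Bonferroni-adjusted across tested genes. Cluster signatures are
the top-k genes ranked by the signed z statistic with a deterministic
tie-break, and a signature score is the arithmetic mean of log expression
over the signature genes, optionally z-scored across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSignature",
    "GatingConfig",
    "qc_filter_cells",
    "normalize_rna",
    "normalize_protein_clr",
    "gate_t_compartments",
    "cluster_cells",
    "differential_expression",
    "derive_signature",
    "score_signature",
    "sum_hla_expression",
]

MITO_MAX_IMMUNE = 0.06
MITO_MAX_TUMOR = 0.20
MIN_GENES = 200
MAX_GENES = 2500
MIN_CELLS_PER_GENE = 3


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]
    source_cluster: str = ""

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError("signature must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=float)


def qc_filter_cells(adata: ad.AnnData, *, min_genes: int = MIN_GENES,
                    max_genes: int = MAX_GENES,
                    mito_max_immune: float = MITO_MAX_IMMUNE,
                    mito_max_tumor: float = MITO_MAX_TUMOR,
                    min_cells_per_gene: int = MIN_CELLS_PER_GENE) -> ad.AnnData:
    """Remove low-quality cells, then rarely-detected genes.

    Cells are removed when they have detectable expression in fewer than
    ``min_genes`` genes, more than ``max_genes`` genes, or a mitochondrial
    count fraction strictly above the threshold for their fraction label
    (immune CD45pos vs tumor CD45neg). Genes expressed in fewer than
    ``min_cells_per_gene`` of the remaining cells are then dropped. The
    per-rule removal counts are recorded in ``uns["qc_report"]``.
    """
    if "mito" not in adata.var:
        raise ValueError("var['mito'] mitochondrial flag is required")
    if "fraction" not in adata.obs:
        raise ValueError("obs['fraction'] (CD45pos/CD45neg) is required")
    X = _dense(adata.X)
    detected = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    mito = adata.var["mito"].to_numpy(dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, X[:, mito].sum(axis=1) / totals, 0.0)
    is_immune = adata.obs["fraction"].to_numpy() == "CD45pos"
    mito_max = np.where(is_immune, mito_max_immune, mito_max_tumor)

    too_few = detected < min_genes
    too_many = detected > max_genes
    too_mito = mito_frac > mito_max
    keep_cells = ~(too_few | too_many | too_mito)
    if not keep_cells.any():
        raise ValueError("QC removed every cell")

    n_cells_expr = (X[keep_cells] > 0).sum(axis=0)
    keep_genes = n_cells_expr >= min_cells_per_gene

    out = adata[keep_cells, keep_genes].copy()
    out.uns["qc_report"] = {
        "cells_in": int(adata.n_obs),
        "cells_removed_min_genes": int(too_few.sum()),
        "cells_removed_max_genes": int(too_many.sum()),
        "cells_removed_mito": int(too_mito.sum()),
        "cells_out": int(out.n_obs),
        "genes_in": int(adata.n_vars),
        "genes_removed_min_cells": int((~keep_genes).sum()),
        "genes_out": int(out.n_vars),
    }
    return out


def normalize_rna(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts, then log(1 + x).

    Raw counts are kept in ``layers["counts"]``. Natural log with a
    pseudocount of 1, the dominant single-cell convention.
    """
    X = _dense(adata.X)
    totals = X.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        names = list(adata.obs_names[zero[:5]])
        raise ValueError(f"all-zero cells cannot be normalized: {names}")
    out = adata.copy()
    out.layers["counts"] = X.copy()
    out.X = np.log1p(X * (target_sum / totals[:, None]))
    out.uns["normalization"] = {"target_sum": target_sum, "log": "natural, log1p"}
    return out


def normalize_protein_clr(protein_counts: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform per cell: log1p(x) minus its row mean.

    Row sums of the result are zero by construction.
    """
    logx = np.log1p(protein_counts.to_numpy(dtype=float))
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=protein_counts.index,
                        columns=protein_counts.columns)


@dataclass(frozen=True)
class GatingConfig:
    """CLR gate positions per surface marker plus the CD68 RNA gate.

    The default gate for every protein marker is CLR > 0, i.e. above the
    cell's own geometric-mean background; the monocyte/macrophage exclusion
    uses normalized CD68 RNA expression <= ``cd68_rna_max``.
    """

    thresholds: dict = field(default_factory=lambda: {
        "CD45": 0.0, "CD3": 0.0, "CD4": 0.0, "CD8": 0.0, "CD20": 0.0})
    cd68_rna_max: float = 1.0
    cd68_gene: str = "CD68"


def gate_t_compartments(adata: ad.AnnData, clr: pd.DataFrame,
                        gates: GatingConfig | None = None) -> ad.AnnData:
    """Assign each cell to the CD4 or CD8 T compartment, or exclude it.

    CD4 compartment: CD45+, CD3+, CD20-, CD68(RNA)-low, CD4+, CD8-; the CD8
    compartment is symmetric. Double-positive and double-negative cells are
    excluded. ``adata.X`` must hold normalized RNA expression (for the CD68
    gate). Gate settings are recorded in ``uns["gating"]``.
    """
    gates = gates or GatingConfig()
    required = ["CD45", "CD3", "CD4", "CD8", "CD20"]
    missing = [m for m in required if m not in clr.columns]
    if missing:
        raise ValueError(f"missing protein markers: {missing}")
    clr = clr.loc[adata.obs_names]
    pos = {m: clr[m].to_numpy() > gates.thresholds[m] for m in required}
    if gates.cd68_gene in adata.var_names:
        cd68 = _dense(adata[:, gates.cd68_gene].X).ravel()
    else:
        cd68 = np.zeros(adata.n_obs)
    t_cell = pos["CD45"] & pos["CD3"] & ~pos["CD20"] & (cd68 <= gates.cd68_rna_max)
    cd4 = t_cell & pos["CD4"] & ~pos["CD8"]
    cd8 = t_cell & pos["CD8"] & ~pos["CD4"]
    compartment = np.where(cd4, "CD4", np.where(cd8, "CD8", "excluded"))
    out = adata.copy()
    out.obs["compartment"] = pd.Categorical(compartment,
                                            categories=["CD4", "CD8", "excluded"])
    out.uns["gating"] = {"thresholds": dict(gates.thresholds),
                         "cd68_rna_max": gates.cd68_rna_max}
    return out


def cluster_cells(adata: ad.AnnData, resolution: float, *,
                  n_top_genes: int = 2000, n_pcs: int = 20,
                  random_state: int = 0) -> pd.Series:
    """Leiden community labels via the scanpy backend.

    Clustering is delegated (highly-variable-gene selection, PCA, kNN graph,
    Leiden); the analysis's own content is downstream of the labels. The
    published resolutions were 0.7 for CD8 cells and 0.8 for CD4 cells.
    """
    import scanpy as sc

    work = adata.copy()
    sc.pp.highly_variable_genes(work, n_top_genes=min(n_top_genes, work.n_vars - 1))
    work = work[:, work.var["highly_variable"]].copy()
    sc.pp.scale(work, max_value=10)
    sc.tl.pca(work, n_comps=min(n_pcs, work.n_vars - 1, work.n_obs - 1),
              random_state=random_state)
    sc.pp.neighbors(work, random_state=random_state)
    sc.tl.leiden(work, resolution=resolution, random_state=random_state,
                 flavor="igraph", n_iterations=2, directed=False)
    return pd.Series(work.obs["leiden"].astype(str).to_numpy(),
                     index=adata.obs_names, name="cluster")


def _wilcoxon_z(expr: np.ndarray, in_group: np.ndarray):
    """Vectorized tie-corrected normal-approximation rank-sum per gene.

    Returns (U, z) for group-vs-rest, z signed so that positive means higher
    expression in the group.
    """
    n1 = int(in_group.sum())
    n2 = expr.shape[0] - n1
    ranks = stats.rankdata(expr, axis=0)
    r1 = ranks[in_group].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    # tie correction per gene
    n = n1 + n2
    tie_term = np.zeros(expr.shape[1])
    for j in range(expr.shape[1]):
        _, counts = np.unique(expr[:, j], return_counts=True)
        t = counts[counts > 1]
        if t.size:
            tie_term[j] = (t**3 - t).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var_u > 0, (u - mean_u) / np.sqrt(var_u), 0.0)
    return u, z


def differential_expression(expr, labels, group: str,
                            exact_max_n: int = 10) -> pd.DataFrame:
    """Wilcoxon rank-sum DE of one cluster versus all other cells.

    Parameters
    ----------
    expr : DataFrame (cells x genes) of normalized log expression, or AnnData.
    labels : per-cell cluster labels aligned with ``expr`` rows.
    group : the cluster to test against the rest.

    Returns a DataFrame indexed by gene with columns ``u``, ``z``, ``p``,
    ``p_adj`` (Bonferroni across tested genes) and ``lfc`` (difference of
    mean log expression, group minus rest), sorted by z descending with the
    deterministic tie-break (z, then lfc, then gene id).
    """
    if isinstance(expr, ad.AnnData):
        expr = pd.DataFrame(_dense(expr.X), index=expr.obs_names,
                            columns=expr.var_names)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two clusters")
    in_group = labels == group
    if not in_group.any():
        raise ValueError(f"group {group!r} absent from labels")
    n1, n2 = int(in_group.sum()), int((~in_group).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each side needs at least 2 cells")
    X = expr.to_numpy(dtype=float)
    u, z = _wilcoxon_z(X, in_group)
    if max(n1, n2) <= exact_max_n:
        p = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            col = X[:, j]
            n_distinct = np.unique(col).size
            if n_distinct == 1:
                p[j] = 1.0
                continue
            method = "asymptotic" if n_distinct < col.size else "exact"
            p[j] = stats.mannwhitneyu(col[in_group], col[~in_group],
                                      alternative="two-sided",
                                      method=method, use_continuity=False).pvalue
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    p_adj = np.minimum(p * X.shape[1], 1.0)
    lfc = X[in_group].mean(axis=0) - X[~in_group].mean(axis=0)
    out = pd.DataFrame({"u": u, "z": z, "p": p, "p_adj": p_adj, "lfc": lfc},
                       index=pd.Index(expr.columns, name="gene"))
    out = out.sort_values(["z", "lfc", "gene"],
                          ascending=[False, False, True],
                          kind="stable")
    out.attrs["group"] = group
    out.attrs["ranking"] = "signed z descending, ties by lfc then gene id"
    return out


def derive_signature(de_result: pd.DataFrame, k: int = 25,
                     name: str | None = None) -> GeneSignature:
    """Top-k DE genes as a cluster signature (z, then lfc, then gene id)."""
    if len(de_result) < k:
        raise ValueError(f"only {len(de_result)} testable genes, need {k}")
    ranked = de_result.reset_index().sort_values(
        ["z", "lfc", "gene"], ascending=[False, False, True], kind="stable")
    genes = tuple(ranked["gene"].head(k))
    cluster = de_result.attrs.get("group", "")
    return GeneSignature(name=name or f"{cluster}_top{k}", genes=genes,
                         source_cluster=cluster)


def score_signature(expr: pd.DataFrame, sig: GeneSignature,
                    standardize: bool = False) -> pd.Series:
    """Mean log expression over the signature genes, per sample (row).

    With ``standardize=True`` scores are z-scored across samples (mean 0,
    sample SD 1). Missing signature genes are an error, never silently
    dropped.
    """
    missing = [g for g in sig.genes if g not in expr.columns]
    if missing:
        raise KeyError(f"signature genes missing from expression: {missing}")
    score = expr[list(sig.genes)].mean(axis=1)
    score.name = sig.name
    if standardize:
        sd = score.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError("zero variance: scores cannot be standardized")
        score = (score - score.mean()) / sd
    return score


def sum_hla_expression(expr: pd.DataFrame,
                       locus_gene_sets: dict[str, list[str]]):
    """Per-cell totals over HLA locus gene sets plus the per-gene values.

    Returns (totals, per_gene) where ``totals`` has one column per locus set
    (sum over its genes) and ``per_gene`` is the expression sub-matrix of all
    genes referenced, for per-gene distribution comparisons.
    """
    genes_used: list[str] = []
    totals = {}
    for name, genes in locus_gene_sets.items():
        if not genes:
            raise ValueError(f"empty gene set: {name}")
        missing = [g for g in genes if g not in expr.columns]
        if missing:
            raise KeyError(f"{name}: genes missing from expression: {missing}")
        totals[name] = expr[list(genes)].sum(axis=1)
        genes_used.extend(g for g in genes if g not in genes_used)
    return pd.DataFrame(totals), expr[genes_used].copy()
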