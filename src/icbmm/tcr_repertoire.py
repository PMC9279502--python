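"""Clonotype calling, expansion, Shannon diversity, and clone sharing.

A clonotype is a set of cells with identical TRA and TRB CDR3 amino-acid
sequences; cells lacking a paired TRA+TRB or carrying multiple chains of
either locus are removed before calling. An expanded clone has more than one
cell. Repertoire diversity is the Shannon entropy H = -sum p_i ln p_i with
Hutcheson's variance estimate

    Var(H) = [sum p_i (ln p_i)^2 - (sum p_i ln p_i)^2] / N + (S - 1) / (2 N^2)

and two repertoires are compared with Hutcheson's t-test
(t = (H1 - H2)/sqrt(V1 + V2), Welch-style non-integer df).

Clone sharing between phenotypic clusters is a directed graph: the weight of
edge A->B is the percent of A's clones that also have at least one cell in B,
so the graph is generally asymmetric. Low-weight edges are pruned at an
inclusive empirical quantile of the nonzero weights (ties at the cutoff are
removed); published figures pruned the lowest tertile (CD4) and quartile
(CD8).
"""

from __future__ import annotations

import math
from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "call_clonotypes",
    "expansion_stats",
    "shannon_entropy",
    "hutcheson_t_test",
    "prune_cutoff",
    "clone_sharing_graph",
]


def prune_cutoff(weights, quantile: float) -> float:
    """Inclusive empirical quantile used to prune low-weight edges.

    Edges with weight at or below the returned cutoff are removed; e.g.
    nonzero weights {10, 20, 30, 40} at quantile 0.25 give cutoff 10, so the
    10% edge (a tie at the cutoff) is removed.
    """
    return float(np.quantile(np.asarray(weights, dtype=float), quantile,
                             method="lower"))


def call_clonotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Filter chain records and assign clone ids.

    Parameters
    ----------
    records : AIRR-style long format with columns cell_id, locus
        (TRA/TRB), junction_aa.

    Returns a per-cell table (cell_id, tra_cdr3, trb_cdr3, clone_id,
    clone_size) containing only cells with exactly one TRA and one TRB.
    Removal counts per rule are stored in ``attrs["report"]``. Clone ids are
    assigned per unique (TRA, TRB) pair; two cells share a clone id iff both
    CDR3 sequences are identical.
    """
    required = {"cell_id", "locus", "junction_aa"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    dup = records.duplicated(subset=["cell_id", "locus", "junction_aa"])
    if dup.any():
        bad = records.loc[dup, "cell_id"].unique()[:5]
        raise ValueError(f"duplicate chain rows for cells: {list(bad)}")

    counts = records.pivot_table(index="cell_id", columns="locus",
                                 values="junction_aa", aggfunc="count",
                                 fill_value=0)
    for locus in ("TRA", "TRB"):
        if locus not in counts.columns:
            counts[locus] = 0
    report = {
        "cells_in": int(counts.shape[0]),
        "removed_no_tra": int((counts["TRA"] == 0).sum()),
        "removed_no_trb": int((counts["TRB"] == 0).sum()),
        "removed_multi_tra": int((counts["TRA"] > 1).sum()),
        "removed_multi_trb": int((counts["TRB"] > 1).sum()),
    }
    ok = counts.index[(counts["TRA"] == 1) & (counts["TRB"] == 1)]
    kept = records[records["cell_id"].isin(ok)]
    wide = kept.pivot(index="cell_id", columns="locus", values="junction_aa")
    table = pd.DataFrame({
        "cell_id": wide.index,
        "tra_cdr3": wide["TRA"].to_numpy(),
        "trb_cdr3": wide["TRB"].to_numpy(),
    }).reset_index(drop=True)
    pair = list(zip(table["tra_cdr3"], table["trb_cdr3"]))
    codes, _ = pd.factorize(pd.Series(pair), sort=True)
    table["clone_id"] = codes
    table["clone_size"] = table.groupby("clone_id")["clone_id"].transform("size")
    report["cells_out"] = int(len(table))
    report["n_clones"] = int(table["clone_id"].nunique())
    table.attrs["report"] = report
    return table


def expansion_stats(table: pd.DataFrame,
                    groups: dict[str, pd.Series | np.ndarray] | None = None,
                    group_col: str | None = None) -> pd.DataFrame:
    """Per-group clonal-expansion summary.

    Clone sizes are recomputed within each analyzed group, so "expanded"
    means >= 2 cells of the clone inside that group. Returns one row per
    group: n_cells, n_clones, n_expanded_clones, expanded_cell_fraction, and
    the clone-size histogram (size -> number of clones) as a dict.
    """
    if group_col is not None:
        groups = {g: (table[group_col] == g).to_numpy()
                  for g in pd.unique(table[group_col])}
    if groups is None:
        groups = {"all": np.ones(len(table), dtype=bool)}
    rows = []
    for name, mask in groups.items():
        sub = table.loc[np.asarray(mask, dtype=bool)]
        if sub.empty:
            raise ValueError(f"empty group: {name}")
        sizes = sub.groupby("clone_id").size()
        expanded = sizes[sizes >= 2]
        rows.append({
            "group": name,
            "n_cells": int(len(sub)),
            "n_clones": int(len(sizes)),
            "n_expanded_clones": int(len(expanded)),
            "expanded_cell_fraction": float(expanded.sum() / len(sub)),
            "clone_size_histogram": dict(Counter(sizes.to_numpy())),
        })
    return pd.DataFrame(rows).set_index("group")


def shannon_entropy(clone_counts) -> tuple[float, float, int, int]:
    """Shannon entropy of a repertoire with Hutcheson's variance.

    Parameters
    ----------
    clone_counts : per-clone cell counts (all >= 1).

    Returns (H, Var(H), N, S): entropy in nats, its Hutcheson variance
    estimate, the number of cells, and the number of clones.
    """
    c = np.asarray(clone_counts, dtype=float)
    if c.size == 0:
        raise ValueError("empty repertoire")
    if np.any(c < 1):
        raise ValueError("clone counts must be >= 1")
    n = c.sum()
    p = c / n
    logp = np.log(p)
    h = float(-np.sum(p * logp))
    s = int(c.size)
    var = float((np.sum(p * logp**2) - np.sum(p * logp) ** 2) / n
                + (s - 1) / (2.0 * n**2))
    return h, var, int(n), s


def hutcheson_t_test(rep1, rep2) -> tuple[float, float, float]:
    """Hutcheson's t-test comparing the Shannon entropy of two repertoires.

    Returns (t, df, p two-sided). t is negative when rep1 is less diverse
    than rep2. df follows the Welch-Satterthwaite form
    (V1 + V2)^2 / (V1^2/N1 + V2^2/N2) and need not be an integer.
    """
    h1, v1, n1, _ = shannon_entropy(rep1)
    h2, v2, n2, _ = shannon_entropy(rep2)
    vsum = v1 + v2
    if vsum == 0:
        if h1 == h2:
            return 0.0, float("inf"), 1.0
        raise ValueError("zero combined variance with unequal entropies")
    t = (h1 - h2) / math.sqrt(vsum)
    df = vsum**2 / (v1**2 / n1 + v2**2 / n2)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def clone_sharing_graph(table: pd.DataFrame, prune_quantile: float = 0.0,
                        cluster_col: str = "cluster_label",
                        weight_by: str = "clones",
                        min_clone_size: int = 1) -> nx.DiGraph:
    """Directed clone-sharing graph between clusters.

    weight(A->B) = 100 * |clones with a cell in both A and B| / |clones in A|
    (``weight_by="cells"`` instead weights by the fraction of A's cells whose
    clone also appears in B). Zero-weight edges and self-edges are dropped;
    remaining edges with weight at or below the inclusive empirical
    ``prune_quantile`` of the nonzero weights are removed (no pruning at
    quantile 0). ``min_clone_size`` restricts the clones considered.
    """
    if not (0.0 <= prune_quantile < 1.0):
        raise ValueError("prune_quantile must be in [0, 1)")
    if weight_by not in ("clones", "cells"):
        raise ValueError("weight_by must be 'clones' or 'cells'")
    if cluster_col not in table.columns:
        raise ValueError(f"missing cluster column {cluster_col!r}")
    sizes = table.groupby("clone_id")["clone_id"].transform("size")
    sub = table.loc[sizes >= min_clone_size]
    clusters = list(pd.unique(sub[cluster_col]))
    clones_in = {c: set(sub.loc[sub[cluster_col] == c, "clone_id"]) for c in clusters}

    g = nx.DiGraph(pruning_rule=f"quantile={prune_quantile}",
                   weight_by=weight_by)
    g.add_nodes_from(clusters)
    edges = []
    for a in clusters:
        if not clones_in[a]:
            continue
        cells_a = sub.loc[sub[cluster_col] == a]
        for b in clusters:
            if a == b:
                continue
            shared = clones_in[a] & clones_in[b]
            if weight_by == "clones":
                w = 100.0 * len(shared) / len(clones_in[a])
            else:
                w = 100.0 * cells_a["clone_id"].isin(shared).mean()
            if w > 0:
                edges.append((a, b, w))
    if edges and prune_quantile > 0:
        cutoff = prune_cutoff([w for _, _, w in edges], prune_quantile)
        edges = [(a, b, w) for a, b, w in edges if w > cutoff]
    g.add_weighted_edges_from(edges)
    return g
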