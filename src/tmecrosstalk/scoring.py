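"""Per-cell pathway enrichment and composite phenotype scores.

Single-sample GSEA scores each cell against a gene set by walking down the
cell's expression ranking and accumulating the difference between the
rank-weighted empirical CDF of in-set genes and the unweighted CDF of
out-set genes:

    score = sum_i [ P_in(i) - P_out(i) ],
    P_in(i) = sum_{j in S, pos(j) <= i} r_j^alpha / sum_{j in S} r_j^alpha,
    P_out(i) = #{j not in S, pos(j) <= i} / (N - |S|)

with r_j the (average, tie-aware) expression rank of gene j (N = highest
expression) and positions taken in descending rank order. alpha defaults to
0.25. Composite phenotype scores summarize a correlated pathway family by
the first principal component of the z-scored score matrix, sign-oriented
to correlate positively with the family mean.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "read_gmt",
    "write_gmt",
    "normalize_counts",
    "cpm",
    "ssgsea_cell",
    "ssgsea_scores",
    "composite_score",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into {set name: gene list}."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"empty gene set: {name}")
            if len(set(genes)) != len(genes):
                genes = list(dict.fromkeys(genes))
            sets[name] = genes
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per cell (columns = cells, rows = genes)."""
    totals = counts.sum(axis=0)
    return counts.div(totals.where(totals > 0, np.nan), axis=1) * 1e6


def normalize_counts(counts: pd.DataFrame, min_cells: int = 10) -> pd.DataFrame:
    """log(1 + CPM) expression after the standard coverage filter.

    Genes expressed (count > 0) in fewer than ``min_cells`` cells are
    removed before normalization; all-zero cells are dropped with a warning
    reporting how many.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    zero_cells = counts.columns[counts.sum(axis=0) == 0]
    if len(zero_cells):
        warnings.warn(f"dropped {len(zero_cells)} all-zero cells")
        counts = counts.drop(columns=zero_cells)
    expressed_in = (counts > 0).sum(axis=1)
    counts = counts.loc[expressed_in >= min_cells]
    return np.log1p(cpm(counts))


def _walk_order(expr: np.ndarray, genes: np.ndarray):
    """Ranks and descending walk order with stable gene-id tie-breaking."""
    ranks = rankdata(expr, method="average")
    order = np.lexsort((genes, -ranks))
    return ranks, order


def ssgsea_cell(expression: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """ssGSEA running-sum score of one cell for one gene set."""
    genes = expression.index.to_numpy().astype(str)
    in_set = np.isin(genes, np.asarray(list(gene_set), dtype=str))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set does not overlap the expressed genes")
    if n_in == len(genes):
        raise ValueError("gene set covers all genes; out-set is empty")
    ranks, order = _walk_order(expression.to_numpy(float), genes)
    in_o = in_set[order]
    w = np.where(in_o, np.abs(ranks[order]) ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_o) / (len(genes) - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expression: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.25,
    normalize_range: bool = False,
) -> pd.DataFrame:
    """Cells x pathways ssGSEA score matrix.

    ``expression`` is genes x cells (e.g. the output of
    :func:`normalize_counts`). Gene sets with no overlap (or covering every
    measured gene) are dropped with a warning. With ``normalize_range`` the
    matrix is divided by its global score range (the optional secondary
    normalization; off by default since the downstream hierarchical model
    standardizes implicitly).
    """
    genes = expression.index.to_numpy().astype(str)
    X = expression.to_numpy(float)
    n_genes, n_cells = X.shape
    # per-cell ranks and walk orders
    ranks = np.apply_along_axis(rankdata, 0, X)
    cols = {}
    for name, gset in gene_sets.items():
        in_set = np.isin(genes, np.asarray(list(gset), dtype=str))
        n_in = int(in_set.sum())
        if n_in == 0 or n_in == n_genes:
            warnings.warn(f"gene set {name!r} dropped (overlap {n_in}/{n_genes})")
            continue
        scores = np.empty(n_cells)
        denom_out = n_genes - n_in
        for c in range(n_cells):
            order = np.lexsort((genes, -ranks[:, c]))
            in_o = in_set[order]
            w = np.where(in_o, ranks[order, c] ** alpha, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~in_o) / denom_out
            scores[c] = np.sum(p_in - p_out)
        cols[name] = scores
    out = pd.DataFrame(cols, index=expression.columns)
    if normalize_range and out.size:
        rng = out.to_numpy().max() - out.to_numpy().min()
        if rng > 0:
            out = out / rng
    return out


def composite_score(score_matrix: pd.DataFrame, pathway_subset=None) -> pd.Series:
    """First-PC composite of a correlated pathway family.

    Pathways are centered and scaled before projection; zero-variance
    pathways are dropped with a warning. The component sign is fixed so the
    composite correlates positively with the mean of the input pathways.
    """
    sub = score_matrix if pathway_subset is None else score_matrix.loc[:, list(pathway_subset)]
    sd = sub.std(axis=0, ddof=0)
    dead = sd.index[sd == 0]
    if len(dead):
        warnings.warn(f"dropped {len(dead)} zero-variance pathways: {list(dead)[:5]}")
        sub = sub.drop(columns=dead)
        sd = sd.drop(dead)
    if sub.shape[1] < 2:
        raise ValueError("composite needs >=2 pathways with variance")
    Z = (sub - sub.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    comp = U[:, 0] * S[0]
    ref = Z.mean(axis=1).to_numpy()
    if np.dot(comp - comp.mean(), ref - ref.mean()) < 0:
        comp = -comp
    return pd.Series(comp, index=score_matrix.index, name="composite")
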