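"""Phenotype-axis analysis for a single cell type (fibroblast-centric).

Reconstructs the major axes of within-cell-type phenotypic variation:
intrinsic dimensionality by the packing-number estimator, a deterministic
embedding into that many axes, spline F-tests for genes changing smoothly
along an axis, a high/low mesenchymal split at the centered axis score of
zero, and the ERBB ligand-score contrast between the strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeAxes",
    "estimate_intrinsic_dimension",
    "embed",
    "detect_dynamic_genes",
    "plateau_diagnostic",
    "classify_mesenchymal",
    "erbb_ligand_contrast",
]


@dataclass
class PhenotypeAxes:
    intrinsic_dim: int
    coordinates: pd.DataFrame         # cells x dim
    axis_correlations: np.ndarray     # pairwise |r| between axes
    dynamic_genes: dict | None = None


def _packing_count(points: np.ndarray, radius: float, order: np.ndarray) -> int:
    """Greedy epsilon-packing: keep a point iff farther than radius from all kept."""
    kept: list[np.ndarray] = []
    r2 = radius * radius
    for i in order:
        p = points[i]
        ok = True
        for q in kept:
            d = p - q
            if float(d @ d) <= r2:
                ok = False
                break
        if ok:
            kept.append(p)
    return len(kept)


def estimate_intrinsic_dimension(
    points,
    radii: tuple[float, float] | None = None,
    n_shuffles: int = 10,
    seed: int = 0,
    subsample: int = 1000,
) -> tuple[int, dict]:
    """Packing-number estimate of intrinsic dimensionality.

    Greedy epsilon-packings are counted at two radii r1 < r2 and the
    dimension is D = -(log M(r2) - log M(r1)) / (log r2 - log r1), averaged
    over ``n_shuffles`` random insertion orders and rounded. Default radii
    are the 5th and 10th percentiles of pairwise distances on a subsample:
    scale-adaptive, and small enough to sit in the scaling regime below the
    manifold's curvature scale (coarser radii read curved manifolds as their
    coarse-grained skeleton). Degenerate clouds (equal packing counts, or
    all points identical) return D = 0 with a flag.
    """
    X = np.asarray(points, float)
    if X.ndim != 2:
        raise ValueError("points must be 2-D (n x features)")
    rng = np.random.default_rng(seed)
    if radii is None:
        idx = rng.choice(len(X), size=min(subsample, len(X)), replace=False)
        sub = X[idx]
        d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
        d = np.sqrt(d2[np.triu_indices(len(sub), k=1)])
        d = d[d > 0]
        if d.size == 0:
            return 0, {"flag": "degenerate", "radii": (np.nan, np.nan)}
        r1, r2 = np.percentile(d, [5, 10])
    else:
        r1, r2 = radii
    if not 0 < r1 < r2:
        raise ValueError("need radii 0 < r1 < r2")
    ests = []
    counts = []
    for _ in range(n_shuffles):
        order = rng.permutation(len(X))
        m1 = _packing_count(X, r1, order)
        m2 = _packing_count(X, r2, order)
        counts.append((m1, m2))
        if m1 != m2:
            ests.append(-(np.log(m2) - np.log(m1)) / (np.log(r2) - np.log(r1)))
    if not ests:
        return 0, {"flag": "degenerate", "radii": (float(r1), float(r2)), "counts": counts}
    D = int(round(float(np.mean(ests))))
    return max(D, 0), {"flag": None, "radii": (float(r1), float(r2)),
                       "estimates": ests, "counts": counts}


def embed(matrix, dim: int, seed: int = 0, method: str = "pca") -> pd.DataFrame:
    """Deterministic embedding of cells into ``dim`` phenotype axes.

    The default is a linear principal-component projection (axes in
    decreasing variance order, sign fixed by the largest-loading rule), which
    is exactly reproducible. ``method='umap'`` plugs in the nonlinear
    neighbour embedding when the optional dependency is installed.
    """
    X = np.asarray(matrix, float)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(len(X))
    if method == "umap":
        try:
            import umap
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("umap-learn is not installed; use method='pca'") from exc
        coords = umap.UMAP(n_components=dim, random_state=seed).fit_transform(X)
    else:
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        # deterministic sign: largest-magnitude loading positive
        for k in range(min(dim, Vt.shape[0])):
            j = np.argmax(np.abs(Vt[k]))
            if Vt[k, j] < 0:
                Vt[k] *= -1.0
                U[:, k] *= -1.0
        coords = (U[:, :dim] * S[:dim])
    return pd.DataFrame(coords, index=index,
                        columns=[f"axis{k + 1}" for k in range(coords.shape[1])])


def _spline_basis(x: np.ndarray, n_knots: int = 5, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with interior knots at coordinate quantiles."""
    from scipy.interpolate import BSpline

    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    interior = np.quantile(x, qs)
    lo, hi = x.min(), x.max()
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    n_basis = len(t) - degree - 1
    B = np.empty((x.size, n_basis))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        B[:, j] = BSpline(t, c, degree, extrapolate=False)(x)
    return np.nan_to_num(B)


def detect_dynamic_genes(
    expression: pd.DataFrame,
    coordinate,
    k_top: int = 25,
    n_knots: int = 5,
) -> pd.DataFrame:
    """Rank genes by smooth (cubic-spline) variation along a phenotype axis.

    Each gene's log1p expression is regressed on a cubic B-spline basis of
    the axis coordinate; the F statistic of the smooth against the
    intercept-only model measures dynamic change. Returns the full ranked
    table with the top ``k_top`` flagged.
    """
    x = np.asarray(coordinate, float)
    B = _spline_basis(x, n_knots=n_knots)
    X = np.column_stack([np.ones_like(x), B[:, 1:]])  # drop one basis column for identifiability
    n, p = X.shape
    Y = np.log1p(expression.to_numpy(float))
    if Y.shape[0] == len(expression.index) and Y.shape[1] == x.size:
        Y = Y.T  # accept genes x cells
    XtX = X.T @ X
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    resid = Y - X @ beta
    rss1 = (resid ** 2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    df1, df2 = p - 1, n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    # constant genes: zero variance up to float rounding -> no dynamic signal
    flat = rss0 <= 1e-12 * n * (1.0 + Y.mean(axis=0) ** 2)
    F = np.clip(np.where(flat, 0.0, F), 0.0, None)
    from scipy.stats import f as fdist

    genes = expression.index if Y.shape[1] == len(expression.index) else expression.columns
    out = pd.DataFrame({"gene": genes, "F": F,
                        "p": fdist.sf(np.clip(F, 0, None), df1, df2)})
    out = out.sort_values("F", ascending=False, kind="mergesort").reset_index(drop=True)
    out["top"] = np.arange(len(out)) < k_top
    return out


def plateau_diagnostic(marker_expression: pd.Series, axis_score, n_bins: int = 20,
                       ax=None) -> pd.DataFrame:
    """Binned marker means along an axis, for eyeballing the high/low plateau.

    Supports the choice of the zero cutoff in :func:`classify_mesenchymal`:
    differentiation markers (collagens, fibronectin) should rise along the
    mesenchymal axis and plateau above the cutoff. Returns a table of bin
    centers and mean log1p marker expression; pass a matplotlib ``ax`` to
    draw it.
    """
    s = pd.Series(axis_score, dtype=float)
    centered = s - s.mean()
    edges = np.linspace(centered.min(), centered.max(), n_bins + 1)
    idx = np.clip(np.digitize(centered, edges) - 1, 0, n_bins - 1)
    vals = np.log1p(pd.Series(marker_expression, dtype=float).reindex(s.index))
    out = pd.DataFrame({"bin_center": 0.5 * (edges[:-1] + edges[1:]),
                        "marker_mean": [vals[idx == b].mean() for b in range(n_bins)]})
    if ax is not None:
        ax.plot(out["bin_center"], out["marker_mean"], marker="o")
        ax.axvline(0.0, linestyle="--")
        ax.set_xlabel("centered axis score")
        ax.set_ylabel("mean log1p marker expression")
    return out


def classify_mesenchymal(axis_score, delta: float = 0.0) -> pd.Series:
    """High/low mesenchymal split at a centered axis score of zero (+ optional shift)."""
    s = pd.Series(axis_score, dtype=float)
    centered = s - s.mean()
    labels = pd.Series(np.where(centered > delta, "high", "low"), index=s.index)
    if (labels == "high").sum() == 0:
        warnings.warn("no cells above the mesenchymal cutoff; 'high' stratum empty")
    return labels


def erbb_ligand_contrast(
    expression: pd.DataFrame,
    ligand_genes,
    strata: pd.Series,
    samples: pd.Series,
) -> dict:
    """ERBB ligand score contrast between mesenchymal strata, across samples.

    Per-cell score: mean over ligand genes of z-scored log1p expression.
    Scores are averaged per (sample, stratum) to respect the
    non-independence of cells within a tumor, then the high-low difference
    is tested across samples by one-way ANOVA.
    """
    import statsmodels.api as sm

    genes = [g for g in ligand_genes if g in expression.index]
    if not genes:
        raise ValueError("none of the ligand genes are in the expression matrix")
    E = np.log1p(expression.loc[genes].to_numpy(float))
    mu = E.mean(axis=1, keepdims=True)
    sd = E.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (E - mu) / sd
    cell_score = pd.Series(Z.mean(axis=0), index=expression.columns, name="erbb_score")
    df = pd.DataFrame({"score": cell_score,
                       "stratum": strata.reindex(cell_score.index),
                       "sample": samples.reindex(cell_score.index)})
    per = df.groupby(["sample", "stratum"], observed=True)["score"].mean().reset_index()
    hi = per.loc[per.stratum == "high", "score"]
    lo = per.loc[per.stratum == "low", "score"]
    if len(hi) == 0 or len(lo) == 0:
        return {"estimate": np.nan, "p": np.nan, "per_sample": per,
                "flag": "missing stratum"}
    if len(per) <= 2:
        return {"estimate": float(hi.mean() - lo.mean()), "p": np.nan,
                "per_sample": per, "flag": "too few samples for ANOVA"}
    y = per["score"].to_numpy(float)
    X = sm.add_constant((per["stratum"] == "high").astype(float).to_numpy())
    fit = sm.OLS(y, X).fit()
    return {"estimate": float(fit.params[1]), "se": float(fit.bse[1]),
            "p": float(fit.f_pvalue), "F": float(fit.fvalue),
            "per_sample": per, "flag": None}
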