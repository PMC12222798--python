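"""Subpopulation-weighted ligand-receptor communication scoring.

For each tumor sample, every broad cell type is subdivided into phenotype
subpopulations of >= 30 cells binned at equal interval width along its
phenotype axes. With P_i the proportion of subpopulation i among all cells
of the sample, x_ik the mean ligand CPM of sender subpopulation i for
ligand-receptor (LR) pathway k, and y_jk the mean receptor CPM of receiver
subpopulation j, communication follows the extended expression product:

    C_{i->j,k} = y_jk * x_ik * P_i

Signals from all sender subpopulations of a cell type are summed and
averaged over receiver subpopulations weighted by their abundance:

    C_{S->Rbar,k} = sum_z [ y_zk * (sum_i x_ik P_i) * P_z ] / sum_z P_z

Scores are log(1+C) transformed and standardized across samples per
(sender, receiver, pathway) before temporal contrasts; endpoint (day 0 vs
180) shifts are tested with linear models and BH-FDR, receptor families with
a mixed model pooling LR pathways, and cell-type sources summarized as a
directed weighted network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import cpm
from .stats import TestResult, fdr_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "CommProfile",
    "define_subpopulations",
    "build_profiles",
    "pairwise_score",
    "received_communication",
    "communication_table",
    "standardize_scores",
    "compare_pre_post",
    "receptor_trend_lmm",
    "communication_network",
    "default_erbb_pairs",
]


def default_erbb_pairs() -> pd.DataFrame:
    """Built-in ERBB growth-factor LR pathway table (editable default)."""
    from importlib.resources import files

    path = files("tmecrosstalk").joinpath("data/erbb_lr_pairs.tsv")
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Subpopulation binning
# ---------------------------------------------------------------------------

def define_subpopulations(
    coords: pd.DataFrame,
    cell_types: pd.Series,
    n_bins: int = 3,
    min_cells: int = 30,
) -> pd.Series:
    """Equal-interval phenotype bins per cell type, merged up to >= min_cells.

    ``coords`` holds the phenotype-axis coordinates (cells x axes) and
    ``cell_types`` the broad type of each cell (same index). Bins are the
    cross-product of equal-width intervals along each axis; bins under
    ``min_cells`` are merged into the nearest neighbour along the first axis
    until all subpopulations reach the floor. Cell types with fewer than
    ``min_cells`` cells form a single subpopulation.
    """
    coords = coords.loc[cell_types.index]
    labels = pd.Series(index=cell_types.index, dtype=object)
    axes = list(coords.columns)
    for ct, idx in cell_types.groupby(cell_types).groups.items():
        sub = coords.loc[idx]
        if len(idx) < min_cells or not axes:
            labels.loc[idx] = f"{ct}|0"
            continue
        bin_idx = np.zeros((len(idx), len(axes)), dtype=int)
        for a, ax in enumerate(axes):
            x = sub[ax].to_numpy(float)
            lo, hi = x.min(), x.max()
            if hi <= lo:
                continue
            bin_idx[:, a] = np.minimum((n_bins * (x - lo) / (hi - lo)).astype(int), n_bins - 1)
        keys = pd.Series([tuple(row) for row in bin_idx], index=idx)
        groups = {k: list(v) for k, v in keys.groupby(keys).groups.items()}
        centroid = {k: float(sub.loc[v, axes[0]].mean()) for k, v in groups.items()}
        while len(groups) > 1 and min(len(v) for v in groups.values()) < min_cells:
            small = min(groups, key=lambda k: len(groups[k]))
            others = [k for k in groups if k != small]
            tgt = min(others, key=lambda k: (abs(centroid[k] - centroid[small]), -len(groups[k])))
            merged = groups.pop(small) + groups.pop(tgt)
            key = tgt  # keep the larger/nearest bin's identity
            groups[key] = merged
            centroid[key] = float(sub.loc[merged, axes[0]].mean())
        for rank, (k, v) in enumerate(sorted(groups.items())):
            labels.loc[v] = f"{ct}|{rank}"
    return labels


# ---------------------------------------------------------------------------
# Profiles and scores
# ---------------------------------------------------------------------------

@dataclass
class CommProfile:
    """Per-sample subpopulation summary feeding the communication equations."""

    sample: str
    cell_type: pd.Series          # subpop -> parent cell type
    P_hat: pd.Series              # subpop -> proportion (sums to 1 over the sample)
    x: pd.DataFrame               # subpop x pathway mean ligand CPM
    y: pd.DataFrame               # subpop x pathway mean receptor CPM

    def __post_init__(self) -> None:
        if abs(float(self.P_hat.sum()) - 1.0) > 1e-9:
            raise ValueError("subpopulation proportions must sum to 1 per sample")


def _filter_pairs(lr_pairs: pd.DataFrame, genes) -> pd.DataFrame:
    genes = set(map(str, genes))
    ok = lr_pairs["ligand"].astype(str).isin(genes) & lr_pairs["receptor"].astype(str).isin(genes)
    if (~ok).any():
        dropped = lr_pairs.loc[~ok, "pathway_id"].tolist()
        logger.warning("dropped %d LR pathways with genes absent from the matrix: %s",
                       len(dropped), dropped[:10])
    return lr_pairs.loc[ok].reset_index(drop=True)


def build_profiles(
    counts: pd.DataFrame,
    cell_meta: pd.DataFrame,
    lr_pairs: pd.DataFrame,
    within_type_proportions: bool = False,
) -> dict[str, CommProfile]:
    """Per-sample CommProfiles from raw counts and cell labels.

    ``counts`` is genes x cells (raw); ``cell_meta`` is indexed by cell
    barcode with columns ``sample``, ``cell_type``, ``subpopulation``.
    Proportions are taken among all cells of the sample by default (flag
    switches to within-cell-type proportions). Ligand/receptor means are on
    CPM of the raw counts.
    """
    lr_pairs = _filter_pairs(lr_pairs, counts.index)
    if lr_pairs.empty:
        raise ValueError("no LR pathway has both genes in the count matrix")
    C = cpm(counts)
    profiles = {}
    for sample, meta_s in cell_meta.groupby("sample"):
        cells = meta_s.index
        sub = meta_s["subpopulation"]
        sizes = sub.value_counts()
        if within_type_proportions:
            type_tot = meta_s.groupby("cell_type").size()
            parent = meta_s.groupby("subpopulation")["cell_type"].first()
            P = sizes / parent.map(type_tot).reindex(sizes.index)
            P = P / P.sum()  # keep the invariant over the whole sample
        else:
            P = sizes / float(len(cells))
        ct = meta_s.groupby("subpopulation")["cell_type"].first()
        Xs = C.loc[:, cells]
        grp = Xs.T.groupby(sub).mean()  # subpop x gene mean CPM
        x = pd.DataFrame({pid: grp[lig].to_numpy()
                          for pid, lig in zip(lr_pairs["pathway_id"], lr_pairs["ligand"])},
                         index=grp.index)
        y = pd.DataFrame({pid: grp[rec].to_numpy()
                          for pid, rec in zip(lr_pairs["pathway_id"], lr_pairs["receptor"])},
                         index=grp.index)
        profiles[sample] = CommProfile(sample=sample, cell_type=ct,
                                       P_hat=P.sort_index(), x=x.sort_index(), y=y.sort_index())
    return profiles


def pairwise_score(x_ik: float, y_jk: float, P_i: float) -> float:
    """Extended expression product C = y * x * P (units CPM^2 * proportion)."""
    return y_jk * x_ik * P_i


def received_communication(profile: CommProfile, sender: str, receiver: str, pathway) -> float:
    """Strength of communication S -> typical cell of R for one LR pathway.

    Sums sender-subpopulation ligand output x*P and averages over receiver
    subpopulations weighted by their abundance.
    """
    if pathway not in profile.x.columns:
        logger.warning("pathway %s missing from profile %s", pathway, profile.sample)
        return float("nan")
    send = profile.cell_type.index[profile.cell_type == sender]
    recv = profile.cell_type.index[profile.cell_type == receiver]
    if len(recv) == 0 or len(send) == 0:
        return float("nan")
    total = float((profile.x.loc[send, pathway] * profile.P_hat.loc[send]).sum())
    Pr = profile.P_hat.loc[recv]
    num = float((profile.y.loc[recv, pathway] * total * Pr).sum())
    return num / float(Pr.sum())


def communication_table(profiles: dict[str, CommProfile], pairs=None) -> pd.DataFrame:
    """Tidy per-sample (sender, receiver, pathway) communication scores."""
    rows = []
    for sample, prof in profiles.items():
        types = sorted(prof.cell_type.unique())
        pathways = prof.x.columns if pairs is None else [p for p in pairs if p in prof.x.columns]
        for S in types:
            for R in types:
                for k in pathways:
                    rows.append((sample, S, R, k,
                                 received_communication(prof, S, R, k)))
    return pd.DataFrame(rows, columns=["sample", "sender", "receiver", "pathway", "C"])


def standardize_scores(table: pd.DataFrame) -> pd.DataFrame:
    """log(1+C) then z-score across samples per (sender, receiver, pathway).

    Constant scores get z = 0 and ``constant = True``.
    """
    out = table.copy()
    out["log1p_C"] = np.log1p(out["C"])
    out["constant"] = False

    def _z(g):
        v = g["log1p_C"]
        sd = v.std(ddof=1)  # sample sd across tumors
        if sd == 0 or np.isnan(sd):
            g = g.assign(z=0.0, constant=True)
        else:
            g = g.assign(z=(v - v.mean()) / sd)
        return g

    out = (out.groupby(["sender", "receiver", "pathway"], group_keys=False)[out.columns]
              .apply(_z))
    return out.reset_index(drop=True)


def compare_pre_post(table: pd.DataFrame, timepoints: pd.Series,
                     use: str = "log1p_C") -> pd.DataFrame:
    """Endpoint (t=0 vs t=1) linear-model contrast per (sender, receiver, pathway).

    ``timepoints`` maps sample -> 0/1. Returns estimate (post-pre difference
    of the transformed score), fold change on the (1+C) scale, p and BH q.
    """
    import statsmodels.api as sm

    df = table.copy()
    if "log1p_C" not in df.columns:
        df["log1p_C"] = np.log1p(df["C"])
    df["t"] = df["sample"].map(timepoints).astype(float)
    if df["t"].isna().any():
        raise ValueError("every sample needs a timepoint label")
    rows = []
    for (S, R, k), g in df.groupby(["sender", "receiver", "pathway"]):
        g = g.dropna(subset=[use])
        if g["t"].nunique() < 2 or len(g) < 3:
            rows.append((S, R, k, np.nan, np.nan, np.nan))
            continue
        y = g[use].to_numpy(float)
        X = sm.add_constant(g["t"].to_numpy(float))
        if np.var(y) < 1e-30:
            rows.append((S, R, k, 0.0, 1.0, 1.0))
            continue
        fit = sm.OLS(y, X).fit()
        delta = float(g.loc[g.t == 1, "log1p_C"].mean() - g.loc[g.t == 0, "log1p_C"].mean())
        rows.append((S, R, k, float(fit.params[1]), float(np.exp(delta)), float(fit.pvalues[1])))
    out = pd.DataFrame(rows, columns=["sender", "receiver", "pathway",
                                      "estimate", "fold_change", "p"])
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out


def receptor_trend_lmm(table: pd.DataFrame, timepoints: pd.Series,
                       receptor_of: pd.Series | None = None) -> dict:
    """Pooled temporal trend across a family of LR pathways sharing receptors.

    Fixed effects: per-receptor intercepts and per-receptor timepoint trends.
    Random effects: intercept and trend per LR pathway and intercept per
    sample. A single-pathway family collapses to the plain endpoint linear
    model. Inference on the pooled trend uses an LRT against the no-trend
    model.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats as sps

    df = table.copy()
    if "log1p_C" not in df.columns:
        df["log1p_C"] = np.log1p(df["C"])
    df["t"] = df["sample"].map(timepoints).astype(float)
    df["receptor"] = (df["pathway"].map(receptor_of) if receptor_of is not None
                      else df["pathway"])
    df = df.dropna(subset=["log1p_C", "t"])
    # a column literally named "C" shadows patsy's categorical operator
    df = df.drop(columns=[c for c in ("C", "z") if c in df.columns])
    n_path = df["pathway"].nunique()
    if n_path == 1:
        y = df["log1p_C"].to_numpy(float)
        X = sm.add_constant(df["t"].to_numpy(float))
        fit = sm.OLS(y, X).fit()
        return {"trend": float(fit.params[1]), "se": float(fit.bse[1]),
                "per_receptor": {df["receptor"].iloc[0]: float(fit.params[1])},
                "test": TestResult(statistic=float(fit.tvalues[1] ** 2), df=1,
                                   p_value=float(fit.pvalues[1]), estimate=float(fit.params[1])),
                "collapsed": True}

    one_receptor = df["receptor"].nunique() == 1
    fixed_full = "log1p_C ~ t" if one_receptor else "log1p_C ~ 0 + C(receptor) + C(receptor):t"
    fixed_null = "log1p_C ~ 1" if one_receptor else "log1p_C ~ 0 + C(receptor)"
    df["_g"] = 1
    vc = {"pathway": "0 + C(pathway)", "pathway_t": "0 + C(pathway):t",
          "tumor": "0 + C(sample)"}

    def _fit(formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm(formula, df, groups=df["_g"], vc_formula=vc, re_formula="0")
            return m.fit(reml=False, method="lbfgs", maxiter=400)

    full = _fit(fixed_full)
    nul = _fit(fixed_null)
    trend_terms = {k: float(v) for k, v in full.fe_params.items() if ":t" in k or k == "t"}
    pooled = float(np.mean(list(trend_terms.values())))
    stat = max(0.0, 2.0 * (full.llf - nul.llf))
    df_test = len(trend_terms)
    per_receptor = ({df["receptor"].iloc[0]: pooled} if one_receptor else
                    {k.split("[")[1].split("]")[0]: v for k, v in trend_terms.items()})
    ses = [float(full.bse_fe[k]) for k in trend_terms]
    return {"trend": pooled, "se": float(np.mean(ses)), "per_receptor": per_receptor,
            "test": TestResult(statistic=stat, df=df_test,
                               p_value=float(sps.chi2.sf(stat, df_test)), estimate=pooled),
            "collapsed": False}


def communication_network(table: pd.DataFrame, timepoints: pd.Series | None = None):
    """Directed cell-type network of mean communication with pre/post fold edges.

    Edge weight: mean over pathways and tumors of log(1+C) (post-treatment
    samples when timepoints are given, otherwise all samples). Edge
    ``fold_change``: exp of the mean across tumors of the within-tumor
    post-minus-pre mean difference on the log(1+C) scale.
    """
    import networkx as nx

    df = table.copy()
    if "log1p_C" not in df.columns:
        df["log1p_C"] = np.log1p(df["C"])
    G = nx.DiGraph()
    for ct in sorted(set(df["sender"]) | set(df["receiver"])):
        G.add_node(ct)
    if timepoints is not None:
        df["t"] = df["sample"].map(timepoints).astype(float)
        post = df[df["t"] == 1]
    else:
        post = df
    for (S, R), g in df.groupby(["sender", "receiver"]):
        gp = post[(post["sender"] == S) & (post["receiver"] == R)]
        weight = float(gp["log1p_C"].mean()) if len(gp) else 0.0
        fc = np.nan
        if timepoints is not None:
            m1 = g.loc[g.t == 1].groupby("sample")["log1p_C"].mean()
            m0 = g.loc[g.t == 0].groupby("sample")["log1p_C"].mean()
            if len(m0) and len(m1):
                fc = float(np.exp(m1.mean() - m0.mean()))
        G.add_edge(S, R, weight=0.0 if np.isnan(weight) else weight, fold_change=fc)
    return G
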