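"""Orchestration: configuration, stage execution, and format plumbing.

A run is described by one YAML config (unknown keys rejected for typo
safety). Stages execute in dependency order

    simulate -> score -> resistance -> communicate -> axes -> mutualism -> growth

each reading the previous stage's tidy outputs from the run directory and
writing its own, plus a manifest recording the package version, seed and
SHA-256 digests of all inputs so identical configs give identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "read_cohort", "write_cohort"]

STAGE_ORDER = ["simulate", "score", "resistance", "communicate", "axes", "mutualism", "growth"]

_TOP_KEYS = {"seed", "outdir", "stages", "simulate", "score", "resistance",
             "communicate", "axes", "mutualism", "growth", "log_level"}
_STAGE_KEYS = {
    "simulate": {"n_patients", "n_cells_per_sample", "n_genes", "n_pathways",
                 "frac_active_pathways", "beta0_mean", "beta_t_effect", "sigma_u0",
                 "sigma_ut", "sigma_e", "zinb_dispersion", "zinb_zero_prob",
                 "shift", "growth_cv", "growth_times"},
    "score": {"gmt", "n_sets", "genes_per_set", "alpha"},
    "resistance": {"min_cells"},
    "communicate": {"lr_table", "n_bins"},
    "axes": {"cell_type", "n_bins", "k_top"},
    "mutualism": {"params_json", "beta_grid_points", "x_grid_points"},
    "growth": {"curves_csv"},
}


class RunConfig:
    """Validated pipeline configuration."""

    def __init__(self, data: dict):
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.seed = int(data.get("seed", 0))
        self.outdir = Path(data.get("outdir", "run_out"))
        self.stages = list(data.get("stages", STAGE_ORDER))
        bad = [s for s in self.stages if s not in STAGE_ORDER]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        self.blocks = {}
        for stage in STAGE_ORDER:
            block = data.get(stage, {}) or {}
            unknown = set(block) - _STAGE_KEYS[stage]
            if unknown:
                raise ValueError(f"unknown keys in stage {stage!r}: {sorted(unknown)}")
            self.blocks[stage] = block
        # referenced paths must exist up front
        for stage, key in (("score", "gmt"), ("communicate", "lr_table"),
                           ("mutualism", "params_json"), ("growth", "curves_csv")):
            p = self.blocks[stage].get(key)
            if p is not None and not Path(p).exists():
                raise ValueError(f"config field {stage}.{key} points at a missing path: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Cohort round-trip I/O (MatrixMarket + TSV dialect)
# ---------------------------------------------------------------------------

def write_cohort(counts: pd.DataFrame, cell_meta: pd.DataFrame, outdir) -> None:
    """Write genes x cells counts and metadata (matrix.mtx, genes.tsv, barcodes.tsv, cell_meta.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")


def read_cohort(indir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`; order-preserving and lossless."""
    indir = Path(indir)
    mtx_path = indir / "matrix.mtx"
    with open(mtx_path) as fh:
        first = fh.readline()
    if not first.startswith("%%MatrixMarket"):
        raise ValueError(f"{mtx_path}: line 1: not a MatrixMarket header: {first.strip()!r}")
    mat = scipy.io.mmread(mtx_path)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    counts = pd.DataFrame(np.asarray(sp.csr_matrix(mat).todense()),
                          index=genes, columns=barcodes)
    meta = pd.read_csv(indir / "cell_meta.tsv", sep="\t", index_col=0)
    missing = barcodes[~barcodes.isin(meta.index)].tolist()
    extra = [b for b in meta.index if b not in set(barcodes)]
    if missing or extra:
        raise ValueError(f"barcodes/metadata mismatch; in matrix only: {missing[:5]}, "
                         f"in metadata only: {extra[:5]}")
    return counts, meta.loc[barcodes]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> list[str]:
    from .communication import default_erbb_pairs
    from .mutualism import invitro_params
    from .synthetic import CohortConfig, generate_count_cohort, generate_growth_curves, generate_score_cohort

    b = cfg.blocks["simulate"]
    cc_kwargs = {k: v for k, v in b.items() if k not in ("shift", "growth_cv", "growth_times")}
    config = CohortConfig(seed=cfg.seed, **cc_kwargs)
    lr = default_erbb_pairs()
    shift = b.get("shift", [{"cell_type": "fibroblast", "gene": "NRG1", "fold": 3.0}])
    cohort = generate_count_cohort(config, lr_pairs=lr, shift_spec=shift)
    write_cohort(cohort.counts, cohort.cell_meta, out / "cohort")
    scores, meta, truth = generate_score_cohort(config)
    scores.to_csv(out / "pathway_scores.tsv", sep="\t")
    meta.to_csv(out / "score_meta.tsv", sep="\t")
    with open(out / "truth.json", "w") as fh:
        json.dump({"beta_t": truth, "shifts": {f"{k[0]}:{k[1]}": v
                                               for k, v in cohort.truth["shifts"].items()},
                   "lr_fold": cohort.truth.get("lr_fold", {})}, fh, indent=2)
    times = b.get("growth_times", list(np.arange(0.0, 97.0, 24.0)))
    params = invitro_params()
    curves = generate_growth_curves(params, {"C0": 10_000, "F0": 10_000}, times,
                                    cv_noise=b.get("growth_cv", 0.1), seed=cfg.seed)
    curves.to_csv(out / "growth_curves.csv", index=False)
    return ["cohort/matrix.mtx", "pathway_scores.tsv", "score_meta.tsv",
            "truth.json", "growth_curves.csv"]


def _stage_score(cfg: RunConfig, out: Path) -> list[str]:
    from .scoring import normalize_counts, read_gmt, ssgsea_scores

    b = cfg.blocks["score"]
    counts, meta = read_cohort(out / "cohort")
    expr = normalize_counts(counts)
    if b.get("gmt"):
        sets = read_gmt(b["gmt"])
    else:
        rng = np.random.default_rng(cfg.seed + 1)
        genes = expr.index.to_numpy()
        n_sets, per = int(b.get("n_sets", 10)), int(b.get("genes_per_set", 15))
        sets = {f"set{j:02d}": list(rng.choice(genes, size=min(per, len(genes) - 1),
                                               replace=False)) for j in range(n_sets)}
    scores = ssgsea_scores(expr, sets, alpha=float(b.get("alpha", 0.25)))
    scores.to_csv(out / "cell_pathway_scores.tsv", sep="\t")
    return ["cell_pathway_scores.tsv"]


def _stage_resistance(cfg: RunConfig, out: Path) -> list[str]:
    from .stats import screen_pathways

    scores = pd.read_csv(out / "pathway_scores.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(out / "score_meta.tsv", sep="\t", index_col=0)
    res = screen_pathways(scores, meta["patient"], meta["t"], seed=cfg.seed,
                          min_cells=int(cfg.blocks["resistance"].get("min_cells", 20)))
    res.to_csv(out / "resistance_screen.tsv", sep="\t", index=False)
    return ["resistance_screen.tsv"]


def _stage_communicate(cfg: RunConfig, out: Path) -> list[str]:
    import networkx as nx

    from .communication import (build_profiles, communication_network, communication_table,
                                compare_pre_post, default_erbb_pairs, standardize_scores)

    b = cfg.blocks["communicate"]
    if b.get("lr_table"):
        lr = pd.read_csv(b["lr_table"], sep="\t")
    else:
        lr = default_erbb_pairs()
    if not {"pathway_id", "ligand", "receptor"} <= set(lr.columns):
        raise ValueError("LR table needs columns pathway_id, ligand, receptor")
    counts, meta = read_cohort(out / "cohort")
    profiles = build_profiles(counts, meta, lr)
    table = communication_table(profiles)
    table = standardize_scores(table)
    table.to_csv(out / "comm_scores.tsv", sep="\t", index=False)
    tp = meta.groupby("sample")["t"].first()
    tests = compare_pre_post(table, tp)
    tests.to_csv(out / "comm_tests.tsv", sep="\t", index=False)
    G = communication_network(table, tp)
    nx.write_graphml(G, out / "comm_network.graphml")
    edges = nx.to_pandas_edgelist(G)
    edges.to_csv(out / "comm_edges.tsv", sep="\t", index=False)
    return ["comm_scores.tsv", "comm_tests.tsv", "comm_network.graphml", "comm_edges.tsv"]


def _stage_axes(cfg: RunConfig, out: Path) -> list[str]:
    from .axes import classify_mesenchymal, detect_dynamic_genes, embed, estimate_intrinsic_dimension
    from .scoring import normalize_counts

    b = cfg.blocks["axes"]
    ct = b.get("cell_type", "fibroblast")
    counts, meta = read_cohort(out / "cohort")
    cells = meta.index[meta["cell_type"] == ct]
    expr = normalize_counts(counts.loc[:, cells])
    coverage = (counts.loc[expr.index, cells] > 0).mean(axis=1)
    expr = expr.loc[coverage > 0.05]
    dim, info = estimate_intrinsic_dimension(expr.T.to_numpy(), seed=cfg.seed)
    dim = max(dim, 1)
    coords = embed(expr.T, dim=dim, seed=cfg.seed)
    strata = classify_mesenchymal(coords.iloc[:, 0])
    dyn = detect_dynamic_genes(expr, coords.iloc[:, 0].to_numpy(), k_top=int(b.get("k_top", 25)))
    aug = meta.loc[cells].copy()
    for c in coords.columns:
        aug[c] = coords[c].to_numpy()
    aug["mesenchymal"] = strata.to_numpy()
    aug.to_csv(out / "fibroblast_axes.tsv", sep="\t")
    dyn.to_csv(out / "dynamic_genes.tsv", sep="\t", index=False)
    with open(out / "intrinsic_dim.json", "w") as fh:
        json.dump({"intrinsic_dim": int(dim), "radii": info["radii"]}, fh)
    return ["fibroblast_axes.tsv", "dynamic_genes.tsv", "intrinsic_dim.json"]


def _stage_mutualism(cfg: RunConfig, out: Path) -> list[str]:
    from .mutualism import MutualismParams, invitro_params, steady_state, stress_gradient_scan

    b = cfg.blocks["mutualism"]
    params = (MutualismParams.from_json(b["params_json"]) if b.get("params_json")
              else invitro_params())
    ss = steady_state(params.replace(X=0.5))
    scan = stress_gradient_scan(params,
                                np.linspace(0.0, params.beta_C, int(b.get("beta_grid_points", 15))),
                                np.linspace(0.0, 1.0, int(b.get("x_grid_points", 11))))
    rows = []
    for a, X in enumerate(scan["X"]):
        for bb, bC in enumerate(scan["beta_C"]):
            rows.append((X, bC, scan["C_star"][a, bb], scan["F_star"][a, bb],
                         bool(scan["extinct"][a, bb])))
    pd.DataFrame(rows, columns=["X", "beta_C", "C_star", "F_star", "extinct"]).to_csv(
        out / "stress_gradient_scan.csv", index=False)
    with open(out / "steady_state.json", "w") as fh:
        json.dump({"C_star": ss.C_star, "F_star": ss.F_star, "converged": ss.converged,
                   "residual": ss.residual, "X": 0.5}, fh, indent=2)
    return ["stress_gradient_scan.csv", "steady_state.json"]


def _stage_growth(cfg: RunConfig, out: Path) -> list[str]:
    from .growth import fit_growth_rate

    b = cfg.blocks["growth"]
    path = Path(b.get("curves_csv") or out / "growth_curves.csv")
    curves = pd.read_csv(path)
    rows = []
    for (rep, channel), g in curves.groupby(["replicate", "channel"]):
        rate, se = fit_growth_rate(g["hour"], g["value"])
        rows.append((rep, channel, rate, se))
    pd.DataFrame(rows, columns=["replicate", "channel", "rate", "se"]).to_csv(
        out / "growth_rates.tsv", sep="\t", index=False)
    return ["growth_rates.tsv"]


_STAGE_FN = {"simulate": _stage_simulate, "score": _stage_score,
             "resistance": _stage_resistance, "communicate": _stage_communicate,
             "axes": _stage_axes, "mutualism": _stage_mutualism, "growth": _stage_growth}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    from importlib.metadata import version

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        pkg_version = version("tmecrosstalk")
    except Exception:
        pkg_version = "unknown"
    manifest: dict = {"package": "tmecrosstalk", "version": pkg_version,
                      "seed": config.seed, "stages": {}, "input_digests": {}}
    for stage, key in (("score", "gmt"), ("communicate", "lr_table"),
                       ("mutualism", "params_json"), ("growth", "curves_csv")):
        p = config.blocks[stage].get(key)
        if p:
            manifest["input_digests"][f"{stage}.{key}"] = _sha256(Path(p))
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        try:
            outputs = _STAGE_FN[stage](config, out)
        except Exception:
            manifest["stages"][stage] = {"status": "failed"}
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            logger.exception("stage %s failed; partial outputs preserved in %s", stage, out)
            raise
        manifest["stages"][stage] = {"status": "ok", "outputs": outputs}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
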