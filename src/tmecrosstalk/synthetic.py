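"""Synthetic cohorts with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs and carry ground truth for
recovery tests:

* :func:`generate_score_cohort` draws per-cell pathway scores from the
  hierarchical random intercept/slope model (patient-level bivariate-normal
  effects, iid Gaussian cell noise, timepoint coded 0/1 for day 0/180).
* :func:`generate_count_cohort` draws gene x cell counts from a
  zero-inflated negative binomial around cell-type/subpopulation mean
  profiles, with lognormal library-size variation, Dirichlet subpopulation
  proportions per sample, and treatment-shifted ligand expression in a
  chosen sender cell type.
* :func:`generate_growth_curves` integrates the mutualism ODE and applies
  multiplicative lognormal measurement noise, emulating the fluorescence
  spheroid assays (monocultures by seeding the partner at zero).

All randomness flows from the single seed in the config/arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mutualism import MutualismParams, simulate

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_score_cohort",
    "generate_count_cohort",
    "generate_growth_curves",
]


@dataclass
class CohortConfig:
    """Study-design and noise parameters for the synthetic cohorts.

    Score-model fields mirror the hierarchical shift model: ``beta0_mean``
    and ``beta_t_effect`` are the cohort baseline and treatment shift in
    score units; ``sigma_u0``/``sigma_ut`` the patient-level intercept/slope
    SDs (``u_corr`` their correlation); ``sigma_e`` the cell-level SD.
    Count-model fields set the zero-inflated negative binomial noise and
    library-size spread.
    """

    n_patients: int = 20
    n_cells_per_sample: int = 200
    n_genes: int = 200
    n_pathways: int = 20
    frac_active_pathways: float = 0.25
    beta0_mean: float = 0.0
    beta_t_effect: float = 0.01
    sigma_u0: float = 0.02
    sigma_ut: float = 0.01
    sigma_e: float = 0.02
    u_corr: float = 0.0
    zinb_dispersion: float = 2.0
    zinb_zero_prob: float = 0.05
    lib_cv: float = 0.3
    mean_counts_per_cell: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_u0, self.sigma_ut, self.sigma_e) < 0:
            raise ValueError("all sds must be >= 0")
        if self.n_cells_per_sample < 30:
            raise ValueError("n_cells_per_sample must be >= 30 (cohort inclusion rule)")
        if not 0 <= self.frac_active_pathways <= 1:
            raise ValueError("frac_active_pathways must be in [0, 1]")
        if not 0 <= self.zinb_zero_prob <= 1:
            raise ValueError("zinb_zero_prob must be in [0, 1]")
        if self.zinb_dispersion <= 0:
            raise ValueError("zinb_dispersion must be > 0")
        omega = self.omega_u
        if abs(self.u_corr) > 1 or np.linalg.eigvalsh(omega).min() < -1e-12:
            raise ValueError(
                f"random-effect covariance is not positive semidefinite (u_corr={self.u_corr})"
            )

    @property
    def omega_u(self) -> np.ndarray:
        cov = self.u_corr * self.sigma_u0 * self.sigma_ut
        return np.array([[self.sigma_u0 ** 2, cov], [cov, self.sigma_ut ** 2]])


def _psd_sqrt(omega: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(omega)
    w = np.clip(w, 0.0, None)
    return V @ np.diag(np.sqrt(w)) @ V.T


def generate_score_cohort(config: CohortConfig):
    """Per-cell pathway scores from the hierarchical model, with truth.

    Returns ``(scores, meta, truth)``: a cells x pathways DataFrame, per-cell
    metadata (patient, day in {0, 180}, t in {0, 1}), and a dict mapping each
    pathway to its true beta_t (0 for null pathways).
    """
    rng = np.random.default_rng(config.seed)
    P, n = config.n_patients, config.n_cells_per_sample
    pathways = [f"pw{k:03d}" for k in range(config.n_pathways)]
    active = rng.random(config.n_pathways) < config.frac_active_pathways
    truth = {pw: (config.beta_t_effect if a else 0.0) for pw, a in zip(pathways, active)}

    A = _psd_sqrt(config.omega_u)
    patients = np.repeat([f"patient{i:02d}" for i in range(P)], 2 * n)
    t = np.tile(np.repeat([0, 1], n), P)
    meta = pd.DataFrame({"patient": patients, "t": t, "day": np.where(t == 0, 0, 180)})
    meta.index = [f"cell{c:06d}" for c in range(len(meta))]

    scores = np.empty((len(meta), config.n_pathways))
    for k, pw in enumerate(pathways):
        u = rng.standard_normal((P, 2)) @ A.T          # (u0, ut) per patient
        beta_t = truth[pw]
        tt = np.repeat([0.0, 1.0], n)  # per patient: n pre cells then n post cells
        mu = config.beta0_mean + u[:, 0][:, None] + (beta_t + u[:, 1][:, None]) * tt[None, :]
        e = rng.normal(0.0, config.sigma_e, size=(P, 2 * n))
        scores[:, k] = (mu + e).ravel()
    scores = pd.DataFrame(scores, index=meta.index, columns=pathways)
    return scores, meta, truth


@dataclass
class SyntheticCohort:
    counts: pd.DataFrame            # genes x cells, nonnegative ints
    cell_meta: pd.DataFrame         # per cell: patient, sample, day, t, cell_type, subpopulation
    truth: dict = field(default_factory=dict)


DEFAULT_CELL_TYPES = ("cancer", "fibroblast", "epithelial")


def generate_count_cohort(
    config: CohortConfig,
    lr_pairs: pd.DataFrame | None = None,
    shift_spec: Sequence[dict] | None = None,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    n_subpops: int = 2,
) -> SyntheticCohort:
    """ZINB count cohort with cell-type/subpopulation structure and LR shifts.

    ``shift_spec`` is a list of dicts ``{"cell_type": ..., "gene": ...,
    "fold": ...}``; the named gene's mean is multiplied by ``fold`` in
    post-treatment cells of that type. Subpopulation proportions are drawn
    from a symmetric Dirichlet(alpha=2) per sample. Truth records the
    requested shifts and, when ``lr_pairs`` is given, the implied fold change
    per LR pathway whose ligand was shifted.
    """
    rng = np.random.default_rng(config.seed)
    named = []
    if lr_pairs is not None:
        named = sorted(set(lr_pairs["ligand"].astype(str)) | set(lr_pairs["receptor"].astype(str)))
    n_bg = max(config.n_genes - len(named), 10)
    genes = named + [f"g{j:04d}" for j in range(n_bg)]

    shift_spec = list(shift_spec or [])
    for s in shift_spec:
        if s["gene"] not in genes:
            raise ValueError(f"shift gene {s['gene']!r} not in the gene universe")
        if s["cell_type"] not in cell_types:
            raise ValueError(f"shift cell type {s['cell_type']!r} unknown")

    # base mean profile (relative expression), lognormal across genes
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    # named LR genes kept comfortably expressed so CPM means are informative
    base[: len(named)] = rng.lognormal(mean=1.0, sigma=0.5, size=len(named))
    units = [(ct, sp) for ct in cell_types for sp in range(n_subpops)]
    unit_factor = {u: rng.lognormal(mean=0.0, sigma=0.3, size=len(genes)) for u in units}

    rows_meta = []
    count_cols = []
    cells_names = []
    theta, pi = config.zinb_dispersion, config.zinb_zero_prob
    for i in range(config.n_patients):
        pat = f"patient{i:02d}"
        for t, day in ((0, 0), (1, 180)):
            sample = f"{pat}_d{day}"
            props = rng.dirichlet(np.full(len(units), 2.0))
            alloc = rng.multinomial(config.n_cells_per_sample, props)
            for (ct, sp), n_u in zip(units, alloc):
                if n_u == 0:
                    continue
                m = base * unit_factor[(ct, sp)]
                if t == 1:
                    for s in shift_spec:
                        if s["cell_type"] == ct:
                            m = m.copy()
                            m[genes.index(s["gene"])] *= s["fold"]
                lib = config.mean_counts_per_cell * (
                    rng.lognormal(-0.5 * np.log(1 + config.lib_cv ** 2),
                                  np.sqrt(np.log(1 + config.lib_cv ** 2)), size=n_u)
                    if config.lib_cv > 0 else np.ones(n_u))
                rate = np.outer(m / m.sum(), lib)  # genes x cells expected counts
                if theta > 1e6:
                    lam = rate
                else:
                    lam = rng.gamma(shape=theta, scale=rate / theta)
                cnt = rng.poisson(lam)
                if pi > 0:
                    cnt = cnt * (rng.random(cnt.shape) >= pi)
                # keep column sums positive (invariant): give empty cells one count
                empty = cnt.sum(axis=0) == 0
                if empty.any():
                    cnt[rng.integers(0, len(genes), size=int(empty.sum())), np.flatnonzero(empty)] = 1
                count_cols.append(cnt)
                for c in range(n_u):
                    name = f"{sample}_{ct}{sp}_{c:04d}"
                    cells_names.append(name)
                    rows_meta.append((name, pat, sample, day, t, ct, f"{ct}|{sp}"))

    counts = pd.DataFrame(np.concatenate(count_cols, axis=1), index=genes, columns=cells_names)
    meta = pd.DataFrame(rows_meta, columns=["cell", "patient", "sample", "day", "t",
                                            "cell_type", "subpopulation"]).set_index("cell")
    truth: dict = {"shifts": {(s["cell_type"], s["gene"]): s["fold"] for s in shift_spec}}
    if lr_pairs is not None:
        lr_truth = {}
        for _, row in lr_pairs.iterrows():
            folds = [s["fold"] for s in shift_spec if s["gene"] == row["ligand"]]
            lr_truth[row["pathway_id"]] = float(np.prod(folds)) if folds else 1.0
        truth["lr_fold"] = lr_truth
    return SyntheticCohort(counts=counts, cell_meta=meta, truth=truth)


def generate_growth_curves(
    params: MutualismParams,
    seeding: dict,
    times: Sequence[float],
    cv_noise: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    halt_division: bool = False,
) -> pd.DataFrame:
    """Noisy mono/coculture growth curves from the mutualism ODE.

    ``seeding`` holds ``C0`` and ``F0`` (either may be 0 for a monoculture).
    Trajectories are multiplied by mean-one lognormal noise of coefficient of
    variation ``cv_noise``. ``halt_division=True`` emulates a saturating
    cytostatic treatment (division terms set to zero, pure exponential decay
    at the death rate) as used by the death-rate assay. Returns a tidy frame
    (replicate, channel, hour, value).
    """
    if cv_noise < 0:
        raise ValueError("cv_noise must be >= 0")
    C0, F0 = float(seeding["C0"]), float(seeding["F0"])
    if C0 < 0 or F0 < 0:
        raise ValueError("seeding abundances must be >= 0")
    p = params.replace(r_C=0.0, r_F=0.0) if halt_division else params
    traj = simulate(p, C0, F0, np.asarray(times, float))
    rng = np.random.default_rng(seed)
    sig = np.sqrt(np.log(1.0 + cv_noise ** 2)) if cv_noise > 0 else 0.0
    rows = []
    for rep in range(n_replicates):
        for channel, curve in (("cancer", traj["C"]), ("fibroblast", traj["F"])):
            noise = (np.exp(rng.normal(-0.5 * sig ** 2, sig, size=len(curve)))
                     if sig > 0 else np.ones(len(curve)))
            for h, v in zip(traj["times"], curve * noise):
                rows.append((rep, channel, float(h), float(v)))
    return pd.DataFrame(rows, columns=["replicate", "channel", "hour", "value"])
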