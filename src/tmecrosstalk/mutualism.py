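"""Cancer-fibroblast mutualism dynamics.

A two-species ODE in which each population stimulates the division of the
other (facilitation), endocrine drug pressure ``X`` divides the cancer
division term hyperbolically, and a constant per-capita death rate applies
to both populations:

    dC/dt = r_C * (1 + beta_C * F) / (1 + X) * C * (1 - C/K_C) - mu * C
    dF/dt = r_F * (1 + beta_F * C)           * F * (1 - F/K_F) - mu * F

Units: rates are cells/cell/hour, abundances are cells, ``X`` is a rescaled
fulvestrant dose in [0, 1] (0 nM -> 0, 5 nM -> 1) and ``beta`` terms are
per cocultured partner cell.

The module provides simulation, Newton steady-state analysis, extinction
boundary scans over (beta_C, X), and the growth-rate-difference parameter
estimators used to infer facilitation from mono/coculture spheroid assays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MutualismParams",
    "SteadyState",
    "invitro_params",
    "rhs",
    "jacobian",
    "simulate",
    "steady_state",
    "persistence_threshold",
    "stress_gradient_scan",
    "fit_loglinear_rate",
    "exponential_window",
    "estimate_params",
    "dose_to_X",
]


@dataclass
class MutualismParams:
    """Parameters of the mutualism ODE (rates in cells/cell/hour)."""

    r_C: float
    r_F: float
    beta_C: float
    beta_F: float
    mu: float
    K_C: float
    K_F: float
    X: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_C", "r_F", "beta_C", "beta_F", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.K_C <= 0 or self.K_F <= 0:
            raise ValueError("carrying capacities must be > 0")
        if not 0.0 <= self.X <= 1.0:
            raise ValueError("X must lie in [0, 1]")

    def replace(self, **kw) -> "MutualismParams":
        d = asdict(self)
        d.update(kw)
        return MutualismParams(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MutualismParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def invitro_params(C0: float = 10_000.0, F0: float = 10_000.0, X: float = 0.0) -> MutualismParams:
    """Inferred in-vitro parameter set with carrying capacity fixed at 100x seeding."""
    return MutualismParams(
        r_C=1.1e-3, r_F=1e-5, beta_C=4.19e-4, beta_F=0.207,
        mu=1e-3, K_C=100.0 * C0, K_F=100.0 * F0, X=X,
    )


@dataclass
class SteadyState:
    C_star: float
    F_star: float
    converged: bool
    residual: float


def rhs(state: Sequence[float], params: MutualismParams) -> np.ndarray:
    """Time derivatives (dC/dt, dF/dt) at a state (C, F)."""
    C, F = state
    dC = params.r_C * (1.0 + params.beta_C * F) / (1.0 + params.X) * C * (1.0 - C / params.K_C) - params.mu * C
    dF = params.r_F * (1.0 + params.beta_F * C) * F * (1.0 - F / params.K_F) - params.mu * F
    return np.array([dC, dF])


def jacobian(state: Sequence[float], params: MutualismParams) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` with respect to (C, F)."""
    C, F = state
    gC = params.r_C * (1.0 + params.beta_C * F) / (1.0 + params.X)
    gF = params.r_F * (1.0 + params.beta_F * C)
    j11 = gC * (1.0 - 2.0 * C / params.K_C) - params.mu
    j12 = params.r_C * params.beta_C / (1.0 + params.X) * C * (1.0 - C / params.K_C)
    j21 = params.r_F * params.beta_F * F * (1.0 - F / params.K_F)
    j22 = gF * (1.0 - 2.0 * F / params.K_F) - params.mu
    return np.array([[j11, j12], [j21, j22]])


def simulate(
    params: MutualismParams,
    C0: float,
    F0: float,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict:
    """Integrate the ODE at the requested times with an adaptive stiff/non-stiff solver.

    Returns a dict with keys ``times``, ``C``, ``F``. Populations are clipped
    at zero (extinction is absorbing in the model; the clip only removes
    solver-level negative round-off).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if C0 < 0 or F0 < 0:
        raise ValueError("initial abundances must be >= 0")
    t0 = min(0.0, times[0])
    sol = solve_ivp(
        lambda t, y: rhs(y, params),
        (t0, times[-1]),
        [C0, F0],
        method="LSODA",
        t_eval=times,
        jac=lambda t, y: jacobian(y, params),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}; last state {sol.y[:, -1] if sol.y.size else None}")
    return {"times": times, "C": np.clip(sol.y[0], 0.0, None), "F": np.clip(sol.y[1], 0.0, None)}


def _scaled_residual(y: np.ndarray, params: MutualismParams) -> float:
    """Max |dN/dt| scaled by total abundance: a per-capita-rate convergence measure."""
    return float(np.max(np.abs(rhs(y, params))) / (1.0 + float(np.sum(np.abs(y)))))


def _newton(params: MutualismParams, init: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, float, bool]:
    y = np.asarray(init, dtype=float)
    for _ in range(max_iter):
        res = _scaled_residual(y, params)
        if res < tol:
            return y, res, True
        J = jacobian(y, params)
        try:
            step = np.linalg.solve(J, rhs(y, params))
        except np.linalg.LinAlgError:
            break
        y_new = np.clip(y - step, 0.0, None)
        if not np.all(np.isfinite(y_new)):
            break
        y = y_new
    return y, _scaled_residual(y, params), False


def steady_state(
    params: MutualismParams,
    init: Sequence[float] | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> SteadyState:
    """Locate a nonnegative steady state by Newton-Raphson with integration fallback.

    Newton starts at ``init`` (default: both populations at carrying
    capacity). If it fails to converge, the system is integrated for a long
    horizon and Newton is restarted from the endpoint. The reported residual
    is max |dN/dt| divided by (1 + total abundance) — a per-capita rate, so
    the same tolerance is meaningful from 10^2 to 10^6 cells.
    """
    if init is None:
        init = [params.K_C, params.K_F]
    y, res, ok = _newton(params, np.asarray(init, float), tol, max_iter)
    if not ok or np.any(y < 0):
        horizon = 50.0 / max(params.mu, params.r_C, params.r_F, 1e-6)
        traj = simulate(params, max(float(init[0]), 1e-6), max(float(init[1]), 1e-6),
                        np.linspace(1.0, horizon, 200), rtol=1e-10, atol=1e-12)
        y, res, ok = _newton(params, np.array([traj["C"][-1], traj["F"][-1]]), tol, max_iter)
        if not ok:
            y = np.array([traj["C"][-1], traj["F"][-1]])
            res = _scaled_residual(y, params)
            ok = res < tol
    C_star, F_star = (float(v) if v > tol else 0.0 for v in y)
    return SteadyState(C_star=C_star, F_star=F_star, converged=bool(ok), residual=res)


def persistence_threshold(params: MutualismParams, F_star: float) -> float:
    """Analytic low-density persistence margin for cancer.

    Cancer invades (C* > 0) iff r_C (1 + beta_C F*) / (1 + X) > mu, i.e.
    beta_C F* > (1 + X) mu / r_C - 1. Returns beta_C*F_star minus that bound;
    positive values mean persistence.
    """
    if params.r_C == 0:
        return -np.inf
    return params.beta_C * F_star - ((1.0 + params.X) * params.mu / params.r_C - 1.0)


def stress_gradient_scan(
    params: MutualismParams,
    beta_C_grid: Sequence[float],
    X_grid: Sequence[float],
) -> dict:
    """Steady-state cancer abundance over a (beta_C, X) grid, from high-density init.

    Returns the C* and F* surfaces, a boolean extinction mask, and for each X
    the analytic persistence margin evaluated at the fibroblast-only steady
    state (the relevant boundary when cancer is rare).
    """
    beta_C_grid = np.asarray(beta_C_grid, float)
    X_grid = np.asarray(X_grid, float)
    C = np.zeros((len(X_grid), len(beta_C_grid)))
    F = np.zeros_like(C)
    margin = np.zeros_like(C)
    for a, X in enumerate(X_grid):
        for b, bC in enumerate(beta_C_grid):
            p = params.replace(X=float(X), beta_C=float(bC))
            ss = steady_state(p)
            C[a, b], F[a, b] = ss.C_star, ss.F_star
            margin[a, b] = persistence_threshold(p, ss.F_star)
    return {
        "beta_C": beta_C_grid,
        "X": X_grid,
        "C_star": C,
        "F_star": F,
        "extinct": C <= 0.0,
        "persistence_margin": margin,
    }


# ---------------------------------------------------------------------------
# Parameter inference from growth curves
# ---------------------------------------------------------------------------

def fit_loglinear_rate(times: Sequence[float], abundances: Sequence[float]) -> tuple[float, float]:
    """Least-squares slope of log abundance against time; returns (rate, SE)."""
    t = np.asarray(times, float)
    n = np.asarray(abundances, float)
    keep = n > 0
    t, n = t[keep], n[keep]
    if t.size < 2:
        raise ValueError("need >=2 positive abundances for a rate fit")
    y = np.log(n)
    A = np.vstack([np.ones_like(t), t]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    dof = t.size - 2
    if dof > 0:
        resid = y - A @ coef
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        se = float(np.sqrt(cov[1, 1]))
    else:
        se = np.nan
    return float(coef[1]), se


def exponential_window(times: Sequence[float], abundances: Sequence[float], tol: float = 0.10) -> np.ndarray:
    """Indices of the earliest contiguous run where growth is exponential.

    Starting from the first two points, timepoints are appended while every
    abundance in the candidate window stays within ``tol`` (relative, i.e.
    within 10% by default) of the window's fitted exponential — an absolute
    residual bound on the log scale. Saturating or accelerating stretches are
    excluded.
    """
    t = np.asarray(times, float)
    n = np.asarray(abundances, float)
    pos = np.flatnonzero(n > 0)
    if pos.size < 2:
        raise ValueError("need >=2 positive abundances")
    t, logn = t[pos], np.log(n[pos])
    end = 2
    while end < t.size:
        idx = slice(0, end + 1)
        A = np.vstack([np.ones(end + 1), t[idx]]).T
        coef, *_ = np.linalg.lstsq(A, logn[idx], rcond=None)
        if np.any(np.abs(logn[idx] - A @ coef) > tol):
            break
        end += 1
    return pos[: end + 1]


def dose_to_X(dose_nM: float, saturating_dose_nM: float = 5.0) -> float:
    """Linear rescaling of fulvestrant dose to the drug-effect axis X in [0, 1]."""
    if dose_nM < 0:
        raise ValueError("dose must be >= 0")
    X = dose_nM / saturating_dose_nM
    if X > 1.0:
        import warnings

        warnings.warn(f"dose {dose_nM} nM above the {saturating_dose_nM} nM rescaling range; capping X at 1")
        X = 1.0
    return X


@dataclass
class EstimatedParams:
    params: MutualismParams
    se: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def _window_fit(times, abund, use_window: bool):
    """Log-linear rate over the exponential window; returns residual stats for pooling."""
    t = np.asarray(times, float)
    n = np.asarray(abund, float)
    if use_window:
        idx = exponential_window(t, n)
        t, n = t[idx], n[idx]
    g, se = fit_loglinear_rate(t, n)
    y = np.log(n[n > 0])
    tt = t[n > 0]
    A = np.vstack([np.ones_like(tt), tt]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((y - A @ coef) ** 2))
    dof = max(tt.size - 2, 0)
    sxx = float(np.sum((tt - tt.mean()) ** 2))
    return g, se, t, n, (rss, dof, sxx)


def estimate_params(
    mono_control: dict,
    mono_death: dict,
    coculture: dict,
    fibro_control: dict,
    C0: float,
    F0: float,
    dose_nM: float = 0.0,
    use_window: bool = True,
    partner_abundance: str = "window_mean",
) -> EstimatedParams:
    """Infer MutualismParams from mono/coculture growth curves.

    Each curve argument is a dict with ``times`` (hours) and the relevant
    abundance arrays (``C`` and/or ``F``). ``mono_death`` is the cancer
    monoculture under saturating cytostatic treatment (division halted), from
    which the death rate is read as the log-linear decline. Intrinsic
    division is the control growth rate plus the death rate, corrected for
    the logistic crowding factor at the observed window-mean abundance.
    Facilitation is inferred from the coculture minus monoculture growth-rate
    difference, inverted through the model's division term and divided by the
    partner's abundance (window mean by default, or the seeded value when
    ``partner_abundance='seeded'``).

    Carrying capacities follow the 100x-seeding rule (K = 100 * C0).
    """
    flags: list[str] = []
    K_C, K_F = 100.0 * C0, 100.0 * F0
    X = dose_to_X(dose_nM)

    # death rate: log-linear decline with division halted
    g_d, se_d, _, _, st_d = _window_fit(mono_death["times"], mono_death["C"], use_window)
    mu = -g_d
    if mu < 0:
        flags.append("death_rate_inadmissible")
        mu = 0.0

    # cancer intrinsic division from control monoculture
    g_m, se_m, t_m, n_m, st_m = _window_fit(mono_control["times"], mono_control["C"], use_window)
    crowd_C = 1.0 - float(np.mean(n_m)) / K_C
    r_C = (g_m + mu) * (1.0 + X) / crowd_C
    if r_C < 0:
        flags.append("r_C_inadmissible")
        r_C = 0.0

    # fibroblast intrinsic division from fibroblast monoculture
    g_f, se_f, t_f, n_f, st_f = _window_fit(fibro_control["times"], fibro_control["F"], use_window)
    crowd_F = 1.0 - float(np.mean(n_f)) / K_F
    r_F = (g_f + mu) / crowd_F
    if r_F < 0:
        flags.append("r_F_inadmissible")
        r_F = 0.0

    # facilitation of cancer by fibroblasts
    g_cc, se_cc, t_cc, n_cc, st_cc = _window_fit(coculture["times"], coculture["C"], use_window)
    idx = exponential_window(coculture["times"], coculture["C"]) if use_window else slice(None)
    F_part = float(np.mean(np.asarray(coculture["F"], float)[idx])) if partner_abundance == "window_mean" else F0
    crowd_cc = 1.0 - float(np.mean(n_cc)) / K_C
    if r_C > 0 and F_part > 0:
        beta_C = ((g_cc + mu) * (1.0 + X) / (r_C * crowd_cc) - 1.0) / F_part
    else:
        beta_C = np.nan
        flags.append("beta_C_unidentifiable")
    # facilitation of fibroblasts by cancer
    g_fc, se_fc, t_fc, n_fc, st_fc = _window_fit(coculture["times"], coculture["F"], use_window)
    C_part = float(np.mean(np.asarray(coculture["C"], float)[idx])) if partner_abundance == "window_mean" else C0
    crowd_fc = 1.0 - float(np.mean(n_fc)) / K_F
    if r_F > 0 and C_part > 0:
        beta_F = ((g_fc + mu) / (r_F * crowd_fc) - 1.0) / C_part
    else:
        beta_F = np.nan
        flags.append("beta_F_unidentifiable")

    beta_C = max(float(beta_C), 0.0) if np.isfinite(beta_C) else 0.0
    beta_F = max(float(beta_F), 0.0) if np.isfinite(beta_F) else 0.0
    params = MutualismParams(r_C=r_C, r_F=r_F, beta_C=beta_C, beta_F=beta_F,
                             mu=mu, K_C=K_C, K_F=K_F, X=X)
    # delta-method SEs on the log-linear slopes, propagating the division-rate
    # uncertainty into the facilitation estimates (covariances ignored). The
    # residual variance is pooled across all five curve fits: the assays share
    # one measurement process, and short exponential windows alone leave too
    # few residual dof for a stable per-fit variance.
    all_stats = [st_d, st_m, st_f, st_cc, st_fc]
    tot_dof = sum(d for _, d, _ in all_stats)
    if tot_dof > 0:
        sigma2 = sum(r for r, _, _ in all_stats) / tot_dof
        se_d, se_m, se_f, se_cc, se_fc = (
            float(np.sqrt(sigma2 / sxx)) if sxx > 0 else np.nan
            for _, _, sxx in all_stats)
    var_mu = se_d ** 2
    var_rC = ((1.0 + X) / crowd_C) ** 2 * (se_m ** 2 + var_mu)
    var_rF = (1.0 / crowd_F) ** 2 * (se_f ** 2 + var_mu)
    se = {"mu": se_d, "r_C": float(np.sqrt(var_rC)), "r_F": float(np.sqrt(var_rF))}
    if r_C > 0 and F_part > 0:
        A = (g_cc + mu) * (1.0 + X) / crowd_cc
        var_A = ((1.0 + X) / crowd_cc) ** 2 * (se_cc ** 2 + var_mu)
        se["beta_C"] = float(np.sqrt(var_A / r_C ** 2 + (A / r_C ** 2) ** 2 * var_rC) / F_part)
    else:
        se["beta_C"] = np.nan
    if r_F > 0 and C_part > 0:
        B = (g_fc + mu) / crowd_fc
        var_B = (1.0 / crowd_fc) ** 2 * (se_fc ** 2 + var_mu)
        se["beta_F"] = float(np.sqrt(var_B / r_F ** 2 + (B / r_F ** 2) ** 2 * var_rF) / C_part)
    else:
        se["beta_F"] = np.nan
    return EstimatedParams(params=params, se=se, flags=flags)
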