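# Methods

This note records the models implemented in `tmecrosstalk`, the numerical
and statistical choices behind them, what the synthetic generators do and do
not emulate, and known limitations.

## Hierarchical resistance screen (`tmecrosstalk.stats`)

**Model.** Per-cell pathway score of cell j in tumor i at timepoint
t ∈ {0, 1} (day 0 / day 180; the coding makes β_t the full pre→post shift):

    P_ij = (β₀ + u_0i) + (β_t + u_ti) t + e_ij,
    (u_0i, u_ti) ~ N(0, Ω_u),  e_ij ~ N(0, σ²_e).

**Likelihood and fitting.** Within a patient all cells share one of two
design rows, so the marginal covariance is compound-symmetric within each
timepoint group. The likelihood therefore depends on the data only through
each (patient, timepoint) group's size, mean and within-group sum of
squares: the within-group contrasts are iid N(0, σ²_e) and the two group
means are bivariate normal, with the Jacobian of the orthonormal transform
(−½ log n per group) included so the blocked likelihood equals the dense
multivariate-normal likelihood exactly (verified to 1e-6 against a dense
oracle in the test suite, and against `statsmodels MixedLM` for the fixed
effects). ML maximizes over (log σ²_e, Cholesky(Ω_u)) by bounded L-BFGS-B
with profiled GLS fixed effects, seed-controlled random restarts
(default 3), and a moment-based start. Degenerate (zero-variance) data fall
back to fixed effects with a flag. Cost is O(patients) per likelihood
evaluation, independent of cells per sample.

**Testing.** Activation is a likelihood-ratio test against the nested
β_t = 0 null; the random slope u_ti is retained in the null (a
`drop_null_slope` flag removes it). The default reference is a small-sample
calibration rather than χ²₁: cells within a sample are not independent, so
the contrast is effectively tested across the m patients with the baseline
mean and the intercept–slope covariance as nuisances, leaving m − 2
effective degrees of freedom. The statistic is mapped through the exact
one-sample relation stat = m·log(1 + t²/(m − 2)) and referred to F(1, m−2);
this converges to χ²₁ as m grows and holds the 5% type-I error at 20
patients (measured 0.040–0.058 over independent 500-simulation batches,
versus ≈0.072 for plain χ²₁). `reference="chisq"` restores the plain
version. FDR control is Benjamini–Hochberg with monotonicity enforcement;
NaN p-values propagate and are excluded from m.

Satterthwaite degrees of freedom, REML, and Kenward–Roger corrections are
out of scope; the LRT path covers the screen's inferential needs.

## ssGSEA and composites (`tmecrosstalk.scoring`)

Counts are filtered to genes expressed in ≥10 cells, all-zero cells are
dropped with a warning, and expression is log(1 + CPM). The per-cell ssGSEA
score walks genes in descending rank order (average ranks for ties, stable
gene-id order within ties) accumulating Σ_i [P_in(i) − P_out(i)], with the
in-set ECDF weighted by rank^α (α = 0.25 by default) and the out-set ECDF
unweighted. An optional global range normalization exists but is off: the
hierarchical model standardizes implicitly. Composites of correlated
pathway families are the first principal component of the z-scored score
matrix (deterministic SVD), sign-oriented to correlate positively with the
family mean.

## Communication scoring (`tmecrosstalk.communication`)

Subpopulations are equal-interval bins along each phenotype axis,
cross-producted over axes, with bins under 30 cells merged into the nearest
neighbour along the first axis (centroid distance); cell types under 30
cells form one subpopulation. Proportions P̂ are taken among all cells of a
sample (a flag switches to within-cell-type proportions); ligand/receptor
means are CPM of raw counts. The pairwise score is the extended expression
product C = y·x·P̂; cell-type-level communication sums over sender
subpopulations and abundance-weights over receiver subpopulations. Scores
are log(1+C)-transformed and standardized across samples per
(sender, receiver, pathway) using the sample (n−1) standard deviation;
constant scores get z = 0 with a flag. Endpoint day 0 vs 180 contrasts use
OLS with BH-FDR; fold changes are computed on the (1+C) scale so zeros are
tolerated. Receptor-family trends pool LR pathways in a mixed model (fixed
receptor × time effects; random pathway intercept/slope and sample
intercept via variance components), collapsing to the endpoint OLS for a
single-pathway family. Networks average log(1+C) per (sender, receiver)
over pathways and post-treatment samples, with per-edge fold changes from
within-tumor mean differences. Multi-subunit ligand/receptor complexes are
not supported; permutation-based specificity nulls (CellPhoneDB-style) are
out of scope.

## Fibroblast phenotype axes (`tmecrosstalk.axes`)

Intrinsic dimension uses the greedy ε-packing estimator at two radii,
D = −Δlog M / Δlog r, averaged over 10 shuffled insertion orders and
rounded. Default radii are the 5th and 10th percentiles of pairwise
distances on a ≤1000-point subsample: radii must sit in the scaling regime
below the manifold's curvature scale — at coarser radii (e.g. 25th/50th
percentiles) a torus surface reads as its one-dimensional skeleton. The
default embedding is a deterministic PCA projection (axes in decreasing
variance order, largest-loading sign convention); UMAP is pluggable when
installed. Dynamic genes along an axis are ranked by the F statistic of a
cubic B-spline fit (5 interior knots at coordinate quantiles, one basis
column dropped for identifiability) against the intercept-only model on
log1p expression; penalization is omitted — F-ranking at this scale is
robust to the basis choice. Mesenchymal classification thresholds the
centered axis score at zero (the plateau of differentiation markers can be
eyeballed with `plateau_diagnostic`); the ERBB ligand contrast averages
z-scored log1p ligand expression per cell, then per (sample, stratum) to
respect within-tumor dependence, and compares strata across samples by
ANOVA. Genes are pre-filtered to >5% coverage in the cell type before axis
work.

## Mutualism ODE (`tmecrosstalk.mutualism`)

    dC/dt = r_C (1 + β_C F)/(1 + X) C (1 − C/K_C) − μC
    dF/dt = r_F (1 + β_F C) F (1 − F/K_F) − μF

Rates are cells/cell/hour; X rescales fulvestrant dose linearly with 5 nM
→ 1 (doses above 5 nM cap at 1 with a warning); carrying capacities default
to 100× the seeded abundance. The bundled `invitro_params()` set is r_C =
1.1e-3, r_F = 1e-5, β_C = 4.19e-4, β_F = 0.207, μ = 1e-3. Simulation uses
LSODA (rtol 1e-8, atol 1e-10) with the analytic Jacobian; populations are
clipped at solver round-off. Steady states use Newton–Raphson from a
high-density start with a long-integration fallback; the reported residual
is max |dN/dt| / (1 + total abundance) — a per-capita rate, because at 10⁶
cells the raw |dN/dt| cancellation floor in double precision (~1e-10) is of
the same order as any meaningful tolerance. `stress_gradient_scan` maps C*
and F* over a (β_C, X) grid and returns the analytic low-density
persistence margin β_C F* − ((1+X)μ/r_C − 1) alongside the numerical
extinction mask.

**Parameter inference.** Growth rates are least-squares slopes of log
abundance vs time, optionally restricted to the earliest contiguous
exponential window (every point within 10% of the window's fitted
exponential — an absolute bound on the log scale). Death: μ̂ is the
log-linear decline of a monoculture with division halted (a saturating
cytostatic treatment); under finite X the decline is r/(1+X) − μ, so the
assay's reading of −μ is only exact in that limit. Division: r̂ =
(ĝ + μ̂)(1+X)/(1 − N̄/K), correcting logistic crowding at the window-mean
abundance. Facilitation inverts the model's division term:
β̂ = ((ĝ_co + μ̂)(1+X)/(r̂ (1 − N̄/K)) − 1)/partner abundance, with the
window-mean partner abundance by default (the partner grows during the
assay; `partner_abundance="seeded"` restores the seeding value). Slope
standard errors pool the residual variance across the five curve fits (the
assays share one measurement process) and propagate through the delta
method, including the r̂ uncertainty in the facilitation SEs (covariances
ignored, slightly conservative).

**Identifiability limits.** β is a ratio with r̂ in the denominator. The
delta-method SEs are trustworthy when the relative SE of r̂ is ≲20%; when
the monoculture growth signal is below assay noise (e.g. r_F = 1e-5/h
against 10% fluorescence noise) no honest standard error exists for β on
the original scale, and non-positive r̂ is flagged
(`*_inadmissible` / `beta_*_unidentifiable`) rather than propagated.
Noiseless round-trips recover the bundled parameter set to <0.1%; noisy
recovery is demonstrated at an identifiable operating point (r_C = 5e-3,
r_F = 3e-3, β_C = 1e-4, β_F = 2e-5, μ = 1e-3 per hour) over a 96-hour,
13-point, 3-replicate design with 10% lognormal noise — measured 3-SE
coverage is nominal (1 exceedance in 1000 parameter checks). The 14-day
horizon of the physical assay is not used for inference here because with
mutual facilitation the coculture reaches carrying capacity within it,
violating the exponential-phase assumption the estimators rely on.

## Growth quantification (`tmecrosstalk.growth`)

Fluorescence→abundance calibration is OLS with the inverse map floored at
zero (flagged). Growth rates are log-linear least squares (the nonlinear
natural-scale alternative is intentionally omitted; log-scale matches the
ODE estimators), excluding non-positive readings. `facilitation_effect`
keeps the raw descriptive quotient (g_co − g_mono)/partner abundance — on
ODE-generated curves it tracks r_C β_C/(1+X), not β_C itself.
`facilitation_lmm` pools the coculture effect across cell lines with a
random intercept+slope per line (single line collapses to OLS; LRT
inference), and `dose_trend` fits a low-rank spline of the coculture
benefit over dose.

## Synthetic generators (`tmecrosstalk.synthetic`)

All randomness flows from the single seed in `CohortConfig` or the function
arguments. The score generator draws the hierarchical model exactly
(bivariate-normal patient effects with optional correlation, validated
positive semidefinite; Gaussian cell noise; every patient sampled at both
timepoints). The count generator draws zero-inflated negative-binomial
counts (gamma–Poisson with dispersion θ, Poisson in the θ → ∞ limit;
Bernoulli zero-inflation) around lognormal gene means with per
(cell type, subpopulation) lognormal perturbations fixed across samples,
lognormal library sizes (CV 30% by default), symmetric Dirichlet(α = 2)
subpopulation proportions per sample, and multiplicative post-treatment
fold changes on chosen ligand genes in a chosen sender type; empty cells
receive one count so column sums stay positive. The growth generator
integrates the ODE and applies mean-one lognormal noise of a given CV;
`halt_division=True` emulates the saturating cytostatic death-rate assay.

Defaults were chosen once to mirror the study conditions: 20 patients × 200
cells for calibration/power work, pathway shifts of ~0.01 score units
against σ_e = 0.02 cell noise and patient SDs (0.02, 0.01) — the magnitude
scale of the cohort estimates — and 10,000-cell seedings for spheroids.
The generators do **not** emulate transcriptome-wide correlation structure,
doublets, ambient RNA, gene length/GC biases, batch effects, or cell-type
annotation error; passing tests demonstrate the statistical machinery is
correct under its stated model, not that real-data preprocessing is solved.

## Pipeline (`tmecrosstalk.pipeline`, CLI `tmecrosstalk`)

One YAML config per run; unknown keys are rejected (typo safety) and
referenced paths are validated up front. Stages run in dependency order
(simulate → score → resistance → communicate → axes → mutualism → growth),
exchange tidy TSV/CSV/JSON plus MatrixMarket cohorts, and write a manifest
(package version, seed, SHA-256 input digests, per-stage outputs; no
timestamps) so identical configs reproduce byte-identical outputs. A stage
failure preserves partial outputs and the manifest records it. Problem
sizes in the shipped demo config (4 patients × 120 cells, 80 genes) keep a
full run under ten seconds; all stages scale linearly in cells.
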