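# tmecrosstalk

Tools for asking how a tumor's microenvironment helps cancer cells survive
endocrine therapy, built around paired pre/post-treatment single-cell
RNA-seq cohorts and spheroid coculture assays in ER+ breast cancer. The
package detects treatment-induced phenotype shifts that recur across
patients, quantifies which cell types supply growth-factor ligands to
resistant cancer cells, characterizes the fibroblast states that produce
them, and models the resulting cancer–fibroblast mutualism as a dynamical
system. Every analysis runs end to end on built-in synthetic cohorts that
carry known ground truth, so the statistical machinery is testable without
any data download.

## The models

**Resistance phenotype screen.** For each pathway, per-cell ssGSEA scores
P_ij (cell j, tumor i) over the paired design (t = 0 pre, t = 1 post) follow
a hierarchical random-effects model

    P_ij = (β₀ + u_0i) + (β_t + u_ti)·t + e_ij,
    (u_0i, u_ti) ~ N(0, Ω_u),  e_ij ~ N(0, σ²_e),

where β_t is the cohort-level activation during treatment and the patient
random intercepts/slopes absorb tumor-specific baselines and responses.
Activation is tested by a likelihood-ratio test against the nested β_t = 0
null with a small-sample F(1, m−2) reference (m patients) and BH-FDR across
pathways. The ML fitter exploits the two-timepoint compound-symmetry
structure, so a fit costs microseconds per patient regardless of cells per
sample.

**Ligand–receptor communication.** Cell types are split into phenotype
subpopulations (≥30 cells, equal-interval bins along phenotype axes). With
P̂_i the proportion of subpopulation i in a sample, x_ik its mean ligand CPM
and y_jk a receiver subpopulation's mean receptor CPM for LR pathway k,
communication follows the extended expression product
C_{i→j,k} = y_jk · x_ik · P̂_i, summed over sender subpopulations and
averaged over receiver subpopulations weighted by abundance. Scores are
log(1+C)-transformed, standardized across samples, and contrasted day 0 vs
day 180 with linear and mixed models; cell-type sources are summarized as a
directed weighted network.

**Fibroblast phenotype axes.** Intrinsic dimensionality by the
packing-number estimator, deterministic embedding, spline F-tests for genes
changing smoothly along each axis, a high/low mesenchymal split at the
centered axis score of zero, and an ANOVA contrast of ERBB ligand output
between the strata.

**Cancer–fibroblast mutualism.** A two-species ODE in which each population
stimulates the other's division and endocrine drug pressure X ∈ [0, 1]
divides the cancer division term:

    dC/dt = r_C (1 + β_C F)/(1 + X) · C (1 − C/K_C) − μC
    dF/dt = r_F (1 + β_F C)         · F (1 − F/K_F) − μF

with simulation (LSODA), Newton steady states, extinction-boundary scans
over (β_C, X), and estimators that read r, μ and the facilitation rates β
off log-linear growth rates of mono- and coculture spheroid curves.

## Worked example

`python examples/mutualism_dynamics.py` analyzes the inferred in-vitro
parameter set (r_C = 1.1e-3, r_F = 1e-5, β_C = 4.19e-4, β_F = 0.207,
μ = 1e-3 per hour, K = 100 × 10,000 seeded cells):

```
net low-density growth without drug: r_C - mu = 1.0e-04 cells/cell/hour
cancer alone, X=0:            C* = 90,909 cells (= K_C (1 - mu/r_C) = 90,909)
cancer alone, X=0.5:          C* = 0 cells (division r_C/1.5 < mu: extinct)
with fibroblast facilitation: C* = 996,752, F* = 999,515 cells

14-day coculture under X=0.5: C grows 99.7x (10,000 -> 996,752 cells)
```

Without help, cancer barely outgrows its death rate (net 1e-4 per hour) and
a half-maximal endocrine dose suffices for extinction; with fibroblast
facilitation it instead grows to near carrying capacity at the same dose —
the quantitative case for breaking the mutualism (e.g. pan-ERBB inhibition)
rather than escalating the endocrine dose. The other scripts in `examples/`
demonstrate the resistance screen (`resistance_screen.py`), communication
scoring and network (`communication_shift.py`), fibroblast axes
(`fibroblast_axes.py`), growth-curve inference (`growth_inference.py`), and
the end-to-end pipeline (`full_pipeline.py`, or the `tmecrosstalk` CLI with
`examples/pipeline_config.yaml`).

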