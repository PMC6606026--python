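# Methods

This note documents the models, estimators, numerical choices and known
limitations of `cohesinquant`, and what the synthetic-data layer does and
does not emulate.

## FCS: model, fitting and quality control

The autocorrelation of the fluorescence trace from a Gaussian confocal
volume with two freely diffusing components is

G(τ) = G∞ + (1/N)·Σᵢ fᵢ·(1 + τ/τᵢ)⁻¹·(1 + τ/(κ²τᵢ))⁻¹ᐟ²,  f₁ + f₂ = 1,

with particle number `N`, diffusion times τᵢ (ms), and structure parameter κ
(axial/lateral extent of the detection volume). No triplet/blinking term is
included: the fitted species (EGFP fusions at moderate excitation) are
modelled as purely diffusive, and the synthetic curves contain no triplet
kinetics either. κ is fixed during fitting — from the dye calibration when
one is supplied, 5.0 by default — because κ and the τᵢ are strongly
correlated on noisy single curves; `AcfFitConfig(fit_kappa=True)` frees it.

Fitting is bounded least squares (lmfit/Levenberg-Marquardt) with
data-driven starts: the baseline from the last decade of lags, `N` from the
short-lag amplitude, τ starts bracketing the half-amplitude lag. `frac1` is
box-constrained to [0, 1]; the component-exchange symmetry is broken after
the fit by relabelling so τ₁ < τ₂. Non-convergence sets a `success=False`
flag; such fits are counted and removed by QC, never silently dropped.

**Goodness of fit.** R² is the ordinary coefficient of determination.
The reduced χ² per point divides the residual sum of squares by a per-point
noise variance and the number of lag points. The noise *scale* is estimated
from the ACF tail (half the variance of successive differences over the last
decade of lags, which is robust to residual slope); because ACF noise is
heteroscedastic, the per-point variance follows the photon-noise profile
sd(τ) ∝ G(τ) + 1/N, normalised to the tail level. Under the true model this
statistic is ≈ 1, so the acceptance threshold χ²/N < 1.2 separates model
misfit from ordinary noise. A constant (tail-only) variance would bias the
statistic to 1.5–2.5 for *correct* fits of heteroscedastic noise and make
the threshold reject nearly everything.

**QC cascade**, in order: drop failed fits; require R² > 0.92 and
χ²/N < 1.2; remove counts-per-molecule (CPM) outliers outside Tukey fences
of 3 interquartile ranges; remove fits with CPM ≥ 10× the mean free-mEGFP
CPM. The brightness cap is read as *keep CPM strictly below* ten reference
brightnesses (removing aggregates and bright junk); the per-rule rejection
counts are reported so the filter is auditable. Loosening any threshold can
only grow the retained set when the CPM population is stable; note that the
Tukey fences are recomputed on the surviving set, so pathological inputs can
in principle interact across stages.

**Volumes and copy numbers.** The dye calibration gives
V_eff = N/(C·N_A); concentrations are C = N/(V_eff·N_A) in nM; copies are
C·V·N_A with 1 µm³ = 10⁻¹⁵ L. Cytoplasmic volumes use
V_cyt ≈ V_nuc(V_r − 1) with V_r = 3.04 (interphase) and 5.72 (prometaphase).
Condition summaries are the median and the central 68% interval
(16th–84th percentile, linear interpolation between order statistics).

**Method-comparison bootstrap.** Each of `n_boot` iterations resamples both
measurement sets with replacement (full size) and forms the ratio of their
summary statistics (median by default); the ratio distribution's median and
central 68% interval summarise the agreement. This dataset-pair resampling
is what makes the 68% interval an approximate 68% confidence interval for
the ratio; resampling single measurement pairs would instead describe the
population spread and cover the null ratio almost always. Zero-denominator
pairs are redrawn and counted.

## iFRAP: normalisation, fits, partition

The difference between unbleached- and bleached-region intensities is
normalised to the pre-bleach mean and anchored to 1 at the first post-bleach
frame (t = 0, frames at 1-min intervals). Fits are bounded least squares of

- single: f(t) = e^(−kOff1·t)
- double: f(t) = a·e^(−kOff1·t) + (1−a)·e^(−kOff2·t), a ∈ [0, 1],
  1/kOff2 ∈ [1.5 h, 15 h] (hard box bounds)

with the fast/slow labels restored after fitting if the optimiser swaps
them. A slow residence pinned at either box bound is flagged. Degenerate
non-recovering curves report the rate at its lower bound with a warning.
Model selection uses AICc (small-sample corrected AIC; k = 1 vs 3
parameters), with ties resolved toward the single model; both fits remain
available to the caller. Pure reaction kinetics are assumed — no
reaction-diffusion FRAP modelling, no photobleaching correction beyond the
stated normalisation.

The soluble fraction is the relative drop of the unbleached-region signal
immediately after bleaching, divided by the bleached volume fraction
(default 0.5 — half the nucleus is bleached; configurable). Fractions
partition as: bound = 1 − soluble; stable = bound·(1 − a) (0 for the single
model); dynamic = bound·a. Per-condition fractions are means over cells with
across-cell SDs, matching mean ± SD reporting. Copy numbers multiply the
nuclear FCS median by the fractions; the stable pool takes the float
remainder so the three pools sum to the total up to one rounding ulp.

## SRM: spike-in arithmetic

fmol_light = (light apex height / heavy apex height) · spiked heavy fmol,
per transition; zero-heavy transitions are retracted (never zero-filled).
Peptide amounts are unweighted means over retained transitions (three
monitored per peptide); copies/cell = fmol·10⁻¹⁵·N_A/n_cells. Protein values
are unweighted means across peptides of replicate means; the reported SD is
over all replicate × peptide values. The combiner is deliberately the plain
mean — flags on the output (single-peptide, two-peptides, single-replicate)
let downstream consumers weigh the evidence. The measured ~17%
acetone-precipitation loss is exposed as an optional multiplicative
correction (1/(1−0.17)), off by default because the published tables do not
state whether it was applied. Cell-count uncertainty (62,500 ± 3,100 per
chromatin aliquot) is likewise not folded into the SD by default.
Stoichiometry ratios are per-replicate subunit/reference ratios with a
t-based 95% CI; STAG1 and STAG2 can be summed before ratioing.

## Equilibrium model

C_T = U + D + S with k_on·U = k_off·D at steady state gives
b_T = k_on/(k_on+k_off) + k_off/(k_on+k_off)·s — affine in the stable
fraction with intercept + slope = 1. The G1 bound fraction (s = 0)
identifies the intercept and hence only the *ratio* k_on/k_off; supplying an
absolute k_off (e.g. the inverse dynamic residence time) anchors both rates.
The model asserts, rather than tests, that k_on and k_off are unchanged by
stabilisation. Partitions keep full precision; three-decimal rounding
happens only in the report layer. s > b_T is rejected (the stable pool is a
subset of the bound pool).

## Genome occupancy

Coordinates are BED-convention 0-based half-open; strand is ignored; input
intervals are merged per chromosome at load. Whole-genome site counts scale
the mappable-genome counts by total/mappable genome size (2.7 → 7.9 Gb for
HeLa, hypotriploid, 64 chromosomes). Inter-peak distances are
**consecutive** midpoint-to-midpoint distances per chromosome (configurable
to edge-to-edge), never across chromosomes; single-peak chromosomes are
logged and skipped. Connected overlaps group mutually overlapping intervals
across datasets by a sweep; each component counts once and is labelled by
its contributing sets, so per-set totals in the overlap display are ≤ raw
peak counts. Touching half-open intervals do not overlap. Occupancy and
extrusion estimates are pure arithmetic; paper-style rounding (nearest
thousand / hundred / integer) lives in the report layer so raw values are
never lost.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic given seed + parameters, with one named
substream per generated entity (curve, cell, peptide, chromosome), so
enlarging an experiment never shifts existing noise.

- **FCS**: exact closed-form ACFs plus additive Gaussian noise with
  sd ∝ G(τ) + 1/N on a multiple-tau-style quasi-logarithmic lag ladder. This
  is a stand-in for photon statistics adequate for exercising the fitter; it
  does not simulate photon arrival times, detector afterpulsing, triplet
  kinetics or acquisition bleaching.
- **iFRAP**: region intensities built from the two-exponential bound-pool
  decay and instantaneous soluble re-equilibration (unbleached region reads
  1 − soluble·bleach-fraction immediately after the bleach), Gaussian noise
  on each region. Default conditions are 19 cells, 1-min frames over 60 min,
  noise SD 0.03 on the normalised signal — with a 60-min window the 8.6-h
  slow residence is identified mainly through the constraint box plus the
  late-time slope, which is exactly the published fitting situation.
- **SRM**: log-normal multiplicative noise on light/heavy ratios
  (mean-corrected; cv ≈ relative SD), constant heavy apex heights, three
  transitions per peptide. No chromatogram or spectral simulation.
- **Peak sets**: midpoint gaps drawn from constant/exponential/log-normal
  models (floored at the peak width so peaks never overlap), peaks clipped
  and flagged at chromosome ends. Real ChIP peak sets have width and
  enrichment structure this does not model.

Passing recovery tests on these inputs demonstrates estimator correctness
under the stated noise models, not robustness to every artefact of real
microscopy or MS data.

## Problem sizes and numerical defaults

Recovery tests run at the study's own scales where printed (19 FRAP cells
per condition, 2 biological × 2 technical SRM replicates, three transitions
per peptide) and at 100–200 curves/cells for ensemble medians; the
end-to-end pipeline default is 40 FCS curves, 8 FRAP cells and 2,000
bootstrap draws per run, chosen as comfortable desk-scale sizes that leave
the estimators' sampling error well inside the tolerances tested. Bootstrap
method comparisons default to 100,000 draws, matching the published
procedure. Tolerances asserted in tests: exact printed-precision equality
for deterministic arithmetic; 1% for reproducing the partition table from
rounded printed fractions; 5–15% for stochastic parameter recovery at the
stated noise levels.

## Known limitations

- Real FCS noise is correlated across lags; the independent-Gaussian
  synthetic noise makes the tail variance estimate optimistic relative to
  real correlator output.
- The χ²/N statistic depends on the fitted model through the noise profile;
  an entirely wrong model changes the profile as well as the residuals.
- The soluble-fraction estimate assumes instantaneous re-equilibration of
  the soluble pool during bleaching and a known bleached volume fraction.
- Peptide→protein aggregation weighs all peptides equally; discordant
  peptides (e.g. modified or miscleaved) are not down-weighted.
- The equilibrium model is deterministic and spatially homogeneous; no
  stochastic or polymer extensions.
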