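# cohesinquant

Quantitative machinery for measuring **absolute copy numbers and
chromatin-binding dynamics of cohesin, CTCF and their regulators** in human
(HeLa) cells, as done by combining targeted mass spectrometry,
fluorescence-correlation spectroscopy (FCS) and inverse fluorescence recovery
after photobleaching (iFRAP).

It is a library for researchers who want to go from raw-ish measurement
tables — autocorrelation curves, FRAP intensity series, SRM transition
exports, ChIP-seq peak coordinates — to absolute molecule counts per cell,
kinetic pool partitions, and genome-occupancy arithmetic, with the full QC
and statistics pipeline in between. A seeded synthetic-data layer generates
every input type with known ground truth, so each estimator has a
parameter-recovery test surface without any external downloads.

## What it computes

**FCS** (`cohesinquant.fcs`) — autocorrelation curves are fitted with a
two-component free 3D diffusion model

```
G(τ) = G∞ + (1/N) Σᵢ fᵢ (1 + τ/τᵢ)⁻¹ (1 + τ/(κ²τᵢ))⁻¹ᐟ²
```

where `N` is the particle number in the effective confocal volume
(calibrated with a 50 nM dye solution), giving concentrations
`C = N/(V_eff·N_A)` and, with segmented compartment volumes
(`V_cyt ≈ V_nuc(V_r − 1)`), copies per cell. A QC cascade (R² > 0.92,
χ²/N < 1.2, Tukey fences on molecular brightness, a 10× free-mEGFP
brightness cap) mirrors the published measurement filtering; a resampling
bootstrap compares FCS against orthogonal LC-MS counts.

**iFRAP** (`cohesinquant.frap`) — normalised bleached/unbleached difference
signals are fitted with `f(t) = a·e^(−kOff1·t) + (1−a)·e^(−kOff2·t)`
(slow residence box-constrained to 1.5–15 h), model selection by corrected
AIC, and the nuclear pool partitions into soluble, dynamic and stable
fractions that convert to copies via the FCS medians.

**SRM** (`cohesinquant.srm`) — light/heavy elution-apex height ratios times
the heavy-peptide spike give fmol per aliquot; dividing by the cell count
gives copies per cell, aggregated over transitions → peptides → proteins
with replicate SDs and subunit:SCC1 stoichiometry ratios (t-based 95% CIs).

**Equilibrium model** (`cohesinquant.equilibrium`) — with balanced exchange
`k_on·U = k_off·D`, the chromatin-bound fraction is affine in the stable
fraction: `b_T = k_on/(k_on+k_off) + k_off/(k_on+k_off)·s`. Calibrating at
G1 (s = 0, b_T = 0.635) predicts G2 binding with no free parameters.

**Genome occupancy** (`cohesinquant.occupancy`) — BED peak-set arithmetic:
extrapolating mappable-genome site counts to the full genome, inter-peak
spacing distributions, connected-overlap (Venn) counting where mutually
overlapping peaks collapse into one genomic site, and occupancy /
loop-extrusion rate estimates.

## Worked example

Calibrate the equilibrium model on G1 and predict the G2 bound fraction
(`python examples/equilibrium_prediction.py`):

```
calibrated on G1: intercept=0.635 slope=0.365
anchored rates:   k_on=0.1270 min^-1  k_off=0.0730 min^-1
predicted G2 bound fraction b_T(0.367) = 0.769
observed 0.728 -> absolute discrepancy 0.041
G1 partition of 250,755 nuclear copies: unbound 91,526, dynamic 159,229, stable 0
```

Stabilising ~37% of nuclear cohesin in G2 is, by itself, enough to raise the
chromatin-bound fraction from 0.635 to ~0.77 — close to the observed 0.73 —
without any change in the binding/unbinding rates. The copy-number partition
splits the ~250,000 nuclear G1 cohesin complexes into ~160,000
dynamically chromatin-bound and ~92,000 unbound molecules.

The other `examples/` scripts each exercise one capability end to end
(FCS → copy numbers, iFRAP → pool partition, SRM → copies and stoichiometry,
peak-set arithmetic, and the full pipeline report); each prints the numbers
it computes and a line on what they mean.

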