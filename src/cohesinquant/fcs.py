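"""Fluorescence correlation spectroscopy: ACF fitting, QC and copy numbers.

FCS infers the concentration of a fluorescently tagged protein from intensity
fluctuations in a ~femtolitre confocal volume.  The autocorrelation function
(ACF) of the photon-count trace is fitted with a two-component free 3D
diffusion model,

    G(tau) = offset + (1/N) * sum_i f_i * (1 + tau/tau_i)^-1
                                    * (1 + tau/(kappa^2 * tau_i))^-1/2,

where ``N`` is the mean particle number in the effective volume, ``tau_i``
the diffusion times of the two components (e.g. freely diffusing versus
chromatin-interacting molecules), ``f_i`` their fractions and ``kappa`` the
axial/lateral structure parameter of the detection volume.  The effective
volume is calibrated with a dye solution of known concentration, after which
``N`` converts to a molar concentration and, with segmented compartment
volumes, to absolute copies per cell.

The module implements the measurement QC cascade (R², reduced chi-square,
Tukey fences and a brightness cap relative to free mEGFP), the summary
statistics used for the published copy-number tables (median and central 68%
interval) and the bootstrap used to compare FCS with orthogonal LC-MS counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .constants import AVOGADRO, UM3_TO_L

__all__ = [
    "AcfRecord",
    "AcfFit",
    "AcfFitConfig",
    "ConfocalCalibration",
    "CellGeometry",
    "CopyNumberSummary",
    "QcThresholds",
    "QcReport",
    "BootstrapRatio",
    "acf_two_component",
    "multiple_tau_lags",
    "correlate_trace",
    "fit_acf",
    "calibrate_confocal_volume",
    "concentration_from_fit",
    "qc_filter",
    "copies_from_concentration",
    "cytoplasmic_volume",
    "summarize_condition",
    "cpm_stoichiometry",
    "bootstrap_method_ratio",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AcfRecord:
    """One FCS measurement: an autocorrelation curve plus trace metadata.

    ``lags`` are in milliseconds, ``mean_intensity`` in kHz and ``duration``
    in seconds (photon counts are recorded for 30 s per position in the
    automated workflow this emulates).
    """

    lags: np.ndarray
    acf_values: np.ndarray
    mean_intensity: float = 0.0
    duration: float = 30.0
    cell_id: str = ""
    compartment: str = "nucleus_chromatin"
    condition: str = "G1"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.acf_values = np.asarray(self.acf_values, dtype=float)
        if self.lags.ndim != 1 or self.lags.shape != self.acf_values.shape:
            raise ValueError("lags and acf_values must be matching 1-D arrays")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.lags <= 0):
            raise ValueError("lags must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class AcfFit:
    """Fitted two-component diffusion parameters for one ACF."""

    n_particles: float
    tau1: float
    tau2: float
    frac1: float
    structure_param: float
    offset: float
    r_squared: float
    chisq_per_point: float
    cpm: float  # kHz per molecule = mean_intensity / N
    success: bool = True
    message: str = ""

    @property
    def failed(self) -> bool:
        return not self.success


@dataclass
class AcfFitConfig:
    """Settings for :func:`fit_acf`.

    ``kappa`` is fixed by default (from the dye calibration when available;
    5.0 otherwise).  A triplet/blinking term is intentionally not part of the
    model; ``fit_kappa=True`` frees the structure parameter.
    """

    kappa: float = 5.0
    fit_kappa: bool = False
    max_tau_ratio: float = 1e5  # bound on tau2/tau1 during fitting


@dataclass(frozen=True)
class ConfocalCalibration:
    """Effective confocal volume from a dye solution of known concentration."""

    effective_volume: float  # litres
    structure_param: float = 5.0
    dye_concentration: float = 50.0  # nM

    def __post_init__(self) -> None:
        if self.effective_volume <= 0:
            raise ValueError("effective volume must be positive")


@dataclass(frozen=True)
class CellGeometry:
    """Per-cell compartment geometry: nuclear volume and cell/nucleus ratio."""

    cell_id: str
    v_nucleus: float  # µm³
    v_ratio: float  # Vcell / Vnuc, dimensionless
    condition: str = "G1"

    def __post_init__(self) -> None:
        if self.v_nucleus <= 0:
            raise ValueError("nuclear volume must be positive")
        if self.v_ratio <= 1:
            raise ValueError("cell/nucleus volume ratio must exceed 1")


@dataclass(frozen=True)
class CopyNumberSummary:
    """Median copies and central 68% interval for one protein/condition."""

    protein: str
    condition: str
    compartment: str
    median: float
    interval_68: tuple[float, float]
    n_measurements: int

    def __post_init__(self) -> None:
        low, high = self.interval_68
        if not (low <= self.median <= high):
            raise ValueError("summary interval must bracket the median")


@dataclass(frozen=True)
class QcThresholds:
    r2_min: float = 0.92
    chisq_max: float = 1.2
    tukey_k: float = 3.0
    cpm_cap: float = 10.0  # multiples of the mEGFP reference CPM


@dataclass
class QcReport:
    """Per-rule rejection counts of the FCS quality-control cascade."""

    n_input: int = 0
    n_failed_fit: int = 0
    n_fail_r2: int = 0
    n_fail_chisq: int = 0
    n_cpm_outlier: int = 0
    n_cpm_cap: int = 0
    n_retained: int = 0
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    megfp_mean_cpm: float = float("nan")

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0


@dataclass(frozen=True)
class BootstrapRatio:
    """Bootstrap distribution summary of the ratio of two methods."""

    median: float
    interval_68: tuple[float, float]
    n_boot: int
    n_redrawn: int = 0


# ---------------------------------------------------------------------------
# ACF model and correlation
# ---------------------------------------------------------------------------

def acf_two_component(
    lags: np.ndarray,
    n_particles: float,
    tau1: float,
    tau2: float,
    frac1: float,
    kappa: float,
    offset: float = 0.0,
) -> np.ndarray:
    """Two-component free 3D diffusion ACF for a Gaussian confocal volume."""
    tau = np.asarray(lags, dtype=float)

    def component(tau_d: float) -> np.ndarray:
        return (1.0 + tau / tau_d) ** -1 * (1.0 + tau / (kappa**2 * tau_d)) ** -0.5

    g = frac1 * component(tau1) + (1.0 - frac1) * component(tau2)
    return offset + g / n_particles


def multiple_tau_lags(
    dt: float = 0.002, m: int = 16, max_lag: float = 1.0e3
) -> np.ndarray:
    """Quasi-logarithmic lag ladder in the style of a multiple-tau correlator.

    The first ``m`` lags are linear multiples of ``dt``; thereafter the lag
    spacing doubles every ``m // 2`` points, matching the ladder of hardware
    and software correlators.  Units follow ``dt`` (milliseconds by default).
    """
    if dt <= 0 or m < 2 or max_lag <= dt:
        raise ValueError("need dt > 0, m >= 2 and max_lag > dt")
    lags = [dt * k for k in range(1, m + 1)]
    spacing = 2.0 * dt
    while lags[-1] + spacing <= max_lag:
        start = lags[-1]
        for k in range(1, m // 2 + 1):
            lag = start + spacing * k
            if lag > max_lag:
                break
            lags.append(lag)
        spacing *= 2.0
    return np.asarray(lags)


def correlate_trace(
    binned_intensity: np.ndarray,
    bin_width: float,
    m: int = 16,
    **record_kwargs,
) -> AcfRecord:
    """Estimate G(tau) = <dI(t) dI(t+tau)> / <I>^2 from a binned photon trace.

    Lags follow a multiple-tau ladder in units of ``bin_width`` (ms).  The
    estimator is the direct normalised autocovariance at each ladder lag.
    """
    trace = np.asarray(binned_intensity, dtype=float)
    if trace.ndim != 1 or trace.size < 2:
        raise ValueError("need a 1-D trace with at least 2 bins")
    mean = trace.mean()
    if mean == 0:
        raise ValueError("zero mean intensity: ACF normalisation undefined")

    n = trace.size
    # integer-bin ladder: 1..m then doubling spacing, capped at n // 4
    max_lag_bins = max(1, n // 4)
    lags_bins: list[int] = list(range(1, min(m, max_lag_bins) + 1))
    spacing = 2
    while lags_bins[-1] + spacing <= max_lag_bins:
        start = lags_bins[-1]
        for k in range(1, m // 2 + 1):
            lag = start + spacing * k
            if lag > max_lag_bins:
                break
            lags_bins.append(lag)
        spacing *= 2

    delta = trace - mean
    acf = np.array(
        [np.mean(delta[:-k] * delta[k:]) / mean**2 for k in lags_bins]
    )
    mean_intensity_khz = record_kwargs.pop(
        "mean_intensity", mean / bin_width  # counts/ms == kHz
    )
    duration = record_kwargs.pop("duration", n * bin_width / 1e3)
    return AcfRecord(
        lags=np.asarray(lags_bins, dtype=float) * bin_width,
        acf_values=acf,
        mean_intensity=mean_intensity_khz,
        duration=duration,
        **record_kwargs,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _tail_noise_variance(lags: np.ndarray, acf: np.ndarray) -> float:
    """Per-point noise variance estimated from the last decade of lags.

    The tail of the ACF is nearly flat, so half the variance of successive
    differences is a slope-robust estimate of the point noise.
    """
    tail = acf[lags >= lags[-1] / 10.0]
    if tail.size < 3:
        tail = acf[-3:]
    return float(np.var(np.diff(tail)) / 2.0)


def fit_acf(record: AcfRecord, config: AcfFitConfig | None = None) -> AcfFit:
    """Least-squares fit of the two-component diffusion model to one ACF.

    Reports R², chi-square per point (residual sum of squares over the
    tail-estimated point variance and the number of points) and the counts
    per molecule.  Component exchange symmetry is broken by relabelling so
    that ``tau1 < tau2``.  Non-convergence is flagged, never silent.
    """
    config = config or AcfFitConfig()
    lags, acf = record.lags, record.acf_values
    if lags.size < 10:
        raise ValueError("need at least 10 lag points to fit the ACF")

    # data-driven starting values
    offset0 = float(np.mean(acf[lags >= lags[-1] / 10.0]))
    amp0 = max(float(np.median(acf[:3])) - offset0, 1e-6)
    n0 = 1.0 / amp0
    below_half = np.nonzero(acf - offset0 <= amp0 / 2.0)[0]
    tau_half = float(lags[below_half[0]]) if below_half.size else float(lags[lags.size // 2])
    tau_half = max(tau_half, float(lags[0]))

    params = lmfit.Parameters()
    params.add("n_particles", value=n0, min=1e-8)
    params.add("tau1", value=tau_half / 5.0, min=lags[0] / 100.0, max=lags[-1] * 100.0)
    params.add("tau2", value=tau_half * 5.0, min=lags[0] / 100.0, max=lags[-1] * 100.0)
    params.add("frac1", value=0.5, min=0.0, max=1.0)
    params.add("offset", value=offset0, min=-1.0, max=1.0)
    params.add("kappa", value=config.kappa, vary=config.fit_kappa, min=1.0 + 1e-9)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return (
            acf_two_component(
                lags,
                p["n_particles"].value,
                p["tau1"].value,
                p["tau2"].value,
                p["frac1"].value,
                p["kappa"].value,
                p["offset"].value,
            )
            - acf
        )

    try:
        result = lmfit.minimize(residual, params, method="leastsq")
        success = bool(result.success)
        message = str(result.message)
        p = result.params
    except Exception as exc:  # pragma: no cover - lmfit raises rarely
        return AcfFit(
            n_particles=float("nan"), tau1=float("nan"), tau2=float("nan"),
            frac1=float("nan"), structure_param=config.kappa, offset=float("nan"),
            r_squared=float("nan"), chisq_per_point=float("inf"), cpm=float("nan"),
            success=False, message=f"fit raised: {exc}",
        )

    tau1, tau2 = p["tau1"].value, p["tau2"].value
    frac1 = p["frac1"].value
    if tau1 > tau2:  # relabel to break component-exchange symmetry
        tau1, tau2 = tau2, tau1
        frac1 = 1.0 - frac1

    resid = residual(p)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((acf - acf.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-20 else 0.0)

    # per-point variance: scale set by the ACF tail, lag dependence from the
    # photon-noise profile sd(tau) ~ G(tau) + 1/N (flat == tail level)
    sigma2_tail = _tail_noise_variance(lags, acf)
    if sigma2_tail <= 0:
        chisq_per_point = 0.0 if rss < 1e-18 else float("inf")
    else:
        n_hat = max(p["n_particles"].value, 1e-12)
        g_fit = acf_two_component(
            lags, n_hat, tau1, tau2, frac1, p["kappa"].value, p["offset"].value
        )
        tail_level = p["offset"].value + 1.0 / n_hat
        if tail_level > 0:
            profile = np.maximum((g_fit + 1.0 / n_hat) / tail_level, 1e-6)
        else:
            profile = np.ones_like(lags)
        chisq_per_point = float(
            np.sum((resid / profile) ** 2) / (sigma2_tail * lags.size)
        )

    n_particles = p["n_particles"].value
    cpm = record.mean_intensity / n_particles if n_particles > 0 else float("nan")
    return AcfFit(
        n_particles=n_particles,
        tau1=tau1,
        tau2=tau2,
        frac1=frac1,
        structure_param=p["kappa"].value,
        offset=p["offset"].value,
        r_squared=r_squared,
        chisq_per_point=chisq_per_point,
        cpm=cpm,
        success=success,
        message=message,
    )


# ---------------------------------------------------------------------------
# calibration, concentrations, volumes
# ---------------------------------------------------------------------------

def calibrate_confocal_volume(
    dye_fit: AcfFit, known_concentration: float
) -> ConfocalCalibration:
    """Effective confocal volume from the dye fit: V_eff = N / (C * N_A).

    ``known_concentration`` is in nM (the calibration standard is a 50 nM
    fluorescent dye solution).
    """
    if dye_fit.failed:
        raise ValueError("dye fit did not converge; cannot calibrate")
    if known_concentration <= 0:
        raise ValueError("calibration concentration must be positive")
    if dye_fit.n_particles <= 0:
        raise ValueError("non-positive particle number in dye fit")
    conc_molar = known_concentration * 1e-9
    volume = dye_fit.n_particles / (conc_molar * AVOGADRO)
    return ConfocalCalibration(
        effective_volume=volume,
        structure_param=dye_fit.structure_param,
        dye_concentration=known_concentration,
    )


def concentration_from_fit(fit: AcfFit, cal: ConfocalCalibration) -> float:
    """Concentration in nM implied by a fitted particle number: C = N/(V*N_A)."""
    if cal is None:
        raise ValueError("confocal calibration required")
    if fit.failed:
        raise ValueError("cannot convert a failed fit to a concentration")
    return fit.n_particles / (cal.effective_volume * AVOGADRO) / 1e-9


def copies_from_concentration(concentration_nm: float, volume_um3: float) -> float:
    """Copies = C[mol/L] * V[L] * N_A, with concentration in nM, volume in µm³."""
    if volume_um3 <= 0:
        raise ValueError("compartment volume must be positive")
    if concentration_nm < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_nm * 1e-9 * volume_um3 * UM3_TO_L * AVOGADRO


def cytoplasmic_volume(geom: CellGeometry) -> float:
    """Vcyt = Vcell - Vnuc ~= Vnuc * (Vr - 1), in µm³."""
    return geom.v_nucleus * (geom.v_ratio - 1.0)


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------

def qc_filter(
    fits: list[AcfFit],
    megfp_mean_cpm: float,
    thresholds: QcThresholds | None = None,
) -> tuple[list[AcfFit], QcReport]:
    """Apply the FCS quality-control cascade and report per-rule rejections.

    In order: drop failed fits; require R² above and chi-square per point
    below threshold; remove CPM outliers outside Tukey fences of ``tukey_k``
    interquartile ranges; remove fits at least ``cpm_cap`` times brighter
    than the free-mEGFP reference (aggregates / bright junk).
    """
    if megfp_mean_cpm <= 0:
        raise ValueError("mEGFP reference CPM must be positive")
    thresholds = thresholds or QcThresholds()
    report = QcReport(
        n_input=len(fits), thresholds=thresholds, megfp_mean_cpm=megfp_mean_cpm
    )
    if not fits:
        return [], report

    converged = [f for f in fits if not f.failed]
    report.n_failed_fit = len(fits) - len(converged)

    passed_r2 = [f for f in converged if f.r_squared > thresholds.r2_min]
    report.n_fail_r2 = len(converged) - len(passed_r2)

    passed_chisq = [f for f in passed_r2 if f.chisq_per_point < thresholds.chisq_max]
    report.n_fail_chisq = len(passed_r2) - len(passed_chisq)

    retained = passed_chisq
    if retained:
        cpms = np.array([f.cpm for f in retained])
        q1, q3 = np.percentile(cpms, [25, 75])
        iqr = q3 - q1
        low, high = q1 - thresholds.tukey_k * iqr, q3 + thresholds.tukey_k * iqr
        kept = [f for f in retained if low <= f.cpm <= high]
        report.n_cpm_outlier = len(retained) - len(kept)
        retained = kept

    kept = [f for f in retained if f.cpm < thresholds.cpm_cap * megfp_mean_cpm]
    report.n_cpm_cap = len(retained) - len(kept)
    retained = kept

    report.n_retained = len(retained)
    return retained, report


# ---------------------------------------------------------------------------
# summaries, stoichiometry and the method-comparison bootstrap
# ---------------------------------------------------------------------------

def summarize_condition(
    copy_numbers,
    protein: str = "",
    condition: str = "",
    compartment: str = "",
) -> CopyNumberSummary:
    """Median and central 68% (16th–84th percentile) interval of copy numbers."""
    values = np.asarray(list(copy_numbers), dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty set of measurements")
    low, median, high = np.percentile(values, [16, 50, 84])
    return CopyNumberSummary(
        protein=protein,
        condition=condition,
        compartment=compartment,
        median=float(median),
        interval_68=(float(low), float(high)),
        n_measurements=int(values.size),
    )


def cpm_stoichiometry(protein_cpms, megfp_cpms) -> float:
    """Ratio of median brightness to the free-mEGFP reference.

    A ratio of ~1 indicates monomers, ~2 dimers: an EGFP-tagged dimer carries
    two fluorophores and is twice as bright per diffusing entity.
    """
    protein = np.asarray(list(protein_cpms), dtype=float)
    reference = np.asarray(list(megfp_cpms), dtype=float)
    if protein.size == 0 or reference.size == 0:
        raise ValueError("both CPM samples must be non-empty")
    ref_median = float(np.median(reference))
    if ref_median == 0:
        raise ValueError("zero reference median CPM")
    return float(np.median(protein)) / ref_median


def bootstrap_method_ratio(
    sample_a,
    sample_b,
    n_boot: int = 100_000,
    seed: int | np.random.Generator = 0,
    statistic=np.median,
    max_redraws: int = 100,
) -> BootstrapRatio:
    """Bootstrap the ratio of two methods' summary statistics.

    Each bootstrap pair resamples both samples with replacement (full size),
    computes ``statistic(a*) / statistic(b*)`` and the ratio distribution's
    median and central 68% interval summarise the method agreement.  Pairs
    whose denominator statistic is zero are redrawn (and counted) so ratios
    stay finite.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    stat_a = statistic(a[rng.integers(0, a.size, size=(n_boot, a.size))], axis=1)
    stat_b = statistic(b[rng.integers(0, b.size, size=(n_boot, b.size))], axis=1)

    n_redrawn = 0
    for _ in range(max_redraws):
        zero = stat_b == 0
        if not np.any(zero):
            break
        k = int(zero.sum())
        n_redrawn += k
        stat_a[zero] = statistic(a[rng.integers(0, a.size, size=(k, a.size))], axis=1)
        stat_b[zero] = statistic(b[rng.integers(0, b.size, size=(k, b.size))], axis=1)
    else:  # pragma: no cover - pathological all-zero input
        raise ValueError("could not draw a non-zero denominator statistic")

    ratios = stat_a / stat_b
    low, median, high = np.percentile(ratios, [16, 50, 84])
    return BootstrapRatio(
        median=float(median),
        interval_68=(float(low), float(high)),
        n_boot=n_boot,
        n_redrawn=n_redrawn,
    )
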