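"""Seeded generators for FCS, iFRAP, SRM and peak-set inputs with known truth.

Every downstream stage of the pipeline (ACF fitting, FRAP kinetic
partitioning, SRM copy-number arithmetic, spacing/overlap statistics) gets a
parameter-recovery test surface from these generators, without any raw
microscopy or mass-spectrometry downloads.

Randomness discipline: each generated entity (curve, cell, peptide table,
chromosome) draws from its own named substream derived from the master seed,
so adding entities never shifts the noise of existing ones, and identical
seed + parameters give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fcs import AcfRecord, acf_two_component, multiple_tau_lags
from .frap import FrapCurve
from .occupancy import PeakSet

__all__ = [
    "FcsTruth",
    "FrapTruth",
    "SrmTruth",
    "SpacingModel",
    "simulate_fcs_measurement",
    "simulate_frap_experiment",
    "simulate_srm_table",
    "simulate_peak_set",
]

# substream kind tags so different generators never share a stream
_KIND_FCS, _KIND_FRAP, _KIND_SRM, _KIND_PEAKS = 1, 2, 3, 4


def _substream(seed: int, kind: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), kind, index]))


# ---------------------------------------------------------------------------
# FCS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FcsTruth:
    """Ground-truth parameters of a simulated FCS measurement.

    ``n_particles`` is the mean particle number in the focal volume; the two
    diffusion times are in ms, ``cpm`` (counts per molecule) in kHz.
    ``noise_sd_scale`` scales an additive Gaussian noise whose SD is
    proportional to G(tau) + 1/N — a simple stand-in for photon statistics
    that is adequate for exercising the fitter.
    """

    n_particles: float = 10.0
    tau1: float = 0.5
    tau2: float = 50.0
    frac1: float = 0.6
    structure_param: float = 5.0
    offset: float = 0.0
    cpm: float = 30.0
    noise_sd_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if not 0.0 <= self.frac1 <= 1.0:
            raise ValueError("frac1 must lie in [0, 1]")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("diffusion times must be positive")
        if self.structure_param <= 1:
            raise ValueError("structure parameter must exceed 1")


def simulate_fcs_measurement(
    truth: FcsTruth,
    lag_grid: np.ndarray | None = None,
    index: int = 0,
    **record_kwargs,
) -> AcfRecord:
    """Simulate one ACF curve from the two-component 3D diffusion model.

    Returns the noiseless closed form when ``noise_sd_scale`` is zero.
    ``index`` names the entity substream (one per simulated measurement).
    """
    lags = multiple_tau_lags() if lag_grid is None else np.asarray(lag_grid, float)
    if np.any(lags <= 0):
        raise ValueError("lag grid must be positive")
    if np.any(np.diff(lags) <= 0):
        raise ValueError("lag grid must be strictly increasing")

    g = acf_two_component(
        lags,
        truth.n_particles,
        truth.tau1,
        truth.tau2,
        truth.frac1,
        truth.structure_param,
        truth.offset,
    )
    if truth.noise_sd_scale > 0:
        rng = _substream(truth.seed, _KIND_FCS, index)
        sd = truth.noise_sd_scale * (g + 1.0 / truth.n_particles)
        g = g + rng.normal(0.0, sd)
    return AcfRecord(
        lags=lags,
        acf_values=g,
        mean_intensity=truth.cpm * truth.n_particles,
        duration=record_kwargs.pop("duration", 30.0),
        **record_kwargs,
    )


# ---------------------------------------------------------------------------
# iFRAP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapTruth:
    """Ground truth of a simulated iFRAP experiment.

    ``stable_frac_of_bound`` is 1 - a of the double-exponential difference
    decay (the stably bound share of the chromatin-bound pool); rates are in
    min^-1; ``times`` is the post-bleach sampling grid in minutes (1-min
    frame interval over an hour by default); ``noise_sd`` is the absolute
    Gaussian noise on the normalised difference signal.
    """

    soluble_frac: float = 0.365
    stable_frac_of_bound: float = 0.0
    k_off_dynamic: float = 1.0 / 13.7
    k_off_stable: float = 1.0 / (8.6 * 60.0)
    noise_sd: float = 0.03
    n_cells: int = 19
    times: tuple = tuple(float(t) for t in range(0, 61))
    condition: str = "G1"
    bleached_volume_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.soluble_frac <= 1.0:
            raise ValueError("soluble_frac must lie in [0, 1]")
        if not 0.0 <= self.stable_frac_of_bound <= 1.0:
            raise ValueError("stable_frac_of_bound must lie in [0, 1]")
        if self.k_off_dynamic <= 0 or self.k_off_stable < 0:
            raise ValueError("off-rates must be positive")
        t = np.asarray(self.times, float)
        if t.size == 0:
            raise ValueError("empty time grid")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and increase strictly")

    def difference_decay(self, t: np.ndarray) -> np.ndarray:
        """Noiseless normalised difference signal a*e^(-k1 t)+(1-a)*e^(-k2 t)."""
        a = 1.0 - self.stable_frac_of_bound
        return a * np.exp(-self.k_off_dynamic * t) + (1.0 - a) * np.exp(
            -self.k_off_stable * t
        )


def simulate_frap_experiment(truth: FrapTruth) -> list[FrapCurve]:
    """Simulate per-cell iFRAP intensity series.

    Half (``bleached_volume_fraction``) of the nucleus is bleached; the
    soluble pool re-equilibrates instantly, so immediately after bleaching
    the unbleached region reads ``1 - soluble * fraction`` of the pre-bleach
    intensity, and the bleached/unbleached difference then decays with the
    bound-pool exchange kinetics.  The noiseless difference signal at t=0 is
    exactly the chromatin-bound fraction, which normalises to 1.
    """
    t = np.asarray(truth.times, dtype=float)
    f = truth.difference_decay(t)
    sigma = truth.soluble_frac
    bound = 1.0 - sigma
    # post-bleach expectations (pre-bleach mean == 1):
    soluble_level = sigma * (1.0 - truth.bleached_volume_fraction)
    unbleached = soluble_level + bound * (1.0 + f) / 2.0
    bleached = soluble_level + bound * (1.0 - f) / 2.0

    curves = []
    for i in range(truth.n_cells):
        rng = _substream(truth.seed, _KIND_FRAP, i)
        # difference-signal noise noise_sd splits between the two regions
        region_sd = truth.noise_sd * bound / np.sqrt(2.0)
        u = unbleached + (rng.normal(0.0, region_sd, t.size) if truth.noise_sd else 0.0)
        b = bleached + (rng.normal(0.0, region_sd, t.size) if truth.noise_sd else 0.0)
        curves.append(
            FrapCurve(
                cell_id=f"cell{i:03d}",
                condition=truth.condition,
                times=t,
                bleached_signal=b,
                unbleached_signal=u,
                prebleach_mean=1.0,
                postbleach_unbleached=float(u[0]),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# SRM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SrmTruth:
    """Ground truth of a simulated SRM transition table.

    ``true_fmol`` maps peptide -> analyte amount per aliquot; ``protein_map``
    assigns peptides to proteins; ``spike_fmol`` is the heavy reference spike
    (scalar or per-peptide).  ``cv`` is the SD of the log light/heavy ratio
    (~ relative SD); three transitions are monitored per peptide.
    """

    true_fmol: dict = field(default_factory=lambda: {"pep1": 10.0})
    protein_map: dict = field(default_factory=lambda: {"pep1": "SCC1"})
    spike_fmol: float | dict = 10.0
    n_cells_per_aliquot: int = 62_500
    cv: float = 0.1
    n_bio_reps: int = 2
    n_tech_reps: int = 2
    condition: str = "G1"
    fraction: str = "chromatin"
    heavy_base_height: float = 50_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_fmol:
            raise ValueError("need at least one peptide")
        for pep, amount in self.true_fmol.items():
            if amount <= 0:
                raise ValueError(f"true_fmol for {pep} must be positive")
            if self.spike_for(pep) <= 0:
                raise ValueError(f"spike_fmol for {pep} must be positive")
            if pep not in self.protein_map:
                raise ValueError(f"peptide {pep} missing from protein_map")
        if self.n_cells_per_aliquot <= 0:
            raise ValueError("n_cells_per_aliquot must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ValueError("replicate counts must be >= 1")

    def spike_for(self, peptide: str) -> float:
        if isinstance(self.spike_fmol, dict):
            return float(self.spike_fmol[peptide])
        return float(self.spike_fmol)


def simulate_srm_table(truth: SrmTruth, n_transitions: int = 3) -> pd.DataFrame:
    """Simulate a light/heavy SRM transition table (Skyline-style export).

    Light/heavy apex-height ratios have expectation ``true/spike`` with
    log-normal multiplicative noise of the stated cv (mean-corrected).
    """
    rows = []
    for p_idx, (pep, amount) in enumerate(sorted(truth.true_fmol.items())):
        rng = _substream(truth.seed, _KIND_SRM, p_idx)
        spike = truth.spike_for(pep)
        for bio in range(1, truth.n_bio_reps + 1):
            for tech in range(1, truth.n_tech_reps + 1):
                for trans in range(1, n_transitions + 1):
                    heavy = truth.heavy_base_height
                    ratio = amount / spike
                    if truth.cv > 0:
                        z = rng.normal()
                        ratio *= np.exp(truth.cv * z - truth.cv**2 / 2.0)
                    rows.append(
                        {
                            "protein": truth.protein_map[pep],
                            "peptide": pep,
                            "transition_id": f"{pep}.t{trans}",
                            "replicate_bio": bio,
                            "replicate_tech": tech,
                            "condition": truth.condition,
                            "fraction": truth.fraction,
                            "light_apex_height": heavy * ratio,
                            "heavy_apex_height": heavy,
                            "spike_fmol": spike,
                            "n_cells": truth.n_cells_per_aliquot,
                            "retained": True,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# peak sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpacingModel:
    """Inter-peak spacing model for simulated ChIP-seq peak sets.

    ``distribution`` is one of ``constant``, ``exponential`` or
    ``lognormal``; parameters are in bp and describe the midpoint-to-midpoint
    distance of consecutive peaks.  ``peak_width`` is the called peak width.
    """

    distribution: str = "exponential"
    params: dict = field(default_factory=lambda: {"mean": 67_500.0})
    peak_width: int = 500
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 50_000_000})

    def __post_init__(self) -> None:
        if self.distribution not in ("constant", "exponential", "lognormal"):
            raise ValueError(f"unknown spacing distribution {self.distribution!r}")
        if self.peak_width <= 0:
            raise ValueError("peak width must be positive")
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must be non-empty")

    def draw_gaps(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.distribution == "constant":
            gaps = np.full(n, float(self.params["value"]))
        elif self.distribution == "exponential":
            gaps = rng.exponential(float(self.params["mean"]), n)
        else:
            gaps = rng.lognormal(
                float(self.params["mu"]), float(self.params["sigma"]), n
            )
        # keep consecutive peaks non-overlapping
        return np.maximum(gaps, float(self.peak_width))


def simulate_peak_set(
    model: SpacingModel, seed: int = 0, name: str = "synthetic"
) -> PeakSet:
    """Generate a non-overlapping peak set with the given spacing model.

    Peaks are laid down chromosome by chromosome by cumulating midpoint gaps;
    a final peak extending beyond the chromosome end is clipped (and logged).
    The empirical consecutive-midpoint distance distribution converges to the
    model as the peak count grows.
    """
    intervals: dict[str, np.ndarray] = {}
    half = model.peak_width / 2.0
    for c_idx, (chrom, length) in enumerate(sorted(model.chrom_sizes.items())):
        rng = _substream(seed, _KIND_PEAKS, c_idx)
        mids: list[float] = []
        # first midpoint one gap from the chromosome start
        pos = float(model.draw_gaps(rng, 1)[0])
        while pos < length:
            mids.append(pos)
            pos += float(model.draw_gaps(rng, 1)[0])
        if not mids:
            continue
        arr = np.empty((len(mids), 2), dtype=np.int64)
        arr[:, 0] = np.maximum(np.round(np.asarray(mids) - half), 0)
        arr[:, 1] = np.round(np.asarray(mids) + half)
        clipped = arr[:, 1] > length
        if np.any(clipped):
            import logging

            logging.getLogger(__name__).warning(
                "peak beyond end of %s clipped (%d)", chrom, int(clipped.sum())
            )
            arr[clipped, 1] = length
        intervals[chrom] = arr
    return PeakSet(name=name, intervals=intervals, provenance="synthetic")
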