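"""Genomic occupancy arithmetic for ChIP-seq peak sets.

Operations on called peak coordinates: extrapolating mappable-genome site
counts to the whole (hypotriploid HeLa) genome, inter-peak spacing
distributions, connected-overlap (Venn) counting across datasets, and the
back-of-envelope occupancy / loop-extrusion estimates that relate absolute
copy numbers to binding-site counts.

Coordinates follow the BED convention: 0-based, half-open, strand ignored.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "OccupancyInputs",
    "SpacingResult",
    "OverlapComponent",
    "OverlapResult",
    "OccupancyRatio",
    "scale_to_genome",
    "expected_spacing",
    "spacing_distribution",
    "connected_overlap",
    "occupancy_ratio",
    "extrusion_rate",
    "per_chromosome_copies",
    "DEFAULT_CATEGORY_EDGES",
]

#: Pairwise-distance category edges in bp (10 kb ... 2 Mb pie-chart bins).
DEFAULT_CATEGORY_EDGES = (
    10_000, 25_000, 50_000, 100_000, 250_000, 500_000, 1_000_000, 2_000_000
)


@dataclass
class PeakSet:
    """A named set of genomic intervals for one ChIP target.

    Intervals are merged and sorted per chromosome at construction, so the
    invariant "sorted, non-overlapping" holds for every instance.
    """

    name: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        merged: dict[str, np.ndarray] = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size == 0:
                continue
            if np.any(arr[:, 0] >= arr[:, 1]):
                raise ValueError(f"{self.name}/{chrom}: intervals need start < end")
            merged[chrom] = _merge(arr)
        self.intervals = merged

    @classmethod
    def from_dataframe(cls, name: str, df: pd.DataFrame, provenance: str = "") -> "PeakSet":
        intervals = {
            str(chrom): grp[["start", "end"]].to_numpy()
            for chrom, grp in df.groupby("chrom", sort=True)
        }
        return cls(name=name, intervals=intervals, provenance=provenance)

    @classmethod
    def from_bed(cls, path, name: str | None = None) -> "PeakSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
        )
        return cls.from_dataframe(name or str(path), df, provenance=f"bed:{path}")

    def to_dataframe(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"chrom": chrom, "start": arr[:, 0], "end": arr[:, 1]})
            for chrom, arr in sorted(self.intervals.items())
        ]
        if not frames:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(frames, ignore_index=True)

    def to_bed(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", header=False, index=False)

    def __len__(self) -> int:
        return sum(arr.shape[0] for arr in self.intervals.values())

    def midpoints(self, chrom: str) -> np.ndarray:
        arr = self.intervals[chrom]
        return (arr[:, 0] + arr[:, 1]) / 2.0


def _merge(arr: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping half-open intervals."""
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [arr[0].copy()]
    for start, end in arr[1:]:
        if start < out[-1][1]:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append(np.array([start, end]))
    return np.asarray(out)


@dataclass(frozen=True)
class OccupancyInputs:
    """Inputs for genome-scaling and occupancy arithmetic."""

    mappable_sites: float
    mappable_genome: float  # bp
    total_genome: float  # bp
    bound_copies: float = 0.0
    n_chromosomes: int = 64

    def __post_init__(self) -> None:
        if min(self.mappable_sites, self.mappable_genome, self.total_genome) <= 0:
            raise ValueError("site counts and genome sizes must be positive")
        if self.mappable_genome > self.total_genome:
            raise ValueError("mappable genome cannot exceed total genome")


# ---------------------------------------------------------------------------
# scaling and spacing
# ---------------------------------------------------------------------------

def scale_to_genome(inputs: OccupancyInputs) -> float:
    """Extrapolate mappable-genome site counts to the whole genome.

    Assumes equal site frequency in the unmappable (repetitive) fraction:
    total sites = mappable sites / mappable bp * total bp.
    """
    return inputs.mappable_sites / inputs.mappable_genome * inputs.total_genome


def expected_spacing(mappable_genome: float, n_sites: float) -> float:
    """Mean inter-site spacing in bp if sites were uniformly distributed."""
    if n_sites <= 0:
        raise ValueError("need a positive site count")
    return mappable_genome / n_sites


@dataclass
class SpacingResult:
    distances: np.ndarray  # bp, consecutive same-chromosome distances
    fractions: dict[str, float]
    category_edges: tuple
    n_pairs: int
    n_single_peak_chromosomes: int

    def fraction_within(self, limit_bp: float) -> float:
        if self.distances.size == 0:
            return float("nan")
        return float(np.mean(self.distances <= limit_bp))


def spacing_distribution(
    peaks: PeakSet,
    category_edges=DEFAULT_CATEGORY_EDGES,
    anchor: str = "midpoint",
) -> SpacingResult:
    """Distances between consecutive peaks per chromosome, binned by category.

    Distances never cross chromosomes; the anchor is peak midpoints by
    default (``anchor="edge"`` uses end-to-start gaps).  Chromosomes with a
    single peak contribute no distances and are counted in the result.
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks")
    if anchor not in ("midpoint", "edge"):
        raise ValueError("anchor must be 'midpoint' or 'edge'")
    distances: list[np.ndarray] = []
    n_single = 0
    for chrom, arr in sorted(peaks.intervals.items()):
        if arr.shape[0] < 2:
            n_single += 1
            logger.info("spacing: chromosome %s has <2 peaks, skipped", chrom)
            continue
        if anchor == "midpoint":
            pos = (arr[:, 0] + arr[:, 1]) / 2.0
            distances.append(np.diff(pos))
        else:
            distances.append(arr[1:, 0] - arr[:-1, 1])
    dists = np.concatenate(distances) if distances else np.array([])

    edges = tuple(category_edges)
    labels = (
        [f"<{edges[0]}"]
        + [f"{lo}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]
        + [f">{edges[-1]}"]
    )
    if dists.size:
        counts, _ = np.histogram(dists, bins=[0, *edges, np.inf])
        fractions = {lab: c / dists.size for lab, c in zip(labels, counts)}
    else:
        fractions = {lab: float("nan") for lab in labels}
    return SpacingResult(
        distances=dists,
        fractions=fractions,
        category_edges=edges,
        n_pairs=int(dists.size),
        n_single_peak_chromosomes=n_single,
    )


# ---------------------------------------------------------------------------
# connected overlaps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapComponent:
    chrom: str
    start: int
    end: int
    members: frozenset  # names of the contributing peak sets


@dataclass
class OverlapResult:
    """Venn-style counts of connected genomic sites across peak sets."""

    components: list[OverlapComponent]
    set_names: tuple

    @property
    def counts_by_members(self) -> Counter:
        return Counter(c.members for c in self.components)

    def count(self, *names: str) -> int:
        """Number of connected sites whose members are exactly ``names``."""
        return self.counts_by_members[frozenset(names)]

    def total_for(self, name: str) -> int:
        """Connected sites touched by ``name`` (<= that set's raw peak count)."""
        return sum(1 for c in self.components if name in c.members)

    @property
    def n_components(self) -> int:
        return len(self.components)


def connected_overlap(sets: list[PeakSet]) -> OverlapResult:
    """Group mutually overlapping intervals across datasets into components.

    Two peaks from one set spanning a single peak in another collapse into
    one connected genomic site counted once; the sum of per-set counts in the
    overlap display is therefore smaller than the sum of raw peak counts.
    Half-open semantics: intervals that merely touch do not overlap.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 peak sets")
    names = tuple(ps.name for ps in sets)
    if len(set(names)) != len(names):
        raise ValueError("peak set names must be unique")

    chroms = sorted({c for ps in sets for c in ps.intervals})
    components: list[OverlapComponent] = []
    for chrom in chroms:
        rows = [
            (int(start), int(end), ps.name)
            for ps in sets
            for start, end in ps.intervals.get(chrom, np.empty((0, 2)))
        ]
        rows.sort(key=lambda r: (r[0], r[1]))
        cur_start, cur_end, members = rows[0][0], rows[0][1], {rows[0][2]}
        for start, end, name in rows[1:]:
            if start < cur_end:  # strict: touching is not overlapping
                cur_end = max(cur_end, end)
                members.add(name)
            else:
                components.append(
                    OverlapComponent(chrom, cur_start, cur_end, frozenset(members))
                )
                cur_start, cur_end, members = start, end, {name}
        components.append(
            OverlapComponent(chrom, cur_start, cur_end, frozenset(members))
        )
    return OverlapResult(components=components, set_names=names)


# ---------------------------------------------------------------------------
# occupancy and extrusion estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccupancyRatio:
    copies_per_site: float
    sites_per_copy: float


def occupancy_ratio(bound_copies: float, sites_total: float) -> OccupancyRatio:
    """Bound copies per predicted binding site (and its inverse).

    ``sites_per_copy`` is the chromatin-bound fraction below which not every
    site can be occupied simultaneously (e.g. 120,000 sites for 180,000
    nuclear CTCF copies gives 0.67).
    """
    if sites_total <= 0:
        raise ValueError("need a positive site count")
    return OccupancyRatio(
        copies_per_site=bound_copies / sites_total,
        sites_per_copy=sites_total / bound_copies if bound_copies else float("inf"),
    )


def extrusion_rate(loop_size_kb: float, residence_min: float) -> float:
    """Loop-extrusion speed (kb/min) needed to extrude ``loop_size_kb`` within
    one chromatin residence time."""
    if residence_min <= 0:
        raise ValueError("residence time must be positive")
    return loop_size_kb / residence_min


def per_chromosome_copies(total_copies: float, n_chromosomes: int) -> float:
    """Average copies per chromosome (e.g. centromeric cohesin in prometaphase)."""
    if n_chromosomes <= 0:
        raise ValueError("need a positive chromosome count")
    return total_copies / n_chromosomes
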