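"""Peak-set arithmetic: site extrapolation, spacing and connected overlaps.

Scales mappable-genome ChIP-seq site counts to the whole HeLa genome,
compares copy numbers with binding-site counts, and demonstrates the
spacing-distribution and connected-overlap operations on synthetic peak
sets with a realistic ~67.5 kb mean spacing.
"""

from cohesinquant import occupancy as occ, synthetic as syn
from cohesinquant.constants import (
    CHIP_SITE_COUNTS, HELA_CHROMOSOME_COUNT, HELA_GENOME_BP, MAPPABLE_GENOME_BP,
    MEDIAN_TAD_KB, RESIDENCE_G1_MIN,
)
from cohesinquant.workbench import round_to_nearest

for target in ("cohesin", "CTCF"):
    sites = occ.scale_to_genome(
        occ.OccupancyInputs(CHIP_SITE_COUNTS[target], MAPPABLE_GENOME_BP, HELA_GENOME_BP)
    )
    print(f"{target}: {CHIP_SITE_COUNTS[target]:,} mappable sites -> "
          f"{sites:,.0f} (~{round_to_nearest(sites, 1000):,.0f}) per genome")

spacing = occ.expected_spacing(MAPPABLE_GENOME_BP, CHIP_SITE_COUNTS["cohesin"])
print(f"uniform spacing: one site every {spacing / 1000:.1f} kb")

ratio = occ.occupancy_ratio(180_000, 120_000)
print(f"CTCF: occupancy of all sites needs a bound fraction of "
      f"{ratio.sites_per_copy:.2f}")

rate = occ.extrusion_rate(MEDIAN_TAD_KB, RESIDENCE_G1_MIN)
print(f"extruding a {MEDIAN_TAD_KB:.0f} kb TAD within one {RESIDENCE_G1_MIN} min "
      f"residence time: {rate:.1f} (~{round_to_nearest(rate, 1):.0f}) kb/min")

per_chrom = occ.per_chromosome_copies(14_165, HELA_CHROMOSOME_COUNT)
print(f"prometaphase: 14,165 bound copies / {HELA_CHROMOSOME_COUNT} chromosomes "
      f"= {per_chrom:.0f} (~{round_to_nearest(per_chrom, 100):.0f}) per centromere")

# synthetic peak sets: spacing distribution and connected overlaps
model = syn.SpacingModel(
    distribution="exponential", params={"mean": 67_500.0},
    chrom_sizes={"chr1": 150_000_000, "chr2": 100_000_000},
)
smc3 = syn.simulate_peak_set(model, seed=5, name="SMC3")
ctcf = syn.simulate_peak_set(model, seed=6, name="CTCF")
dist = occ.spacing_distribution(smc3)
print(f"synthetic SMC3 set: {len(smc3):,} peaks, "
      f"{100 * dist.fraction_within(100_000):.0f}% within 100 kb of a neighbour")

venn = occ.connected_overlap([smc3, ctcf])
shared = venn.count("SMC3", "CTCF")
print(f"connected sites: {venn.n_components:,} total, {shared:,} shared "
      f"(two peaks spanning one are counted once)")
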