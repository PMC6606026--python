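"""Physical constants and the published HeLa study constants used across modules.

The tables below transcribe the printed summary tables of the cohesin/CTCF
quantification study (LC-MS copies per cell, FCS copy numbers, FCS/iFRAP
population partition) together with the scalar constants of its Methods
(volume ratios, genome sizes, kinetic parameters).  They are *inputs* to the
report arithmetic in :mod:`cohesinquant.workbench`; nothing in the analysis
modules depends on them.
"""

from __future__ import annotations

# -- physical -----------------------------------------------------------------

AVOGADRO = 6.02214076e23
"""Avogadro's constant, mol^-1 (exact, SI 2019)."""

UM3_TO_L = 1e-15
"""1 µm³ in litres."""

FMOL_TO_MOL = 1e-15

# -- cell geometry ------------------------------------------------------------

#: Cell-to-nucleus volume ratio Vr = Vcell/Vnuc for interphase (G1/G2) cells.
VR_INTERPHASE = 3.04
#: Cell-to-nucleus volume ratio for nocodazole-arrested prometaphase cells.
VR_PROMETAPHASE = 5.72

# -- genome arithmetic --------------------------------------------------------

#: Mappable (non-repetitive) human genome, bp.
MAPPABLE_GENOME_BP = 2.7e9
#: Total HeLa genome, bp (hypotriploid karyotype).
HELA_GENOME_BP = 7.9e9
#: Average HeLa chromosome count.
HELA_CHROMOSOME_COUNT = 64
#: Median TAD size from Hi-C, kb.
MEDIAN_TAD_KB = 185.0

#: ChIP-seq enrichment-site counts in the mappable genome (G1-synchronised).
CHIP_SITE_COUNTS = {
    "SMC3": 37_000,
    "STAG1": 35_000,
    "STAG2": 47_000,
    "CTCF": 41_000,
    # generic rounded per-target count used for the cohesin extrapolation
    "cohesin": 40_000,
}

# -- kinetics (iFRAP) ---------------------------------------------------------

#: G1 dynamic residence time, minutes (mean ± sd over cells).
RESIDENCE_G1_MIN = 13.7
RESIDENCE_G1_SD_MIN = 2.2
#: G2 dynamic residence time, minutes.
RESIDENCE_G2_DYNAMIC_MIN = 10.0
#: G2 stable residence time, hours.
RESIDENCE_G2_STABLE_HR = 8.6

#: Fraction of nuclear cohesin bound to chromatin in G1 (no stable pool).
BOUND_FRACTION_G1 = 0.635
#: Experimentally derived stable fraction of nuclear cohesin in G2.
STABLE_FRACTION_G2 = 0.367
#: Experimentally observed chromatin-bound fraction in G2.
OBSERVED_BOUND_FRACTION_G2 = 0.728

#: Population fractions of nuclear SCC1-mEGFP (soluble/dynamic/stable).
POPULATION_FRACTIONS = {
    "G1": {"soluble": 0.365, "dynamic": 0.635, "stable": 0.0},
    "G2": {"soluble": 0.27, "dynamic": 0.36, "stable": 0.37},
}

# -- SRM ----------------------------------------------------------------------

#: Cells per chromatin aliquot for the SRM quantification.
SRM_CHROMATIN_CELLS = 62_500
SRM_CHROMATIN_CELLS_SD = 3_100
#: Heavy reference peptide spike levels, fmol, per extract fraction.
SRM_SPIKE_FMOL = {"soluble": (2.5, 5.0), "chromatin": (10.0, 15.0)}
#: Average acetone-precipitation loss measured by Bradford.
ACETONE_LOSS_FRACTION = 0.17

# -- LC-MS copies per cell (mean, [mean - sd, mean + sd]) ----------------------

#: protein -> condition -> fraction -> (mean, low, high); None = not measured.
LCMS_COPIES = {
    "SMC1": {
        "G1": {"chromatin": (61125, 47609, 74640), "soluble": None},
        "G2": {"chromatin": (142290, 120274, 164306), "soluble": None},
        "prometaphase": {"chromatin": (12461, 11497, 13425), "soluble": None},
    },
    "SMC3": {
        "G1": {"chromatin": (66430, 53421, 79440), "soluble": (350228, 312360, 388095)},
        "G2": {"chromatin": (158478, 129846, 187111), "soluble": (622117, 557712, 686522)},
        "prometaphase": {"chromatin": (14165, 12173, 16158), "soluble": (899510, 816643, 982376)},
    },
    "SCC1": {
        "G1": {"chromatin": (69275, 54577, 83972), "soluble": (281140, 199837, 362444)},
        "G2": {"chromatin": (149500, 127373, 171627), "soluble": (356850, 270483, 443217)},
        "prometaphase": {"chromatin": (13973, 10478, 17468), "soluble": (494155, 314240, 674070)},
    },
    "STAG1": {
        "G1": {"chromatin": (14718, 11295, 18140), "soluble": (114355, 104557, 124152)},
        "G2": {"chromatin": (23017, 17947, 28087), "soluble": (120960, 119860, 122061)},
        "prometaphase": {"chromatin": (2797, 1842, 3752), "soluble": (152033, 147488, 156577)},
    },
    "STAG2": {
        "G1": {"chromatin": (44812, 37745, 51879), "soluble": (144160, 131233, 157086)},
        "G2": {"chromatin": (106106, 93591, 118621), "soluble": (235980, 213879, 258081)},
        "prometaphase": {"chromatin": (8112, 6863, 9361), "soluble": (336062, 305203, 366922)},
    },
}

# -- FCS copy numbers (median, [16th, 84th percentile]) ------------------------

#: protein -> condition -> compartment -> (median, low, high); None = below
#: detection or too few retained measurements.
FCS_COPIES = {
    "SCC1": {
        "G1": {"nucleus": (250755, 160752, 387511), "cytoplasm": (10690, 2426, 28277)},
        "G2": {"nucleus": (291939, 228902, 547040), "cytoplasm": (6279, 2917, 9460)},
        "prometaphase": {"nucleus": (52195, 35147, 72881), "cytoplasm": (203259, 138338, 303046)},
    },
    "STAG1": {
        "G1": {"nucleus": (50062, 26338, 95212), "cytoplasm": (1738, 419, 6726)},
        "G2": {"nucleus": (90712, 59923, 152640), "cytoplasm": (1048, 359, 3369)},
        "prometaphase": {"nucleus": (10714, 6958, 16682), "cytoplasm": (34860, 26096, 50824)},
    },
    "STAG2": {
        "G1": {"nucleus": (221261, 158694, 291715), "cytoplasm": (18168, 5571, 59386)},
        "G2": {"nucleus": (281503, 202964, 384802), "cytoplasm": (29080, 9410, 92086)},
        "prometaphase": {"nucleus": (67163, 46974, 105183), "cytoplasm": (249048, 183810, 360561)},
    },
    "NIPBL": {
        "G1": {"nucleus": (146764, 107180, 202180), "cytoplasm": (7314, 3462, 13262)},
        "G2": {"nucleus": (162915, 101109, 218244), "cytoplasm": (10537, 4819, 18812)},
        "prometaphase": {"nucleus": (32357, 22248, 44222), "cytoplasm": (135313, 114223, 172737)},
    },
    "WAPL": {
        "G1": {"nucleus": (91114, 68317, 115878), "cytoplasm": None},
        "G2": {"nucleus": (100084, 70256, 125633), "cytoplasm": None},
        "prometaphase": {"nucleus": (20196, 13253, 30023), "cytoplasm": (88677, 68173, 141144)},
    },
    "SORORIN": {
        "G1": {"nucleus": (44396, 21054, 84541), "cytoplasm": (1216, 363, 3551)},
        "G2": {"nucleus": (104939, 40639, 163976), "cytoplasm": (4580, 832, 27180)},
        "prometaphase": {"nucleus": (25099, 16846, 38736), "cytoplasm": (103462, 61909, 139749)},
    },
    "CTCF": {
        "G1": {"nucleus": (181157, 131295, 259610), "cytoplasm": (3671, 1192, 6294)},
        "G2": {"nucleus": (206494, 157309, 284756), "cytoplasm": (9708, 9256, 10160)},
        "prometaphase": {"nucleus": (51898, 32725, 80216), "cytoplasm": (143505, 87355, 243766)},
    },
}

# -- FCS/iFRAP partition of nuclear SCC1-mEGFP (copies ± sd) -------------------

FRAP_PARTITION_COPIES = {
    "G1": {
        "soluble": (91318, 10277),
        "dynamic": (159437, 10277),
        "stable": (0, 0),
        "total": (250755, None),
    },
    "G2": {
        "soluble": (79239, 21371),
        "dynamic": (104952, 26360),
        "stable": (107748, 26360),
        "total": (291939, None),
    },
}
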