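"""Published summary profile of the ancient *Sophora japonica* SSR panel.

The study genotyped 416 ancient *S. japonica* accessions from three
provincial populations (Shandong 374, Hebei 16, Shanxi 26) at 16 SSR loci.
The raw genotype table was not deposited; what is available are the
published per-locus summary statistics and the study design constants.
This module records them so the synthetic-data generator can emulate the
design and so structurally determined quantities (allele totals, column
means, subset sizes) can be recomputed from the published numbers.

All values are transcribed as printed (two decimals for most columns).
"""

from __future__ import annotations

import pandas as pd

#: Population labels and sizes (the germplasm-source listing; the
#: per-population diversity table prints 375 for SD — an internal
#: inconsistency of the publication that we do not resolve).
POPULATION_SIZES: dict[str, int] = {"SD": 374, "HB": 16, "SX": 26}

#: Total accessions genotyped.
N_ACCESSIONS: int = sum(POPULATION_SIZES.values())  # 416

#: The candidate core-collection sampling proportions scanned by the study.
CORE_PROPORTIONS: tuple[float, ...] = (
    0.50, 0.45, 0.40, 0.35, 0.30, 0.25, 0.20, 0.15, 0.10, 0.05,
)

#: Per-locus published diversity statistics, in the published row order.
#: Columns: MAF major allele frequency, N non-missing sample count,
#: Na observed alleles, Ne effective alleles, I Shannon index,
#: Ho/He observed/expected heterozygosity, Fis/Fit/Fst Wright statistics,
#: Nm island-model gene flow, PIC polymorphism information content.
LOCUS_PROFILE: pd.DataFrame = pd.DataFrame(
    [
        # locus   MAF    N   Na    Ne     I    Ho    He    Fis    Fit   Fst     Nm   PIC
        ("2541", 0.41, 416,  4, 3.32, 1.28, 0.65, 0.70,  0.09,  0.10, 0.01, 23.20, 0.64),
        ("2128", 0.28, 416, 10, 5.99, 1.95, 0.81, 0.83, -0.06, -0.02, 0.04,  6.35, 0.81),
        ("2114", 0.40, 415,  7, 3.66, 1.50, 0.66, 0.73, -0.04,  0.02, 0.06,  3.93, 0.69),
        ("1970", 0.30, 410, 10, 5.35, 1.84, 0.77, 0.81, -0.02,  0.00, 0.02, 10.66, 0.79),
        ("2844", 0.33, 416, 19, 5.90, 2.12, 0.57, 0.83,  0.20,  0.23, 0.04,  6.27, 0.81),
        ("3049", 0.36, 415, 13, 4.19, 1.71, 0.68, 0.76,  0.01,  0.04, 0.03,  7.45, 0.73),
        ("1609", 0.54, 412,  8, 2.76, 1.25, 0.54, 0.64,  0.15,  0.21, 0.07,  3.48, 0.59),
        ("1302", 0.56, 416, 10, 2.79, 1.41, 0.49, 0.64,  0.10,  0.13, 0.04,  6.78, 0.61),
        ("1060", 0.33, 416, 15, 4.00, 1.66, 0.71, 0.75,  0.03,  0.04, 0.01, 18.33, 0.71),
        ("2434", 0.34, 416,  7, 3.60, 1.42, 0.66, 0.72, -0.04,  0.07, 0.11,  2.12, 0.67),
        ("1820", 0.58, 416,  7, 2.55, 1.21, 0.58, 0.61, -0.01,  0.02, 0.03,  8.40, 0.57),
        ("1663", 0.38, 414,  8, 3.20, 1.28, 0.62, 0.69,  0.04,  0.05, 0.02, 13.97, 0.63),
        ("953",  0.37, 416, 11, 4.76, 1.83, 0.76, 0.79,  0.03,  0.06, 0.03,  8.98, 0.77),
        ("1527", 0.47, 416,  6, 3.03, 1.25, 0.62, 0.67, -0.07, -0.06, 0.02, 15.04, 0.62),
        ("2270", 0.25, 414, 12, 5.24, 1.79, 0.79, 0.81,  0.04,  0.07, 0.03,  7.30, 0.78),
        ("756",  0.31, 412, 13, 5.00, 1.80, 0.33, 0.80,  0.33,  0.34, 0.02, 13.59, 0.77),
    ],
    columns=["locus", "MAF", "N", "Na", "Ne", "I", "Ho",
             "He", "Fis", "Fit", "Fst", "Nm", "PIC"],
).set_index("locus")

#: Locus names in published order.
LOCUS_NAMES: tuple[str, ...] = tuple(LOCUS_PROFILE.index)

#: Published per-locus allele counts (sums to 160 distinct alleles).
ALLELES_PER_LOCUS: tuple[int, ...] = tuple(int(x) for x in LOCUS_PROFILE["Na"])

#: Multi-locus differentiation reported for the collection.
REPORTED_FST: float = 0.04

#: Published core-vs-original comparison: mean Na of the 25% core (104
#: accessions) and of the full collection, from which the Na retention
#: rate 87.50% follows.
CORE_NA, ORIGINAL_NA = 8.75, 10.00
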