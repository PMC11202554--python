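"""Published reference tables for the Mongolian gerbil SNP panel.

Three small tables travel with the package because they are *inputs* to
reproducible analyses, not results: the genotype-frequency table of the
seven loci that discriminate the three outbred colonies, the fifteen
panel loci fixed for different alleles in the two inbred disease-model
lines, and the per-colony diversity summary of the 206-locus panel.
"""

from __future__ import annotations

import numpy as np

from .discrimination import genotype_counts_from_frequencies
from .model import GenotypeMatrix, PanelDefinition, PanelEntry

#: animals genotyped per outbred colony
OUTBRED_COHORT_SIZES = {"Zhejiang": 37, "Dalian": 32, "CMU": 31}

#: genotype frequencies of the seven colony-discriminating loci
#: (locus -> population -> genotype class -> frequency, as printed)
SEVEN_DISCRIMINATING_LOCI: dict[str, dict[str, dict[str, float]]] = {
    "MG15": {
        "Zhejiang": {"AA": 0.08, "AG": 0.35, "GG": 0.57},
        "Dalian": {"AA": 0.09, "AG": 0.47, "GG": 0.44},
        "CMU": {"AA": 0.00, "AG": 0.00, "GG": 1.00},
    },
    "MG89": {
        "Zhejiang": {"CC": 0.00, "CT": 0.05, "TT": 0.95},
        "Dalian": {"CC": 0.00, "CT": 0.00, "TT": 1.00},
        "CMU": {"CC": 0.68, "CT": 0.32, "TT": 0.00},
    },
    "MG126": {
        "Zhejiang": {"CC": 0.03, "CT": 0.09, "TT": 0.89},
        "Dalian": {"CC": 1.00, "CT": 0.00, "TT": 0.00},
        "CMU": {"CC": 0.00, "CT": 0.00, "TT": 1.00},
    },
    "MG159": {
        "Zhejiang": {"CC": 0.97, "TT": 0.03},
        "Dalian": {"CC": 0.59, "TT": 0.41},
        "CMU": {"CC": 0.97, "TT": 0.03},
    },
    "MG164": {
        "Zhejiang": {"AA": 0.32, "AC": 0.35, "CC": 0.32},
        "Dalian": {"AA": 0.97, "AC": 0.03, "CC": 0.00},
        "CMU": {"AA": 0.74, "AC": 0.26, "CC": 0.00},
    },
    "MG206": {
        "Zhejiang": {"AA": 0.22, "AG": 0.62, "GG": 0.16},
        "Dalian": {"AA": 0.97, "AG": 0.03, "GG": 0.00},
        "CMU": {"AA": 0.39, "AG": 0.42, "GG": 0.19},
    },
    "MG215": {
        "Zhejiang": {"CC": 0.03, "CT": 0.54, "TT": 0.43},
        "Dalian": {"CC": 0.00, "CT": 0.00, "TT": 1.00},
        "CMU": {"CC": 0.90, "CT": 0.10, "TT": 0.00},
    },
}

#: the fifteen loci fixed for different alleles in the two inbred lines:
#: (locus, scaffold, 1-based pos, classification, ref, alt,
#:  cerebral-ischemia-line genotype, diabetes-line genotype)
INBRED_DISTINGUISHING_LOCI: list[tuple[str, str, int, str, str, str, str, str]] = [
    ("MG37", "NW_018657859.1", 1081095, "5'Flank", "C", "G", "G/G", "C/C"),
    ("MG46", "NW_018657888.1", 735326, "Missense_Mutation", "A", "G", "A/A", "G/G"),
    ("MG47", "NW_018657888.1", 1469235, "Nonstop_Mutation", "A", "T", "T/T", "A/A"),
    ("MG49", "NW_018657893.1", 1416535, "Missense_Mutation", "C", "T", "C/C", "T/T"),
    ("MG54", "NW_018657915.1", 154939, "Intron", "T", "C", "T/T", "C/C"),
    ("MG73", "NW_018658000.1", 110223, "Missense_Mutation", "T", "C", "T/T", "C/C"),
    ("MG82", "NW_018658044.1", 1083386, "Missense_Mutation", "G", "T", "T/T", "G/G"),
    ("MG94", "NW_018658087.1", 982880, "Missense_Mutation", "T", "C", "C/C", "T/T"),
    ("MG107", "NW_018658151.1", 621718, "3'Flank", "G", "T", "T/T", "G/G"),
    ("MG114", "NW_018658168.1", 333441, "5'Flank", "C", "T", "T/T", "C/C"),
    ("MG124", "NW_018658203.1", 697270, "Missense_Mutation", "C", "T", "T/T", "C/C"),
    ("MG132", "NW_018658278.1", 540596, "Nonsense_Mutation", "C", "A", "A/A", "C/C"),
    ("MG142", "NW_018658707.1", 206847, "Missense_Mutation", "C", "A", "A/A", "C/C"),
    ("MG190", "NW_018661696.1", 2303, "Missense_Mutation", "A", "G", "G/G", "A/A"),
    ("MG219", "NW_018692212.1", 1211, "5'Flank", "G", "A", "G/G", "A/A"),
]

#: per-colony summary of the 206-locus panel (published to 4 decimals)
OUTBRED_SUMMARY: dict[str, dict[str, float]] = {
    "CMU": dict(n=31, na=1.9903, ne=1.6953, shannon_i=0.5753,
                obs_hom=0.6019, obs_het=0.3981, exp_hom=0.6002,
                exp_het=0.3998, ave_het=0.3934, pct_polymorphic=0.9903),
    "Zhejiang": dict(n=37, na=2.0000, ne=1.6550, shannon_i=0.5594,
                     obs_hom=0.6229, obs_het=0.3771, exp_hom=0.6167,
                     exp_het=0.3833, ave_het=0.3782, pct_polymorphic=1.0000),
    "Dalian": dict(n=32, na=1.5146, ne=1.3408, shannon_i=0.2882,
                   obs_hom=0.7770, obs_het=0.2230, exp_hom=0.8014,
                   exp_het=0.1986, ave_het=0.1955, pct_polymorphic=0.5146),
}

#: loci monomorphic within each inbred line across the 206-locus panel
INBRED_MONOMORPHIC_COUNTS = {"CerebralIschemia": 156, "Diabetes": 77, "both": 64}


def seven_locus_count_tables() -> dict[str, tuple[np.ndarray, list[str], list[str]]]:
    """Integer genotype-count tables for the seven discriminating loci.

    Counts are reconstructed per population with largest-remainder
    rounding so every row sums to that colony's sample size.
    Returns locus -> (counts, populations, genotype classes).
    """
    out = {}
    for locus, by_pop in SEVEN_DISCRIMINATING_LOCI.items():
        pops = list(by_pop)
        classes = list(next(iter(by_pop.values())))
        counts = np.vstack([
            genotype_counts_from_frequencies(
                [by_pop[p].get(g, 0.0) for g in classes], OUTBRED_COHORT_SIZES[p]
            )
            for p in pops
        ])
        out[locus] = (counts, pops, classes)
    return out


def seven_locus_reference_matrix() -> GenotypeMatrix:
    """The seven discriminating loci as a genotype matrix.

    Individuals within a colony are assigned the reconstructed genotype
    counts in blocks (assignment order is immaterial to contingency
    statistics)."""
    tables = seven_locus_count_tables()
    loci = list(tables)
    pops = list(OUTBRED_COHORT_SIZES)
    samples, populations = [], {}
    for pop, n in OUTBRED_COHORT_SIZES.items():
        for i in range(n):
            s = f"{pop}_{i + 1:03d}"
            samples.append(s)
            populations[s] = pop
    calls = np.empty((len(samples), len(loci)), dtype=object)
    for j, locus in enumerate(loci):
        counts, tab_pops, classes = tables[locus]
        row = 0
        for pop in pops:
            r = tab_pops.index(pop)
            geno_seq = []
            for g, c in zip(classes, counts[r]):
                geno_seq += [tuple(sorted(g))] * int(c)
            for i, call in enumerate(geno_seq):
                calls[row + i, j] = call
            row += OUTBRED_COHORT_SIZES[pop]
    return GenotypeMatrix(samples, loci, calls, populations)


def inbred_reference_matrix(n_per_line: int = 10) -> GenotypeMatrix:
    """The fifteen line-diagnostic loci as two fixed inbred lines.

    Every animal of a line carries that line's published fixed genotype;
    line sizes default to the ten animals genotyped per line.
    """
    loci = [row[0] for row in INBRED_DISTINGUISHING_LOCI]
    lines = ["CerebralIschemia", "Diabetes"]
    samples, populations = [], {}
    for line in lines:
        for i in range(n_per_line):
            s = f"{line}_{i + 1:03d}"
            samples.append(s)
            populations[s] = line
    calls = np.empty((len(samples), len(loci)), dtype=object)
    for j, row in enumerate(INBRED_DISTINGUISHING_LOCI):
        g_ci = tuple(sorted(row[6].split("/")))
        g_db = tuple(sorted(row[7].split("/")))
        for i in range(n_per_line):
            calls[i, j] = g_ci
            calls[n_per_line + i, j] = g_db
    return GenotypeMatrix(samples, loci, calls, populations)


def inbred_reference_panel() -> PanelDefinition:
    """The fifteen line-diagnostic loci as a panel definition."""
    return PanelDefinition([
        PanelEntry(r[0], r[1], r[2], r[3], r[4], r[5])
        for r in INBRED_DISTINGUISHING_LOCI
    ])
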