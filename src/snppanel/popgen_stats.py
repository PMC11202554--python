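"""Per-locus and per-population genetic diversity statistics.

Estimator conventions (chosen to match the classical population-genetics
program output these summaries mirror):

* average heterozygosity is Nei's gene diversity, h = 1 - sum(p_i^2);
* expected heterozygosity applies the Levene small-sample correction,
  2n/(2n-1) * h, where n is the number of called diploids at the locus;
* the Shannon index uses natural logarithms;
* PIC (polymorphism information content) is
  1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2;
* a locus is polymorphic iff >= 2 alleles are observed (no frequency
  criterion), so for a biallelic panel Na = 1 + proportion polymorphic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import GenotypeMatrix

log = logging.getLogger("snppanel")


def levene_factor(n: int) -> float:
    """Small-sample correction 2n/(2n-1) for expected heterozygosity."""
    if n < 1:
        raise ValueError("need at least one called diploid")
    return 2 * n / (2 * n - 1)


def expected_het_from_ave(ave_het: float, n: int) -> float:
    """Levene-corrected expected heterozygosity from gene diversity, capped at 1."""
    return min(1.0, levene_factor(n) * ave_het)


def allele_frequencies(
    matrix: GenotypeMatrix, population: str, locus: str
) -> tuple[dict[str, float], int]:
    """Allele -> frequency at a locus within one population.

    Frequencies are allele counts over 2n chromosomes, n the number of
    non-missing diploid calls.  Returns ``({}, 0)`` when the locus is
    uncallable in this population.
    """
    counts: dict[str, int] = {}
    n = 0
    for call in matrix.locus_calls(locus, population):
        if call is None:
            continue
        n += 1
        for allele in call:
            counts[allele] = counts.get(allele, 0) + 1
    if n == 0:
        return {}, 0
    return {a: c / (2 * n) for a, c in sorted(counts.items())}, n


def population_allele_frequencies(
    matrix: GenotypeMatrix, loci: Sequence[str] | None = None
) -> dict[str, dict[str, tuple[dict[str, float], int]]]:
    """Nested frequency tables: population -> locus -> (freqs, n)."""
    loci = matrix.loci if loci is None else list(loci)
    return {
        pop: {locus: allele_frequencies(matrix, pop, locus) for locus in loci}
        for pop in matrix.population_labels()
    }


@dataclass(frozen=True)
class LocusStats:
    na: int
    ne: float
    shannon_i: float
    obs_hom: float
    obs_het: float
    exp_hom: float
    exp_het: float
    ave_het: float
    pic: float
    n: int


def locus_stats(freqs: Mapping[str, float], het_count: int, n: int) -> LocusStats:
    """Diversity statistics for one locus from its allele frequencies.

    ``het_count`` is the number of heterozygous calls among the ``n``
    called diploids.  Monomorphic loci yield na=1, ne=1 and zero for all
    diversity measures.
    """
    if n == 0:
        raise ValueError("locus has no called genotypes")
    p = [f for f in freqs.values() if f > 0]
    total = sum(p)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies must sum to 1, got {total}")
    sum_p2 = sum(x * x for x in p)
    ave_het = 1.0 - sum_p2
    exp_het = expected_het_from_ave(ave_het, n)
    pic = ave_het - sum(
        2 * p[i] ** 2 * p[j] ** 2 for i in range(len(p)) for j in range(i + 1, len(p))
    )
    obs_het = het_count / n
    return LocusStats(
        na=len(p),
        ne=1.0 / sum_p2,
        shannon_i=-sum(x * math.log(x) for x in p),
        obs_hom=1.0 - obs_het,
        obs_het=obs_het,
        exp_hom=1.0 - exp_het,
        exp_het=exp_het,
        ave_het=ave_het,
        pic=pic,
        n=n,
    )


def locus_stats_from_matrix(
    matrix: GenotypeMatrix, population: str, locus: str
) -> LocusStats | None:
    """Convenience: compute :func:`locus_stats` straight from calls.

    Returns ``None`` for a locus with no calls in this population."""
    freqs, n = allele_frequencies(matrix, population, locus)
    if n == 0:
        return None
    het = sum(
        1
        for call in matrix.locus_calls(locus, population)
        if call is not None and call[0] != call[1]
    )
    return locus_stats(freqs, het, n)


@dataclass(frozen=True)
class PopulationSummary:
    """One summary row: unweighted means of per-locus statistics."""

    population: str
    na: float
    ne: float
    shannon_i: float
    obs_hom: float
    obs_het: float
    exp_hom: float
    exp_het: float
    ave_het: float
    pic: float
    pct_polymorphic: float
    n_samples: int
    n_loci: int

    COLUMNS = (
        "population", "na", "ne", "shannon_i", "obs_hom", "obs_het",
        "exp_hom", "exp_het", "ave_het", "pic", "pct_polymorphic",
        "n_samples", "n_loci",
    )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.COLUMNS}


def population_summary(
    matrix: GenotypeMatrix, population: str, loci: Sequence[str] | None = None
) -> PopulationSummary:
    """Mean per-locus diversity over the panel for one population.

    Monomorphic loci contribute zeros to the diversity means (and 1 to
    the allele count); loci with no calls in this population are excluded
    from all means with a warning.
    """
    loci = matrix.loci if loci is None else list(loci)
    per_locus: list[LocusStats] = []
    uncallable = 0
    for locus in loci:
        stats = locus_stats_from_matrix(matrix, population, locus)
        if stats is None:
            uncallable += 1
        else:
            per_locus.append(stats)
    if uncallable:
        log.warning("%d loci uncallable in population %s; excluded from means",
                    uncallable, population)
    if not per_locus:
        raise ValueError(f"no callable loci for population {population}")
    m = len(per_locus)

    def mean(attr: str) -> float:
        return sum(getattr(s, attr) for s in per_locus) / m

    return PopulationSummary(
        population=population,
        na=mean("na"),
        ne=mean("ne"),
        shannon_i=mean("shannon_i"),
        obs_hom=mean("obs_hom"),
        obs_het=mean("obs_het"),
        exp_hom=mean("exp_hom"),
        exp_het=mean("exp_het"),
        ave_het=mean("ave_het"),
        pic=mean("pic"),
        pct_polymorphic=sum(s.na >= 2 for s in per_locus) / m,
        n_samples=len(matrix.samples_in(population)),
        n_loci=m,
    )


def summarize_all(matrix: GenotypeMatrix, loci: Sequence[str] | None = None) -> list[PopulationSummary]:
    return [population_summary(matrix, pop, loci) for pop in matrix.population_labels()]
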