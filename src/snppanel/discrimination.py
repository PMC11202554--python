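"""Loci that discriminate populations or inbred lines.

Outbred populations are compared with Pearson chi-square tests on
genotype-class contingency tables (populations x genotype classes),
annotated with distribution patterns (monomorphic in some populations,
fixed for different genotypes).  Inbred lines are compared by the fixed-
difference rule: a locus distinguishes two lines iff each line is fixed
homozygous and the fixed alleles differ.

Published tables report genotype *frequencies*; counts are reconstructed
with largest-remainder rounding so each population's counts sum to its
sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .model import GenotypeMatrix

log = logging.getLogger("snppanel")


def genotype_counts_from_frequencies(
    freqs: Sequence[float], n: int, tol: float = 0.02
) -> np.ndarray:
    """Integer genotype counts from printed frequencies summing to ~1.

    Rounds each class down, then distributes the remaining individuals to
    the classes with the largest fractional remainders (ties resolved in
    input order), so the counts always sum to ``n``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0):
        raise ValueError("negative frequency")
    total = float(freqs.sum())
    if abs(total - 1.0) > tol:
        raise ValueError(f"frequencies sum to {total}, outside tolerance {tol}")
    raw = freqs * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - int(counts.sum())
    if short < 0:  # frequency sum slightly above 1 can overfill
        for idx in np.argsort(remainder, kind="stable"):
            if short == 0:
                break
            if counts[idx] > 0:
                counts[idx] -= 1
                short += 1
    else:
        for idx in np.argsort(-remainder, kind="stable"):
            if short == 0:
                break
            counts[idx] += 1
            short -= 1
    return counts


@dataclass
class ContingencyResult:
    """Genotype-distribution comparison of one locus across populations."""

    locus: str
    populations: list[str]
    genotype_classes: list[str]
    counts: np.ndarray  # populations x genotype classes
    chi2: float | None
    df: int | None
    p: float | None
    monomorphic_in: list[str] = field(default_factory=list)
    fixed_different: bool = False
    flagged: bool = False

    @property
    def pattern(self) -> str:
        if self.fixed_different:
            return "fixed-different"
        if self.monomorphic_in:
            return "monomorphic-in {" + ",".join(self.monomorphic_in) + "}"
        return "distribution-shift"


def _patterns(counts: np.ndarray, populations: Sequence[str]) -> tuple[list[str], bool]:
    nonzero_per_pop = [np.flatnonzero(row) for row in counts]
    mono = [
        pop
        for pop, nz, row in zip(populations, nonzero_per_pop, counts)
        if row.sum() > 0 and len(nz) == 1
    ]
    poly_exists = any(len(nz) > 1 for nz in nonzero_per_pop)
    monomorphic_in = mono if poly_exists else []
    fixed_different = (
        all(len(nz) == 1 for nz in nonzero_per_pop)
        and len({nz[0] for nz in nonzero_per_pop}) > 1
    )
    return monomorphic_in, fixed_different


def chi_square_test(
    counts: np.ndarray,
    populations: Sequence[str],
    genotype_classes: Sequence[str],
    locus: str = "",
) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) on a genotype table.

    All-zero genotype columns are dropped before testing.  A degenerate
    table (fewer than two nonzero rows or columns) has no defined test;
    chi2/df/p are reported as ``None``.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or np.any(counts < 0):
        raise ValueError("counts must be a non-negative 2-D table")
    populations = list(populations)
    genotype_classes = list(genotype_classes)
    keep = np.flatnonzero(counts.sum(axis=0) > 0)
    trimmed = counts[:, keep]
    classes_kept = [genotype_classes[j] for j in keep]
    nonzero_rows = np.flatnonzero(trimmed.sum(axis=1) > 0)
    monomorphic_in, fixed_different = _patterns(counts, populations)
    res = ContingencyResult(
        locus, populations, genotype_classes, counts,
        chi2=None, df=None, p=None,
        monomorphic_in=monomorphic_in, fixed_different=fixed_different,
    )
    if trimmed.shape[1] < 2 or len(nonzero_rows) < 2:
        return res
    chi2, p, df, _ = stats.chi2_contingency(trimmed[nonzero_rows], correction=False)
    res.chi2, res.p = float(chi2), float(p)
    res.df = (len(nonzero_rows) - 1) * (len(classes_kept) - 1)
    return res


def contingency_from_matrix(
    matrix: GenotypeMatrix, locus: str, populations: Sequence[str] | None = None
) -> ContingencyResult:
    """Build and test the genotype table of one locus from raw calls."""
    pops = list(populations) if populations is not None else matrix.population_labels()
    class_set: set[tuple[str, str]] = set()
    per_pop = []
    for pop in pops:
        cnt = matrix.genotype_counts(locus, pop)
        per_pop.append(cnt)
        class_set.update(cnt)
    classes = sorted(class_set)
    counts = np.array([[cnt.get(g, 0) for g in classes] for cnt in per_pop], dtype=int)
    labels = ["".join(g) for g in classes]
    return chi_square_test(counts, pops, labels, locus=locus)


def population_specific_loci(
    matrix: GenotypeMatrix,
    alpha: float = 0.001,
    require_pattern: bool = False,
    bonferroni: bool = False,
    loci: Sequence[str] | None = None,
) -> tuple[list[ContingencyResult], list[ContingencyResult]]:
    """Flag loci whose genotype distribution separates populations.

    A locus is flagged when its chi-square p-value falls below ``alpha``
    (optionally Bonferroni-adjusted across loci).  With
    ``require_pattern`` the flag additionally demands a categorical
    pattern — monomorphic in at least one population while polymorphic in
    another, or fixed for different genotypes; by default the pattern is
    reported descriptively but does not gate the flag, since a strong
    frequency shift already identifies the source population.

    Returns (flagged results, all results).
    """
    loci = matrix.loci if loci is None else list(loci)
    threshold = alpha / len(loci) if bonferroni else alpha
    results = [contingency_from_matrix(matrix, locus) for locus in loci]
    for r in results:
        significant = r.p is not None and r.p < threshold
        has_pattern = bool(r.monomorphic_in) or r.fixed_different
        r.flagged = significant and (has_pattern or not require_pattern)
    flagged = [r for r in results if r.flagged]
    return flagged, results


@dataclass
class InbredComparison:
    """Fixed-difference screen between two inbred lines."""

    line_a: str
    line_b: str
    distinguishing: list[tuple[str, str, str]]  # (locus, genotype_a, genotype_b)
    monomorphic_a: int
    monomorphic_b: int
    monomorphic_both: int

    @property
    def n_distinguishing(self) -> int:
        return len(self.distinguishing)


def _fixed_genotype(counts) -> tuple[str, str] | None:
    """The single genotype class of a line, or None if absent/segregating."""
    if len(counts) != 1:
        return None
    return next(iter(counts))


def inbred_distinguishers(
    matrix: GenotypeMatrix,
    line_a: str,
    line_b: str,
    loci: Sequence[str] | None = None,
) -> InbredComparison:
    """Loci fixed homozygous for different alleles in two inbred lines.

    A locus is reported iff every called genotype within each line is the
    same *homozygous* genotype and the two lines' genotypes differ
    (heterozygous uniformity does not count as fixation).  Also reports
    how many loci are monomorphic within each line and within both.
    """
    loci = matrix.loci if loci is None else list(loci)
    distinguishing = []
    mono_a = mono_b = mono_both = 0
    for locus in loci:
        ga = _fixed_genotype(matrix.genotype_counts(locus, line_a))
        gb = _fixed_genotype(matrix.genotype_counts(locus, line_b))
        mono_a += ga is not None
        mono_b += gb is not None
        if ga is not None and gb is not None:
            mono_both += 1
            if ga[0] == ga[1] and gb[0] == gb[1] and ga != gb:
                distinguishing.append((locus, "/".join(ga), "/".join(gb)))
    return InbredComparison(line_a, line_b, distinguishing, mono_a, mono_b, mono_both)
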