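"""Core containers: variant sites, genotype matrices, panel definitions.

Conventions used throughout the package:

* genomic coordinates are 1-based (as in VCF and the panel TSV); BED export
  converts to 0-based half-open intervals at write time;
* a genotype call is an *unordered* diploid allele pair, stored as a sorted
  2-tuple of single-base allele strings; a missing call is ``None``;
* loci are identified by "MG<k>" ids assigned in genomic order
  (scaffold lexicographic, then position) when a panel is first defined.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: functional classes treated as phenotype-relevant when ranking candidates
DAMAGING_CLASSES = frozenset(
    {"Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation"}
)

#: classification vocabulary accepted on variant records
KNOWN_CLASSES = DAMAGING_CLASSES | {"Intron", "5'Flank", "3'Flank", "Other"}

#: tokens accepted as a missing genotype on read; "./." is written
MISSING_TOKENS = {"./.", ".|.", ".", "..", "NN", "N/N", "", "NA", "--"}

_CALL_SEP = re.compile(r"[/|]")


def parse_call(token: str | None) -> tuple[str, str] | None:
    """Normalize a genotype token to a sorted allele pair, or ``None``.

    Accepts compact ("AG"), separated ("A/G", "A|G") and missing ("./.",
    "NN") forms.  The pair is unordered: "GA" and "AG" yield the same call.
    Phasing separators are ignored.
    """
    if token is None:
        return None
    tok = token.strip()
    if tok in MISSING_TOKENS:
        return None
    parts = _CALL_SEP.split(tok) if _CALL_SEP.search(tok) else list(tok)
    if len(parts) != 2:
        raise ValueError(f"cannot parse genotype call {token!r}")
    a, b = parts
    if a in {".", "N"} or b in {".", "N"}:
        return None
    return (a, b) if a <= b else (b, a)


def format_call(call: tuple[str, str] | None) -> str:
    return "./." if call is None else f"{call[0]}/{call[1]}"


@dataclass
class VariantSite:
    """A biallelic variant record with its call-quality annotations.

    ``qd``/``fs``/``mq``/``dp`` are the per-site INFO annotations emitted by
    standard short-read callers (quality by depth, Fisher-strand phred
    score, RMS mapping quality, read depth); ``None`` marks an unavailable
    metric, which the QC stage treats conservatively as failing.
    """

    scaffold: str
    pos: int
    ref: str
    alt: str
    qd: float | None = None
    fs: float | None = None
    mq: float | None = None
    dp: float | None = None
    classification: str = "Other"
    is_indel: bool | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.scaffold}:{self.pos}")
        if self.is_indel is None:
            self.is_indel = len(self.ref) != 1 or len(self.alt) != 1

    @property
    def key(self) -> tuple[str, int]:
        """(scaffold, pos) — the genomic identity of the site."""
        return (self.scaffold, self.pos)


class GenotypeMatrix:
    """Samples x loci diploid calls plus a sample -> population map.

    ``calls`` is an object array of shape (n_samples, n_loci) whose entries
    are sorted allele pairs or ``None``.  Every sample must carry a
    population label.
    """

    def __init__(
        self,
        samples: Sequence[str],
        loci: Sequence[str],
        calls: np.ndarray,
        populations: Mapping[str, str],
    ) -> None:
        self.samples = list(samples)
        self.loci = list(loci)
        calls = np.asarray(calls, dtype=object)
        if calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        self.calls = calls
        missing = [s for s in self.samples if s not in populations]
        if missing:
            raise ValueError(f"samples without a population label: {missing[:5]}")
        self.populations = {s: populations[s] for s in self.samples}
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}
        self._locus_idx = {l: j for j, l in enumerate(self.loci)}

    # -- lookups ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s in self.samples if self.populations[s] == population]

    def locus_calls(self, locus: str, population: str | None = None) -> list[tuple[str, str] | None]:
        j = self._locus_idx[locus]
        if population is None:
            rows = range(self.n_samples)
        else:
            rows = [self._sample_idx[s] for s in self.samples_in(population)]
        return [self.calls[i, j] for i in rows]

    def genotype_counts(self, locus: str, population: str | None = None) -> Counter:
        """Counts of non-missing genotype classes at a locus."""
        return Counter(c for c in self.locus_calls(locus, population) if c is not None)

    def subset(
        self,
        loci: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        loci = self.loci if loci is None else list(loci)
        samples = self.samples if samples is None else list(samples)
        rows = [self._sample_idx[s] for s in samples]
        cols = [self._locus_idx[l] for l in loci]
        calls = self.calls[np.ix_(rows, cols)]
        return GenotypeMatrix(samples, loci, calls, self.populations)

    # -- numeric views ---------------------------------------------------

    def observed_alleles(self, locus: str) -> list[str]:
        """Sorted distinct alleles seen in non-missing calls at a locus."""
        alleles: set[str] = set()
        for call in self.locus_calls(locus):
            if call is not None:
                alleles.update(call)
        return sorted(alleles)

    def dosage_matrix(
        self, alt_by_locus: Mapping[str, str] | None = None
    ) -> tuple[np.ndarray, dict[str, str | None]]:
        """Per-sample counts of a chosen "counted" allele at each locus.

        Returns a float array (n_samples x n_loci; ``nan`` = missing) and
        the counted allele per locus.  Without an explicit ``alt_by_locus``
        the lexicographically larger observed allele is counted — complete
        linkage and PCA are invariant to this arbitrary orientation.
        """
        dos = np.full((self.n_samples, self.n_loci), np.nan)
        counted: dict[str, str | None] = {}
        for j, locus in enumerate(self.loci):
            if alt_by_locus is not None and locus in alt_by_locus:
                alt = alt_by_locus[locus]
            else:
                obs = self.observed_alleles(locus)
                alt = obs[-1] if obs else None
            counted[locus] = alt
            if alt is None:
                continue
            for i in range(self.n_samples):
                call = self.calls[i, j]
                if call is not None:
                    dos[i, j] = (call[0] == alt) + (call[1] == alt)
        return dos, counted


@dataclass(frozen=True)
class PanelEntry:
    """One panel locus in the published TSV schema (Number, CHROM, POS,
    Variant_Classification, REF, ALT)."""

    locus_id: str
    scaffold: str
    pos: int
    classification: str
    ref: str
    alt: str

    @property
    def key(self) -> tuple[str, int]:
        return (self.scaffold, self.pos)


@dataclass
class PanelDefinition:
    """An ordered set of panel loci with stable MG-numbered ids."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.locus_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids in panel")
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (scaffold, pos) in panel")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def loci(self) -> list[str]:
        return [e.locus_id for e in self.entries]

    @classmethod
    def from_sites(cls, sites: Iterable[VariantSite], prefix: str = "MG") -> "PanelDefinition":
        """Number sites sequentially in genomic order (scaffold, then pos)."""
        ordered = sorted(sites, key=lambda s: (s.scaffold, s.pos))
        entries = [
            PanelEntry(f"{prefix}{k}", s.scaffold, s.pos, s.classification, s.ref, s.alt)
            for k, s in enumerate(ordered, start=1)
        ]
        return cls(entries)

    def restrict(self, keep_ids: Iterable[str]) -> "PanelDefinition":
        """Subset preserving original ids and order (ids keep their gaps)."""
        keep = set(keep_ids)
        return PanelDefinition([e for e in self.entries if e.locus_id in keep])

    def entry(self, locus_id: str) -> PanelEntry:
        for e in self.entries:
            if e.locus_id == locus_id:
                return e
        raise KeyError(locus_id)
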