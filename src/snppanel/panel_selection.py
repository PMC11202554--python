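"""Candidate SNP panel selection and post-genotyping optimization.

Selection composes five criteria on top of site QC:

1. polymorphism — each allele's cohort frequency within configurable
   bounds, optionally with a stricter minor-allele-frequency floor;
2. amplification specificity — no other variant (SNP or indel, of any
   quality) within a flanking window of the candidate;
3. phenotype relevance — candidates ranked by the local density of
   missense/nonsense/nonstop classifications;
4. genome dispersal — greedy spacing in rank order so accepted loci on a
   scaffold stay a minimum distance apart;
5. independence — completely linked locus groups (identical or
   complementary dosage vectors, empirical r^2 = 1) reduced to one locus.

After genotyping, :func:`optimize_panel` re-screens the panel with the
locus mapping-quality filter, drops loci showing a single genotype across
every sample of every population, and prunes complete linkage again.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    DAMAGING_CLASSES,
    GenotypeMatrix,
    PanelDefinition,
    VariantSite,
)
from .variant_qc import QcThresholds, apply_locus_mapq_filter, apply_site_qc

log = logging.getLogger("snppanel")


class PanelSelectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable criteria for candidate selection.

    ``freq_low``/``freq_high`` bound every allele's frequency (inclusive);
    ``maf_floor`` additionally requires minor-allele frequency strictly
    above the floor (set to ``None`` to disable).  ``flank_bp`` is the
    exclusion radius for neighboring variants (inclusive at the boundary);
    ``min_spacing_bp`` the minimum same-scaffold distance between accepted
    loci; ``density_window_bp`` the half-width of the window in which
    damaging classifications are counted for ranking.
    """

    freq_low: float = 0.25
    freq_high: float = 0.75
    maf_floor: float | None = 0.30
    flank_bp: int = 200
    min_spacing_bp: int = 500_000
    density_window_bp: int = 100_000
    prefer_classes: frozenset[str] = DAMAGING_CLASSES

    def __post_init__(self) -> None:
        if not (0 <= self.freq_low < self.freq_high <= 1):
            raise ValueError("need 0 <= freq_low < freq_high <= 1")
        if self.flank_bp <= 0:
            raise ValueError("flank_bp must be positive")
        if self.min_spacing_bp < 0:
            raise ValueError("min_spacing_bp must be >= 0")


Dosages = Mapping[tuple[str, int], np.ndarray]


def _alt_frequency(dos: np.ndarray) -> tuple[float | None, int]:
    """ALT-allele frequency and number of called diploids (-1 = missing)."""
    dos = np.asarray(dos)
    called = dos[dos >= 0]
    n = called.size
    if n == 0:
        return None, 0
    return float(called.sum()) / (2 * n), n


def frequency_filter(
    sites: Sequence[VariantSite],
    dosages: Dosages,
    cfg: SelectionConfig = SelectionConfig(),
) -> tuple[list[VariantSite], dict[str, int]]:
    """Keep sites whose allele frequencies show usable polymorphism.

    A site passes iff both allele frequencies lie in
    [freq_low, freq_high] (boundaries inclusive) and, when enabled, the
    minor-allele frequency strictly exceeds ``maf_floor``.  Sites with no
    called genotypes are rejected and counted separately.
    """
    kept: list[VariantSite] = []
    rejected = {"uncalled": 0, "frequency": 0, "maf_floor": 0}
    for site in sites:
        p, n = _alt_frequency(dosages[site.key])
        if n == 0:
            rejected["uncalled"] += 1
            continue
        q = 1.0 - p
        if not (cfg.freq_low <= p <= cfg.freq_high and cfg.freq_low <= q <= cfg.freq_high):
            rejected["frequency"] += 1
            continue
        if cfg.maf_floor is not None and min(p, q) <= cfg.maf_floor:
            rejected["maf_floor"] += 1
            continue
        kept.append(site)
    return kept, rejected


def _positions_by_scaffold(variants: Sequence[VariantSite]) -> dict[str, list[int]]:
    by_scaffold: dict[str, list[int]] = {}
    for v in variants:
        by_scaffold.setdefault(v.scaffold, []).append(v.pos)
    for positions in by_scaffold.values():
        positions.sort()
    return by_scaffold


def flank_uniqueness_filter(
    candidates: Sequence[VariantSite],
    all_variants: Sequence[VariantSite],
    cfg: SelectionConfig = SelectionConfig(),
) -> list[VariantSite]:
    """Drop candidates with any other variant within ``flank_bp`` bases.

    ``all_variants`` must be the full unfiltered call set (SNPs and
    indels, including QC failures) so that low-quality neighbors still
    disqualify.  The distance boundary is inclusive: a neighbor exactly
    ``flank_bp`` away removes the candidate.
    """
    by_scaffold = _positions_by_scaffold(all_variants)
    kept = []
    for cand in candidates:
        positions = by_scaffold.get(cand.scaffold, [])
        lo = bisect.bisect_left(positions, cand.pos - cfg.flank_bp)
        hi = bisect.bisect_right(positions, cand.pos + cfg.flank_bp)
        n_window = hi - lo
        n_self = sum(1 for k in range(lo, hi) if positions[k] == cand.pos)
        if n_window - n_self == 0:
            kept.append(cand)
    return kept


def annotation_density_rank(
    candidates: Sequence[VariantSite],
    all_variants: Sequence[VariantSite],
    cfg: SelectionConfig = SelectionConfig(),
) -> list[tuple[VariantSite, int]]:
    """Score candidates by nearby damaging-classification density.

    The score counts variants whose classification is in
    ``prefer_classes`` within +-``density_window_bp`` of the candidate
    (the candidate itself included when it qualifies).  The result is
    sorted by (score desc, scaffold, pos) — a stable, deterministic rank.
    """
    damaging = [v for v in all_variants if v.classification in cfg.prefer_classes]
    by_scaffold = _positions_by_scaffold(damaging)
    scored = []
    for cand in candidates:
        positions = by_scaffold.get(cand.scaffold, [])
        lo = bisect.bisect_left(positions, cand.pos - cfg.density_window_bp)
        hi = bisect.bisect_right(positions, cand.pos + cfg.density_window_bp)
        scored.append((cand, hi - lo))
    scored.sort(key=lambda t: (-t[1], t[0].scaffold, t[0].pos))
    return scored


def spacing_select(
    ranked: Sequence[VariantSite | tuple[VariantSite, int]],
    cfg: SelectionConfig = SelectionConfig(),
) -> list[VariantSite]:
    """Greedy dispersal: accept candidates in rank order, rejecting any
    candidate closer than ``min_spacing_bp`` to an accepted locus on the
    same scaffold.  Loci on distinct scaffolds never conflict.
    """
    accepted: list[VariantSite] = []
    taken: dict[str, list[int]] = {}
    for item in ranked:
        cand = item[0] if isinstance(item, tuple) else item
        positions = taken.get(cand.scaffold, [])
        if any(abs(cand.pos - p) < cfg.min_spacing_bp for p in positions):
            continue
        accepted.append(cand)
        taken.setdefault(cand.scaffold, []).append(cand.pos)
    return accepted


# ---------------------------------------------------------------------------
# Complete linkage
# ---------------------------------------------------------------------------

def _linked(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff dosage vectors are completely linked (empirical r^2 = 1).

    Over samples called at both loci: vectors identical or exactly
    complementary (d vs 2-d), both non-constant, overlap >= 2.
    """
    mask = (a >= 0) & (b >= 0)
    if mask.sum() < 2:
        return False
    x, y = a[mask], b[mask]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return False
    return bool(np.array_equal(x, y) or np.array_equal(x, 2 - y))


def complete_linkage_prune(
    sites: Sequence[VariantSite],
    dosages: Dosages,
) -> tuple[list[VariantSite], list[tuple[VariantSite, VariantSite]]]:
    """Reduce each completely linked group to its most informative locus.

    Two loci are completely linked iff, over samples non-missing at both,
    their dosage vectors are identical or exactly complementary.  From
    each linked group the highest-MAF locus is kept (ties broken by the
    smallest genomic coordinate).  Loci with fewer than two informative
    samples are left unpruned with a warning.

    Returns (kept sites in input order, list of (removed, kept-instead)).
    """
    n = len(sites)
    vecs = [np.asarray(dosages[s.key]) for s in sites]
    for s, v in zip(sites, vecs):
        if (v >= 0).sum() < 2:
            log.warning("locus %s:%d has <2 informative samples; linkage not assessed",
                        s.scaffold, s.pos)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _linked(vecs[i], vecs[j]):
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    def maf(i: int) -> float:
        p, m = _alt_frequency(vecs[i])
        if p is None:
            return -1.0
        return min(p, 1.0 - p)

    keep_idx: set[int] = set()
    removed: list[tuple[VariantSite, VariantSite]] = []
    for members in groups.values():
        best = min(members, key=lambda i: (-maf(i), sites[i].scaffold, sites[i].pos))
        keep_idx.add(best)
        removed += [(sites[i], sites[best]) for i in members if i != best]
    kept = [sites[i] for i in range(n) if i in keep_idx]
    return kept, removed


# ---------------------------------------------------------------------------
# Full pipelines
# ---------------------------------------------------------------------------

@dataclass
class SelectionLog:
    """Bookkeeping for a selection run: input/output sizes per stage."""

    n_input: int = 0
    n_indel_excluded: int = 0
    qc_rejections: dict = field(default_factory=dict)
    frequency_rejections: dict = field(default_factory=dict)
    n_after_qc: int = 0
    n_after_frequency: int = 0
    n_after_flank: int = 0
    n_after_spacing: int = 0
    n_after_linkage: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def select_panel(
    variants: Sequence[VariantSite],
    dosages: Dosages,
    cfg: SelectionConfig = SelectionConfig(),
    qc: QcThresholds = QcThresholds(),
) -> tuple[PanelDefinition, SelectionLog]:
    """Run the full candidate-selection pipeline and number the panel.

    Stage order: site QC -> frequency filter -> flank uniqueness ->
    density ranking -> greedy spacing -> complete-linkage pruning ->
    MG-numbering in genomic order.  Deterministic given inputs and
    configuration; raises :class:`PanelSelectionError` when nothing
    survives.
    """
    logrec = SelectionLog(n_input=len(variants))
    passing, logrec.qc_rejections = apply_site_qc(variants, qc)
    snps = [s for s in passing if not s.is_indel]
    logrec.n_indel_excluded = len(passing) - len(snps)
    logrec.n_after_qc = len(snps)

    polymorphic, logrec.frequency_rejections = frequency_filter(snps, dosages, cfg)
    logrec.n_after_frequency = len(polymorphic)

    isolated = flank_uniqueness_filter(polymorphic, variants, cfg)
    logrec.n_after_flank = len(isolated)

    ranked = annotation_density_rank(isolated, variants, cfg)
    spaced = spacing_select(ranked, cfg)
    logrec.n_after_spacing = len(spaced)

    kept, _removed = complete_linkage_prune(spaced, dosages)
    logrec.n_after_linkage = len(kept)

    if not kept:
        raise PanelSelectionError("no loci met criteria")
    return PanelDefinition.from_sites(kept), logrec


#: deletion-rule labels, in application order, for optimize_panel logs
OPTIMIZE_RULES = ("MAPQ", "monomorphic", "linked")


def optimize_panel(
    panel: PanelDefinition,
    matrix: GenotypeMatrix,
    locus_mapq: Mapping[str, float],
    qc: QcThresholds = QcThresholds(),
) -> tuple[PanelDefinition, list[tuple[str, str]]]:
    """Post-genotyping cleanup of an established panel.

    Applies, in order: the locus mapping-quality filter; removal of loci
    carrying a single identical called genotype across all samples of all
    populations; complete-linkage pruning.  Each deletion is attributed
    to the first rule that removed it.

    Returns (final panel with original ids, deletion log of
    (locus_id, rule)).
    """
    missing = [l for l in panel.loci if l not in matrix.loci]
    if missing:
        raise ValueError(f"genotyping run lacks panel loci: {missing[:10]}")
    deletions: list[tuple[str, str]] = []

    retained, low_mapq = apply_locus_mapq_filter(locus_mapq, qc, loci=panel.loci)
    deletions += [(l, "MAPQ") for l in low_mapq]

    surviving = []
    for locus in retained:
        classes = matrix.genotype_counts(locus)
        if len(classes) <= 1:
            deletions.append((locus, "monomorphic"))
        else:
            surviving.append(locus)

    alt_by_locus = {e.locus_id: e.alt for e in panel}
    dmat, _ = matrix.dosage_matrix(alt_by_locus)
    col = {l: matrix.loci.index(l) for l in surviving}
    dosages = {}
    pseudo_sites = []
    entry_by_id = {e.locus_id: e for e in panel}
    for locus in surviving:
        e = entry_by_id[locus]
        site = VariantSite(e.scaffold, e.pos, e.ref, e.alt, classification=e.classification)
        pseudo_sites.append(site)
        vec = dmat[:, col[locus]]
        dosages[site.key] = np.where(np.isnan(vec), -1, vec).astype(np.int8)
    kept_sites, removed_pairs = complete_linkage_prune(pseudo_sites, dosages)
    kept_keys = {s.key for s in kept_sites}
    for locus in surviving:
        if entry_by_id[locus].key not in kept_keys:
            deletions.append((locus, "linked"))

    final_ids = [l for l in panel.loci if l not in {d[0] for d in deletions}]
    return panel.restrict(final_ids), deletions
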