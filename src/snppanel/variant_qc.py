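"""Site-level quality filters for called variants.

Two stages: the discovery-time filter on caller annotations (QD, FS, MQ,
DP) applied before panel selection, and the genotyping-time filter that
drops panel loci whose mean mapping quality shows the amplicon maps to a
non-unique region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import VariantSite

log = logging.getLogger("snppanel")

#: rejection-rule order used for first-failing-rule attribution
QC_RULES = ("QD", "FS", "MQ", "DP")


@dataclass(frozen=True)
class QcThresholds:
    """Thresholds for both QC stages.

    A site passes the discovery filter iff qd >= min_qd, mq >= min_mq,
    dp >= min_dp, and its Fisher-strand score is acceptable.  FS is a
    strand-bias badness score (phred-scaled), so the conventional filter
    removes sites with FS *above* the cutoff; ``fs_direction="lt"``
    inverts this to remove sites below it instead.  Boundary values always
    pass ("less than" removes).
    """

    min_qd: float = 2.0
    max_fs: float = 60.0
    min_mq: float = 30.0
    min_dp: float = 8.0
    min_locus_mapq: float = 59.0
    fs_direction: str = "gt"  # "gt": remove FS > max_fs; "lt": remove FS < max_fs

    def __post_init__(self) -> None:
        for name in ("min_qd", "max_fs", "min_mq", "min_dp", "min_locus_mapq"):
            v = getattr(self, name)
            if not (v >= 0 and v == v and v != float("inf")):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.fs_direction not in ("gt", "lt"):
            raise ValueError("fs_direction must be 'gt' or 'lt'")

    def fs_fails(self, fs: float | None) -> bool:
        if fs is None:
            return True
        return fs > self.max_fs if self.fs_direction == "gt" else fs < self.max_fs


def _first_failing_rule(site: VariantSite, t: QcThresholds) -> str | None:
    """Name of the first failing rule in QD, FS, MQ, DP order, or None.

    An unavailable metric counts as failing (conservative)."""
    if site.qd is None or site.qd < t.min_qd:
        return "QD"
    if t.fs_fails(site.fs):
        return "FS"
    if site.mq is None or site.mq < t.min_mq:
        return "MQ"
    if site.dp is None or site.dp < t.min_dp:
        return "DP"
    return None


def apply_site_qc(
    sites: Sequence[VariantSite], t: QcThresholds = QcThresholds()
) -> tuple[list[VariantSite], dict[str, int]]:
    """Split sites into passing and per-rule rejection counts.

    Rejected sites are attributed to the first failing rule in QD, FS,
    MQ, DP order, so the counts partition the rejected set.
    """
    passing: list[VariantSite] = []
    counts = {rule: 0 for rule in QC_RULES}
    for site in sites:
        rule = _first_failing_rule(site, t)
        if rule is None:
            passing.append(site)
        else:
            counts[rule] += 1
    return passing, counts


def apply_locus_mapq_filter(
    locus_mapq: Mapping[str, float],
    t: QcThresholds = QcThresholds(),
    loci: Sequence[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Retain loci whose genotyping-run mean MAPQ is >= the cutoff.

    ``loci`` defaults to all loci in the table; a requested locus without
    a MAPQ value is an error — reads that were never assessed cannot be
    assumed unique.
    Returns (retained, removed) in input order.
    """
    if loci is None:
        loci = list(locus_mapq)
    missing = [l for l in loci if l not in locus_mapq or locus_mapq[l] is None]
    if missing:
        raise ValueError(f"no mapping quality recorded for loci: {missing[:10]}")
    retained = [l for l in loci if locus_mapq[l] >= t.min_locus_mapq]
    removed = [l for l in loci if locus_mapq[l] < t.min_locus_mapq]
    return retained, removed
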