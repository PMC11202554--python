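"""Readers and writers for the external formats the pipeline touches.

VCF is read through :mod:`cyvcf2`; everything else (genotype TSV, popmap,
panel TSV, per-locus MAPQ table, log-probability table, BED, Newick) is
plain tab-separated text.  Coordinates are 1-based everywhere except BED,
which is 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    GenotypeMatrix,
    PanelDefinition,
    PanelEntry,
    VariantSite,
    format_call,
    parse_call,
)

log = logging.getLogger("snppanel")

PANEL_COLUMNS = ["Number", "CHROM", "POS", "Variant_Classification", "REF", "ALT"]

_INFO_FIELDS = ("QD", "FS", "MQ", "DP")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _site_from_record(v, alt: str, classification_key: str) -> VariantSite:
    info = {}
    for k in _INFO_FIELDS:
        raw = v.INFO.get(k)
        info[k.lower()] = float(raw) if raw is not None else None
    cls = v.INFO.get(classification_key)
    if isinstance(cls, bytes):
        cls = cls.decode()
    return VariantSite(
        scaffold=v.CHROM,
        pos=v.POS,
        ref=v.REF,
        alt=alt,
        classification=cls if cls else "Other",
        **info,
    )


def read_variants(
    path: str | Path,
    classification_key: str = "VC",
    split_multiallelic: bool = False,
) -> list[VariantSite]:
    """Read biallelic variant sites (SNPs and indels) from a VCF.

    Multi-allelic records are rejected with a logged count by default, or
    split into one site per ALT when ``split_multiallelic`` is set.
    Missing INFO metrics are retained as ``None`` (marked unavailable).
    """
    sites: list[VariantSite] = []
    n_multi = 0
    try:
        vcf = VCF(str(path))
        for v in vcf:
            alts = v.ALT
            if len(alts) > 1 and not split_multiallelic:
                n_multi += 1
                continue
            for alt in alts:
                sites.append(_site_from_record(v, alt, classification_key))
    except OSError as exc:  # cyvcf2/htslib parse failure
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    if n_multi:
        log.info("rejected %d multi-allelic records in %s", n_multi, path)
    return sites


def read_vcf_cohort(
    path: str | Path,
    classification_key: str = "VC",
    split_multiallelic: bool = False,
) -> tuple[list[VariantSite], list[str], dict[tuple[str, int], np.ndarray]]:
    """Read sites together with per-sample ALT-allele dosages.

    Returns ``(sites, samples, dosages)`` where ``dosages`` maps each site's
    (scaffold, pos) key to an int8 vector over samples (0/1/2; -1 missing).
    Multi-allelic records follow the same policy as :func:`read_variants`
    but are never split here (per-sample dosage would be ambiguous).
    """
    if split_multiallelic:
        raise ValueError("cannot split multi-allelic records when reading genotypes")
    sites: list[VariantSite] = []
    dosages: dict[tuple[str, int], np.ndarray] = {}
    n_multi = 0
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        for v in vcf:
            if len(v.ALT) > 1:
                n_multi += 1
                continue
            site = _site_from_record(v, v.ALT[0], classification_key)
            # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = np.asarray(v.gt_types)
            dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
            sites.append(site)
            dosages[site.key] = dos.astype(np.int8)
    except OSError as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    if n_multi:
        log.info("rejected %d multi-allelic records in %s", n_multi, path)
    return sites, samples, dosages


def write_vcf(
    path: str | Path,
    sites: Sequence[VariantSite],
    samples: Sequence[str] = (),
    dosages: Mapping[tuple[str, int], np.ndarray] | None = None,
    classification_key: str = "VC",
    header_comments: Iterable[str] = (),
) -> None:
    """Write sites (and optional GT columns from dosage vectors) as VCF text."""
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##{c}" for c in header_comments]
    for contig in dict.fromkeys(s.scaffold for s in sites):
        lines.append(f"##contig=<ID={contig}>")
    lines += [
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f'##INFO=<ID={classification_key},Number=1,Type=String,'
        'Description="Functional classification">',
    ]
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        cols += "\tFORMAT\t" + "\t".join(samples)
    lines.append(cols)
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    for s in sorted(sites, key=lambda x: (x.scaffold, x.pos)):
        info_parts = []
        for k in _INFO_FIELDS:
            val = getattr(s, k.lower())
            if val is not None:
                if k == "DP":
                    info_parts.append(f"{k}={int(val)}")
                else:
                    info_parts.append(f"{k}={val:g}")
        info_parts.append(f"{classification_key}={s.classification}")
        row = f"{s.scaffold}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t{';'.join(info_parts)}"
        if samples:
            if dosages is None or s.key not in dosages:
                raise ValueError(f"no genotypes supplied for site {s.key}")
            gts = "\t".join(gt_of.get(int(d), "./.") for d in dosages[s.key])
            row += "\tGT\t" + gts
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Genotype matrix TSV + popmap
# ---------------------------------------------------------------------------

def read_genotype_matrix(
    geno_path: str | Path,
    popmap_path: str | Path,
    alleles_by_locus: Mapping[str, tuple[str, str]] | None = None,
) -> GenotypeMatrix:
    """Read a samples x loci call table plus a sample -> population map.

    The genotype TSV has a header row of locus ids and sample ids in the
    first column; cells are "AG", "A/G" or "./." style.  The popmap is a
    headerless two-column TSV (sample, population).  Popmap entries for
    unknown samples are ignored with a warning.  When ``alleles_by_locus``
    is given, calls carrying alleles outside {ref, alt} raise a validation
    error listing the offending cells.
    """
    table = pd.read_csv(geno_path, sep="\t", index_col=0, dtype=str)
    popmap = pd.read_csv(popmap_path, sep="\t", header=None, dtype=str)
    populations = dict(zip(popmap[0], popmap[1]))
    samples = [str(s) for s in table.index]
    loci = [str(c) for c in table.columns]
    unknown = sorted(set(populations) - set(samples))
    if unknown:
        log.warning("popmap names %d samples absent from the matrix: %s",
                    len(unknown), unknown[:5])
    calls = np.empty(table.shape, dtype=object)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            raw = table.iat[i, j]
            calls[i, j] = parse_call(None if pd.isna(raw) else str(raw))
    if alleles_by_locus is not None:
        offenders = []
        for j, locus in enumerate(loci):
            if locus not in alleles_by_locus:
                continue
            valid = set(alleles_by_locus[locus])
            for i, sample in enumerate(samples):
                call = calls[i, j]
                if call is not None and not set(call) <= valid:
                    offenders.append(f"{sample}@{locus}={format_call(call)}")
        if offenders:
            raise ValueError(
                f"calls with alleles outside {{ref,alt}}: {offenders[:10]}"
                + ("..." if len(offenders) > 10 else "")
            )
    return GenotypeMatrix(samples, loci, calls, populations)


def write_genotype_matrix(
    matrix: GenotypeMatrix, geno_path: str | Path, popmap_path: str | Path
) -> None:
    rows = []
    for i, sample in enumerate(matrix.samples):
        rows.append(
            [sample] + [format_call(matrix.calls[i, j]) for j in range(matrix.n_loci)]
        )
    df = pd.DataFrame(rows, columns=["Sample"] + matrix.loci)
    df.to_csv(geno_path, sep="\t", index=False)
    with open(popmap_path, "w") as fh:
        for sample in matrix.samples:
            fh.write(f"{sample}\t{matrix.populations[sample]}\n")


# ---------------------------------------------------------------------------
# Panel TSV / BED / Newick / auxiliary tables
# ---------------------------------------------------------------------------

def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    """Write the panel in the published column order (Number CHROM POS
    Variant_Classification REF ALT)."""
    if not len(panel):
        raise ValueError("refusing to write an empty panel")
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for e in panel:
            fh.write(
                f"{e.locus_id}\t{e.scaffold}\t{e.pos}\t{e.classification}"
                f"\t{e.ref}\t{e.alt}\n"
            )


def read_panel(path: str | Path) -> PanelDefinition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != PANEL_COLUMNS:
        raise ValueError(f"unexpected panel columns in {path}: {list(df.columns)}")
    entries = [
        PanelEntry(r.Number, r.CHROM, int(r.POS), r.Variant_Classification, r.REF, r.ALT)
        for r in df.itertuples()
    ]
    return PanelDefinition(entries)


def write_roi_bed(
    panel: PanelDefinition, path: str | Path, amplicon_half_width: int = 130
) -> None:
    """Write amplicon regions of interest as BED (0-based half-open).

    A locus at 1-based position p with half-width w spans [p-1-w, p+w);
    intervals running below the scaffold start are clamped at 0.
    """
    w = amplicon_half_width
    with open(path, "w") as fh:
        for e in panel:
            start = e.pos - 1 - w
            if start < 0:
                log.warning("ROI for %s clamped at scaffold start", e.locus_id)
                start = 0
            fh.write(f"{e.scaffold}\t{start}\t{e.pos + w}\t{e.locus_id}\n")


def write_newick(tree, path: str | Path | None = None) -> str:
    """Render a dendrogram (see :mod:`snppanel.distance_tree`) as Newick
    with branch lengths; optionally write it to ``path``."""
    text = tree.newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_mapq_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV (locus id, mean MAPQ from the genotyping run)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str, 1: float})
    return dict(zip(df[0], df[1]))


def write_mapq_table(mapq: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for locus, q in mapq.items():
            fh.write(f"{locus}\t{q:g}\n")


def read_lnp_table(path: str | Path) -> dict[int, list[float]]:
    """TSV with columns K, replicate, lnP -> mapping K -> replicate values.

    Replicates are ordered by their replicate index so that runs stay
    paired across K values.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("k", "replicate", "lnp"):
        if needed not in cols:
            raise ValueError(f"log-probability table must have columns K, replicate, lnP")
    out: dict[int, list[float]] = {}
    for k, grp in df.groupby(cols["k"]):
        grp = grp.sort_values(cols["replicate"])
        out[int(k)] = [float(x) for x in grp[cols["lnp"]]]
    return dict(sorted(out.items()))
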