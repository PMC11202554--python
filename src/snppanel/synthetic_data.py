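"""Synthetic colonies and variant sets with planted ground truth.

Two generators cover the pipeline's inputs end to end:

* :func:`simulate_colonies` draws a genotyping run — outbred populations
  under Hardy–Weinberg at drifted allele frequencies, inbred lines fixed
  homozygous — and can plant the three post-genotyping failure modes
  (low per-locus MAPQ, a single genotype in every sample, complete
  linkage) with known multiplicities;
* :func:`simulate_variant_set` emits a discovery-cohort variant set in
  which "perfect" loci satisfy every selection criterion while each decoy
  violates exactly one (a QC metric, the frequency bounds, a flanking
  variant, a linkage twin, or a spacing conflict), so selection can be
  scored against exact planted truth.

Drift is modeled as a truncated-normal perturbation of the ancestral
frequency (standard deviation = the population's divergence level)
rather than explicit Wright–Fisher generations; that reproduces the
frequency differentiation the downstream statistics consume at a
fraction of the cost.  All randomness flows from a single seed, which is
embedded in generated file headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .model import GenotypeMatrix, PanelDefinition, PanelEntry, VariantSite
from . import io_formats

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Colony genotyping runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """One colony: outbred (HWE at drifted frequencies) or inbred line."""

    label: str
    n: int
    divergence: float = 0.05
    inbred: bool = False
    fixation: float = 1.0  # per-locus probability an inbred line is fixed

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if not 0 <= self.fixation <= 1:
            raise ValueError("fixation must be a probability")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")


@dataclass(frozen=True)
class PlantedFeatures:
    """Failure modes planted into a genotyping run, with multiplicities."""

    n_low_mapq: int = 0
    n_monomorphic: int = 0
    n_linked_pairs: int = 0
    low_mapq: float = 45.0
    good_mapq: float = 60.0


@dataclass(frozen=True)
class ColonyScenario:
    """Study conditions for a simulated genotyping run.

    Defaults mirror the gerbil monitoring study design: three outbred
    colonies (37/31/32 animals) plus two inbred disease-model lines of 10,
    ancestral allele frequencies uniform on [0.25, 0.75], and moderate
    per-colony drift.
    """

    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("Zhejiang", 37, divergence=0.05),
        PopulationSpec("CMU", 31, divergence=0.05),
        PopulationSpec("Dalian", 32, divergence=0.12),
        PopulationSpec("CerebralIschemia", 10, inbred=True),
        PopulationSpec("Diabetes", 10, inbred=True),
    )
    n_loci: int = 206
    freq_low: float = 0.25
    freq_high: float = 0.75
    missing_rate: float = 0.0
    planted: PlantedFeatures = PlantedFeatures()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        p = self.planted
        if p.n_low_mapq + p.n_monomorphic + 2 * p.n_linked_pairs > self.n_loci:
            raise ValueError("planted features exceed locus count")

    @classmethod
    def genotyping_run(cls, seed: int = 0, n_loci: int = 219,
                       failures: tuple[int, int, int] = (3, 7, 3)) -> "ColonyScenario":
        """A candidate-panel genotyping run with the three deletion
        categories planted (low MAPQ, monomorphic, completely linked)."""
        lo, mono, linked = failures
        return cls(
            n_loci=n_loci,
            planted=PlantedFeatures(
                n_low_mapq=lo, n_monomorphic=mono, n_linked_pairs=linked
            ),
            seed=seed,
        )


@dataclass
class SimulatedColonies:
    matrix: GenotypeMatrix
    panel: PanelDefinition
    mapq: dict[str, float]
    truth: dict


def _drifted_frequencies(
    p0: np.ndarray, divergence: float, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal perturbation of ancestral frequencies on [0.05, 0.95].

    Sampled by rejection, which is exact for the truncation bounds used
    here (acceptance stays high for divergence values well under the
    distance from p0 to the bounds)."""
    if divergence == 0:
        return p0.copy()
    out = rng.normal(p0, divergence)
    bad = (out < 0.05) | (out > 0.95)
    while bad.any():
        out[bad] = rng.normal(p0[bad], divergence)
        bad = (out < 0.05) | (out > 0.95)
    return out


def _hwe_dosages(p_alt: float, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(1, p_alt, size=(n, 2)).sum(axis=1)


def simulate_colonies(scenario: ColonyScenario) -> SimulatedColonies:
    """Draw a genotyping run for the scenario's populations.

    Outbred populations are sampled under HWE at per-population drifted
    frequencies; inbred lines emit fixed homozygotes at the stated
    per-locus fixation probability.  Planted failure loci are then
    overlaid and recorded in the truth dict (keys ``low_mapq``,
    ``monomorphic``, ``linked`` and per-locus allele frequencies).
    """
    rng = np.random.default_rng(scenario.seed)
    pops = scenario.populations
    samples, populations = [], {}
    for spec in pops:
        for i in range(spec.n):
            name = f"{spec.label}_{i + 1:03d}"
            samples.append(name)
            populations[name] = spec.label

    n_loci = scenario.n_loci
    entries = []
    ref_alt = []
    for j in range(n_loci):
        ref, alt = rng.choice(4, size=2, replace=False)
        ref_alt.append((str(_BASES[ref]), str(_BASES[alt])))
        entries.append(PanelEntry(
            f"MG{j + 1}", f"NW_SIM{j:05d}.1", 500_000,
            "Missense_Mutation", ref_alt[j][0], ref_alt[j][1],
        ))
    panel = PanelDefinition(entries)

    p0 = rng.uniform(scenario.freq_low, scenario.freq_high, size=n_loci)
    calls = np.empty((len(samples), n_loci), dtype=object)
    pop_freqs: dict[str, list[float]] = {}
    row = 0
    for spec in pops:
        freqs = _drifted_frequencies(p0, spec.divergence, rng)
        pop_freqs[spec.label] = [float(f) for f in freqs]
        for j in range(n_loci):
            ref, alt = ref_alt[j]
            p_alt = float(freqs[j])
            if spec.inbred and rng.random() < spec.fixation:
                allele = alt if rng.random() < p_alt else ref
                dos = np.full(spec.n, 2 if allele == alt else 0)
            else:
                dos = _hwe_dosages(p_alt, spec.n, rng)
            for i, d in enumerate(dos):
                calls[row + i, j] = _dosage_call(ref, alt, int(d))
        row += spec.n

    if scenario.missing_rate:
        mask = rng.random(calls.shape) < scenario.missing_rate
        calls[mask] = None

    # --- plant failure modes -------------------------------------------
    planted = scenario.planted
    n_special = planted.n_low_mapq + planted.n_monomorphic + 2 * planted.n_linked_pairs
    special = rng.choice(n_loci, size=n_special, replace=False)
    cursor = 0
    low_mapq_idx = special[cursor:cursor + planted.n_low_mapq]; cursor += planted.n_low_mapq
    mono_idx = special[cursor:cursor + planted.n_monomorphic]; cursor += planted.n_monomorphic
    link_idx = special[cursor:]

    loci = panel.loci
    mapq = {l: planted.good_mapq for l in loci}
    for j in low_mapq_idx:
        mapq[loci[j]] = planted.low_mapq

    for j in mono_idx:
        ref, alt = ref_alt[j]
        calls[:, j] = [(ref, ref)] * len(samples)

    linked_pairs: list[tuple[str, str]] = []
    for k in range(planted.n_linked_pairs):
        src, twin = sorted((int(link_idx[2 * k]), int(link_idx[2 * k + 1])))
        sref, salt = ref_alt[src]
        tref, talt = ref_alt[twin]
        for i in range(len(samples)):
            call = calls[i, src]
            if call is None:
                calls[i, twin] = None
            else:
                d = (call[0] == salt) + (call[1] == salt)
                calls[i, twin] = _dosage_call(tref, talt, d)
        linked_pairs.append((loci[src], loci[twin]))

    matrix = GenotypeMatrix(samples, loci, calls, populations)
    truth = {
        "seed": scenario.seed,
        "low_mapq": [loci[j] for j in low_mapq_idx],
        "monomorphic": [loci[j] for j in mono_idx],
        "linked": linked_pairs,
        "alt_frequencies": {
            spec.label: dict(zip(loci, pop_freqs[spec.label])) for spec in pops
        },
    }
    return SimulatedColonies(matrix, panel, mapq, truth)


def _dosage_call(ref: str, alt: str, d: int) -> tuple[str, str]:
    pair = (ref, ref) if d == 0 else ((ref, alt) if d == 1 else (alt, alt))
    return (pair[0], pair[1]) if pair[0] <= pair[1] else (pair[1], pair[0])


def plant_line_distinguishers(
    sim: SimulatedColonies, line_a: str, line_b: str, k: int, seed: int = 0
) -> list[str]:
    """Overwrite k loci so the two inbred lines are fixed for opposite
    homozygotes; returns the planted locus ids (also stored in truth)."""
    rng = np.random.default_rng(seed)
    matrix = sim.matrix
    idx_a = [matrix.samples.index(s) for s in matrix.samples_in(line_a)]
    idx_b = [matrix.samples.index(s) for s in matrix.samples_in(line_b)]
    chosen = rng.choice(matrix.n_loci, size=k, replace=False)
    planted = []
    entry = {e.locus_id: e for e in sim.panel}
    for j in chosen:
        locus = matrix.loci[j]
        e = entry[locus]
        for i in idx_a:
            matrix.calls[i, j] = (e.ref, e.ref)
        for i in idx_b:
            matrix.calls[i, j] = (e.alt, e.alt)
        planted.append(locus)
    sim.truth["line_distinguishers"] = planted
    return planted


# ---------------------------------------------------------------------------
# Discovery variant sets for selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSetScenario:
    """A discovery cohort with planted perfect loci and one-fault decoys.

    The cohort mirrors the discovery design (two colonies of 20 animals
    whole-genome sequenced).  ``n_decoys_per_class`` applies to each of
    the five decoy classes: failed QC metric, out-of-bounds frequency,
    flanking variant, complete-linkage twin, spacing conflict.
    """

    n_perfect: int = 20
    n_decoys_per_class: int = 20
    cohort: tuple[tuple[str, int], ...] = (("DiscoveryA", 20), ("DiscoveryB", 20))
    seed: int = 0


@dataclass
class SimulatedVariants:
    sites: list[VariantSite]
    samples: list[str]
    dosages: dict[tuple[str, int], np.ndarray]
    truth: dict


def _planted_dosages(n_hom_ref: int, n_het: int, n_hom_alt: int,
                     rng: np.random.Generator) -> np.ndarray:
    dos = np.array([0] * n_hom_ref + [1] * n_het + [2] * n_hom_alt, dtype=np.int8)
    return rng.permutation(dos)


def simulate_variant_set(scenario: VariantSetScenario = VariantSetScenario()) -> SimulatedVariants:
    """Emit a variant set where selection truth is known by construction.

    Perfect loci sit alone on their scaffolds (plus two QC-failing
    damaging-class "density booster" SNPs 50 kb away) with exact allele
    frequency 0.5.  Decoy classes, each violating exactly one criterion:

    - ``qc``: one caller annotation out of bounds (rotating QD/FS/MQ/DP);
    - ``frequency``: allele frequency 0.05, or 0.275 (inside the coarse
      bounds but below the minor-allele-frequency floor);
    - ``flank``: an indel planted 150 bp away;
    - ``linkage``: dosage column copied from a perfect locus, on a
      scaffold that sorts after it;
    - ``spacing``: a clean low-rank locus 300 kb from a perfect locus.
    """
    rng = np.random.default_rng(scenario.seed)
    n_samples = sum(n for _, n in scenario.cohort)
    samples = [f"{label}_{i + 1:03d}" for label, n in scenario.cohort for i in range(n)]
    half = n_samples // 4

    sites: list[VariantSite] = []
    dosages: dict[tuple[str, int], np.ndarray] = {}
    truth: dict = {"seed": scenario.seed, "perfect": [], "decoys": {
        "qc": [], "frequency": [], "flank": [], "linkage": [], "spacing": []}}

    damaging_cycle = ("Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation")

    def good_metrics() -> dict:
        return dict(qd=25.0, fs=1.5, mq=60.0, dp=300.0)

    def add(site: VariantSite, dos: np.ndarray) -> None:
        sites.append(site)
        dosages[site.key] = dos

    def balanced() -> np.ndarray:
        # exact p = 0.5 regardless of seed: quarter hom-ref, half het, quarter hom-alt
        return _planted_dosages(half, n_samples - 2 * half, half, rng)

    perfect_dos: list[np.ndarray] = []
    for i in range(scenario.n_perfect):
        scaf = f"NW_SIMP{i:04d}.1"
        dos = balanced()
        perfect_dos.append(dos)
        site = VariantSite(scaf, 500_000, "A", "G",
                           classification="Missense_Mutation", **good_metrics())
        add(site, dos)
        truth["perfect"].append(list(site.key))
        for offset, cls in ((-50_000, damaging_cycle[i % 3]),
                            (50_000, damaging_cycle[(i + 1) % 3])):
            booster = VariantSite(scaf, 500_000 + offset, "C", "T",
                                  qd=0.5, fs=2.0, mq=60.0, dp=250.0,
                                  classification=cls)
            add(booster, _planted_dosages(n_samples - 4, 4, 0, rng))

    nd = scenario.n_decoys_per_class

    for i in range(nd):  # QC decoys: one metric fails, everything else perfect
        metrics = good_metrics()
        fail = ("qd", "fs", "mq", "dp")[i % 4]
        metrics[fail] = {"qd": 1.0, "fs": 80.0, "mq": 20.0, "dp": 4.0}[fail]
        site = VariantSite(f"NW_SIMQ{i:04d}.1", 500_000, "A", "G",
                           classification="Missense_Mutation", **metrics)
        add(site, balanced())
        truth["decoys"]["qc"].append(list(site.key))

    for i in range(nd):  # frequency decoys
        if i % 2 == 0:
            dos = _planted_dosages(n_samples - 4, 4, 0, rng)  # p = 0.05
        else:
            n_hom_alt = max(1, round(0.275 * n_samples) - 7)
            n_het = round(0.275 * 2 * n_samples) - 2 * n_hom_alt
            dos = _planted_dosages(n_samples - n_het - n_hom_alt, n_het, n_hom_alt, rng)
        site = VariantSite(f"NW_SIMF{i:04d}.1", 500_000, "A", "G",
                           classification="Missense_Mutation", **good_metrics())
        add(site, dos)
        truth["decoys"]["frequency"].append(list(site.key))

    for i in range(nd):  # flank decoys: a neighboring indel 150 bp away
        scaf = f"NW_SIMN{i:04d}.1"
        site = VariantSite(scaf, 500_000, "A", "G",
                           classification="Missense_Mutation", **good_metrics())
        add(site, balanced())
        indel = VariantSite(scaf, 500_150, "AT", "A",
                            qd=20.0, fs=3.0, mq=55.0, dp=200.0,
                            classification="Other")
        add(indel, _planted_dosages(n_samples - 4, 4, 0, rng))
        truth["decoys"]["flank"].append(list(site.key))

    # linkage and spacing decoys are defined relative to perfect loci
    nd_rel = nd if scenario.n_perfect else 0
    for i in range(nd_rel):  # linkage decoys: twin of a perfect locus
        twin_of = i % scenario.n_perfect
        site = VariantSite(f"NW_SIMZ{i:04d}.1", 500_000, "C", "T",
                           classification="Missense_Mutation", **good_metrics())
        add(site, perfect_dos[twin_of].copy())
        truth["decoys"]["linkage"].append(list(site.key))

    for i in range(nd_rel):  # spacing decoys: 300 kb from a perfect locus, low rank
        scaf = f"NW_SIMP{i % scenario.n_perfect:04d}.1"
        dos = balanced()
        mate = perfect_dos[i % scenario.n_perfect]
        while np.array_equal(dos, mate) or np.array_equal(dos, 2 - mate):
            dos = balanced()
        site = VariantSite(scaf, 800_000, "A", "G",
                           classification="Intron", **good_metrics())
        add(site, dos)
        truth["decoys"]["spacing"].append(list(site.key))

    return SimulatedVariants(sites, samples, dosages, truth)


def write_variant_set(sim: SimulatedVariants, path: str | Path, seed: int) -> None:
    """Write the simulated cohort as VCF text; deterministic per seed."""
    io_formats.write_vcf(
        path, sim.sites, sim.samples, sim.dosages,
        header_comments=(f"snppanel_simulation_seed={seed}",),
    )
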