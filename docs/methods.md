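# Methods

This note records the statistical conventions, numerical choices and
open design decisions behind `snppanel`, and what the synthetic-data
tests do and do not establish about real colony data.

## Selection criteria and their parameters

Candidate screening composes site QC and five criteria in a fixed order:
site QC → frequency filter → flank uniqueness → density ranking → greedy
spacing → complete-linkage pruning. The order matters only between
ranking and spacing: ranking first means the greedy dispersal keeps the
most phenotype-relevant locus of any same-scaffold conflict. Since no
canonical ordering exists for these criteria, this choice is ours and is
documented here rather than configurable.

| parameter | default | units | rationale |
|---|---|---|---|
| `min_qd` | 2.0 | caller score | standard hard-filter floor for quality/depth |
| `max_fs` | 60.0 | phred | strand-bias ceiling; FS is a badness score, so the default removes FS **>** 60 (`fs_direction="lt"` inverts) |
| `min_mq` | 30.0 | phred | RMS mapping-quality floor |
| `min_dp` | 8.0 | reads | per-site INFO depth floor (site total, not per-sample mean) |
| `freq_low/high` | 0.25 / 0.75 | proportion | per-allele frequency band ensuring usable polymorphism; boundaries inclusive |
| `maf_floor` | 0.30 | proportion | stricter minor-allele floor (strict `>`), separating true SNPs from rare variants; `None` disables |
| `flank_bp` | 200 | bp | exclusion radius for any neighboring variant, inclusive at exactly 200 bp; low-quality neighbors still disqualify because primer specificity does not care about call quality |
| `min_spacing_bp` | 500 000 | bp | same-scaffold spacing; scaffold-aware rather than one-per-scaffold, since legitimate panels carry two well-separated loci on one scaffold |
| `density_window_bp` | 100 000 | bp | half-width of the window in which missense/nonsense/nonstop classifications are counted for ranking; the window size is an explicit stand-in for an unquantified "high concentration" notion |
| `min_locus_mapq` | 59 | phred | genotyping-stage mean-MAPQ floor; below it amplicon reads are not uniquely placed (`MAPQ < 59` removes) |

The "genotype frequency 25–75 %" polymorphism rule is interpreted as
*per-allele* frequency bounds: three genotype classes cannot in general
all lie inside one band, while the equivalent allele-frequency statement
(MAF ≥ 0.25) composes cleanly with the stricter MAF > 0.3 floor.

Complete linkage is defined empirically on the sample set at hand: two
loci are completely linked iff, over samples called at both, their
dosage vectors are identical or exactly complementary (r² = 1). Both
vectors must be non-constant (r² is undefined for a monomorphic locus)
and overlap in at least two informative samples — below that the pair is
left unpruned with a warning rather than silently deleted. Each linked
group keeps its highest-MAF locus; ties go to the smallest genomic
coordinate (scaffold lexicographic, then position), which makes pruning
deterministic and order-independent.

Post-genotyping optimization applies, in order: the MAPQ filter, removal
of loci with a single identical called genotype across every sample of
every population, and linkage pruning. Deletions are attributed to the
first rule that removed them, so the per-rule counts partition the
deleted set.

## Estimator conventions

Per locus, with allele frequencies `p_i` over `n` called diploids:
`Na = #{p_i > 0}`, `Ne = 1/Σp_i²`, `I = −Σ p_i ln p_i` (natural log),
gene diversity `h = 1 − Σp_i²` (reported as "average heterozygosity"),
expected heterozygosity `h·2n/(2n−1)` (Levene small-sample correction,
capped at 1), `PIC = h − Σ_{i<j} 2p_i²p_j²`, observed heterozygosity the
heterozygote fraction of called genotypes. Population summaries are
unweighted means over loci; monomorphic loci contribute zeros (and
`Na = 1`); loci uncallable in a population are excluded with a warning,
so `n` varies by locus when data are missing. A locus is polymorphic iff
two alleles are observed — no 95 %/99 % frequency criterion — which for
a biallelic panel forces the identity `Na = 1 + fraction polymorphic`.

This exact pairing — Levene correction on expected heterozygosity,
uncorrected Nei gene diversity beside it — is what classical colony
monitoring reports print, and the package's acceptance tests verify both
identities on the published per-colony summary rows to one unit of the
printed 4-decimal precision (the published inputs are themselves
rounded, so agreement tighter than 1e-4 is not attainable).

Nei's (1972) standard distance accumulates `J_xy`, `J_x`, `J_y` over all
loci callable in both populations (excluded pairwise otherwise); a pair
with identity 0 gets distance +inf with a warning. UPGMA joins clusters
by average linkage with node height = half the average distance, so
branch lengths stay in distance units and trees are ultrametric by
construction (checked to 1e-9). Distance ties are broken by joining the
pair whose lexicographically smallest leaf labels sort first, making the
topology deterministic; UPGMA is implemented in-package because this
tie-break is not controllable through `scipy.cluster.hierarchy`, whose
average-linkage heights serve as an independent oracle in the tests.

## Discrimination

Contingency tests use the Pearson chi-square without continuity
correction on populations × genotype-class tables; all-zero classes are
dropped, and degenerate tables (fewer than two nonzero rows or columns)
report an undefined p rather than 0 or 1. Counts reconstructed from
printed frequency tables use largest-remainder rounding (ties to the
earlier class), so each population's counts always sum to its cohort
size. The significance threshold defaults to 0.001 per locus with no
multiple-testing correction, matching per-locus reporting conventions; a
Bonferroni switch exists.

A locus is flagged population-specific when its p-value clears the
threshold; the categorical pattern (monomorphic in some populations
while polymorphic elsewhere, or fixed for different genotypes) is
reported descriptively. The pattern does not gate the flag by default
because a strong frequency shift without any monomorphic population
already identifies the source colony — three of the seven published
discriminating loci are of exactly this kind. `require_pattern=True`
restores the stricter conjunction.

The inbred-line rule requires each line fixed for a single *homozygous*
genotype with the two lines differing; uniform heterozygosity does not
count as fixation (a line of all A/B animals is not fixed, and real
fixed-difference panels print only homozygotes).

At small sample sizes the asymptotic chi-square p and the exhaustive
label-permutation (conditional hypergeometric) p differ by construction
— up to ≈0.27 against the permutation mid-p over all 2×2 tables with
n ≤ 12 and margins ≥ 3. The test suite therefore checks the Pearson
statistic exactly against an independent hand-coded formula on every
table of the permutation support, and checks the p-value against the
exact mid-p within that family's worst-case gap, which the test computes
itself by exhaustive scan rather than assuming.

## Ordination

PCA uses 0/1/2 dosages of a per-locus counted allele, column-centered
with no variance scaling: centering-only avoids up-weighting rare-allele
loci and is the common default for genotype PCA at monitoring scale.
Missing dosages are imputed to the locus mean (a `drop` mode removes
incomplete loci instead). Components come from the exact SVD; explained
fractions are covariance eigenvalues over the trace; each component's
sign is fixed by making its largest-magnitude loading positive, so
results are invariant (up to that convention) to locus order and allele
relabeling.

Evanno ΔK consumes replicate log-probabilities per K from an external
admixture program (the MCMC itself is out of scope):
`ΔK = mean_r |L_r(K+1) − 2L_r(K) + L_r(K−1)| / sd(L(K))`, replicates
paired by index and truncated to the shortest run, sd across replicates
with ddof = 1. K values with zero sd are excluded from the argmax with a
warning; at least three consecutive K and two replicates per K are
required.

## Synthetic data: what it emulates, and what it does not

`simulate_colonies` draws genotypes under Hardy–Weinberg equilibrium at
per-population frequencies obtained by perturbing a shared ancestral
frequency (uniform on [0.25, 0.75], the band the selection criteria
target) with a truncated normal on [0.05, 0.95] whose standard deviation
is the population's divergence level — a cheap stand-in for
Wright–Fisher drift that reproduces the frequency differentiation the
downstream statistics consume. Default populations mirror the monitoring
study design: three outbred colonies of 37/31/32 animals (the
longest-confined colony given larger drift, 0.12 vs 0.05) and two fully
fixed inbred lines of 10. The genotyping-run scenario plants the three
deletion categories at their published multiplicities (3 low-MAPQ, 7
monomorphic, 3 linked) among 219 loci; with 100 outbred samples at
intermediate frequencies, the probability of an accidental extra
monomorphic or completely linked locus is negligible (< 1e-4 per run),
so the 206-locus outcome is stable across seeds.

`simulate_variant_set` plants 20 "perfect" candidates (exact allele
frequency 0.5 by construction, so recovery does not depend on sampling
luck) among five decoy classes of 20, each violating exactly one
criterion, plus QC-failing damaging-class "booster" SNPs that exercise
density ranking without being selectable.

What passing these tests shows: the filters implement their definitions
exactly, the estimators match their closed forms and published
identities, and the pipeline's bookkeeping is airtight. What it does not
show: behavior under linkage structure (loci are simulated
independently; only *complete* linkage is planted), under genotyping
error or allele dropout, under Hardy–Weinberg departures (inbreeding
within outbred colonies), or under the site-metric correlations of real
callers. Published whole-panel diversity values, dendrogram branch
lengths and PCA percentages cannot be reproduced without the unreleased
raw genotypes; the tests assert the internal identities and ordinal
relations those publications imply (e.g. Zhejiang closer to CMU than
either is to Dalian, from the seven-locus frequency table).

## Degenerate inputs and numerical notes

Multi-allelic VCF records are rejected with a logged count (the panel
model is biallelic); `split_multiallelic` opts into per-ALT splitting
where genotypes are not needed. Unavailable site metrics fail QC
conservatively. Genotype calls are stored as sorted allele pairs;
"AG", "A/G" and "G|A" are one call, "./." and "NN" read as missing,
"./." written. BED export is 0-based half-open with intervals clamped at
0 (warning); panel TSV and VCF are 1-based. Frequencies are exact
rationals of small integers in float arithmetic; comparisons that must
be exact (QC boundaries, r² = 1 linkage, frequency bounds) use direct
integer-derived values rather than tolerances. The amplicon ROI
half-width defaults to 130 bp (260 bp window), matching the upper end of
the 160–260 bp amplicon design range.

Problem sizes in the test suite (a few hundred to a few thousand loci,
up to 400 diploids) were chosen so that Monte-Carlo checks have
comfortable margins — e.g. heterozygosity to ±0.02 of its HWE
expectation, zero-divergence Nei distance below 0.005 where the
finite-sample bias is O(pq/n) ≈ 1e-3 — while the whole suite stays
interactive.
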