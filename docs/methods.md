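# Methods

This note records the models implemented in `lohqtl`, their assumptions,
the defaults that matter, and the choices made where the design was
genuinely open.

## Genome representation

A phased HetSNP map is a set of chromosomes (1-based inclusive bp
coordinates, physical length, centromere position, named loci) plus a
sorted list of marker positions. The two ancestral haplotypes are
labelled **M** and **P**; a gamete is a vector of per-marker origins and
a diploid is a vector of genotypes in {M/M, M/P, P/P}, coded 0/1/2 so
that the diploid code is the sum of the two gamete codes. There is no
nucleotide-level representation: haploid sequencing data enters only
through the allele-calling rule (call ALT when the alternative-allele
read frequency strictly exceeds 0.95; REF only when zero alternative
reads; NOCALL otherwise). The NOCALL branch exists for completeness of
the rule — the simulator never produces ambiguous calls.

Two loci are special. **MAT** (mating type, chromosome 3; default
position 200 kb) and **ACE2** (chromosome 12; default 520 kb, where the
*ace2-A7* frameshift allele causes cell aggregation) drive spore
selection, so markers within ±50 kb of MAT and ±75 kb of ACE2 are
excluded before QTL scanning (closed intervals; both windows
configurable). The allele-to-haplotype assignment (M carries MATa and
*ace2-A7*; P carries MATα and *ACE2*) is an arbitrary package
convention — phase labels themselves are arbitrary.

## Synthetic map generator

The generator emulates a partially eroded hybrid genome: ~12,023
markers over 16 chromosomes with approximately real *S. cerevisiae*
lengths (total ~12.07 Mb), with markers confined to "heterozygous
blocks" covering ~60% of the genome (`target_het_genome_fraction`).
Block and gap lengths alternate as lognormal draws (mean block 40 kb,
σ = 0.6 on the log scale, gap mean set so expected coverage hits the
target); marker positions are uniform within blocks. Neither the
block-length distribution nor the within-block density is constrained
by data — these are the simplest choices that reproduce the coverage
target, and the realized layout is stored on the map
(`map.blocks`, `map.block_fraction`) so tests assert coverage exactly.

Three chromosomes get distinctive profiles mirroring the UPD study
chromosomes: chromosome 4 carries few markers (150) in a single central
cluster; chromosome 14 carries ~700 markers with one long (~30% of its
length) marker-free segment; chromosome 15 carries ~12% of all markers
scattered full-length. All counts are configurable; remaining markers
are distributed over the other chromosomes in proportion to length.
Generation is driven by NumPy's PCG64 generator; a fixed seed
reproduces the identical map on any platform.

## Meiosis and inbreeding

Each meiosis replicates both homologs of each chromosome into four
chromatids. The genome-wide crossover count is Poisson with mean 90
(the experimentally estimated per-meiosis count), allocated to
chromosomes in proportion to physical length; with the default
`obligate_chiasma` flag each chromosome receives at least one crossover,
avoiding whole-chromosome non-recombinant artifacts. Each crossover
picks one chromatid of each homolog uniformly and exchanges everything
distal to a uniform bp breakpoint. There is no crossover interference
and no gene conversion — the heterozygosity accounting the design rests
on ignores both, and without gene conversion 2:2 segregation at every
marker is structural, not statistical.

The four chromatids are dealt to the four spores by a uniform random
permutation, independently per chromosome. Whole chromatids travel
together, so linkage within a chromosome (including MAT and ACE2 to
their neighbouring markers — tracked exactly through the exchanges, not
read off a flanking marker) is physical. Across chromosomes the deal is
exchangeable; this is a deliberate idealization. A strictly physical
model would share one meiosis-I spindle partition across all
chromosomes, which couples each marker's segregation pattern to its
centromere distance and, on a karyotype with many short chromosomes,
pushes mean sib-mating heterozygosity retention to ~0.70. The classic
accounting the inbreeding design is built on — a random pair of
opposite-mating-type sibling spores retains exactly 2/3 of
heterozygosity at loci unlinked to MAT, an inter-tetrad pair 1/2, and
the MATα *ACE2* × MATa *ace2-A7* selection rejects 1/6 of tetrads —
holds exactly under exchangeable dealing, and those are the quantities
this package is built to reproduce and test.

The inbred collection follows the study design: simulate tetrads from
the fully heterozygous ancestor, keep the first 13 whose spore selection
succeeds (one MATα *ACE2* and one MATa *ace2-A7* spore each), and cross
every unordered tetrad pair {i, j}, i < j, as α(i) × a(j), giving
C(13,2) = 78 diploids with no intra-tetrad crosses. The orientation
rule is a convention; the design's combinatorics do not depend on it.

## Targeted UPD and the counter-selection screen

`apply_upd` sets every marker of one chromosome to M/M or P/P and
touches nothing else (idempotent by construction). The screen model
reflects what the wet assays can see: PCR-RFLP genotypes at three
markers (left-arm distal, centromere-proximal, right-arm distal) and a
tetrad-viability test. Counter-selected clones come in four mechanistic
classes — cassette point mutation (markers heterozygous, 4:0 viable),
interstitial LOH (tract anchored over the centromere-adjacent cassette,
exponential arm lengths with configurable mean, truncated to never span
both telomeres; 4:0), monosomy (hemizygous alleles read "homozygous";
2:2), and true UPD (all homozygous; 4:0). The decision tree rejects on
markers, then on viability, then accepts. Its one structural blind spot
is an LOH tract long enough to cover all three markers, which is
indistinguishable from UPD by these assays; tests assert that accepted
clones are exactly the UPD class plus such tracts. Class mixture
proportions in simulated populations are caller-chosen (no rates are
reported for the real screen).

## Serial-transfer competition

Batch growth between 1%-transfers is collapsed into *g* generations per
cycle. Both competitors regrow from the bottleneck to a shared
saturation, so the default is g = log₂(D) = log₂(100) ≈ 6.64; g is
exposed because the "~3% division-rate difference" back-calculation for
strains reaching 90%/10% by cycle 8 is only consistent with g ≈ 10
(`required_s(0.9, 8)` returns 0.042 at g = 6.64 and 0.028 at g = 10 —
both conventions are documented rather than guessing intent). The
deterministic core is exactly multiplicative,
odds₍c₊₁₎ = odds_c · (1+s)^g, from an initial 50:50 inoculum.
Measurement noise is binomial over 10,000 gated flow-cytometry events
with a symmetric misclassification rate (default 0.002) absorbing
gating imperfections; transfer-bottleneck drift is negligible at ~10⁷
cells per 1% transfer and is not simulated. `estimate_selection`
regresses ln(odds) on cycle over all replicate readings strictly inside
(0,1), after inverting the known misclassification
(f = (f_obs − m)/(1 − 2m)), and returns ŝ = exp(slope/g) − 1 with the
SE propagated from the slope. The long-control model adds rare
beneficial lineages (per-cycle emergence probability, seed fraction
10⁻⁴, advantage `mutant_s`) to reproduce the rationale for trusting
only the first 8 cycles. For QTL mapping the phenotype is the cycle-5
mean fraction, where the trajectory is steepest before extreme ratios
plateau.

## Phenotype model

Each planted QTL contributes a·x + d·z to a latent trait, with
x = −1/0/+1 for P/P, M/P, M/M and z = 1 for heterozygotes, plus
Gaussian residual noise (SD 1 by default). Heat tolerance is an ordinal
0–5 colony-size score obtained by thresholding the liability at five
cutpoints (−2.0, −1.2, −0.525, 0.525, 1.2), placed so ~40% of a null
population scores 3 — matching the share of inbreds that scored like
the parent; any monotone link would do, and thresholding is the
simplest testable one. Scores are summarized as the median over three
replicates with SE(median) = √(π/2) × SE(mean) ≈ 1.253 × SE(mean).
Competition latent values map to a per-generation selection coefficient
by a bounded identity link (0.01 per latent unit, clipped inside
±0.2).

## QTL scan

With fully observed dense genotypes, Haley–Knott regression at a marker
degenerates to ordinary least squares on (x, z) — equivalently the
three genotype-class means — so the scan computes, per marker,
LOD = (n/2)·log₁₀(RSS₀/RSS₁) with RSS₀ from the intercept-only model.
Markers with fewer than two genotype classes in the sample are flagged
and excluded from both the scan and the permutation maxima. A constant
phenotype yields LOD 0 everywhere; an exact fit is reported as +inf
with a warning. The favored allele at a marker is the haplotype of the
homozygous class with the higher mean phenotype.

Genome-wide significance: each permutation run shuffles the phenotype
10,000 times (genotypes fixed, preserving the LD structure), records
the maximum LOD over scanned markers, and takes the 95th percentile by
the nearest-rank convention; the reported threshold is the median of
five runs. (Interpolating percentile conventions differ negligibly at
10,000 iterations.) For a single fully informative marker the threshold
has a closed form via F(2, n−3), used as an independent oracle in the
tests (~1.35 at n = 78). Regions are maximal runs of consecutive
above-threshold scanned markers on one chromosome (ties at the peak
break leftmost); a `gap` option can bridge isolated sub-threshold
markers but defaults to strict runs. Inheritance at a region peak is
classified from Tukey HSD pairwise comparisons at α = 0.05:
overdominant if the heterozygote mean lies strictly outside the
homozygote range and differs significantly from both; dominant if the
two homozygotes differ while the heterozygote is indistinguishable from
exactly one of them; additive otherwise. PVE is 100·R² of the
genotype-class model; relative PVE normalizes to the largest locus;
multi-locus PVE uses forward selection over region peaks ordered by
single-locus LOD, retaining loci whose partial F-test has p < 0.01.
The optional 2-D scan fits, for marker pairs on distinct chromosomes of
a decimated grid, the full nine-cell two-locus model against the
additive pair model; the interaction LOD has a null mean of
df/(2 ln 10) ≈ 0.9, not zero, at finite n.

## Pipeline and reproducibility

`run_pipeline` derives one generator per stage (map, meiosis, QTL
truth, phenotype, competition, scan) from the global seed via
`SeedSequence.spawn` in a fixed order, so re-running one stage never
perturbs another's randomness and identical config + seed gives
byte-identical outputs. Every TSV carries a provenance comment
(version, seed, config hash); the run summary is deterministic JSON.

## What the synthetic data does and does not emulate

The generator reproduces the *scale and structure* of the data such an
experiment yields:
marker counts and their chromosomal layout, the 60% heterozygous-block
coverage, the 13-tetrad/78-strain design, score distributions centred
like the parent's, and co-culture trajectories with realistic
measurement noise. It does not reproduce the real strain's marker
coordinates, its allele effects, epistatic architecture or any
region-level result (which depend on genotype/phenotype tables not
modelled here); passing tests therefore validate the machinery and the
design arithmetic, not biological conclusions about any particular
strain. Gene conversion, crossover interference, spore inviability,
aneuploidy and mitotic LOH during propagation are all outside the
meiosis model; the competition model has no mechanistic nutrient
dynamics.

## Problem sizes used by the test suite

Chosen as a balance between Monte-Carlo precision and a small compute
footprint: retention statistics use the full ~12,000-marker map with
1,000 sib-mating tetrads, 500 inter-tetrad pairs, 500 two-round
lineages, and 20 independent 78-strain collections; scan benchmarks use
a 600-marker map with 50 collections × 1,000-iteration permutation
runs. The planted-QTL recovery benchmark constructs each phenotype so
the planted locus' realized in-sample PVE is exactly 25% (residual
noise orthogonalized to the marker's genotype classes, then scaled):
with 78 strains from 13 founder tetrads, the realized PVE of an
expectation-calibrated effect fluctuates by ~8 percentage points, and
the benchmark is meant to exercise the scan-threshold-region chain, not
that finite-sample fluctuation. `scripts/acceptance.py` uses 1,000
tetrads (t2), 1,000 independent tetrad pairs (t3), 500 lineages (t4)
and 20 collections (t5).
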