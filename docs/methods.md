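# Methods

## Study design being emulated

The pipeline reproduces, at desk scale, a combined expression study of
temperature-dependent growth abnormalities in triploid wheat hybrids: a
wild-type synthetic hexaploid line and a *Net2*-carrying line that shows
type II necrosis at low temperature and grass-clump dwarfism at normal
temperature.  The small-RNA arm uses four unreplicated libraries (2
genotypes × 2 temperatures, 24 °C and 4 °C) from crown tissue; the mRNA arm
uses two-replicate single-channel microarrays comparing abnormal lines to
the wild type.  All inputs are generated synthetically with recorded ground
truth; nothing in the package downloads or re-analyzes the original
deposits.

## Synthetic-data generator

`SimConfig` fixes the study conditions.  Defaults: two 100 kb chromosomes
("A" and "D", a desk-scale echo of the A- and D-genome references), 12
known + 8 novel miRNA loci, 8 decoy ncRNAs in three families (rRNA-, tRNA-,
snoRNA-like; the Rfam stand-in), 20 tandem-repeat tracts from four unit
families (the Repbase stand-in), and 50,000 reads per library.

**Hairpin design.**  Each locus is mature + loop (12–24 nt) + reverse
complement of the mature carrying 1–2 planted stem mismatches.  At least
one mismatch is mandatory: a perfect inverted repeat would let the mature
read align exactly to the star site on the opposite strand, creating a
mirror locus that no exact-match aligner can distinguish — real
miRNA/miRNA\* duplexes are imperfect anyway.  Sequences are resampled until
the designed duplex structure scores ≤ −27 kcal/mol under the folding
model, a ≥ 5 kcal/mol margin below the −20 discovery gate, so gate
decisions are robust to the exact energy parameterization.  Features are
placed with ≥ 100 nt spacing so planted loci never share a read cluster.

**Reads.**  Library composition: ~55% miRNA reads (mature:star 9:1), 12%
decoy fragments, 12% repeat fragments, 13% random genome fragments
(uniform length 16–32 nt so the 18–30 filter has work to do), 5% stop-oligo
contaminants, 3% reads from two catalog miRNAs absent from the genome
(exercising the rescue path).  Counts are multinomial at the configured
depth.  Mature/star reads are emitted at truth coordinates with probability
0.8, else jittered ±1 nt at one end (isomiR noise, still an exact genome
substring).  The full 3' adapter is appended to every read; a flag reserved
for partial adapters is off by default.  Dummy FASTQ quality is "I".

**Expression model.**  Per-locus base abundance is log-normal (clipped to
[0.3, 8]); a shared log-normal 4 °C/24 °C response ratio models temperature
responsiveness.  A configured 30% of loci are differentially responsive
between genotypes with planted statistic S = R_wt/R_mut of 8 (alternating
direction).  Because library proportions are compositional, realized S
deviates from 8 by a common per-line factor; the planted 8-fold margin over
the 3-fold screen threshold absorbs this.

**Arrays, Ct tables, annotation.**  Microarray intensities are log-normal
(log₂ base N(10, 1.2)) with per-measurement log₂ noise of SD 0.1 and 10%
planted 8-fold probes, half up, half down — the study's own contrasts call
13–15% of probes differential, so 10% is the realistic default.  The paired
3-group simulation (one reference line, two abnormal lines) shares half of
the planted probes between the two contrasts, giving overlapping Venn sets
and positive cross-contrast correlation.  Ct tables carry planted relative
expression as ΔCt offsets against an actin-like control with 3 technical
replicates (SD 0.05 cycles).  The GO-style map is a 3-level DAG (1 root, 5
mid, 30 leaf terms), base annotation probability 0.08; planted enrichment
multiplies the annotation odds by 10 for test-set genes on 3 leaves.

**What the generator does not model** (hence what passing tests do not
show): sequencing errors beyond end jitter, quality scores, homoeologous
subgenome copies, expression-dependent GC bias, partial adapters, and any
real-genome repeat structure.  Recovery results on this generator
demonstrate the machinery is correct, not that it would achieve the same
sensitivity on the original genome-scale data.

## Preprocessing

Fixed cascade: stop-oligo removal (substring match) → exact adapter
trimming (leftmost ≥ 6 nt adapter-prefix match, or any shorter prefix that
runs off the read end; reads without an adapter are discarded since insert
size is unknown) → deduplication to unique sequences with counts → decoy
filter → 18–30 nt length filter → exact alignment.  The decoy rule mimics a
short-query BLASTn screen: remove a read when its best-scoring plus-strand
local alignment (match +1, mismatch −2, gap −2; Biopython PairwiseAligner)
to any decoy has identity ≥ 0.90 over columns spanning ≥ 0.90 of the read
length.  A score bound skips hopeless pairs: any alignment passing both
gates scores ≥ (0.9 − 2·0.1)·0.9·L = 0.63·L.  Alignment is exact-match,
both strands, all occurrences; hard-masked (N) positions never match.

## Folding model

A structure is a set of nested AU/GC/GU pairs with hairpin loops ≥ 3 nt.
Energy is the sum of stack terms over adjacent pairs (GC/GC −3.3, AU/AU
−0.9, GU/GU −0.5 kcal/mol; mixed stacks are the mean of the two homogeneous
values), +4.0 per hairpin loop, +3.0 per bulge or internal loop, 0 per
multibranch loop (the model prices no loop-length terms), 0 for external
bases.  `fold_mfe` is an exact Zuker-style dynamic program over this model;
because the internal-loop penalty is length-independent, interior loops
reduce to a running minimum and the DP is O(n³).  Energies are exact
multiples of 0.05 kcal/mol, so the DP runs on integers with the pair count
packed into the state, breaking ties toward fewer pairs exactly; remaining
ties resolve by a fixed traceback order preferring earlier-opening pairs.
The empty structure is always admissible, so reported MFE ≤ 0.  The energy
table is replaceable (TSV) for cross-checks against richer parameter sets.

This is a gating model, not ensemble thermodynamics: it has no entropic
destabilization, so arbitrary few-hundred-nt windows fold far below zero.
That motivates a design choice in discovery (below).

## miRNA discovery

Alignments pooled over the four libraries are clustered per
chromosome/strand with a 50 nt gap; only hits with library-level read count
≥ 2 seed or bound clusters (`min_read_count`), because at desk-scale depth
unique background fragments tile the genome and would otherwise chain
unrelated loci into one cluster.  All reads still count in quantification.

Each cluster's highest-count read is the anchor (mature candidate); gates
follow the mireap parameter set: anchor length 18–26 nt, star search within
400 nt on either side, duplex bulge ≤ 3, 20 nt flanks, precursor energy
≤ −20 kcal/mol.  The star is found by scanning every antiparallel register
for complementarity; the duplex bulge is the count of unpairable positions
at the register.  The energy gate is evaluated on the hairpin structure the
duplex asserts over the precursor window (scored with the same energy
model), not on the window's unconstrained MFE: under a model without
entropic terms the free MFE of any window passes −20 trivially and tests
nothing hairpin-specific, while the unconstrained MFE is by definition at
least as low as the hairpin energy, so the "precursor MFE ≤ −20" contract
still holds a fortiori for every accepted locus (and is asserted with
`fold_mfe` as the oracle in the acceptance suite).  Rejections carry
machine-readable reasons: `length_gate`, `no_hairpin` (no register with at
most 6 unpairable positions), `bulge_gate` (best register above 3),
`energy_gate`.

A star arm is "observed" when a cluster read maps within ±2 nt of the
predicted star; star-less acceptance cannot occur since the star search
defines the hairpin.  The 2-nt 3' overhang is computed and logged, not
gated.  Known/novel classification and the unaligned-read rescue both use
the decoy-filter identity rule (≥ 90% identity over ≥ 90% of the query)
against the mature catalog, ties broken by identity then catalog order.
Multi-mapping reads count at every matching locus and flag the locus
non-unique; a uniqueness column lets users switch to unique-only counting.

## Expression statistics

Per-array normalization drops the ⌈0.02·n⌉ largest and smallest values,
then scales by 2500/trimmed-mean; the post-condition (trimmed mean exactly
2500, idempotence) is asserted in tests.  DE calls: fold change is the
ratio of group means on the normalized linear scale (a mean-of-ratios flag
exists); the two-sided equal-variance Student *t* runs on log₂(x+1) for
variance stabilization (raw-scale flag available); BH adjustment is an
in-package step-up cross-checked against statsmodels; a probe is `up` iff
fold ≥ 3 and q < 0.05, `down` iff fold ≤ 1/3 and q < 0.05.  With n = 2 the
*t* test is conservative and erratic; the null-calibration suite therefore
asserts a seeds-with-any-false-call fraction ≤ 0.10 rather than a nominal
FDR.  Venn regions use inclusion–exclusion over 2–3 sets.  Cross-contrast
correlation is Pearson on per-probe log₂ intensity-difference vectors.
Clustering is UPGMA (scipy average linkage) on 1 − Pearson distance over
per-replicate log₂ ratios of the DE-probe union, cut to k = 6; constant
profiles are dropped with a warning; the dendrogram serializes to Newick.

The responsiveness screen normalizes each library to counts per million,
adds a pseudocount of 1 (both choices are unstated in the emulated design
and config-exposed), forms R = (CPM at 4 °C + 1)/(CPM at 24 °C + 1) per
genotype and S = R_wt/R_mut, and selects S > 3 or S < 1/3; the scatter-plot
flag at 2-fold is a separate parameter.  ΔΔCt quantification averages
technical replicates, takes ΔCt against the control gene and ΔΔCt against
the calibrator sample, returning 2^−ΔΔCt (calibrator = 1 by construction).

## Enrichment and target prediction

Per term, the 2×2 table (in-term/not × test/rest-of-reference) is tested
with the two-sided Fisher exact test (scipy's minimum-likelihood rule,
verified against full hypergeometric enumeration in tests), BH-adjusted
across terms, significant at q < 0.05.  The reference set is the whole
probe universe.  Up/down sets can be tested separately or pooled.  Term
rollup maps each term to its ancestors at the requested depth (shortest
path from a root, root = 1) in a parent DAG; cycles raise.

Target expectation is the minimal alignment penalty under a
psRNATarget-style V2 scheme: mismatch 1, G:U 0.5, gap 2, all doubled at
miRNA positions 2–13, at most 2 gaps; every constant is in
`TargetScanParams`.  `score_duplex` is an exact (i, j, gaps) DP; `scan`
anchors candidate sites at the base pairing miRNA position 1, computes an
ungapped penalty profile over all anchors with numpy, and runs the full DP
only where the profile is within `max_expectation + (L − 13) + 2`: an
in-seed gap costs 4 (more than the cutoff of 2), and a non-seed gap leaves
at most an (L − 13)-nt mismatched tail at the anchor's ungapped register,
so no qualifying hit escapes; boundary gaps are equivalent to shifting the
anchor.  Overlapping hits of one miRNA on one transcript collapse to the
lowest expectation, ties 5'-most.  The predicted cleavage coordinate is the
transcript base opposite miRNA position 10; when position 10 itself is
gapped the coordinate falls back to the anchor-offset estimate.
Translation-inhibition classification and accessibility terms are out of
scope.

## Orchestration and reporting

`run_pipeline` executes the stages in order, writes each artifact
(FASTA/FASTQ/GFF3/TSV/Newick/JSON; GFF3 converts the package's internal
0-based half-open intervals to 1-based closed), and emits a manifest with
SHA-256 hashes, the seed and the package version; identical configurations
reproduce byte-identical artifacts (single-threaded, all randomness from
`numpy` generators keyed on (seed, stream)).  Percentages in the report are
100·count/total rounded half-away-from-zero to 2 decimals.  Every report
number is recomputable from the written artifacts, which the tests verify
on a reduced-scale run.  In-memory matrices are pandas DataFrames
throughout (feature × sample with group metadata carried by column naming);
no bespoke matrix container is introduced.

## Problem sizes

The acceptance suite and `scripts/acceptance.py` use the full default
configuration (2 × 100 kb genome, 4 × 50,000 reads, 2,000 probes × 2
contrasts), one DE-recovery array, 100–200 global-null array seeds and
30–50 null-annotation seeds; folding-oracle enumeration covers sequences up
to 22 nt and Fisher enumeration all tables with n ≤ 14 plus a seeded sample
with margins ≤ 30.  A full pipeline run takes well under a minute on one
CPU; the complete test suite a few minutes.

## Known limitations

* The folding model is a gating heuristic; absolute energies are not
  comparable to Turner-model values, and the −20 gate is only meaningful
  relative to this model (the generator's ≥ 5 kcal/mol design margin is
  what makes gate decisions model-robust).
* Discovery assumes the mature arm is the cluster's most abundant read;
  loci whose star out-expresses the mature would be reported with arms
  swapped.
* The screen statistic is compositional (CPM); strong global shifts in
  library composition bias S by a common factor.
* `classify_known` measures identity on the optimal-score local alignment;
  a sub-optimal-score alignment with higher identity (pathological cases)
  is not searched.
* No moderated variance estimation is used for n = 2 arrays by design; the
  equal-variance *t* matches the emulated analysis, at the cost of power.
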