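# Methods

## The experimental design being modelled

An ascus of *Neurospora*-like fungi holds eight spores: four meiotic
products, each doubled by one post-meiotic mitosis. Sequencing four
non-sister spores samples each meiotic product once. A mutation that arose
before meiosis (during the premeiotic mitoses or by RIP, which acts after
cell fusion but before nuclear fusion) is present on one parental
chromosome and therefore in exactly two of the four sampled spores (2:2 in
octad terms). A mutation arising during/after meiosis is carried by one
sampled spore (3:1). Comparing each spore against both sequenced parents
identifies de novo events; segregation then stages them.

## Synthetic-data generator

The simulator reproduces the statistical structure this analysis assumes,
at roughly 1/100 genome scale (default: 2 contigs × 200 kb vs the 40.46 Mb
reference). What it emulates:

* **Duplicate architecture.** TE-like duplicate pairs (mean 2030 bp,
  GC 0.374) and CDS-like pairs (mean 338 bp, GC 0.546) planted as
  copy/diverged-copy (default 8% substitution divergence, so pairwise
  identity ≈ 0.92, comfortably above the 65% detector threshold), totalling
  ≈ 16–17% of the genome. CDS-like duplicates are covered by the CDS track
  (target fraction 0.375); TE-like ones are not. One AT-rich (GC 0.30)
  centromere per contig. Copies are kept > 1 kb apart even after flank
  leak so a mutation cluster can never span two distinct copies.
* **RIP.** Per parent lineage and duplicate copy, an attack occurs with
  probability `rate × n_GC / run_mean`; an attacked copy receives one run:
  a geometric number (mean `rip_run_mean = 8`) of consecutive C sites on
  one strand (or G sites, i.e. the other strand) mutated to T (A),
  anchored at a random site, occasionally (p = 0.1) leaking into ±400 bp
  of flank. This makes `rip_rate_per_gc_site` the marginal per-G:C-site
  mutation probability per cycle while keeping the observed run structure:
  strand-exclusive, tightly spaced (nearest-neighbour distances of a few
  bp to tens of bp, qualitatively matching the "median 41 bp" style of
  clustering at full genome scale).
* **Scale choice for the default rate.** A 1/100-scale genome cannot
  simultaneously match the study's absolute per-genome mutation count and
  its per-duplicate-bp density. The default (`1e-3` per G:C site per
  cycle) preserves the *density* regime in which cluster statistics are
  informative: tens of mutations per haploid genome over ~66 kb of
  duplicate, so random re-placement over duplicate G:C sites does not
  saturate the 1 kb cluster definition. At the paper's genome size the
  same machinery runs unchanged with a correspondingly smaller rate.
* **Background processes.** Premeiotic mitotic mutations per parent at
  `rate_per_division × divisions` per bp (default 6.03e-10 × 300),
  uniform over the genome with a uniform 12-class spectrum (so the
  C→T + G→A share is ≈ 2/12 at balanced composition). Post-meiotic events
  per spore at `post_meiotic_rate` per bp, emitted as present in exactly
  1 of 4 sampled spores.
* **Meiosis.** Parental SNPs at 0.5% (the sequenced crosses span 0.01–
  1.06%); per contig a Poisson(0.3) number of crossovers exchanges one
  chromatid between the two parental pairs, so every position is carried
  by exactly two spores per parent. 0.3 reflects that a 200 kb contig is
  a ~1/30-scale chromosome; it also keeps crossovers inside duplicate
  copies (which can legitimately mix a C-run and a G-run in one spore)
  rare.
* **Read depth.** Independent per-site negative binomial (spores mean 37,
  parents 76, dispersion 8) with `low_coverage_fraction` of each sample in
  ~2 kb Poisson(2)-depth patches — the false-negative mechanism. Call
  quality is a deterministic function of depth (20 + 4·depth) so the
  depth-5 and quality-30 filters are aligned; `depth_floor` lets tests
  construct loss-free datasets. Optional noise injects haploid
  "heterozygous" artifact calls inside duplicates and low-quality calls.

What it does **not** emulate: read-level errors and alignment (no FASTQ),
indels/structural variants, selection, GC-biased repair, context-dependent
mutation (trinucleotide structure), or a realistic recombination map.
Passing tests therefore demonstrate the *pipeline's* correctness and
calibration under the assumed generative structure, not robustness to
alignment artifacts in real data.

## Mutation identification

Filters mirror standard haploid trio practice: calls must be homozygous
(haploid samples; heterozygous calls are a mis-mapping signature), quality
≥ 30, depth ≥ 5 in the focal spore and ≥ 5 in both parents at the site, and
the allele must differ from both parents (parental allele = parental call
if present, else reference). Manual inspection of candidates is replaced by
a reproducible heuristic: sites within 3 bp of a reference homopolymer run
≥ 6 bp are rejected. Classification requires the state of all four spores:
carriers are spores with a passing call; every non-carrier must be covered
(depth ≥ 5) and free of a conflicting failed call, otherwise the event is
held "unresolvable" and excluded from rate numerators — the FNR
normalization accounts for exactly this coverage loss. Carrier counts of 2
map to 2:2; 1 or 3 map to 3:1 (3-of-4 patterns are labelled 3:1 but kept
distinguishable via the stored carrier set); 0 or 4 are rejected as
parental-call failures. Parent of origin comes from the nearest flanking
parental SNPs within 50 kb (at 0.5% SNP density a flanking SNP is
near-certain); discordant flanks or carriers — e.g. a recombination
breakpoint — give "unassigned".

## Duplicate detectors

*Dup-Blast* is a native all-vs-self seed-and-extend aligner: 11-mer seeds
bucketed by diagonal, chained within 150 bp, extended ungapped with X-drop
25, identity = matches/length; hits of ≥ 100 bp at > 65% identity
contribute both copies' intervals, merged per contig. Exact coordinates may
differ from NCBI BLAST at region edges; the thresholds are what matters and
the simulated-truth recovery requirement (≥ 95% of duplicate bases at pair
identity ≥ 0.8) pins the behaviour. Ungapped extension suffices because
substitution divergence dominates between young duplicate copies; a gapped
aligner would shift edges, not calls.

*Dup-Depth* takes windows whose median depth falls in [1.75, 2.5]× the
genome-wide median ("2× on average"); *Dup-Het* pads (±500 bp) and merges
runs of ≥ 2 heterozygous calls within 1 kb in any haploid sample;
*Dup-Period* is an operationalization of homology-sensing periodicity: a
window is reported when offsets between successive occurrences of the same
3-mer (capped at 50 bp) are dominated (> 0.5) by the 10–12 bp band, unless
the window is already Dup-Blast-covered. The precise published matching-
period statistic is not specified anywhere we could implement from; this
definition is declared, not inferred, and is exercised by constructed
periodic sequences in the tests.

Site classes use merged Dup-Blast regions with a 400 bp flank: within >
near > non. The efficiency table reports, per method and for the union,
% genome covered vs % of 2:2 mutations enclosed; the union's complement is
the most conservative "non-duplicate by any definition" class.

## Rates and false negatives

FNR is estimated per ascus and per region class by spike-in: synthetic 2:2
(default 5000) and 3:1 (1000) sites drawn uniformly, carriers drawn at
random, injected as homozygous calls whose depth is the carrier's actual
local depth, then pushed through the identical filter + classification
code; FNR = 1 − recovered/generated. Counts are normalized as
raw/(1 − FNR) per ascus before averaging; means over asci divide by the 2
source parents unless counts are already parent-assigned (a parent-origin-
restricted count is a per-genome quantity as-is). Per-bp rates divide by
the regional base counts. When a region class yields no or degenerate
spike-in data (FNR undefined or 1), no correction is applied for that cell
rather than producing an infinite count. In the package's own calibration
experiment the spike-in recovery and the realized recovery of true events
agree to within sampling error, and the corrected estimate recovers a
configured rate within 3 SEM over 20 asci where the uncorrected one is
biased low by the induced coverage loss. The recovery experiment is run
with RIP off and the mitotic rate raised to 2e-5/bp/cycle so the target has
a closed-form expectation and the 20-ascus study has adequate counts at
1/100 genome scale; spike-in sizes of 2500/200 per ascus keep the
per-(ascus, region) FNR tight, since 1/(1 − FNR) is convex and a noisy FNR
would bias the correction upward.

RIP attribution is (rate_proficient − rate_deficient)/rate_total on a
common scale; the asexual variant extrapolates a per-day rate over a
20-day sexual cycle (15 divisions/day for per-division conversions). Yates-
corrected chi-squared implements the 2×2 shortcut n(|ad−bc|−n/2)²/(R₁R₂C₁C₂)
and the cell-wise |O−E|−0.5 goodness-of-fit form (correction clipped at
zero); scipy's corrected `chi2_contingency` is used in tests as an
independent oracle only.

## Cluster statistics and randomization

Clusters are single-linkage chains of ≥ 2 mutations with adjacent gaps
≤ 1 kb within one haploid genome (chaining resolves the pairwise ambiguity
of "within 1 kb" for runs; observed RIP tracks are contiguous). Strand
class is C_run/G_run/mixed by member changes. The permutation null
re-places each haploid genome's mutations uniformly without replacement
over the G:C sites of the duplicate regions (per-spore counts preserved)
and re-counts clustered mutations (the count of mutations in clusters; the
"number of clusters" statistic is available as an option); the overlap
null re-places cluster intervals uniformly within same-contig duplicate
regions, lengths preserved, and counts mutations in clusters overlapping a
different spore's cluster. Both report p = (n+1)/(m+1), are seeded, and
log m and n. The permutation null is validated against exhaustive
enumeration on a 10-site toy genome.

## Ne and the drift-barrier critique

N<sub>e</sub> = π/(μ·D·(1−π)), D = 2 for haploids, 4 for diploids. Because
μ enters the denominator, regressing log μ (or the μ-derived CDS mutation
count) on log N<sub>e</sub> is partially circular; the critique permutes π
among taxa (optionally holding one taxon fixed), recomputes N<sub>e</sub>,
and reports the fraction of randomizations with negative / significantly
negative (t-approximation at 0.05) correlation and the extremity
p = (n+1)/(m+1) of the observed slope. Axes are log10 (the relationships
are displayed log-log); Pearson on logs is the primary correlation with
Spearman alongside. With constant π and D the construction forces
Spearman(μ, N<sub>e</sub>) = −1 exactly — the tautology the critique
exposes. A synthetic lognormal taxa table ships for exercising the
machinery; the published cross-taxa compendium loads through the same TSV
reader when available.

## Numerical and design notes

* Coordinates are 0-based half-open internally; VCF positions are 1-based
  at the boundary; BED stays 0-based half-open.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` seed sequences (`[seed, stream, unit]`), so
  every simulation, spike-in and randomization is reproducible and
  byte-identical across runs; fixed seed implies byte-identical FASTA/VCF.
* Degenerate inputs: empty event sets give NaN fractions (not zero);
  zero-denominator RIP-index ratios are NaN and the verdict falls to the
  other criterion; a genome-wide median depth of zero, duplicate regions
  without G:C sites, clusters that fit in no duplicate region, and
  out-of-genome positions raise errors naming the constraint.
* Problem sizes used by the shipped studies — 120–400 kb genomes, 2–20
  asci, m = 1000 randomizations, 2500/200 spike-in sites per ascus — were
  chosen so each study resolves its target quantity (3 SEM rate recovery,
  p-floor discrimination, binomial spectrum error) at interactive runtimes.
* Known limitations: the generator's qual model is depth-deterministic, so
  quality and depth filters are not independently stressed; Dup-Period is
  an operationalization (above); the overlap-shuffle statistic counts
  mutations in cross-spore overlapping clusters, which is one of several
  defensible readings of "overlap"; per-ascus FNR correction is slightly
  convexity-biased for small spike-in sizes (quantified above and
  mitigated by larger spike-ins).
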