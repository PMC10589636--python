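# Methods

`mutscenarios` re-implements, as a tested pipeline, a multi-variant-class
mutational-signature analysis for tumor whole-genome cohorts: mutation
catalogs and signature inference for SNVs, indels and structural variants
(SVs); copy-number states and rearrangement topography (kataegis, clustered
rearrangements, chromothripsis filters); subclonal exposure trajectories;
and an unsupervised stratification of patients into "mutational scenarios".
Everything runs end to end on synthetic cohorts with known ground truth; no
external data or download is required.

## Coordinate conventions

All interval types (CNA segments, genes, arms, complex-event intervals) are
0-based half-open; point variants (SNVs, indels, SV breakpoints) are stored
1-based following VCF. Conversions live only in the readers and writers.
Chromosome names are normalized against the reference index by adding or
stripping a `chr` prefix.

## Consensus SV calling

Per-caller call sets (BEDPE or VCF-BND) are merged by collapsing breakpoint
pairs that agree in SV class and chromosomes with both breakpoints within
500 bp (inclusive). Matching components are built jointly across callers,
so chains (A~B, B~C) collapse into one component; a component is emitted
when it spans at least 2 distinct callers and contains at least one record
that passed its caller's filters. Insertions are exempt from the
multi-caller rule for one designated caller (default `svaba`), because only
that caller reports them reliably. Representative coordinates come from the
first passing record under a deterministic (caller, position) order — a
package choice, since no convention exists for which caller's coordinates a
merged record should carry.

Cohort QC iteratively flags samples whose SV count exceeds 5x the median SV
count of the retained samples, recomputing the median after each removal.

## Mutation catalogs

* **SBS-96** — single-base substitutions by pyrimidine-normalized
  substitution type and flanking trinucleotide (purine reference bases are
  reverse-complemented together with their context).
* **ID-83** — the COSMIC v3 indel scheme: 1-bp deletions/insertions of C/T
  by homopolymer length (deletions 1..6+, insertions 0..5+ existing
  copies), longer events by length (2,3,4,5+) x repeat-unit count, and
  microhomology deletions by deletion length x homology length. Repeat
  counting runs in both directions on the + strand; an event that is a
  whole-number multiple of a flanking repeat takes the repeat channel, and
  microhomology applies only to >=2-bp deletions that are not
  repeat-mediated (COSMIC precedence). 1-bp purine events are complemented
  to C/T.
* **SV-38** — DEL/DUP/INV x six size bins (<1 kb, 1–10 kb, 10–100 kb,
  100 kb–1 Mb, 1–10 Mb, >10 Mb; half-open with inclusive lower edges) x
  clustered status, plus translocations x clustered status. A breakpoint is
  clustered when some 1 Mb window containing it holds >=10 of the sample's
  breakpoints (sliding, translation-invariant; a translocation contributes
  one breakpoint to each chromosome); an SV is clustered if either
  breakpoint is. Insertions are excluded from the catalog with a logged
  count.

## Signature inference

De novo extraction follows the iterated-NMF stability recipe: per
iteration, each sample's channel counts are bootstrap-resampled from a
multinomial; the resampled catalog is factorized under the generalized
Kullback–Leibler objective with multiplicative updates from random
non-negative initialization (the objective is asserted non-increasing every
10 updates); the pooled signature vectors across iterations are clustered
by cosine distance (k-means on L2-normalized vectors) and each cluster's
renormalized mean is the consensus signature. The factorization rank is the
candidate with the highest mean silhouette (ties toward the smaller rank);
the cophenetic correlation of the pooled vectors is reported alongside.
The production default is 500 iterations with rank candidates {4, 5, 6}
for SBS; tests and the acceptance study use 10–100 iterations, which is
sufficient for the planted-recovery problems they pose.

Matching against a reference catalog is a greedy one-to-one assignment in
descending cosine similarity with an acceptance threshold of 0.85;
de novo signatures below the threshold are reported as novel.

Supervised exposure fitting is per-sample non-negative least squares
(`min ||counts − W e||₂, e >= 0`), the linear-combination-decomposition
equivalent. Optional per-signature relative-exposure cutoffs zero
signatures below their floor and refit to a fixed point (cutoffs default to
zero; the published cutoff table is not redistributed). A cohort-level
filter drops signatures carrying less than 5% of the cohort's total
mutation count and refits the remainder.

## Copy-number topography

Segment states come from `log2((cn_major + cn_minor)/ploidy)`: gain above
+0.3 (strict), loss below −0.3 (strict, mirroring the printed strict gain),
homozygous deletion at total 0, amplification above 1.25 combined with the
canonical total-copy-number rule ((ploidy <= 2.7 and total >= 5) or
(ploidy > 2.7 and total >= 9)). LOH (minor allele 0, total >= 1) is an
orthogonal flag. Arm events require a single gain/loss segment whose
intersection covers >=60% of the arm; coverage does not accumulate across
segments (the stricter of the two readings of the published rule; the
whole-segment-inside-arm variant is selectable). The HRD-LOH index counts
merged LOH runs longer than 15 Mb that do not span a whole chromosome.
The six-feature HRD probability (microhomology-deletion proportion, three
SBS exposures, one SV exposure, HRD-LOH) feeds a standardized logistic
model whose weights are configuration; the shipped zero-weight default is a
structural placeholder for testing, not the published model.

## Rearrangement topography

Kataegis: per chromosome, maximal runs of >=6 consecutive SNVs with every
inter-mutation distance strictly below 1 kb, regardless of substitution
class. Clustered rearrangements: regions where a 10 Mb window holds >=10
consensus-SV breakpoints (qualifying windows merged); regions overlapping
any known complex event of the same sample are removed. Chromothripsis
candidates per chromosome need >=6 interleaved intrachromosomal SVs
(largest connected set of partially overlapping, non-nested intervals) and
>=7 contiguous segments oscillating between exactly two total-CN values;
high confidence additionally requires a fragment-join chi-square consistent
with equal class proportions and either a non-significant
Kolmogorov–Smirnov test of inter-breakpoint distances against a fitted
exponential or significant chromosomal enrichment (alpha 0.05). The
published tool distinguishes four join classes including the two inversion
orientations; the breakpoint-pair schema here carries no orientation, so
the chi-square runs over DEL/DUP/INV. Low-confidence candidates overlapping
amplified segments are flagged for review, never silently accepted.

Complex events from external reconstruction tools (ecDNA, BFB, CnC,
chromoplexy, TIC, rigma, pyrgo) enter through a TSV adapter; their
reconstruction is out of scope. Same-sample events with reciprocal interval
overlap >=0.5 (not quantified in the source, configurable) collapse to the
most informative class under the fixed precedence ecDNA > BFB >
chromothripsis > CnC > chromoplexy > TIC > rigma > pyrgo > clustered.

## Subclonal trajectories

Mutations with a cancer cell fraction (CCF) are sorted by descending CCF
and split into equal-count bins (default 10 bins of >=50 mutations,
degrading gracefully); exposures are refit per bin with all cutoffs zeroed,
and the highest- vs lowest-CCF endpoints per signature support
clonal-vs-subclonal contrasts. This replaces changepoint-based trajectory
segmentation with fixed binning — the endpoint comparison, which is the
quantity actually tested downstream, is preserved; within-trajectory
changepoint locations are not reproduced. A standard VAF-to-CCF helper
(`ccf = vaf (purity·cn_total + 2(1−purity))/purity`, capped at 1) supports
the synthetic path; no CCF estimation is performed on real inputs.

## Mutational scenarios

The feature table joins per-scheme relative signature exposures with
per-class complex-event counts (counts, not booleans, since event frequency
is the stated feature; boolean encoding is available). Metadata (risk
group, driver-gene status, arm events) never enters. Features are z-scaled;
constant features are dropped with a log.

Clustering is the hybrid hierarchical/k-means procedure: Ward linkage on
Euclidean distances cut at k initializes Lloyd's k-means (tol 1e-6, max 300
iterations) — deterministic given the input order. The number of clusters
is assessed with the gap statistic: B=50 uniform reference draws, and the
first-SE rule (smallest k with gap(k) >= gap(k+1) − s(k+1)). The reference
is drawn uniformly in the PCA-rotated bounding box of the data (the default
of the canonical R implementation). This choice matters: the exposure
blocks are compositional (each scheme's relative exposures sum to 1), so
within-cluster variation is rank-deficient; an axis-aligned full-rank
uniform reference then keeps gaining log-dispersion faster than the data at
every k and the first-SE rule over-selects. The plain bounding-box
reference remains available (`reference="original"`).

Defining features of a cluster are scaled centroid components with
magnitude >=0.3, signed enriched/depleted. Concordance maps each cluster to
its majority clinical label and reports the fraction of labelled samples
matching. Co-occurrence uses pairwise Spearman correlation with
Benjamini–Hochberg control at alpha 0.05; group contrasts use
Kruskal–Wallis plus pairwise Wilcoxon rank-sum tests (exact when both
groups have <=25 observations without ties, normal approximation with tie
correction otherwise).

## Synthetic cohorts

The generator produces everything the pipeline consumes, with ground truth
sufficient to score every recovery test.

* **Reference genome** — default 8 chromosomes (7 of 2–5 Mb plus one 12 Mb
  chromosome so the 10 Mb window logic is exercised), random sequence with
  planted homopolymers (runs 4–9) and tandem repeats (units 2–5, 2–6
  copies) at 0.5 and 0.2 events/kb, so every indel channel family is
  reachable.
* **SNVs** — per sample, channel counts are multinomial draws from the
  planted signature mixture; each draw lands on a uniformly chosen
  reference position with the matching trinucleotide context (channels
  sharing a context draw jointly without replacement, so positions are
  unique per sample). Reclassification reproduces the drawn channel counts
  exactly.
* **Indels** — candidate indels are rejection-sampled from the genome,
  classified, and pooled per ID-83 channel; per-sample channel counts are
  drawn from the planted exposure mix and realized from the pools. A
  requested channel with no eligible site is a parameter error.
* **SVs** — background SVs are drawn as SV-38 channels from a planted
  mixture of the bundled SV signatures and realized on the genome
  (clustered channels place at least one breakpoint in a per-sample dense
  window so the clustered flag re-emerges from breakpoint density); each
  true SV is emitted as up to three per-caller copies with breakpoint
  jitter <=150 bp, per-caller dropout, and FILTER flags, to exercise the
  consensus stage. Explicit breakpoint clusters (region, count) can also be
  planted.
* **CNA** — diploid baseline with planted state intervals realized exactly
  under the default classification thresholds.
* **Kataegis** — planted clusters of 6–12 SNVs spaced under 1 kb with a
  cytosine-biased substitution spectrum.
* **CCF** — clonal mutations draw CCF in [0.75, 1], subclonal in
  [0.15, 0.5]; groups with a designated clonal/subclonal signature switch
  place one signature almost entirely subclonally.

The default three-group design emulates a high-risk amplified, a high-risk
non-amplified and a non-high-risk profile: distinct SBS/ID/SV signature
mixtures (800/700/450 expected SNVs, 150/160/90 indels, 28/35/8 SVs),
group-defining complex-event classes (ecDNA for the first group, CnC and
TIC for the second, none for the third), group-specific CNA plants
(focal amplification + arm gain; segmental losses + LOH; whole-chromosome
gain), kataegis rates 0.8/0.4/0.1 and a subclonal switch in the second
group. Two deliberate design choices keep the planted structure exactly
three groups: group-defining event classes are present in every member
(multiplicity 1 + Poisson above rate 1.0) rather than Bernoulli at
intermediate rates — an event-positive minority separates by several
standard deviations in scaled space and would plant a genuine fourth
cluster — and per-sample heterogeneity enters through a Dirichlet jitter
(concentration 15, substantial inter-patient variability) on the group
exposure mixtures.

What the generator does **not** emulate: sequencing noise and caller error
profiles beyond breakpoint jitter/dropout, mutation rate variation along
the genome (replication timing, chromatin), subclonal copy-number states,
germline contamination, and realistic genome size. Passing recovery tests
therefore show the pipeline's operations are correct and well-calibrated on
clean planted structure at desk scale, not that the biological conclusions
of any particular cohort would be reproduced.

## Problem sizes and determinism

Tests run on reduced genomes (hundreds of kb) for unit-level checks and the
default ~35 Mb genome for end-to-end recovery; the end-to-end study uses 10
replicates of 60-sample cohorts, and rank-selection studies use 20
replicates of 50-sample catalogs with 30 bootstrap iterations. All
randomness flows from named `SeedSequence` substreams of one cohort seed;
identical seeds reproduce byte-identical cohort directories and pipeline
manifests (manifests carry no timestamps).

## Known limitations

* The ID-83 homopolymer/repeat counting runs on the + strand in both
  directions from the event; tools differ in 5' vs 3' conventions for rare
  ambiguous placements.
* The chromothripsis statistical filters are simplified stand-ins
  (chi-square, KS) for the published tool's tests; confidence tiers follow
  the same counting thresholds but p-values are not comparable.
* The hybrid clustering is deterministic given row order; permuting input
  rows can change Ward tie-breaks on degenerate data.
* NNLS exposures on very small catalogs (tens of SVs) are noisy and
  zero-inflated; cohort-level interpretation should use the filtered
  exposures.
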