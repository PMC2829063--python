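# Methods

This note records the models, numerical choices and open design decisions
behind `pangei`, and what the synthetic benchmarks do and do not establish
about real data.

## Coordinate and data conventions

All intervals are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at I/O only. Features spanning the origin of a
circular replicon are represented as split records sharing a base id with
`/1`, `/2` suffixes; a `part=` attribute in the emitted GFF3 preserves the
5′→3′ part order, which genomic coordinates alone cannot encode across an
origin. Mobility classes (IS transposase, integrase, phage, excisionase) are
derived from free-text `product`/`Note` annotation by a configurable
first-match keyword list — annotation pipelines rarely expose a structured
mobility field, so keyword matching is the practical rule; the defaults
cover the usual vocabulary but will miss nonstandard phrasing.

## Codon statistics

RSCU is computed over 57 retained sense codons: the three stop codons are
excluded, as are the cysteine duet (TGT/TGC) and the AGA/AGG arginine duet,
which are known to inject systematic artefacts into codon-usage
ordinations. Synonymous families are defined over the retained codons (the
arginine family is the four CGN codons), so observed-family RSCU values sum
exactly to the family size — the invariant the tests fuzz. Families absent
from a gene score 0 for all members and are recorded as missing.

CAI follows the Sharp–Li geometric-mean form: relative adaptiveness
w(c) = RSCU_ref(c) / max_family RSCU_ref pooled over a designated
highly-expressed reference set, with ATG, TGG, stops and the four excluded
codons uninformative. Codons unobserved in the reference set get a floor
weight of 0.01 so the geometric mean stays defined. The simulator marks 5%
of host genes as the reference set; on real genomes a ribosomal-protein
keyword set plays that role.

Composition anomaly screening uses robust z-scores — (x − median)/MAD with
the 1.4826 normal-consistency factor — because island genes contaminate the
genome-wide distribution they are compared against; a zero MAD falls back to
mean/sd with a warning. Note the robust scores do not have exact mean 0/sd 1
by construction; that property holds only in the fallback.

GC tracks use non-overlapping windows (default 1000 bp, last partial window
kept): GC deviation is window GC minus whole-replicon GC, and GC skew is
(G−C)/(G+C), defined as 0 for windows without G or C.

Correspondence analysis is the classical chi-square-metric decomposition,
applied directly to the RSCU matrix (the codon-usage-literature convention)
rather than raw counts: scale to relative frequencies P, form standardized
residuals S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD, principal coordinates
F = D_r^{−1/2}UΣ and G = D_c^{−1/2}VΣ; axis inertias are squared singular
values and sum to the total inertia (Σ‖S‖²). All-zero columns are dropped
with a notice; coordinates are deterministic up to axis sign.

## CGH segmentation and status calling

Segmentation is circular binary segmentation: over all arcs (i, j] of the
current segment the statistic |mean(arc) − mean(rest)| / (σ̂ √(1/w + 1/(n−w)))
is maximized, with σ̂ estimated once from the whole segment (the
likelihood-ratio form of the original algorithm). Because Σx and Σx² are
permutation-invariant, σ̂ is constant under permutation and observed and
permuted maxima compare directly. The breakpoint test shuffles the segment's
values (seeded), recomputes the max-arc statistic, and accepts the split
when p = (1 + #exceed)/(1 + n_perm) < α, defaults n_perm = 1000, α = 0.01;
the accepted arc's endpoints cut the segment into two or three pieces that
are segmented recursively. Arc and complement must each hold min_width = 2
probes; constant or singleton segments stop the recursion. Ties in the arc
search resolve to the smallest width, then the smallest start; an arc and
its complement describe the same split.

Two performance devices leave the test exact but make it cheap: permutations
stop early once the exceedance count makes significance impossible, and for
each permutation the centered prefix sums form a bridge whose range bounds
every arc's numerator, so only widths w with w(1 − w/n) ≤ range²/observed²
can possibly exceed — under a strong observed signal that is a handful of
extreme widths, reducing each permutation from O(n²) to nearly O(n). The
inner kernel is numba-compiled.

Per-gene status is the probe-count-weighted mean of the segment means
covering the gene's probes (the segmentation-then-identification order),
thresholded at log2 ≤ −1 for absent/divergent and ≥ +1 for duplicated, both
inclusive. Genes without probes are reported missing. Probe-level calls are
never thresholded directly; how probe calls aggregate to genes is this
package's choice, as the segment-mean rule.

Quantile normalization (each strain column mapped onto the across-strain
mean of sorted values, rank order preserved) stands in for spline-based
two-channel normalization: same intent — distribution matching — with a much
simpler, monotone construction. It is *not* applied by default in
`call_status`: forcing identical distributions across strains that genuinely
differ in deletion load relabels part of one strain's conserved genes as
deleted. It belongs upstream, between technical replicates or dye channels
of comparable composition; the simulator emits final log-ratios directly, so
there is nothing technical to remove. Dye-swap pairs combine as (a − b)/2,
halving technical variance.

## Pan-genome

A gene is dispensable for a strain subset iff called absent/divergent in at
least one subset strain; duplicated genes are present, hence
core-compatible, but still count as "variable" in per-strain flexible
fractions — the two notions are deliberately distinct, and percentages are
reported at 1 decimal. Genes with a missing cell in the subset are excluded
from the partition and counted. Strain clustering uses Hamming distance over
the trinary codes, missing cells excluded pairwise and normalized by the
compared count, with average linkage; neither metric nor linkage is canon in
the source analyses, so both are arguments. Strains are sorted
lexicographically before linkage so ties break deterministically.

## Orthology and synteny

Ortholog pairs are accepted by reciprocal best bit-score hit (ties to the
lowest subject id) or by the threshold branch: identity ≥ 40% over ≥ 80% of
the shorter protein. The BBH branch is an injective partial matching; the
threshold branch may be many-to-many. Blocks chain anchors sorted by
reference-genome rank when at most `gap` (default 5) genes intervene on both
genomes — counted as rank difference minus one — with inversions allowed and
orientation recorded. This interval chaining is a deliberate reduction of
the exact graph-theoretic synteny formulation (multiple correspondences,
fusions, rearrangements); only the island-evidence core is needed here. An
interval's synteny coverage is the fraction of its CDS in any block; the
island caller flags a break below 0.2 (configurable), and a geneless
interval counts as fully covered (no evidence of a break).

## Island calling

Candidates are maximal runs of ≥ 5 consecutive CDS with z_GC3 or z_CAI
≤ −1.5, and runs of genes CGH-variable in ≥ 1 strain; overlapping runs
merge. The five criteria — composition anomaly (median z of the interval's
genes ≤ −1.5), synteny break, ≥ 1 mobile-element gene, a tRNA 3′ end within
1 kb of the island start, and a flanking direct repeat — are recomputed on
the final interval, so stored evidence is idempotent. The acceptance policy
(composition anomaly required, plus ≥ `min_criteria` = 2 of 5 overall) is
explicit configuration, and the full evidence vector is always reported so
alternative policies cost nothing; the z-threshold, run length, flank size
and tRNA distance have no canonical published values and live in
`IslandConfig`.

Direct repeats: seed-and-extend matching between the flanking windows
(default 5 kb, exact by default; `dr_max_mismatch` exposes almost-perfect
repeats), lengths clipped to [10, 112] bp, longest match preferred, ties to
the boundary-nearest pair. Matches must *hug the boundaries*: the inner edge
of each repeat has to lie within `dr_max_offset` (300 bp) of the interval
edge. Unanchored exact matching over two 5 kb windows would almost surely
return chance ≥10-mers (expected count ≈ 25·10⁶/4¹⁰ ≈ 24); anchoring
reflects how integration footprints abut the element and drives the chance
rate to ~10⁻². Because a composition run can leak a boundary host gene, the
caller retries the search with up to two boundary genes trimmed per side and
keeps the longest repeat found, then snaps the island to the inner repeat
edges; boundaries never move farther than the flank size.

## Trees

Gap-column filtering removes columns with strictly more than 5% gaps (a
column at exactly 5% stays). Distances are p-distances with gapped positions
excluded pairwise; the distance model is a configurable hook rather than a
commitment, since nothing downstream depends on a correction. Neighbor
joining is the standard Q-criterion agglomeration with lexicographic
tie-breaks, branch lengths from the two-point formulas, negatives clamped to
0 and flagged; trees are skbio `TreeNode`s, so Newick and path queries come
from scikit-bio. "Evolutionary origin" of a gene reduces to the nearest
taxon by path length (ties lexicographic) plus a user-supplied taxon→group
mapping.

## The synthetic-data generator

The generator is the package's study conditions, not a tuning surface.
Defaults: a 500 kb host backbone of 450 genes (plus the islands on top),
host GC3 0.70 versus island GC3 0.45, four islands of 30/22/26/18 kb
carrying 3/2/4/2 IS genes plus one integrase each, tRNA genes at each 5′
boundary, direct repeats of 20/35/60/112 bp; four strains whose events are
mostly deletions (S1: one; S2: two; S3: three) and one duplication (S4) —
deletions dominate among conspecific isolates in CGH comparisons; probes
every 60 bp (50-mers), log2 shifts −2.5 for deletion and +1.0 for
duplication with Gaussian noise sd 0.3. Gene lengths are normal around
≈280–300 codons with a 180-codon floor so every gene carries at least 8
probes; 5% of host genes form the highly-expressed CAI reference set drawn
from a sharply biased codon table. All outputs are pure functions of
(config, seed).

Genes are sampled codon-by-codon from two multinomial codon tables whose
within-family G/C-ending mass equals the target GC3 — amino-acid composition
is uniform and no selective realism is attempted, because only composition
statistics are consumed downstream. A probe belongs to the gene containing
its midpoint; intergenic probes carry no gene but still segment, and probes
inside a deleted island's intergenic stretches shift too, as the whole
segment is physically absent. "Absent" and "highly divergent" are not
distinguished (both produce the deletion shift), mirroring how CGH cannot
separate them. The island-free comparator genome regenerates the identical
host backbone from the same seed, which gives the synteny stage its ground
truth; hit tables give shared genes reciprocal 80–100% identity hits and
island genes at most sub-threshold (<40%) decoys.

What passing these benchmarks does not show: real arrays have probe-level
biases, spatial artifacts and distribution shifts the noise model omits
(probe spacing here is also ~10× sparser than a real tiling array); real
islands have ragged composition signals, partial IS copies and composite
substructure; real annotation mislabels mobility. The benchmarks validate
the algorithmic machinery — segmentation correctness against an exhaustive
oracle, false-positive control at the permutation level, exact recovery
under the stated signal model — not field performance.

## Numerical choices and degenerate inputs

The duplication shift (+1.0) sits exactly at the ≥ +1 call threshold, so a
duplicated segment's estimated mean falls below threshold in roughly half of
noisy runs; deletion calls (−2.5 against the −1 threshold) are robust. This
is why the default panel's status accuracy lands between ~98.7% and 100%
rather than pinned at 100%. Permutation seeds derive from the configuration
seed; the per-(strain, replicon) segmentations decorrelate their RNG streams
by fixed offsets. Empty probe tables, constant columns, all-missing strain
pairs, rank-deficient CA inputs, alignments that lose every column, and
sub-3-taxon distance matrices all raise or warn explicitly rather than
returning silently wrong output.

## Problem sizes

The default panel is ~10,000 probes × 4 strains and segments in seconds
thanks to the width-pruned permutation kernel; the acceptance script's
oracle comparisons use 200 signals of n ≤ 60 (where exhaustive enumeration
is exact and fast), 100 pure-noise replicates of n = 200 for false-positive
control, 100 random 4–12-taxon trees, and 20 random CA matrices. These sizes
were chosen so the full benchmark battery reruns from scratch in well under
a minute of compute beyond the panel segmentation itself.
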