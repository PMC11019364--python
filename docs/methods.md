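# Methods

## The problem

An assembly built from an inbred individual can be audited with genotype
panels from the same and related inbred strains. Two failure modes leave
distinct genotype signatures. A *collapsed repeat* (two near-identical
copies represented once) attracts the reads of both copies: read depth
roughly doubles and the small differences between the copies surface as
dense runs of heterozygous or no-call genotypes — impossible genotypes for
an inbred animal, and therefore diagnostic of the reference rather than the
sample. A *base-level error* (wrong nucleotide recorded as the reference
allele) makes every sample, including replicates of the reference strain
itself, appear homozygous-alternate at that site. `refpanelqc` detects the
first as flagged genomic intervals and the second as a per-site mask, then
carries out strain-relationship and coordinate-translation analyses on the
cleaned panel.

## Misassembly scan

**Statistic.** For each variant site, count heterozygous plus missing
calls over a designated subset (by default the reference-strain
replicates) and transform:

    y_i = log2(het_i + na_i + 2)

The pseudocount of 2 places the clean-region baseline at log2(2) = 1,
mimicking two DNA copies; with 12 reference samples the ceiling is
log2(14) ≈ 3.81, mimicking up to 14 copies piled onto one locus.

**Segmentation.** The series is segmented recursively in the style of
circular binary segmentation. Within an interval, every admissible arc
[i, j) is scored with a two-sample t-like statistic comparing the arc mean
against the complement mean (pooled variance, n−2 degrees of freedom;
degenerate zero-variance cases map to +∞ when the means differ, 0
otherwise). A split must leave every resulting piece at least
`min_width = 5` sites. Significance is decided by permutation: the
interval's values are shuffled `permutations = 1000` times and the split is
accepted when p = (#exceedances + 1)/(n_perm + 1) < α = 0.001. Each
interval's shuffles come from a generator seeded by (seed, interval start,
interval end), so results are independent of recursion order and exactly
reproducible by an external implementation. Intervals shorter than
2×min_width, or constant, return a single segment.

Two numerical shortcuts keep the scan fast without changing decisions:

* the permutation loop stops as soon as the exceedance count already
  guarantees p ≥ α (at α = 0.001 with 1000 permutations, a single
  exceedance suffices), which makes null intervals cheap;
* for intervals longer than 512 sites, the arc search runs on a strided
  candidate grid of ≤ 256 boundaries and the winning arc is then refined
  exactly within ± one stride; permutations use the same strided search so
  the observed and null statistics remain comparable. Intervals of ≤ 512
  sites are searched exhaustively — which covers the regime where the test
  suite checks exact agreement with a brute-force oracle.

**Merging.** Raw segmentation over-segments. A sliding-triplet scan merges
the first two segments of the current triplet when any of four conditions
holds: (1) both means above the threshold T = 1.5; (2) both means at or
below it (a mean exactly equal to T classifies as LOW); (3) high–low–high
with the middle segment shorter than 5 kb (a "positive flicker"); (4)
low–high–low with a short middle ("negative flicker"). After a merge the
next triplet starts from the merged segment; otherwise the scan advances
one segment. A trailing pair is merged on conditions (1)/(2) only. Merged
means are site-count-weighted averages (the statistic is per-site);
segment widths for the min-width rule count sites, flicker lengths count
bp — the two units are deliberately mixed this way. The scan is repeated
until no merge fires: a flicker merge can flip the merged segment's state
and expose a same-state pair behind the cursor that a single pass would
never revisit; iterating to the fixpoint makes the operation idempotent
while leaving ordinary inputs unchanged after the first pass.

**Output.** Final segments with mean > T become flagged regions, emitted
as 0-based half-open BED (start = position of first member site − 1,
end = position of last member site) with the mean het+NA count
back-transformed as 2^mean − 2.

Raising T does not monotonically shrink the *count* of merged flagged
regions (a high block that merged across a now-LOW middle can split into
two flags); the count of HIGH segments in a fixed segmentation is monotone,
and that is the property the tests assert.

## Shared anomalous sites

A site is *shared* when at least ⌈0.95·n⌉ samples carry a non-reference
genotype (HET or HOM_ALT) and — by default — every reference-strain sample
does too. Among the carriers, heterozygous calls ≥ homozygous-alternate
calls classifies the site HET_SHARED (ties deliberately fall to the more
suspicious class), else HOM_SHARED. Per-site depth is averaged over all
samples; the class summary reports mean ± SD depth and the het/hom depth
ratio, whose value near 2 is the collapsed-repeat signature. Masking
removes exactly the recorded sites (site counts conserve) and emits them
as BED. The fold reduction between two references' shared-site counts is
their ratio rounded to one decimal.

## Strain genetics

**IBS.** For a sample pair, each co-called site contributes the shared
allele fraction — identical genotypes 1, het vs either homozygote 0.5,
opposite homozygotes 0 — and IBS is the mean over those sites (sites
missing in either sample are excluded pairwise; a pair with no co-called
sites is an error). By default only biallelic SNP sites enter. This is the
standard identity-by-state convention; tools differ in detail, so
genome-scale published means are not asserted.

**UPGMA.** Distance 1 − IBS; iteratively join the minimum-distance pair,
with new-cluster distances as size-weighted averages (equivalently the
plain average over leaf pairs) and node height = join distance / 2, giving
an ultrametric rooted tree serialised as newick. Ties are broken by the
lexicographically smallest (min-label, max-label) pair so trees are
bit-reproducible.

**Proxies and mislabels.** A living proxy for a historical strain is the
best-IBS sample outside the query's own substrain(s), reported against a
0.995 threshold. Mislabel rules: same-substrain pairs with IBS < 0.97
(expected ≈ 1 for true replicates) and different-strain pairs with
IBS ≥ 0.98 (expected well below for unrelated inbreds). The defaults
bracket observed exemplars (0.92 low, 0.98–0.99 high) and are
configurable; flags sort by distance from the violated threshold. Note a
label swap also implicates the swapped samples' replicate partners — their
same-substrain pair now has low IBS — so recovery is judged per affected
strain, not per flagged pair.

**Sharing.** A strain carries a site iff any of its samples is
non-reference there; the summary reports per-strain totals, private
(carried by exactly one strain) counts, the shared-by-all count, and a
per-chromosome table by number of carrying strains.

## Coordinate maps

Chain records follow the UCSC convention (`chain score tName tSize tStrand
tStart tEnd qName qSize qStrand qStart qEnd id`; block lines `size dt
dq`), with the t-side as the lift source and block arithmetic validated
against the declared spans. A position lifts by offset within the
highest-scoring chain that *aligns* it; positions falling in a
higher-score chain's gap may still lift through a lower-score chain (this
is how inversion chains nested inside a main chain's gap behave), and
positions aligned by no chain are unmapped with a reason (gap vs absent
chromosome). Reverse-strand blocks map position = block target end −
offset, and applying the inverted chain set returns every mapped position
to its origin. Lifted reverse-strand variants are not
allele-complemented — a documented limitation; variant set comparisons key
on (chrom, pos, alleles).

Simulated lift evaluation places sites at 1, 1+spacing, … (1-based) on
every source chromosome and reports the lifted fraction; on synthetic
chains this equals the truth-map mappable fraction exactly.

cis/trans classification of SNP–gene pairs: same chromosome and distance
< 1 Mb is CIS; different chromosome or distance > 5 Mb is TRANS; the
closed interval [1 Mb, 5 Mb] is AMBIGUOUS (both published bounds are
strict, so the boundary values fall in the middle class). Conversion
tables count pairs by (class under map A, class under map B) with a
per-gene rollup of TRANS→CIS and CIS→TRANS moves.

Genetic-map concordance: Spearman rank correlation between genetic (cM)
and physical (bp) marker order per chromosome, plus maximal runs of ≥ 5
consecutive markers with locally decreasing genetic position flagged as
inversion candidates with bp extents.

## Assembly statistics

Every FASTA record is a scaffold; contigs are obtained by splitting at
maximal N-runs of ≥ 10 (shorter runs, wherever they fall, stay inside a
contig and count toward its length; only the letter N, either case,
defines a gap). No minimum-length filtering anywhere. Nx is the length at
which the descending cumulative sum first reaches x% of the total; Lx the
number of sequences in that prefix. Quotable fold ratios round N50 ratios
≥ 100 to the nearest 10 and count ratios to the nearest integer, matching
how such comparisons are conventionally cited.

## Synthetic data

The generator emulates the statistical structure of a jointly-called
inbred rat panel: site positions from a Poisson process with mean spacing
1000/density bp (default density 6.0/kb, matching observed per-kb variant
density); per-strain homozygous-alternate draws at probability 0.3 with
replicates copying the strain genotype; residual heterozygosity and
missingness as independent per-sample noise at 0.005 each (keeping samples
~98–99% homozygous at non-missing non-reference calls); read depth
Poisson with mean 30. Strain 0 is the reference strain — its genome *is*
the reference, so its background calls are homozygous-reference — and can
carry more replicates than other strains (`reference_replicates`, default
equal to `replicates_per_strain`; the scan conditions use 12).

Planted truth: collapsed regions draw het-or-missing per sample at the
configured rate (3:1 het:missing split) and multiply depth; shared error
sites set every sample non-reference, one quarter of them heterozygous
with doubled depth (mirroring the observed skew toward homozygous base
errors while keeping the het class populated) and the rest homozygous;
label swaps exchange sample *metadata* after generation, leaving genotype
columns in place, because mislabel detection must see discordant metadata
over concordant genotypes. Site QUAL values draw from N(70, 20) clipped at
1, matching observed genotype-quality scales; about 2% of sites therefore
fall below the QUAL ≥ 30 filter, including occasionally a planted error
site — end-to-end recovery through the filtered pipeline is accordingly
near-exact rather than exact, while the scan operation itself recovers
planted sites exactly on the unfiltered panel.

What the generator does **not** model: linkage disequilibrium and
realistic haplotype sharing between strains (each strain draws
independently, so between-strain IBS sits near 0.5–0.6 rather than the
~0.7 of real classic inbreds), indels and multi-allelic sites, alignment
artefacts other than the two planted defect classes, read-level data, and
structural variation. Passing tests therefore demonstrate that the
algorithms recover exactly the planted signal classes under faithful noise
models — not that real-genome outputs (region counts, lift rates, IBS
means) are reproduced; those depend on the real assemblies and call sets.

## QC conventions

Variant filter keeps QUAL ≥ 30 exactly (sites *below* the threshold are
removed); sample QC passes missing rate ≤ 0.04 and mean depth ≥ 10, both
boundaries inclusive on the passing side; filtering precedes masking and
all downstream analyses. MISSING genotypes count toward missingness but
never toward non-reference carriage. Multi-allelic genotype class derives
from allele indices alone (two distinct called indices → HET, two
identical non-zero → HOM_ALT). Coordinates are 1-based VCF throughout,
converted to 0-based half-open only at BED boundaries. Sex chromosomes
and the mitochondrion are excluded at parse time by default — the scans
are autosome-only.

## Problem sizes

The test suite and acceptance script run the full pipeline at 20 strains ×
2 replicates (12 reference replicates) over two 10-Mb chromosomes
(~120,000 sites), with five planted collapsed regions of 30–60 kb, 200
planted error sites, and one label swap — large enough for every stage to
operate in its intended regime while completing in well under a minute.
Exhaustive-oracle checks run at series length ≤ 25 (segmentation) and
≤ 8 leaves (UPGMA), where brute force is tractable.
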