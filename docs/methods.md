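# Methods

## Spatial model and normalization

A tomo-seq specimen is a gene × section count matrix whose columns are
20 µm cryosections in physical anterior–posterior order. Sections differ
in captured material and sequencing depth, so counts are first divided
by the section total (`normalized` columns sum to 1); a section with a
zero total carries no information and is dropped with a warning (the
only section-level QC applied by default — the data this emulates report
tens of thousands of transcripts per section, so deeper QC is left to
the caller). Per-gene z-scores are computed across one specimen's
sections on the normalized values with the sample (n−1) standard
deviation, matching the convention of standard scaling functions. A gene
whose normalized profile is constant (most commonly all-zero) has no
defined z row; it is carried as NaN and excluded from every downstream
median rather than set to 0, which would fabricate "below-average"
evidence for genes with no signal at all.

## Marker-peak segmentation

Regions are anatomical units defined by marker cohorts. For each marker
set the per-section signal is the mean z over its members, smoothed by a
running median; peaks are the maximal runs of sections with smoothed
signal strictly above `min_z` (default 1), ordered A–P. A marker family
elevated in two structures (the MSP-like sperm marker) produces two
runs, and its regions select the first or second by a peak *ordinal*.
Boundary rules, which the underlying protocol leaves open, are: seeded
peak intervals must appear in configured order (otherwise an error);
the gap between two consecutive seeded regions is split at its midpoint
with the odd section going to the anterior region (the least-informative
choice); an indirectly defined region takes all sections strictly
between its two anchors; the first and last regions absorb leading and
trailing sections.

Two numerical facts shaped the defaults. First, a gene elevated in *w*
of *n* sections has a z-score ceiling of √(n/w − 1) regardless of fold
change: a marker spanning two regions (w ≈ 10 of 40) cannot exceed
z ≈ 1.7, so wide double markers sit close to the detection threshold.
Second, with negative-binomial counts at dispersion 0.3 the per-gene,
per-section z noise has standard deviation near 1.5, so a single gene
cannot reliably stay above z = 1 across its whole region; reliable runs
need the averaged signal of a co-expressed cohort. The pipeline
therefore smooths with a width-5 running median by default (a width-3
median passes single-section dropouts straight through at run edges),
while the lower-level peak operation keeps a width-3 default for
minimally processed signals.

## Pooling, expressed and regional genes

Specimens are pooled by concatenating, per region, all sections of all
specimens and taking the median z (`median_z`) and median normalized
count (`median_norm`). The gene universe is the genes detected (nonzero
total) in at least `min_specimens` specimens — by default all of them,
the conservative reading of "expressed in all specimens". A gene is
*expressed* in a region if `median_norm > 0` and *regional* if
`median_z > 1`, strictly; the two flags are independent criteria and
`regional` does not require `expressed` (an AND-ing strict mode is a
flag). Undefined z entries are excluded from medians; an all-undefined
pool leaves the gene non-regional there.

## Orthology and overrepresentation

Reciprocal best hits are computed on a combined-database hit table:
self-hits removed, e-value strictly below 10⁻³, best hit per gene by
lowest e-value with ties broken by higher bitscore then lexicographic
target id (determinism; the underlying convention is unstated). A gene
whose best within-species non-self hit strictly outranks its best
cross-species hit is excluded as having an inparalog
(`reject_if_within_species_hit_better`, default on) — this reproduces
what a combined-database best-hit construction does without full
Inparanoid clustering, which is out of scope.

Fisher's exact test is implemented on the hypergeometric log-pmf with
the probability-ordering two-sided definition (all same-margin tables
whose probability is ≤ the observed, relative tie tolerance 10⁻⁷);
degenerate margins give p = 1 and the sample odds ratio ad/bc is
reported (∞ when bc = 0 and ad > 0, 0 when ad = 0). BH-FDR is the
step-up rule with monotonicity enforcement, stable under input
permutation. Cross-species region-pair tests use as universe the
ortholog pairs expressed in both species (the natural analogue of the
"all expressed genes" background used for domains; config-overridable);
within-species tests and domain enrichment use that species' expressed
genes. Domain tests additionally report the member count and cumulative
expression (Σ of `median_norm` over member regional genes). Two-sided
tests are the default, one-sided available by flag.

## Phylostratigraphy

The ladder configuration lists, from young to old, disjoint taxon sets;
stratum 1 is the focal species alone. Evidence that a taxon has a
homolog of gene *g* is the union of protein hits below the protein
threshold (10⁻³) and nucleotide hits below the nucleotide threshold
(10⁻⁵) — the nucleotide route exists to rescue genes whose annotated
ORFs are wrong, so union is the only sensible combination. The stratum
is the maximum stratum index over taxa with evidence; genes with no
qualifying hits anywhere are stratum 1 by the phylostratigraphic
definition of species-specificity. Age compositions report per-set
stratum fractions plus a genome-wide "Ref" over the full annotated
universe (a flag restricts to expressed genes). The young-fraction test
is a one-sided (greater) Fisher test of young vs old membership of each
region's regional set against the rest of the universe, BH-corrected
across regions, with regions also ranked by raw young fraction. The
"young" stratum set is configuration (default I–III).

## Evolutionary rates

Rate tables carry one row per ortholog-cluster member. One-to-one
reduction keeps, per focal gene, the partner with minimal dS (dS is the
least saturated neutral clock available per pair); ties break by
minimal ω then lexicographic partner id, a documented convention. Rows
with dS = 0 (ω undefined) are excluded and logged. Group summaries use
linear-interpolation (type-7) quantiles, stated here because boxplot
conventions differ. Species-pair matching minimizes |median dS −
reference|, ties preferring the larger (more conservative) divergence.

## Reference-isoform selection and ORFs

One representative isoform per gene: (1) the isoform with a poly-A tail,
defined as a terminal run of ≥ 6 adenines (a strict suffix — six A's
anywhere near the end do not count); (2) among several tailed isoforms,
the one whose best protein hit (lowest e-value, bitscore tie-break) ends
most 3′ on the transcript, measured as alignment end divided by
transcript length (absolute coordinates would favour long isoforms; a
flag restores them); (3) otherwise the longest isoform — applied within
the candidate set the earlier rules narrowed (among tailed isoforms when
several are tailed but none has a hit), with lexicographic id as the
final tie-break. ORF extraction translates the three forward frames only
(the assemblies emulated are strand-specific; a flagged 6-frame mode is
out of scope here) and returns the longest stop-free codon run — no
start codon required, ambiguity codons translate to X without breaking
the run, ties prefer the most 5′ start then the lowest frame.

## Synthetic data: what it emulates and what it does not

The generator produces two species × 4 specimens × 40 sections × 3,000
genes by default. Counts are negative binomial (variance m + 0.3 m²)
around lognormal per-gene baselines (median 10) with lognormal
per-section library-size factors (σ = 0.3) — the minimal model that
makes section-total normalization necessary. About 29% of genes are
regional (fold 4 inside their region), split into equal per-region
quotas; marker cohorts (10 genes per region, a 40-member MSP-like family
shared by the two sperm regions) carry fold 10. Region boundaries jitter
by ±1 section between specimens with a minimum width of 4; the sperm
regions are kept narrow, as the z ceiling above dictates for a
two-region marker. Gene ages are i.i.d. from a reference distribution
(30/12/8/10/15/25% across six strata, i.e. ~30% species-specific); the
two sperm regions draw their regional genes with weight β (default 3)
for young-stratum genes, so their stratum distribution is exactly the
reference with young:old odds multiplied by β, and equals the reference
at β = 1. Homology hits encode each gene's stratum (qualifying hits up
to its stratum, a fraction rescued only by nucleotide hits, plus
above-threshold decoys); 30% of genes get a one-to-one partner whose
regional assignment is conserved with probability 0.6; rate tables give
each stratum ≥ II gene a true partner with minimal dS in its cluster and
ω ~ Gamma with mean 0.4·0.7^(stratum−2), strictly decreasing with age.
One master seed drives named `SeedSequence` child streams, so every
output file is bit-identical on regeneration.

Passing recovery tests on these data shows the pipeline's logic is
correct under its own statistical assumptions. They do not establish
performance on real tomo-seq: real sections have heterogeneous tissue
composition, mappability and gene-length biases, non-NB overdispersion,
correlated marker families, incomplete annotations, and homology-
detection failure that systematically under-ages fast-evolving genes —
none of which the generator models.

## Default problem sizes

The test suite and acceptance script run the generator at its default
scale (3,000 genes, 40 sections, 4 specimens per species) with 10–50
seed replicates per experiment, sizes at which every planted effect is
comfortably detectable while a full run stays in seconds.

## Known limitations

- Segmentation assumes every marker-defined region's peak is present;
  a specimen genuinely missing a structure fails loudly rather than
  degrading gracefully.
- Pairwise-complete Pearson distances can make the section dendrogram
  non-metric in extreme missingness; sections with undefined correlation
  everywhere are dropped with a warning.
- Strict RBH with inparalog rejection undercalls orthologs in recently
  expanded families by design; it trades recall for one-to-one purity.
- Phylostratigraphy inherits BLAST's homology-detection horizon: highly
  diverged members of ancient families are classified young.
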