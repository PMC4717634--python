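# Methods

This note documents the models implemented in `subrvis`, the choices
made where the procedure admits more than one reasonable reading, and
what the synthetic cohorts do and do not establish.

## Region divisions

A gene's CDS coordinate space is `[0, L)` over its coding exons in
transcription order. Genomic intervals are 0-based half-open (BED);
protein alignment coordinates are 1-based inclusive (BLAST), converted
as `((aa_start − 1)·3, aa_end·3)`. The CDS↔genomic map is a bijection on
covered bases; for minus-strand genes, genomic blocks are emitted in
transcription order (descending coordinate).

The domain division keeps profile-search alignments with E-value
≤ 1e-2, resolves overlaps greedily in descending bit score (ties: lower
E-value, then lexicographic domain id), dropping any alignment that
overlaps an already-kept one, and labels every maximal uncovered
stretch `unaligned`. Terminal uncovered stretches are included as
regions so that every division tiles the CDS exactly — the
size-conservation property the region-shuffle permutation test depends
on. Zero-length gaps between abutting alignments produce no region.
Alignments extending past the CDS end (annotation slop, incomplete
terminal codons) are rejected with a warning rather than truncated;
truncation would create region boundaries the alignment itself does not
attest. CDS lengths not divisible by 3 are tolerated and flagged. When
several transcripts are supplied, the canonical one is the longest CDS
(ties: smallest transcript id).

## subRVIS

Site qualification: mean coverage ≥ 10× (default), and variant sites
must carry the `PASS` filter. Counting: `total` = all qualifying
variants in the region; `common` = non-synonymous variants with folded
MAF strictly > 0.001. One OLS line (with intercept) of `common` on
`total` is fitted jointly across all regions of a division, and each
region's score is its externally studentized residual (leave-one-out
error variance; internal studentization is available as an option — at
tens of thousands of regions the two are numerically indistinguishable,
but the convention must be pinned for exact tests). A residual that is
numerically zero studentizes to zero, which also covers the degenerate
perfect-fit case where the error variance vanishes. The regression
requires ≥ 3 regions and non-constant totals. Per-division fits are
separate (domain and exon scores come from different regressions).

subGERP averages whatever per-base conservation values the (possibly
sparse) track provides over a region's genomic blocks; a region with no
covered base is missing, never zero. Mutation rates sum a
(context, alt) rate table over every region position and all three
substitutions, using one flanking base on each side of the region so
boundary contexts are defined; positions with `N` in context are
skipped. The per-gene variability score is the sample SD of a gene's
sub-region scores, defined only for genes with ≥ 3 scored sub-regions.

## Pathogenic test set

Kept: ClinVar label exactly `Pathogenic`, or HGMD label exactly `DM`;
canonical transcript; `missense_variant` present; none of
`incomplete_terminal_codon_variant`, `splice_region_variant`,
`stop_gained`, `stop_lost`. The splice-adjacency exclusion is carried
entirely by the `splice_region_variant` term — no independent distance
computation. Identical (chrom, pos, alt) records across sources count
once. The filter is idempotent.

## Gene-specific test

`E_i = (ΣY)·Z_i/ΣZ`; `C = cov(Y − E, X)` with the n−1 sample
denominator (pinned by the worked two-region example: Y=(4,0), Z=(1,1),
X=(−1,1) gives C = −4). Null: `Y* ~ Multinomial(ΣY, Z/ΣZ)`;
`p = (G+1)/(n_p+1)` with the inclusive tail `C* ≤ C`, so `p ≥ 1/(n_p+1)`.
Genes with < 2 regions, no pathogenic variant, a non-positive rate or a
missing score are skipped with a structured reason (no imputation).
Each gene draws from a deterministic RNG substream derived from the run
seed and a CRC-32 of the gene id, so results are independent of
processing order. BH FDR is applied across assessable genes.

## Genome-wide test

Scores are divided by their population SD (computed over all tested
regions of the division, before any model-specific subsetting) so `β2`
reads per-SD. The fit is maximum-likelihood logistic with Wald
p-values; natural log for `log Z`; degenerate responses, zero-variance
scores and non-convergence (separation) are rejected. A gene-constant
score vector is just another score column — nothing in the fit is
region-specific. The resampling null redistributes the ones of `Y` by
weighted sampling without replacement with probabilities `Z/ΣZ`
(successive draws over the renormalised remainder, via
`numpy.random.Generator.choice(replace=False, p=…)`), preserving `ΣY`
exactly in every draw; `C` counts null p-values *strictly* larger than
the observed one. Null refits that fail contribute p = 1
(conservative). AIC comparison: `p = exp((AIC_min − AIC_max)/2)`,
exactly `exp(−|ΔAIC|/2)`. The division permutation test re-lays every
gene's regions in random order (preserving count and size multiset),
re-tallies variants and pathogenic counts against the new boundaries,
refits scores and rates, records `β2`, and uses the strict count
`X = #{|β2*| < |β2|}` in `(n_p − X + 1)/(n_p + 1)`.

## Hot zone

Effect score: synonymous → 0; canonical splice, stop gain, stop loss →
1; missense → its PolyPhen-2 HumVar score (missing → excluded from both
numerator and denominator). Percentile: `100 · #{scores ≤ s}/n`, so
intolerant regions sit near 0; the classification thresholds (effect
≥ 0.95, percentile ≤ 25) are both inclusive. Enrichment uses a
two-sided Fisher's exact test, which reproduces the published epilepsy
table p-value of 0.018. MutationTaster conversion: polymorphism → its
probability (∈ [0.5, 1]); disease_causing → 1 − probability
(∈ [0, 0.5]); `*_automatic` labels with probability < 0.5 are flipped
to the classifier's side with probability 1 − p before applying the
non-automatic rule. De novo filtering removes calls observed as
standing population variants and, under the sibling-cohort rules,
requires the call to be absent in both siblings and either validated by
at least one center or labelled `strong` by one center with no center
calling it `weak`/`not_called`.

## Synthetic cohorts

The generator emulates the statistical structure the tests assume, on
one synthetic chromosome: random multi-exon gene models (CDS 120–500
aa, ~4 exons), random non-overlapping domain alignments (~1.8 per
gene, 30–120 aa) giving about five sub-regions per gene, i.i.d. uniform
ACGT sequence, and a seeded lognormal (context, alt) rate table around
1e-8 — a synthetic stand-in with the shape of empirically calibrated
context tables. A fraction (default 20%) of domain regions is planted
intolerant: their common non-synonymous variants are thinned by a
suppression factor (default 5), their conservation is elevated, and
pathogenic variants are placed per gene by a multinomial with weights
`Z_i × enrichment` (default 5) on intolerant regions. Variant sites
arrive at 0.03 per CDS base, 70% non-synonymous, 30% common before
suppression, with 5% low-coverage and 5% filter-failing sites to
exercise qualification; ~15% of pathogenic records are decoys (wrong
label or excluded consequence) to exercise the filter. With suppression
and enrichment at 1 the cohort *is* the multinomial null of the
gene-specific test. Named presets: `concentrated` (a few strongly
intolerant regions carrying nearly all pathogenic variants),
`graded` (milder contrast spread over half the regions), `null`.

What passing on synthetic data does **not** show: real cohorts have
non-uniform base composition, linked sites, coverage that correlates
with sequence context, ascertainment bias in clinical databases, and
multi-transcript genes — none of which the generator models. The tests
establish correctness and calibration of the statistics, not empirical
effect sizes in human data.

## Problem sizes and numerical choices

Default statistical settings follow the method's standard operating
points: gene test `n_p` = 20,000, genome resampling `R` = 1,000,
division permutations `n_p` = 100. The validation suite uses scaled
problem sizes chosen to make the checks sharp but quick: calibration
over 2,000 null genes at `n_p` = 2,000; logistic recovery at n = 20,000
regions; the division-shuffle conservation check over a 500-gene
cohort. Permutation statistics are vectorized (one multinomial draw
matrix per gene); covariance uses the centered dot product over n−1.
All randomness flows through `numpy.random.Generator` seeded from a
single integer; per-gene substreams make parallel and serial runs
identical.

## Known limitations

Single-transcript gene models only (the canonical-transcript rule is
applied upstream of scoring); no analytic approximation to the
permutation p; the multi-domain-model exclusion for domain databases is
delegated to an input filter on domain ids, since database membership
metadata is external; Y/MT-chromosome exclusion is an input-preparation
convention rather than an enforced check.
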