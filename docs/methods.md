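# Methods

This note documents the statistical models, conventions and design choices
behind `eqtlatlas`, and what the synthetic-study tests do and do not
establish about real data.

## Coordinate and identifier conventions

Internally every interval is 0-based half-open. SNP positions arrive
1-based (the dbSNP convention) in the SNP map and association tables and
are converted at the boundary; BED tracks are consumed as 0-based
half-open. All inputs must share one genome build; no liftover is
performed.

Gene resolution tries the canonical gene key and the symbol first, then
aliases; an alias claimed by more than one gene is never assigned — the
record is dropped with reason `ambiguous_alias`. SNP resolution tries the
rsid first, then alias identifiers mapped back to a canonical rsid. SNPs
with more than one genomic placement or a pseudo-autosomal placement are
dropped (`multi_map`, `pseudo_autosomal`). Every drop is logged with a
reason code; drops are never silent.

## Distance and location classes

The SNP–gene distance is 0 inside the gene's maximal isoform-union span,
otherwise the gap in bases to the nearest span edge, signed by gene
orientation (negative = 5′/upstream). In-gene SNPs are assigned distance 0
rather than a signed offset; this makes `in_gene` a class of its own rather
than folding it into cis, and the pooled "cis summary" reported alongside
the four-way split is `in_gene + cis`. The cis window default is 500 kb and
*inclusive* (a SNP exactly 500,000 bp away is cis); beyond the window the
class is `trans_same_chr`, and a different chromosome is always
`trans_diff_chr`. The four classes partition all mapped records.

Best-eQTL selection takes the minimum p per (dataset, gene) after exact
duplicate removal. "Strongest" does not define an order for ties, so a
deterministic cascade is imposed: smaller |distance| (cross-chromosome
treated as +∞), then smaller position, then lexicographic rsid. This makes
the entire pipeline invariant to input row order.

## Occurrence analysis and clustering

The occurrence matrix is binary presence of an entity (eGene or eQTL rsid)
per dataset; an rsid best for two genes in the same dataset counts once.
Clustering uses the binary (asymmetric Jaccard) dissimilarity — discordant
positions over positions where either vector is 1, with 0/0 cells carrying
no information — and agglomerative clustering with complete linkage on both
axes, the defaults of the classic R `heatmap` workflow for presence/absence
matrices. The linkage method is configurable. Two all-zero rows are defined
to have distance 0 (such rows are excluded upstream anyway, since entities
absent everywhere never enter the matrix). Scipy's hierarchical engine
provides the linkage; a hand-run three-row example pins the expected merge
order and heights in the tests.

The sample-size saturation curve is an ordinary least-squares fit of
per-dataset eGene count against ln(sample size), with r² the squared
Pearson correlation of fitted and observed counts; constant counts are
reported as slope 0, r² 0 rather than NaN.

## Trans hotspots

SNPs are grouped into blocks of perfect linkage disequilibrium — connected
components of the proxy graph restricted to r² = 1 (tolerance 1e-12) —
because different studies tag the same locus through different, perfectly
correlated markers. A block is a hotspot when its members' trans best
associations draw support from at least `min_datasets` datasets (default
4: most multi-tissue publications contain at most 3 tissues from the same
individuals, so 4 forces support from more than one study). "Supporting
datasets" counts datasets, not target genes. Blocks whose targets are all
on the block's own chromosome are labelled `long_range_cis`, all elsewhere
`diff_chr`, otherwise `mixed`. Known homology or cross-hybridization
artifacts can be screened with an exclusion list of (rsid, gene) pairs;
no sequence analysis is attempted.

## Per-base binomial track enrichment

For track coverage c, genome length G (default 3,080,436,451 bp) and
targeted fraction f (default 1): p₀ = c/(fG), effective n = round(f·n) for
n unique single-base SNP positions, expected = p₀·n_eff, and the one-sided
enrichment p-value is the exact binomial upper tail P(X ≥ observed). The
targeted-fraction convention models assays (such as 5C) that interrogate
only part of the genome: both the base probability and the number of
informative positions are restricted to the targeted territory.

One-sidedness is deliberate — depleted tracks report ratios < 1 with p near
1. The tail is computed via the binomial survival function in log space;
when even the log survival function underflows, the tail is accumulated as
a log-sum-exp over individual log-pmf terms, so log₁₀ p remains finite and
exact arbitrarily far below the smallest normal double, while the linear-
scale value is reported as 0.0. Reported probability, expected, ratio and
p are rounded to 3 significant figures for tabulation; `*_exact` fields
retain full precision. Interval merging and position counting are plain
sort/merge and binary search; a per-base bitmap oracle verifies both on toy
chromosomes.

## GWAS integration

Genomic inflation λ is the median-based genomic-control estimator: each
p-value is mapped to its 1-df chi-square deviate and the median deviate is
divided by the null median 0.4549364 (computed from the chi-square
quantile function, not hardcoded to fewer digits). λ depends only on the
median, making it robust to a small fraction of extreme signals.

Subset enrichment compares λ of the subset against λ of its *complement*
within the same scan (not subset vs all — the complement keeps the two
groups disjoint), both genome-wide and restricted to the significant tail
(scan p < 10⁻²), plus a two-sided two-sample Kolmogorov–Smirnov test on the
raw p-value distributions (K-S is invariant to the monotone −log₁₀
rescaling, so the scale choice is immaterial). Catalog overlap
deduplicates catalog SNPs to unique rsids; proxy expansion closes the eQTL
set over connected components of the r² = 1 graph, so chained proxies are
included.

## Positional and group summaries

Per-dataset distance profiles use population (biased) central moments:
skewness g₁ = m₃/m₂^1.5 and excess kurtosis g₂ = m₄/m₂² − 3. The kurtosis
convention for sharply peaked eQTL distance distributions is not
standardized; the population/Fisher form is the documented default and the
estimator is isolated in one function if a different convention is needed.
TSS histograms orient distances by strand (downstream always positive),
with the TSS at the 5′ end of the union span. Tissue-group comparisons of a
location class use a 2×2 chi-square test without continuity correction,
substituting Fisher's exact test when any expected cell is below 5.
Chromosome rankings divide cis-eQTL counts by four normalizers (chromosome
length, coding-gene count, RNA length, variant count), rank each density
column descending with mid-ranks for ties, and average the four ranks; the
result is invariant to rescaling any metric column. The housekeeping
comparison is the classic pooled-variance two-sample t-test on
datasets-per-eGene counts (Welch available via `equal_var=False`).

## The synthetic-study generator

The generator emulates the *statistical structure* the downstream analyses
assume, at a scale where the full pipeline runs in seconds: 3 chromosomes
of 10 Mb, 300 genes, 53 datasets split 24 brain / 14 blood / 5 liver /
3 fat / 7 other, sample sizes 50–1500. Sharing structure: ~20 master genes
present in a dataset with probability 0.9; background genes 0.02 (so their
modal occurrence is a single dataset, reproducing the heavy left edge of
real occurrence spectra); a housekeeping stratum boosted by +0.15; 20% of
genes tissue-group-specific at 0.35 within their home group. Significance
follows a distance-decay model: candidate SNPs placed with two-sided
exponential displacement (τ = 20 kb) around each gene, −log₁₀ p = 6 +
12·exp(−|d|/τ) + N(0,1), truncated at a per-dataset reporting threshold
drawn from [5, 8]; the top candidate of a significant (gene, dataset) pair
is always reported, mirroring the fact that source studies published the
gene as significant under their own criteria. A 4% minority of signals
(10% in brain datasets, planting the brain excess of different-chromosome
trans) is re-placed on random trans markers; two perfect-LD hotspot blocks
are planted with 8 supporting datasets each. The SNP map is corrupted at
configured rates (5% aliases, 1% multi-mapped, 0.5% pseudo-autosomal) to
exercise the filters. Tracks: a TSS-proximal track and a coverage-matched
uniform null, plus a targeted-subregion track at f = 0.01. GWAS scans are
Uniform(0,1] with a planted 10% subset drawn from Beta(0.5, 1); a tenth of
the scan universe reuses genuine eQTL rsids so catalog overlap is
non-trivial.

All draws descend from one root seed through named substreams, so adding a
generator leaves the others bit-identical. The truth ledger (master set,
labels, planted subsets, hotspot blocks) is written to a separate file and
never read by pipeline code.

What passing tests on this generator do **not** show: the generator has no
realistic LD structure, allele frequencies, probe effects, overlapping
study samples, or correlated gene expression — so recovery results bound
the pipeline's correctness, not its behavior under real-data confounding
such as cross-hybridization or shared-sample correlation between datasets.

## Numerical and degenerate-input choices

- Ties everywhere are broken deterministically (documented cascades); all
  outputs are invariant to input row order.
- p-values must lie in (0, 1]; zero or negative p is rejected rather than
  clamped.
- Zero-coverage tracks with zero observed overlaps report expected 0,
  p = 1; observed > 0 with zero coverage is an input error.
- Zero-variance distance profiles and sub-3-sample profiles are flagged
  undefined rather than returning NaN silently.
- Constant saturation counts report slope 0, r² 0 (a fit has no explanatory
  power there).
- Clustering of fewer than two entities returns a degenerate single-leaf
  result instead of raising.

## Known limitations

- No probe-sequence or homology analysis; trans artifacts from
  cross-hybridization must be screened externally via the exclusion list.
- No genome-build conversion; mixed-build inputs will silently mis-map.
- The per-base enrichment model treats SNP positions as exchangeable single
  bases; it does not condition on SNP ascertainment (array design) or local
  gene density, so gene-proximal tracks inherit some enrichment from the
  gene-centricity of eQTLs themselves.
- λ-based subset enrichment assumes the scan's complement is a fair null
  reference; strong polygenicity inflates both sides.
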