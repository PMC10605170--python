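# Methods

This note records the models, conventions and design choices behind
`regscan`, in the spirit of a statistical methods appendix: what each stage
assumes, which knobs matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Coordinate conventions

All genomic coordinates are 0-based half-open (BED). The survey window is
treated as half-open, so a 1,050,000 bp window in 100 bp bins yields exactly
10,500 bins. Two intervals overlap iff they share ≥1 bp under half-open
arithmetic; a peak ending exactly where a bin starts does not overlap it. A
window length not divisible by the bin size truncates the final partial bin
with a warning rather than emitting a short bin.

## Co-expression survey

Per cohort, every gene's Spearman correlation with the focal gene is
computed on average ranks (ties handled as in `scipy.stats.spearmanr`),
vectorized as Pearson correlation of rank-transformed rows. Zero-variance
genes get a *missing* correlation — never 0, which would fake evidence of
independence. The focal gene is excluded from its own correlation vector,
which also keeps its trivial ρ = 1 out of the standardization moments.

The z-transform standardizes each cohort's correlation vector with the
cohort mean and **sample** standard deviation (n−1); the convention is
internal (any consistent choice rescales all z equally within a cohort) but
is fixed so the mean-0/sd-1 identity holds exactly under the same ddof. A
cohort whose correlations have zero variance, or fewer than two defined
correlations, is an error rather than a silent vector of zeros.

The pan-cancer summary is the per-gene **median of available z-scores**
across cohorts; genes need not appear everywhere, and the number of
contributing cohorts is recorded per gene with a reporting threshold
(default 3 cohorts). The summary operates on z-scores rather than raw
correlations — raw-rho medians can be obtained by passing correlation
vectors to the same median operation, but the z-scale is the one used for
ranking and GSEA downstream.

## Chromatin scan

Quantile normalization is the classic rank-mean construction: each sample's
values are replaced by the across-sample mean of order statistics at the
value's rank. Ties receive the reference value interpolated at their
average rank (so equal counts stay equal after normalization); consequently
the "sorted columns identical" identity is exact on tie-free data and holds
up to tie-averaging otherwise. An optional block of reference rows — e.g.
a genome-wide coordinate panel for global normalization — participates in
rank computation and is dropped from the output; the coordinate panel
itself is user-supplied, not packaged.

Bin-level Spearman p-values use the t approximation (two-sided), matching
`scipy.stats.spearmanr`. The BH family is **all bins in the window** — the
scan is window-scoped, not genome-wide. Constant bins keep their grid row
with ρ missing and p = 1, preserving grid alignment for the overlap stage;
their signed score is 0. Samples are joined on exact sample ID and fewer
than 4 matched samples is an error. The signed display score is
sign(ρ)·(−log₁₀ padj); it is infinite when padj underflows to 0 (|ρ| = 1),
which is reported as-is rather than floored.

Composite signal tracks take the per-position 75th percentile across tracks
with the linear-interpolation quantile convention (numpy default); the
convention matters only at small track counts and is recorded here because
the upper-quartile definition does not pin it down.

## Overlap enrichment

"Overlap frequency" counts **bins overlapped** (≥1 peak touching the bin),
not peaks: the unit of analysis is the significant-bin set. The expected
overlap relocates the *query bins* uniformly at random within a declared
background (default: the survey window; any containing region can be
supplied), preserving bin widths and allowing relocated bins to collide;
peaks stay fixed. 100 permutations is the default. This local
re-specification replaces a web service's server-side permutation whose
internals are not published; it is documented as this package's convention,
not asserted as identical.

Factor-level inference pools the per-experiment (obs − exp) values across
all factors and, for a factor with k experiments, draws n = 10,000 sums of
k pool values **without replacement** — a draw of k real experiments, which
controls for experiment count. The permutation p uses the add-one estimator
(never 0, never > 1); BH runs across factors; z is the aggregate's distance
from the null mean in null sd units (missing when the null is degenerate);
and the enrichment score is log₂(Σobs/Σexp) × −log₁₀(padj). An exhaustive
mode enumerates all C(n, k) subsets for tiny pools and then reports the
exact permutation p (the observed subset is part of the enumeration, so the
add-one correction is unnecessary there). A peak-score import filter stands
in for an upstream peak-quality cutoff and is exposed as a flag
(`min_peak_score`), applied when experiments are loaded.

## Target sets, distances, GSEA

A gene is a factor's target iff ≥1 peak of that factor overlaps
[TSS − 1000, TSS + 1000) and the **mean score of the overlapping peaks,
pooled across the factor's experiments**, exceeds 50. The alternative
reading (per-experiment minimum) was rejected because averaging across
experiments is the natural meaning of a "minimum average" filter on a
factor's evidence; a score of exactly 50 fails the filter. One
representative TSS per gene is required (the table is gene-level, not
transcript-level); missing strand defaults to '+' with a warning — the
window is symmetric, so strand affects nothing but provenance.

Distances are Euclidean between binary occupancy rows. Genes are ranked by
ascending distance with ties broken by input order (determinism) and cut
into consecutive 40-gene bins; the focal gene (distance 0) is excluded from
its own ranking by default, with a flag to include it. PCA removes
zero-variance gene rows, centers columns, and takes the SVD; each
component's sign is fixed by making its largest-magnitude loading positive.
When loadings tie in magnitude exactly (symmetric toy configurations) the
tie is broken by float comparison — deterministic, but not predictable by
hand, which is why oracle tests compare the leading axis up to sign.

Preranked GSEA uses the classic weighted Kolmogorov–Smirnov running sum:
genes ordered by descending score, hits incremented by |score|¹ normalized
to the in-set total, misses decremented by 1/(N − k); ES is the deviation
of maximum magnitude. The exponent-0 (unweighted) variant is available via
`weight=0` and is invariant to monotone rescaling of the ranking. The null
is gene-set permutation: random same-size sets, n = 10,000 by default, with
an exhaustive enumeration mode for tiny universes. NES divides ES by the
mean |null ES| of matching sign; p comes from the matching-sign null with
the add-one estimator; FDR is BH across the tested sets. This deliberately
replaces an adaptive multilevel p-refinement scheme used by a popular fast
implementation — the add-one permutation p is simpler, unbiased-
conservative, and exactly testable against enumeration; the cost is a p
floor of 1/(n+1). A set covering the whole ranking has no misses and is
reported as degenerate (ES 0) with a warning.

Overrepresentation of annotation terms is the one-sided hypergeometric tail
P(X ≥ overlap) after intersecting terms with the declared universe, BH
across terms. Distribution comparisons between a designated gene group and
non-targets use the two-sided Wilcoxon rank-sum test — a deliberate choice
of a rank test to match the rank-based scores being compared. The
integration stage combines NES × −log₁₀(FDR) per factor (selectable:
plain NES or ES) and Spearman-correlates it against promoter-proximal
signal over the inner join of factors, requiring ≥4 shared factors.

## Synthetic data

Rank correlations are planted with a Gaussian copula: latent bivariate
normal with Pearson r = 2·sin(π·ρ_s/6), whose Spearman image is exactly the
target ρ_s, pushed through monotone maps — exponentiation for expression
(positive, continuous, RSEM-like scale) and round(exp(·)) for accessibility
counts (non-negative integers, overdispersed, Spearman-preserving up to
rounding ties). |ρ| = 1 with zero extra noise gives exact (anti)monotone
copies; requesting |ρ| = 1 together with added rank noise is rejected as
unsatisfiable. Planted peak enrichment places each of a fold-f factor's
peaks so that it overlaps the significant-bin set with probability
min(1, f·q), where q is the probability for a uniformly placed peak — fold
1 is therefore *exactly* the uniform background, and impossible folds clamp
with a warning. Target sets share a configurable fraction of the focal
gene's neighborhood (focal + planted regulators) for planted factors and
are uniform draws otherwise, so zero co-membership reproduces the
hypergeometric overlap null.

One global seed expands into named per-stage substreams
(`SeedSequence([seed, crc32(stage)])`), so each stage is reproducible in
isolation and the whole pipeline is byte-deterministic.

What the generator does **not** emulate: RSEM/ATAC noise families
(library-size effects, GC bias, zero inflation), linkage between
neighboring bins, correlated peak experiments within a factor, or cohort
batch structure. Passing recovery tests therefore demonstrate that the
statistics recover the *rank-correlation and overlap structure* they target
at realistic sizes — not that they are robust to every artifact of real
compendia.

## Study sizes

Defaults mirror the survey's scale: a 1.05 Mb window in 100 bp bins
(10,500 bins) with 409 accessibility samples; recovery tests use 8 cohorts
× 100 samples × 2,000 genes with regulators planted at |ρ| = 0.6, 20 bins
planted at ρ = 0.8, and factor studies of 100 (null calibration) or 20
factors with a fold-3 planted factor. The packaged smoke study
(`fixture_config`) scales everything to seconds — 100 kb window, 3 cohorts
× 50 × 300 genes, 8 factors — and is used only for contract checks
(determinism, format round-trips), never for power claims. The numbered
analysis drivers use an intermediate study (6 cohorts × 80 × 800 genes,
2,000 bins) chosen so each driver finishes in seconds while every planted
signal remains comfortably detectable.

## Known limitations

- The permutation background for expected overlap is single-interval;
  multi-interval (e.g. mappability-masked) backgrounds would need the
  relocation step generalized.
- GSEA p-values are floored at 1/(n_perm+1); deeply significant sets are
  distinguished by NES, not p.
- The q-value–style peak-inclusion filter is a plain score threshold at
  import time; no per-experiment FDR modeling is attempted.
- Bin-level Spearman p uses the t approximation, adequate at the sample
  sizes surveyed (n ≥ 4 enforced, hundreds typical) but approximate for
  tiny n or heavy ties.
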