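# Methods

## Weighted methylation and nonconversion correction

Every level in this package is a *weighted* methylation level: methylated
basecalls pooled over all reference cytosines of a context within a scope,
divided by the pooled total basecalls. Pooling counts (rather than
averaging per-site levels) weights each cytosine by its coverage and makes
the level of a union of disjoint regions equal to count-pooling of the
parts — a property the test suite asserts. The CH super-context is never
stored; it is the query-time union of CA, CC and CT, again pooled at the
count level. Its nonconversion rate is likewise the pooled spike-in rate
over the three sub-contexts.

Incomplete bisulfite conversion makes a fraction of unmethylated cytosines
read as methylated. We estimate this rate per context from a fully
unmethylated spike-in genome as its apparent methylation, and subtract it
from each raw level, clipping at zero. Under the additive observation
model used by the generator,

    p_obs = p_true + (1 − p_true) · nc,

the expectation of the corrected level is p_true·(1 − nc): subtraction
leaves a deterministic shortfall of p_true·nc (≈ 3·10⁻⁴ at p = 0.053,
nc = 0.005). The exact unbiased correction would divide by (1 − nc); we
keep plain subtraction because it is the field's standard practice, and
the tests account for the analytic shortfall explicitly. The corrected
estimator's standard error pools two binomial terms — sample calls and
spike-in calls — and recovery tests use that pooled SE.

Zero-coverage scopes yield *missing* values, never 0: a gene without calls
is excluded from matrices (below a per-feature floor of 20 calls by
default), not zero-filled, since 0 is a meaningful methylation level.

## Synthetic study design

The generator emulates the data structure of a WGBS panel over neuronal
differentiation: per-cytosine count tables for ESC, NPC, in vitro neuron,
in vivo neuron, glia and fetal cortex samples, plus a lambda-like
spike-in. Per site, depth ~ Poisson(30) (the experiment's average
coverage) and methylated counts ~ Binomial(depth, p_obs) with
nonconversion 0.005.

Sites are laid out at 0.12 sites/bp with context shares CG 0.16, CA 0.378,
CC 0.21, CT 0.252; the layout, drawn once per (seed, chromosome), is
shared by all samples so that sites align across groups. Each random
stream is seeded from the master seed plus stable label hashes of
(purpose, sample, chromosome), so output does not depend on generation
order.

Group set-points mirror the measured global levels of the panel: mCA/CA
0.053 (in vitro neuron, day 38), 0.045 (adult cortical neurons), 0.0125
(ESC), 0.008 (NPC); glia and fetal mCH below 0.001; gene-body mCG 0.73 to
0.86 with CpG islands at 0.08 to 0.15. A group profile stores the pooled
CH level and the CA share of methylated CH calls; per-sub-context
probabilities are derived from the layout's context shares. Within a
feature class and group, site methylation is homogeneous by default (no
overdispersion), so analytic binomial standard errors hold and the
recovery tests can use 3-SE bands.

Regional structure is off by default and enabled per scenario: a shared
per-100 kb-block pattern (additive for CG, amplitude 0.05; multiplicative
for CH, amplitude 0.4; block effects are clipped at ±2 SD so their mean is
exactly preserved), plus an optional group-private CG regional deviation
(SD 0.05 for the in vitro neuron in the clustering scenario). The private
deviation is what separates the in vitro sample in CG-bin clustering:
rank correlations are invariant to any uniform offset, so a *global*
hypermethylation alone cannot reproduce the observed tree — the separation
is carried by regionally varying hypermethylation, which is also what the
real data show.

Planted DMRs shift p_true by a chosen delta inside selected regions of one
sample and redraw the counts at unchanged depths; truth regions are picked
as runs of consecutive context sites dense enough (> 3.5 Cs/100 bp by
construction) to satisfy the DMR density definition — planting a "DMR"
that the definition itself excludes would make recall meaningless.

Expression is drawn as log(TPM+1) = a + b·mCH + N(0, sd) with defaults
a = 3, b = −30, sd = 0.5, giving TPM in a realistic 0–20 range over the
mCH range 0–0.06 and a clearly negative but noisy rank correlation.

What the generator does *not* emulate: read-level errors and mapping
artefacts, strand- or sequence-composition biases, within-group replicate
variance, realistic CGI/gene architecture, or spatial autocorrelation
below the block scale. Passing tests therefore validate the *computations*
(estimators, filters, calibrations) under a controlled model, not the
biological conclusions one would draw from real data.

## Differential analysis choices

Per-gene deltas are in vitro minus in vivo over the full TSS→TES span
(whether "gene body" includes introns only is ambiguous; the full span is
used). Hyper/hypo fractions use genes with non-missing levels in both
samples as the denominator. Heatmap ordering is descending delta with
lexicographic tie-breaks, making output order-deterministic.

Bin clustering uses corrected levels in 100 kb tiling bins (chrX/Y
excluded; the last bin of a chromosome may be short), pairwise Spearman ρ
over the bins unmasked in both samples of each pair (pairwise rather than
global masking maximises usable bins), distance 1 − ρ, and average
linkage. The linkage choice is a declared default (the correlation is
standard; the linkage is not dictated by anything upstream) and is
deterministic and invariant to sample/bin input order.

## DMR definition

The built-in candidate caller merges runs of consecutive shared sites
whose per-site level difference has the same sign and magnitude ≥ 0.1,
with inter-site gaps ≤ 500 bp and ≥ 3 sites per run. It is deliberately
simple plumbing: any external segmentation can be supplied as a BED and
passed through the same filters. The filters carry the scientific
definition: ≥ 3 cytosines each with coverage ≥ 5 in *both* samples (the
strictest reading of "minimum coverage of 5 per sample"; a region-mean
alternative is available behind `coverage_mode="region_mean"`), strictly
more than 3 cytosines per 100 bp of the retained-site span, and |pooled
delta| ≥ 0.2. Tightening any parameter can only shrink the output
(monotonicity is tested).

Feature enrichment assigns each DMR to the class containing its midpoint —
a partition, avoiding double counting where classes overlap — and divides
observed counts by size-proportional expectations over merged class
intervals. Under uniformly random midpoints the enrichment of every class
is 1 in expectation; the test suite verifies this calibration over 1000
randomisations.

## Similarity score and GSEA

The per-gene similarity score is s₁ = |y − 1| with y = |m_invitro −
m_invivo| (the sign convention of y is immaterial after the absolute
value; levels lie in [0, 1] so y does too), and s₂ = |mean(neuron levels)
− mean(glia, fetal levels)|. The combination is the arithmetic mean
followed by a min-max rescale over scored genes (a "divide by 2 only"
variant is available via `scale="none"`; the rescale choice is recorded in
the output). The score is symmetric in the two neuron samples and in the
two non-neuron samples. If every gene has the same combined score the
rescale is degenerate and all genes are assigned 0.5 with a warning.

GSEA is the classic weighted Kolmogorov–Smirnov statistic with weight
exponent 1 (hits weighted by |ranking score|; a set whose scores are all
zero falls back to equal hit weights). The ES is computed from hit
positions in O(|set|) and matches an independent full-walk implementation
to 1e-12 and the R fgsea `calcGseaStat` reference values frozen in the
tests. The permutation null draws random same-size gene sets from the
ranked list, shared across sets of equal size within one call. NES divides
ES by the mean |null ES| of matching sign; the p-value is add-one within
the matching sign class, so it can never be zero and its floor is
1/(1 + same-sign null count). The multilevel p-value refinement used by
fgsea for very small p is intentionally not reproduced: downstream
filtering only needs p < 0.05, far above permutation resolution.

## Expression integration

The sliding-window profile orders genes by descending TPM (ties broken by
gene name, making the profile invariant to input order), averages gene-body
mCH and log10(TPM+1) in 20-gene windows at step 1, and reports the
Spearman ρ of the *unwindowed* pairs as the headline statistic — rank
correlation is robust to the unknown axis transform. A linear fit on the
windowed means is emitted and labelled as such. Enhancer deltas use
corrected CG levels with a 20-call floor per enhancer and sample; flagged
hypermethylation is delta > 0.5 among covered enhancers. The TF panel
normalises each gene's expression and mCH by the larger of the two
samples' values, so the larger sample reads exactly 1; a pair with maximum
0 is missing, mirroring "no reads found".

## Problem sizes and numerical conventions

Default synthetic genomes are 2 × 400 kb (~96,000 sites per sample), which
at 30× yields ~1.1 million CA calls — enough that 3-SE recovery bands on
mCA are below 10⁻³ while every pipeline stage completes in seconds. Tests
use 1 × 150 kb genomes. All coordinates are 0-based half-open internally;
cytosine-report files are 1-based and converted at the I/O boundary. Ties
are always broken lexicographically by name. Levels with no supporting
calls are NaN with an attached reason, and every sort is a stable
mergesort so that equal keys preserve a documented order.

## Known limitations

* The subtraction correction's p·nc shortfall is documented but not
  removed; at nc = 0.005 it is negligible relative to biological effect
  sizes but visible at very large call counts.
* The built-in DMR candidate caller has no statistical model of spatial
  autocorrelation; it is a stand-in whose output is only as good as the
  downstream filters, and real analyses should feed an external
  segmentation through `filter_dmrs`.
* Similarity-score rescaling ("scaled to values between 0 and 1") admits
  more than one reading; min-max is the default and the alternative is one
  flag away.
* The generator's homogeneous-within-class methylation understates real
  biological variance; calibration results on synthetic data are
  best-case.
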