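# Methods

## The problem

A gene signature — here the motivating example is a set of 35 type I
interferon (IFN)-regulated genes measured in whole blood — can be "active"
in some patients and quiescent in others. The common way to score a sample
is the mean log2 expression of the signature genes against a
healthy-control threshold. `cabsig` implements an alternative that scores
*profile shape* rather than level: samples whose signature is active are
not only brighter, their signature genes are induced in a characteristic
gene-by-gene pattern, and the genes are more strongly co-expressed across
samples. The toolkit provides the shape-based classifier, the co-expression
profiling that motivates it, the classical mean score for comparison, and a
paired monitoring workflow for treatment studies.

## The classifier (CABS)

Given a training cohort and a signature of M genes:

1. **Prototype construction.** The cohort is split into two groups —
   supplied by the user, or bootstrapped by agglomerative clustering of the
   samples on their M-gene profiles. Each group i is summarized by its
   per-gene median expression vector `G_i = (G_i1, ..., G_iM)`. The group
   with the larger mean signature expression is the "high" prototype.
2. **Decision variable.** For a sample profile x, `COR_high = r(x, G_high)`
   and `COR_low = r(x, G_low)` are Pearson correlations across the M genes;
   the decision variable is `d = COR_high / COR_low`.
3. **Call.** The sample is "high" iff `COR_high >= COR_low`. When
   `COR_low > 0` this is exactly `d >= 1`; when `COR_low <= 0` the ratio
   changes sign and the two rules disagree, so the correlation comparison
   governs (it is total and sign-safe), while d is still reported for
   continuity of plots and monitoring. A tie (`d = 1`) is called high.
   `COR_low = 0` yields a signed-infinity d sentinel.

Prototypes are fit once and serialized to JSON; classification of further
cohorts never refits them. Pearson is invariant to affine maps of the
profile, so the call depends only on profile shape, not on level or scale.

### Bootstrap clustering

The clustering behind the initial high/low split is not fully determined by
the original description (a GUI tool's defaults), so it is pinned here and
exposed as configuration. Default: Ward linkage on per-sample z-scored
profiles. For standardized profiles, squared Euclidean distance is
proportional to `1 − r`, so this clusters in the same correlation geometry
the classifier scores in while keeping Ward's tendency to balanced
clusters; in simulation it recovers planted groups where average linkage on
`1 − r` splits off singletons and raw-profile Ward partially clusters by
overall level. `linkage_method="average", metric="correlation"` (classic
1 − Pearson/average) and `metric="euclidean"` (level-sensitive) are
available. Cluster ties are resolved deterministically by input order; a
singleton cluster triggers a warning, not an error.

## Filtering

Before heterogeneity analysis, genes are filtered in two stages, in this
order:

1. **Intensity**: drop genes with median log2 expression strictly below a
   threshold (default 6.0 ≈ twice a typical array background; exposed as a
   parameter, not estimated).
2. **Variability**: drop genes whose MAD across samples is strictly below
   the median of the MADs of the stage-1 survivors.

"Strictly below" means equality survives in both stages, so the MAD stage
always retains at least half of its input genes. MAD is the raw
`median(|x − median(x)|)` — no 1.4826 consistency factor, which would
cancel against the cutoff anyway. Medians of even-length sets are the mean
of the central pair.

## Correlation profiling

Within a sample group, every unordered pair of signature genes gets a
Pearson correlation across the group's samples. A gene's *correlation
index* is the median of its M−1 correlations with the other genes; the
group's `r_median` is the median of the M indexes (the median of the
off-diagonal pairwise values is also reported, since the two readings of a
group-level "median correlation" differ slightly). Two groups are compared
with a two-sided Mann–Whitney U on the off-diagonal pairwise correlations
by default, or on the indexes (`unit="index"`). The pairwise values share
samples and are mutually dependent, so these p-values are descriptive; no
Fisher z-transform is applied anywhere, and groups need ≥ 3 samples (with 2
every correlation is ±1).

## Mean score and comparison

The classical score is the arithmetic mean of the signature-gene log2
values. The activation threshold is `mean + 1.96 · SD` of a healthy
reference cohort's scores (sample SD, n−1); a score exactly at the
threshold is called high. The head-to-head comparison reports the Spearman
rank correlation between d and the score (exact permutation p for n ≤ 9,
t approximation above, average ranks for ties), the 2×2 agreement table,
and the discordant fraction.

## Paired monitoring

Patients classified at baseline are re-evaluated after treatment within
baseline strata (the stratum is fixed at the baseline call even if the call
flips). The change `d_after − d_before` is tested with a two-sided Wilcoxon
signed-rank test: zeros dropped before ranking (Wilcoxon's original
procedure — at small n this choice changes p and is therefore pinned), the
exact null by full enumeration of the 2^n sign assignments (midranks, so
tied magnitudes are handled) for n ≤ 12 nonzero differences, and a
tie-corrected normal approximation without continuity correction above.
An all-zero stratum is reported as direction "none" with p = 1; the
low-level test distinguishes this case by raising. The monitored quantity
is d itself, not the raw correlations.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes. For
sample s in group g and signature gene j:

    x_js = b_j + shift_g · w_j + (λ_g + δ_j) · f_s + ε_js

- `f_s ~ N(0,1)` — one latent activation factor per sample, shared by all
  signature genes of the group; this is what creates within-group
  co-expression. `λ_g = σ·sqrt(ρ/(1−ρ))` gives every gene pair correlation
  exactly ρ when δ = 0.
- `b_j ~ N(baseline_mean, baseline_sd²)` — gene-specific baseline level
  (defaults 8.0 and 1.0 log2 units, typical of normalized array data).
- `w_j` — gene-specific induction weights, uniform on
  `[1−s, 1+s]` (default s = 1) normalized to mean exactly 1, scaling the
  group's activation shift `shift_g` (reference designs use +2 log2 for
  activated groups). Real signature genes sit at different levels and are
  induced to different degrees; without `b_j` and `w_j` the two prototypes
  would be near-constant and near-collinear and shape-based classification
  would carry no information, so these are structural, not cosmetic.
- `δ_j ~ N(0, loading_jitter²)` (default 0.1) — gene-to-gene loading
  heterogeneity, giving the per-gene correlation indexes realistic spread.
  Jitter biases the mean pairwise correlation by O(jitter²) (~ −0.01 at the
  default), so closed-form recovery checks run at jitter 0.
- Background genes are independent `N(b_j, noise_sd²)`.

Gene-level draws come from substreams keyed by `gene_seed` (default: the
main seed), so cohorts generated with the same `gene_seed` share gene
identities — required whenever prototypes fitted on one cohort classify
another. Reference design points: ρ = 0.63 (activated) vs 0.33 (quiescent),
M = 35, with {0.27, 0.44, 0.68} as further profiling points. Sample-size
defaults follow the simulation scale used throughout the tests (50+50
cohorts; 2000 samples for closed-form checks; 11- and 22-pair monitoring
designs, the strata sizes of a realistic treatment sub-study).

`paired_cohort` regenerates the factor and noise under per-group
(ρ, shift) changes while keeping gene effects and pairing metadata. The
canonical designed treatment effect is full reversion of the activated
stratum to the quiescent state (ρ 0.63→0.33, shift +2→0): both after-state
values are themselves reference design points. Before/after factors are
drawn independently (no within-patient persistence is modeled).

What the generator does *not* emulate: count-based (RNA-seq) noise,
batch effects, probe-level artifacts, multiple overlapping signatures,
patient-specific activation trajectories. Tests passing on this generator
show that the algorithms recover the structure they assume; they do not
show robustness to real-data violations of those assumptions.

## Numerical and degenerate-input policy

- Pearson denominators of zero (constant vectors) raise immediately, with
  the offending sample or gene named; correlations are clipped into
  [−1, 1] and pairwise matrices symmetrized before medians are taken.
- Matrix I/O parses floats exactly (round-trip at full precision); missing
  values are rejected unless a drop-genes policy is requested, because
  every downstream statistic (Pearson, median, MAD) degrades silently
  under imputation.
- Filters: strict-< removal; see above for tie policy.
- Exact Wilcoxon enumeration uses integer convolution over doubled
  midranks; p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).
- All simulation entry points take explicit seeds; identical seeds give
  byte-identical CLI outputs.

## Known limitations

- The decision variable d is undefined in ratio form when `COR_low ≤ 0`;
  downstream plots treat the comparison-based call as authoritative.
- Correlation-level p-values ignore the dependence between pairwise
  correlations sharing samples.
- The bootstrap split assumes exactly two states (k = 2); graded or
  multi-signature activation is out of scope.
- Row IDs are opaque: probe-set-to-gene mapping, normalization and batch
  correction are upstream of this toolkit.
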