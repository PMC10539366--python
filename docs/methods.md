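# Methods

This note documents the statistical models behind `immffl`, the default
parameters and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make runs exactly
reproducible.

## Synthetic cohort model

The generator emulates a bulk RNA-seq tumor/normal cohort:

- **Counts.** Gamma–Poisson (negative binomial): a feature's baseline mean
  is log-normal across features (`log2 mean ~ N(5, 1.5)`), and counts have
  variance `mu + dispersion * mu^2` with `dispersion = 0.2` (inverse size),
  a typical bulk RNA-seq overdispersion. Planted differential features have
  the tumor-group mean multiplied by `2^(±de_log2fc)` with alternating sign
  so both tails are always populated; the default effect is
  `|log2FC| = 3` against the calling threshold of 2.
- **Cohort shape.** 120 tumor / 12 normal samples by default, mirroring the
  strong tumor/normal imbalance of public tumor cohorts at reduced scale so
  the differential machinery is exercised under imbalance. Batches cycle
  over samples; batches ≥ 2 receive a +0.5 log2 location shift, which the
  location-only batch centering removes exactly.
- **Networks.** A clique over the hub genes is planted in the PPI table at
  confidence > 0.9 on top of uniform [0.4, 0.95] background edges.
  The regulatory table carries each planted FFL's three edges plus decoy
  rows that exercise every filter (non-significant TF evidence,
  non-differential miRNA sources, targets outside the hub set). Decoy
  miRNAs that boost node degrees target either the TF or the mRNA of a
  planted triple, never both, so no unplanned loop closes and the first
  planted triple is deterministically the top-degree motif.
- **Infiltration.** Targeted cell-type scores are Gaussian-copula
  transforms of the named gene's expression ranks. The latent correlation
  is pre-warped with `2 sin(pi*rho/6)` so the *realized Spearman*
  correlation matches the requested `rho`; fractions are `0.35 * Phi(z)`,
  bounded in [0, 1]; purity is negatively coupled to total infiltration.
  The default planted `rho = 0.35` is in the range of published
  gene-vs-infiltration correlations for chemokine receptors.
- **Survival.** Times are exponential with hazard
  `lambda0 * exp(beta * z)` where `z` is the marker's standardized log2
  expression and `lambda0 = log(2)/40` months. Censoring times are uniform
  on `[0, c_max]`, independent of survival, with `c_max` calibrated by root
  finding so the *expected* censored fraction equals `censor_rate`
  (default 0.3) — the simplest mechanism satisfying the non-informative
  censoring assumed by Kaplan–Meier.

What the generator does **not** model: sequencing-depth variation, GC and
length bias, isoform structure, read-level data, correlated genes
(co-expression modules), non-exponential baseline hazards, or the
deconvolution noise of real infiltration estimates. Passing recovery tests
therefore demonstrate correctness of the algorithms under a clean generative
model, not robustness to every artifact of real cohorts. One such artifact
*is* present by construction: CPM normalization is compositional, so when a
large fraction of features is differential the estimated fold changes
shrink toward zero (visible already at 10–17% planted features). The
default configurations keep the planted fraction at 10%.

## Differential expression

Per feature, the two-group contrast uses the pooled residual variance
`s^2` with `df = n1 + n2 - 2`. The empirical-Bayes prior is the scaled-F
model: `s^2 ~ s0^2 * F(df, d0)`. Hyperparameters are fitted by method of
moments on `log s^2`: the excess of `var(log s^2)` over the trigamma
variance implied by the residual chi-square alone determines `d0` (via a
Newton inversion of the trigamma function); no excess spread gives
`d0 = inf` (full shrinkage). The moderated statistic is
`t = log2FC / sqrt(s_tilde^2 (1/n1 + 1/n2))` on `df + d0` degrees of
freedom; `d0 = 0` reduces exactly to the classic pooled t, which is the
oracle equivalence checked in the tests. Array weights, mean-variance
trends and robust fitting are deliberately out of scope — the plain
two-group moderated t is the whole model. Calls use strict inequalities
(`|log2FC| > 2`, BH-adjusted `p < 1e-4`) because the thresholds are
defined as strict bounds.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
`P(X >= k)` with the universe defined as all features surviving
preprocessing (not the genome) — configurable, but the surviving-feature
universe is the honest null for a cohort-derived query. BH adjustment is
applied within one namespace (BP, MF, CC, pathway) at a time, never pooled
across namespaces, matching how per-namespace term counts are reported.

## MCODE-style clustering

Vertex weight = `k * density` of the highest k-core of the closed
neighborhood. Complexes grow breadth-first from the heaviest unassigned
seed, admitting neighbors with weight ≥ `(1 - node_score_cutoff) *` seed
weight; each vertex belongs to at most one complex. The haircut iterates to
a fixed point (removing members whose in-complex degree falls below the
degree cutoff can expose new low-degree members); post-haircut singletons
are dropped. Parameters are fixed at the conventional defaults (node score
cutoff 0.2, degree cutoff 2, haircut on, fluff off). Ties — in seed order
and in the final ranking (score, then size, then lexicographically smallest
member tuple) — are broken deterministically, so output is independent of
edge insertion order. Complex score is `density * member count`.

## FFL network

Node classes (miRNA, TF, mRNA) are inferred from edge types and must be
disjoint; a conflict is a hard error because a class-ambiguous node would
silently corrupt motif enumeration. TF→mRNA evidence is retained at
`p <= 0.001` (inclusive, as the cutoff is defined with ≤). Degree counts
every incident edge once regardless of direction or type. "Highest-order"
motif ranking means maximal summed degree of the motif's three nodes;
per-node maximum degree is available by sorting the exported motif table
differently. miRNA-family restriction is a plain id list — no seed-sequence
inference.

The printed per-class average degrees in the source analysis are mutually
inconsistent with its printed class sizes (all three are consistent with
division by 8 rather than by 7/4/5); `network_stats` divides class-incident
degree sums by the true class size and treats the sum identities
(nodes = 7+4+5 = 16, edges = 12+10+15 = 37) as the normative check.

## Association statistics

AUC is the Mann–Whitney statistic with half credit for ties; the 95% CI is
DeLong's placement-variance interval, clamped to [0, 1] (the clamp is why
printed intervals can end exactly at 1). Orientation is never flipped: a
marker lower in tumors reports AUC < 0.5. Partial Spearman is
rank-transform-then-partial-Pearson with `n - 3` df, the convention used by
purity-adjusted infiltration analyses; a constant covariate degrades to the
plain Spearman with an explicit flag. The two-group t is the
pooled-variance Student test (Welch is available via
`scipy.stats.ttest_ind(equal_var=False)` upstream but the pooled form is
the default to match the reported convention); a fully degenerate input
(both groups constant and equal) returns `p = 1` rather than NaN.

## Survival

Dichotomization defaults to the median split (ties to "low"); the
best-cutoff scan over the interquartile range is offered but its minimal
log-rank p is selection-biased and flagged as such — it must not be quoted
as a test result. The log-rank statistic accumulates a 2×2 table per
distinct event time (tied events share one table) with the hypergeometric
variance; the hazard ratio is Mantel–Haenszel,
`(O_low/E_low)/(O_high/E_high)`, oriented so HR > 1 means worse survival
with low expression, with Wald CI `exp(log HR ± 1.96·sqrt(1/E_low +
1/E_high))`. A proportional-hazards regression is deliberately not
implemented: the Mantel–Haenszel estimate is fully specified by the
dichotomized data and is the quantity the KM-style comparisons need. A
Cox fit on the same data can differ slightly.

## Problem sizes and tolerances

Recovery and calibration checks run at fixed seeds on: 2,000 features with
200 planted at |log2FC| = 3 and n = 30/group (sensitivity ≥ 0.9, false
discovery proportion ≤ 0.05); 5,000 variances for hyperparameter recovery
(d0 = 4 recovered within [2.5, 7]); n = 400 samples for infiltration
correlation (±0.1); n = 500 vs an n = 20,000 oracle for the hazard ratio
(within 15%); 10,000 null features for type-I calibration ([0.04, 0.06] at
alpha 0.05) and n = 1,000 for the null HR ([0.8, 1.25]). Oracle
equivalences (FFL enumeration, AUC, hypergeometric tail, log-rank
chi-square, unmoderated t) are exact to 1e-10–1e-12 on ≥ 100 random small
instances each. Byte-level determinism is enforced: all randomness flows
from `numpy.random.default_rng([stream, seed])` with a distinct stream tag
per generator, floats are rounded before writing, and JSON is written with
sorted keys.

## Known limitations

- CPM+log2 is the only normalization; compositional bias is documented
  above but not corrected (no TMM/median-of-ratios).
- The two-group contrast carries no covariates (no sex/batch terms in the
  design; batch is handled by prior centering only).
- Enrichment does no ontology-graph propagation or redundancy trimming.
- The PPI confidence score is treated as an opaque [0, 1] weight.
- Survival supports right censoring only, with no covariate adjustment.
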