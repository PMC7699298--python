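# Methods

This note documents the statistical procedures implemented in `mirtrend`,
the assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the package's known
limitations. Every number quoted here is computed by the test suite or by
`scripts/acceptance.py`; none is asserted from outside the code.

## The trend screen

**Design.** Cells are treated with a miRNA mimic, an inhibitor, or matched
controls, in two contexts: ordinary monolayer culture and colonosphere
(CSC-enriched) culture, in triplicate. The treatments define an ordered
factor on the miRNA-activity axis: inhibitor < control < mimic. A four-arm
design (separate mimic and inhibitor controls) is accepted; the two control
arms are tied at the middle activity level, which for a rank statistic is
identical to pooling them.

**Direction.** Each gene is classified as *promoted* (expression rises with
miRNA activity) or *inhibited* from the sign of the Kendall rank correlation
between the treatment codes and expression, pooled across contexts. An exact
zero correlation breaks toward "promoted" (documented tie-break); a gene
with no expression variation is flagged degenerate and excluded.

**Test.** The Jonckheere–Terpstra statistic sums Mann–Whitney counts over
ordered group pairs, with cross-group ties contributing ½ to each side so
that JT(order) + JT(reversed) equals the number of cross-group pairs
exactly. Significance is assessed one-sided in the fitted direction by
permutation of treatment labels: the empirical p is (b+1)/(B+1) where b is
the number of permutations with JT as or more extreme, B = 10,000 by
default. For small designs an exhaustive mode enumerates all
distinguishable assignments (e.g. 90 for three groups of two) and returns
the exact fraction. Monte-Carlo draws are taken after canonicalising sample
order within (stratum, group), which makes p-values bitwise invariant to
sample order within groups, not merely invariant in distribution.

Fitting the direction and testing on the same data makes the per-gene test
one-sided *post hoc*: a null gene's chance of a small p in the fitted
direction is roughly doubled. The screen's headline call ("consistent with
the working hypothesis") requires agreement of the fitted direction in
*both* contexts plus per-context significance, which suppresses this
selection effect multiplicatively; the per-gene operating characteristics
below are therefore quoted for a fixed direction.

**Combined transition trend.** Whether a gene is *progressively* regulated
from monolayer to CSC is tested on six ordered groups
(monolayer-inhibitor … CSC-mimic), one-sided increasing for promoted genes
and decreasing for inhibited ones on the same layout. The permutation null
shuffles labels across contexts: the cross-context pair count of JT is
invariant under within-context shuffles, so a context-stratified null
reduces the six-group test exactly to the pooled within-context trend and
cannot see the transition at all (verified numerically: the stratified p is
identical for any context offset). A `stratify_contexts=True` option keeps
the blocked null for users who want a pure within-context combination. A
consequence of the unstratified null is that a context main effect aligned
with the trend *is* part of the signal — which is precisely what
"progressive regulation in the transition" means — so the combined p should
be read together with, not instead of, the per-context p-values.

**Multiple testing.** Three reporting modes: raw per-gene empirical p
(`none`), Benjamini–Hochberg over genes (`bh`, the default), and
Westfall–Young single-step max-T family-wise correction (`maxt`) in which
all genes share one permutation stream per test family and each gene's
standardized JT is compared with the permutation distribution of the
familywise maximum. The consistency call uses whichever mode is selected.

**Reproducibility.** Each gene draws its permutations from a child stream
derived from SHA-256 of `run_seed:gene_id`, so per-gene results are
independent of gene order and of which other genes are present.

**Operating characteristics** (computed by `tests/test_acceptance.py` and
`scripts/acceptance.py`; triplicates, noise σ = 0.5 log2 units): the fixed-
direction per-gene test on the combined layout has type-I error ≈ 0.044–0.048
at α = 0.05 over 2000 null genes (B = 1000); per-context detection power for
planted consistent trends of 1.5σ per step is ≈ 0.88–0.90. The joint
both-contexts consistency call has power ≈ 0.78 under the same conditions —
requiring two independent significant contexts is deliberately stricter.
Genes planted with opposite directions in the two contexts are never called
consistent (the call is conditioned on direction agreement, not on p-values
alone).

## Pooled count comparison

TMM scale factors follow the canonical defaults of the trimmed-mean-of-M-
values method: reference sample = the one whose 0.75-quantile library share
is closest to the mean; features with a zero count in either sample of a
pair are excluded; 30% of M values and 5% of A values trimmed from both
tails (by ranks); surviving M values averaged with inverse delta-method
variance weights; factors rescaled to geometric mean 1. The implementation
reproduces edgeR's `calcNormFactors(method="TMM")` to 10 significant digits
on a frozen fixture. Normalised values are counts per million of the
effective (factor-scaled) library. Because the variance weights depend on
depth, a pure depth change in one sample is absorbed only to first order
(factor shifts of ~0.2% at 4× depth; edgeR behaves identically).

Group fold changes are log2 ratios of group means, with no pseudocount: a
zero group mean raises an error rather than silently distorting the
worked examples (pool counts in scope are large). Worked-example fold
changes use raw mode because the published pool table prints raw average
copy numbers. Tests are the pooled-variance Student t (Welch behind a
flag) and one-way ANOVA, with a documented degenerate-limit convention
(p = 1 for identical groups, p = 0 for zero within-variance with distinct
means). BH adjustment is delegated to `statsmodels.stats.multitest`. The
stool abundance filter keeps a feature iff its median count strictly
exceeds 20 in at least one group.

## qPCR relative quantification

Replicates are averaged per (sample, assay) first; ΔCt is the target's mean
Ct minus the arithmetic mean of the reference assays' Ct means (equivalent
to a geometric mean of linear quantities, matching mean-expression-value
normalisation with several reference miRNAs); ΔΔCt subtracts the calibrator
condition, FC = 2^−ΔΔCt, so the calibrator has FC 1 by construction and any
global Ct shift cancels. Group comparisons are unpaired Student t-tests on
per-sample ΔCt values — ΔCt is approximately normal, whereas fold changes
are log-normal. Efficiency-corrected (standard-curve) quantification is out
of scope.

## Meta-analysis

Per-study effects are Hedges' g: the pooled-SD standardized mean difference
with bias correction J = 1 − 3/(4·df − 1) and variance
J²((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))). DerSimonian–Laird pooling computes Q
under fixed-effect weights, τ² = max(0, (Q − df)/C), random-effect weights
1/(vᵢ + τ²), and a 95% CI from the 1.96 normal quantile. The normal CI was
chosen over Knapp–Hartung to match the symmetric intervals this workflow
reports; a log-fold-change effect scale is available behind a flag. The
implementation agrees with `statsmodels.stats.meta_analysis.combine_effects`
to machine precision.

**Known limitation.** With few studies and substantial heterogeneity the
DL normal-quantile CI undercovers: at k = 5, τ² = 0.05 and ~100 per arm
(I² ≈ 0.7) the measured coverage of the generating SMD is ≈ 0.89–0.91, the
well-documented behaviour of this estimator. This is a property of the
method, reported honestly by the acceptance checks, not a defect of the
implementation (the identical estimates from statsmodels give the same
coverage).

## Enrichment

The weighted Kolmogorov–Smirnov running sum rises by |s|^w / Σ_set |s|^w at
set members and falls by 1/(N − |set|) elsewhere; ES is the signed maximum
deviation, bounded by 1, and the sum returns to zero after the last gene.
Exponent w = 1 is the standard weighting; w = 0 gives the classical
(unweighted) statistic — for a set occupying the top half of a 10-gene
ranking the running sum is 0.2, 0.4, …, 1.0, 0.8, …, 0, ES = 1. The default
null permutes set membership over the measured universe (uniform over all
C(N, k) memberships; the p-value matches exhaustive enumeration on small
universes); a sample-mode null scores sets against rankings rebuilt from
design permutations supplied by the screen (standardized combined-JT
scores), for users who want the null to respect inter-gene correlation.
Ranking metric from the screen: signed −log10 of the combined empirical p,
promoted positive. Normalized enrichment scores and FDR q-values across
set-size strata are out of scope; the workflow reports per-set ES and
empirical p.

## Synthetic data

All generators derive their stream from
`SeedSequence(seed, spawn_key=(stream_index,))` with a fixed index per
generator, return their planted truth, and are bitwise reproducible.

* **Pooled counts** — negative binomial with mean = library_size ×
  baseline-share × group effect and dispersion α (variance μ + αμ²),
  Poisson at α = 0. Defaults emulate the three-group × two-replicate pooled
  serum design: 200 miRNAs, 5×10⁶ expected counts per pool (the worked
  example's most abundant miRNA alone exceeds 10⁶ copies), α = 0.05
  (technical pool replicates), one planted down-trending miRNA with effects
  (1, 0.64, 0.55) — the log2 ratios −0.64 and −0.86 of the serum contrasts.
* **Expression** — additive Gaussian on the log2 scale: baselines uniform
  on [6, 12] (typical log2 intensity range), replicate noise σ = 0.5 log2
  units, per-step planted slopes in the flagged contexts; inconsistent
  genes reverse the slope in the second context; baselines are equal across
  contexts, so null genes carry no context main effect.
* **Ct tables** — reference assay at 20 cycles, target at 25, the treated
  condition shifted by `target_shift`, replicate noise σ = 0.1 cycles by
  default (0 gives the exact closed-form round trip FC = 2^−shift).
* **Meta summaries** — per-study true effects true_smd + N(0, τ²), each arm
  sampled as unit-variance normal data of size uniform on [80, 120] and
  summarised, so summaries carry realistic within-study sampling noise.

What the generators do **not** emulate: read-level artifacts (adapters,
mapping), probe-level microarray effects and their normalisation,
context-dependent baseline shifts for null genes, correlated genes, and
non-normal expression noise. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under its stated
model, not robustness to those real-data features.

## Problem sizes used by the checks

The acceptance checks use 2000 null genes and 500 planted genes at
B = 1000 permutations, 1000 meta-analysis repetitions, 1000 enrichment
null repetitions at B = 199, and exhaustive JT enumeration up to 8 samples
in 4 groups against B = 10,000 Monte-Carlo draws; these sizes give
Monte-Carlo standard errors comfortably below the decision margins of each
check while keeping the full run in the minutes range on one CPU.
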