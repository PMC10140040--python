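# Methods

## The model

`coaction` quantifies combinatorial associations between two gene sets —
tumor-associated process (TAP) genes and immune-checkpoint (ICP) genes —
and an immune-associated phenotype (IAP) measured per sample, using a
synergy-score formalism borrowed from drug-combination analysis.

For a gene pair (g1, g2) the cohort is stratified at each gene's median
expression into quadrants LL, LH, HL, HH (first letter: g1; a value **at or
below** the median is "L" — a deterministic tie rule that keeps quadrants
non-empty under skewed expression).  Because only ranks relative to the
median matter, stratification is invariant to any strictly increasing
transform of a gene's expression; whether the matrix is log-scale or linear
scale does not change the split.

Four configurations are evaluated, one per hypothesis about how the genes
relate to the phenotype (both activating, both deactivating, or mixed).
Each configuration fixes a baseline quadrant (both genes inactive), a
target quadrant (both active) and two single-effect quadrants:

| configuration | baseline | single 1 | single 2 | target |
|---|---|---|---|---|
| act_act       | LL | HL | LH | HH |
| deact_deact   | HH | LH | HL | LL |
| act_deact     | LH | HH | LL | HL |
| deact_act     | HL | LL | HH | LH |

Per quadrant the **median deviation** from baseline is

    M_n = med(x_n) − med(x_baseline),

computed on the scaled phenotype (below).  To suppress noise, M_n is set to
zero when |M_n| falls below its standard error
sem(M_n) = sqrt(sem_n² + sem_baseline²), where the standard error of a
median is estimated by the asymptotic normal-theory formula
sqrt(π/2)·sd/√n ≈ 1.2533·sd/√n (the equality case keeps M_n).  A
bootstrap estimator (200 resamples) is available via `sem_method="bootstrap"`
for sensitivity analysis.

The additive expectation for the target quadrant under independent action
is either the Highest Single Agent (HSA) reference, M_E = max(M1, M2), or
the Bliss independence reference, M_E = M1 + M2 − M1·M2.  On [0, 1]-scaled
phenotypes with nonnegative deviations HSA ≤ Bliss, so Bliss is the more
stringent reference.  The combined-action score is

    S = sign(M) · (M_target − M_E)   if M_target − M_E > 0, else 0,

where sign(M) is the direction of change from baseline shared by the
nonzero deviations.  Thresholded zeros are sign-neutral; if the nonzero
deviations disagree in sign the configuration has no consistent direction
and its score is **missing**.  If all three deviations are zero, S = 0 with
sign recorded as +1.  The configuration with the highest signed score wins;
ties resolve in the fixed order act_act, deact_deact, act_deact, deact_act
for reproducibility.  The definition is applied literally, so S can be
negative when sign = −1; no magnitude-based reinterpretation is applied and
downstream filters use |S| where a magnitude is needed.  Pair order is
immaterial: swapping (g1, g2) swaps the mixed configurations (act_deact ↔
deact_act) and leaves the winning score unchanged.

Pairs with any quadrant smaller than `min_group_size` (default 10 — medians
and their standard errors are unstable below that) are flagged unscorable.

## Phenotype scaling

Raw IAPs arrive in arbitrary units (expression of a marker gene, a
leukocyte fraction, a signature score).  To make scores comparable across
phenotypes each IAP is rescaled onto [0, 1] by the branch map

* identity, when all raw values already lie in [0, 1] (this branch takes
  precedence when the range is exactly filled);
* (tanh(x/σ) + 1)/2, when any raw value is negative;
* tanh(x/σ), for nonnegative unbounded values;

with σ the sample standard deviation (n−1 denominator; unspecified
upstream, chosen to match the estimator used for the median standard
error).  Missing values are excluded from σ and stay missing.  A constant
IAP has σ = 0 and is rejected as degenerate.

Signature-based IAPs are the mean over signature genes of each gene's
z-score of log2(x+1) expression across samples.  log2(x+1) is the standard
RNA-seq transform and is defined at zero; the mean/sd use the same n−1
convention, and a zero-variance gene contributes z = 0 rather than
polluting the mean.

## Statistical validation

**Robustness.** The score is recomputed on `n_boot` (default 1000)
sub-cohorts of ⌊coverage·n⌋ samples (default 70%) drawn without
replacement, re-stratifying at the subsample's own medians each time.

    R = RMSD(S_complete, S_partial) / |S_complete|

and a pair is robust when −log(R) > 0 (R < 1).  Resamples whose score is
missing are dropped; if fewer than half survive the pair is flagged
non-robust regardless of R.  Robustness is undefined for S = 0 or missing
(such pairs fail earlier).

**Significance.** The target quadrant's phenotype values are compared to
each of the other three quadrants.  The upstream description names a
Wilcoxon signed-rank test, but the quadrants contain *different* patients,
so a paired signed-rank statistic is undefined; the unpaired Wilcoxon
rank-sum (Mann–Whitney) test, two-sided, is used.  This is a deliberate,
documented reading.  The exact null distribution is used when both groups
have ≤ 25 tie-free observations, the normal approximation with tie
correction otherwise.  The reported p is the **maximum** of the three
comparisons — the target must differ from every other quadrant.  A fully
degenerate comparison (all values identical) reports p = 1.

**Specificity.** For each focal gene of a pair, `n_random` (default 1000)
partner genes are drawn uniformly without replacement from the supplied
matrix (the analysis "genome", excluding the pair itself) and scored
against the same IAP.  The gene's p-value is the add-one empirical tail
probability (1 + #{S_null ≥ S_obs}) / (1 + #valid), a conservative,
distribution-free operationalization of "no better than random partners";
the pair reports p_max, the larger of its two gene-level p-values.  Null
draws are a deterministic function of (seed, gene, IAP) and are cached and
shared across pairs containing the gene.  Fewer than 50 valid null scores
for either gene leaves specificity undefined and the pair fails.

**Staging and multiple testing.** Validation is staged: robustness first,
then significance with Benjamini–Hochberg correction over the robust set,
then specificity with BH over the robust-and-significant set, each filtered
at Q < `q_threshold` (default 0.1).  The staged BH denominators mean a pair
can receive a slightly smaller Q than it would under a single global
correction; this mirrors the sequential screening design and is asserted as
documented behavior in the test suite.  BH runs per IAP.

## Networks

Passing interactions with |S| ≥ `score_cutoff` become edges of a per-IAP
network.  A node is a (gene, state) record: state "high"/"low" is the side
of the median split the gene occupies in the winning configuration's target
quadrant, so one gene may appear as two nodes if it interacts in both
states (this two-node policy is this package's convention).  Edge direction
is "up"/"down" per the winning sign.  Edges whose unordered gene pair
appears in a user-supplied ligand-receptor table are flagged; the same
table can expand the input gene lists (partners of a TAP gene join the TAP
list, partners of an ICP gene the ICP list; partners missing from the
matrix are dropped with a warning).  Networks serialize as GraphML plus a
flat edge TSV; no layout or rendering is computed.

## Auxiliary statistics

*Partial correlation.*  Spearman partial correlation of a gene with one
cell-type fraction controlling for the remaining fractions: all columns are
rank-transformed, the two focal rank vectors are residualized on the
controls by least squares, and the Pearson correlation of residuals is
reported.  (Residualization and precision-matrix inversion are algebraically
identical here; the test suite cross-checks the result against an
independent reference implementation.)  p uses the t approximation with
n − 2 − k degrees of freedom and Bonferroni adjustment over the cell types
tested per gene.  Exactly collinear controls are dropped with a warning.
With no controls the statistic reduces to the ordinary Spearman correlation.

*Survival.*  Unweighted log-rank test (standard hypergeometric-variance
form, which handles ties) across the four quadrants, plus the two-group
target-vs-baseline test for a winning configuration.  Cohorts with zero
events warn and report p = 1.

## Synthetic cohorts

The generator produces the minimal structure the score assumes: per-gene
log-normal expression (per-gene baseline log-level drawn uniform on [1, 8],
shared log-sd `expression_log_sd` = 1 — the location shifts do not affect
median splits), independent across genes and samples, and one phenotype

    raw IAP = Σ_pairs [ e1·1(g1 active) + e2·1(g2 active)
                        + e_int·1(target quadrant) ] + N(0, noise_sd)

where "active" is each gene's own within-cohort median side under the
planted configuration.  Defaults are a 400-sample cohort, 300 null genes,
single effects 1.0 and interaction effect 3.0 in units of noise_sd = 1.
It deliberately omits tumor purity, cell-type mixture and gene–gene
correlation structure; passing recovery tests therefore demonstrates that
the estimator and its validation stack behave correctly under the model's
own assumptions, not that real cohorts satisfy those assumptions.

Everything is driven by `numpy.random.default_rng` (PCG64), so a cohort is
bit-for-bit reproducible from its config.

## Reference studies and problem sizes

`coaction.experiments` fixes two canned studies used by the acceptance
script: planted recovery (one act_act pair with interaction effect 3× the
noise sd among exactly 30 null pairs — 5 null TAPs × 6 null ICPs — with
n_boot = 200 resamples and n_random = 200 partner genes, 20 cohorts) and
null calibration (all-noise phenotype, 50 pairs, same validation settings,
20 cohorts).  These sizes keep a full study at a few minutes on one core
while leaving the empirical null and resampling distributions well
populated.

## Known limitations

* Mutation-status stratification is an extension point only; v1 stratifies
  by median expression.
* Negative-sign (deactivating-direction) scores follow the literal score
  definition; their magnitude semantics are weaker than for positive scores
  and they are flagged rather than reinterpreted.
* The exact rank-sum null is skipped in favor of the tie-corrected normal
  approximation whenever ties are present, even in small groups.
* The shipped ligand-receptor handling is a static table lookup; no live
  database access.
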