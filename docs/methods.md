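# Methods

## Design and scenarios

The study design is within-person, between-group: each subject attends two
sessions one week apart (one with an acute psychosocial stressor, one
without) with four blood draws per session at nominal 0, 75, 135 and 285
minutes from the first draw. A *test–retest scenario* names the subset of
draws whose agreement is being rated: four two-draw scenarios and one
four-draw scenario per session, plus `CrossSessionT1`, which pairs the two
sessions' baseline draws one week apart. In `CrossSessionT1` the two
occasions of the crossed model are the sessions' T1 draws themselves.

## Per-probe model and ICC

Each probe is fitted separately with

    y_it = β0 + β1·monocyte_it + β2·batch_i + ω_i + ν_t + ε_it,

a two-way *crossed* design: the occasion effect ν_t has one level per
timepoint (or per session for `CrossSessionT1`) and is shared by all
subjects, so session-wide shifts (circadian drift, a shared meal) load on
σ²_ν rather than on the residual. ICCs are absolute-agreement intraclass
correlations computed from the variance components:

    ICC(2,1) = σ²_ω / (σ²_ω + σ²_ν + σ²_ε),
    ICC(2,k) = k·σ²_ω / (k·σ²_ω + σ²_ν + σ²_ε),   k = number of occasions.

ICCs are computed on β-values (the methylation-fraction scale); M-values
(logit2 of β) are reserved for per-probe significance testing, where their
approximate homoscedasticity matters. "Adjusted" toggles only the monocyte
covariate; the batch (array) fixed effect is included in adjusted *and*
unadjusted fits, since every calculation controls for array assignment.

### Estimation

Variance components are estimated by REML. The residual variance is
profiled out analytically, leaving a search over the two non-negative
variance ratios λ_f = σ²_f/σ²_ε; non-negativity is enforced by squaring the
optimizer's parameters and ratios are capped at 1e8, so probes that fit
perfectly (residual → 0) terminate on an ICC ≈ 1 plateau instead of
diverging. The search is Nelder–Mead from a method-of-moments start plus a
flat restart, each polished by a simplex restart (relative function
tolerance 1e-12–1e-13). For the single-ratio random-intercept model the
search is a bounded Brent minimization.

On balanced designs the Gram matrices of the two random-effect factors
commute, so the model covariance is jointly diagonalized once per scenario
and every REML evaluation is O(n) — this is what makes per-probe fitting
at array scale feasible. Unbalanced designs (samples lost to quality
filters) fall back to dense Cholesky factorizations; both paths are
cross-checked against statsmodels MixedLM in the test suite.

Probes whose fit does not converge, or whose values have variance below
1e-12 across samples, are recorded with ICC 0 and `converged=False`,
which places them in the "<0.01" exclusion bin used everywhere downstream.

### Relationship to the ANOVA estimator

For a complete balanced grid without covariates the REML solution equals
the Shrout–Fleiss two-way mean-squares estimator whenever the latter is
interior (all components positive); both estimators ship in the package
and the equivalence is asserted to 1e-6–1e-3 in tests. When a mean square
falls below the residual mean square the ANOVA estimate goes negative
while constrained REML pins that component at zero and re-profiles the
rest — at such boundary points the two legitimately differ, and the tests
only require the REML component to sit at zero.

## Filtering

Order is fixed: first samples (mean detection p over probes strictly below
0.05), then probes (detection p strictly above 0.05 in strictly more than
10% of the retained samples), plus removal of chrX/chrY probes. β-values
of exactly 0 or 1 are clipped to [1e-6, 1−1e-6] before the M transform.
Normalization is an upstream concern; the pipeline consumes normalized
β-values through a pass-through hook.

## Descriptive statistics and comparisons

All descriptive analyses exclude probes with ICC < 0.01 (exactly 0.01 is
included). Stability bins are half-open at the printed boundaries:
[0, 0.01), [0.01, 0.50), [0.50, 0.75), [0.75, 0.90), [0.90, 1]. Skewness
is the bias-corrected Fisher–Pearson G1 and kurtosis the bias-corrected
excess G2; constant vectors get 0 by convention. Paired scenario
comparisons are paired t-tests on matched probe vectors (the reported β is
the mean difference); differences in the count of probes below 0.01 are
Pearson chi-square tests on the 2×2 table without continuity correction
(negligible at these counts). Scenario correlation matrices use, per pair,
the probes included in both members; hierarchical clustering of scenarios
uses Euclidean distance with complete linkage on the probes included in
every scenario, rendered as a Newick tree. Subject subsampling draws an
independent subject subset per probe (so no single draw drives the
distribution), reproducibly from a seed.

## Enrichment

Probe sets are scored against the descending ICC ranking (ties broken by
probe id) with the preranked weighted Kolmogorov–Smirnov running sum:
hits advance by |stat|^p normalized over the set (p = 1 by default, p = 0
for the unweighted statistic), misses retreat by 1/(N−|S|), and the ES is
the maximal signed deviation. The null is random probe sets of the same
size; the one-sided p toward high stability is
(1 + #{ES_null ≥ ES_obs})/(n_perm + 1) with 10,000 permutations by
default, and NES divides the observed ES by the mean same-sign null ES.
Sets larger than 35,000 probes are down-sampled with the run's seed; sets
overlapping the ranked universe in fewer than 5 probes are rejected. The
implementation is cross-checked against the Bioconductor preranked
reference on fixtures, and against exhaustive enumeration on a 5-probe
universe.

## Highly stable probes and stress effects

Probes with ICC(2,1) ≥ 0.90 (inclusive, per the selection wording; the
descriptive bin ">0.90" remains exclusive) in *all five* NoStress
scenarios and `CrossSessionT1`, restricted to TSS probes, form the
highly-stable list. Stress effects are tested within the Stress session
with a subject-random-intercept linear mixed model — timepoint as a
categorical factor with T1 as reference, monocyte and batch as covariates
— i.e., a repeated-measures ANOVA that tolerates covariates and mild
imbalance. Wald t-tests on the timepoint coefficients use
df = N − rank(X) − (n_subjects − 1). The M-value model supplies p-values;
a parallel β-value model supplies effect sizes on the methylation-fraction
scale (the two agree in sign, the link being monotone). Significance is
Bonferroni: α divided by the number of *probes* in the highly-stable list,
always computed from the list, never hard-coded.

## Synthetic cohorts

The generator draws per-probe M-values from exactly the crossed model
above, then converts to β, so every probe has an analytic true ICC and
simulation on the M scale keeps the noise near-Gaussian. Defaults describe
the study conditions: 15 subjects per group (ELA / control, 30 total,
matching the 29–31 subjects of the stress-session analyses), 2 sessions ×
4 timepoints, one array batch per subject alternating between two arrays.
Probe classes mix high / medium / low stability with a circadian-like
class whose variance sits in the occasion term; baseline M-values follow
the bimodal unmethylated/methylated mixture typical of arrays. Monocyte
proportions are subject baseline (mean 0.20, sd 0.05) plus a shared
diurnal drift and per-draw noise (sd 0.03), entering at 1.5 M-units per
unit proportion; the batch offset is 0.25 M. Stress responsiveness plants
a −0.2 M shift at T4 (the magnitude of the largest observed stress
effects) on 20 high-stability TSS probes, only in the Stress session. The
ELA effect inflates residual variance ×2 in the Stress session only —
reproducing lower ICC under stress for exposed subjects without asserting
a mechanism. Expression counts couple a fraction (0.30) of TSS probes to
their gene's log2 abundance with slope −0.8 (promoter methylation
represses), Poisson counts at log-normal library sizes around 5e6 reads.
Detection p-values are small everywhere except planted whole-sample
failures (rate 0 by default).

Two calibration-study configurations deviate deliberately and are fixed
by design, not tuned:

- *Cell-adjustment direction.* Monocyte adjustment raises ICC only when
  the covariate's within-subject variation dominates its between-subject
  variation (otherwise adjustment removes between-subject variance too and
  the net effect is ~0). The planted-covariate cohort therefore uses
  between-sd 0.01, within-sd 0.06 and a 10 M/proportion coefficient —
  session-time cell-composition drift, the mechanism the adjustment
  exists for.
- *Stress-effect calibration.* Null and planted stress cohorts use a
  single stable class (0.95, 0, 0.05) with zero occasion variance: the
  repeated-measures model treats timepoint as fixed, so a probe with a
  shared occasion effect has a genuinely nonzero timepoint coefficient
  and is not null; probes that survive the ICC ≥ 0.9-everywhere selection
  carry essentially no occasion-level drift.

What the generator does *not* emulate: raw array intensities and
normalization artefacts, probe cross-hybridization and SNP overlap,
genetic (mQTL) structure, realistic linkage between neighbouring CpGs,
lymphocyte-subtype composition beyond the single monocyte proportion, and
the session-specific sample dropout of real cohorts. Passing recovery and
calibration tests therefore demonstrates correctness of the estimators
under the stated model, not robustness to artefacts the model excludes.

## Problem sizes and numerical choices

Test and acceptance runs use scaled problem sizes chosen to exercise the
asymptotics that matter: oracle equivalence at 50 subjects × 2 occasions ×
500 probes; parameter recovery at 200 subjects × 900 probes (median
estimate within ±0.05 of truth per class); enrichment calibration with
10^4 random-set draws against independent 10^4-permutation nulls; stress
FWER over 200 replicate cohorts of 120 highly stable probes. Convergence
tolerances: simplex function tolerance 1e-12, variance-ratio cap 1e8,
probe-variance floor 1e-12. Degenerate inputs (constant probes, all-zero
variance components, single-subject or single-occasion designs, empty
probe lists, zero-variance correlation pairs) raise errors or are flagged
rather than silently imputed.

## Known limitations

No confidence intervals for ICC; no Bayesian fits; the fixed-permutation
enrichment estimator (not the adaptive multilevel one) with p bounded
below by 1/(n_perm+1); no genomic inflation control or FDR alternatives in
the stress stage; single-covariate cell adjustment. The observational
Stress/NoStress contrast inherits all caveats of the underlying design —
the package quantifies stability, it does not identify mechanisms.
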