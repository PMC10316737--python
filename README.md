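# methstab

Biological test–retest stability of DNA methylation array probes.

Repeated methylation measurements from the same person drift with time of
day, acute stress, and shifting immune-cell composition. `methstab`
quantifies how reliable each CpG probe is across repeated draws — per probe,
per *test–retest scenario* (a named pair or quadruple of blood-draw
timepoints within or across sessions) — and provides the downstream
analyses that sit on top of those reliabilities: scenario comparisons,
probe-set enrichment, extraction of highly stable promoter probes, testing
of acute-stress effects on them, and a methylation↔expression correlation
stage. A synthetic cohort generator with fully known ground truth makes
every stage testable end to end.

It is aimed at epigenomics researchers designing or re-analysing
within-person repeated-measures EPIC/450K studies.

## The model

For each probe, the β-values `y_it` of subject *i* at occasion *t* follow a
two-way crossed random-effects model with covariates:

```
y_it = β0 + β1·x1_it + β2·x2_it + ω_i + ν_t + ε_it

ω_i ~ N(0, σ²_ω)   subject effect
ν_t ~ N(0, σ²_ν)   occasion effect, shared across subjects
ε_it ~ N(0, σ²_ε)  residual
```

where `x1` is the monocyte proportion and `x2` the array (batch).
Variance components are estimated by REML (non-negativity enforced by
optimizing variance ratios; balanced designs use a shared eigenbasis so a
genome's worth of probes is feasible) and converted to intraclass
correlations:

```
ICC(2,1) = σ²_ω / (σ²_ω + σ²_ν + σ²_ε)             single measurement
ICC(2,k) = k·σ²_ω / (k·σ²_ω + σ²_ν + σ²_ε)         mean of k measurements
```

"Adjusted" ICCs include the monocyte covariate; the batch effect is always
controlled. A Shrout–Fleiss two-way ANOVA mean-squares estimator is shipped
alongside as an independent closed-form cross-check.

## Worked example

```python
from methstab import SimConfig, generate_cohort, compute_scenario_icc, SCENARIOS
from methstab.stability import summarize, compare_paired

cohort = generate_cohort(SimConfig(n_subjects_per_group=15, n_probes=200, seed=7))
table = compute_scenario_icc(cohort.beta, cohort.sheet,
                             SCENARIOS["NoStressT1-2"], adjust=True)
s = summarize(table["icc21"], scenario="NoStressT1-2")
print(f"{s.scenario}: median ICC(2,1) = {s.median:.3f} "
      f"(n_included = {s.n_included}, excluded ICC<0.01: {s.n_excluded_low})")
beta, p = compare_paired(table["icc21"], table["icc2k"])
print(f"ICC(2,1) - ICC(2,k): beta = {beta:.3f}, p = {p:.2e}")
```

prints

```
NoStressT1-2: median ICC(2,1) = 0.458 (n_included = 189, excluded ICC<0.01: 11)
ICC(2,1) - ICC(2,k): beta = -0.113, p = 1.24e-70
```

The cohort has 30 subjects measured 8 times each (two sessions × four
draws). `NoStressT1-2` rates the agreement of the first two no-stress draws
(75 minutes apart): the median single-measurement reliability is ≈0.46, and
rating single measurements is systematically more conservative than rating
the mean of both draws (negative paired difference, strongly significant).

The same machinery is exposed on the command line:

```sh
methstab simulate --outdir cohort --seed 7
methstab preprocess --beta cohort/beta.tsv --detp cohort/detection_p.tsv \
    --sheet cohort/sample_sheet.csv --annot cohort/annotation.csv --out filtered
methstab icc --beta filtered/beta.filtered.tsv \
    --sheet filtered/sample_sheet.filtered.csv --scenario all --out icc.tsv
methstab summarize --icc icc.tsv --out summary.json
methstab enrich --icc icc.tsv --sets sets.csv --nperm 10000 --seed 1 --out enrich.tsv
methstab stress --icc icc.tsv --beta filtered/beta.filtered.tsv \
    --sheet filtered/sample_sheet.filtered.csv --annot cohort/annotation.csv \
    --out stress.tsv
```

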