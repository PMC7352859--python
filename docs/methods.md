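# Methods

This note documents the statistical models and procedures implemented in
`bioperturb`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Data model

A cohort is a participants × markers table with binary steatosis status,
an ordinal severity grade (0 none, 1 mild, 2 moderate/severe; grade > 0
iff case), sex, age (years), BMI-for-age z-score and waist circumference
(cm), plus strictly positive marker concentrations in native units. All
multivariate stages work on log10-transformed, column-standardized values
(sample n−1 SD); the transform is recorded per marker and invertible.
Missing markers are allowed in read panels: correlation stages use
pairwise-complete observations, multivariate stages (clustering, DBP,
sparse CCA, logistic models) listwise-complete rows. Validation rejects —
never silently repairs — grade/steatosis mismatches and non-positive
concentrations.

## Synthetic cohorts

`generate_cohort` draws log10 concentrations multivariate normal:
mean = control location + steatosis·effect + grade·grade-slope, per-marker
SD, and a group-specific correlation matrix; concentrations are 10**draws.
The default study configuration is a 36 + 36 cohort (cases split 18/18
between mild and moderate/severe — the real split is unpublished, so a
symmetric default is used) over 25 markers with locations and log10 SDs
set to typical adolescent reference values (tight spreads for
hematology/albumin/fT4, wide for CRP/ferritin/insulin and the ELISA
markers). Case shifts: ALT +0.15, GGT +0.12, TGF-β +0.30,
triglycerides +0.10, AST +0.08, HO-1 −0.12, alkaline phosphatase −0.08,
HDL-c −0.06 (log10 units); grade slopes +0.08 (ALT) and +0.05
(triglycerides) per grade step.

Correlation matrices are built from explicit factor loadings
(corr = LLᵀ + uniqueness), which guarantees positive semidefiniteness and
encodes physiology directly: cholesterol, triglyceride/metabolic,
insulin-resistance, liver-enzyme, erythroid, bilirubin and inflammation
axes shared by both groups; in the case group the liver axis tightens and
broadens (recruiting triglycerides, TGF-β, hemoglobin) and fT4 loads
negatively on the metabolic axes, so every fT4 correlation is negative.
User-supplied matrices are rejected if not PSD; `nearest_psd` repairs only
on explicit request.

Covariates are independent of the markers except an optional linear
coupling of standardized BMI-z into chosen markers on the log scale
(default λ = 0.3 into TGF-β and ALT, giving Pearson ρ ≈ λ/√(1+λ²) ≈ 0.29,
the weak positive BMI correlation expected of liver-associated markers).
`null_study_config` zeroes every effect, shares one correlation matrix and
equalizes covariate distributions — the two groups are then identical in
law, which is the calibration scenario.

What the generator does *not* emulate: assay detection limits and
left-censoring, measurement batch effects, non-lognormal skew, and the
study's true (unpublished) covariance. Passing tests therefore demonstrate
correctness and calibration of the *methods* under a realistic but idealized
data-generating process, not agreement with any particular patient cohort.

## Univariate stage

Two-group comparisons use the Mann-Whitney U test: exact enumeration when
the pooled sample is tie-free with n ≤ 12, otherwise the normal
approximation with tie and continuity corrections (continuity switchable);
the reported statistic is min(Uₓ, Uᵧ). Multi-group comparisons use
Kruskal-Wallis with tie correction; Dunn's pairwise z-tests use pooled
mid-ranks with the standard tie term, Holm-adjusted within the pairwise
family (configurable). The severity trend test is Cuzick's Wilcoxon-type
statistic T = Σ score(group)·rank with its exact permutation mean and
variance (mid-ranks absorb ties), chosen as the standard nonparametric
post-Kruskal-Wallis trend test. Proportions use Pearson chi-square without
continuity correction.

Family-wise error over the marker panel is controlled by Holm-Bonferroni
step-down, implemented directly (sort, multiply by m−i+1, enforce
monotonicity, cap at 1) — a library call would do the same arithmetic but
is too slow for the Monte-Carlo calibration loops. The full 25-marker
panel is the default adjustment family. Fold differences are reported as
10^(Δ median log10), i.e. the case/control median ratio with geometric
interpolation for even group sizes — the median, not the mean, because the
data are treated as non-Gaussian throughout.

## Clustering

Ward minimum-variance linkage on Euclidean distances (the only metric
under which Ward's variance interpretation holds) of log10 + z-scored
data, standardized over the whole cohort. Bootstrap support of an internal
node is the fraction of feature-resampled replicate trees containing the
identical leaf set — when clustering markers, the "features" are the
participants, so support reflects resampling people; 100 replicates by
default. Severity profiles are per-marker medians of log10 values per
grade group, z-scored across the three group values (a `stat="mean"`
switch exists); rows with equal group medians become zeros.

## Correlation networks

Spearman rho uses mid-ranks; p-values are exact by permutation enumeration
for tie-free pairs with n ≤ 7 and the t approximation otherwise. With
complete data the whole matrix is computed vectorized from column ranks.
Edges require unadjusted p < α (default 0.05) — deliberately unadjusted,
matching the descriptive network-visualization convention; optional
Holm/Benjamini-Hochberg control is available behind a flag for users who
want error control. Participant-bootstrap support (same-sign, same-rule
re-detection frequency over 100 replicates) is *reported*, never used for
edge selection. Note that conditioning an edge on p < α biases its
bootstrap support upward: under full independence, selected (spurious)
edges still show mean support ≈ 0.65 — well below the ≈ 1.0 of genuinely
correlated pairs, but far from negligible, which is why support
complements rather than replaces the p-value rule.

## Degree of Biochemical Perturbation

z-deviations are computed on log10 concentrations against the reference
(no-steatosis) group's mean and sample SD; the per-sample score is the
mean absolute deviation over available markers (a signed-mean variant
exists behind a flag). The raw-scale option exists but log10 is the
default for consistency with every other multivariate stage. Markers with
zero reference SD are excluded with a warning. The perturbation threshold
is reference-mean + 2·reference-SD of the scores.

A structural caveat: reference samples are standardized in-sample (their
z-columns have exactly mean 0, SD 1), while non-reference samples carry
the sampling error of the reference mean and SD — an out-of-sample
variance inflation of roughly (1 + 1/n_ref). At n = 36 this yields a flag
rate a few percentage points higher in the non-reference group even when
both groups share one distribution. The calibration test asserts agreement
within 5 points and this mechanism is the reason the band is not tighter.

## Sparse CCA discriminant

The penalized rank-1 matrix-decomposition formulation: maximize uᵀXᵀYv
subject to ‖u‖₂ ≤ 1, ‖v‖₂ ≤ 1, ‖u‖₁ ≤ c₁, ‖v‖₁ ≤ c₂, solved by
alternating updates u ← Π(XᵀYv), v ← Π(YᵀXu), where Π soft-thresholds and
L2-normalizes, with the threshold found by bisection to meet the L1
budget. Initialization is the leading singular vector of XᵀY, making the
fit deterministic; feasibility holds after every iteration and the
objective is monotone. Penalties must be ≥ 1 (the L1 ball must intersect
the L2 sphere); defaults c₁ = 1 + 0.5(√p − 1) (moderate marker sparsity)
and c₂ = √q (no sparsity on the outcome side). Y is two centered group
indicators — rank 1 for a binary outcome, which makes the discriminant
well-posed with a single meaningful canonical pair; the second pair of the
vector-projection view is therefore flagged degenerate whenever XᵀY has no
second dimension (second singular value ≈ 0). Scores are oriented so cases
score higher. Resubstitution ROC is the default (with a logged optimism
warning); leave-one-out refits the model per held-out sample,
restandardizing within each training fold.

## Association chain

Screening: variables with univariate p < 0.2 (Mann-Whitney for continuous,
chi-square for sex) enter the multivariable logistic model; sex, age,
BMI-z and waist are always retained as adjustments. Markers enter as
log10, so a coefficient is the log-odds per 1-log concentration change.
Fitting is maximum likelihood (IRLS) with Wald CIs
(OR = e^β, CI = e^(β ± 1.96 SE)). Separation is detected from
non-convergence, a perfectly fit likelihood or exploding Wald SEs — not
from coefficient size alone, which is legitimately large per 1-log for
low-variance markers — and flagged rather than silently reported. With the
default synthetic cohort the fully screened model (≈ 15–18 terms at
n = 72) is usually quasi-separated, exactly as such over-parameterized
fits behave on real panels; the headline adjusted odds ratio therefore
comes from the single-marker + adjustments model.

ROC: empirical sweep over all distinct thresholds (positive = score ≥ t);
AUC by the trapezoid rule, which equals the Mann-Whitney identity
U/(n₁n₀) under mid-rank tie handling; 95% CI by DeLong's analytic
variance of placement values. The optimal cutoff maximizes the Youden
index (sens + spec − 1), ties broken toward higher specificity, reported
in native units. Constant scores give AUC 0.5 with a degenerate flag.

## Pipeline and reproducibility

The pipeline runs simulate → preprocess → univariate → clustering →
network → DBP → sCCA → association in dependency order; one run seed
spawns per-stage substreams (`numpy.random.SeedSequence`), so toggling one
stage never perturbs another's randomness and identical configurations
produce byte-identical exports. Floats are serialized with 17 significant
digits so panel CSVs round-trip bit-for-float.

## Problem sizes used in the test suite

Oracle checks run on exhaustive small instances (n ≤ 12 enumeration for
Mann-Whitney, 6–7-item matrices for Ward, 3-marker toys for sparse CCA).
Calibration uses 1000 null cohorts for the family-wise error rate, 250 for
network edge counts, 300 for DBP flag rates; parameter recovery uses 200
cohorts for the binormal AUC (theory Φ(√2) ≈ 0.921) and 500 replicates at
n = 500 for logistic slope bias and CI coverage; pattern reproduction uses
10–100 seeds per property at n = 200 + 200 or 36 + 36 as appropriate.
These sizes put Monte-Carlo error comfortably inside each asserted band
while keeping the whole suite around a minute on one CPU.

## Known limitations

- The sparse CCA solves the diagonal-penalty (covariance) formulation;
  with strongly collinear markers its weights are not the classical
  (whitened) canonical weights. The equivalence holds exactly for
  orthogonal designs, which is how it is tested.
- DeLong CIs are asymptotic; at n = 36 + 36 they are approximate and a
  bootstrap CI flag is a sensible future addition.
- The DBP score inherits the out-of-sample inflation described above;
  comparisons *between* non-reference subgroups are unaffected.
- Network edge selection at unadjusted p < 0.05 is descriptive, not an
  inferential claim; expect ≈ α·C(p,2) spurious edges under independence.
- The experimental "correlation-profile" feature mode for the discriminant
  (each sample described by its leave-one-in correlation deviations) is
  not implemented; the discriminant operates on standardized
  concentrations, with the correlation structure entering through the
  weight vector's joint fit.
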