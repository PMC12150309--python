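# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Study design being modelled

Preterm neonates contribute plasma samples in three groups: **control**
(no signs of sepsis), **SINS** (suspected sepsis later judged
non-infectious — systemic inflammation without sepsis) and **sepsis**
(culture-positive or culture-negative late-onset sepsis). Suspected
episodes may contribute a follow-up sample 6–48 h later, which keeps the
episode's group label. Two analysis sets derive from this: the
*comprehensive* set (all samples, follow-ups consolidated, repeated
measures per subject) for pathophysiology screens, and the
*single-time-point (STP)* set (one sample per subject — the first sepsis
episode, else the first SINS episode; controls only from subjects with no
episode at all) for diagnostic modelling at the moment of suspicion.

## Synthetic-data generator

`septomics.simulate` draws cohorts and abundance tables from the same model
family the analysis assumes, plus a `GroundTruth` record.

**Cohort.** Defaults give 180 subjects with group probabilities
(86, 37, 57)/180 and a 50% follow-up rate, so expected sample counts are
~86/56/85 (control/SINS/sepsis) — the scale of the study cohort. Ten
confounder covariates are drawn per subject or per sample with demographic
defaults (gestational age 26.67 ± 2.07 weeks; birthweight 891.9 ± 279.45 g;
postnatal age 21.19 ± 18.45 days truncated at 3; TPN proportion
0.38 ± 0.38 clipped to [0,1]; oxygen 30.13 ± 14.33% clipped to [21,100];
male probability 0.599; arterial sampling 0.225). Mechanical ventilation
and intraventricular hemorrhage get a +1.2 log-odds shift in sepsis
subjects, mirroring their association with sepsis outcome; the remaining
covariates are independent of group. Sepsis subjects receive a pathogen
label with probabilities (42, 29, 14)/85 for culture-negative /
gram-positive / gram-negative.

**Abundances.** Feature *j* of sample *t* (subject *i*) on the log2 scale:

    y = baseline_j + shift_j(group, sex, pathogen) + x_t' L_j + u_ij + eps

with `u_ij ~ N(0, τ²)` drawn independently per feature and subject
(`τ² = icc/(1−icc)·σ²`, default ICC 0.3) and `eps ~ N(0, σ²)`, σ = 1 by
default. Effects are parameterized in **residual-SD units** so magnitudes
comparable to reported mixed-model estimates (~0.3–1.0) are directly
usable; the default draw is U(0.3, 1.0) with random sign. Class semantics:
*shared_inflammation* shifts SINS and sepsis equally; *progressive* shifts
SINS by half the sepsis shift; *sepsis_specific* / *sins_specific* shift
one group; *sex_specific* and *pathogen_specific* shift only sepsis samples
of a target sex / pathogen. Subject intercepts are drawn independently per
feature deliberately: a shared per-subject intercept would correlate all
features and distort the null calibration of a per-feature screen (a global
sample-level shift is a normalization problem, not a random-intercept one).

**Censoring.** Missingness is purely left-censored: each feature's values
below its empirical `censor_quantile` (default 0.10) are set missing and
the threshold recorded. There is no MCAR component by default, matching
QRILC's assumption. Observed-vs-missing status is therefore a deterministic
function of the uncensored value and the recorded threshold.

**QC materials.** A pooled-QC replicate is the per-feature grand mean times
mean-preserving lognormal noise with CV = `technical_cv` (default 0.10); a
blank is `blank_fraction` (default 0.05) of the grand mean under the same
noise. QC-rule violators are planted by passing per-feature arrays.

**Markers.** IL-6/CRP/PCT are lognormal with latent shifts of 0.8 SD for
inflammation and (0.32, 0.11, 0.18) SD for sepsis-vs-SINS, chosen from the
binormal identity AUC = Φ(Δ/√2) to give single-marker SINS-vs-sepsis AUCs
of ≈0.59/0.53/0.55 — weakly discriminative markers by construction.

**What the generator does not emulate:** batch effects and drift,
feature-feature correlation beyond the shared design (real metabolite
classes are strongly co-regulated), non-normal heavy-tailed abundances,
assay-specific missingness beyond the censoring mechanism, and clinical
label noise. Passing tests therefore demonstrate correctness of the
machinery and its operating characteristics under the assumed model, not
performance on real cohorts.

## Preprocessing

Fixed order: feature QC filter → Rosner outlier removal → derived features
→ log2 → QRILC → autoscaling. RSD and blank% are computed on the linear
scale, where these assay metrics are defined. All three QC rules are strict
inequalities (`< 30 / < 40 / < 20`); a zero QC mean makes RSD undefined and
auto-fails the feature. The missingness rule is applied per feature over
all study samples. Derived features (ratio, sum, mean) are computed on the
linear scale before log2 — so log2 of a ratio is the difference of log2
values — inherit missingness from their operands, and face no further QC.

**Rosner test.** The generalized extreme studentized deviate test
(α = 0.05, kmax = 5) runs on a per-sample internal-standard summary (the
generator emits `is_log_mean`); λ-critical values use the standard
t-quantile formula, and for kmax = 1 the test reduces exactly to Grubbs'
test (checked against that closed form in the suite).

**QRILC.** Per sample: with missing fraction m, sorted observed values get
plotting positions `p_k = m + (1−m)(k−0.5)/n_obs`; least squares of the
observed values on Φ⁻¹(p_k) gives the censored-normal fit (μ̂ = intercept,
σ̂ = slope). Missing entries are drawn from N(μ̂, tune·σ̂) truncated above
at `μ̂ + tune·σ̂·Φ⁻¹(m)` — the left-tail region censoring removed — with
tune = 1. Preconditions: ≥ 30% observed per sample; a nonpositive slope
falls back to half-minimum imputation with a warning. A per-feature mode is
available behind `per_feature=True`. Observed values are returned bitwise
unchanged.

## Mixed-model screening

**Contrast coding.** Inflamed: all samples, 1 iff group ∈ {SINS, sepsis};
Sepsis: all samples, 1 iff sepsis; C_SINS / C_S / SINS_S restrict to the
two named groups with the second-named coded 1.

**Confounder identification.** Outcome association: Fisher exact
(categorical) or Welch t (continuous) versus sepsis status at α = 0.05.
Metabolome association: Spearman (continuous) or Welch-t/ANOVA
(categorical) against each of the top 5 principal-component scores of the
autoscaled table. The union enters all models as fixed effects;
stratification removes the stratum variable from the set.

**REML engine.** All screens share one design matrix, so the package ships
a profiled-REML random-intercept solver: rotating each subject's rows onto
an orthonormal basis whose first vector is the subject mean turns
`σ²(I + λZZ')` into a diagonal with entries `1 + λk` on mean rows
(k = subject size) and 1 on within rows. Sufficient statistics per
eigenvalue class make the restricted likelihood an O(p²) function of the
variance ratio λ = τ²/σ², minimized by bounded scalar search over
log λ ∈ [−10, 10] with an explicit λ = 0 boundary comparison (τ̂² = 0 sets
a boundary flag; the fit then *is* the fixed-effects least-squares fit).
Wald inference uses a t reference with n − p degrees of freedom, which
reduces exactly to OLS when each subject has one sample. The suite
cross-checks β̂, SE and τ̂² against statsmodels `MixedLM` on repeated-
measures data and verifies OLS equivalence to 1e-6. Degrees-of-freedom
choice: at the cohort sizes involved (≥150 subjects) the difference
between this t reference and a Satterthwaite adjustment is negligible;
the suite verifies 95% Wald coverage empirically instead of adjusting df.

**Scales.** Screens run on the autoscaled imputed log2 data (estimates in
SD units, matching the ~0.3–1.0 scale of reported estimates); fold changes
are computed on the unscaled imputed log2 data (ratios of geometric means,
reference = first-named group). BH-FDR is applied within each model/stratum
over all its features (m = 296 in the default layout), headline threshold
q < 0.1; trend letters and stratified-model discussion use uncorrected
p < 0.05.

**Trend classification.** From the three pairwise models at p < 0.05:
shared inflammation (C_SINS and C_S significant, same sign, SINS_S not);
progressive up/down (C_SINS and SINS_S significant, same sign, monotone
group means); sepsis-specific (SINS_S and C_S significant, C_SINS not);
SINS-specific (C_SINS significant, C_S not, SINS_S either not significant
or significant with the opposite sign — the compact-letter pattern a/b/a;
at large samples a genuine SINS-only shift *does* separate SINS from
sepsis, so requiring SINS_S non-significance would misclassify exactly the
clearest cases); otherwise unclassified.

**Stratified models.** Sex strata keep all samples of one sex. Pathogen
and culture strata keep all non-sepsis samples and the sepsis samples of
the stratum (e.g. gram-positive sepsis vs all non-sepsis); this comparator
keeps the non-sepsis arm at full power and makes strata comparable, at the
cost of sharing controls between strata.

## Diagnostic framework

**Bootstrap-aggregated LASSO.** B = 100 class-stratified bootstrap
resamples (unstratified resampling at n ≈ 60 frequently loses a class).
Within each resample the L1 penalty is chosen by 5-fold cross-validated
deviance over a 6-point grid, C ∈ logspace(−2, 0.5), using the
**one-standard-error rule** — the strongest penalty within one SE of the
CV minimum. The raw CV minimum is deliberately not used: at n = 60 it
admits so many noise features that selection frequencies saturate and
stability selection loses its meaning; the 1-SE rule is the standard
sparser choice. Out-of-bag samples are scored with the penalized model
itself (AUC, and sensitivity/specificity at probability 0.5); iterations
whose OOB set lacks a class contribute no metrics.

**Stability selection.** The panel is every feature selected in strictly
more than 45% of the B fits. An intrinsic limit documented by the
validation experiments: with five planted 0.8-SD effects among 100 nulls
at n = 60, the *realized* per-dataset signal of a planted feature
(point-biserial r ≈ 0.37 ± 0.10) overlaps the maximum of 100 null
correlations (≈ 0.33), so at this sample size no selection rule reliably
recovers ≥4 of 5 planted features while admitting ≤2 nulls — the dataset's
strongest realized null is re-selected persistently across bootstrap
resamples of the same data. The acceptance suite measures this recovery
rate under exactly those conditions and reports it as is.

**LOOCV.** Unpenalized logistic fits (Newton–Raphson) on n−1 samples;
separation inside a fold triggers a small-ridge refit (counted).
Out-of-fold probabilities give the ROC/AUC; sensitivity, specificity, PPV
and F1 are reported at the threshold maximizing Youden's J on those
probabilities. Two properties worth knowing: LOOCV AUC tracks the binormal
closed form Φ(Δ/√2) well when signal exists, and under a *pure-noise*
model it is systematically pessimistic (removing a class-1 sample lowers
that fold's base rate, anti-correlating held-out probabilities with the
removed label; null AUC sits well below 0.5). Reported marker-only AUCs
near or below chance should be read with this in mind.

**Model variants and comparison.** Nine variants: panel; IL-6; CRP; PCT;
all markers; panel+each marker; panel+all markers. Markers enter as
log-transformed, autoscaled covariates. Each variant is compared against
the panel by McNemar's test at classification threshold 0.5: exact
two-sided binomial on the discordant counts when b + c < 25, else χ² with
continuity correction `(|b−c|−1)²/(b+c)`.

## Correlation analysis

Spearman ρ (average ranks, t-approximation p) within each condition;
differential correlation by the Fisher r-to-z two-sample statistic
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))` with two-sided normal
p. The 1.06 variance inflation appropriate for Spearman input is available
behind `spearman_adjust=True` but off by default; its effect at the sample
sizes involved is small, and the unadjusted statistic's type-I error is
verified empirically in the suite. No multiplicity correction is applied
within the correlation family by default (the family is small and
hypothesis-generating).

## Validation experiments and problem sizes

`septomics.experiments` contains the seeded experiments the acceptance
suite runs: BH-FDR control on 100 all-null 296-feature screens at 150
subjects; recovery of a planted 0.8-SD sepsis effect over 600 replicates
at 200 subjects (600 rather than the minimal 200 keeps the Monte-Carlo
error of the coverage estimate well inside the 0.92–0.98 band); the QRILC
benchmark over 50 replicates of 8 samples × 300 features at 20% censoring
(8 units per replicate so the MAE contrast, not sampling noise, decides
wins); stability-selection recovery over 50 replicates at the STP scale;
LOOCV binormal calibration averaged over 5 datasets of n = 200 per Δ;
exact-McNemar brute-force equivalence over all b + c ≤ 20; the
differential-correlation type-I rate over 2000 replicates at n = 40; and
trend-archetype recovery with 15 features per class at 1.2 SD — the
magnitude of the clearest reported trend metabolites (a control-vs-SINS
fold change of 2.4 is 1.26 on the log2 scale) — across 300 subjects.
`scripts/acceptance.py` runs the same experiments (some at reduced
replicate counts to stay desk-scale) and one end-to-end default study.

## Numerical choices

- RNG: numpy `default_rng` throughout; every public generator takes a seed
  and is a pure function of (spec, seed).
- REML search: bounded Brent on log λ, xatol 1e-8; singular normal
  equations or a nonpositive-definite X'V⁻¹X yield an NA result row with a
  convergence flag, never a crash of a screen.
- Logistic IRLS: step tolerance 1e-10, linear predictor clipped at ±30;
  separation detected by non-convergence or |β| > 50 → ridge 1e-2 refit.
- BH with missing p-values: NaNs are excluded from m and propagate as NaN q.
- Fisher exact on a zero-margin table returns p = 1 with a warning.
- Ties in Youden's J resolve to the highest qualifying threshold.

## Limitations

- The generator's independence assumptions (features conditionally
  independent given design; confounders mostly independent) make power
  estimates optimistic relative to correlated real data.
- The REML engine fits a single random intercept only — no random slopes,
  no crossed effects; that is the screening model, not a general mixed
  model.
- STP curation assumes one episode per subject in the generator; the
  curation rules handle multi-episode metadata but are exercised on
  synthetic single-episode cohorts.
- Real-data headline metrics (e.g. panel AUCs) are functions of the actual
  cohort and cannot be reproduced from simulations; the pipeline reproduces
  the *procedure* and verifies its operating characteristics.
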