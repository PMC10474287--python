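# Methods notes

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical conventions.

## Data model and scales

Methylation enters as beta values β ∈ (0, 1) (fraction methylated at a CpG
site); all statistics run on M-values, M = log2(β/(1−β)), the
variance-stabilized logit scale. The two are exact inverses in the code and
a round-trip is tested to 1e-12 relative tolerance. Mosaic mixtures are
formed on the **beta** scale (cell fractions average linearly in β, not in
M) and M-values are recomputed from the mixture; a test asserts the two
orders of operation genuinely differ.

## Quality control

Probes are dropped for detection p > 0.01, sex-chromosome / SNP-overlap /
cross-reactivity annotation flags, or call rate < 95%; samples for mean
detection p > 0.05 or call rate < 95%. The aggregation of the per-cell
detection rule is not uniquely defined by the thresholds alone; the default
is strict (one failing sample excludes the probe), with a fraction-based
rule available (`det_p_fail_fraction`). Outlier screening uses the first
two principal components of the site-centered (unscaled — M-values share a
scale) matrix and a χ²₂-quantile confidence ellipse at coverage 0.99 on the
empirical PC covariance; an F-based small-sample ellipse would be slightly
wider, but the χ² form is the simpler default and its coverage is verified
by Monte-Carlo (0.99 ± 0.005). Samples within 1% (relative, on the squared
Mahalanobis scale) of the quantile are reported "border", making the
"within or at the border" language operational.

## EWAS

Per site, ordinary least squares of M on [intercept, status, covariates],
with the status coefficient's two-sided t test; vectorized across sites.
Primary selection requires p < 5e-8 **and** raw between-group
|mean M difference| > 0.4 (both strict), ordered by p. Two open choices
were resolved as: the 0.4 threshold applies to the **M-value** scale (the
scale of the regression) and to the **raw** group difference, not the
adjusted coefficient; both are arguments. An optional moderated mode
shrinks residual variances toward a scaled-inverse-χ² prior fitted by the
log-variance moment identities (digamma/trigamma inversion) and augments
the degrees of freedom accordingly — useful at n ≈ 26, but plain OLS is the
default because it is transparent and closed-form checkable. No
multiplicity correction beyond the fixed genome-wide threshold. At
desk-scale site counts (hundreds to thousands rather than 850k) the
genome-wide threshold is far out of reach of any true effect's sampling
noise floor, so tests and examples pass `p_thresh = 1e-6`; the threshold is
a parameter everywhere.

## mRMR

Relevance and redundancy use the Gaussian mutual-information surrogate
MI = −ln(1−ρ²)/2 nats with Pearson ρ (point-biserial against the 0/1
phenotype). The greedy step maximizes MI(x, y) − mean MI with the selected
set; |ρ| = 1 is capped at −½ ln(1e-15) ≈ 17.3 nats so exact duplicates are
maximally penalized but finite. Ties are broken by ascending EWAS p then
lexicographic site ID (determinism). The ensemble runs b bootstraps of the
samples, **stratified by class** — with 7 cases an unstratified resample
can lose a class entirely — and unions the b selections in order of first
appearance. Greedy selections have the prefix property (larger s only
appends), which is tested, and every greedy pick is tested against
brute-force score maximization on small instances.

## Classifier

Linear-kernel SVM (cost C = 1.0 by default; the margin, not the direction,
is the only thing C tunes at these sample sizes) with inverse-frequency
class weights (7 cases vs 19 controls), Platt sigmoid calibration fit on
cross-validated decision values (5-fold or the smallest class count), and a
recorded 10-fold cross-validated accuracy. The probability cut-off is a
single constant 0.5 everywhere. A model serializes losslessly to a weight
vector + intercept + two Platt constants (JSON/TSV, no binaries); the
serialized scorer reproduces `predict_proba` to 1e-15.

Stepwise re-training repeats the full chain (EWAS on the current case set →
dual-threshold selection → ensemble mRMR → SVM) and forms the next case set
as the initial cases plus all candidates scoring ≥ 0.5. The initial cases
are never removed; iteration stops at a fixed point, a detected cycle
(possible in principle since membership is recomputed each step), or
max_iter. Re-running site selection each step is the default because the
episignature is observed to change across re-trainings; `refit_sites=False`
freezes the step-0 sites and re-fits only the SVM.

The length sweep trains one classifier per (b, s) in 1..20 × 2..15 (280
configurations), averages specificity and pseudo-sensitivity (verified
positives over the maximum across configurations) per realized
episignature length k, and reports the plateau onset: the smallest k from
which every window of 5 consecutive realized k deviates ≤ 1.5% from its
window mean. The window width is a convention; 5 keeps single-k noise from
ending a plateau.

## Mosaic evaluation

Flagging: |k − n/2| > √n, i.e. more than 2 SD of Bin(n, ½) — equivalently a
variant read fraction below 0.5 − 1/√n. Count corrections after read
re-examination add misinterpreted reads and half of the non-informative
reads (unbiased allelic sampling assumption): k = called + extra +
noninformative/2. Fractional k is allowed; a separate helper computes the
deviation from a (rounded) table-reported VAF, since the two roundings give
visibly different second decimals.

In-silico mosaics: for every leave-2-out subset of the training cases a
classifier is trained (no re-training) on the fixed signature sites; the
left-out cases enlarge the affected donor pool. Each mosaic draws an
affected and an unaffected donor, d ~ U(0,1), mixes betas, and draws
n from a lower-truncated normal (rejection sampling; exact, and cheap at
desk scale) and k ~ Bin(n, d/2). Depth presets (184, 93, >47) and
(213, 121, >14) ship for the two studied genes. Scores are pooled across
ensembles before binning (the natural reading of subsampling 3000 mosaics),
then 5th/95th percentiles are computed in 0.025-wide bins of k/n ∈ [0, 0.5]
and loess-smoothed against bin centers. The x-axis is the *simulated read
fraction* k/n, not d/2 — read-sampling noise belongs in the band.

The loess smoother is a direct-fit local quadratic with tricube weights,
span 0.75 — the R default dialect; it matches an independent reference fit
to 1e-8 on a frozen 20-point series, and the span is exposed. After
smoothing, the lower curve is clipped to the upper one (crossings can occur
in sparse bins). Suspects receive the mean and a t-based 95% CI over the m
leave-2-out scores (a "95% CI" admits several constructions; the
t-interval is the conservative default, and with m = 21 the t and normal
intervals differ by only ~5%), and the verdict
compares the mean against the band at the suspect's read fraction, with
nearest-endpoint extrapolation (warned) outside the band's support.

## Severity statistic

Per signature site, z = (M − μ_ctrl)/σ_ctrl with control mean/SD (ddof 1)
computed from the training controls — the statistic is defined against the
same reference the classifier was trained with; the control set is an
argument. The score is the mean |z|; for a control-like sample it
approaches E|N(0,1)| = √(2/π) ≈ 0.798 as the site count grows, which is
tested. Onset association is a single-covariate Cox proportional-hazards
fit with right-censoring and a likelihood-ratio test (lifelines; Breslow
tie handling — ties are rare at desk scale). Pearson correlation with age
at onset substitutes the examination age for censored samples, mirroring
the proxy analysis.

## Synthetic cohorts — what they emulate, and what not

Defaults mirror a single-gene study arm: 19 training controls, 7 initial
unambiguous cases, 28 further carriers (≈ the 35-carrier arm), an optional
held-out control panel, 5000 CpG sites with a 100-site planted signature
(desk-scale stand-ins for ~694k measured and >1000 significant sites), and
the (184, 93, >47) depth model. Baseline betas come from a three-component
mixture (hypo ≈ 0.1, hemi ≈ 0.5, hyper ≈ 0.9) matching the bimodal marginal
of array methylation, perturbed in M space. Covariate confounding is
linear: per-site slopes ~ N(0, σ_c) against sex, age, and two blood-cell
fractions. Cases add u·Δ at the signature sites on the M scale — Δ = 2.0 M
units for a full-effect case (comfortably above the 0.4 selection
threshold, near the strong end of reported episignature effects), u ∈
(0, 1] the allelic-series multiplier, drawn from (0.3, 1.0) unless given
explicitly. Mosaic cases mix affected/unaffected profiles with the same
beta-scale rule the evaluation module uses, by construction. Age at onset
decreases linearly in the effective dose u·d with Gaussian scatter and is
censored at the examination age. Betas are clipped to
(1e-9, 1 − 1e-9) so M stays finite.

Not emulated: probe-level chemistry noise, batch/plate structure,
nonlinear or interacting covariate effects, genomic correlation among
sites beyond the planted signature, and any genotype beyond one causal
variant per case. Passing tests therefore demonstrate the *pipeline's*
statistical behavior (calibration, recovery, monotonicity, specificity
preservation) under a faithful but idealized generative model — not
performance on real arrays.

## Problem sizes and determinism

Tests and the worked example run cohorts of 250–2000 sites, re-training
over 20 seeds, 3150-mosaic ensembles, 400–500-replicate null calibrations,
and the full 280-configuration sweep; the whole suite completes in well
under a minute on one core. One global seed fans out to per-component
child streams (numpy `SeedSequence.spawn`); identical seeds give
bit-identical cohorts, selections, and score tables, which is tested at
both library and CLI level.

## Known limitations

- The Gaussian MI surrogate is exact only for jointly Gaussian pairs; for
  a binary phenotype it is a monotone transform of the point-biserial
  correlation, which is precisely its intended role here.
- Platt calibration on ~26 training samples saturates below 1 (the
  smoothed targets bound scores near (n₊+1)/(n₊+2)); thresholding at 0.5
  is unaffected.
- The plateau detector needs ≥ 5 realized k values and returns "none"
  otherwise; with few distinct k (small site pools) the onset is
  undefined.
- `evaluate_specificity` can only check training overlap for models that
  carry their training IDs; the JSON-round-tripped scorer does not.
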