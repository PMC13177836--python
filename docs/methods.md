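# Methods

## The estimand and the effect sizes

One observation is a comparison of a parasite-success metric (prevalence,
load, or virulence/mortality) between a group of host populations with high
genetic diversity and a group with low genetic diversity, each summarised
as (mean, SD, n). Two effects per comparison:

**SMD (Hedges' g).** `d = (m_H − m_L)/s_pool` with the pooled SD over the
two groups, small-sample corrected by `J = 1 − 3/(4(n_H+n_L−2)−1)`;
sampling variance `(n_H+n_L)/(n_H n_L) + g²/(2(n_H+n_L))`. An alternative
denominator `2(n_H+n_L−3.94)` is available behind
`smd(..., variance_form="adjusted")` for cross-checks. Positive g = more
parasite success under high host diversity.

**lnCVR.** `ln(s_H/m_H) − ln(s_L/m_L) + 1/(2(n_H−1)) − 1/(2(n_L−1))`;
variance `s_L²/(n_L m_L²) + 1/(2(n_L−1)) + s_H²/(n_H m_H²) + 1/(2(n_H−1))`.
This is the independence form: the mean–SD correlation term of the full
formula is set to zero because the inputs are group summaries, not paired
replicate series. Positive lnCVR = relatively more variable parasite
success under high host diversity.

Before effect-size computation a log-safety offset (default 0.001) is added
to every mean and SD of every record — uniformly, not only where zeros
occur, so that all records are on the same transformed scale; a
`zeros_only` policy exists as a sensitivity switch. SMD and lnCVR both see
the offset (the alternative order — offset only before lnCVR — is
available by computing SMD with `offset_policy="never"`).

**Harmonisation.** Groups that share a diversity level are pooled with the
total-sum-of-squares rule (pooled variance = within + between components,
i.e. the variance of the concatenated sample). Continuous diversity
gradients are median-split into equal-sized high/low groups; with an odd
population count the median population is dropped (ties broken by stable
input order). Survival-coded proportions are complemented into mortality;
survival-coded metrics on unbounded scales (e.g. survival time) cannot be
complemented, so they are flagged and the SMD sign is negated
(`d(−x) = −d(x)`), and lnCVR is not computed for them because a shifted
mean changes the CV arbitrarily.

## Shared-control covariance

When several high-diversity groups are compared against one low-diversity
control, their effects share sampling error. Within each shared-control
block the covariance is `r·√(v_i v_j)` with a fixed r (default 0.5, always
reported alongside results because the choice is a convention, not an
estimate); for SMD an exact form `1/n_C + g_i g_j/(2N)` is available.
The assembled matrix is validated positive semidefinite and the offending
block is reported on failure — no silent repair, because a non-PSD matrix
usually signals a data error.

## The multilevel model

`Σ = V + τ²_study Z_s Z_s' + τ²_genus Z_g Z_g' + τ²_exp[(1−ρ)I + ρ Z_e Z_e']`

Fixed effects use a cell-means parameterisation: the first moderator term
contributes one dummy per observed level (no intercept), so coefficients
are directly the subgroup means shown in orchard-style figures; further
terms are treatment-coded. Variance components are estimated by REML —
maximising `−½[ln|Σ| + ln|X'Σ⁻¹X| + r'Σ⁻¹r]` with r the GLS residual — via
bounded L-BFGS-B on the log-variance scale (ρ bounded to [0, 0.999]) with
up to five dispersed starts, followed by a coordinate-wise Brent polish
(two sweeps, absolute tolerance 1e-10) that tightens the optimum on flat
likelihood surfaces. Bulk simulation paths (parameter recovery,
leave-one-out) use one start and skip the polish for throughput; on the
instances checked the resulting estimates differ at the 1e-6 level.
The likelihood evaluation detects the block-diagonal structure induced by
the grouping factors and batches equal-sized blocks, which makes hundreds
of refits per minute feasible on one core.

Inference is Wald-z, matching standard multilevel meta-analysis defaults.
ρ is estimated only when some experiment carries more than one comparison;
otherwise it is held at 0 (unidentifiable). The genus effect is a plain
exchangeable intercept, not a phylogenetic covariance. When each study
contributes a single genus, study and genus variance components are nearly
aliased: their sum is well identified but the split between them is
ridge-like; downstream summaries should read their combined share.

**I² decomposition.** With Higgins–Thompson "typical" sampling variance
`v̄ = (k−1)Σw / ((Σw)² − Σw²)`, `I²_level = τ²_level/(Στ² + v̄)·100`,
summing to `I²_total`. A second decomposition (each level's share of Στ²
alone, ignoring v̄) is exported alongside as `i2_alternative` since
published attributions sometimes use that convention.

**Contrasts.** General linear hypotheses `L'β = 0` with Wald-z tests; the
2×2 analysis reports (1) specialist − generalist averaged over parasite
diversity and (2) low − high parasite diversity within each host range,
Holm-adjusted as a family. Single-moderator analyses report all pairwise
level contrasts (Holm within moderator) plus an omnibus QM chi-square test
of level equality. Prediction intervals are `β ± 1.96·√(SE² + Στ̂²)`.

**Bias and sensitivity.** The publication-bias check is the Pearson
correlation between effects and their SEs with a Fisher-z CI (reported as a
correlation because that matches how such results are usually quoted for
multilevel data, where the classical regression intercept test is not
directly valid); the precision-weighted regression variant is available
behind `method="regression"`. Leave-one-out omits one study, or one set of
comparisons sharing a control group, refits the overall model, and reports
the unweighted arithmetic mean of estimate, SE, z, p and CI bounds across
iterations (a precision-weighted average is exported as a secondary
column). Failed refits are recorded and excluded from averages.

## The synthetic-data generator

The generator emulates the comparison table the analysis expects, with
known truth. Per comparison, the true effects are
`θ = cell effect + study + genus + experiment deviations`, where the cell
is one of the 2×2 parasite-genetic-diversity × host-range combinations
(assigned per experiment), study/genus deviations are iid normal, and
experiment deviations are compound-symmetric within an experiment
(correlation `rho_experiment`). Group parameters: the low group has
`μ_L = control_mean`, `σ_L = control_cv·μ_L`; the high group has
`CV_H = CV_L·exp(θ_lnCVR)` and `μ_H` solving
`μ_H = μ_L + θ_SMD·s_pool(σ_L, CV_H·μ_H)` (a quadratic; the root matching
the sign of θ is taken, with a bisection fallback, and infeasibly negative
effects on the positive scale are clamped and counted). Observed summaries
are then drawn with the exact Gaussian sampling distributions —
`mean ~ N(μ, σ²/n)`, `variance ~ σ²χ²_{n−1}/(n−1)` — which makes the
analytic effect-size variance formulas exactly correct and gives a clean
calibration target. `sampling_noise=False` yields the analytic limit
(summaries equal their population values).

Default scenario (`diversity_uncertainty_preset`): 48 studies, 1–3
experiments per study, 1–3 comparisons per experiment (≈190 comparisons),
group sizes 5–30, a quarter of multi-comparison experiments sharing a
control, 10% of studies sharing a genus. Cell magnitudes are illustrative
(the conceptual model is qualitative) and use the subgroup point estimates
this kind of analysis reports: specialist SMD −0.54/−0.76 and lnCVR
−0.54/+0.61 under low/high parasite diversity; generalist SMD −0.42/−0.23
and lnCVR 0 — i.e. diversity lowers mean success everywhere, and flips the
variability effect with parasite diversity only for specialists. Moderator
levels are drawn from independent marginals.

Heterogeneity defaults: `tau2_study = 0.45`, `tau2_genus = 0.02`,
`tau2_experiment = 0.08`, `rho = 0.5`. A study-level τ² near 1 would match
the ≈84% study-level I² seen in real compilations, but on a strictly
positive Normal metric with CV 0.2 it would push high-group means negative
at plausible draws, which is incompatible with lnCVR; 0.45 is the largest
round value that keeps the scale valid (clamps are counted and were 0 in
all shipped runs). What the generator deliberately does *not* emulate:
bounded proportion scales and count mean–variance coupling (summaries are
Gaussian on one common scale), moderator collinearity (real compilations
have strongly confounded moderators, e.g. parasite diversity with
laboratory setting), selective publication, and extraction error. Passing
tests therefore certify the estimator and pipeline under the stated
sampling model, not robustness to those real-data features. One visible
consequence: in the scenario the lnCVR effect–SE correlation is sizeably
positive purely because the lnCVR sampling variance grows with the high
group's CV, which co-varies with the true effect — a reminder that this
diagnostic responds to mean–variance structure, not only to publication
bias.

## Problem sizes and checks

The parameter-recovery check fits the 2×2 model (full three-level random
structure) to 500 replicate datasets of 100 studies each, requiring
per-cell |bias| < 0.05 and pooled 95% Wald-CI coverage within [0.92, 0.98]
for both effect kinds; the acceptance script runs the same calibration at
150 replicates. REML fits are verified against (a) an exhaustive
grid-refinement maximiser of the restricted likelihood on ≥100 random
small instances (agreement to 1e-4 in β and τ²), (b) closed-form
inverse-variance weighting at τ² = 0 (exact), and (c) frozen reference
values from an independent multilevel meta-analysis implementation on two
deterministic datasets (agreement to ~5e-4, including the estimated
within-experiment correlation).

## Known limitations

- Wald-z inference mildly undercovers at small study counts (no
  Knapp–Hartung-style t adjustment; a t option exists but is off by
  default to match common practice).
- The fixed-r shared-control covariance is a convention; conclusions
  should be checked under the exact SMD mode and other r values.
- Only two-level diversity contrasts are supported (continuous gradients
  are dichotomised, discarding within-half information).
- No selection models or trim-and-fill; the bias module is diagnostic
  only.
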