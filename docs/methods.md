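# Methods

`stentrisk` models the risk that an implanted iliac-vein stent occludes
within one year of placement, from a flat table of 22 perioperative
predictors (demographics, etiology, stent geometry, coagulation markers,
and 30-day recanalization rates). The pipeline is: stratified 80/20
split, dual-stage AutoML driven by a population metaheuristic, a
six-model comparison, an evaluation layer (discrimination, calibration,
decision curves), and an interpretability layer (L1 path validation and
Shapley attribution). Because no patient-level data ship with the
package, a synthetic cohort generator reproduces the study population's
published marginal summaries and encodes its reported effect structure,
so every stage is testable end to end.

## Baseline statistics

Continuous variables are compared between the training and test
partitions with the Student (pooled-variance) two-sample t-test when both
groups pass Shapiro–Wilk normality at α = 0.05, otherwise with the
Mann–Whitney U test (mid-rank ties; exact p for min(n) ≤ 8 without ties);
categorical variables use the uncorrected Pearson χ². The pooled t and
the uncorrected χ² are the forms that reproduce the published
baseline-table statistics to the printed three decimals; Welch's t and
the Yates correction do not, so they are not offered as defaults.

Stratified splitting rounds the overall training size first
(round(f·N)), then allocates per-outcome-stratum seats by largest
remainder with ties awarded to the minority class. For 826 records with
128 events at f = 0.8 this gives the 661/165 partition with 103 training
events — the only rounding of the 102.4/558.4 quotas whose parts sum to
661 with the extra seat on the event stratum.

## The sequoia optimizer

The optimizer is a population metaheuristic patterned on the
self-regulation of a redwood stand. Per generation, with iteration t of
T:

1. **Canopy growth.** Every individual moves toward the incumbent best
   with coefficient `c·r`, `c = 2(1 − t/T)`, `r ~ U(0,1)^d`. Early
   generations can overshoot the leader (exploration); late generations
   contract onto it.
2. **Seed dispersal.** A uniformly chosen half of the population adds a
   Lévy-flight step `α(t) · levy ⊗ range`, with Mantegna draws at
   β = 1.5. Moves are accepted greedily (an individual relocates only to
   strictly better ground).
3. **Fire renewal.** The worst ⌊0.1·pop⌋ individuals are re-seeded
   across the whole domain each generation.

Positions are clipped to the box; non-finite objective values reject the
candidate with a warning; the best-so-far trajectory is recorded per
iteration, so histories are non-increasing by construction.

The *improved* variant adds two ingredients, and the base variant is
defined as the improved one with both removed:

* **Chaotic initialization.** Latin strata per dimension with
  within-stratum offsets taken from a logistic-map orbit (r = 4) pushed
  through the arcsine CDF so the offsets have uniform marginals. A raw
  reshaped orbit was tried first and rejected: consecutive orbit values
  lie on the map's invariant curve, which *clusters* points in ≥2
  dimensions (it lost every one of 50 seeded minimum-pairwise-distance
  trials against iid uniform, while the stratified form won 41/50).
* **Dynamic step control.** `α(t) = α₀·exp(−4t/T)` (α₀ = 0.1). The base
  variant keeps α fixed at α₀. The dispersal step is scaled by the
  domain range rather than by the distance to the leader: a
  leader-relative step self-anneals as the swarm contracts, which makes
  the fixed-scale base variant exploit just as finely and removes any
  benefit of the decay schedule; with range-scaled steps the schedule is
  the genuine improvement (10–12 of 12 benchmark functions won at the
  scaled protocol, versus 0 with relative steps).

The benchmark harness uses twelve standard test functions (sphere,
ellipsoid, Rosenbrock, Rastrigin, Ackley, Griewank, Zakharov, Lévy,
Schwefel 2.22, Alpine, sum-of-different-powers, expanded Schaffer), each
with its optimum translated to a seeded random point inside the central
60% of the box to avoid origin bias. The comparison protocol is
dimension 10, population 30, and 30 independent runs at 500 iterations;
the test suite runs a scaled version (100 iterations, 10 runs) that
finishes in a few seconds and preserves the ranking. Comparison
baselines (PSO, GA, GWO, WOA) are compact textbook implementations under
the same seeded, clipped, monotone-history contract.

## Dual-stage AutoML

Stage 1 screens a feature mask with one bit per predictor *variable*
(one-hot groups are kept or dropped together). Optimizer positions in
[−4, 4]^p pass through a sigmoid transfer: bit_i = 1 iff u_i < S(x_i); an
all-zero draw is rescued by setting the bit with the largest activation.
The all-features mask is always evaluated as a reference candidate, so a
variable is dropped only when dropping it actually scores better. After
the search, the four best masks are re-scored under a second fold split
and the final mask is chosen by the averaged score — without this, the
argmax over many noisily scored masks systematically favours lucky ones.

Stage 2 tunes the learner in its hyperparameter box (trees 50–500, depth
2–8, learning rate 0.01–0.3, subsample 0.5–1, min leaf 1–20, L2 0–10;
integers rounded at evaluation), conditioned on the stage-1 mask, with
the default configuration seeded into the search so tuning can never end
worse than the default.

Fitness for both stages is the mean out-of-fold ROC-AUC under stratified
k-fold cross-validation (k = 5 by default; the resource-bounded tests use
k = 3) minus a parsimony penalty of 0.01·(selected/total). Inside each
fold, standardization parameters and SMOTE neighbours are fitted on the
fold-training rows only; an audit callback exposes the fold index sets so
tests can assert that no validation row ever reaches the scaler or the
neighbour search. SMOTE (k = 5) interpolates synthetic minority points
uniformly along segments between a minority sample and one of its k
nearest minority neighbours, growing the minority to parity by default.

The tuned learner is a LightGBM gradient-boosted tree ensemble — chosen
for tabular performance and cheap per-sample attribution — behind a small
interface so it can be swapped. The comparison zoo (logistic regression,
Platt-calibrated SVM, AdaBoost, XGBoost, LightGBM) runs with library
defaults on the full feature set; only the AutoML arm selects features
and tunes itself. An optional `paper_mode` additionally oversamples the
*evaluation* partitions to class parity before scoring; it exists because
some studies report metrics whose implied prevalence only arises under
that protocol, and it is never the default because it inflates apparent
prevalence.

## Evaluation

Confusion counts use the tie rule p ≥ threshold → positive, threshold
0.5 by default. The panel is precision, sensitivity, specificity,
accuracy, F1 (harmonic mean), trapezoidal ROC-AUC, and average-precision
PR-AUC (step rule, not trapezoid, to avoid optimistic interpolation).
Calibration uses 10 equal-width bins (empty bins counted but not
plotted) with the Brier score. Decision-curve analysis evaluates

    NB(p_t) = TP/N − (FP/N) · p_t/(1 − p_t)

on the grid 0.01–0.99 (step 0.01), against treat-all
(prev − (1−prev)·p_t/(1−p_t), which crosses zero exactly at the
prevalence) and treat-none (identically zero).

## Interpretability

The L1 logistic path runs on a 100-point log-spaced grid from just above
the null-model threshold λ_max down to 10⁻⁴·λ_max (each solution fitted
with scikit-learn's saga solver at C = 1/(nλ), intercept unpenalized);
five-fold CV deviance selects λ_1se, the largest penalty within one
standard error of the minimum deviance. KKT subgradient conditions
(|∇_j| ≤ λ + 10⁻⁶ on the inactive set) are asserted along the whole path
in the tests. The overlap between the L1-selected and AutoML-selected
variable sets is reported with the L1 set size as denominator.

Shapley values are computed against a background sample: the value of a
coalition is the mean model output with coalition features taken from
the explained record and the rest from background rows. Problems with
d ≤ 16 use exact subset enumeration; larger ones use permutation
sampling with antithetic (forward/reverse) pairs. Both satisfy local
accuracy exactly — the permutation estimator's per-permutation
contributions telescope to f(x) − base — while the per-feature
Monte-Carlo standard error (reported alongside the values) shrinks as
1/√(permutations). Importance is mean |φ| per feature, summed over a
variable's one-hot columns when reporting at the variable level, ties
broken alphabetically.

Interaction analysis partitions samples into the four quadrants of a
thresholded feature pair and reports the mean of the pair's summed
contributions per quadrant plus the difference-in-differences excess
`m_hh − m_hl − m_lh + m_ll`, which is ~0 for additive models. The
`interaction_probe` helper draws explained samples quadrant-balanced (up
to 35 per quadrant) because the high/high cell is rare (~14% of the
cohort for the CRP/D-dimer pair) and would otherwise dominate the
probe's Monte-Carlo error.

## Synthetic cohort generator

Marginals are matched to the published training-column summaries:

* mean ± SD variables → normal, truncated at physical bounds;
* median [IQR] variables → a three-parameter shifted log-normal whose
  shift solves (m−θ)² = (q1−θ)(q3−θ) in closed form (reflected for
  left-skewed triples; an exactly symmetric triple falls back to a
  normal with σ = IQR/1.349);
* when a physical bound (recanalization ∈ [0, 100], positivity) would
  truncate more than ~10⁻⁴ of mass, the three parameters are re-solved
  numerically so the *truncated* quartiles match the printed ones — both
  skew orientations are tried, because truncation itself skews and can
  flip the orientation of the best-fitting base distribution;
* binary/categorical variables → published frequencies; stent count →
  the smallest-support count distribution (P(1,2,3) = 0.6/0.3/0.1)
  reproducing the printed median 1 [1–2].

Sampling is inverse-CDF throughout, so an optional Gaussian-copula
correlation matrix can impose dependence for sensitivity studies;
predictors are independent by default since the source study reports no
correlation structure.

The outcome is Bernoulli with a logistic linear predictor whose terms
encode the reported effect structure: ordinal etiology weights rising to
the DVT + Cockett + PE triad (0 / 0.30 / 0.45 / 1.10 / 2.00); linear
risk slopes for CFV recanalization (−0.028 per %), D-dimer (+0.34 per
mg/L), EIV recanalization (−0.012), CRP (+0.015); protective jumps for
stent diameter > 14 mm (−0.55) and IVC extension > 20 mm (−0.45; the
source's Results and Discussion disagree on this sign and the Results
direction is used); an AV-fistula and male-sex term; anticoagulation
group weights (warfarin 0, NOAC −0.10, none +0.70) with an APTT slope
active only in the no-anticoagulation group; a CRP > 10 × D-dimer > 1.5
synergy indicator (+0.80); and a dual-recanalization indicator
(CFV < 70% and EIV < 70%) whose coefficient is root-found so the
typical-patient risk ratio across the threshold is 2.0. The intercept is
calibrated by bisection on a fixed 10⁵-record Monte-Carlo sample to a
15.5% outcome prevalence (tolerance 0.002); coefficient and intercept
are alternated twice since they interact weakly.

Magnitudes are sized so the intended top-3 effects (etiology, CFV
recanalization, D-dimer — the ordering the source study reports) carry a
clearly larger contribution SD (~0.5) than the next tier (~0.27);
without that margin the end-to-end recovery property ("the generator's
strongest effects surface in the fitted model's Shapley top-5") is
ambiguous by construction, not merely hard. `true_effect_strength`
computes these SDs on a sampled cohort, splitting an interaction term's
SD equally among its members.

What the generator does *not* emulate: predictor correlations (by
default), site-level heterogeneity across the seven contributing
hospitals, time-to-event structure (the outcome is a fixed one-year
binary), measurement error, and missingness. Tests passing on this
generator therefore demonstrate that the pipeline recovers planted
structure under the published marginals and prevalence — not that the
published real-data AUCs are reproducible, which they are not without
the patient data.

## Problem sizes and numerical choices

The test suite runs the benchmark at 100 iterations × 10 runs, effect
recovery at the study's own cohort size (n = 826, 20 seeds, 3-fold CV,
small optimizer budgets), and synergy detection at n = 1000 (20 seeds) —
sizes chosen so each property has comfortable statistical power while
the whole suite stays in the tens of minutes on one CPU. Tolerances:
printed statistics to their printed precision; quantile matching to
1e−6; Shapley local accuracy to 1e−9 (exact and permutation); sampled
vs exact attribution within 3 Monte-Carlo SEs; KKT to 1e−6. Seeds are
fixed everywhere; all simulations are deterministic given the seed.

## Known limitations

* The sequoia optimizer's published description names only the metaphor;
  the operator set here is this package's own concretization, isolated
  behind `iseq_optimize`/`baseline_optimize` so it can be replaced.
* CV scores from the dual-stage search are model-selection scores, not
  unbiased generalization estimates (no nested CV, matching the source
  protocol).
* The L1 path's sparsity is not strictly monotone in λ with correlated
  predictors; the tests check the coarse direction only.
* Exact Shapley enumeration is O(2^d) and guarded at d ≤ 16; the
  permutation estimator's SE is reported but no bias bound is claimed
  for non-tree models with dependent backgrounds.
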