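# Methods

This note documents the models and procedures behind `retscreen`: what the
synthetic-cohort generator assumes, how its parameters are calibrated, the
numerical conventions of each analysis, and the design choices that were
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Cohort model

Each simulated patient has two eyes with true vertical cup-to-disc ratios
(CDR) and is observed by three expert annotators, an AI tool and a junior
clinician ("resident"), each with its own error process and gradability.

**True CDR.** Per-eye truth t is a truncated normal,
t ~ TN(μ = 0.45, σ = 0.12; [0.10, 0.95]), with the two eyes of one
patient sharing a latent factor (correlation `eye_corr`, default 0.6,
applied before truncation; pairs are rejection-sampled so both eyes land
in bounds). The mean/SD place the clinically interesting 0.55–0.6 region
in the upper tail, so the suspect rule labels a minority of patients
positive, as in screening populations; the inter-eye correlation keeps
truth-level asymmetry > 0.2 rare, so the asymmetry clause contributes to
the reference label without dominating it. Clinical CDR distributions are
not literally Gaussian; the truncated normal is a deliberate idealization.

**Expert annotators.** Expert i reads e_i = clip(t + ε_i, 0, 1),
ε_i ~ N(0, s_i²) independent across experts and eyes. The reference
("ground truth") CDR is the mean of the three expert reads, so it carries
noise of SD √(Σ s_i²)/3 around the truth. The s_i are not free knobs:
they are solved from the three configured pairwise expert correlations
(defaults 0.553, 0.820, 0.650) through the shared-truth factor model
r_ij = c_i·c_j with c_i = σ_t/√(σ_t² + s_i²), giving
s = (0.078, 0.135, 0.023) at the defaults — a middle, a noisy and a tight
annotator.

**AI estimates.** a = clip(t + β + ε, 0, 1) with additive bias β = −0.04
and ε ~ N(0, s_AI²). s_AI is calibrated by inverting the folded-normal
mean of the difference (a − reference), whose SD is √(s_AI² + reference
noise²), so that the implied MAE equals the configured target
(default 0.056). The inversion is closed-form-plus-`brentq`, not a grid
search, and raises `CalibrationError` when a target is unattainable
(below |bias|, or below the noise floor the expert-mean reference itself
imposes on the difference).

**Resident estimates.** r = clip(0.5 + λ(t − 0.5) + ε, 0, 1) with slope
λ = 1.5 about center 0.5: one parameter produces the characteristic
proportional bias (underestimating small CDRs, overestimating large
ones) and, because the truth mean sits below the center, a net negative
bias of (λ−1)(μ_t − 0.5) ≈ −0.025. The noise SD is calibrated to the
resident MAE target (default 0.105) the same way as for the AI.

**A note on joint attainability.** Once the truth spread and expert noise
are fixed, MAE and the Pearson correlation with the expert-mean reference
are not independent: for any joint distribution,
SD(a − g) ≥ SD(g)·√(1 − r²), so a small MAE forces a high correlation.
With the default truth SD, the calibrated AI error (MAE 0.056, bias
−0.04) implies r(AI, reference) ≈ 0.90; a substantially lower correlation
at the same MAE would require a much narrower truth distribution.
`SimulationConfig.resolve()` exposes all implied summaries
(`implied["ai_r"]` etc.), and the parameter-recovery tests check the
Monte-Carlo estimates against these self-consistent implied values.

**Gradability.** Per-rater gradability rates (defaults: AI 0.616, experts
0.786, resident 0.954 for optic-disc CDR; AI 0.908 for retinal analysis)
are eye-level marginals. A Gaussian copula shares a patient factor across
eyes (`gradability_eye_corr`, default 0.8). With `nested_gradability`
(default on) all raters threshold the same latent uniform, so the harder
an image, the stricter the set of raters that fail it — reproducing the
observed ordering AI ⊂ experts ⊂ resident without extra parameters. The
retinal-analysis flag is patient-level and correlated with the CDR
gradability through the same patient factor; it is separate because
optic-disc quality gating is stricter than whole-fundus gradability.
A missing estimate and a false gradability flag are the same event by
construction.

**Disease labels and calls.** Each patient draws a risk tier
(none/mild/medium/high) from configured prevalences (defaults 239:75:40:41
out of 395 — the integer structure implied by the printed tier-stratified
panel; see §5). Rater disease calls are Bernoulli at per-tier
sensitivities and an overall specificity per rater.
`simulate_table3_cohort` allocates tiers by largest remainder and, in
deterministic mode, issues calls at exact expected counts, which makes the
tier-panel structure reproducible without sampling noise.

**Ancillary fields.** Age ~ TN(59.1, 15.7; [18, 95]); four
cataract-related symptom flags at fixed plausible first-visit rates
(blurry vision 0.35, colour change 0.08, light sensitivity 0.15, night
difficulty 0.20); resident cataract diagnosis at a base rate 0.03 plus
0.12 for age ≥ 65. These are plausibility choices, not calibrated values;
only the media-opacity rule logic consumes them. The generator makes no
claim that its opacity/cataract joint distribution matches any particular
clinic's.

**Randomness.** One `numpy` `Generator` per field group, spawned from the
master seed with a fixed spawn key per group (append-only registry):
identical (config, seed) pairs give bit-identical cohorts, and adding a
new field group never perturbs existing draws.

**What passing tests show.** The generator validates the analysis
machinery under a known error structure. It does not emulate real fundus
images, heteroscedastic or image-difficulty-correlated rater errors, or
disease-dependent image quality (a hook for the latter exists in the
quality-ablation scenario only), so agreement between this simulator and
the pipeline says nothing about any specific AI product's real-world
performance.

## 2. CDR geometry

Height is the vertical *extent* (max_row − min_row + 1) of the largest
4-connected component — robust to interior holes, unlike counting
foreground rows. The cup is intersected with the disc before measurement
(anatomical containment; prevents CDR > 1 from segmentation spill-over;
CDR > 1 remains representable and flagged for pathological
multi-component discs). ROI boxes are 0-based half-open; padding is a
fraction of the box's own height/width, rounded half-up and clipped to
the raster. Rescaled pixel counts round half-up. The synthetic fixture
rasterizes axis-aligned ellipses through pixel centers, so an integer
vertical semi-axis b spans exactly 2b + 1 rows and the round-trip error
of `compute_cdr` after `synthesize_mask_pair` is bounded by 2/(2b + 1) —
the bound the tests assert over a grid of target CDRs. Image-quality
gating is a caller-supplied predicate, not a learned model.

## 3. Classification rules

Boundary semantics are fixed: the CDR threshold clause is inclusive (≥),
the asymmetry clause strict (> 0.2). The reference rule uses both
clauses on the expert-mean per-eye CDRs; AI and resident predictions
threshold the patient-level maximum without the asymmetry clause
(thresholds 0.55 and 0.6). Applying the threshold to the patient maximum
rather than per eye, and reading the resident's prediction off their
recorded CDR at the clinical 0.6 cutoff, are the documented defaults; the
rule objects accept any threshold/asymmetry combination. Note the full
reference rule is *not* monotone in each eye separately — raising the
lower eye can close the inter-eye gap — only in the higher eye; the
property tests encode exactly that.

The OR-synergy combiner is tri-state: positive if either call is
positive, undetermined only if both are; a single determinate rater
decides. Undetermined-undetermined patients drop out of synergy metrics.

Risk tiers are ordinal (none < mild < medium < high) and a finding set
maps to its highest tier. The shipped finding→tier lookup is a
reviewable default (high covers vitreous hemorrhage, retinal detachment,
neovascularization, severe/proliferative disease), with tessellated
fundus excluded from disease positivity; deployments should replace it
with their own referral criteria. Media-opacity logic is a configurable
set of conjunction rules; the default set contains exactly one rule
(age ≥ 60 ∧ blurry vision ∧ no image meeting the retinal quality
threshold).

F1-optimal threshold selection searches the unique observed scores and
breaks ties toward the largest threshold (the highest-specificity
operating point).

## 4. Metrics, ROC and inference

Metrics with zero denominators are `None`, never silently 0. Printed
percentages are matched with round-half-up to one decimal in exact
integer arithmetic (no float edge cases).

The ROC threshold grid is the unique observed scores plus +∞ with ≥ call
semantics — lossless on finite data. The synergy envelope is reported as
the Pareto set of achievable operating points (not the convex hull: every
reported point is one a program could run at), each annotated with one
achieving threshold pair, closed at (0,0) and (1,1), with trapezoidal
AUC. Missing scores never contribute a positive call; patients missing
both scores are excluded. On instances of ≤ 15 patients the frontier is
verified against exhaustive threshold-pair enumeration.

Bootstrap: the resampling unit is the patient for classification metrics
and the eye for CDR-error metrics, matching the unit of the respective
analyses. Intervals are percentile (n_boot default 2000); p-values are
two-sided with the tie mass at zero counted on both sides and a floor of
1/n_boot. A metric undefined in more than half the resamples is an
error, not a silent NaN. All resampling is seeded; identical seeds give
identical intervals.

Agreement: relative error uses the reference CDR as denominator (the
pair-mean alternative is available); Bland–Altman differences are
estimate − reference; the 1.96 multiplier is fixed (not t-adjusted).
Correlation matrices are pairwise-complete Pearson with a minimum of two
pairs per cell.

## 5. Reconstruction oracle

For a panel of raters sharing one ground truth, the oracle enumerates
every positive count P = 1..n−1 and, per rater, every (tp, tn) cell whose
metrics round (half-up, one decimal) to all printed values; extra printed
metrics (accuracy/PPV/F1) act as joint filters. Uniqueness is asserted,
never assumed: an ambiguous panel raises with the candidate list. The
tier variant recovers (mild, medium, high) splits from tier-restricted
sensitivities, using cross-tier consistency (high-tier true positives
cannot exceed medium-plus true positives) to discard spurious candidates.
The default disease prevalences in §1 are the unique solution for the
panel shipped in the acceptance script.

## 6. Pipeline subsets and the quality ablation

Analysis subsets are explicit and logged: glaucoma classification needs a
patient-level max CDR from reference, AI and resident; eye-level
agreement needs all raters per eye; retinal metrics need an
AI-assessable patient; opacity agreement uses everyone. Reported
exclusion counts must sum with the analyzed n to the cohort size (tested).
An inclusion-policy switch (`resident_inclusion`) controls whether
patients with partially missing resident CDRs enter the resident
analyses; the default requires resident coverage of every
reference-graded eye.

The quality ablation contrasts the study with the AI's image-quality gate
on and off. Simulated cohorts carry an `cdr_ai_ungated` estimate for
every eye — equal to the gated estimate where the gate passes, noisier
(extra SD `ungated_ai_extra_noise_sd`, default 0.10) where it would
reject — so removing the gate trades coverage for error, and the
expected direction (specificity does not rise) is asserted as a sign
test over independent cohorts.

## 7. Problem sizes and numerical conventions

Default analysis cohorts are study-sized (435 patients). Parameter
recovery runs at 10,000 patients (20,000 eyes), where Monte-Carlo error
on bias is ~0.001 against a ±0.005 tolerance. Bootstrap calibration uses
300 replications of an identical-rater null at n = 500 with 400
resamples, checking the empirical type-I error at α = 0.05 against
[0.02, 0.09]. The synergy-frontier oracle check runs 500 random instances
of ≤ 15 patients. The geometry grid covers target CDRs 0.0–1.0 in steps
of 0.1 at disc semi-axes 40, 100 and 200 px. These sizes keep the full
suite and the acceptance script each within a few seconds on one CPU
while leaving the statistical tolerances comfortably non-binding.

## 8. Known limitations

Rater errors are homoscedastic and independent of image difficulty, so
simulated inter-rater correlations on the *estimate* scale run higher
than real clinical data at the same MAE (see §1); percentile bootstrap
intervals can undercover slightly at small n (BCa is out of scope); the
finding→tier lookup and symptom/cataract rates are defaults to review,
not validated clinical content; and no learned segmentation or image
enhancement is included — mask inputs are taken as given.
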