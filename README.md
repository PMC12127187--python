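# retscreen

Evaluation toolkit for AI-vs-clinician ophthalmic screening studies:
glaucoma-suspect classification from cup-to-disc ratio (CDR), retinal-disease
detection with risk-of-vision-loss tiers, media-opacity logic, and the
statistics used to compare raters — bootstrap confidence intervals and
paired p-values, ROC analysis including the dual-threshold OR-synergy
envelope, Cohen's kappa, Bland–Altman agreement, and an integer
confusion-matrix reconstruction oracle for published metric panels.

It is written for biostatisticians and screening researchers who want to
(a) replicate the analysis design of a human-vs-AI screening evaluation on
their own cohort tables, (b) stress-test the statistical machinery on
synthetic cohorts with known error structure, or (c) recover exact counts
from published diagnostic-accuracy tables.

## The statistics at the core

**Glaucoma-suspect rule.** A patient is a suspect when
max(CDR_right, CDR_left) ≥ τ, or (for the reference standard) when
|CDR_right − CDR_left| > 0.2. The reference uses τ = 0.6 on the mean of
three expert annotations; rater predictions use a plain threshold on the
patient-level maximum (τ = 0.55 for the AI's F1-optimal operating point).

**OR-synergy and its ROC envelope.** Two raters are combined by calling a
patient positive when *either* is positive. For continuous scores s_A, s_B
the rule (s_A ≥ τ_A) ∨ (s_B ≥ τ_B) traces, over all threshold pairs, a
two-parameter set of (FPR, TPR) points; `synergy_roc` returns its
Pareto-dominant frontier with AUC by the trapezoid rule. Because τ_B = +∞
recovers rater A's own curve, the envelope dominates both single-score
ROCs pointwise — so sensitivity(OR) ≥ each component's and
specificity(OR) ≤ each component's, as an identity.

**Bootstrap inference.** Metrics (accuracy, sensitivity, specificity, PPV,
F1) carry percentile 95% CIs from resampling patients with replacement;
two raters observed on the same patients are compared with a paired
bootstrap p-value p = 2·min(P(Δ* ≤ 0), P(Δ* ≥ 0)), clipped below at
1/n_boot.

**Agreement.** Continuous CDR agreement is summarized by MAE, relative
error, Pearson r, and Bland–Altman bias ± 1.96·SD limits (differences
oriented estimate − reference). Categorical agreement uses Cohen's
κ = (p_o − p_e)/(1 − p_e) and percent agreement.

**Reconstruction oracle.** Given a table of percentages printed to one
decimal for several raters sharing one ground truth, `reconstruct_counts`
brute-forces every integer 2×2 table consistent with all printed values
(round-half-up, exact integer arithmetic) and certifies uniqueness — often
recovering the exact counts behind a published panel.

**CDR geometry.** From binary disc/cup segmentation masks, CDR = vertical
extent of the cup's largest 4-connected component (after intersecting with
the disc) divided by the disc's, with ROI extraction and half-up pixel
rescaling between resized and original frames.

## Worked example

Recover the exact confusion matrices behind a printed glaucoma-suspect
panel (three approaches, n = 245, percentages to one decimal):

```python
from retscreen import metric_set, reconstruct_counts

printed = {
    "resident": {"sensitivity": 50.0, "specificity": 90.5},
    "ai":       {"sensitivity": 63.0, "specificity": 94.5},
    "synergy":  {"sensitivity": 80.4, "specificity": 86.4},
}
positives, cells = reconstruct_counts(printed, n=245)
```

Running `python examples/reconstruct_printed_panel.py` prints:

```
unique solution: 46 positives / 199 negatives

resident  tp= 23 fp= 19 fn= 23 tn=180  -> accuracy 82.9%, ppv 54.8%, f1 52.3%
ai        tp= 29 fp= 11 fn= 17 tn=188  -> accuracy 88.6%, ppv 72.5%, f1 67.4%
synergy   tp= 37 fp= 27 fn=  9 tn=172  -> accuracy 85.3%, ppv 57.8%, f1 67.3%
```

Six printed sensitivity/specificity values pin down a unique positive
count (46) and unique cells per approach; the derived accuracy/PPV/F1
columns are implied by those counts and can be checked against the
published ones.

The other capabilities each have a narrative script under `examples/`:
cohort simulation (`simulate_cohort.py`), mask-based CDR measurement
(`cdr_from_masks.py`), the synergy ROC envelope
(`synergy_roc_envelope.py`), Bland–Altman agreement
(`agreement_bland_altman.py`) and the full pipeline
(`full_study_report.py`). A thin CLI mirrors the pipeline:
`retscreen simulate | run | ablate | cdr-from-masks | reconstruct-counts`.

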