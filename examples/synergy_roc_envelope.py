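"""The OR-synergy ROC envelope of two raters' CDR scores.

A patient is called glaucoma-suspect when either the resident's or the
AI's maximum per-patient CDR exceeds its own threshold. Sweeping both
thresholds traces a two-parameter family of operating points whose
Pareto frontier dominates each single-rater ROC curve.
"""

from retscreen import (
    SimulationConfig,
    cohort_to_frames,
    operating_point,
    roc_curve,
    simulate_cohort,
    synergy_roc,
)

eyes, _ = cohort_to_frames(simulate_cohort(SimulationConfig(n_patients=435, seed=7)))
complete = eyes.dropna(subset=["cdr_gt", "cdr_ai", "cdr_resident"])
g = complete.groupby("patient_id").agg(
    gt=("cdr_gt", "max"), ai=("cdr_ai", "max"), res=("cdr_resident", "max")
)
truth = (g["gt"] >= 0.6).to_numpy()
print(f"{len(g)} patients with a max CDR from every rater, "
      f"{truth.sum()} suspects by the reference rule")

ai = roc_curve(g["ai"], truth)
res = roc_curve(g["res"], truth)
syn = synergy_roc(g["res"], g["ai"], truth)
print(f"\nAUC: AI {ai.auc:.3f}, resident {res.auc:.3f}, OR-synergy {syn.auc:.3f}")
print("the synergy AUC can never fall below the better component: setting "
      "one threshold to +inf recovers the other rater's curve")

p = operating_point(syn, "match_specificity", target=0.90)
print(f"\nat specificity >= 0.90 the envelope offers sensitivity "
      f"{p.tpr:.3f} (resident threshold {p.threshold_a}, AI threshold "
      f"{p.threshold_b})")
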