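"""Continuous agreement of CDR estimates: MAE, Bland-Altman, correlations.

Compares AI and resident CDR estimates with the expert-mean reference on
the eyes every rater measured, the way human-vs-algorithm measurement
agreement is conventionally reported.
"""

from retscreen import (
    SimulationConfig,
    agreement,
    cohort_to_frames,
    correlation_matrix,
    simulate_cohort,
)

eyes, _ = cohort_to_frames(simulate_cohort(SimulationConfig(n_patients=2000, seed=3)))
sub = eyes.dropna(subset=["cdr_gt", "cdr_ai", "cdr_resident"])
print(f"{len(sub)} eyes measured by all three expert annotators, the AI "
      "and the resident\n")

for rater, col in (("AI", "cdr_ai"), ("resident", "cdr_resident")):
    s = agreement(sub[col].to_numpy(), sub["cdr_gt"].to_numpy())
    print(f"{rater:9s} MAE {s.mae:.3f} (SD {s.mae_sd:.3f}), relative error "
          f"{s.relative_error_mean:.1f}%, r {s.pearson_r:.3f}")
    print(f"          bias {s.bias:+.3f}, limits of agreement "
          f"[{s.loa_low:+.3f}, {s.loa_high:+.3f}]")

corr = correlation_matrix(
    eyes[["cdr_expert_1", "cdr_expert_2", "cdr_expert_3", "cdr_gt", "cdr_ai",
          "cdr_resident"]]
)
print("\npairwise-complete Pearson correlations:")
print(corr.round(3).to_string())
print("\nNarrower limits of agreement mean more consistent estimates; the "
      "limits are bias ± 1.96 SD of the estimate-minus-reference differences.")
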