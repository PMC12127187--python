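"""Generate a synthetic screening cohort and look at its error structure.

The generator draws per-eye true cup-to-disc ratios from a truncated
normal, then derives three expert reads, an AI estimate and a resident
estimate whose noise levels are calibrated so the cohort reproduces the
configured summary statistics (expert pairwise correlations, rater MAE
and bias against the expert-mean reference).
"""

from retscreen import SimulationConfig, cohort_to_frames, simulate_cohort, write_cohort

cfg = SimulationConfig(n_patients=2000, seed=42)
resolved = cfg.resolve()
print("calibrated noise SDs:")
print(f"  experts: {[round(s, 4) for s in resolved.expert_noise_sd]}")
print(f"  ai: {resolved.ai_noise_sd:.4f}  resident: {resolved.resident_noise_sd:.4f}")

records = simulate_cohort(cfg)
eyes, patients = cohort_to_frames(records)
write_cohort(records, "scratch_cohort")

complete = eyes.dropna(subset=["cdr_gt", "cdr_ai", "cdr_resident"])
d_ai = complete["cdr_ai"] - complete["cdr_gt"]
d_res = complete["cdr_resident"] - complete["cdr_gt"]
print(f"\n{len(patients)} patients, {len(eyes)} eyes, "
      f"{len(complete)} eyes measured by every rater")
print(f"AI:       MAE {d_ai.abs().mean():.3f} (target {cfg.ai_mae_target}), "
      f"bias {d_ai.mean():+.3f} (target {cfg.ai_bias})")
print(f"resident: MAE {d_res.abs().mean():.3f} (target {cfg.resident_mae_target}), "
      f"bias {d_res.mean():+.3f}")
print("\nA negative bias means the rater underestimates the cup-to-disc "
      "ratio relative to the expert-mean reference; the MAE targets are the "
      "calibration constants the noise model was solved for.")
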