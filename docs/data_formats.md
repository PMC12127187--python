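# Data formats

## Cohort tables

A cohort is two UTF-8, comma-separated tables with header rows; missing
values are the literal string `NA`. `retscreen.write_cohort` /
`read_cohort` produce and parse them; user-supplied cohorts in the same
schema run through the pipeline unchanged.

### eyes.csv — one row per eye

| column | type | meaning |
| --- | --- | --- |
| `patient_id` | int | joins to patients.csv |
| `side` | `right` / `left` | at most one row per side per patient |
| `cdr_true` | float [0,1] | simulator truth (synthetic cohorts only; ignored by analyses) |
| `cdr_expert_1..3` | float or NA | the three expert annotations |
| `cdr_gt` | float or NA | expert-mean reference; present iff all three experts are |
| `cdr_ai` | float or NA | AI estimate, quality-gated |
| `cdr_resident` | float or NA | resident estimate |
| `cdr_ai_ungated` | float | AI estimate with the quality gate removed (used by the ablation) |
| `gradable_ai`, `gradable_expert`, `gradable_resident` | bool | a false flag corresponds exactly to a missing estimate |

### patients.csv — one row per patient

| column | type | meaning |
| --- | --- | --- |
| `patient_id` | int | |
| `age` | float, years | |
| `disease_tier_true` | `none` / `mild` / `medium` / `high` | risk-of-vision-loss tier |
| `disease_pos_ai`, `disease_pos_resident` | bool or NA | retinal-disease calls; NA when the rater had no assessable image |
| `retina_gradable_ai` | bool | at least one fundus image passed the AI's retinal-analysis quality check (distinct from the stricter optic-disc gradability in eyes.csv) |
| `blurry_vision`, `color_change`, `light_sensitivity`, `night_difficulty` | bool | cataract-related symptoms |
| `cataract_dx_resident` | bool | resident cataract diagnosis |

## Config YAML

`SimulationConfig.to_yaml` / `from_yaml` serialize the generator
configuration as a flat mapping of the dataclass fields (see
`retscreen/config.py` for defaults and validation). Example:

```yaml
n_patients: 435
seed: 7
cdr_mean: 0.45
cdr_sd: 0.12
cdr_bounds: [0.10, 0.95]
expert_corr_targets: [0.553, 0.820, 0.650]
ai_bias: -0.04
ai_mae_target: 0.056
resident_slope: 1.5
resident_mae_target: 0.105
gradability_rates: {ai: 0.616, expert: 0.786, resident: 0.954, ai_retinal: 0.908}
disease_prevalence: {none: 0.60506, mild: 0.18987, medium: 0.10127, high: 0.10380}
```

Noise SDs left unset are derived from the calibration targets at
resolve time; set them explicitly (e.g. to 0) to bypass calibration.
Prevalences must sum to 1 within 1e-9.

## Masks

Disc and cup masks are single-channel PNGs, 0 = background, nonzero =
foreground, sharing one coordinate frame (row 0 at the top; the row axis
is "vertical"). `retscreen cdr-from-masks --disc d.png --cup c.png`
prints a one-line JSON measurement.

## Reconstruction panel YAML

For `retscreen reconstruct-counts --panel panel.yaml`:

```yaml
n: 245
printed:
  resident: {sensitivity: 50.0, specificity: 90.5}
  ai:       {sensitivity: 63.0, specificity: 94.5}
  synergy:  {sensitivity: 80.4, specificity: 86.4}
```

Percentages must be given to one decimal; metrics may be any subset of
accuracy/sensitivity/specificity/ppv/f1 per rater.
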