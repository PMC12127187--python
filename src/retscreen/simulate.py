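"""Synthetic screening-cohort generator.

Emulates the statistical structure of a two-eye ophthalmic screening
cohort evaluated by three expert annotators, an AI tool and a junior
clinician: correlated true CDRs per patient, per-rater measurement error
calibrated to summary targets (see :mod:`retscreen.config`), per-rater
gradability with a nested quality ordering, tiered retinal-disease labels
with per-tier rater operating points, ages, cataract-related symptoms and
resident cataract diagnoses.

Randomness is organised as one independent stream per field group, each
derived from the master seed with a fixed spawn key, so adding a new field
group never perturbs the draws of existing ones and identical
(config, seed) pairs yield bit-identical cohorts.

What the generator deliberately does NOT emulate: real fundus images, the
empirical (non-Gaussian) shape of clinical CDR distributions, and
systematic dependence of image quality on disease beyond the configurable
hooks. Passing tests on these cohorts validate the analysis machinery,
not any claim about real-world rater performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig

__all__ = [
    "EyeObservation",
    "PatientRecord",
    "simulate_cohort",
    "simulate_table3_cohort",
    "cohort_to_frames",
    "write_cohort",
    "read_cohort",
]

SIDES = ("right", "left")
TIERS = ("none", "mild", "medium", "high")
SYMPTOMS = ("blurry_vision", "color_change", "light_sensitivity", "night_difficulty")

# fixed registry of per-field-group RNG streams (spawn keys off the master
# seed); append-only so existing draws stay stable when fields are added
_STREAMS = (
    "cdr_true",
    "expert",
    "ai",
    "resident",
    "gradability",
    "disease_tier",
    "disease_calls",
    "age",
    "symptoms",
    "cataract",
    "ai_ungated",
    "retina_gradability",
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    key = _STREAMS.index(stream)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass(frozen=True)
class EyeObservation:
    """One eye's CDR estimates across raters, with gradability flags.

    A missing estimate (None) corresponds exactly to a false gradability
    flag for that rater; ``cdr_gt`` (the expert-mean reference) is present
    iff all three expert values are. ``cdr_ai_ungated`` is the estimate the
    AI would produce with its quality gate removed: identical to ``cdr_ai``
    on gradable eyes, noisier on ungradable ones.
    """

    patient_id: int
    side: str
    cdr_true: float
    cdr_expert_1: float | None
    cdr_expert_2: float | None
    cdr_expert_3: float | None
    cdr_gt: float | None
    cdr_ai: float | None
    cdr_resident: float | None
    cdr_ai_ungated: float
    gradable_ai: bool
    gradable_expert: bool
    gradable_resident: bool


@dataclass(frozen=True)
class PatientRecord:
    """One patient: up to two eyes plus patient-level labels and calls."""

    patient_id: int
    age: float
    eyes: tuple[EyeObservation, ...]
    disease_tier_true: str
    disease_pos_ai: bool | None
    disease_pos_resident: bool | None
    retina_gradable_ai: bool
    symptoms: frozenset[str] = frozenset()
    cataract_dx_resident: bool = False

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if len(self.eyes) > 2:
            raise ValueError("at most two eyes per patient")
        sides = [e.side for e in self.eyes]
        if len(set(sides)) != len(sides):
            raise ValueError("eyes must have distinct sides")
        if self.disease_tier_true not in TIERS:
            raise ValueError(f"unknown tier {self.disease_tier_true!r}")


def _sample_truth(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """(n, 2) true CDRs: correlated within patient, truncated marginals."""
    lo, hi = cfg.cdr_bounds
    rho = cfg.eye_corr
    out = np.empty((n, 2))
    todo = np.arange(n)
    while todo.size:
        zp = rng.standard_normal(todo.size)
        ze = rng.standard_normal((todo.size, 2))
        lat = np.sqrt(rho) * zp[:, None] + np.sqrt(1.0 - rho) * ze
        t = cfg.cdr_mean + cfg.cdr_sd * lat
        ok = ((t >= lo) & (t <= hi)).all(axis=1)
        out[todo[ok]] = t[ok]
        todo = todo[~ok]
    return out


def _gradability(rng, n: int, cfg: SimulationConfig):
    """Per-eye gradability flags (n, 2) per rater plus the patient-level
    retinal-analysis flag. A Gaussian copula shares a patient factor across
    eyes; with nested gradability all raters threshold the same uniform, so
    harder images fail the stricter raters first."""
    rates = cfg.gradability_rates
    g = cfg.gradability_eye_corr
    zp = rng.standard_normal(n)

    def eye_uniform():
        ze = rng.standard_normal((n, 2))
        return stats.norm.cdf(np.sqrt(g) * zp[:, None] + np.sqrt(1.0 - g) * ze)

    if cfg.nested_gradability:
        v = eye_uniform()
        flags = {r: v < rates[r] for r in ("ai", "expert", "resident")}
    else:
        flags = {r: eye_uniform() < rates[r] for r in ("ai", "expert", "resident")}
    return flags, zp


def _retina_gradability(rng, zp: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    g = cfg.gradability_eye_corr
    z = rng.standard_normal(zp.size)
    v = stats.norm.cdf(np.sqrt(g) * zp + np.sqrt(1.0 - g) * z)
    return v < cfg.gradability_rates.get("ai_retinal", 1.0)


def simulate_cohort(config: SimulationConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` records; deterministic under
    ``config.seed``."""
    cfg = config
    n = cfg.n_patients
    if n == 0:
        return []
    res = cfg.resolve()
    seed = cfg.seed

    t = _sample_truth(_rng(seed, "cdr_true"), n, cfg)                       # (n, 2)

    rng_e = _rng(seed, "expert")
    experts = np.clip(
        t[:, :, None] + np.array(res.expert_noise_sd) * rng_e.standard_normal((n, 2, 3)),
        0.0,
        1.0,
    )
    gt = experts.mean(axis=2)

    rng_a = _rng(seed, "ai")
    ai = np.clip(t + cfg.ai_bias + res.ai_noise_sd * rng_a.standard_normal((n, 2)), 0.0, 1.0)

    rng_r = _rng(seed, "resident")
    resident = np.clip(
        cfg.resident_center
        + cfg.resident_slope * (t - cfg.resident_center)
        + res.resident_noise_sd * rng_r.standard_normal((n, 2)),
        0.0,
        1.0,
    )

    flags, zp = _gradability(_rng(seed, "gradability"), n, cfg)
    retina_ok = _retina_gradability(_rng(seed, "retina_gradability"), zp, cfg)

    rng_u = _rng(seed, "ai_ungated")
    extra_sd = np.sqrt(res.ai_noise_sd**2 + cfg.ungated_ai_extra_noise_sd**2)
    ai_ungated_raw = np.clip(
        t + cfg.ai_bias + extra_sd * rng_u.standard_normal((n, 2)), 0.0, 1.0
    )
    ai_ungated = np.where(flags["ai"], ai, ai_ungated_raw)

    tiers = _rng(seed, "disease_tier").choice(
        TIERS, size=n, p=[cfg.disease_prevalence[k] for k in TIERS]
    )

    rng_c = _rng(seed, "disease_calls")
    calls = {}
    for rater in ("ai", "resident"):
        ops = cfg.rater_operating_points[rater]
        p_pos = np.where(
            tiers == "none",
            1.0 - ops["specificity"],
            np.select(
                [tiers == k for k in ("mild", "medium", "high")],
                [ops["sensitivity"][k] for k in ("mild", "medium", "high")],
                default=0.0,
            ),
        )
        calls[rater] = rng_c.uniform(size=n) < p_pos

    a_lo, a_hi = cfg.age_bounds
    aa, ab = (a_lo - cfg.age_mean) / cfg.age_sd, (a_hi - cfg.age_mean) / cfg.age_sd
    ages = stats.truncnorm.ppf(
        _rng(seed, "age").uniform(size=n), aa, ab, loc=cfg.age_mean, scale=cfg.age_sd
    )

    rng_s = _rng(seed, "symptoms")
    symp = {s: rng_s.uniform(size=n) < cfg.symptom_probs[s] for s in SYMPTOMS}

    p_cat = cfg.cataract_base_rate + cfg.cataract_elderly_extra * (ages >= 65.0)
    cataract = _rng(seed, "cataract").uniform(size=n) < np.clip(p_cat, 0.0, 1.0)

    records = []
    for i in range(n):
        eyes = []
        for j, side in enumerate(SIDES):
            ge = bool(flags["expert"][i, j])
            ga = bool(flags["ai"][i, j])
            gr = bool(flags["resident"][i, j])
            ev = [float(experts[i, j, k]) if ge else None for k in range(3)]
            eyes.append(
                EyeObservation(
                    patient_id=i,
                    side=side,
                    cdr_true=float(t[i, j]),
                    cdr_expert_1=ev[0],
                    cdr_expert_2=ev[1],
                    cdr_expert_3=ev[2],
                    cdr_gt=float(gt[i, j]) if ge else None,
                    cdr_ai=float(ai[i, j]) if ga else None,
                    cdr_resident=float(resident[i, j]) if gr else None,
                    cdr_ai_ungated=float(ai_ungated[i, j]),
                    gradable_ai=ga,
                    gradable_expert=ge,
                    gradable_resident=gr,
                )
            )
        any_res = any(e.gradable_resident for e in eyes)
        records.append(
            PatientRecord(
                patient_id=i,
                age=float(ages[i]),
                eyes=tuple(eyes),
                disease_tier_true=str(tiers[i]),
                disease_pos_ai=bool(calls["ai"][i]) if retina_ok[i] else None,
                disease_pos_resident=bool(calls["resident"][i]) if any_res else None,
                retina_gradable_ai=bool(retina_ok[i]),
                symptoms=frozenset(s for s in SYMPTOMS if symp[s][i]),
                cataract_dx_resident=bool(cataract[i]),
            )
        )
    return records


def _largest_remainder(fractions: Sequence[float], n: int) -> list[int]:
    """Integer allocation of n by the largest-remainder method."""
    raw = [f * n for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    short = n - sum(base)
    order = np.argsort([b - x for b, x in zip(base, raw)])  # largest remainder first
    for k in order[:short]:
        base[int(k)] += 1
    return base


def simulate_table3_cohort(
    config: SimulationConfig, deterministic: bool = False
) -> list[PatientRecord]:
    """Cohort for tier-stratified retinal-disease analysis only.

    Tier counts follow the configured prevalences by largest-remainder
    allocation. With ``deterministic=True`` rater calls hit their per-tier
    operating points in exact expected counts (no sampling); otherwise
    calls are Bernoulli draws at those rates. All patients are
    retina-gradable; eye-level CDR fields are not generated.
    """
    cfg = config
    n = cfg.n_patients
    if n == 0:
        return []
    counts = _largest_remainder([cfg.disease_prevalence[k] for k in TIERS], n)
    tiers = np.repeat(TIERS, counts)

    calls = {}
    rng = _rng(cfg.seed, "disease_calls")
    for rater in ("ai", "resident"):
        ops = cfg.rater_operating_points[rater]
        pos = np.zeros(n, dtype=bool)
        start = 0
        for tier, cnt in zip(TIERS, counts):
            p = (1.0 - ops["specificity"]) if tier == "none" else ops["sensitivity"][tier]
            block = slice(start, start + cnt)
            if deterministic:
                k = int(np.floor(p * cnt + 0.5))
                pos[start : start + k] = True
            else:
                pos[block] = rng.uniform(size=cnt) < p
            start += cnt
        calls[rater] = pos

    return [
        PatientRecord(
            patient_id=i,
            age=cfg.age_mean,
            eyes=(),
            disease_tier_true=str(tiers[i]),
            disease_pos_ai=bool(calls["ai"][i]),
            disease_pos_resident=bool(calls["resident"][i]),
            retina_gradable_ai=True,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# tabular serialization: eyes.csv + patients.csv (UTF-8, comma-separated,
# header row, literal NA for missing)
# ---------------------------------------------------------------------------

EYE_COLUMNS = [
    "patient_id",
    "side",
    "cdr_true",
    "cdr_expert_1",
    "cdr_expert_2",
    "cdr_expert_3",
    "cdr_gt",
    "cdr_ai",
    "cdr_resident",
    "cdr_ai_ungated",
    "gradable_ai",
    "gradable_expert",
    "gradable_resident",
]

PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "disease_tier_true",
    "disease_pos_ai",
    "disease_pos_resident",
    "retina_gradable_ai",
    *SYMPTOMS,
    "cataract_dx_resident",
]


def cohort_to_frames(records: Iterable[PatientRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(eyes, patients) DataFrames with the documented column schemas."""
    eye_rows, pat_rows = [], []
    for rec in records:
        for e in rec.eyes:
            eye_rows.append({c: getattr(e, c) for c in EYE_COLUMNS})
        row = {
            "patient_id": rec.patient_id,
            "age": rec.age,
            "disease_tier_true": rec.disease_tier_true,
            "disease_pos_ai": rec.disease_pos_ai,
            "disease_pos_resident": rec.disease_pos_resident,
            "retina_gradable_ai": rec.retina_gradable_ai,
            "cataract_dx_resident": rec.cataract_dx_resident,
        }
        for s in SYMPTOMS:
            row[s] = s in rec.symptoms
        pat_rows.append(row)
    eyes = pd.DataFrame(eye_rows, columns=EYE_COLUMNS)
    patients = pd.DataFrame(pat_rows, columns=PATIENT_COLUMNS)
    return eyes, patients


def write_cohort(records: Iterable[PatientRecord], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    eyes, patients = cohort_to_frames(records)
    eyes.to_csv(directory / "eyes.csv", index=False, na_rep="NA")
    patients.to_csv(directory / "patients.csv", index=False, na_rep="NA")


_BOOL_COLS_EYES = ["gradable_ai", "gradable_expert", "gradable_resident"]
_BOOL_COLS_PATIENTS = [
    "disease_pos_ai",
    "disease_pos_resident",
    "retina_gradable_ai",
    *SYMPTOMS,
    "cataract_dx_resident",
]


def _parse_bools(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    for c in cols:
        if c in df.columns and df[c].dtype == object:
            df[c] = df[c].map({"True": True, "False": False, True: True, False: False})
    return df


def read_cohort(directory) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read eyes.csv / patients.csv back into DataFrames (NA -> NaN/None)."""
    directory = Path(directory)
    eyes = pd.read_csv(directory / "eyes.csv", na_values=["NA"], keep_default_na=False)
    patients = pd.read_csv(directory / "patients.csv", na_values=["NA"], keep_default_na=False)
    missing = set(EYE_COLUMNS) - set(eyes.columns)
    if missing:
        raise ValueError(f"eyes.csv missing columns: {sorted(missing)}")
    missing = set(PATIENT_COLUMNS) - set(patients.columns)
    if missing:
        raise ValueError(f"patients.csv missing columns: {sorted(missing)}")
    return _parse_bools(eyes, _BOOL_COLS_EYES), _parse_bools(patients, _BOOL_COLS_PATIENTS)
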