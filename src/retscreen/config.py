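"""Simulation configuration and analytic calibration.

The synthetic-cohort generator is parameterized by summary statistics a
screening-evaluation study would report (expert pairwise correlations,
rater MAE against the expert-mean reference, bias, gradability rates,
tiered disease prevalence, per-tier rater operating points). This module
turns those calibration targets into generator noise parameters in closed
form:

* expert per-annotator noise SDs follow from the three pairwise
  correlation targets via the shared-truth factor model
  r_ij = c_i * c_j with c_i = sd_t / sqrt(sd_t^2 + s_i^2);
* AI / resident noise SDs follow from the MAE targets by inverting the
  folded-normal mean of the estimate-minus-reference difference.

The resolved parameters also expose the *implied* downstream summaries
(bias, MAE, Pearson r against the expert mean) so parameter-recovery tests
compare Monte-Carlo estimates against analytically derived values rather
than against copied constants. Not every trio of published summaries is
jointly attainable: once the truth spread and expert noise are fixed, the
correlation with the expert mean is determined up to the rater noise, and
a small MAE forces a high correlation. The implied values are the
self-consistent ones.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = ["SimulationConfig", "ResolvedParams", "CalibrationError"]


class CalibrationError(ValueError):
    """A calibration target is unattainable under the configured model."""


def _default_gradability() -> dict[str, float]:
    # fraction of patients each rater can assess: optic-disc CDR gradability
    # for ai/expert/resident, plus the (laxer) retinal-analysis gradability
    return {"ai": 0.616, "expert": 0.786, "resident": 0.954, "ai_retinal": 0.908}


def _default_prevalence() -> dict[str, float]:
    # retinal-disease risk tiers among patients with an AI-assessable eye
    return {"none": 239 / 395, "mild": 75 / 395, "medium": 40 / 395, "high": 41 / 395}


def _default_operating_points() -> dict[str, dict]:
    # per-tier detection sensitivity and overall specificity per rater
    return {
        "ai": {
            "sensitivity": {"mild": 46 / 75, "medium": 32 / 40, "high": 1.0},
            "specificity": 229 / 239,
        },
        "resident": {
            "sensitivity": {"mild": 30 / 75, "medium": 18 / 40, "high": 33 / 41},
            "specificity": 216 / 239,
        },
    }


def _default_symptoms() -> dict[str, float]:
    # plausible symptom rates for a first-visit tertiary-care population
    return {
        "blurry_vision": 0.35,
        "color_change": 0.08,
        "light_sensitivity": 0.15,
        "night_difficulty": 0.20,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic cohort generator.

    Noise SDs left as ``None`` are derived from the calibration targets at
    :meth:`resolve` time; setting them explicitly (e.g. to zero for the
    noise-free degenerate cohort) bypasses calibration.
    """

    n_patients: int = 435
    seed: int = 0

    # true CDR distribution: truncated normal per eye, correlated between
    # the two eyes of a patient
    cdr_mean: float = 0.45
    cdr_sd: float = 0.12
    cdr_bounds: tuple[float, float] = (0.10, 0.95)
    eye_corr: float = 0.6

    # expert annotators: three independent noisy reads of the truth
    expert_corr_targets: tuple[float, float, float] = (0.553, 0.820, 0.650)  # r12, r13, r23
    expert_noise_sd: tuple[float, float, float] | None = None

    # AI CDR estimates: additive bias + noise, calibrated to an MAE target
    ai_bias: float = -0.04
    ai_mae_target: float = 0.056
    ai_noise_sd: float | None = None

    # resident CDR estimates: proportional bias about a center (slope > 1
    # underestimates small CDRs and overestimates large ones) + noise
    resident_slope: float = 1.5
    resident_center: float = 0.5
    resident_mae_target: float = 0.105
    resident_noise_sd: float | None = None

    gradability_rates: dict[str, float] = field(default_factory=_default_gradability)
    nested_gradability: bool = True
    gradability_eye_corr: float = 0.8

    disease_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    rater_operating_points: dict[str, dict] = field(default_factory=_default_operating_points)

    age_mean: float = 59.1
    age_sd: float = 15.7
    age_bounds: tuple[float, float] = (18.0, 95.0)
    symptom_probs: dict[str, float] = field(default_factory=_default_symptoms)
    cataract_base_rate: float = 0.03
    cataract_elderly_extra: float = 0.12  # added probability when age >= 65

    # extra estimate noise on eyes the quality gate would reject (used by
    # the quality-ablation scenario)
    ungated_ai_extra_noise_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        lo, hi = self.cdr_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("cdr_bounds must satisfy 0 < lo < hi < 1")
        if self.cdr_sd <= 0:
            raise ValueError("cdr_sd must be positive")
        if not 0.0 <= self.eye_corr < 1.0:
            raise ValueError("eye_corr must be in [0, 1)")
        if self.resident_slope <= 0:
            raise ValueError("resident_slope must be positive")
        for name, p in {**self.gradability_rates, **self.symptom_probs}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        prev = self.disease_prevalence
        if set(prev) != {"none", "mild", "medium", "high"}:
            raise ValueError("disease_prevalence must cover exactly none/mild/medium/high")
        if any(not 0.0 <= p <= 1.0 for p in prev.values()):
            raise ValueError("prevalences must be probabilities")
        if abs(sum(prev.values()) - 1.0) > 1e-9:
            raise ValueError(f"tier prevalences sum to {sum(prev.values())}, not 1")
        for rater, ops in self.rater_operating_points.items():
            for tier, s in ops["sensitivity"].items():
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"{rater} sensitivity[{tier}]={s} outside [0, 1]")
            if not 0.0 <= ops["specificity"] <= 1.0:
                raise ValueError(f"{rater} specificity outside [0, 1]")

    # -- persistence ------------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        kwargs = dict(raw)
        for key in ("cdr_bounds", "age_bounds", "expert_corr_targets", "expert_noise_sd"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def resolve(self) -> "ResolvedParams":
        return _resolve(self)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass(frozen=True)
class ResolvedParams:
    """Calibrated generator parameters plus implied downstream summaries."""

    mu_t: float          # mean of the truncated true-CDR distribution
    sd_t: float          # its SD
    expert_noise_sd: tuple[float, float, float]
    gt_noise_sd: float   # SD of the expert-mean reference around the truth
    ai_noise_sd: float
    resident_noise_sd: float
    implied: dict[str, float]


def folded_normal_mean(mu: float, sigma: float) -> float:
    """E|X| for X ~ N(mu, sigma^2)."""
    if sigma == 0.0:
        return abs(mu)
    return sigma * math.sqrt(2.0 / math.pi) * math.exp(
        -(mu * mu) / (2.0 * sigma * sigma)
    ) + mu * math.erf(mu / (sigma * math.sqrt(2.0)))


def _solve_sigma_for_mae(mu: float, mae: float) -> float:
    """Invert the folded-normal mean in sigma for fixed mu."""
    if mae < abs(mu):
        raise CalibrationError(f"MAE target {mae} below |bias| {abs(mu)}")
    if math.isclose(mae, abs(mu), rel_tol=0, abs_tol=1e-12):
        return 0.0
    f = lambda s: folded_normal_mean(mu, s) - mae
    return float(optimize.brentq(f, 1e-9, 2.0, xtol=1e-12))


def _resolve(cfg: SimulationConfig) -> ResolvedParams:
    lo, hi = cfg.cdr_bounds
    a, b = (lo - cfg.cdr_mean) / cfg.cdr_sd, (hi - cfg.cdr_mean) / cfg.cdr_sd
    mu_t, var_t = stats.truncnorm.stats(a, b, loc=cfg.cdr_mean, scale=cfg.cdr_sd, moments="mv")
    mu_t, var_t = float(mu_t), float(var_t)
    sd_t = math.sqrt(var_t)

    # expert noise from pairwise correlation targets (shared-truth factors)
    if cfg.expert_noise_sd is not None:
        s_experts = tuple(float(s) for s in cfg.expert_noise_sd)
    else:
        r12, r13, r23 = cfg.expert_corr_targets
        if min(r12, r13, r23) <= 0:
            raise CalibrationError("pairwise correlation targets must be positive")
        c1sq = r12 * r13 / r23
        c2sq = r12 * r23 / r13
        c3sq = r13 * r23 / r12
        if max(c1sq, c2sq, c3sq) > 1.0:
            raise CalibrationError(
                f"correlation targets {cfg.expert_corr_targets} violate the "
                "shared-truth factor model (some c_i^2 > 1)"
            )
        s_experts = tuple(
            sd_t * math.sqrt(1.0 / csq - 1.0) for csq in (c1sq, c2sq, c3sq)
        )
    gt_noise_var = sum(s * s for s in s_experts) / 9.0
    gt_noise_sd = math.sqrt(gt_noise_var)
    var_gt = var_t + gt_noise_var

    # AI noise from the MAE target (difference vs the expert mean)
    if cfg.ai_noise_sd is not None:
        s_ai = float(cfg.ai_noise_sd)
    else:
        sd_diff = _solve_sigma_for_mae(cfg.ai_bias, cfg.ai_mae_target)
        if sd_diff * sd_diff < gt_noise_var:
            raise CalibrationError(
                f"AI MAE target {cfg.ai_mae_target} unattainable: the expert-mean "
                f"reference alone contributes SD {gt_noise_sd:.4f} to the difference"
            )
        s_ai = math.sqrt(sd_diff * sd_diff - gt_noise_var)

    # resident noise from the MAE target, accounting for the proportional
    # bias component (slope - 1) * (t - center)
    slope = cfg.resident_slope
    res_bias = (slope - 1.0) * (mu_t - cfg.resident_center)
    prop_var = (slope - 1.0) ** 2 * var_t
    if cfg.resident_noise_sd is not None:
        s_res = float(cfg.resident_noise_sd)
    else:
        sd_diff = _solve_sigma_for_mae(res_bias, cfg.resident_mae_target)
        floor = prop_var + gt_noise_var
        if sd_diff * sd_diff < floor:
            raise CalibrationError(
                f"resident MAE target {cfg.resident_mae_target} unattainable: "
                f"slope and reference noise already contribute SD {math.sqrt(floor):.4f}"
            )
        s_res = math.sqrt(sd_diff * sd_diff - floor)

    # implied summaries (pre-clipping normal approximations)
    c = [sd_t / math.sqrt(var_t + s * s) for s in s_experts]
    var_ai = var_t + s_ai * s_ai
    var_res = slope * slope * var_t + s_res * s_res
    implied = {
        "expert_r12": c[0] * c[1],
        "expert_r13": c[0] * c[2],
        "expert_r23": c[1] * c[2],
        "ai_bias": cfg.ai_bias,
        "ai_mae": folded_normal_mean(cfg.ai_bias, math.sqrt(s_ai * s_ai + gt_noise_var)),
        "ai_r": var_t / math.sqrt(var_ai * var_gt),
        "resident_bias": res_bias,
        "resident_mae": folded_normal_mean(
            res_bias, math.sqrt(prop_var + s_res * s_res + gt_noise_var)
        ),
        "resident_r": slope * var_t / math.sqrt(var_res * var_gt) if var_res > 0 else 1.0,
    }
    return ResolvedParams(
        mu_t=mu_t,
        sd_t=sd_t,
        expert_noise_sd=s_experts,
        gt_noise_sd=gt_noise_sd,
        ai_noise_sd=s_ai,
        resident_noise_sd=s_res,
        implied=implied,
    )
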