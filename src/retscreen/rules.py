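"""Rule-based classifiers for ophthalmic screening evaluation.

Covers the glaucoma-suspect CDR rule (max CDR over eyes at an inclusive
threshold, optionally with an inter-eye asymmetry clause), retinal-disease
positivity over per-eye finding sets, ordinal risk-of-vision-loss tiers,
conjunction rules for possible media opacities, the OR-synergy combiner of
two raters' calls, and F1-optimal threshold selection.

Predicates on possibly-missing inputs are tri-state: ``True``, ``False`` or
``None`` (undetermined, e.g. no gradable image). ``None`` values propagate
by the documented conventions of each rule rather than by accident.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SuspectRuleParams",
    "RiskTierMap",
    "TIER_ORDER",
    "DEFAULT_RISK_TIERS",
    "DEFAULT_EXCLUDED_FINDINGS",
    "MediaOpacityRule",
    "glaucoma_suspect",
    "patient_max_cdr",
    "retinal_disease_positive",
    "risk_tier",
    "media_opacity",
    "synergy_or",
    "optimize_threshold_f1",
]

TIER_ORDER = ("none", "mild", "medium", "high")


@dataclass(frozen=True)
class SuspectRuleParams:
    """Parameters of the CDR-based glaucoma-suspect rule.

    The reference (ground-truth) rule is max CDR >= 0.6 or an inter-eye CDR
    difference > 0.2. Rater predictions use a plain threshold on the
    patient's maximum CDR without the asymmetry clause (0.55 for the AI's
    F1-optimized operating point, 0.6 for the clinical cutoff).
    """

    cdr_threshold: float = 0.6
    asymmetry_threshold: float = 0.2
    use_asymmetry: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.cdr_threshold < 1.0:
            raise ValueError("cdr_threshold must be in (0, 1)")
        if not 0.0 < self.asymmetry_threshold < 1.0:
            raise ValueError("asymmetry_threshold must be in (0, 1)")


GROUND_TRUTH_RULE = SuspectRuleParams(0.6, 0.2, use_asymmetry=True)
AI_PREDICTION_RULE = SuspectRuleParams(0.55, 0.2, use_asymmetry=False)
RESIDENT_PREDICTION_RULE = SuspectRuleParams(0.6, 0.2, use_asymmetry=False)


def _check_cdr(value: float | None) -> float | None:
    if value is None:
        return None
    v = float(value)
    if math.isnan(v):
        return None
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"CDR {v} outside [0, 1]")
    return v


def glaucoma_suspect(
    cdr_right: float | None,
    cdr_left: float | None,
    params: SuspectRuleParams = GROUND_TRUTH_RULE,
) -> bool | None:
    """Apply the CDR suspect rule to one patient's two eyes.

    True iff the maximum available CDR reaches ``cdr_threshold``
    (inclusive), or — when both eyes are available and the asymmetry clause
    is enabled — the inter-eye difference strictly exceeds
    ``asymmetry_threshold``. ``None`` (undetermined) when no CDR is
    available.
    """
    r = _check_cdr(cdr_right)
    l = _check_cdr(cdr_left)
    avail = [v for v in (r, l) if v is not None]
    if not avail:
        return None
    if max(avail) >= params.cdr_threshold:
        return True
    if params.use_asymmetry and r is not None and l is not None:
        if abs(r - l) > params.asymmetry_threshold:
            return True
    return False


def patient_max_cdr(eyes: Iterable[object], rater: str) -> float | None:
    """Maximum CDR over a patient's gradable eyes for one rater.

    ``eyes`` are objects exposing ``cdr_<rater>`` attributes (or mappings
    with those keys); missing values are skipped; ``None`` when no eye has
    a value.
    """
    attr = f"cdr_{rater}"
    vals = []
    for eye in eyes:
        v = eye.get(attr) if isinstance(eye, Mapping) else getattr(eye, attr)
        v = _check_cdr(v)
        if v is not None:
            vals.append(v)
    return max(vals) if vals else None


# ---------------------------------------------------------------------------
# retinal findings
# ---------------------------------------------------------------------------

#: Default mapping from finding labels to risk-of-vision-loss tiers. The
#: high tier covers findings that threaten vision imminently (vitreous
#: hemorrhage, retinal detachment, neovascularization); the medium tier
#: covers disease warranting prompt management; mild covers early disease.
#: This lookup is a configurable default — review it against local
#: referral criteria before relying on tier-stratified outputs.
DEFAULT_RISK_TIERS: Mapping[str, str] = {
    "mild_npdr": "mild",
    "small_drusen": "mild",
    "mild_hypertensive_retinopathy": "mild",
    "epiretinal_membrane": "mild",
    "moderate_npdr": "medium",
    "macular_edema": "medium",
    "amd": "medium",
    "pathological_myopia": "medium",
    "chorioretinal_scar": "medium",
    "severe_npdr": "high",
    "proliferative_dr": "high",
    "neovascularization": "high",
    "vitreous_hemorrhage": "high",
    "retinal_detachment": "high",
}

#: Findings recorded by graders but not counted as retinal disease.
DEFAULT_EXCLUDED_FINDINGS = frozenset({"tessellated_fundus"})


@dataclass(frozen=True)
class RiskTierMap:
    """Finding-label -> tier lookup with an exclusion list."""

    mapping: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_RISK_TIERS))
    excluded: frozenset[str] = DEFAULT_EXCLUDED_FINDINGS

    def __post_init__(self) -> None:
        bad = {t for t in self.mapping.values() if t not in TIER_ORDER[1:]}
        if bad:
            raise ValueError(f"invalid tiers in map: {sorted(bad)}")

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self.mapping) | self.excluded


def _gather_findings(
    findings: Mapping[str, Iterable[str]] | Iterable[str],
) -> set[str]:
    if isinstance(findings, Mapping):
        out: set[str] = set()
        for labels in findings.values():
            out.update(labels)
        return out
    return set(findings)


def retinal_disease_positive(
    findings: Mapping[str, Iterable[str]] | Iterable[str],
    tier_map: RiskTierMap = RiskTierMap(),
) -> bool:
    """True iff any eye carries a counted retinal-disease finding.

    ``findings`` is either a per-eye mapping (side -> labels) or a flat
    label collection. Excluded labels (tessellated fundus by default) never
    trigger positivity; labels outside the configured vocabulary raise.
    """
    labels = _gather_findings(findings)
    unknown = labels - tier_map.vocabulary
    if unknown:
        raise KeyError(f"unknown finding labels: {sorted(unknown)}")
    return bool(labels - tier_map.excluded)


def risk_tier(
    findings: Mapping[str, Iterable[str]] | Iterable[str],
    tier_map: RiskTierMap = RiskTierMap(),
) -> str:
    """Highest risk tier among the findings; ``"none"`` for no findings."""
    labels = _gather_findings(findings) - tier_map.excluded
    tiers = set()
    for lab in labels:
        if lab not in tier_map.mapping:
            raise KeyError(f"unmapped finding label: {lab!r}")
        tiers.add(tier_map.mapping[lab])
    if not tiers:
        return "none"
    return max(tiers, key=TIER_ORDER.index)


# ---------------------------------------------------------------------------
# media opacities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediaOpacityRule:
    """One conjunction: age floor AND at least one listed symptom AND
    (optionally) no image of gradable quality."""

    min_age: float = 60.0
    symptoms_any: tuple[str, ...] = ("blurry_vision",)
    requires_no_gradable: bool = True

    def fires(self, age: float, symptoms: Iterable[str], any_gradable: bool) -> bool:
        if age < self.min_age:
            return False
        if self.symptoms_any and not set(self.symptoms_any) & set(symptoms):
            return False
        if self.requires_no_gradable and any_gradable:
            return False
        return True


DEFAULT_OPACITY_RULES: tuple[MediaOpacityRule, ...] = (MediaOpacityRule(),)


def media_opacity(
    age: float,
    symptoms: Iterable[str],
    any_gradable_image: bool,
    rules: Sequence[MediaOpacityRule] = DEFAULT_OPACITY_RULES,
) -> bool:
    """True iff any configured conjunction rule fires. The default rule set
    holds exactly one rule: age >= 60, blurry vision, and no image meeting
    the retinal quality threshold."""
    sym = set(symptoms)
    return any(rule.fires(age, sym, any_gradable_image) for rule in rules)


# ---------------------------------------------------------------------------
# synergy and threshold optimization
# ---------------------------------------------------------------------------

def _tri_bool(v) -> bool | None:
    """Normalize a tri-state call (accepts numpy booleans and NaN)."""
    if v is None:
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    return bool(v)


def synergy_or(pred_a: bool | None, pred_b: bool | None) -> bool | None:
    """OR-combine two possibly-undetermined calls.

    Positive if either call is positive; when exactly one rater is
    determinate, that rater decides; undetermined only when both are.
    """
    a, b = _tri_bool(pred_a), _tri_bool(pred_b)
    if a or b:
        return True
    if a is None and b is None:
        return None
    return False


def optimize_threshold_f1(
    scores: Sequence[float], labels: Sequence[bool]
) -> float:
    """Threshold (from the unique observed scores) maximizing the F1 of the
    rule ``score >= threshold``; ties break toward the largest threshold,
    i.e. the highest-specificity operating point."""
    s = [float(v) for v in scores]
    y = [bool(v) for v in labels]
    if len(s) != len(y):
        raise ValueError("scores and labels must be paired")
    if any(math.isnan(v) for v in s):
        raise ValueError("scores must be complete")
    if all(y) or not any(y):
        raise ValueError("both classes must be present")
    best_tau, best_f1 = None, -1.0
    for tau in sorted(set(s)):
        tp = sum(1 for v, lab in zip(s, y) if lab and v >= tau)
        fp = sum(1 for v, lab in zip(s, y) if not lab and v >= tau)
        fn = sum(y) - tp
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        if f1 >= best_f1:  # >= : later (larger) tau wins ties
            best_tau, best_f1 = tau, f1
    assert best_tau is not None
    return best_tau
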