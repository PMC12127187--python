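"""End-to-end study replica: from a cohort table to a full evaluation report.

Applies the CDR suspect rules, retinal-disease calls and media-opacity
logic to a cohort (simulated or user-supplied), computes confusion-matrix
metrics with bootstrap confidence intervals and paired bootstrap p-values,
single-score and OR-synergy ROC curves, tier-stratified sensitivities,
kappa/percent agreement for opacity vs cataract, and continuous CDR
agreement statistics.

Analysis subsets mirror a screening-evaluation design and are logged
explicitly, because every headline n is subset-driven:

* glaucoma classification: patients with a patient-level max CDR from the
  reference (all three experts), the AI and the resident;
* eye-level CDR agreement: eyes measured by every rater;
* retinal disease: patients with at least one AI-assessable fundus image;
* opacity agreement: all patients.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__ as _version
from .agreement import AgreementSummary, agreement, correlation_matrix
from .metrics import (
    BootstrapResult,
    ConfusionMatrix,
    METRIC_NAMES,
    MetricSet,
    bootstrap_metric,
    cohen_kappa,
    confusion,
    metric_set,
    paired_bootstrap_pvalue,
    percent_agreement,
)
from .roc import RocFrontier, operating_point, roc_curve, synergy_roc
from .rules import (
    AI_PREDICTION_RULE,
    GROUND_TRUTH_RULE,
    RESIDENT_PREDICTION_RULE,
    SuspectRuleParams,
    glaucoma_suspect,
    media_opacity,
    optimize_threshold_f1,
    synergy_or,
)
from .simulate import EYE_COLUMNS, PATIENT_COLUMNS, SYMPTOMS

__all__ = ["StudyParams", "ApproachResult", "StudyReport", "AblationReport",
           "run_study", "quality_ablation"]

APPROACHES = ("resident", "ai", "synergy")


@dataclass(frozen=True)
class StudyParams:
    """Knobs of the analysis (not of the data generator)."""

    truth_rule: SuspectRuleParams = GROUND_TRUTH_RULE
    ai_rule: SuspectRuleParams = AI_PREDICTION_RULE
    resident_rule: SuspectRuleParams = RESIDENT_PREDICTION_RULE
    n_boot: int = 2000
    compute_pvalues: bool = True
    #: include a patient in the resident ROC only when the resident CDR is
    #: available for every analysed eye ("complete") or for any ("any")
    resident_inclusion: str = "complete"


@dataclass(frozen=True)
class ApproachResult:
    name: str
    cm: ConfusionMatrix
    metrics: MetricSet
    ci: dict[str, BootstrapResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cm": dataclasses.asdict(self.cm),
            "metrics": dataclasses.asdict(self.metrics),
            "ci": {k: dataclasses.asdict(v) for k, v in self.ci.items()},
        }


def _approach(name, pred, truth, n_boot, seeds, with_ci=True) -> ApproachResult:
    cm = confusion(pred, truth)
    ms = metric_set(cm)
    ci = {}
    if with_ci:
        for k, m in enumerate(METRIC_NAMES):
            if getattr(ms, m) is None:
                continue
            try:
                ci[m] = bootstrap_metric(pred, truth, m, n_boot=n_boot, seed=seeds[k])
            except ValueError:
                pass  # metric undefined in too many resamples
    return ApproachResult(name=name, cm=cm, metrics=ms, ci=ci)


def _seed_stream(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _max_by_side(eyes: pd.DataFrame, col: str) -> pd.DataFrame:
    """Per-patient right/left values of one CDR column."""
    return eyes.pivot_table(index="patient_id", columns="side", values=col, aggfunc="first")


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlaucomaSection:
    n_total: int
    n_analyzed: int
    excluded: dict[str, int]
    approaches: dict[str, ApproachResult]
    p_values: dict[str, float]
    roc: dict[str, RocFrontier]
    ai_f1_threshold: float | None
    operating_points: dict[str, tuple]


@dataclass(frozen=True)
class RetinalSection:
    n_total: int
    n_analyzed: int
    excluded: dict[str, int]
    tier_counts: dict[str, int]
    approaches: dict[str, ApproachResult]
    tier_sensitivity: dict[str, dict[str, ApproachResult]]
    p_values: dict[str, float]


@dataclass(frozen=True)
class OpacitySection:
    n: int
    cm: ConfusionMatrix
    kappa: float
    agreement: float


@dataclass(frozen=True)
class AgreementSection:
    n_eyes: int
    summaries: dict[str, AgreementSummary]
    correlations: pd.DataFrame


@dataclass(frozen=True)
class StudyReport:
    glaucoma: GlaucomaSection | None
    retinal: RetinalSection | None
    opacity: OpacitySection | None
    agreement: AgreementSection | None
    provenance: dict

    def to_dict(self) -> dict:
        return _to_plain(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def write(self, outdir) -> None:
        """Write report.json plus the delimited tables."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json(), encoding="utf-8")
        if self.glaucoma is not None:
            _metrics_table(self.glaucoma.approaches).to_csv(out / "table1.csv", index=False)
            rows = []
            for name, fr in self.glaucoma.roc.items():
                df = fr.to_frame()
                df.insert(0, "curve", name)
                rows.append(df)
            pd.concat(rows).to_csv(out / "roc_points.csv", index=False)
        if self.retinal is not None:
            t3 = _metrics_table(self.retinal.approaches)
            for tier_key, per in self.retinal.tier_sensitivity.items():
                t3[f"sensitivity_{tier_key}"] = [
                    None
                    if a not in per or per[a].metrics.sensitivity is None
                    else per[a].metrics.sensitivity
                    for a in t3["approach"]
                ]
            t3.to_csv(out / "table3.csv", index=False)
        if self.opacity is not None:
            cm = self.opacity.cm
            pd.DataFrame(
                {
                    "": ["no_cataract_resident", "cataract_resident"],
                    "no_media_opacity_ai": [cm.tn, cm.fn],
                    "media_opacity_ai": [cm.fp, cm.tp],
                }
            ).to_csv(out / "table4.csv", index=False)
        if self.agreement is not None:
            rows = []
            for rater, s in self.agreement.summaries.items():
                d = dataclasses.asdict(s)
                d["rater"] = rater
                rows.append(d)
            pd.DataFrame(rows).to_csv(out / "agreement.csv", index=False)


def _metrics_table(approaches: Mapping[str, ApproachResult]) -> pd.DataFrame:
    rows = []
    for name, res in approaches.items():
        row = {"approach": name, "n": res.cm.total}
        for m in METRIC_NAMES:
            v = getattr(res.metrics, m)
            row[m] = v
            if m in res.ci:
                row[f"{m}_ci_low"] = res.ci[m].ci_low
                row[f"{m}_ci_high"] = res.ci[m].ci_high
        rows.append(row)
    return pd.DataFrame(rows)


def _to_plain(obj):
    if isinstance(obj, (StudyReport, GlaucomaSection, RetinalSection, OpacitySection,
                        AgreementSection)):
        return {
            f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, ApproachResult):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_plain(dataclasses.asdict(obj))
    if isinstance(obj, RocFrontier):
        return {"auc": obj.auc, "points": [list(p) for p in obj.points]}
    if isinstance(obj, pd.DataFrame):
        return {
            "columns": list(map(str, obj.columns)),
            "data": [[None if pd.isna(v) else v for v in row] for row in obj.to_numpy()],
        }
    if isinstance(obj, Mapping):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def _validate_schema(eyes: pd.DataFrame, patients: pd.DataFrame) -> None:
    problems = []
    for name, df, cols in (("eyes", eyes, EYE_COLUMNS), ("patients", patients, PATIENT_COLUMNS)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            problems.append(f"{name}: missing columns {missing}")
    if not problems:
        for col in ("cdr_gt", "cdr_ai", "cdr_resident"):
            vals = eyes[col].dropna()
            bad = vals[(vals < 0) | (vals > 1)]
            if len(bad):
                problems.append(
                    f"eyes: {col} outside [0,1] at rows {list(bad.index[:5])}"
                )
        bad_age = patients["age"].dropna()
        bad_age = bad_age[bad_age <= 0]
        if len(bad_age):
            problems.append(f"patients: non-positive age at rows {list(bad_age.index[:5])}")
    if problems:
        raise ValueError("cohort schema violations: " + "; ".join(problems))


def _glaucoma_section(eyes, params: StudyParams, seed: int) -> GlaucomaSection | None:
    if eyes.empty:
        return None
    ids = eyes["patient_id"].unique()
    side = {c: _max_by_side(eyes, c) for c in ("cdr_gt", "cdr_ai", "cdr_resident")}

    def suspect(col, rule):
        tab = side[col].reindex(ids)
        r = tab["right"] if "right" in tab else pd.Series(np.nan, index=ids)
        l = tab["left"] if "left" in tab else pd.Series(np.nan, index=ids)
        return pd.Series(
            [glaucoma_suspect(rv if pd.notna(rv) else None, lv if pd.notna(lv) else None, rule)
             for rv, lv in zip(r, l)],
            index=ids,
            dtype=object,
        )

    truth = suspect("cdr_gt", params.truth_rule)
    pred_ai = suspect("cdr_ai", params.ai_rule)
    pred_res = suspect("cdr_resident", params.resident_rule)
    max_ai = side["cdr_ai"].reindex(ids).max(axis=1)
    max_res = side["cdr_resident"].reindex(ids).max(axis=1)
    if params.resident_inclusion == "complete":
        res_n = eyes.groupby("patient_id")["cdr_resident"].count().reindex(ids).fillna(0)
        gt_n = eyes.groupby("patient_id")["cdr_gt"].count().reindex(ids).fillna(0)
        res_ok = (res_n >= gt_n) & max_res.notna()
    elif params.resident_inclusion == "any":
        res_ok = max_res.notna()
    else:
        raise ValueError(f"unknown resident_inclusion {params.resident_inclusion!r}")

    has_truth = truth.notna()
    mask = has_truth & max_ai.notna() & res_ok
    excluded = {
        "no_reference_cdr": int((~has_truth).sum()),
        "no_ai_cdr": int((has_truth & max_ai.isna()).sum()),
        "no_resident_cdr": int((has_truth & max_ai.notna() & ~res_ok).sum()),
    }
    n_analyzed = int(mask.sum())
    if n_analyzed == 0:
        return None
    t = truth[mask].astype(bool).to_numpy()
    if t.all() or not t.any():
        return None  # metrics undefined with a single class
    pa = pred_ai[mask].astype(bool).to_numpy()
    pr = pred_res[mask].astype(bool).to_numpy()
    ps = np.array([synergy_or(a, b) for a, b in zip(pa, pr)], dtype=bool)

    seeds = _seed_stream(seed, 32)
    approaches = {
        "resident": _approach("resident", pr, t, params.n_boot, seeds[0:5]),
        "ai": _approach("ai", pa, t, params.n_boot, seeds[5:10]),
        "synergy": _approach("synergy", ps, t, params.n_boot, seeds[10:15]),
    }
    p_values = {}
    if params.compute_pvalues:
        for k, m in enumerate(METRIC_NAMES):
            try:
                p_values[m] = paired_bootstrap_pvalue(
                    pa, pr, t, m, n_boot=params.n_boot, seed=seeds[15 + k]
                )
            except ValueError:
                pass

    sa = max_ai[mask].to_numpy()
    sr = max_res[mask].to_numpy()
    roc = {
        "ai": roc_curve(sa, t),
        "resident": roc_curve(sr, t),
        "synergy": synergy_roc(sr, sa, t),
    }
    ai_f1_tau = optimize_threshold_f1(sa, t)
    ops = {}
    res_spec = approaches["resident"].metrics.specificity
    if res_spec is not None:
        ops["ai_at_resident_specificity"] = tuple(
            operating_point(roc["ai"], "match_specificity", target=res_spec)
        )
    syn_sens = approaches["synergy"].metrics.sensitivity
    if syn_sens is not None:
        try:
            ops["ai_at_synergy_sensitivity"] = tuple(
                operating_point(roc["ai"], "match_sensitivity", target=syn_sens)
            )
        except ValueError:
            pass
    return GlaucomaSection(
        n_total=len(ids),
        n_analyzed=n_analyzed,
        excluded=excluded,
        approaches=approaches,
        p_values=p_values,
        roc=roc,
        ai_f1_threshold=ai_f1_tau,
        operating_points=ops,
    )


def _retinal_section(patients, params: StudyParams, seed: int) -> RetinalSection | None:
    df = patients
    ok = (
        df["retina_gradable_ai"].fillna(False).astype(bool)
        & df["disease_pos_ai"].notna()
        & df["disease_pos_resident"].notna()
    )
    excluded = {
        "ai_not_gradable": int((~df["retina_gradable_ai"].fillna(False).astype(bool)).sum()),
        "missing_rater_call": int(
            (df["retina_gradable_ai"].fillna(False).astype(bool) & ~ok).sum()
        ),
    }
    sub = df[ok]
    if sub.empty:
        return None
    truth = (sub["disease_tier_true"] != "none").to_numpy()
    if truth.all() or not truth.any():
        return None
    pa = sub["disease_pos_ai"].astype(bool).to_numpy()
    pr = sub["disease_pos_resident"].astype(bool).to_numpy()
    ps = pa | pr
    seeds = _seed_stream(seed + 1, 64)
    approaches = {
        "resident": _approach("resident", pr, truth, params.n_boot, seeds[0:5]),
        "ai": _approach("ai", pa, truth, params.n_boot, seeds[5:10]),
        "synergy": _approach("synergy", ps, truth, params.n_boot, seeds[10:15]),
    }
    tiers = sub["disease_tier_true"].to_numpy()
    tier_counts = {k: int((tiers == k).sum()) for k in ("none", "mild", "medium", "high")}
    tier_sens: dict[str, dict[str, ApproachResult]] = {}
    for key, members in (("medium_plus", ("medium", "high")), ("high", ("high",))):
        m = np.isin(tiers, members)
        if not m.any():
            continue
        per = {}
        for off, (name, pred) in enumerate(
            (("resident", pr), ("ai", pa), ("synergy", ps))
        ):
            per[name] = _approach(
                name, pred[m], truth[m], params.n_boot, seeds[15 + 5 * off : 20 + 5 * off]
            )
        tier_sens[key] = per
    p_values = {}
    if params.compute_pvalues:
        for k, m in enumerate(METRIC_NAMES):
            try:
                p_values[m] = paired_bootstrap_pvalue(
                    pa, pr, truth, m, n_boot=params.n_boot, seed=seeds[30 + k]
                )
            except ValueError:
                pass
    return RetinalSection(
        n_total=len(df),
        n_analyzed=len(sub),
        excluded=excluded,
        tier_counts=tier_counts,
        approaches=approaches,
        tier_sensitivity=tier_sens,
        p_values=p_values,
    )


def _opacity_section(eyes, patients) -> OpacitySection | None:
    if patients.empty:
        return None
    if not eyes.empty:
        any_ok = eyes.groupby("patient_id")["gradable_ai"].any()
    else:
        any_ok = pd.Series(dtype=bool)
    retina_ok = patients.set_index("patient_id")["retina_gradable_ai"].fillna(False)
    ai_pred = []
    for _, row in patients.iterrows():
        symptoms = {s for s in SYMPTOMS if bool(row.get(s, False))}
        gradable = bool(retina_ok.get(row["patient_id"], False))
        ai_pred.append(media_opacity(row["age"], symptoms, gradable))
    resident = patients["cataract_dx_resident"].fillna(False).astype(bool).to_numpy()
    cm = confusion(np.array(ai_pred), resident)
    try:
        kappa = cohen_kappa(cm)
    except ValueError:
        return None
    return OpacitySection(
        n=cm.total, cm=cm, kappa=kappa, agreement=percent_agreement(cm)
    )


def _agreement_section(eyes) -> AgreementSection | None:
    if eyes.empty:
        return None
    complete = eyes.dropna(subset=["cdr_gt", "cdr_ai", "cdr_resident"])
    summaries = {}
    if len(complete) >= 2:
        gt = complete["cdr_gt"].to_numpy()
        if (gt > 0).all():
            summaries = {
                "ai": agreement(complete["cdr_ai"].to_numpy(), gt),
                "resident": agreement(complete["cdr_resident"].to_numpy(), gt),
            }
    cols = {
        "expert_1": "cdr_expert_1",
        "expert_2": "cdr_expert_2",
        "expert_3": "cdr_expert_3",
        "ground_truth": "cdr_gt",
        "ai": "cdr_ai",
        "resident": "cdr_resident",
    }
    corr = correlation_matrix(eyes[list(cols.values())].rename(columns={v: k for k, v in cols.items()}))
    if not summaries:
        return None
    return AgreementSection(n_eyes=len(complete), summaries=summaries, correlations=corr)


def run_study(
    eyes: pd.DataFrame,
    patients: pd.DataFrame,
    params: StudyParams | None = None,
    seed: int = 0,
) -> StudyReport:
    """Run the full evaluation on a cohort; deterministic under ``seed``."""
    params = params or StudyParams()
    _validate_schema(eyes, patients)
    glaucoma = _glaucoma_section(eyes, params, seed)
    retinal = _retinal_section(patients, params, seed)
    opacity = _opacity_section(eyes, patients)
    agr = _agreement_section(eyes)
    if glaucoma is None and retinal is None and opacity is None and agr is None:
        raise ValueError("cohort yields no analyzable subset in any section")
    return StudyReport(
        glaucoma=glaucoma,
        retinal=retinal,
        opacity=opacity,
        agreement=agr,
        provenance={
            "package_version": _version,
            "seed": seed,
            "n_boot": params.n_boot,
            "truth_rule": dataclasses.asdict(params.truth_rule),
            "ai_rule": dataclasses.asdict(params.ai_rule),
            "resident_rule": dataclasses.asdict(params.resident_rule),
            "resident_inclusion": params.resident_inclusion,
        },
    )


@dataclass(frozen=True)
class AblationReport:
    """Paired reports with and without the AI quality gate, plus the AI
    glaucoma metrics split by original image quality."""

    gated: StudyReport
    ungated: StudyReport
    by_quality: dict[str, ApproachResult]

    def to_dict(self) -> dict:
        return {
            "gated": self.gated.to_dict(),
            "ungated": self.ungated.to_dict(),
            "by_quality": {k: v.to_dict() for k, v in self.by_quality.items()},
        }


def quality_ablation(
    eyes: pd.DataFrame,
    patients: pd.DataFrame,
    params: StudyParams | None = None,
    seed: int = 0,
) -> AblationReport:
    """Contrast the study with the AI's image-quality gate on vs off.

    Ungated analysis substitutes ``cdr_ai_ungated`` (an AI estimate for
    every eye, including ones the gate would reject) for ``cdr_ai``. The
    by-quality split recomputes the AI glaucoma metrics within ungated
    patients whose images all passed / any failed the gate.
    """
    params = params or StudyParams()
    _validate_schema(eyes, patients)
    if eyes.empty or eyes["cdr_ai_ungated"].isna().all():
        raise ValueError("no AI estimates available for ablation")
    gated = run_study(eyes, patients, params, seed)
    un_eyes = eyes.copy()
    un_eyes["cdr_ai"] = un_eyes["cdr_ai_ungated"]
    ungated = run_study(un_eyes, patients, params, seed)

    by_quality: dict[str, ApproachResult] = {}
    gl = _glaucoma_ablation_split(eyes, un_eyes, params)
    if gl:
        by_quality = gl
    return AblationReport(gated=gated, ungated=ungated, by_quality=by_quality)


def _glaucoma_ablation_split(eyes, un_eyes, params) -> dict[str, ApproachResult]:
    ids = un_eyes["patient_id"].unique()
    side_gt = _max_by_side(un_eyes, "cdr_gt")
    side_ai = _max_by_side(un_eyes, "cdr_ai")

    def susp(tab, rule):
        tab = tab.reindex(ids)
        r = tab["right"] if "right" in tab else pd.Series(np.nan, index=ids)
        l = tab["left"] if "left" in tab else pd.Series(np.nan, index=ids)
        return pd.Series(
            [glaucoma_suspect(rv if pd.notna(rv) else None, lv if pd.notna(lv) else None, rule)
             for rv, lv in zip(r, l)],
            index=ids, dtype=object,
        )

    truth = susp(side_gt, params.truth_rule)
    pred = susp(side_ai, params.ai_rule)
    all_gradable = eyes.groupby("patient_id")["gradable_ai"].all().reindex(ids, fill_value=False)
    mask = truth.notna() & pred.notna()
    out = {}
    for key, sel in (
        ("sufficient_quality", mask & all_gradable),
        ("insufficient_quality", mask & ~all_gradable),
    ):
        if not sel.any():
            continue
        t = truth[sel].astype(bool).to_numpy()
        p = pred[sel].astype(bool).to_numpy()
        if t.all() or not t.any():
            continue
        out[key] = ApproachResult(name=f"ai_{key}", cm=confusion(p, t),
                                  metrics=metric_set(confusion(p, t)))
    return out
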