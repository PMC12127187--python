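"""Confusion-matrix metrics, kappa, bootstrap inference and the integer
reconstruction oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retscreen.metrics import (
    ConfusionMatrix,
    ReconstructionError,
    bootstrap_metric,
    cohen_kappa,
    confusion,
    metric_set,
    paired_bootstrap_pvalue,
    percent_agreement,
    reconstruct_counts,
    reconstruct_tier_counts,
    round_half_up,
)

# printed 2x2 media-opacity vs cataract table: tn=both negative, fp=AI-only
# positive, fn=clinician-only positive, tp=both positive
TABLE4 = ConfusionMatrix(tp=14, fp=35, fn=26, tn=360)


class TestMetricSet:
    def test_glaucoma_ai_cells(self):
        ms = metric_set(ConfusionMatrix(29, 11, 17, 188))
        assert ms.sensitivity == pytest.approx(29 / 46)
        assert ms.specificity == pytest.approx(188 / 199)
        assert ms.accuracy == pytest.approx(217 / 245)
        assert ms.ppv == pytest.approx(29 / 40)
        assert ms.f1 == pytest.approx(58 / 86)
        pct = ms.as_percent()
        assert pct == {
            "accuracy": 88.6,
            "sensitivity": 63.0,
            "specificity": 94.5,
            "ppv": 72.5,
            "f1": 67.4,
        }

    def test_degenerate_cells(self):
        perfect = metric_set(ConfusionMatrix(1, 0, 0, 1))
        assert all(v == 1.0 for v in perfect.__dict__.values())
        ms = metric_set(ConfusionMatrix(0, 0, 1, 1))
        assert ms.sensitivity == 0.0
        assert ms.ppv is None  # undefined, not zero

    @given(
        st.tuples(*(st.integers(0, 200) for _ in range(4))).filter(
            lambda c: sum(c) > 0 and c[0] + c[2] > 0 and c[1] + c[3] > 0
        )
    )
    def test_accuracy_decomposition(self, cells):
        """accuracy = sens * prevalence + spec * (1 - prevalence), exactly."""
        cm = ConfusionMatrix(*cells)
        ms = metric_set(cm)
        prev = cm.prevalence
        assert ms.accuracy == pytest.approx(
            ms.sensitivity * prev + ms.specificity * (1 - prev), abs=1e-12
        )


class TestAgreementCoefficients:
    def test_kappa_printed_table(self):
        assert round_half_up(cohen_kappa(TABLE4), 3) == 0.237

    def test_percent_agreement_printed_table(self):
        assert percent_agreement(TABLE4) == pytest.approx(374 / 435)
        assert round_half_up(100 * percent_agreement(TABLE4), 1) == 86.0

    def test_kappa_bounds_and_extremes(self):
        assert cohen_kappa(ConfusionMatrix(50, 0, 0, 50)) == 1.0
        assert cohen_kappa(ConfusionMatrix(25, 25, 25, 25)) == 0.0

    @given(
        st.tuples(*(st.integers(0, 100) for _ in range(4))).filter(
            lambda c: sum(c) > 0
            and ((c[0] + c[1]) * (c[0] + c[2]) + (c[2] + c[3]) * (c[1] + c[3]))
            < sum(c) ** 2
        )
    )
    def test_kappa_range(self, cells):
        k = cohen_kappa(ConfusionMatrix(*cells))
        assert -1.0 <= k <= 1.0


class TestConfusion:
    def test_hand_counted(self):
        pred = [True, True, False, False, True, False]
        truth = [True, False, True, False, True, False]
        cm = confusion(pred, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 1, 2)

    def test_agreement_extremes(self):
        t = np.array([True, False, True, False])
        assert confusion(t, t).fp == confusion(t, t).fn == 0
        flipped = confusion(~t, t)
        assert flipped.tp == flipped.tn == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion([True], [True, False])


class TestBootstrap:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        truth = rng.uniform(size=400) < 0.3
        pred = truth ^ (rng.uniform(size=400) < 0.15)
        a = bootstrap_metric(pred, truth, "sensitivity", n_boot=300, seed=42)
        b = bootstrap_metric(pred, truth, "sensitivity", n_boot=300, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_perfect_data_degenerate_ci(self):
        truth = np.array([True, False] * 30)
        r = bootstrap_metric(truth, truth, "accuracy", n_boot=200, seed=1)
        assert (r.point, r.ci_low, r.ci_high) == (1.0, 1.0, 1.0)

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_metric([True] * 10, [True] * 10, "accuracy", n_boot=1)

    def test_undefined_point_rejected(self):
        truth = np.ones(20, dtype=bool)
        with pytest.raises(ValueError):
            bootstrap_metric(truth, truth, "specificity", n_boot=200, seed=0)

    def test_ci_coverage_of_known_sensitivity(self):
        """Percentile CIs from patient resampling cover the generating
        sensitivity at roughly the nominal rate."""
        gen = np.random.default_rng(7)
        hits = 0
        reps = 300
        for _ in range(reps):
            truth = gen.uniform(size=1000) < 0.3
            pred = np.where(truth, gen.uniform(size=1000) < 0.8, gen.uniform(size=1000) < 0.1)
            r = bootstrap_metric(pred, truth, "sensitivity", n_boot=300,
                                 seed=int(gen.integers(2**31)))
            hits += r.ci_low <= 0.8 <= r.ci_high
        assert 0.91 <= hits / reps <= 0.98

    def test_identical_raters_give_p_one(self):
        truth = np.array([True, False] * 50)
        pred = truth ^ (np.arange(100) % 7 == 0)
        p = paired_bootstrap_pvalue(pred, pred, truth, "accuracy", n_boot=200, seed=3)
        assert p == 1.0

    def test_overwhelming_difference_hits_floor(self):
        truth = np.ones(200, dtype=bool)
        truth[:100] = False
        perfect = truth.copy()
        poor = np.zeros(200, dtype=bool)
        p = paired_bootstrap_pvalue(perfect, poor, truth, "sensitivity", n_boot=500, seed=9)
        assert p == pytest.approx(1 / 500)


class TestReconstruction:
    def test_glaucoma_panel_unique(self):
        printed = {
            "resident": {"sensitivity": 50.0, "specificity": 90.5},
            "ai": {"sensitivity": 63.0, "specificity": 94.5},
            "synergy": {"sensitivity": 80.4, "specificity": 86.4},
        }
        P, cells = reconstruct_counts(printed, 245)
        assert P == 46
        assert cells["ai"] == ConfusionMatrix(29, 11, 17, 188)
        assert cells["resident"] == ConfusionMatrix(23, 19, 23, 180)
        assert cells["synergy"] == ConfusionMatrix(37, 27, 9, 172)

    def test_retinal_panel_unique(self):
        printed = {
            "resident": {"sensitivity": 51.9, "specificity": 90.4, "ppv": 77.9, "f1": 62.3},
            "ai": {"sensitivity": 76.3, "specificity": 95.8},
            "synergy": {"sensitivity": 84.0, "specificity": 87.4},
        }
        P, cells = reconstruct_counts(printed, 395)
        assert P == 156
        assert cells["ai"] == ConfusionMatrix(119, 10, 37, 229)
        assert cells["synergy"].fp == 30

    def test_inconsistent_panel_rejected(self):
        with pytest.raises(ReconstructionError):
            reconstruct_counts({"r": {"sensitivity": 50.0, "specificity": 50.0}}, 3)

    def test_tier_split_unique(self):
        split = reconstruct_tier_counts(
            156,
            sens_medium_plus={"ai": 90.1, "resident": 63.0},
            sens_high={"ai": 100.0, "resident": 80.5},
        )
        assert split == (75, 40, 41)

    @given(
        st.tuples(*(st.integers(1, 40) for _ in range(4))),
        st.tuples(*(st.integers(1, 40) for _ in range(2))),
    )
    @settings(max_examples=30, deadline=None)
    def test_round_trip_contains_original(self, cells_a, tpn_b):
        """Printing a panel to one decimal and reconstructing recovers the
        original counts among the solutions."""
        cm_a = ConfusionMatrix(*cells_a)
        P, N = cm_a.positives, cm_a.negatives
        cm_b = ConfusionMatrix(min(tpn_b[0], P), N - min(tpn_b[1], N),
                               P - min(tpn_b[0], P), min(tpn_b[1], N))
        printed = {
            name: {
                m: round_half_up(100 * v, 1)
                for m, v in metric_set(cm).__dict__.items()
                if v is not None
            }
            for name, cm in (("a", cm_a), ("b", cm_b))
        }
        sols = reconstruct_counts(printed, cm_a.total, unique=False)
        assert any(
            P == p and cm_a in per["a"] and cm_b in per["b"] for p, per in sols
        )
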