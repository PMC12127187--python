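"""Rule-based classifiers: suspect rule, findings, tiers, opacity logic,
OR-synergy and F1 threshold selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retscreen.metrics import confusion, metric_set
from retscreen.rules import (
    RiskTierMap,
    SuspectRuleParams,
    TIER_ORDER,
    glaucoma_suspect,
    media_opacity,
    optimize_threshold_f1,
    patient_max_cdr,
    retinal_disease_positive,
    risk_tier,
    synergy_or,
)

from .oracles import naive_f1_threshold

RULE = SuspectRuleParams(0.6, 0.2, use_asymmetry=True)


class TestGlaucomaSuspect:
    @pytest.mark.parametrize(
        ("right", "left", "expected"),
        [
            (0.65, 0.5, True),      # threshold clause
            (0.3, 0.55, True),      # asymmetry clause: |0.3-0.55| > 0.2
            (0.59, 0.59, False),    # just under threshold, no asymmetry
            (0.6, 0.1, True),       # threshold inclusive, >= semantics
            (0.5, 0.7, True),       # either eye can trigger
            (None, 0.5, False),     # single available eye below threshold
            (None, 0.65, True),
            (None, None, None),     # undetermined
            (0.4, 0.6 - 1e-9, False),
        ],
    )
    def test_rule_cases(self, right, left, expected):
        assert glaucoma_suspect(right, left, RULE) is expected

    def test_asymmetry_is_strict_and_optional(self):
        assert glaucoma_suspect(0.3, 0.5, RULE) is False  # diff exactly 0.2
        no_asym = SuspectRuleParams(0.6, 0.2, use_asymmetry=False)
        assert glaucoma_suspect(0.3, 0.55, no_asym) is False

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            glaucoma_suspect(1.2, 0.5, RULE)

    @given(
        st.floats(0, 1), st.floats(0, 1),
        st.floats(0, 0.2).filter(lambda d: d > 0),
    )
    def test_monotone_in_cdr(self, r, l, bump):
        """The threshold-only rule is monotone in either eye; with the
        asymmetry clause, monotonicity holds for raising the higher eye
        (raising the lower eye can close the inter-eye gap)."""
        no_asym = SuspectRuleParams(0.6, 0.2, use_asymmetry=False)
        if glaucoma_suspect(r, l, no_asym) is True:
            assert glaucoma_suspect(min(r + bump, 1.0), l, no_asym) is True
        hi, lo = max(r, l), min(r, l)
        if glaucoma_suspect(hi, lo, RULE) is True:
            assert glaucoma_suspect(min(hi + bump, 1.0), lo, RULE) is True


class TestPatientMaxCdr:
    def test_variants(self):
        eyes = [{"cdr_ai": 0.4}, {"cdr_ai": 0.7}]
        assert patient_max_cdr(eyes, "ai") == 0.7
        assert patient_max_cdr([{"cdr_ai": None}, {"cdr_ai": 0.5}], "ai") == 0.5
        assert patient_max_cdr([{"cdr_ai": None}], "ai") is None
        assert patient_max_cdr([], "ai") is None


class TestFindings:
    def test_positivity_and_exclusion(self):
        assert retinal_disease_positive({"right": {"moderate_npdr"}}) is True
        assert retinal_disease_positive({"right": {"tessellated_fundus"}}) is False
        assert retinal_disease_positive({"right": set(), "left": set()}) is False
        with pytest.raises(KeyError, match="unknown"):
            retinal_disease_positive({"right": {"not_a_finding"}})

    def test_tier_lookup(self):
        assert risk_tier({"retinal_detachment"}) == "high"
        assert risk_tier({"mild_npdr"}) == "mild"
        assert risk_tier(set()) == "none"
        assert risk_tier({"mild_npdr", "vitreous_hemorrhage"}) == "high"
        with pytest.raises(KeyError, match="unmapped"):
            risk_tier({"sunburn"}, RiskTierMap(mapping={"x": "mild"}, excluded=frozenset()))

    @given(st.sets(st.sampled_from(sorted(RiskTierMap().mapping)), max_size=4),
           st.sampled_from(sorted(RiskTierMap().mapping)))
    def test_adding_finding_never_lowers_tier(self, findings, extra):
        before = risk_tier(findings)
        after = risk_tier(findings | {extra})
        assert TIER_ORDER.index(after) >= TIER_ORDER.index(before)


class TestMediaOpacity:
    @pytest.mark.parametrize(
        ("age", "symptoms", "gradable", "expected"),
        [
            (62, {"blurry_vision"}, False, True),
            (62, {"blurry_vision"}, True, False),   # a gradable image vetoes
            (45, {"blurry_vision"}, False, False),  # age clause fails
            (70, {"night_difficulty"}, False, False),  # symptom clause fails
            (60, {"blurry_vision", "color_change"}, False, True),  # age inclusive
        ],
    )
    def test_default_rule(self, age, symptoms, gradable, expected):
        assert media_opacity(age, symptoms, gradable) is expected


class TestSynergyOr:
    @pytest.mark.parametrize(
        ("a", "b", "expected"),
        [
            (True, False, True),
            (False, False, False),
            (True, True, True),
            (None, False, False),   # the available rater decides
            (None, True, True),
            (False, None, False),
            (None, None, None),
        ],
    )
    def test_truth_table(self, a, b, expected):
        assert synergy_or(a, b) is expected

    def test_dominance_is_exact_on_any_dataset(self, rng):
        """OR-synergy sensitivity >= each component's and specificity <=
        each component's, as a set identity rather than a statistical one."""
        for _ in range(20):
            truth = rng.uniform(size=80) < 0.3
            pa = truth ^ (rng.uniform(size=80) < 0.25)
            pb = truth ^ (rng.uniform(size=80) < 0.35)
            ps = np.array([synergy_or(x, y) for x, y in zip(pa, pb)], dtype=bool)
            ms = metric_set(confusion(ps, truth))
            for comp in (pa, pb):
                mc = metric_set(confusion(comp, truth))
                assert ms.sensitivity >= mc.sensitivity
                assert ms.specificity <= mc.specificity


class TestOptimizeThresholdF1:
    def test_separable_pair(self):
        assert optimize_threshold_f1([0.2, 0.7], [False, True]) == 0.7

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            optimize_threshold_f1([0.2, 0.7], [True, True])

    def test_six_point_example(self):
        scores = [0.1, 0.3, 0.5, 0.55, 0.6, 0.9]
        labels = [False, False, False, True, False, True]
        assert optimize_threshold_f1(scores, labels) == 0.55

    def test_matches_bruteforce(self, rng):
        for _ in range(30):
            s = np.round(rng.uniform(size=15), 1)
            y = rng.uniform(size=15) < 0.4
            if y.all() or not y.any():
                continue
            assert optimize_threshold_f1(s, y) == naive_f1_threshold(list(s), list(y))
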