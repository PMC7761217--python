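"""Discordance classification and the staged variant filter funnel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twindiff.model import ThresholdConfig
from twindiff.variants import (
    UnknownConsequenceError,
    apply_consequence_filter,
    apply_quality_filter,
    apply_rarity_filter,
    classify_discordance,
    run_variant_funnel,
)
from conftest import make_call

CFG = ThresholdConfig()

GENOTYPES = ("homref", "het", "homalt", "missing")


class TestDiscordance:
    @pytest.mark.parametrize(
        "gt_a,gt_h,expected",
        [
            ("het", "homref", "unique_to_affected"),
            ("homalt", "homref", "unique_to_affected"),
            ("het", "missing", "unique_to_affected"),
            ("homalt", "het", "zygosity_difference"),
            ("het", "homalt", "zygosity_difference"),
            ("het", "het", "concordant"),
            ("homref", "homref", "concordant"),
            ("missing", "missing", "concordant"),
            ("homref", "missing", "concordant"),
            ("homref", "het", "unique_to_healthy"),
            ("missing", "homalt", "unique_to_healthy"),
        ],
    )
    def test_classes(self, gt_a, gt_h, expected):
        assert classify_discordance(make_call(gt_affected=gt_a, gt_healthy=gt_h)) == expected

    @settings(deadline=None, derandomize=True)
    @given(st.sampled_from(GENOTYPES), st.sampled_from(GENOTYPES))
    def test_swap_symmetry(self, gt_a, gt_h):
        """Exchanging twins maps unique classes onto each other and fixes the rest."""
        fwd = classify_discordance(make_call(gt_affected=gt_a, gt_healthy=gt_h))
        rev = classify_discordance(make_call(gt_affected=gt_h, gt_healthy=gt_a))
        swap = {
            "unique_to_affected": "unique_to_healthy",
            "unique_to_healthy": "unique_to_affected",
            "concordant": "concordant",
            "zygosity_difference": "zygosity_difference",
        }
        assert rev == swap[fwd]


class TestQualityFilter:
    @pytest.mark.parametrize(
        "gq,dp,expected",
        [(20, 10, True), (19, 30, False), (99, 9, False), (20, 9, False), (50, 50, True)],
    )
    def test_inclusive_bounds_on_carrier(self, gq, dp, expected):
        assert apply_quality_filter(make_call(gq=gq, dp=dp), CFG) is expected

    def test_strict_mode_checks_both_twins(self):
        call = make_call(gq=50, dp=30, gq_h=5, dp_h=30)
        assert apply_quality_filter(call, CFG) is True
        assert apply_quality_filter(call, CFG, strict=True) is False


class TestRarityFilter:
    @pytest.mark.parametrize(
        "maf,kept", [(0.01, False), (0.0099, True), (None, True), (0.5, False)]
    )
    def test_boundary_and_missingness(self, maf, kept):
        assert apply_rarity_filter(make_call(maf=maf), CFG) is kept


class TestConsequenceFilter:
    def test_missense_needs_one_damaging_verdict(self):
        kept = make_call(verdicts=[("sift", "damaging"), ("polyphen2", "tolerated")])
        removed = make_call(
            verdicts=[("sift", "tolerated"), ("polyphen2", "tolerated"),
                      ("mutationtaster", "tolerated")]
        )
        assert apply_consequence_filter(kept, CFG) is True
        assert apply_consequence_filter(removed, CFG) is False

    @pytest.mark.parametrize("cadd,kept", [(15.0, False), (15.01, True), (None, False)])
    def test_noncoding_cadd_strictly_above_cutoff(self, cadd, kept):
        call = make_call(consequence="intergenic_variant", cadd=cadd)
        assert apply_consequence_filter(call, CFG) is kept

    def test_high_impact_unconditional_low_removed(self):
        assert apply_consequence_filter(make_call(consequence="stop_gained"), CFG)
        assert not apply_consequence_filter(make_call(consequence="synonymous_variant"), CFG)

    def test_unknown_class_errors_with_name(self):
        with pytest.raises(UnknownConsequenceError, match="weird_class"):
            apply_consequence_filter(make_call(consequence="weird_class"), CFG)


def ten_hand_built_calls():
    """2 concordant, 3 failing GQ/DP, 2 common, 2 tolerated missense, 1 damaging.

    Expected funnel (unique mode): [8, 5, 3, 1].
    """
    dmg = [("sift", "damaging")]
    tol = [("sift", "tolerated"), ("polyphen2", "tolerated")]
    return [
        make_call(gt_affected="het", gt_healthy="het", pos=1),  # concordant
        make_call(gt_affected="homref", gt_healthy="homref", pos=2),  # concordant
        make_call(gq=10, pos=3, verdicts=dmg),  # fails GQ
        make_call(dp=5, pos=4, verdicts=dmg),  # fails DP
        make_call(gq=19, dp=9, pos=5, verdicts=dmg),  # fails both
        make_call(maf=0.05, pos=6, verdicts=dmg),  # common
        make_call(maf=0.3, pos=7, verdicts=dmg),  # common
        make_call(verdicts=tol, pos=8),  # tolerated missense
        make_call(verdicts=tol, pos=9),  # tolerated missense
        make_call(verdicts=dmg, pos=10),  # damaging missense: the survivor
    ]


class TestFunnel:
    def test_hand_built_funnel_counts(self):
        trace = run_variant_funnel(ten_hand_built_calls(), mode="unique", cfg=CFG)
        assert trace.counts == [8, 5, 3, 1]
        assert [c.site.start for c in trace.survivors] == [10]

    def test_all_concordant_gives_zero_trace(self):
        calls = [make_call(gt_affected="het", gt_healthy="het", pos=i) for i in range(5)]
        trace = run_variant_funnel(calls, mode="unique", cfg=CFG)
        assert trace.counts == [0, 0, 0, 0]

    def test_strict_absence_requires_callable_healthy_site(self):
        call = make_call(gt_healthy="missing", dp_h=3, verdicts=[("sift", "damaging")])
        assert run_variant_funnel([call], cfg=CFG).counts[0] == 1
        assert run_variant_funnel([call], cfg=CFG, strict_absence=True).counts[0] == 0

    def test_zygosity_mode_selects_shared_carriers(self):
        calls = [
            make_call(gt_affected="homalt", gt_healthy="het", verdicts=[("sift", "damaging")]),
            make_call(gt_affected="het", gt_healthy="homref"),
        ]
        trace = run_variant_funnel(calls, mode="zygosity", cfg=CFG)
        assert trace.counts[0] == 1

    def test_funnel_monotone_and_survivors_subset(self):
        calls = ten_hand_built_calls()
        trace = run_variant_funnel(calls, cfg=CFG)
        assert all(a >= b for a, b in zip(trace.counts, trace.counts[1:]))
        positions = {c.site.start for c in calls}
        assert {c.site.start for c in trace.survivors} <= positions


def _random_calls(n, rng):
    consequences = [
        "missense_variant", "stop_gained", "synonymous_variant",
        "intergenic_variant", "intron_variant",
    ]
    calls = []
    for i in range(n):
        verdicts = []
        for tool in ("polyphen2", "sift", "mutationtaster"):
            r = rng.random()
            if r < 0.3:
                verdicts.append((tool, "damaging"))
            elif r < 0.6:
                verdicts.append((tool, "tolerated"))
        calls.append(
            make_call(
                gt_affected=GENOTYPES[rng.integers(0, 4)],
                gt_healthy=GENOTYPES[rng.integers(0, 4)],
                gq=int(rng.integers(0, 100)),
                dp=int(rng.integers(0, 60)),
                consequence=consequences[rng.integers(0, len(consequences))],
                maf=None if rng.random() < 0.4 else float(rng.uniform(0, 0.1)),
                verdicts=verdicts,
                cadd=None if rng.random() < 0.3 else float(rng.uniform(0, 40)),
                pos=i + 1,
            )
        )
    return calls


def test_funnel_matches_brute_force_composition():
    """Survivors equal an independent one-pass re-evaluation of all predicates."""
    rng = np.random.default_rng(123)
    calls = _random_calls(1000, rng)
    trace = run_variant_funnel(calls, mode="unique", cfg=CFG)

    def brute(call):
        if classify_discordance(call) != "unique_to_affected":
            return False
        if call.gq_affected < CFG.min_gq or call.dp_affected < CFG.min_dp:
            return False
        if call.maf is not None and call.maf >= CFG.max_maf:
            return False
        from twindiff.variants import CONSEQUENCE_IMPACT

        impact = CONSEQUENCE_IMPACT[call.consequence]
        if impact == "HIGH":
            return True
        if impact == "MODERATE":
            return any(v == "damaging" for _, v in call.predictor_verdicts)
        if impact == "LOW":
            return False
        return call.cadd is not None and call.cadd > CFG.min_cadd

    expected = {c.site.start for c in calls if brute(c)}
    assert {c.site.start for c in trace.survivors} == expected
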