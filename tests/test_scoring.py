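import itertools

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from hpfscore import (
    Observation,
    SUPPRESSED,
    Thresholds,
    UNDEFINED,
    c1,
    c2,
    delta,
    improvement_score,
    lad,
    percent_change,
    resolve_suppressed,
    score_indicator,
    unit_change,
)
from tests.conftest import EXPECTED_SCORES, SELF_ASSESSED_HEALTH


class TestElementaryIndicators:
    @pytest.mark.parametrize(
        "t1, t2, expected", [(63.7, 60.7, -3.0), (5.0, 5.0, 0.0), (63.4, 65.7, 2.3)]
    )
    def test_delta(self, t1, t2, expected):
        assert delta(t1, t2) == pytest.approx(expected)

    def test_delta_refuses_suppressed(self):
        with pytest.raises(TypeError, match="resolve_suppressed"):
            delta(SUPPRESSED, 1.0)

    @pytest.mark.parametrize("d, expected", [(-3.0, -1), (0.0, 0), (2.3, 1)])
    def test_unit_change_is_sign(self, d, expected):
        assert unit_change(d) == expected

    @pytest.mark.parametrize(
        "t1, t2, expected", [(63.4, 65.7, 3.6), (63.9, 65.1, 1.9), (61.4, 63.3, 3.1)]
    )
    def test_percent_change(self, t1, t2, expected):
        assert round(percent_change(t1, t2), 1) == expected

    def test_percent_change_zero_baseline_is_undefined_not_infinite(self):
        assert percent_change(0.0, 1.4) is UNDEFINED

    @pytest.mark.parametrize(
        "pct, tau, expected",
        [(1.9, 2.0, 0), (-4.6, 2.0, 1), (2.0, 2.0, 1), (UNDEFINED, 2.0, UNDEFINED)],
    )
    def test_c1_uses_absolute_value_and_nonstrict_threshold(self, pct, tau, expected):
        assert c1(pct, tau) is expected if expected is UNDEFINED else c1(pct, tau) == expected

    def test_lad_of_worked_example(self):
        deltas = [-3.0, 2.3, 2.0, 2.1, -2.6, 1.9, 3.9, 1.2]
        assert lad(deltas) == pytest.approx(3.9)

    @pytest.mark.parametrize(
        "deltas, expected", [([0.0, 0.0], 0.0), ([-5.0, 2.0], 5.0)]
    )
    def test_lad_max_of_absolutes(self, deltas, expected):
        assert lad(deltas) == expected

    def test_lad_empty_is_undefined(self):
        assert lad([]) is UNDEFINED

    @pytest.mark.parametrize(
        "d, lad_value, q, expected",
        [
            (1.2, 3.9, 0.10, 1),
            (0.03, 3.9, 0.10, 0),
            (0.0, 0.0, 0.10, 0),   # trivial-LAD guard
            (0.0, 3.9, 0.10, 0),   # no change never earns comparative confidence
            (0.39, 3.9, 0.10, 1),  # threshold is non-strict
        ],
    )
    def test_c2(self, d, lad_value, q, expected):
        assert c2(d, lad_value, q) == expected

    def test_c2_undefined_lad_propagates(self):
        assert c2(1.0, UNDEFINED, 0.1) is UNDEFINED

    @pytest.mark.parametrize(
        "t1, t2, expected_u",
        [(SUPPRESSED, 4.2, 1), (4.2, SUPPRESSED, -1), (SUPPRESSED, SUPPRESSED, 0)],
    )
    def test_resolve_suppressed_inference(self, t1, t2, expected_u):
        u, precluded = resolve_suppressed(t1, t2)
        assert u == expected_u and precluded is True

    def test_resolve_suppressed_misuse(self):
        with pytest.raises(TypeError):
            resolve_suppressed(1.0, 2.0)


class TestImprovementScore:
    @pytest.mark.parametrize(
        "direction, u, c1v, c2v, precluded, expected",
        [
            (1, 1, 0, 1, False, 2),
            (1, -1, 1, 1, False, -3),
            (1, 0, 1, 1, False, 0),
            (-1, -1, 1, 1, False, 3),  # decrease of lower-is-better improves
            (1, 1, UNDEFINED, 1, False, 2),
            (1, 1, UNDEFINED, UNDEFINED, True, 1),
            (-1, 1, 1, 1, True, -1),
        ],
    )
    def test_summation(self, direction, u, c1v, c2v, precluded, expected):
        assert improvement_score(direction, u, c1v, c2v, precluded) == expected

    def test_exhaustive_mapping_matches_combination_table(self):
        """|score| = |U|·(1 + C1 + C2): the full combination table of the
        indicator triple maps onto scores {0, ±1, ±2, ±3} only."""
        magnitudes = {(0, 0, 0): 0, (1, 0, 0): 1, (1, 0, 1): 2, (1, 1, 0): 2,
                      (1, 1, 1): 3}
        seen = set()
        for direction, u, c1v, c2v in itertools.product(
            (1, -1), (-1, 0, 1), (0, 1), (0, 1)
        ):
            score = improvement_score(direction, u, c1v, c2v, False)
            assert abs(score) == (0 if u == 0 else magnitudes[(1, c1v, c2v)])
            if u != 0:
                assert np.sign(score) == direction * u
            seen.add(score)
        assert seen == {-3, -2, -1, 0, 1, 2, 3}


class TestScoreIndicator:
    def test_worked_example_all_columns(self, health_defn, health_observations):
        records = score_indicator(health_observations, health_defn)
        by_juris = {r.jurisdiction: r for r in records}
        assert {j: r.improvement_score for j, r in by_juris.items()} == EXPECTED_SCORES
        for juris, (t1, t2) in SELF_ASSESSED_HEALTH.items():
            r = by_juris[juris]
            assert r.delta == pytest.approx(t2 - t1)
            assert r.lad == pytest.approx(3.9)
            assert r.c2 == 1
        assert by_juris["WA"].c1 == 0 and by_juris["ACT"].c1 == 1

    def test_single_jurisdiction_holds_lad(self, health_defn):
        obs = [Observation(health_defn.indicator_id, "NSW", 10.0, 11.0)]
        (record,) = score_indicator(obs, health_defn)
        assert record.lad == pytest.approx(1.0)
        assert record.c2 == 1
        assert record.improvement_score == 3

    def test_small_baseline_lad_holder_gets_full_score(self, health_defn):
        """A tiny but non-zero baseline yields an extreme relative change;
        holding the LAD earns both confidence indicators."""
        obs = [Observation(health_defn.indicator_id, "ACT", 0.02, 1.40)]
        (record,) = score_indicator(obs, health_defn)
        assert record.delta == pytest.approx(1.38)
        assert record.pct_change == pytest.approx(6900.0)
        assert record.improvement_score == 3

    def test_zero_baseline_is_bounded_without_flag(self, health_defn):
        obs = [
            Observation(health_defn.indicator_id, "ACT", 0.0, 1.4),
            Observation(health_defn.indicator_id, "NSW", 5.0, 5.0),
        ]
        records = {r.jurisdiction: r for r in score_indicator(obs, health_defn)}
        assert records["ACT"].pct_change is UNDEFINED
        assert records["ACT"].c1 is UNDEFINED
        assert abs(records["ACT"].improvement_score) <= 2

    def test_zero_baseline_awards_c1_flag(self, health_defn):
        obs = [Observation(health_defn.indicator_id, "ACT", 0.0, 1.4)]
        (record,) = score_indicator(obs, health_defn, zero_baseline_awards_c1=True)
        assert record.c1 == 1
        assert record.improvement_score == 3

    def test_suppressed_timepoints_bound_score(self, health_defn):
        obs = [
            Observation(health_defn.indicator_id, "NSW", SUPPRESSED, 4.2),
            Observation(health_defn.indicator_id, "Qld", 4.2, SUPPRESSED),
            Observation(health_defn.indicator_id, "NT", SUPPRESSED, SUPPRESSED),
            Observation(health_defn.indicator_id, "WA", 1.0, 3.0),
        ]
        records = {r.jurisdiction: r for r in score_indicator(obs, health_defn)}
        assert records["NSW"].improvement_score == 1
        assert records["Qld"].improvement_score == -1
        assert records["NT"].improvement_score == 0
        for juris in ("NSW", "Qld", "NT"):
            assert records[juris].confidence_precluded
            assert records[juris].c1 is UNDEFINED and records[juris].c2 is UNDEFINED
        # the LAD comes from the numerically complete jurisdictions only
        assert records["WA"].lad == pytest.approx(2.0)

    def test_lad_ties_award_c2_to_all_holders(self, health_defn):
        obs = [
            Observation(health_defn.indicator_id, "NSW", 10.0, 12.0),
            Observation(health_defn.indicator_id, "Qld", 20.0, 18.0),
        ]
        records = score_indicator(obs, health_defn)
        assert all(r.c2 == 1 for r in records)

    def test_merged_and_national_flagged_non_allocatable(self, health_defn):
        obs = [
            Observation(health_defn.indicator_id, "Vic+Tas", 1.0, 2.0),
            Observation(health_defn.indicator_id, "National", 1.0, 2.0),
            Observation(health_defn.indicator_id, "NSW", 1.0, 2.0),
        ]
        records = {r.jurisdiction: r for r in score_indicator(obs, health_defn)}
        assert not records["Vic+Tas"].allocatable
        assert not records["National"].allocatable
        assert records["NSW"].allocatable
        # non-allocatable records are still scored normally
        assert records["Vic+Tas"].improvement_score == records["NSW"].improvement_score


# ---------------------------------------------------------------------------
# property tests

values_1dp = st.integers(min_value=0, max_value=2000).map(lambda v: v / 10.0)


@st.composite
def indicator_panels(draw):
    n = draw(st.integers(min_value=1, max_value=8))
    t1s = draw(st.lists(values_1dp, min_size=n, max_size=n))
    t2s = draw(st.lists(values_1dp, min_size=n, max_size=n))
    return t1s, t2s


def _score_panel(t1s, t2s, direction=1, k=1.0):
    from hpfscore import IndicatorDefinition

    labels = ["NSW", "Vic", "Qld", "WA", "SA", "Tas", "ACT", "NT"]
    obs = [
        Observation("p", labels[i], k * t1, k * t2)
        for i, (t1, t2) in enumerate(zip(t1s, t2s))
    ]
    defn = IndicatorDefinition(
        indicator_id="p", measure_code="1.01", direction_of_effect=direction
    )
    return score_indicator(obs, defn)


def _not_borderline(records, thresholds=Thresholds()):
    """Exclude panels sitting exactly on a threshold, where floating-point
    rescaling may legitimately flip a non-strict comparison."""
    for r in records:
        if r.pct_change is not UNDEFINED:
            if abs(abs(r.pct_change) - thresholds.tau) < 1e-9:
                return False
        if r.lad is not UNDEFINED and r.delta is not UNDEFINED:
            if abs(abs(r.delta) - thresholds.q * r.lad) < 1e-9:
                return False
    return True


class TestScoringProperties:
    @given(panel=indicator_panels(), k=st.sampled_from([0.5, 2.0, 3.0, 10.0]),
           direction=st.sampled_from([1, -1]))
    @settings(max_examples=300, derandomize=True)
    def test_scale_invariance(self, panel, k, direction):
        t1s, t2s = panel
        base = _score_panel(t1s, t2s, direction)
        assume(_not_borderline(base))
        scaled = _score_panel(t1s, t2s, direction, k=k)
        for b, s in zip(base, scaled):
            assert b.unit_change == s.unit_change
            assert b.c1 == s.c1 or (b.c1 is UNDEFINED and s.c1 is UNDEFINED)
            assert b.c2 == s.c2
            assert b.improvement_score == s.improvement_score

    @given(panel=indicator_panels(), direction=st.sampled_from([1, -1]))
    @settings(max_examples=300, derandomize=True)
    def test_sign_coherence(self, panel, direction):
        t1s, t2s = panel
        for r in _score_panel(t1s, t2s, direction):
            if r.delta != 0:
                assert np.sign(r.improvement_score) == direction * np.sign(r.delta)
            else:
                assert r.improvement_score == 0

    @given(panel=indicator_panels())
    @settings(max_examples=300, derandomize=True)
    def test_some_jurisdiction_earns_c2_when_anything_moved(self, panel):
        t1s, t2s = panel
        records = _score_panel(t1s, t2s)
        if any(r.delta != 0 for r in records):
            assert any(r.c2 == 1 for r in records)

    @given(panel=indicator_panels())
    @settings(max_examples=300, derandomize=True)
    def test_score_bounds(self, panel):
        t1s, t2s = panel
        for r in _score_panel(t1s, t2s):
            assert -3 <= r.improvement_score <= 3
            if r.confidence_precluded:
                assert abs(r.improvement_score) <= 1
            if r.c1 is UNDEFINED and not r.confidence_precluded:
                assert abs(r.improvement_score) <= 2
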