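"""Closed-form fitness accounting and the perfect-information concession."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from repskew import (
    DegenerateRelatednessError,
    InvalidScenarioError,
    ModelParams,
    cooperative_fitness,
    critical_concession,
    expected_dominant_fitness_alone,
    group_productivity,
    helping_effect,
    perfect_info_offer,
    solo_fitness,
    subordinate_stays,
)
from repskew.scenarios import constraint_m

from conftest import COLUMNS


class TestHelpingAndProductivity:
    @pytest.mark.parametrize(
        "x,a,m,expected",
        [
            (0.123, 0.0, 0.35, 0.35),   # slope-zero: quality irrelevant
            (0.5, 0.5, 0.35, 0.60),
            (0.5, 2.0, -0.4, 0.60),     # constraint keeps h(0.5) = 0.6
        ],
    )
    def test_helping_effect_examples(self, x, a, m, expected):
        params = ModelParams(b=1.0, r=0.25, a=a, m=m)
        assert helping_effect(x, params) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "x,b,a,m,expected",
        [
            (0.5, 1.0, 0.5, 0.35, 1.6),
            (0.0, 1.0, 0.5, 0.35, 1.35),
            (0.3, 2.0, 0.0, -0.5, 1.0),   # constant-productivity scenario
            (0.9, 2.0, 0.0, -0.5, 1.0),
        ],
    )
    def test_group_productivity_examples(self, x, b, a, m, expected):
        params = ModelParams(b=b, r=0.25, a=a, m=m)
        assert group_productivity(x, params) == pytest.approx(expected, abs=1e-12)

    def test_productivity_balance_constraint_pins_g_at_average_quality(self):
        # m = 0.6 - a/2 makes G(0.5) = 1.6 for every QPC at b = 1
        for a in np.linspace(-1.0, 2.0, 13):
            params = ModelParams(b=1.0, r=0.25, a=a, m=constraint_m(a))
            assert group_productivity(0.5, params) == pytest.approx(1.6, abs=1e-12)

    def test_constant_productivity_scenario_is_flat_in_quality(self):
        for b in (0.5, 1.0, 1.5):
            params = ModelParams(b=b, r=0.25, a=0.0, m=1.0 / b - 1.0)
            g = group_productivity(np.linspace(0, 1, 11), params)
            assert np.allclose(g, 1.0, atol=1e-12)

    def test_nonpositive_productivity_rejected_at_construction(self):
        with pytest.raises(InvalidScenarioError, match="productivity"):
            ModelParams(b=1.0, r=0.25, a=-2.5, m=0.5)  # 1 + m + a*b < 0

    def test_nonpositive_productivity_names_offending_quality(self):
        # valid on [0, b] but queried beyond it, where productivity goes negative
        params = ModelParams(b=1.0, r=0.25, a=-1.0, m=0.5)
        with pytest.raises(InvalidScenarioError, match="x=2.0"):
            group_productivity(np.array([0.5, 2.0]), params)


class TestSoloFitness:
    @pytest.mark.parametrize(
        "x,b,r,expected_dom,expected_sub",
        [
            (0.0, 1.0, 0.0, 1.0, 0.0),
            (0.5, 1.0, 0.25, 1.125, 0.75),
            (2.0, 2.0, 1.0, 4.0, 4.0),  # full-clone symmetry at x = b
        ],
    )
    def test_solo_fitness_examples(self, x, b, r, expected_dom, expected_sub):
        params = ModelParams(b=b, r=r, a=0.0, m=0.35)
        solo = solo_fitness(x, params)
        assert solo.dominant_inclusive == pytest.approx(expected_dom)
        assert solo.subordinate_inclusive == pytest.approx(expected_sub)

    def test_quality_outside_range_rejected(self):
        with pytest.raises(InvalidScenarioError, match="range"):
            solo_fitness(1.5, ModelParams())

    def test_expected_alone_matches_quadrature_of_solo_fitness(self):
        params = ModelParams(b=1.0, r=0.25)
        assert expected_dominant_fitness_alone(params) == pytest.approx(1.125)
        xs = np.linspace(0, 1, 201)
        numeric = np.mean([solo_fitness(x, params).dominant_inclusive for x in xs])
        assert numeric == pytest.approx(expected_dominant_fitness_alone(params),
                                        abs=1e-12)


class TestCooperativeFitness:
    def test_inclusive_is_direct_plus_indirect(self):
        dom, sub = cooperative_fitness(0.7, 0.3, ModelParams(r=0.4))
        assert dom.inclusive == dom.direct + dom.indirect
        assert sub.inclusive == sub.direct + sub.indirect

    def test_zero_share_gives_dominant_everything(self):
        params = ModelParams(b=1.0, r=0.25, a=0.5, m=0.35)
        g = group_productivity(0.6, params)
        dom, sub = cooperative_fitness(0.6, 0.0, params)
        assert dom.inclusive == pytest.approx(g)
        assert sub.inclusive == pytest.approx(params.r * g)

    def test_full_share_unrelated_inverts_payoffs(self):
        params = ModelParams(b=1.0, r=0.0, a=0.5, m=0.35)
        g = group_productivity(0.6, params)
        dom, sub = cooperative_fitness(0.6, 1.0, params)
        assert dom.inclusive == pytest.approx(0.0)
        assert sub.inclusive == pytest.approx(g)

    def test_worked_indifference_point(self):
        # at y = y_c the subordinate's cooperative value equals its outside option
        params = ModelParams(b=1.0, r=0.5, a=2.0, m=-0.4)
        dom, sub = cooperative_fitness(0.5, 0.25, params)
        assert dom.inclusive == pytest.approx(1.4)
        assert sub.inclusive == pytest.approx(1.0)
        assert sub.inclusive == pytest.approx(
            solo_fitness(0.5, params).subordinate_inclusive
        )

    def test_share_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidScenarioError, match="share"):
            cooperative_fitness(0.5, 1.2, ModelParams())

    def test_dominant_inclusive_decreasing_in_share_unless_clonal(self):
        params = ModelParams(b=1.0, r=0.5, a=0.5, m=0.35)
        ys = np.linspace(0, 1, 21)
        vals = [cooperative_fitness(0.5, y, params)[0].inclusive for y in ys]
        assert np.all(np.diff(vals) < 0)
        clone = ModelParams(b=1.0, r=1.0, a=0.5, m=0.35)
        vals = [cooperative_fitness(0.5, y, clone)[0].inclusive for y in ys]
        assert np.allclose(vals, vals[0], atol=1e-12)


class TestCriticalConcession:
    @pytest.mark.parametrize(
        "x,b,r,a,m,expected",
        [
            (0.0, 1.0, 0.0, 0.5, 0.35, 0.0),
            (0.5, 1.0, 0.5, 2.0, -0.4, 0.25),
            (0.1, 1.0, 0.5, 0.5, 0.35, -1.0 / 7.0),  # stays even at zero share
        ],
    )
    def test_examples(self, x, b, r, a, m, expected):
        params = ModelParams(b=b, r=r, a=a, m=m)
        assert critical_concession(x, params) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_relatedness_rejected(self):
        with pytest.raises(DegenerateRelatednessError):
            critical_concession(0.5, ModelParams(r=1.0))

    @given(
        x=st.floats(0.0, 1.0),
        r=st.floats(0.0, 0.95),
        a=st.floats(-1.0, 2.0),
    )
    def test_indifference_identity(self, x, r, a):
        """At y_c in [0, 1] the subordinate is exactly indifferent."""
        params = ModelParams(b=1.0, r=r, a=a, m=constraint_m(a))
        y_c = critical_concession(x, params)
        if not 0.0 <= y_c <= 1.0:
            return
        _, sub = cooperative_fitness(x, y_c, params)
        alone = solo_fitness(x, params).subordinate_inclusive
        assert abs(sub.inclusive - alone) <= 1e-12

    def test_concession_direction_in_relatedness_set_by_helping_surplus(self):
        # dy_c/dr has the sign of x - h(x): the concession falls with
        # relatedness wherever the helping effect exceeds the outside
        # option (h(x) > x), and rises with it in the rare opposite corner
        rs_grid = np.linspace(0.0, 0.9, 10)
        for a, m in COLUMNS:
            for x in (0.2, 0.35, 0.5):
                h = a * x + m
                ys = [critical_concession(x, ModelParams(b=1.0, r=r, a=a, m=m))
                      for r in rs_grid]
                vals = np.array([y for y in ys if 0 < y < 1])
                if h > x:
                    assert np.all(np.diff(vals) < 0)
                elif h < x:
                    assert np.all(np.diff(vals) > 0)


class TestStayDecision:
    def test_indifference_counts_as_staying(self):
        params = ModelParams(b=1.0, r=0.5, a=2.0, m=-0.4)
        y_c = critical_concession(0.5, params)
        assert subordinate_stays(0.5, y_c, params)

    def test_negative_critical_share_means_stay_at_zero(self):
        params = ModelParams(b=1.0, r=0.5, a=0.5, m=0.35)
        assert subordinate_stays(0.1, 0.0, params)

    def test_unrelated_high_quality_leaves_at_zero_share(self):
        params = ModelParams(b=1.0, r=0.0, a=0.5, m=0.35)
        assert not subordinate_stays(0.9, 0.0, params)


class TestPerfectInfoOffer:
    def test_worked_example_accept(self):
        params = ModelParams(b=1.0, r=0.5, a=2.0, m=-0.4)
        offer = perfect_info_offer(0.5, params)
        assert offer.share == pytest.approx(0.25)
        assert offer.dominant_accepts
        assert offer.expected_dominant_inclusive == pytest.approx(1.4)

    def test_negative_critical_share_clamps_to_zero(self):
        params = ModelParams(b=1.0, r=0.5, a=0.5, m=0.35)
        offer = perfect_info_offer(0.1, params)
        assert offer.share == 0.0
        g = group_productivity(0.1, params)
        assert offer.dominant_accepts == (g >= 1.0 + 0.5 * 0.1)

    def test_offer_direction_in_quality_depends_on_qpc(self):
        xs = np.linspace(0.05, 0.95, 19)
        steep = ModelParams(b=1.0, r=0.5, a=2.0, m=-0.4)
        shares = [perfect_info_offer(x, steep).share for x in xs]
        assert np.all(np.diff(shares) < 0)
        shallow = ModelParams(b=1.0, r=0.5, a=0.5, m=0.35)
        shares = [perfect_info_offer(x, shallow).share for x in xs]
        inside = np.array([s for s in shares if 0 < s < 1])
        assert np.all(np.diff(inside) > 0)

    @pytest.mark.parametrize("a,m", COLUMNS)
    @pytest.mark.parametrize("r", [0.0, 0.25, 0.5])
    def test_bruteforce_share_scan_matches_closed_form(self, a, m, r):
        """Independent oracle: scanning a fine share grid for the dominant's
        best retainable share reproduces the closed-form clamped offer."""
        params = ModelParams(b=1.0, r=r, a=a, m=m)
        y_grid = np.linspace(0.0, 1.0, 2001)  # step 5e-4
        for x in np.linspace(0.0, 1.0, 11):
            g = group_productivity(x, params)
            stays = g * (y_grid * (1 - r) + r) >= r + x - 1e-12
            offer = perfect_info_offer(float(x), params)
            if not stays.any():
                assert not offer.dominant_accepts
                continue
            dom = np.where(stays, g * (1 - y_grid * (1 - r)), -np.inf)
            best = int(np.argmax(dom))
            assert abs(y_grid[best] - offer.share) <= 5e-4 + 1e-12
            d_alone = 1.0 + r * x
            margin = dom[best] - d_alone
            # skip the accept comparison within one grid step of an exact
            # tie, where quantizing the share flips the decision
            if abs(margin) > g * (1 - r) * 5e-4:
                assert (margin >= 0) == offer.dominant_accepts


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(b=0.0), dict(b=-1.0), dict(r=-0.1), dict(r=1.2)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidScenarioError):
            ModelParams(**kwargs)
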