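"""Event/DALY projection: closed forms, the microsimulation oracle, properties."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pydantic import ValidationError

from faitkit import (
    EpiParams,
    dalys_averted,
    project_events,
    relative_risk,
    scale_projection,
)


class TestRelativeRisk:
    @pytest.mark.parametrize(
        "delta,rr10,expected",
        [
            (10.0, 0.80, 0.80),
            (0.0, 0.80, 1.0),
            (13.0, 0.80, 0.7482),  # exp((13/10) ln 0.8), 4 dp
        ],
    )
    def test_values(self, delta, rr10, expected):
        assert relative_risk(delta, rr10) == pytest.approx(expected, abs=5e-5)

    def test_negative_reduction_rejected(self):
        with pytest.raises(ValueError, match="delta_sbp"):
            relative_risk(-1.0, 0.8)

    def test_bad_rr_rejected(self):
        for bad in (0.0, 1.2, -0.5):
            with pytest.raises(ValueError):
                relative_risk(5.0, bad)

    @given(
        a=st.floats(0.0, 40.0),
        b=st.floats(0.0, 40.0),
        rr10=st.floats(0.05, 1.0, exclude_min=True),
    )
    def test_log_linearity(self, a, b, rr10):
        """rr(a + b) = rr(a) * rr(b): multiplicative per increment."""
        assert relative_risk(a + b, rr10) == pytest.approx(
            relative_risk(a, rr10) * relative_risk(b, rr10), rel=1e-9
        )

    @given(
        delta=st.floats(0.1, 40.0),
        eps=st.floats(0.1, 10.0),
        rr10=st.floats(0.05, 0.999),
    )
    def test_strictly_decreasing(self, delta, eps, rr10):
        assert relative_risk(delta + eps, rr10) < relative_risk(delta, rr10)


class TestProjectEvents:
    def test_zero_delta_averts_nothing(self, epi_demo):
        proj = project_events(1000, 0.0, epi_demo)
        assert proj.events_averted == 0.0
        assert proj.rr_applied == 1.0

    def test_worked_example(self, epi_demo):
        """n 1,000, risk 0.10, 10 mmHg at RR 0.8 -> 20 events, 6 deaths averted."""
        proj = project_events(1000, 10.0, epi_demo)
        assert proj.events_control == pytest.approx(100.0)
        assert proj.events_averted == pytest.approx(20.0)
        assert proj.deaths_averted == pytest.approx(6.0)

    def test_microsimulation_oracle(self):
        """Closed form matches a per-person Bernoulli simulation within 3 SE."""
        rng = np.random.default_rng(2024)
        n, reps = 2000, 4000
        params = EpiParams(baseline_event_risk=0.10, case_fatality=0.3)
        rr = relative_risk(10.0, params.rr_per_10)
        events_c = (rng.random((reps, n)) < params.baseline_event_risk).sum(axis=1)
        events_i = (rng.random((reps, n)) < params.baseline_event_risk * rr).sum(axis=1)
        averted = events_c - events_i
        se = averted.std(ddof=1) / math.sqrt(reps)
        proj = project_events(n, 10.0, params)
        assert abs(proj.events_averted - averted.mean()) <= 3 * se

    def test_negative_exposure_rejected(self, epi_demo):
        with pytest.raises(ValueError):
            project_events(-1, 5.0, epi_demo)

    @given(
        n=st.floats(0, 1e6),
        d1=st.floats(0, 30),
        d2=st.floats(0, 10),
        risk=st.floats(0, 1),
    )
    def test_monotone_in_delta_and_exposure(self, n, d1, d2, risk):
        params = EpiParams(baseline_event_risk=risk, case_fatality=0.2)
        base = project_events(n, d1, params)
        more_bp = project_events(n, d1 + d2, params)
        more_people = project_events(n * 2, d1, params)
        assert more_bp.events_averted >= base.events_averted
        assert more_people.events_averted >= base.events_averted
        assert base.deaths_averted <= base.events_averted + 1e-9


class TestDalys:
    def test_yll_spans_age_to_life_expectancy(self):
        """One death averted at age 59, life expectancy 69 -> 10 YLL."""
        params = EpiParams(baseline_event_risk=1.0, case_fatality=1.0)
        proj = project_events(1, 10.0, params)
        proj = proj.model_copy(update={"events_averted": 1.0, "deaths_averted": 1.0})
        out = dalys_averted(proj, params)
        assert out.yll_averted == pytest.approx(10.0)
        assert out.yld_averted == 0.0

    def test_nonfatal_uses_disability_weight(self):
        """One non-fatal event, weight 0.39 over 10 years -> 3.9 YLD."""
        params = EpiParams(
            baseline_event_risk=1.0, case_fatality=0.0, nonfatal_duration=10.0
        )
        proj = project_events(1, 10.0, params)
        proj = proj.model_copy(update={"events_averted": 1.0, "deaths_averted": 0.0})
        out = dalys_averted(proj, params)
        assert out.yld_averted == pytest.approx(3.9)
        assert out.yll_averted == 0.0

    def test_zero_events_zero_dalys(self, epi_demo):
        out = dalys_averted(project_events(1000, 0.0, epi_demo), epi_demo)
        assert out.dalys_averted == 0.0

    def test_life_expectancy_below_age_rejected(self):
        with pytest.raises(ValidationError):
            EpiParams(
                baseline_event_risk=0.1,
                case_fatality=0.1,
                mean_age=70,
                life_expectancy=69,
            )

    @given(
        n=st.floats(0, 1e5),
        delta=st.floats(0, 30),
        risk=st.floats(0, 1),
        cf=st.floats(0, 1),
    )
    def test_daly_conservation(self, n, delta, risk, cf):
        """DALYs averted = YLL + YLD exactly, and all terms non-negative."""
        params = EpiParams(baseline_event_risk=risk, case_fatality=cf)
        out = dalys_averted(project_events(n, delta, params), params)
        assert out.dalys_averted == pytest.approx(out.yll_averted + out.yld_averted)
        assert out.yll_averted >= 0 and out.yld_averted >= 0

    def test_discounting_shrinks_dalys(self, epi_demo):
        discounted = EpiParams(
            baseline_event_risk=0.1, case_fatality=0.3, discount_rate=0.03
        )
        proj = project_events(1000, 10.0, epi_demo)
        assert (
            dalys_averted(proj, discounted).dalys_averted
            < dalys_averted(proj, epi_demo).dalys_averted
        )


class TestScale:
    def test_identity_and_zero(self, epi_demo):
        proj = dalys_averted(project_events(1000, 10.0, epi_demo), epi_demo)
        assert scale_projection(proj, 1.0) == proj
        zero = scale_projection(proj, 0.0)
        assert zero.events_averted == 0.0 and zero.dalys_averted == 0.0

    def test_linearity(self, epi_demo):
        proj = dalys_averted(project_events(1000, 10.0, epi_demo), epi_demo)
        scaled = scale_projection(proj, 59.0)
        assert scaled.events_averted == pytest.approx(59.0 * proj.events_averted)
        assert scaled.dalys_averted == pytest.approx(59.0 * proj.dalys_averted)
        # population-invariant fields untouched
        assert scaled.rr_applied == proj.rr_applied
        assert scaled.delta_sbp == proj.delta_sbp

    def test_negative_factor_rejected(self, epi_demo):
        proj = project_events(10, 5.0, epi_demo)
        with pytest.raises(ValueError):
            scale_projection(proj, -2.0)
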