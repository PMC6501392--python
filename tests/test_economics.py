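"""Benefit monetisation and the SROI ratio."""

import pytest
from hypothesis import given
from hypothesis import strategies as st
from pydantic import ValidationError

from faitkit import (
    CostLedger,
    EconParams,
    EventProjection,
    assemble_benefits,
    health_system_savings,
    indirect_benefit,
    productivity_gain,
    project_cost,
    run_scenarios,
    sroi,
)


def make_projection(events=100.0, dalys=50.0) -> EventProjection:
    return EventProjection(
        n_exposed=1000,
        delta_sbp=10.0,
        rr_applied=0.8,
        events_control=events * 5,
        events_intervention=events * 4,
        events_averted=events,
        deaths_averted=events * 0.3,
        yll_averted=dalys * 0.6,
        yld_averted=dalys * 0.4,
        dalys_averted=dalys,
    )


class TestComponents:
    def test_hospital_savings(self, econ_demo):
        assert health_system_savings(0.0, econ_demo) == 0.0
        assert health_system_savings(100.0, econ_demo) == pytest.approx(450_000.0)

    def test_hospital_savings_linear_in_unit_cost(self):
        cheap = EconParams(gni_per_capita=1.0, hosp_cost_per_event=10.0)
        dear = EconParams(gni_per_capita=1.0, hosp_cost_per_event=30.0)
        assert health_system_savings(73_000, dear) == pytest.approx(
            3 * health_system_savings(73_000, cheap)
        )

    def test_productivity_definition(self):
        params = EconParams(gni_per_capita=3000.0, hosp_cost_per_event=0.0)
        assert productivity_gain(1.0, params) == pytest.approx(1500.0)

    def test_base_case_doubles_conservative(self, econ_demo):
        """Fraction 1.0 is exactly twice fraction 0.5 for any input."""
        for dalys in (0.5, 17.3, 1e5):
            assert productivity_gain(dalys, econ_demo, fraction=1.0) == pytest.approx(
                2 * productivity_gain(dalys, econ_demo, fraction=0.5)
            )

    def test_productivity_recovers_printed_scale(self):
        """If 0.5 D g = 192.4M then fraction 1.0 gives exactly 384.8M."""
        g = 3500.0
        d = 192.4e6 / (0.5 * g)
        params = EconParams(gni_per_capita=g, hosp_cost_per_event=0.0)
        assert productivity_gain(d, params, fraction=1.0) == pytest.approx(384.8e6)
        assert indirect_benefit(d, params) == pytest.approx(192.4e6)

    def test_indirect_benefit(self, econ_demo):
        assert indirect_benefit(0.0, econ_demo) == 0.0
        zero = EconParams(
            gni_per_capita=3500.0, hosp_cost_per_event=0.0, indirect_fraction=0.0
        )
        assert indirect_benefit(1e6, zero) == 0.0

    @given(dalys=st.floats(0, 1e7), gni=st.floats(0, 1e5))
    def test_indirect_equals_half_fraction_productivity(self, dalys, gni):
        """With default fractions the two half-GNI streams coincide."""
        params = EconParams(gni_per_capita=gni, hosp_cost_per_event=0.0)
        assert indirect_benefit(dalys, params) == pytest.approx(
            productivity_gain(dalys, params, fraction=0.5)
        )


class TestAssemble:
    def test_zero_projection_all_zero(self, econ_demo):
        out = assemble_benefits(make_projection(events=0.0, dalys=0.0), econ_demo)
        assert out.total_c == 0.0

    def test_total_is_component_sum(self, econ_demo):
        out = assemble_benefits(make_projection(), econ_demo, "conservative", 0.5)
        assert out.total_c == pytest.approx(
            out.health_system_savings + out.productivity_gain + out.indirect_benefit
        )
        assert out.scenario_label == "conservative"

    @pytest.mark.parametrize(
        "components,expected",
        [((333.0, 192.4, 192.4), 717.8), ((333.0, 384.8, 192.4), 910.2)],
    )
    def test_component_addition(self, components, expected):
        hss, prod, ind = components
        assert hss + prod + ind == pytest.approx(expected)


class TestSroi:
    def test_break_even(self):
        ledger = CostLedger(research_cost_a=40.0, implementation_cost_b=60.0)
        assert sroi(100.0, ledger).sroi == pytest.approx(1.0)

    def test_published_component_arithmetic(self, table_ledger):
        """717.8M / 329.3M -> 2.18; 910.2M / 329.3M -> 2.76 (2 dp)."""
        assert round(sroi(717.8e6, table_ledger).sroi, 2) == 2.18
        assert round(sroi(910.2e6, table_ledger).sroi, 2) == 2.76

    def test_zero_costs_undefined(self):
        ledger = CostLedger(research_cost_a=0.0, implementation_cost_b=0.0)
        with pytest.raises(ZeroDivisionError):
            sroi(10.0, ledger)

    def test_negative_inputs_rejected(self, table_ledger):
        with pytest.raises(ValueError):
            sroi(-1.0, table_ledger)
        with pytest.raises(ValidationError):
            CostLedger(research_cost_a=-1.0, implementation_cost_b=5.0)

    @given(
        a=st.floats(0.01, 1e9),
        b=st.floats(0.0, 1e9),
        c=st.floats(0.0, 1e10),
        k=st.floats(0.001, 1e4),
    )
    def test_homogeneity(self, a, b, c, k):
        """Rescaling a, b and c by a common factor leaves SROI unchanged."""
        base = sroi(c, CostLedger(research_cost_a=a, implementation_cost_b=b))
        scaled = sroi(
            c * k, CostLedger(research_cost_a=a * k, implementation_cost_b=b * k)
        )
        assert scaled.sroi == pytest.approx(base.sroi, rel=1e-9)

    @given(
        a=st.floats(0.01, 1e9),
        b=st.floats(0.0, 1e9),
        c=st.floats(0.0, 1e10),
        bump=st.floats(0.01, 1e9),
    )
    def test_monotonicity(self, a, b, c, bump):
        """SROI increases in c and decreases in a and b."""
        ledger = CostLedger(research_cost_a=a, implementation_cost_b=b)
        assert sroi(c + bump, ledger).sroi > sroi(c, ledger).sroi
        dearer = CostLedger(research_cost_a=a + bump, implementation_cost_b=b)
        assert sroi(c, dearer).sroi <= sroi(c, ledger).sroi


class TestScenarios:
    def test_zero_benefits_zero_sroi(self, table_ledger):
        params = EconParams(gni_per_capita=3500.0, hosp_cost_per_event=4500.0)
        results = run_scenarios(
            make_projection(events=0.0, dalys=0.0), params, table_ledger
        )
        assert [r.sroi for r in results] == [0.0, 0.0]

    def test_conservative_below_base(self, econ_demo, table_ledger):
        results = run_scenarios(make_projection(), econ_demo, table_ledger)
        labels = [r.scenario_label for r in results]
        assert labels == ["conservative", "base"]
        assert results[0].sroi <= results[1].sroi

    def test_custom_fraction_between_defaults(self, econ_demo, table_ledger):
        results = run_scenarios(
            make_projection(),
            econ_demo,
            table_ledger,
            custom_fractions={"mid": 0.75},
        )
        by_label = {r.scenario_label: r.sroi for r in results}
        assert by_label["conservative"] < by_label["mid"] < by_label["base"]


class TestProjectCost:
    @pytest.mark.parametrize(
        "annual,years,expected",
        [(500_000.0, 5, 2_500_000.0), (123.0, 0, 0.0), (177_000.0, 1, 177_000.0)],
    )
    def test_values(self, annual, years, expected):
        assert project_cost(annual, years) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            project_cost(-1.0, 5)


def test_annual_cost_consistency_enforced():
    CostLedger(
        research_cost_a=1.0,
        implementation_cost_b=2_500_000.0,
        horizon=5,
        annual_implementation_cost=500_000.0,
    )
    with pytest.raises(ValidationError):
        CostLedger(
            research_cost_a=1.0,
            implementation_cost_b=2_000_000.0,
            horizon=5,
            annual_implementation_cost=500_000.0,
        )
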