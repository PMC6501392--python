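"""Monetising health gains and the social return on investment (SROI).

The cost-benefit layer of the impact assessment.  Three benefit streams are
monetised from an event/DALY projection:

* **health-system savings** — averted hospitalisations (one per CVD event by
  default) at the average unit cost of a CVD hospitalisation;
* **productivity gains** — each healthy life year gained (DALY averted)
  valued at 6-12 months of per-capita Gross National Income (GNI); the
  fraction of a year's GNI is the scenario lever (0.5 conservative, 1.0
  base case);
* **indirect benefits** — non-medical and indirect cost savings, valued at
  half a year's GNI per healthy life year gained.

SROI = c / (a + b), where a is the cost of the research itself, b the cost
of deploying the trialled intervention, and c the sum of monetised benefits.
Currencies are opaque labels: no conversion is performed, and all three
terms must be expressed in the same currency by the user.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .projection import EventProjection

__all__ = [
    "CostLedger",
    "EconParams",
    "BenefitComponents",
    "SroiResult",
    "health_system_savings",
    "productivity_gain",
    "indirect_benefit",
    "assemble_benefits",
    "sroi",
    "run_scenarios",
    "project_cost",
]

#: (scenario label, productivity fraction) pairs run by default.
DEFAULT_SCENARIOS: tuple[tuple[str, float], ...] = (
    ("conservative", 0.5),
    ("base", 1.0),
)


class CostLedger(BaseModel):
    """Costs of the research (a) and of deploying its recommendations (b)."""

    model_config = ConfigDict(frozen=True)

    research_cost_a: float = Field(ge=0.0)
    implementation_cost_b: float = Field(ge=0.0)
    currency_label: str = "USD"
    horizon: float = Field(default=5.0, gt=0.0)
    annual_implementation_cost: Optional[float] = Field(default=None, ge=0.0)

    @model_validator(mode="after")
    def _annual_consistent(self) -> "CostLedger":
        if self.annual_implementation_cost is not None:
            expected = self.annual_implementation_cost * self.horizon
            if abs(expected - self.implementation_cost_b) > 1e-6 * max(1.0, expected):
                raise ValueError(
                    "implementation_cost_b must equal "
                    "annual_implementation_cost * horizon when both are given"
                )
        return self


class EconParams(BaseModel):
    """Valuation parameters for the three benefit streams."""

    model_config = ConfigDict(frozen=True)

    gni_per_capita: float = Field(ge=0.0)
    hosp_cost_per_event: float = Field(ge=0.0)
    productivity_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    indirect_fraction: float = Field(default=0.5, ge=0.0)
    hospitalisations_per_event: float = Field(default=1.0, ge=0.0)


class BenefitComponents(BaseModel):
    """The monetised benefit components and their total (c)."""

    health_system_savings: float = Field(ge=0.0)
    productivity_gain: float = Field(ge=0.0)
    indirect_benefit: float = Field(ge=0.0)
    total_c: float = Field(ge=0.0)
    scenario_label: str = "custom"

    @model_validator(mode="after")
    def _additive(self) -> "BenefitComponents":
        s = self.health_system_savings + self.productivity_gain + self.indirect_benefit
        if abs(s - self.total_c) > 1e-6 * max(1.0, s):
            raise ValueError("total_c must equal the sum of the three components")
        return self


class SroiResult(BaseModel):
    """SROI ratio with the a, b, c inputs echoed for the report."""

    sroi: float
    a: float
    b: float
    c: float
    scenario_label: str = "custom"


def health_system_savings(events_averted: float, params: EconParams) -> float:
    """Hospitalisation costs avoided: events x hospitalisations/event x unit cost."""
    if events_averted < 0:
        raise ValueError("events_averted must be >= 0")
    return events_averted * params.hospitalisations_per_event * params.hosp_cost_per_event


def productivity_gain(
    dalys_averted: float, params: EconParams, fraction: Optional[float] = None
) -> float:
    """GNI-denominated productivity: DALYs x fraction of a year's GNI x GNI.

    ``fraction`` overrides ``params.productivity_fraction`` for scenario runs.
    """
    if dalys_averted < 0:
        raise ValueError("dalys_averted must be >= 0")
    f = params.productivity_fraction if fraction is None else fraction
    return dalys_averted * f * params.gni_per_capita


def indirect_benefit(dalys_averted: float, params: EconParams) -> float:
    """Indirect/non-medical savings: DALYs x indirect fraction x GNI per capita."""
    if dalys_averted < 0:
        raise ValueError("dalys_averted must be >= 0")
    return dalys_averted * params.indirect_fraction * params.gni_per_capita


def assemble_benefits(
    projection: EventProjection,
    params: EconParams,
    scenario_label: str = "custom",
    productivity_fraction: Optional[float] = None,
) -> BenefitComponents:
    """Compute the three benefit streams from a projection and sum them into c."""
    hss = health_system_savings(projection.events_averted, params)
    prod = productivity_gain(projection.dalys_averted, params, productivity_fraction)
    ind = indirect_benefit(projection.dalys_averted, params)
    return BenefitComponents(
        health_system_savings=hss,
        productivity_gain=prod,
        indirect_benefit=ind,
        total_c=hss + prod + ind,
        scenario_label=scenario_label,
    )


def sroi(c: float, ledger: CostLedger, scenario_label: str = "custom") -> SroiResult:
    """Social return on investment: c / (a + b)."""
    if c < 0:
        raise ValueError("benefit c must be >= 0")
    denom = ledger.research_cost_a + ledger.implementation_cost_b
    if denom == 0:
        raise ZeroDivisionError("SROI undefined: a + b = 0")
    return SroiResult(
        sroi=c / denom,
        a=ledger.research_cost_a,
        b=ledger.implementation_cost_b,
        c=c,
        scenario_label=scenario_label,
    )


def run_scenarios(
    projection: EventProjection,
    params: EconParams,
    ledger: CostLedger,
    custom_fractions: Optional[dict[str, float]] = None,
) -> list[SroiResult]:
    """SROI under the conservative (0.5) and base (1.0) productivity scenarios.

    ``custom_fractions`` maps extra scenario labels to productivity fractions
    appended after the two defaults.
    """
    scenarios = list(DEFAULT_SCENARIOS)
    if custom_fractions:
        scenarios.extend(sorted(custom_fractions.items()))
    results = []
    for label, fraction in scenarios:
        benefits = assemble_benefits(
            projection, params, scenario_label=label, productivity_fraction=fraction
        )
        results.append(sroi(benefits.total_c, ledger, scenario_label=label))
    return results


def project_cost(annual_cost: float, years: float) -> float:
    """Total cost of an activity run at ``annual_cost`` for ``years`` years."""
    if annual_cost < 0 or years < 0:
        raise ValueError("annual_cost and years must be >= 0")
    return annual_cost * years
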