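"""Programme logic models, case-study narratives and the data-readiness audit.

The qualitative half of the impact framework.  A programme logic model
(theory of change) chains the need being addressed through activities,
expected outputs and their end-users to the anticipated impact; a case
narrative summarises, for a lay reader, how translation occurred under five
fixed sub-headings (need, research response, outcome, impact, lessons).

The data-readiness audit is the prospective-use safeguard: it checks, before
any computation, whether a pipeline configuration carries every parameter
the quantitative SROI chain needs, and names the downstream outputs each
missing parameter blocks.  A retrospective assessment that lacks, say, a
baseline event risk can then report *what* could not be computed and *why*
instead of failing — the scorecard renders a data-gap note in place of the
SROI block.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "LogicModel",
    "CaseNarrative",
    "ValidationResult",
    "ReadinessReport",
    "validate_logic_model",
    "audit_data_readiness",
    "render_narrative",
]

NARRATIVE_SECTIONS = ("need", "research_response", "outcome", "impact", "lessons")
NARRATIVE_HEADINGS = {
    "need": "Need",
    "research_response": "Research response",
    "outcome": "Outcome",
    "impact": "Impact",
    "lessons": "Lessons",
}

LOGIC_SECTIONS = ("need", "activities", "outputs", "end_users", "anticipated_impact")


class LogicModel(BaseModel):
    """Five-section programme logic model with optional element links."""

    need: str = ""
    activities: list[str] = Field(default_factory=list)
    outputs: list[str] = Field(default_factory=list)
    end_users: list[str] = Field(default_factory=list)
    anticipated_impact: list[str] = Field(default_factory=list)
    #: free-form (from_element, to_element) pairs; elements are the literal
    #: strings appearing in the lists above (or the need text itself).
    links: list[tuple[str, str]] = Field(default_factory=list)

    def elements(self) -> set[str]:
        out = {self.need} if self.need else set()
        for section in LOGIC_SECTIONS[1:]:
            out.update(getattr(self, section))
        return out


class CaseNarrative(BaseModel):
    """Lay-language case study under the five standard sub-headings."""

    need: str
    research_response: str
    outcome: str
    impact: str
    lessons: str

    @model_validator(mode="after")
    def _non_empty(self) -> "CaseNarrative":
        for section in NARRATIVE_SECTIONS:
            if not getattr(self, section).strip():
                raise ValueError(f"narrative section {section!r} must be non-empty")
        return self


class ValidationResult(BaseModel):
    findings: list[str] = Field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.findings


class ReadinessReport(BaseModel):
    """Missing SROI-chain parameters and the outputs they block."""

    missing_fields: list[str] = Field(default_factory=list)
    affected_outputs: list[str] = Field(default_factory=list)
    suggested_approach: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _coupled(self) -> "ReadinessReport":
        if bool(self.missing_fields) != bool(self.affected_outputs):
            raise ValueError(
                "affected_outputs must be empty exactly when missing_fields is"
            )
        return self

    @property
    def ready(self) -> bool:
        return not self.missing_fields


def validate_logic_model(model: LogicModel) -> ValidationResult:
    """List empty sections and dangling links; never raises on content."""
    findings: list[str] = []
    if not model.need.strip():
        findings.append("empty section: need")
    for section in LOGIC_SECTIONS[1:]:
        items = [s for s in getattr(model, section) if s.strip()]
        if not items:
            findings.append(f"empty section: {section}")
    elements = model.elements()
    for src, dst in model.links:
        for end, role in ((src, "source"), (dst, "target")):
            if end not in elements:
                findings.append(f"dangling link {role}: {end!r}")
    return ValidationResult(findings=findings)


# Static dependency graph: each SROI-chain parameter -> the pipeline outputs
# that cannot be computed without it.  Parameters with model defaults
# (relative risk per 10 mmHg, disability weights, ages, fractions) are never
# "missing"; only the setting-specific, literature-sourced values are audited.
_EVENT_OUTPUTS = ("events_averted", "deaths_averted", "dalys_averted")
_BENEFIT_OUTPUTS = ("total_benefit_c", "sroi")
READINESS_DEPENDENCIES: dict[str, tuple[tuple[str, ...], str]] = {
    "epi.baseline_event_risk": (
        _EVENT_OUTPUTS
        + ("health_system_savings", "productivity_gain", "indirect_benefit")
        + _BENEFIT_OUTPUTS,
        "obtain a cumulative CVD event risk over the horizon for the exposed "
        "cohort from local surveillance or published cohort studies",
    ),
    "epi.case_fatality": (
        ("deaths_averted", "dalys_averted", "productivity_gain", "indirect_benefit")
        + _BENEFIT_OUTPUTS,
        "use case-fatality rates for CVD events reported for comparable "
        "middle-income settings",
    ),
    "econ.hosp_cost_per_event": (
        ("health_system_savings",) + _BENEFIT_OUTPUTS,
        "cost the average CVD hospitalisation from national tariff or "
        "insurance claims data",
    ),
    "econ.gni_per_capita": (
        ("productivity_gain", "indirect_benefit") + _BENEFIT_OUTPUTS,
        "take per-capita Gross National Income from national accounts or "
        "World Bank indicators",
    ),
    "costs.research_cost_a": (
        ("sroi",),
        "total the research project's own budget (a)",
    ),
    "costs.implementation_cost_b": (
        ("sroi",),
        "cost the deployment of the trialled intervention at the intended "
        "scale (b), e.g. annual cost x horizon",
    ),
}


def audit_data_readiness(config: dict) -> ReadinessReport:
    """Audit a (possibly partial) pipeline configuration for SROI readiness.

    ``config`` is the raw nested mapping (sections ``epi``, ``econ``,
    ``costs``); a parameter counts as missing when its section or key is
    absent or the value is null.  The dependency graph is static, so the
    audit is monotone: supplying a value can only shrink the report.
    """
    missing: list[str] = []
    affected: set[str] = set()
    approaches: dict[str, str] = {}
    for dotted, (outputs, approach) in READINESS_DEPENDENCIES.items():
        section, key = dotted.split(".")
        value = (config.get(section) or {}).get(key)
        if value is None:
            missing.append(dotted)
            affected.update(outputs)
            approaches[dotted] = approach
    return ReadinessReport(
        missing_fields=missing,
        affected_outputs=sorted(affected),
        suggested_approach=approaches,
    )


def render_narrative(narrative: CaseNarrative, format: str = "markdown") -> str:
    """Render the five-section case study; deterministic, sections in order."""
    if format == "markdown":
        parts = [
            f"**{NARRATIVE_HEADINGS[s]}:** {getattr(narrative, s)}"
            for s in NARRATIVE_SECTIONS
        ]
        return "\n\n".join(parts) + "\n"
    if format == "html":
        parts = [
            f"<p><strong>{NARRATIVE_HEADINGS[s]}:</strong> "
            f"{getattr(narrative, s)}</p>"
            for s in NARRATIVE_SECTIONS
        ]
        return "\n".join(parts) + "\n"
    raise ValueError(f"unsupported format: {format!r}")
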