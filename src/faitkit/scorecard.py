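"""Domains-of-benefit scorecards: load, validate, aggregate, render.

A scorecard is the single integrated artefact of the assessment: a table of
benefit domains (Payback-style), each holding typed metrics and free-text
output/outcome statements; a social-return-on-investment block (or, where
the data to compute one were never collected, an explicit data-gap note);
and the case-study narrative.

Domain names come from a controlled default vocabulary — knowledge
generation, capacity building, policy, clinical practice, health services,
population health, economic benefit, plus the extensions used in practice
(engagement and networking, health systems strengthening) — but the
vocabulary is advisory: unknown names load with a warning, because domains
are meant to be adapted to the project under review.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .economics import CostLedger, SroiResult
from .qualitative import CaseNarrative, render_narrative

__all__ = [
    "Metric",
    "Domain",
    "SroiBlock",
    "Scorecard",
    "DEFAULT_DOMAIN_VOCABULARY",
    "load_scorecard",
    "save_scorecard",
    "aggregate_counts",
    "sum_metrics",
    "render_scorecard",
]

DEFAULT_DOMAIN_VOCABULARY = frozenset(
    {
        "Advance knowledge",
        "Knowledge generation",
        "Capacity-building",
        "Capacity-building and networking",
        "Engagement and networking",
        "Policy development",
        "Clinical practice",
        "Health services",
        "Health systems strengthening",
        "Health outcomes",
        "Population health",
        "Healthy eating: education, behaviour change and healthy food environments",
        "Economic impact",
    }
)


class Metric(BaseModel):
    """One row of a domain's Metrics column.

    Numeric metrics carry a unit so they can be aggregated; text metrics are
    descriptive only.  A ``not_available`` metric has no value — the evidence
    field explains the gap.
    """

    name: str
    value: Optional[Union[float, int, str]] = None
    unit: Optional[str] = None
    evidence: Optional[str] = None
    status: Literal["measured", "estimated", "not_available"] = "measured"

    @model_validator(mode="after")
    def _typed(self) -> "Metric":
        if self.status == "not_available" and self.value is not None:
            raise ValueError("a not_available metric must not carry a value")
        if isinstance(self.value, (int, float)) and not isinstance(self.value, bool):
            if not self.unit:
                raise ValueError(f"numeric metric {self.name!r} requires a unit")
        return self

    @property
    def numeric(self) -> bool:
        return isinstance(self.value, (int, float)) and not isinstance(
            self.value, bool
        )


class Domain(BaseModel):
    """A domain of benefit with its metrics and output/outcome statements."""

    name: str
    metrics: list[Metric] = Field(default_factory=list)
    outputs: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _content(self) -> "Domain":
        if not self.name.strip():
            raise ValueError("domain name must be non-empty")
        if not self.metrics and not self.outputs:
            raise ValueError(f"domain {self.name!r} has neither metrics nor outputs")
        return self


class SroiBlock(BaseModel):
    """SROI section: cost ledger plus per-scenario results."""

    ledger: CostLedger
    results: list[SroiResult] = Field(default_factory=list)


class Scorecard(BaseModel):
    """The full scorecard: domains, SROI block (or gap note), narrative."""

    project_name: str
    domains: list[Domain]
    sroi_block: Optional[SroiBlock] = None
    data_gap_note: Optional[str] = None
    narrative: Optional[CaseNarrative] = None

    @model_validator(mode="after")
    def _consistent(self) -> "Scorecard":
        names = [d.name for d in self.domains]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate domain names: {sorted(dupes)}")
        if self.sroi_block is None and not (self.data_gap_note or "").strip():
            raise ValueError(
                "a scorecard without an SROI block must carry a data_gap_note "
                "explaining why the return on investment could not be computed"
            )
        unknown = [n for n in names if n not in DEFAULT_DOMAIN_VOCABULARY]
        if unknown:
            warnings.warn(
                f"domain names outside the default vocabulary: {unknown}",
                stacklevel=2,
            )
        return self


def load_scorecard(source: Union[str, Path]) -> Scorecard:
    """Load a scorecard from YAML/JSON text or a path to such a file.

    A :class:`Path` (or a string naming an existing file) is read from disk;
    any other string is parsed directly as YAML (a superset of JSON).
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        payload = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed scorecard config: {exc}") from exc
    if not isinstance(payload, dict):
        raise ValueError("scorecard config must be a mapping at top level")
    return Scorecard.model_validate(payload)


def save_scorecard(scorecard: Scorecard, path: Union[str, Path]) -> None:
    """Write a scorecard back to YAML; round-trips through load_scorecard."""
    payload = scorecard.model_dump(mode="json", exclude_none=True)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def sum_metrics(metrics: list[Metric]) -> tuple[float, str]:
    """Sum numeric metrics sharing one unit; mixed units are an error."""
    numeric = [m for m in metrics if m.numeric]
    if not numeric:
        raise ValueError("no numeric metrics to sum")
    units = {m.unit for m in numeric}
    if len(units) > 1:
        raise ValueError(f"cannot sum across mismatched units: {sorted(units)}")
    return float(sum(m.value for m in numeric)), numeric[0].unit


def aggregate_counts(scorecard: Scorecard) -> dict[str, dict[str, float]]:
    """Per-domain numeric totals keyed by unit, plus an overall ``_total``.

    Only numeric metrics contribute; totals never cross units, so metrics
    counted in, say, papers and datasets stay separate.
    """
    summary: dict[str, dict[str, float]] = {}
    overall: dict[str, float] = {}
    for domain in scorecard.domains:
        per_unit: dict[str, float] = {}
        for metric in domain.metrics:
            if metric.numeric:
                per_unit[metric.unit] = per_unit.get(metric.unit, 0.0) + float(
                    metric.value
                )
                overall[metric.unit] = overall.get(metric.unit, 0.0) + float(
                    metric.value
                )
        if per_unit:
            summary[domain.name] = per_unit
    summary["_total"] = overall
    return summary


# --- rendering -----------------------------------------------------------


def _fmt_value(metric: Metric) -> str:
    if metric.status == "not_available":
        note = metric.evidence or "no data collected"
        return f"not available — {note}"
    v = metric.value
    if metric.numeric:
        v = f"{v:g} {metric.unit}"
    return str(v) if v is not None else ""


def _md_escape(text: str) -> str:
    return text.replace("|", "\\|")


def _render_markdown(scorecard: Scorecard) -> str:
    lines = [f"# Impact scorecard: {scorecard.project_name}", ""]
    lines += ["## Domains of benefit", ""]
    for domain in scorecard.domains:
        lines.append(f"### {domain.name}")
        lines.append("")
        if domain.metrics:
            lines.append("| Metric | Value | Status |")
            lines.append("| --- | --- | --- |")
            for m in domain.metrics:
                lines.append(
                    f"| {_md_escape(m.name)} | {_md_escape(_fmt_value(m))} "
                    f"| {m.status} |"
                )
            lines.append("")
        for output in domain.outputs:
            lines.append(f"- {output}")
        if domain.outputs:
            lines.append("")
    lines += ["## Social return on investment", ""]
    if scorecard.sroi_block is not None:
        block = scorecard.sroi_block
        cur = block.ledger.currency_label
        lines.append(f"- Cost of research (a): {block.ledger.research_cost_a:,.1f} {cur}")
        lines.append(
            f"- Cost of using research outcomes (b): "
            f"{block.ledger.implementation_cost_b:,.1f} {cur}"
        )
        for r in block.results:
            lines.append(
                f"- SROI ({r.scenario_label}): {r.sroi:.2f} "
                f"(c = {r.c:,.1f} {cur})"
            )
        lines.append("")
    else:
        lines.append(f"*{scorecard.data_gap_note}*")
        lines.append("")
    if scorecard.narrative is not None:
        lines += ["## Case study", ""]
        lines.append(render_narrative(scorecard.narrative, "markdown"))
    return "\n".join(lines).rstrip() + "\n"


def _render_html(scorecard: Scorecard) -> str:
    from html import escape

    parts = [f"<h1>Impact scorecard: {escape(scorecard.project_name)}</h1>"]
    parts.append("<h2>Domains of benefit</h2>")
    for domain in scorecard.domains:
        parts.append(f"<h3>{escape(domain.name)}</h3>")
        if domain.metrics:
            rows = "".join(
                f"<tr><td>{escape(m.name)}</td><td>{escape(_fmt_value(m))}</td>"
                f"<td>{m.status}</td></tr>"
                for m in domain.metrics
            )
            parts.append(
                "<table><tr><th>Metric</th><th>Value</th><th>Status</th></tr>"
                f"{rows}</table>"
            )
        if domain.outputs:
            items = "".join(f"<li>{escape(o)}</li>" for o in domain.outputs)
            parts.append(f"<ul>{items}</ul>")
    parts.append("<h2>Social return on investment</h2>")
    if scorecard.sroi_block is not None:
        block = scorecard.sroi_block
        cur = escape(block.ledger.currency_label)
        items = [
            f"<li>Cost of research (a): {block.ledger.research_cost_a:,.1f} {cur}</li>",
            f"<li>Cost of using research outcomes (b): "
            f"{block.ledger.implementation_cost_b:,.1f} {cur}</li>",
        ]
        items += [
            f"<li>SROI ({escape(r.scenario_label)}): {r.sroi:.2f} "
            f"(c = {r.c:,.1f} {cur})</li>"
            for r in block.results
        ]
        parts.append("<ul>" + "".join(items) + "</ul>")
    else:
        parts.append(f"<p><em>{escape(scorecard.data_gap_note)}</em></p>")
    if scorecard.narrative is not None:
        parts.append("<h2>Case study</h2>")
        parts.append(render_narrative(scorecard.narrative, "html"))
    return "\n".join(parts) + "\n"


def render_scorecard(scorecard: Scorecard, format: str = "markdown") -> str:
    """Render the scorecard as Markdown or HTML.

    Pure and deterministic: the same scorecard always yields identical
    bytes.  The three top-level blocks appear in the published table order —
    domains of benefit, social return on investment, case study — and a
    missing SROI block renders as the data-gap note.
    """
    if format == "markdown":
        return _render_markdown(scorecard)
    if format == "html":
        return _render_html(scorecard)
    raise ValueError(f"unsupported format: {format!r}")
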