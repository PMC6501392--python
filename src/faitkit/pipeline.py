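"""End-to-end pipeline: simulate -> summarise -> project -> monetise -> report.

A single YAML configuration drives the whole assessment.  Sections:

``cohort``
    either ``params`` (synthetic-cohort parameters) or ``file`` (a CSV
    cohort table); optional for purely qualitative runs.
``epi`` / ``econ`` / ``costs``
    epidemiological assumptions, valuation parameters and the cost ledger.
``scale_factor``
    optional linear scale-up of the cohort projection to a larger
    population (e.g. national deployment).
``scorecard`` / ``logic_model`` / ``narrative``
    the qualitative content: a path to a scorecard YAML or an inline
    mapping; inline logic model and case narrative.
``seed`` / ``output_dir`` / ``project_name``
    run control.

A data-readiness audit runs before any computation.  When parameters are
missing the run either aborts (default), listing what is missing and what it
blocks, or — with ``allow_partial`` — emits a scorecard whose SROI section
is an explicit data-gap note, mirroring how a published assessment reports
"not possible due to lack of data" rather than silently omitting the block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .cohort import CohortParams, TrialSummary, generate_cohort, read_cohort, summarize_cohort
from .economics import CostLedger, EconParams, SroiResult, run_scenarios
from .projection import EpiParams, EventProjection, dalys_averted, project_events, scale_projection
from .qualitative import CaseNarrative, LogicModel, ReadinessReport, audit_data_readiness, validate_logic_model
from .scorecard import Scorecard, SroiBlock, load_scorecard, render_scorecard

__all__ = ["PipelineError", "ReportBundle", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a run cannot proceed (bad config, failed audit)."""


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run plus the files written."""

    scorecard: Scorecard
    readiness: ReadinessReport
    trial_summary: Optional[TrialSummary] = None
    projection: Optional[EventProjection] = None
    scaled_projection: Optional[EventProjection] = None
    sroi_results: list[SroiResult] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)
    paths: dict[str, Path] = field(default_factory=dict)


def load_config(source: Union[str, Path, dict]) -> dict:
    """Parse a pipeline config from a YAML file, YAML text, or mapping."""
    if isinstance(source, dict):
        return source
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        payload = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise PipelineError(f"unreadable config: {exc}") from exc
    if not isinstance(payload, dict):
        raise PipelineError("pipeline config must be a mapping at top level")
    return payload


def _config_digest(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _resolve_delta(config: dict, seed: Optional[int]) -> tuple[Optional[TrialSummary], Optional[float], Optional[float]]:
    """Obtain (summary, delta_sbp, n_exposed) from the cohort section.

    n_exposed is the number of intervention-arm high-risk individuals — the
    group whose blood pressure the intervention actually changed.
    """
    cohort_cfg = config.get("cohort") or {}
    if "file" in cohort_cfg:
        cohort = read_cohort(cohort_cfg["file"])
    elif "params" in cohort_cfg or cohort_cfg.get("use_defaults"):
        raw = dict(cohort_cfg.get("params") or {})
        if seed is not None:
            raw["seed"] = seed
        cohort = generate_cohort(CohortParams(**raw))
    else:
        return None, None, None
    summary = summarize_cohort(cohort)
    return summary, summary.delta_sbp_highrisk, float(summary.n_highrisk["intervention"])


def run_pipeline(
    source: Union[str, Path, dict],
    *,
    seed: Optional[int] = None,
    allow_partial: bool = False,
    output_dir: Optional[Union[str, Path]] = None,
    format: str = "markdown",
    write: bool = True,
) -> ReportBundle:
    """Run the full assessment and write the report bundle.

    Writes, under the output directory: the rendered scorecard, the
    readiness report, the serialised projection and SROI results (when
    computable), and a run manifest carrying the config digest, seed and
    package version for reproducibility.
    """
    config = load_config(source)
    seed = seed if seed is not None else config.get("seed")
    out_dir = Path(output_dir or config.get("output_dir") or "results/run")

    readiness = audit_data_readiness(config)
    if not readiness.ready and not allow_partial:
        raise PipelineError(
            "data-readiness audit failed; missing: "
            + ", ".join(readiness.missing_fields)
            + " (use allow_partial to emit a data-gap scorecard)"
        )

    summary, delta, n_exposed = _resolve_delta(config, seed)

    projection = scaled = None
    sroi_results: list[SroiResult] = []
    ledger = None
    if readiness.ready and delta is not None:
        epi = EpiParams(**(config.get("epi") or {}))
        econ = EconParams(**(config.get("econ") or {}))
        ledger = CostLedger(**(config.get("costs") or {}))
        projection = dalys_averted(
            project_events(n_exposed, max(delta, 0.0), epi), epi
        )
        scaled = projection
        factor = config.get("scale_factor")
        if factor is not None:
            scaled = scale_projection(projection, float(factor))
        sroi_results = run_scenarios(scaled, econ, ledger)
    elif readiness.ready and delta is None and config.get("costs"):
        ledger = CostLedger(**(config.get("costs") or {}))

    scorecard = _build_scorecard(config, readiness, ledger, sroi_results)

    logic_findings = None
    if config.get("logic_model"):
        logic_findings = validate_logic_model(LogicModel(**config["logic_model"]))

    paths: dict[str, Path] = {}
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        ext = "md" if format == "markdown" else "html"
        paths["scorecard"] = out_dir / f"scorecard.{ext}"
        paths["scorecard"].write_text(render_scorecard(scorecard, format))
        paths["readiness"] = out_dir / "readiness.json"
        paths["readiness"].write_text(readiness.model_dump_json(indent=2))
        if projection is not None:
            paths["projection"] = out_dir / "projection.json"
            paths["projection"].write_text(
                json.dumps(
                    {
                        "cohort": projection.model_dump(),
                        "scaled": scaled.model_dump(),
                    },
                    indent=2,
                )
            )
        if sroi_results:
            paths["sroi"] = out_dir / "sroi.json"
            paths["sroi"].write_text(
                json.dumps([r.model_dump() for r in sroi_results], indent=2)
            )
        if logic_findings is not None:
            paths["logic_model"] = out_dir / "logic_model.json"
            paths["logic_model"].write_text(logic_findings.model_dump_json(indent=2))

    manifest = {
        "config_sha256": _config_digest(config),
        "seed": seed,
        "faitkit_version": __version__,
        "outputs": {k: str(v) for k, v in paths.items()},
        "partial": not readiness.ready,
    }
    if write:
        paths["manifest"] = out_dir / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2))

    return ReportBundle(
        scorecard=scorecard,
        readiness=readiness,
        trial_summary=summary,
        projection=projection,
        scaled_projection=scaled,
        sroi_results=sroi_results,
        manifest=manifest,
        paths=paths,
    )


def _build_scorecard(
    config: dict,
    readiness: ReadinessReport,
    ledger: Optional[CostLedger],
    sroi_results: list[SroiResult],
) -> Scorecard:
    source = config.get("scorecard")
    if source is None:
        base = Scorecard(
            project_name=config.get("project_name", "unnamed project"),
            domains=[],
            data_gap_note="no scorecard content supplied",
        )
    elif isinstance(source, dict):
        base = Scorecard.model_validate(source)
    elif isinstance(source, str) and source.startswith("builtin:"):
        from .datasets import fixture_path

        base = load_scorecard(fixture_path(source.removeprefix("builtin:")))
    else:
        base = load_scorecard(Path(source))

    narrative = base.narrative
    if config.get("narrative"):
        narrative = CaseNarrative(**config["narrative"])

    if sroi_results and ledger is not None:
        return base.model_copy(
            update={
                "sroi_block": SroiBlock(ledger=ledger, results=sroi_results),
                "data_gap_note": None,
                "narrative": narrative,
            }
        )
    if base.sroi_block is not None:
        return base.model_copy(update={"narrative": narrative})
    note = base.data_gap_note
    if not readiness.ready:
        note = (
            "Social return on investment not possible due to lack of data. "
            "Missing: " + ", ".join(readiness.missing_fields) + ". "
            + " ".join(
                f"[{k}] {v}" for k, v in sorted(readiness.suggested_approach.items())
            )
        )
    return base.model_copy(update={"data_gap_note": note, "narrative": narrative})
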