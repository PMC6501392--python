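#!/usr/bin/env python
"""Project CVD events, deaths and DALYs averted from the trial BP effect.

Applies the log-linear relative-risk model (0.80 per 10 mmHg) to the
intervention-arm high-risk group of a default synthetic cohort, using the
demonstration epidemiological parameters (illustrative baseline 5-year
event risk 0.19 and case fatality 0.30 — the published assessment took
these from literature sources without printing their values).  Also shows
the linear national scale-up mechanism.  Writes results/projection_demo.json.
"""

import json
from pathlib import Path

from faitkit import (
    CohortParams,
    EpiParams,
    dalys_averted,
    generate_cohort,
    project_events,
    scale_projection,
    summarize_cohort,
)

OUT = Path("results")
OUT.mkdir(exist_ok=True)

summary = summarize_cohort(generate_cohort(CohortParams(seed=20190506)))
epi = EpiParams(baseline_event_risk=0.19, case_fatality=0.30)

n_exposed = summary.n_highrisk["intervention"]
proj = dalys_averted(
    project_events(n_exposed, max(summary.delta_sbp_highrisk, 0.0), epi), epi
)
# Published national-to-trial ratio of events averted (73,000 / 59), used
# here purely to illustrate linear scale-up.
national = scale_projection(proj, 73_000.0 / 59.0)

print(f"Cohort: {n_exposed} intervention-arm high-risk individuals, "
      f"arm contrast {summary.delta_sbp_highrisk:.2f} mmHg")
print(f"Relative risk applied: {proj.rr_applied:.4f}")
print(f"Events averted over {epi.horizon:.0f} years: {proj.events_averted:.1f} "
      f"({proj.deaths_averted:.1f} deaths)")
print(f"DALYs averted: {proj.dalys_averted:.1f} "
      f"(YLL {proj.yll_averted:.1f} + YLD {proj.yld_averted:.1f})")
print(f"National scale-up (x{73_000.0/59.0:.1f}): "
      f"{national.events_averted:,.0f} events, {national.dalys_averted:,.0f} DALYs")

(OUT / "projection_demo.json").write_text(
    json.dumps({"cohort": proj.model_dump(), "national": national.model_dump()}, indent=2)
)
print(f"\nWrote {OUT/'projection_demo.json'}.")
print(
    "Finding: a ~13 mmHg sustained SBP reduction in ~1,200 high-risk people "
    "averts on the order of 60 CVD events over five years under the "
    "illustrative baseline risk; scale-up is exactly linear by construction."
)
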