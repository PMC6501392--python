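# faitkit

Mixed-methods assessment of the impact of translational health research,
as a tested, reproducible pipeline. The package is for research teams and
funders who want to apply a framework-style impact assessment —
particularly in low- and middle-income settings where the economic leg of
such assessments most often fails for lack of data — and for
methodologists who want the economic model itself to be inspectable code
rather than a spreadsheet.

It combines the three approaches such frameworks integrate:

1. **Domains-of-benefit scorecard** (Payback-style): typed metrics and
   outputs per benefit domain, validated, aggregated by unit and rendered
   to Markdown/HTML.
2. **Health-economic assessment**: a cohort model from blood-pressure
   effect to CVD events, DALYs and a social return on investment,

   * RR(Δ) = 0.80^(Δ/10) per Δ mmHg systolic BP reduction,
   * events averted = n · r₀ · (1 − RR(Δ)) over a 5-year horizon,
   * DALYs averted = YLL + YLD with disability weights 1.0 (death) and
     0.39 (survived CVD),
   * SROI = c / (a + b), with conservative/base scenarios valuing each
     healthy life year at 6 or 12 months of per-capita GNI,
3. **Qualitative components**: programme logic model and five-section case
   narrative, plus a **data-readiness audit** that reports, before any
   computation, which missing parameters block which outputs.

A seeded synthetic two-arm screening cohort generator (target cohort
12,088; 91% screened; 22% high-risk; 80% vs 16% medication coverage;
13 mmHg between-arm SBP contrast) stands in for individual-level trial
data so the full chain runs at desk scale. See `docs/methods.md` for the
model details and design choices.

## Worked example

```python
from faitkit import (CohortParams, EpiParams, EconParams, CostLedger,
                     generate_cohort, summarize_cohort, project_events,
                     dalys_averted, run_scenarios)

summary = summarize_cohort(generate_cohort(CohortParams(seed=20190506)))
print(round(summary.delta_sbp_highrisk, 2))   # 12.43 mmHg arm contrast

epi = EpiParams(baseline_event_risk=0.19, case_fatality=0.30)
proj = dalys_averted(project_events(summary.n_highrisk["intervention"],
                                    summary.delta_sbp_highrisk, epi), epi)
print(round(proj.events_averted, 1))          # 56.8 events averted / 5 y
print(round(proj.dalys_averted, 1))           # 325.6 DALYs averted

econ = EconParams(gni_per_capita=3500.0, hosp_cost_per_event=4560.0)
ledger = CostLedger(research_cost_a=1e6, implementation_cost_b=328.3e6)
for r in run_scenarios(proj, econ, ledger):
    print(r.scenario_label, round(r.sroi, 4))
# conservative 0.0042
# base 0.006
```

One village-level trial cohort alone does not repay a national deployment
budget; scaled linearly to national reach (`scale_projection`) the same
configuration gives SROI 5.26 / 7.40 — with *illustrative* epidemiological
and valuation parameters (the literature values behind the original
assessment are not published), so these magnitudes demonstrate mechanics,
not reproduced results. Feeding the published benefit components
themselves through the engine gives the scenario pair 2.18 / 2.76
(`analysis/03_sroi_scenarios.py`).

The `analysis/` scripts run the assessment as a narrative sequence
(simulate → project → monetise → render → audit), writing tables under
`results/`; `analysis/04_render_scorecards.py` produces a complete
scorecard for the quantitative case and a data-gap scorecard for the
partial-data case. The same steps are available as CLI subcommands:

```sh
faitkit simulate --seed 1 --out cohort.csv
faitkit report --config src/faitkit/data/smarthealth_config.yaml --out results/run
faitkit report --config src/faitkit/data/pacific_salt_config.yaml --allow-partial --out results/partial
faitkit audit  --config src/faitkit/data/pacific_salt_config.yaml
```

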