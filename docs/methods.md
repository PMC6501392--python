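# Methods

`faitkit` implements a mixed-methods research-impact assessment for
translational health research: a Payback-style domains-of-benefit
scorecard, a cohort health-economic model that converts a trial
blood-pressure effect into CVD events, DALYs and a social return on
investment (SROI), and the qualitative components (programme logic model,
case narrative) with a data-readiness audit. A synthetic cohort generator
stands in for individual-level trial data so the whole chain runs and is
tested at desk scale.

## Synthetic cohort model

Each of `n_target` people is assigned independently:

* arm ~ Bernoulli(`allocation_fraction`, default 0.5);
* screened ~ Bernoulli(`p_screen`, default 0.91);
* high-risk | screened ~ Bernoulli(`p_highrisk`, default 0.22);
* treated | high-risk ~ Bernoulli(`p_treated_arm`; defaults 0.80
  intervention, 0.16 control);
* SBP ~ Normal(`sbp_mean_control` = 140 mmHg, `sbp_sd` = 15 mmHg), with a
  medication effect subtracted for treated high-risk individuals in
  **both** arms;
* age ~ Normal(59, 8) truncated below at 18 years.

Defaults are calibrated to the reported trial summary: a target cohort of
12,088 gives ≈11,000 screened at 91% coverage (only the 11,000 and the 91%
are reported, so `n_target` is back-solved), 22% of the screened are
high-risk, and treatment coverage is 80% vs 16%.

**Treatment-effect parameterisation.** What a trial report prints — and
what the projection consumes — is the *between-arm* difference in mean SBP
among high-risk individuals (13 mmHg here). `treatment_effect_sbp`
therefore parameterises that expected contrast directly. Since the contrast
is generated by differential medication coverage, the generator derives the
per-treated-person effect as
`treatment_effect_sbp / (p_treated_intervention − p_treated_control)`
(≈20.3 mmHg at the defaults, a plausible medication response in
uncontrolled hypertension) and applies it to every treated high-risk
person regardless of arm. The summariser then recovers
`treatment_effect_sbp` in expectation, which the parameter-recovery suite
checks. Configurations with a positive effect but no coverage gap are
rejected as unidentifiable.

Choices where no value is reported: the SBP distribution family (symmetric
normal, sd 15 mmHg — a conventional adult SBP spread, exposed as a
parameter), the SBP location (140 mmHg; only the contrast matters
downstream), and the age spread (sd 8, truncated at adulthood; only the
mean of 59 is reported). The underlying trial was village-randomised;
clustering is ignored (individual Bernoulli allocation) because the impact
model consumes only arm means and no cluster structure is reported.
Follow-up-visit dynamics and lifestyle outcomes are out of scope. Seeds are
mandatory and all randomness flows through one `numpy` generator per call —
no global RNG state.

What the generator does *not* emulate about real screening data: cluster
correlation, informative screening (risk correlated with SBP and age),
measurement error in BP, and loss to follow-up. Tests passing on these
cohorts show the pipeline arithmetic and calibration are right, not that
the model would fit a real trial's covariance structure.

## Event and DALY projection

Risk scaling is log-linear in SBP reduction: `RR(d) = rr_per_10^(d/10)`
with `rr_per_10 = 0.80`, so increments compose multiplicatively and
13 mmHg gives RR ≈ 0.748. Negative reductions are rejected rather than
extrapolated: the model has nothing to say about a harmful intervention.

Events are closed-form cohort expectations: `events_control = n ×
baseline_event_risk`, with `baseline_event_risk` read as the cumulative
event probability over the whole horizon (default 5 years, no annual
compounding — the simplest reading of a fixed-horizon projection; a
per-year risk model would change magnitudes but not structure).
`events_intervention` multiplies by RR; averted deaths apply the
case-fatality fraction. `baseline_event_risk` and `case_fatality` have no
defaults — they are setting-specific literature parameters the user must
supply, and the readiness audit treats them as such.

DALYs averted = YLL + YLD (exact conservation, tested):

* YLL = deaths averted × dead-state weight (1.0) × (life expectancy −
  mean age) = 10 years per death at the defaults (69 − 59);
* YLD = non-fatal events averted × disability weight 0.39 (a Global Burden
  of Disease weighted average over myocardial infarction and
  moderate-to-severe stroke) × `nonfatal_duration`, which defaults to the
  same 10-year window as the YLL term — the disability is taken as
  persisting over the years the event would otherwise have cost.

An optional annual discount rate (default 0, matching the published
assessment) shrinks both year streams via a continuous annuity factor.
A closed-form/microsimulation equivalence test checks the expectations
against per-person Bernoulli simulation on a grid of (ΔSBP, baseline risk,
case fatality); the grid oracle draws per-replicate event counts as
binomials, which is distributionally identical to summing the Bernoullis.

Scale-up to a larger population is strictly linear (`scale_projection`);
no age-structure or heterogeneity adjustment is attempted because mean age
and life expectancy are the only demographic inputs the model has.

## Economics and SROI

Three benefit streams, all linear:

* health-system savings = events averted × hospitalisations/event
  (default 1) × unit hospitalisation cost;
* productivity = DALYs averted × fraction of a year's GNI per capita
  (the scenario lever: 0.5 conservative, 1.0 base case — i.e. 6 vs 12
  months of income per healthy life year gained);
* indirect benefits = DALYs averted × 0.5 × GNI per capita.

With default fractions the indirect stream equals the conservative
productivity stream for identical inputs, an internal-consistency identity
the tests assert. SROI = c / (a + b) with a the research cost, b the
deployment cost and c the benefit total; it is homogeneous of degree zero
in a common rescaling and monotone in each argument. Currencies are opaque
labels — the source assessments mix AUD, USD and Rupiah without
converting, so the package refuses to convert too and merely carries the
label. Monetary flows are undiscounted by default.

Feeding the published component values (333, 192.4/384.8, 192.4 million
over a + b = 329.3 million) through the engine yields 2.18/2.76; the
published 2.19/2.77 was evidently computed from unrounded components, a
±0.01–0.02 rounding residual that is documented rather than reconciled.
The component totals behind those figures (the national DALY volume, the
GNI value, the unit hospitalisation cost) are not printed in the source
and enter this package only as user parameters; the shipped demo
configuration uses illustrative order-of-magnitude stand-ins
(baseline 5-year risk 0.19, case fatality 0.30, GNI 3,500, unit cost
4,560) and its outputs are labelled as such.

## Scorecard and qualitative components

The scorecard is one integrated artefact: domains of benefit (typed
metrics with units plus free-text outputs), an SROI block, and a case
narrative, rendered deterministically to Markdown or HTML in that order.
Domain names come from an advisory controlled vocabulary (knowledge,
capacity-building, policy/practice/health services/population health,
engagement, health-systems strengthening, economic impact); unknown names
load with a warning because domains are meant to be adapted per project.
Metrics are typed: only numeric metrics aggregate, and only within a unit
(papers never add to datasets). A metric whose data were never collected
is `not_available` and must carry an explanation instead of a value; a
scorecard without an SROI block must carry a data-gap note.

The programme logic model is a flat five-section schema (need, activities,
outputs, end-users, anticipated impact) with optional free-form
`(from, to)` links; validation reports empty sections and dangling links
as findings rather than exceptions. The case narrative is five fixed
sub-headings (need, research response, outcome, impact, lessons), all
required.

The readiness audit declares the parameter→output dependency graph
statically:

| missing parameter | blocks |
| --- | --- |
| `epi.baseline_event_risk` | everything quantitative |
| `epi.case_fatality` | deaths, DALYs, GNI-valued streams, c, SROI |
| `econ.hosp_cost_per_event` | health-system savings, c, SROI |
| `econ.gni_per_capita` | productivity, indirect, c, SROI |
| `costs.research_cost_a` / `costs.implementation_cost_b` | SROI |

Parameters with scientific defaults (relative risk, disability weights,
ages, fractions) are never "missing". The audit is monotone by
construction: supplying a value can only shrink the report. A failed audit
aborts a pipeline run unless `allow_partial` is set, in which case the
scorecard's SROI section becomes an explicit data-gap note listing the
missing parameters and a suggested collection approach for each — the
partial-data failure mode rendered honestly instead of silently.

## Pipeline, determinism, problem sizes

`run_pipeline` wires the stages behind one YAML config and writes the
scorecard, readiness report, serialised projection/SROI results and a run
manifest (config SHA-256, seed, package version). Given a config and seed
the entire bundle is reproducible; the manifest makes that checkable.

Test and script problem sizes are chosen to estimate every stochastic
quantity to well under its tolerance: 20 seeded cohorts of 12,088 for
summary recovery (Monte-Carlo SE of the arm contrast ≈ 0.14 mmHg),
100,000 people for the convergence check, and a 10⁴-replicate × 10⁴-person
grid for the microsimulation equivalence. The full suite runs in a few
seconds.

## Known limitations

* Independent Bernoulli statuses: no risk–SBP correlation, no clustering,
  no survey weights; inference on the synthetic cohorts is not
  design-based.
* Single-compartment event model: no recurrence, competing risks or
  multi-state progression; cumulative-risk reading of the horizon.
* Benefit streams are linear in DALYs and events; no cost-effectiveness
  league tables, CEACs or probabilistic sensitivity analysis (a ratio and
  two named scenarios are the scope).
* The published assessment's exact DALY volume and valuation inputs are
  unrecoverable, so its absolute benefit magnitudes cannot be
  re-derived — only their internal arithmetic is checkable.
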