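# Demonstration pipeline configuration for the SMARThealth-style assessment.
#
# The cohort section uses the package's trial-calibrated defaults.  The
# literature parameters below (baseline 5-year event risk among high-risk
# individuals, case fatality, unit hospitalisation cost, GNI per capita) are
# ILLUSTRATIVE: the published assessment drew them from literature sources
# whose numeric values it does not print, so these are order-of-magnitude
# stand-ins chosen for the worked example, not reproduced inputs.
# scale_factor is the published national-to-trial ratio of events averted
# (73,000 / 59), used to illustrate linear national scale-up.
project_name: "SMARThealth, Malang district, East Java, Indonesia"
seed: 20190506
output_dir: results/smarthealth
cohort:
  params: {}            # package defaults: n_target 12,088; p_screen 0.91; ...
epi:
  baseline_event_risk: 0.19
  case_fatality: 0.30
  # rr_per_10 0.80, dw_nonfatal 0.39, dw_fatal 1.0, mean_age 59,
  # life_expectancy 69, horizon 5 all default
econ:
  gni_per_capita: 3500.0
  hosp_cost_per_event: 4560.0
costs:
  research_cost_a: 1.0e6
  implementation_cost_b: 328.3e6
  currency_label: USD
  horizon: 5
scale_factor: 1237.3
scorecard: builtin:smarthealth_scorecard
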