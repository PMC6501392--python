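# Demonstration pipeline configuration for the Pacific Salt assessment —
# the partial-data case.  Costs are known (research a = AUD 1.2M;
# implementation b = AUD 177,000, the in-project campaign cost), but the
# epidemiological and valuation parameters the SROI chain needs were never
# collected, so the readiness audit fails and a run with allow_partial
# emits the data-gap scorecard instead.
project_name: "Pacific Salt reduction programme, Fiji and Samoa"
seed: 20190506
output_dir: results/pacific_salt
costs:
  research_cost_a: 1.2e6
  implementation_cost_b: 177000.0
  currency_label: AUD
  horizon: 5
scorecard: builtin:pacific_salt_scorecard
logic_model:
  need: High population salt intake driving hypertension and CVD in Fiji and Samoa
  activities:
    - Baseline surveys of population salt consumption
    - Consumer-awareness campaign on the health risks of salt
    - Engagement with food manufacturers to reduce salt in processed foods
    - Support to government on labelling and salt targets
  outputs:
    - First national baseline datasets on salt intake
    - Educational materials and trained health workforce
    - Evaluated national salt-reduction campaign model
  end_users:
    - Ministries of Health in Fiji and Samoa
    - Food industry stakeholders
    - Regional and global health agencies
  anticipated_impact:
    - Reduced population salt intake and blood pressure
    - Policy and regulatory change on salt content
  links:
    - [Baseline surveys of population salt consumption,
       First national baseline datasets on salt intake]
    - [First national baseline datasets on salt intake,
       Ministries of Health in Fiji and Samoa]
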