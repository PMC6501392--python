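# Canonical example: impact scorecard for a digital-health CVD screening
# trial in Malang district, East Java, Indonesia (community health workers
# screening with a clinical decision support system).  The SROI block
# transcribes the published figures; the pipeline recomputes and replaces it
# when run with a full quantitative configuration.
project_name: "SMARThealth, Malang district, East Java, Indonesia"
domains:
  - name: Advance knowledge
    metrics:
      - {name: Peer-reviewed publications under review, value: 2, unit: papers}
      - {name: New clinical decision support algorithms, value: 1, unit: tools,
         evidence: CVD screening and treatment algorithm calibrated to the Indonesian burden of disease}
    outputs:
      - Plain-language reports written and discussed with the district health
        authority and the national health insurance agency
  - name: Capacity-building and networking
    metrics:
      - {name: University partner staff co-authoring papers, value: 5, unit: staff}
      - {name: Partner staff and officials co-applying on follow-up grants, value: 5, unit: staff}
    outputs:
      - New research networks between the trial team, a partner university
        and the district health office
  - name: Health systems strengthening
    metrics:
      - {name: Increase in medication stock at participating facilities, value: 50, unit: percent}
      - {name: Lay health workers (kaders) trained, value: 42, unit: staff}
      - {name: Nurses trained, value: 14, unit: staff}
      - {name: Doctors trained, value: 5, unit: staff}
    outputs:
      - Medicines procured through the local drug procurement system
      - A new electronic record created for every patient screened, shared
        between kaders and doctors where previously none existed
  - name: Health outcomes
    metrics:
      - {name: People screened, value: 11000, unit: persons,
         evidence: 91 percent of the target cohort}
      - {name: Screened found at high risk of a CVD event, value: 22, unit: percent,
         evidence: all referred to a primary healthcare facility}
      - {name: Referred individuals followed up at least once, value: 91, unit: percent}
      - {name: High-risk patients on appropriate medication (intervention), value: 80, unit: percent,
         evidence: versus 16 percent in the control population}
      - {name: Between-arm difference in mean systolic blood pressure, value: 13, unit: mmHg,
         evidence: among high-risk individuals, intervention vs control villages}
    outputs:
      - Modelling suggests 59 fewer CVD events in the intervention villages
        than control over 5 years; expanded nationally, 73,000 CVD events
        could be averted over 5 years
  - name: Economic impact
    metrics:
      - {name: Follow-up grants secured, value: 2, unit: grants,
         evidence: approximately US$ 70,000 and US$ 700,000}
    outputs:
      - Research team wages contributed to the local economy (6 staff
        employed for 12 months)
sroi_block:
  ledger:
    research_cost_a: 1.0e6
    implementation_cost_b: 328.3e6
    currency_label: USD
    horizon: 5
  results:
    - {sroi: 2.19, a: 1.0e6, b: 328.3e6, c: 717.8e6, scenario_label: conservative}
    - {sroi: 2.77, a: 1.0e6, b: 328.3e6, c: 910.2e6, scenario_label: base}
narrative:
  need: >-
    CVDs are the leading cause of death globally. In Indonesia at least
    two-thirds of people with, or at high risk of, CVD receive no
    appropriate treatment, and there are hundreds of thousands of coronary
    heart disease deaths annually.
  research_response: >-
    A primary-care digital health intervention was delivered in four
    villages over 12 months. Lay health workers (kaders) screened adults in
    their communities using a tablet-based clinical decision support
    system, referred high-risk individuals to doctors equipped with a
    physician-facing system, and followed patients up at home.
  outcome: >-
    The project delivered the first comprehensive assessment of CVD burden
    and access to care in rural Indonesia; a high proportion of the target
    population was screened, high-risk cases were referred and most were
    followed up, and health-system support improved medicine supply and
    workforce skills.
  impact: >-
    Use of recommended medications among high-risk people was far higher in
    intervention villages, producing significant blood-pressure reductions.
    Care delivered directly to households was a key success factor and the
    kaders' standing in their communities improved.
  lessons: >-
    A detailed health-systems assessment was critical context: it
    identified support needs in staff training, medicine supply and
    information systems that underpin sustainability.
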