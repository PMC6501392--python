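# Canonical example: impact scorecard for a population salt-reduction
# programme in Fiji and Samoa.  The economic-benefit chain could not be
# completed — the data needed to model it were not collected during the
# project — so the SROI section is a data-gap note, the failure mode the
# readiness audit exists to catch prospectively.
project_name: "Pacific Salt reduction programme, Fiji and Samoa"
domains:
  - name: Advance knowledge
    metrics:
      - {name: Papers resulting directly from the research programme, value: 7, unit: papers,
         evidence: 1 protocol, 2 baseline, 2 impact, 2 process evaluation}
      - {name: Papers linked to the project, value: 7, unit: papers,
         evidence: 2 systematic reviews, 1 methods paper, 4 cross-cutting collaborations}
      - {name: New national datasets established, value: 2, unit: datasets,
         evidence: baseline population salt levels for two Pacific countries with no previous data}
    outputs:
      - Presentations at international public-health and food-governance
        conferences and institutional workshops
  - name: Capacity-building
    metrics:
      - {name: PhD qualifications, value: 1, unit: degrees}
      - {name: Masters qualifications, value: 2, unit: degrees}
      - {name: Salt-reduction training sessions for health staff, value: 6, unit: sessions}
      - {name: Research assistants trained in salt-monitoring data collection, value: 4, unit: staff}
      - {name: Samoan staff attending data-analysis training, value: 14, unit: staff}
    outputs:
      - Four authors from Fiji and Samoa on seven academic publications,
        including one led by a Fijian author
      - Three project staff attended implementation-science training
  - name: "Healthy eating: education, behaviour change and healthy food environments"
    metrics:
      - {name: Increase in population understanding of adverse effects of salt (Samoa), value: 9, unit: percent}
      - {name: Reduction in population always/often adding salt to food (Samoa), value: 16, unit: percent}
      - {name: Increase in population using spices instead of salt in cooking (Samoa), value: 28, unit: percent}
      - {name: Population aware of the salt-reduction campaign (both countries), value: 70, unit: percent}
    outputs:
      - One hospital removed salt shakers from its staff dining room and
        reduced the salt content of hospital meals
      - No-salt-shakers-on-tables introduced into a restaurant grading
        scheme, though without compliance data
  - name: Engagement and networking
    metrics:
      - {name: Public-private forums on food policy per year, value: 2, unit: forums}
      - {name: Face-to-face meetings with individual companies per year, value: 10, unit: meetings}
    outputs:
      - Multi-sectoral working groups convened to oversee programme
        implementation in both countries
  - name: Economic impact
    metrics:
      - {name: Reduced health system costs, status: not_available,
         evidence: could be modelled from reduced hypertension burden and associated health-system cost decrease}
      - {name: Additional lifetime income of trained staff, status: not_available,
         evidence: could be modelled from qualification differentials, but local pay-scale data were unavailable}
      - {name: New research financing secured, value: 150000, unit: AUD}
    outputs: []
data_gap_note: >-
  Social return on investment not possible due to lack of data. The change
  in salt consumption was not converted to DALYs saved over the life of the
  cohort; this could be completed by modelling low, medium and high
  reductions in salt intake under the piloted health-promotion activities
  and any legislative change, estimating avoided morbidity over a specified
  period, and costing the avoided health-system use.
narrative:
  need: >-
    A large share of adults in Samoa and Fiji have high blood pressure, and
    excess salt intake is a key contributor. No accurate information on
    salt intake existed in either country and no Pacific country had run a
    successful salt-reduction campaign.
  research_response: >-
    Researchers collected the first baseline surveys of salt consumption in
    each country and designed a multi-pronged campaign to raise consumer
    awareness and engage food manufacturers, including work with government
    on food labelling and mandatory salt targets, with a rigorous
    evaluation throughout.
  outcome: >-
    The project produced new knowledge on salt levels in two Pacific
    countries and showed that some behaviour change is achievable in a
    short timeframe at low cost; the first public-private consultations on
    salt and health were held and extensive training delivered.
  impact: >-
    The health-promotion campaign achieved high penetration, improving
    consumer knowledge and some behaviours; national food and health
    strategy commitments to reduce salt, fat and sugar followed, and
    Pacific-specific guidance on measuring salt intake was produced and
    internationally endorsed.
  lessons: >-
    Three years is too short to demonstrate a reduction in mean population
    salt intake; future campaigns need wider coverage and longer duration,
    and the dominance of processed food means broader change to the food
    environment will require strong government engagement.
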