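# Packaged treatment-gap study: three chained identifications run FIFO.
queue:
  - topic: incident osteoporotic fracture cohort
    observation: {start: 2010-01-01, end: 2014-12-31}
    index:
      template: osteoporotic_fracture
      settings: [outpatient, admission, emergency]
      washout: none
    criteria:
      - {label: age at least 50, action: require_presence, age_minimum: 50}
      - {label: prior malignant neoplasm, action: exclude_if_present, template: malignancy, window: [-365, -1]}
      - {label: prior osteoporotic fracture, action: exclude_if_present, template: osteoporotic_fracture, window: [-365, -1]}
      - {label: prior Paget disease, action: exclude_if_present, template: paget, window: [-365, -1]}
      - {label: prior AOM use, action: exclude_if_present, template: aom, window: [-365, -1]}
  - topic: continued follow-up within 3 months
    source_list: incident osteoporotic fracture cohort
    observation: {start: 2010-01-01, end: 2014-12-31}
    index:
      template: osteoporotic_fracture
      settings: [outpatient, admission, emergency]
      washout: none
    criteria:
      - {label: follow-up visit within 3 months, action: require_presence, encounter: true, window: [1, 90]}
  - topic: AOM initiation within 1 year
    source_list: incident osteoporotic fracture cohort
    observation: {start: 2010-01-01, end: 2014-12-31}
    index:
      template: osteoporotic_fracture
      settings: [outpatient, admission, emergency]
      washout: none
    criteria:
      - {label: AOM dispensing within 1 year, action: require_presence, template: aom, window: [1, 365]}
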