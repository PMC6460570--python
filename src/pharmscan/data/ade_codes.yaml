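# Synthetic example ADE code list: 79 ICD10 codes for possible drug-induced
# diagnoses, regrouped into 12 diagnostic groups by leading pathophysiological
# mechanism and affected organ system.  This file is an editable template --
# real studies substitute their own curated list.  Codes match diagnosis
# records by prefix ("M60.9" matches "M60.9", "M60" would match any M60.*).
# Codes under `requires_confirmation` lack an explicit drug link in their
# ICD10 title and only count as ADEs when the physician_confirmed flag is set.
groups:
  dermatologic:
    - L10.5
    - L23.3
    - L24.4
    - L25.1
    - L27.0
    - L27.1
    - L43.2
    - L51.1
    - L51.2
    - L56.0
    - L64.0
  hepatic:
    - K71.0
    - K71.1
    - K71.2
    - K71.6
    - K71.9
    - K72.0
    - K75.9
  renal:
    - N14.0
    - N14.1
    - N14.2
    - N14.3
    - N17.9
  myopathy:
    - M60.8
    - M60.9
    - M62.8
    - M79.1
    - G72.0
    - G72.8
  hematologic:
    - D52.1
    - D59.0
    - D59.2
    - D61.1
    - D64.2
    - D68.3
    - D69.5
    - D70
  metabolic_endocrine:
    - E03.2
    - E06.4
    - E16.0
    - E23.1
    - E24.2
    - E27.3
    - E66.1
    - E87.6
  neurologic:
    - G21.1
    - G24.0
    - G25.1
    - G25.4
    - G25.6
    - G44.4
    - G62.0
  respiratory:
    - J70.2
    - J70.3
    - J70.4
    - J70.8
  cardiovascular:
    - I42.7
    - I47.2
    - I49.8
    - I95.2
  gastrointestinal:
    - K25.0
    - K25.9
    - K29.6
    - K52.1
    - K85.3
  immune_allergic:
    - T78.2
    - T78.3
    - T78.4
    - T80.5
    - T80.6
    - T88.0
    - T88.2
    - T88.6
    - T88.7
  skeletal:
    - M10.2
    - M80.4
    - M81.4
    - M83.5
    - M87.1
requires_confirmation:
  - M60.8
  - M60.9
  - M62.8
  - M79.1
  - N17.9
  - K25.0
  - K25.9
  - K29.6
  - K52.1
  - K85.3
  - E66.1
  - E87.6
  - I47.2
  - I49.8
  - D68.3
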