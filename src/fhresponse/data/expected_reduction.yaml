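# Default regimen-efficacy configuration.
# Sections: equivalence (statin potency ladder, agent -> dose -> atorvastatin-
# equivalent mg), expected_reduction (equivalent dose -> expected % LDL-C
# reduction, positive magnitudes; the 80 mg + ezetimibe entry is an
# extrapolation), evolocumab (additional expected % reduction of the add-on).
equivalence:
  atorvastatin:
    10.0: 10.0
    20.0: 20.0
    40.0: 40.0
    80.0: 80.0
  pitavastatin:
    2.0: 10.0
    4.0: 20.0
  rosuvastatin:
    5.0: 10.0
    10.0: 20.0
    20.0: 40.0
    40.0: 80.0
  simvastatin:
    20.0: 10.0
    40.0: 20.0
    80.0: 40.0
evolocumab:
  addon: 54.0
expected_reduction:
  extrapolated_ezetimibe_doses:
  - 80.0
  statin_only:
    10.0: 40.0
    20.0: 46.0
    40.0: 52.0
    80.0: 56.0
  with_ezetimibe:
    20.0: 61.0
    40.0: 66.0
    80.0: 70.0
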