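# Paediatric variant: the same ladder shifted one strength category down
# (child step 1 is "very low" dose ICS). Daily-dose banding does not resolve
# a very-low category below LOW, so a LOW band is treated one step up relative
# to the adult tree and MEDIUM and above saturate at step 4. Not enabled by
# default; under-5 LTRA substitution is out of scope.
addon_classes: [LABA, LTRA, THEOPHYLLINE, OTHER_CONTROLLER]
rules:
  - {bands: [NONE], step: 0}
  - {bands: [LOW], max_addons: 0, step: 2}
  - {bands: [LOW], max_addons: 1, step: 3}
  - {bands: [LOW], step: 4}
  - {bands: [MEDIUM, HIGH, UNKNOWN], step: 4}
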