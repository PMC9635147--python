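# Adult BTS/SIGN treatment-step decision tree, expressed as ordered rules over
# (ICS dose band, number of non-ICS controller add-ons). First matching rule wins.
# Totality over the full band x addon-subset space is validated at load time.
#
#   step 0: no ICS component (includes SABA-only and LABA-only regimens)
#   step 1: low-dose ICS alone (the unique step-1 regimen)
#   step 2: low-dose ICS + one add-on controller
#   step 3: medium-dose ICS (<=1 add-on) or low-dose ICS + >=2 add-ons
#   step 4: high or above-range ("unknown") ICS dose, or medium ICS + >=2 add-ons
addon_classes: [LABA, LTRA, THEOPHYLLINE, OTHER_CONTROLLER]
rules:
  - {bands: [NONE], step: 0}
  - {bands: [LOW], max_addons: 0, step: 1}
  - {bands: [LOW], max_addons: 1, step: 2}
  - {bands: [LOW], step: 3}
  - {bands: [MEDIUM], max_addons: 1, step: 3}
  - {bands: [MEDIUM], step: 4}
  - {bands: [HIGH, UNKNOWN], step: 4}
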