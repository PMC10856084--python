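# Factor definitions for the bundled µSPE screening plan.
# x1-x3: solvent volumes (mL); x4: wash-solution composition (%MeOH v/v);
# x5-x9: dispense/loading speeds (µL/s); x10-x11: dummy error-estimation columns.
# Extraction pH (urine basified to pH 11) is a fixed protocol condition, not a factor.
factors:
  - {name: x1, unit: mL, low: 0.2, high: 0.5, role: real}     # conditioning MeOH volume
  - {name: x2, unit: mL, low: 0.2, high: 0.5, role: real}     # equilibration basic-water volume
  - {name: x3, unit: mL, low: 0.2, high: 0.5, role: real}     # washing-solution volume
  - {name: x4, unit: '%MeOH v/v', low: 0.0, high: 10.0, role: real}  # wash composition
  - {name: x5, unit: µL/s, low: 5.0, high: 25.0, role: real}  # sample loading speed
  - {name: x6, unit: µL/s, low: 15.0, high: 55.0, role: real} # conditioning dispense speed
  - {name: x7, unit: µL/s, low: 15.0, high: 55.0, role: real} # equilibration dispense speed
  - {name: x8, unit: µL/s, low: 5.0, high: 25.0, role: real}  # washing dispense speed
  - {name: x9, unit: µL/s, low: 5.0, high: 25.0, role: real}  # elution dispense speed
  - {name: x10, role: dummy}
  - {name: x11, role: dummy}
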