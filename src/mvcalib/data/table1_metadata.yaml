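design: 25 quaternary mixtures, 5 levels per analyte, 17 calibration + 8 validation
units: ug/mL
reconstructed_cells: []
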