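# Acute 100 uM-equivalent H2O2 bolus, 288 cells, 24 h at 20-min sampling
[condition]
mode = "bolus"
dose = 100.0

[run]
n_cells = 288
seed = 11
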