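L0 = 100
L_max = 354
k = 0.3,0.25,0.2,0.15
steps = 4
abundance = 1000
condition_factor = 0.0104
unit = mm
mortality = 0.8,0.8,0.8,0.8
mortality_order = before-growth
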