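# Example forward-simulation configuration: one purine-selection screen at a
# permissive insertion site, roughly the scale of a single experiment.
n_progeny: 200000
event_rate: 3.0e-5
p_co: 0.68
mean_tract_bp: 800
dsb_window: [-3149, 6998]
location_label: sim-6E
seed: 1
selection_recovery: 2
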