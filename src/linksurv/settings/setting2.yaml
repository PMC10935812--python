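# Setting 2 — MAR: lifetime and matching both depend on x
alpha: [4.4, -0.2, 0.0]
shape_p: 6.0
delta: [-1.0, 2.0, 0.0]
missing_link: logit
followup_c: 50.0
score_beta: [8.0, 2.0]
score_depends_on_z: false
unequivocal_threshold: 0.8
error_base: 1.8
floor_at_census: true
n: 1000
seed: 0
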