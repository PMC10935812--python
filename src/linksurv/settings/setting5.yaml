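# Setting 5 — as setting 4, match-score quality lower when z = 1
alpha: [4.5, -0.2, -0.2]
shape_p: 6.0
delta: [-1.0, 1.0, 1.0]
missing_link: logit
followup_c: 50.0
score_beta: [8.0, 2.0]
score_depends_on_z: true
unequivocal_threshold: 0.8
error_base: 1.8
floor_at_census: true
n: 1000
seed: 0
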