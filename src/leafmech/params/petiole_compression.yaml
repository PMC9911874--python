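# Petiole, uniaxial compression (tension-compression asymmetry is carried
# by separate parameter sets, not by a tension switch in the energy).
label: petiole_compression
mu_eq_iso: 4.5772
lambda_eq_iso: 84.3337
mu_neq_iso: 5.7484
lambda_neq_iso: 12.5273
k1_eq_ani: 3.9487
k2_eq_ani: 0.0230
k1_neq_ani: 20.6416
k2_neq_ani: 8.4126
inv_tau_iso: 0.0083
inv_tau_ani: 0.0938
fiber_direction: [1.0, 0.0, 0.0]
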