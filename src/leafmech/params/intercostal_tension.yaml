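# Intercostal area (mesophyll panels between veins), uniaxial tension.
label: intercostal_tension
mu_eq_iso: 1.3677
lambda_eq_iso: 124.7529
mu_neq_iso: 0.8739
lambda_neq_iso: 19.0484
k1_eq_ani: 1.1358
k2_eq_ani: 0.0306
k1_neq_ani: 3.4247
k2_neq_ani: 20.0358
inv_tau_iso: 0.0121
inv_tau_ani: 0.4246
fiber_direction: [1.0, 0.0, 0.0]
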