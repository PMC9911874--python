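# Leaf venation (vein scaffold), uniaxial tension.
label: venation_tension
mu_eq_iso: 3.4486
lambda_eq_iso: 117.8530
mu_neq_iso: 8.6313
lambda_neq_iso: 9.9861
k1_eq_ani: 27.9664
k2_eq_ani: 0.0274
k1_neq_ani: 24.3466
k2_neq_ani: 10.8627
inv_tau_iso: 0.0004
inv_tau_ani: 0.0566
fiber_direction: [1.0, 0.0, 0.0]
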