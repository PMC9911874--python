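# Petiole, uniaxial tension: fitted constants of the transversely
# isotropic viscoelastic model (moduli in MPa, rates in 1/s).
label: petiole_tension
mu_eq_iso: 5.4636
lambda_eq_iso: 76.9086
mu_neq_iso: 17.3150
lambda_neq_iso: 9.4537
k1_eq_ani: 21.3795
k2_eq_ani: 0.0163
k1_neq_ani: 21.0270
k2_neq_ani: 6.7858
inv_tau_iso: 0.0046
inv_tau_ani: 0.0641
fiber_direction: [1.0, 0.0, 0.0]
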