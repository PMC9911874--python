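# leafmech

Transversely isotropic viscoelastic material modelling of plant leaf
tissues at finite strains.

Leaf organs — the petiole (stalk), the venation scaffold, and the
intercostal mesophyll panels between veins — behave like a soft, nearly
incompressible matrix reinforced by one family of stiff fibers, and
respond to loading in a clearly rate-dependent way: stiffer at higher
strain rates, relaxing toward a rate-independent equilibrium during
holds. `leafmech` implements a finite-strain continuum model of that
behavior for material-point simulation of displacement-driven cyclic
tension/compression stress-relaxation tests, plus everything needed to
work with such tests end to end: protocol construction, conversion of
raw force–displacement records to stress/strain, parameter calibration,
and synthetic data generation. It is aimed at plant biomechanics and
constitutive-modelling researchers.

## The model

The free energy is split additively,

    Ψ = Ψ_eq^iso(C) + Ψ_eq^ani(C, M) + Ψ_neq^iso(C_e^iso) + Ψ_neq^ani(C_e^ani, M̃),

an equilibrium spring (compressible Neo-Hookean matrix + exponential
fiber energy in I₄ = tr(CM), with structural tensor M = N⊗N) in parallel
with two Maxwell branches — one isotropic (matrix), one anisotropic
(fibers). Each branch uses a multiplicative split F = F_e F_i; the
inelastic tensors C_i evolve as Ċ_i = f/τ with driving forces derived
from quadratic relaxation potentials of the Mandel-type branch stresses,
which makes the internal dissipation non-negative for any state (the
Clausius–Duhem inequality holds by construction). States are advanced
with an SPD-preserving implicit exponential-map update. Uniaxial stress
states are produced by prescribing the axial stretch and solving the
transverse stretch so the lateral stresses vanish.

Ten constants per tissue: μ_eq^iso, Λ_eq^iso, μ_neq^iso, Λ_neq^iso
(MPa), K₁,eq^ani, K₁,neq^ani (MPa), K₂,eq^ani, K₂,neq^ani (–), and
relaxation times τ^iso, τ^ani (s). Four fitted sets ship as fixtures:
`petiole_tension`, `petiole_compression`, `venation_tension`,
`intercostal_tension`. See `docs/methods.md` for the full formulation.

## Worked example

```python
import numpy as np
import leafmech as lm

p = lm.load_parameters("petiole_tension")

# three-cycle protocol: 0.5/1/2 % strain at 10 %/min, 300 s holds
proto = lm.make_standard_protocols()["tension_10"]
hist = lm.uniaxial_response(proto, p)

peak = hist.P11.max()
end_of_first_hold = hist.P11[np.argmin(abs(hist.time - 303.0))]
print(f"peak stress          {peak:.3f} MPa")
print(f"stress after hold 1  {end_of_first_hold:.3f} MPa")
print(f"min dissipation rate {hist.dissipation.min():.2e} MPa/s")

ec = lm.lame_to_engineering(p.mu_eq_iso, p.lambda_eq_iso)
print(f"matrix Young's modulus {ec.E:.3f} MPa, Poisson ratio {ec.nu:.3f}")
```

prints

```
peak stress          3.039 MPa
stress after hold 1  0.528 MPa
min dissipation rate 0.00e+00 MPa/s
matrix Young's modulus 16.028 MPa, Poisson ratio 0.467
```

The peak (3.039 MPa at the top of the 2 % ramp) exceeds the relaxed
value because both Maxwell branches carry over-stress during loading;
after the 300-s hold of the first 0.5 % cycle the stress has decayed
toward its equilibrium plateau (0.528 MPa). The dissipation rate never
goes negative. The Young's modulus and Poisson ratio are the small-strain
engineering constants implied by the fitted matrix Lamé parameters.

A thin CLI wraps the same functionality:

```sh
leafmech simulate --params petiole_tension --protocol tension_10 --out sim.csv
leafmech generate --params venation_tension --protocol tension_10 --noise 0.01 --seed 7 --out data/
leafmech convert --in data/replicate_00.csv --l0-mm 20 --area-mm2 4.91 --out observed.csv
leafmech fit --data data/replicate_00.csv --protocol tension_10 --params venation_tension \
    --l0-mm 20 --area-mm2 4.91 --free mu_neq_iso,k1_neq_ani,tau_iso,tau_ani --out report.json
```

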