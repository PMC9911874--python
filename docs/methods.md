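# Methods

`leafmech` simulates the uniaxial cyclic stress-relaxation behavior of
plant leaf tissues — petiole, venation (vein scaffold), and intercostal
(mesophyll) areas — as a transversely isotropic viscoelastic material at
finite strains, evaluated at a single material point.

## Constitutive model

The tissue is treated as an isotropic, nearly incompressible matrix
reinforced by one family of fibers with reference direction **N**
(structural tensor **M** = **N** ⊗ **N**). The rheology is an equilibrium
spring in parallel with two Maxwell branches: one for the viscous response
of the matrix, one for the fibers. Each branch carries a multiplicative
split **F** = **F**ₑ **F**ᵢ of the deformation gradient; the inelastic
right Cauchy–Green tensors **C**ᵢ^iso and **C**ᵢ^ani are the internal
variables, and the elastic tensors are
**C**ₑ = **F**ᵢ⁻ᵀ **C** **F**ᵢ⁻¹ with **C** = **F**ᵀ**F**.

The Helmholtz free energy splits additively into four parts:

- *matrix, equilibrium and branch*: compressible Neo-Hookean,
  Ψ(C) = μ/2 (tr C − 3 − ln det C) + Λ/4 (det C − 1 − ln det C),
  with (μ_eq^iso, Λ_eq^iso) and (μ_neq^iso, Λ_neq^iso);
- *fiber, equilibrium and branch*: exponential in the fourth invariant
  I₄ = tr(C M),
  Ψ(I₄) = K₁/(2K₂) (exp[K₂ (I₄ − 1)²] − 1),
  with (K₁,eq^ani, K₂,eq^ani) and (K₁,neq^ani, K₂,neq^ani); the branch
  term uses I₄ₑ = tr(C_e^ani M̃) with the structural tensor pushed
  forward to the intermediate configuration,
  M̃ = (F_i M F_iᵀ)/(C_i : M), which is again a unit-trace rank-one
  projector.

The second Piola–Kirchhoff stress follows from the Coleman–Noll
procedure,
S = 2∂Ψ/∂C + Σ_branches 2 F_i⁻¹ (∂Ψ/∂C_e) F_i⁻ᵀ,
assembled from closed-form partial derivatives (finite differences are
retained only as test oracles). Flow of each branch is driven by its
Mandel-type stress (Σ^iso = 2C_e ∂Ψ/∂C_e for the matrix; for the fiber
branch the structural-tensor terms cancel analytically, leaving
Γ^ani = 2 β I₄ₑ M̃ with β = ∂Ψ/∂I₄ₑ, which is symmetric by
construction) through quadratic relaxation potentials:

- g^iso = tr((dev Σ)²)/(2 μ_neq^iso) + tr(Σ)²/(9 κ_neq^iso), with the
  bulk modulus κ_neq^iso = Λ_neq^iso + 2/3 μ_neq^iso;
- g^ani = (tr(Γ sym(C_e M̃)))² / (2 K₁,neq^ani).

The evolution equations are Ċᵢ = f/τ per branch, with
f = 2 F_iᵀ (∂g/∂Σ) F_i and relaxation times τ^iso, τ^ani. Because both
potentials are non-negative quadratic forms, the internal dissipation
D = Σ:dᵢ^iso + Γ:dᵢ^ani = (2/τ^iso) g^iso + (2/τ^ani) g^ani
is non-negative for *any* state — the model satisfies the Clausius–Duhem
inequality by construction. Tests verify this over randomized states and
over every simulated protocol step.

### Design choices in genuinely open places

- **Inelastic rotation.** Only **C**ᵢ enters the energies, so the
  rotational part of **F**ᵢ is irrelevant; we fix **F**ᵢ := **U**ᵢ =
  √**C**ᵢ (symmetric), making **C**ᵢ the sole stored internal variable.
- **Fiber-potential squaring.** g^ani uses the scalar-squared reading
  (tr(·))² rather than tr((·)²); it yields fiber-directional flow and
  non-negative dissipation. The choice is isolated in
  `fiber_flow_direction`/`relaxation_potentials` so the tensorial
  alternative could be swapped in one place.
- **K₂ units.** K₂ multiplies a squared dimensionless invariant inside
  an exponential and is treated as dimensionless. The K₂ → 0 limit of
  the fiber energy is implemented analytically (quadratic energy) to
  avoid 0/0.
- **No tension-only fiber switch.** Tension–compression asymmetry is
  carried by separate fitted parameter sets (the shipped
  `petiole_tension` vs `petiole_compression`), not by a conditional in
  the energy.
- **Zero-modulus branches.** A branch whose governing modulus
  (μ_neq^iso resp. K₁,neq^ani) is zero is treated as elastic: zero
  potential, zero flow, no division by zero.

## Time integration

The branch ODEs are integrated with the SPD-preserving exponential map

C_i,n+1 = U_n exp((Δt/τ) U_n⁻¹ f_{n+1} U_n⁻¹) U_n,  U_n = √C_i,n,

with the driving force at the end of the step found by damped fixed-point
iteration (tolerance 1e-10 on the state-increment norm, ≤ 50 iterations),
and automatic step halving (≤ 10 levels) if the iteration stalls, the
iterate leaves a sanity ball (10× the norms of the step's tensors), or
the exponential overflows. The sign and index placement of the update are
fixed by requiring the Δt → 0 limit to reproduce Ċᵢ = f/τ, which is
verified against a fine-step explicit-Euler oracle. The scheme is first
order: halving Δt halves the state error.

Accuracy scales with Δt/τ_eff. For the matrix branch of the petiole
(τ^iso = 217 s) a 1-s step tracks the fine-step oracle to ~1e-6. The
fiber branch relaxes effectively ~4× faster than τ^ani (the quadratic
potential in Γ compounds the I₄ₑ dependence), so the same absolute step
carries proportionally more truncation error; protocol grids resolve
ramps with ≥ 50 and holds with ≥ 200 steps by default, far below either
relaxation time.

The exponential fiber energy grows double-exponentially in strain; far
outside the calibrated regime (stretch errors of order tens of percent
with K₂ ~ 20) the driving force becomes numerically stiff beyond what
substepping can resolve, and the integrator raises a diagnostic error
rather than returning garbage. All shipped protocols stay 4+ orders of
magnitude below that regime.

## Uniaxial driver

The experiments are displacement-driven: engineering strain
ε = u/l₀, F₁₁ = 1 + ε, P₁₁ = R/A (MPa with N and mm). Protocols are
three load–hold–unload cycles at strain levels 0.5/1/2 % and speeds
1/10/500 % min⁻¹; unload rate equals load rate. Hold durations are a
package default of 300 s per cycle (configurable; results always state
the hold used), which keeps the full three-cycle program at 10 % min⁻¹
under the 30-minute testing cap.

At each step the axial stretch is prescribed and the transverse stretch
λ_t is solved so the lateral second Piola–Kirchhoff stresses vanish
(|S₂₂| < 1e-9 MPa), by a secant iteration warm-started from the previous
step with a bracketing/bisection safeguard. With the fiber along the
loading axis the deformation stays diagonal with λ₂ = λ₃; for oblique
fibers a two-unknown root solve (S₂₂ = S₃₃ = 0) is used. The
straightening pre-load of the experiments is not simulated; conversion
of records offers optional baseline subtraction instead.

## Calibration

Fitting minimizes the unweighted pointwise squared difference between
observed and simulated P₁₁ on the observed time grid (the grid is part
of the problem definition and recorded with the result). The optimizer
is bound-constrained least squares (TRF) in log-parameter space, which
enforces positivity, with seeded multi-start: start 0 is the caller's
initial guess, further starts are log-uniform perturbations within the
bounds. Goodness of fit is reported as NRMSE — RMS error divided by the
range of the observed series.

Identifiability: uniaxial data barely constrain Λ_eq^iso because the
matrix is nearly incompressible (ν ≈ 0.47–0.49); Λ enters the axial
stress only through the Poisson contraction. Rather than pretending
uniqueness, the result flags parameters whose relative curve sensitivity
— RMS of ∂P₁₁/∂ln p over the protocol, divided by the observed stress
range — falls below 0.01: below that, an e-fold parameter change moves
the curve by less than a percent of its range, i.e. under a typical
noise floor. On petiole-tension conditions this flags Λ_eq^iso
(sensitivity ~3e-3) and none of μ_neq^iso, K₁,neq^ani, τ^iso, τ^ani
(~0.02–0.045).

Small-strain engineering constants derive from the Lamé pair:
ν = Λ/(2(Λ + μ)), E = 2μ(1 + ν), κ = Λ + 2μ/3. From the four shipped
fitted sets these give E_eq^iso = 16.028/13.496/10.248/4.088 MPa
(petiole tension/compression, venation, intercostal) and an average
Poisson ratio ν̄ = 0.480. Because the shipped constants are rounded to
four decimals, derived values carry ~±0.001 MPa of propagated rounding.

## Synthetic data

The generator emulates the measurement chain: simulate the protocol with
ground-truth parameters, invert stress/strain to force/displacement at
the configured geometry (default 20 mm clamping length, circular 2.5 mm
diameter cross-section ≈ 4.91 mm²), then apply per-replicate
multiplicative Gaussian force noise (default σ = 1 %) plus an additive
floor (default 1 mN, load-cell resolution). Five replicates per
condition by default, mirroring the five samples per testing speed. The
seed fixes the output exactly.

What the generator does *not* emulate — and hence what passing tests do
not show about real tissue: the observed non-recovery to zero stress
after unloading (attributable to damage or water loss, outside a
viscoelastic model), drying dynamics, turgor change, and between-leaf
biological variance. Pipeline-closure and recovery results are
statements about the model–data loop, not about leaf biology.

## Problem sizes used in shipped checks

Acceptance-level checks run the 10 % min⁻¹ three-cycle protocol on a
grid of 12 steps per ramp and 40 per hold (193 points, 300-s holds);
randomized thermodynamic checks use 10⁴ states across all four parameter
sets; the integrator oracle uses 10⁴ explicit fine steps per second;
rate-independence holds run 20·max(τ) per level. Parameter recovery
frees (μ_neq^iso, K₁,neq^ani, τ^iso, τ^ani, Λ_eq^iso) against the mean
of five 1 %-noise replicates and recovers the four well-identified
parameters within ~1–2 % (10 % asserted), with Λ_eq^iso flagged weakly
identified.

## Known limitations

- Single material point; no finite-element assembly or consistent
  algorithmic tangent.
- First-order accurate state update (by construction of the implicit
  exponential map).
- Viscoelastic only: no damage, plasticity, temperature or moisture
  dependence; the model relaxes to zero stress after unloading by
  design.
- Calibration against a single loading rate need not extrapolate to
  arbitrary rates, and the fitted set need not be unique.
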