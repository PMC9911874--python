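"""Two-branch transversely isotropic viscoelastic constitutive model.

The Helmholtz free energy is split additively into four parts,

    Psi = Psi_eq^iso(C) + Psi_eq^ani(C, M)
        + Psi_neq^iso(C_e^iso) + Psi_neq^ani(C_e^ani, M_tilde),

a compressible Neo-Hookean matrix energy (equilibrium and one Maxwell
branch) plus an exponential fiber energy in the squared fourth invariant
(equilibrium and a second Maxwell branch).  The inelastic right
Cauchy-Green tensors of the two branches are the internal variables; their
thermodynamic driving forces follow from quadratic relaxation potentials
of the Mandel-type branch stresses, which makes the internal dissipation a
non-negative quadratic form for any state — the model satisfies the
Clausius-Duhem inequality by construction.

Units: moduli in MPa, relaxation times in seconds, energies in MPa
(per unit reference volume), dissipation rates in MPa/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .kinematics import (
    I3,
    dev,
    elastic_cg,
    pushforward_structure,
    spd_function,
    spd_inv,
    spd_sqrt,
    structure_tensor,
    sym,
)

__all__ = [
    "MaterialParameters",
    "MaterialState",
    "StressBundle",
    "load_parameters",
    "available_parameter_sets",
    "psi_eq_iso",
    "psi_neq_iso",
    "psi_eq_ani",
    "psi_neq_ani",
    "total_energy",
    "second_pk_stress",
    "mandel_stresses",
    "relaxation_potentials",
    "potential_gradients",
    "driving_forces",
    "dissipation_rate",
    "evaluate",
]

PARAM_NAMES = (
    "mu_eq_iso",
    "lambda_eq_iso",
    "mu_neq_iso",
    "lambda_neq_iso",
    "k1_eq_ani",
    "k2_eq_ani",
    "k1_neq_ani",
    "k2_neq_ani",
    "tau_iso",
    "tau_ani",
)


@dataclass
class MaterialParameters:
    """The ten constitutive constants plus the reference fiber direction.

    ``mu_*``/``lambda_*`` are the Lame-type matrix constants (MPa),
    ``k1_*`` (MPa) and ``k2_*`` (dimensionless) the fiber constants, and
    ``tau_iso``/``tau_ani`` (s) the relaxation times of the matrix and
    fiber Maxwell branches.  ``k2`` values multiply a squared
    dimensionless invariant inside an exponential and are therefore
    treated as dimensionless.
    """

    mu_eq_iso: float
    lambda_eq_iso: float
    mu_neq_iso: float
    lambda_neq_iso: float
    k1_eq_ani: float
    k2_eq_ani: float
    k1_neq_ani: float
    k2_neq_ani: float
    tau_iso: float
    tau_ani: float
    fiber_direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.fiber_direction = np.asarray(self.fiber_direction, dtype=float)
        n = np.linalg.norm(self.fiber_direction)
        if n == 0.0:
            raise ValueError("fiber_direction must be non-zero")
        self.fiber_direction = self.fiber_direction / n
        for name in PARAM_NAMES[:8]:
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_iso", "tau_ani"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.kappa_neq_iso <= 0.0 and self.matrix_branch_active:
            raise ValueError("nonequilibrium bulk modulus must be positive")

    @property
    def kappa_neq_iso(self) -> float:
        """Nonequilibrium bulk modulus kappa = Lambda + 2/3 mu (MPa)."""
        return self.lambda_neq_iso + (2.0 / 3.0) * self.mu_neq_iso

    @property
    def matrix_branch_active(self) -> bool:
        return self.mu_neq_iso > 0.0 or self.lambda_neq_iso > 0.0

    @property
    def fiber_branch_active(self) -> bool:
        return self.k1_neq_ani > 0.0

    @property
    def structure(self) -> np.ndarray:
        return structure_tensor(self.fiber_direction)

    def replace(self, **kw) -> "MaterialParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = {name: float(getattr(self, name)) for name in PARAM_NAMES}
        d["fiber_direction"] = [float(x) for x in self.fiber_direction]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialParameters":
        d = dict(d)
        # parameter files may carry the printed inverse relaxation rates
        if "inv_tau_iso" in d:
            d["tau_iso"] = 1.0 / float(d.pop("inv_tau_iso"))
        if "inv_tau_ani" in d:
            d["tau_ani"] = 1.0 / float(d.pop("inv_tau_ani"))
        d.pop("label", None)
        return cls(**d)


def available_parameter_sets() -> list[str]:
    """Names of the parameter fixtures shipped with the package."""
    root = resources.files("leafmech") / "params"
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir() if p.name.endswith(".yaml"))


def load_parameters(name_or_path: str | Path) -> MaterialParameters:
    """Load a parameter set from a shipped fixture name or a YAML path.

    Shipped fixtures: ``petiole_tension``, ``petiole_compression``,
    ``venation_tension``, ``intercostal_tension``.
    """
    p = Path(name_or_path)
    if p.suffix in {".yaml", ".yml", ".json"} and p.exists():
        text = p.read_text()
    else:
        res = resources.files("leafmech") / "params" / f"{name_or_path}.yaml"
        try:
            text = res.read_text()
        except FileNotFoundError:
            raise FileNotFoundError(
                f"no parameter file {name_or_path!r}; shipped sets: "
                f"{', '.join(available_parameter_sets())}"
            ) from None
    return MaterialParameters.from_dict(yaml.safe_load(text))


@dataclass
class MaterialState:
    """Inelastic right Cauchy-Green tensors of the two Maxwell branches."""

    Ci_iso: np.ndarray = field(default_factory=lambda: I3.copy())
    Ci_ani: np.ndarray = field(default_factory=lambda: I3.copy())

    def copy(self) -> "MaterialState":
        return MaterialState(self.Ci_iso.copy(), self.Ci_ani.copy())

    @classmethod
    def identity(cls) -> "MaterialState":
        return cls()


@dataclass
class StressBundle:
    """Stress measures and dissipation at a single material state."""

    S: np.ndarray                 # second Piola-Kirchhoff stress (MPa)
    Sigma_iso: np.ndarray         # matrix-branch Mandel stress (MPa)
    Gamma_ani: np.ndarray         # fiber-branch Mandel stress (MPa)
    dissipation_rate: float       # internal dissipation (MPa/s)
    energy: float = 0.0           # Helmholtz free energy (MPa)


# -- scalar energy kernels ---------------------------------------------------

def _neo_hooke(C: np.ndarray, mu: float, lam: float) -> float:
    detC = np.linalg.det(C)
    if detC <= 0.0:
        raise ValueError(f"det C = {detC:g} <= 0; energy undefined")
    lndet = np.log(detC)
    return 0.5 * mu * (np.trace(C) - 3.0 - lndet) + 0.25 * lam * (detC - 1.0 - lndet)


def _neo_hooke_stress(C: np.ndarray, mu: float, lam: float) -> np.ndarray:
    """2 d/dC of the Neo-Hookean kernel: mu (I - C^-1) + lam/2 (det C - 1) C^-1."""
    Cinv = spd_inv(C)
    return mu * (I3 - Cinv) + 0.5 * lam * (np.linalg.det(C) - 1.0) * Cinv


def _fiber_energy(I4: float, k1: float, k2: float) -> float:
    e = I4 - 1.0
    if k2 == 0.0:
        return 0.5 * k1 * e * e          # analytic k2 -> 0 limit
    return k1 / (2.0 * k2) * (np.exp(k2 * e * e) - 1.0)


def _fiber_coeff(I4: float, k1: float, k2: float) -> float:
    """dPsi/dI4 of the fiber kernel: k1 (I4-1) exp(k2 (I4-1)^2)."""
    e = I4 - 1.0
    return k1 * e * np.exp(k2 * e * e)


def psi_eq_iso(C: np.ndarray, p: MaterialParameters) -> float:
    """Equilibrium Neo-Hookean matrix energy (MPa)."""
    return _neo_hooke(C, p.mu_eq_iso, p.lambda_eq_iso)


def psi_neq_iso(Ce_iso: np.ndarray, p: MaterialParameters) -> float:
    """Nonequilibrium matrix energy, same kernel with the branch constants."""
    return _neo_hooke(Ce_iso, p.mu_neq_iso, p.lambda_neq_iso)


def psi_eq_ani(C: np.ndarray, M: np.ndarray, p: MaterialParameters) -> float:
    """Equilibrium exponential fiber energy in I4 = tr(C M) (MPa)."""
    return _fiber_energy(float(np.tensordot(C, M)), p.k1_eq_ani, p.k2_eq_ani)


def psi_neq_ani(Ce_ani: np.ndarray, Mt: np.ndarray, p: MaterialParameters) -> float:
    """Nonequilibrium fiber energy in tr(C_e M_tilde) (MPa)."""
    return _fiber_energy(float(np.tensordot(Ce_ani, Mt)), p.k1_neq_ani, p.k2_neq_ani)


def total_energy(C: np.ndarray, state: MaterialState, p: MaterialParameters) -> float:
    """Total Helmholtz free energy at (C, state)."""
    M = p.structure
    psi = psi_eq_iso(C, p) + psi_eq_ani(C, M, p)
    if p.matrix_branch_active:
        psi += psi_neq_iso(elastic_cg(C, state.Ci_iso), p)
    if p.fiber_branch_active:
        Mt = pushforward_structure(state.Ci_ani, M)
        psi += psi_neq_ani(elastic_cg(C, state.Ci_ani), Mt, p)
    return psi


# -- stresses ----------------------------------------------------------------

def second_pk_stress(C: np.ndarray, state: MaterialState, p: MaterialParameters) -> np.ndarray:
    """Second Piola-Kirchhoff stress from the Coleman-Noll relation.

    S = 2 dPsi/dC + sum over branches of
    2 F_i^{-1} (dPsi/dC_e) F_i^{-T}, assembled from closed-form partial
    derivatives of the four energy terms.
    """
    M = p.structure
    S = _neo_hooke_stress(C, p.mu_eq_iso, p.lambda_eq_iso)
    S = S + 2.0 * _fiber_coeff(float(np.tensordot(C, M)), p.k1_eq_ani, p.k2_eq_ani) * M
    if p.matrix_branch_active:
        Ui_inv = spd_function(state.Ci_iso, "invsqrt")
        Ce = sym(Ui_inv @ C @ Ui_inv)
        S = S + sym(Ui_inv @ _neo_hooke_stress(Ce, p.mu_neq_iso, p.lambda_neq_iso) @ Ui_inv)
    if p.fiber_branch_active:
        Ui_inv = spd_function(state.Ci_ani, "invsqrt")
        Ce = sym(Ui_inv @ C @ Ui_inv)
        Mt = pushforward_structure(state.Ci_ani, M)
        beta = _fiber_coeff(float(np.tensordot(Ce, Mt)), p.k1_neq_ani, p.k2_neq_ani)
        S = S + 2.0 * beta * sym(Ui_inv @ Mt @ Ui_inv)
    return S


def mandel_stresses(
    C: np.ndarray, state: MaterialState, p: MaterialParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Mandel-type driving stresses (Sigma_iso, Gamma_ani) of the branches.

    Sigma = 2 C_e dPsi/dC_e for the matrix branch.  For the fiber branch
    the extra structural-tensor terms cancel against the convective ones,
    leaving Gamma = 2 beta I4e M_tilde with
    beta = dPsi/dI4e and I4e = tr(C_e M_tilde); both are returned
    symmetrized (the symmetrization residual of the assembled expressions
    is zero to round-off, asserted in tests).
    """
    Sigma = np.zeros((3, 3))
    Gamma = np.zeros((3, 3))
    if p.matrix_branch_active:
        Ce = elastic_cg(C, state.Ci_iso)
        # 2 C_e dPsi/dC_e = mu (C_e - I) + lam/2 (det C_e - 1) I
        Sigma = p.mu_neq_iso * (Ce - I3) + 0.5 * p.lambda_neq_iso * (
            np.linalg.det(Ce) - 1.0
        ) * I3
    if p.fiber_branch_active:
        Ce = elastic_cg(C, state.Ci_ani)
        Mt = pushforward_structure(state.Ci_ani, p.structure)
        I4e = float(np.tensordot(Ce, Mt))
        beta = _fiber_coeff(I4e, p.k1_neq_ani, p.k2_neq_ani)
        Gamma = 2.0 * beta * I4e * sym(Mt)
    return Sigma, Gamma


def fiber_flow_direction(Ce_ani: np.ndarray, Mt: np.ndarray) -> np.ndarray:
    """Tensor direction sym(C_e M_tilde) of the fiber-branch flow."""
    return sym(Ce_ani @ Mt)


def relaxation_potentials(
    Sigma_iso: np.ndarray,
    Gamma_ani: np.ndarray,
    Ce_ani: np.ndarray,
    Mt: np.ndarray,
    p: MaterialParameters,
) -> tuple[float, float]:
    """Quadratic relaxation potentials (g_iso, g_ani) in MPa.

    g_iso splits into an isochoric part scaled by 1/(2 mu_neq) and a
    volumetric part scaled by 1/(9 kappa_neq); g_ani is the squared fiber
    projection of Gamma scaled by 1/(2 k1_neq).  Branches with zero
    modulus are treated as elastic (zero potential).
    """
    g_iso = 0.0
    if p.matrix_branch_active and p.mu_neq_iso > 0.0:
        d = dev(Sigma_iso)
        g_iso = float(np.tensordot(d, d)) / (2.0 * p.mu_neq_iso)
        g_iso += np.trace(Sigma_iso) ** 2 / (9.0 * p.kappa_neq_iso)
    g_ani = 0.0
    if p.fiber_branch_active:
        proj = float(np.tensordot(Gamma_ani, fiber_flow_direction(Ce_ani, Mt)))
        g_ani = proj * proj / (2.0 * p.k1_neq_ani)
    return g_iso, g_ani


def potential_gradients(
    Sigma_iso: np.ndarray,
    Gamma_ani: np.ndarray,
    Ce_ani: np.ndarray,
    Mt: np.ndarray,
    p: MaterialParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form gradients (dg_iso/dSigma, dg_ani/dGamma)."""
    dg_iso = np.zeros((3, 3))
    if p.matrix_branch_active and p.mu_neq_iso > 0.0:
        dg_iso = dev(Sigma_iso) / p.mu_neq_iso + (
            2.0 * np.trace(Sigma_iso) / (9.0 * p.kappa_neq_iso)
        ) * I3
    dg_ani = np.zeros((3, 3))
    if p.fiber_branch_active:
        A = fiber_flow_direction(Ce_ani, Mt)
        dg_ani = (float(np.tensordot(Gamma_ani, A)) / p.k1_neq_ani) * A
    return dg_iso, dg_ani


def branch_force_iso(C: np.ndarray, Ci_iso: np.ndarray, p: MaterialParameters) -> np.ndarray:
    """Driving force f_iso = 2 F_i^T (dg_iso/dSigma) F_i of the matrix branch."""
    if not (p.matrix_branch_active and p.mu_neq_iso > 0.0):
        return np.zeros((3, 3))
    Ui = spd_sqrt(Ci_iso)
    Ui_inv = spd_function(Ci_iso, "invsqrt")
    Ce = sym(Ui_inv @ C @ Ui_inv)
    Sigma = p.mu_neq_iso * (Ce - I3) + 0.5 * p.lambda_neq_iso * (np.linalg.det(Ce) - 1.0) * I3
    dg = dev(Sigma) / p.mu_neq_iso + (2.0 * np.trace(Sigma) / (9.0 * p.kappa_neq_iso)) * I3
    return 2.0 * sym(Ui @ dg @ Ui)


def branch_force_ani(C: np.ndarray, Ci_ani: np.ndarray, p: MaterialParameters) -> np.ndarray:
    """Driving force f_ani = 2 F_i^T (dg_ani/dGamma) F_i of the fiber branch."""
    if not p.fiber_branch_active:
        return np.zeros((3, 3))
    Ui = spd_sqrt(Ci_ani)
    Ui_inv = spd_function(Ci_ani, "invsqrt")
    Ce = sym(Ui_inv @ C @ Ui_inv)
    Mt = pushforward_structure(Ci_ani, p.structure)
    I4e = float(np.tensordot(Ce, Mt))
    Gamma = 2.0 * _fiber_coeff(I4e, p.k1_neq_ani, p.k2_neq_ani) * I4e * sym(Mt)
    A = fiber_flow_direction(Ce, Mt)
    dg = (float(np.tensordot(Gamma, A)) / p.k1_neq_ani) * A
    return 2.0 * sym(Ui @ dg @ Ui)


def driving_forces(
    C: np.ndarray, state: MaterialState, p: MaterialParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Reference-configuration driving forces (f_iso, f_ani).

    f = 2 F_i^T (dg/dSigma) F_i per branch, entering the evolution
    equations dC_i/dt = f / tau.
    """
    return branch_force_iso(C, state.Ci_iso, p), branch_force_ani(C, state.Ci_ani, p)


def dissipation_rate(
    Sigma_iso: np.ndarray,
    Gamma_ani: np.ndarray,
    g_iso: float,
    g_ani: float,
    p: MaterialParameters,
) -> float:
    """Internal dissipation D = Sigma:d_i^iso + Gamma:d_i^ani (MPa/s).

    By quadratic homogeneity of the potentials this equals
    (2/tau_iso) g_iso + (2/tau_ani) g_ani, which is non-negative for any
    state — the model's thermodynamic-consistency guarantee.
    """
    return 2.0 * g_iso / p.tau_iso + 2.0 * g_ani / p.tau_ani


def evaluate(C: np.ndarray, state: MaterialState, p: MaterialParameters) -> StressBundle:
    """Full constitutive evaluation at (C, state)."""
    S = second_pk_stress(C, state, p)
    Sigma, Gamma = mandel_stresses(C, state, p)
    if p.fiber_branch_active:
        Ce_ani = elastic_cg(C, state.Ci_ani)
        Mt = pushforward_structure(state.Ci_ani, p.structure)
    else:
        Ce_ani, Mt = I3, I3
    g_iso, g_ani = relaxation_potentials(Sigma, Gamma, Ce_ani, Mt, p)
    D = dissipation_rate(Sigma, Gamma, g_iso, g_ani, p)
    return StressBundle(
        S=S,
        Sigma_iso=Sigma,
        Gamma_ani=Gamma,
        dissipation_rate=D,
        energy=total_energy(C, state, p),
    )
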