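"""Parameter identification, the NRMSE metric, and elastic-constant maps.

Fitting minimizes the pointwise squared difference between observed and
simulated axial first Piola-Kirchhoff stress over the free parameters
(bound-constrained least squares in log-parameter space with seeded
multi-start).  The normalized root-mean-square error divides the RMS
residual by the range of the observed series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constitutive import PARAM_NAMES, MaterialParameters
from .integration import IntegratorSettings
from .uniaxial import LoadingProtocol, uniaxial_response

__all__ = [
    "ElasticConstants",
    "StressSeries",
    "CalibrationProblem",
    "CalibrationResult",
    "CalibrationError",
    "nrmse",
    "lame_to_engineering",
    "engineering_to_lame",
    "average_poisson",
    "fit_parameters",
    "curve_sensitivities",
]

#: free parameters whose relative curve sensitivity falls below this
#: fraction of the observed stress range are flagged weakly identified;
#: below 0.01 an e-fold parameter change moves the curve by less than a
#: percent of its range, i.e. under a typical measurement-noise floor
WEAK_SENSITIVITY = 0.01

DEFAULT_BOUNDS = {name: (1e-4, 1e4) for name in PARAM_NAMES}
DEFAULT_BOUNDS["tau_iso"] = (1e-2, 1e6)
DEFAULT_BOUNDS["tau_ani"] = (1e-2, 1e6)


class CalibrationError(RuntimeError):
    """All optimization starts failed."""


def nrmse(sim: np.ndarray, exp: np.ndarray) -> float:
    """Root-mean-square error normalized by the range of the observed series."""
    sim = np.asarray(sim, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if sim.shape != exp.shape or exp.size < 2:
        raise ValueError("series must have equal length >= 2")
    rng = float(exp.max() - exp.min())
    if rng == 0.0:
        raise ValueError("observed series has zero range; NRMSE undefined")
    return float(np.sqrt(np.mean((sim - exp) ** 2)) / rng)


@dataclass
class ElasticConstants:
    """Small-strain engineering constants of the isotropic matrix."""

    E: float       # Young's modulus (MPa)
    nu: float      # Poisson's ratio (-)
    kappa: float   # bulk modulus (MPa)


def lame_to_engineering(mu: float, lam: float) -> ElasticConstants:
    """Engineering constants from the Lame pair (mu, Lambda).

    nu = Lambda / (2 (Lambda + mu)), E = 2 mu (1 + nu),
    kappa = Lambda + 2 mu / 3.
    """
    if mu <= 0.0 or lam < 0.0:
        raise ValueError("need mu > 0 and Lambda >= 0")
    nu = lam / (2.0 * (lam + mu))
    return ElasticConstants(E=2.0 * mu * (1.0 + nu), nu=nu, kappa=lam + 2.0 * mu / 3.0)


def engineering_to_lame(E: float, nu: float) -> tuple[float, float]:
    """Inverse map: (mu, Lambda) from (E, nu)."""
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 - 2.0 * nu) * (1.0 + nu))
    return mu, lam


def average_poisson(param_sets) -> float:
    """Arithmetic mean of the matrix Poisson ratios of several fits."""
    sets = list(param_sets)
    if not sets:
        raise ValueError("need at least one parameter set")
    return float(
        np.mean([lame_to_engineering(p.mu_eq_iso, p.lambda_eq_iso).nu for p in sets])
    )


@dataclass
class StressSeries:
    """Observed axial stress over time, aligned with a protocol."""

    time_s: np.ndarray
    P11_MPa: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.P11_MPa = np.asarray(self.P11_MPa, dtype=float)
        if self.time_s.shape != self.P11_MPa.shape:
            raise ValueError("time and stress must have the same shape")


@dataclass
class CalibrationProblem:
    """Least-squares identification problem for one loading protocol."""

    observed: list[StressSeries]
    protocol: LoadingProtocol
    initial: MaterialParameters
    free: list[str] = field(default_factory=lambda: list(PARAM_NAMES))
    bounds: dict = field(default_factory=dict)
    n_starts: int = 4
    seed: int = 0
    start_spread: float = 0.2
    max_nfev: int | None = None
    integrator: IntegratorSettings = field(default_factory=IntegratorSettings)

    def __post_init__(self) -> None:
        unknown = set(self.free) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        for name in self.free:
            lo, hi = {**DEFAULT_BOUNDS, **self.bounds}[name]
            if not (0.0 < lo < hi < np.inf):
                raise ValueError(f"bounds for {name} must be finite and positive")


@dataclass
class CalibrationResult:
    parameters: MaterialParameters
    objective: float                  # 0.5 * sum of squared residuals (MPa^2)
    nrmse: list[float]                # per observed series
    success: bool
    n_evaluations: int
    weakly_identified: list[str]
    sensitivities: dict
    start_costs: list[float] = field(default_factory=list)
    message: str = ""


def _with(p: MaterialParameters, free: list[str], values: np.ndarray) -> MaterialParameters:
    return p.replace(**{name: float(v) for name, v in zip(free, values)})


def _simulate(p, problem: CalibrationProblem) -> list[np.ndarray]:
    return [
        uniaxial_response(problem.protocol, p, problem.integrator, times=series.time_s).P11
        for series in problem.observed
    ]


def _residual_fn(problem: CalibrationProblem):
    obs = np.concatenate([s.P11_MPa for s in problem.observed])
    counter = {"n": 0}

    def fn(logx):
        counter["n"] += 1
        p = _with(problem.initial, problem.free, np.exp(logx))
        try:
            sim = np.concatenate(_simulate(p, problem))
        except Exception:
            return np.full(obs.size, 1e3)
        return sim - obs

    return fn, obs, counter


def curve_sensitivities(
    p: MaterialParameters, problem: CalibrationProblem, rel_step: float = 0.05
) -> dict:
    """Relative stress-curve sensitivity of each free parameter.

    RMS of the central-difference derivative of the simulated P11 curve
    with respect to ln(parameter), normalized by the range of the
    observed stresses; a small value means the data barely constrain the
    parameter.
    """
    obs = np.concatenate([s.P11_MPa for s in problem.observed])
    scale = float(obs.max() - obs.min()) or 1.0
    out = {}
    for name in problem.free:
        v = getattr(p, name)
        hi = np.concatenate(_simulate(p.replace(**{name: v * (1 + rel_step)}), problem))
        lo = np.concatenate(_simulate(p.replace(**{name: v * (1 - rel_step)}), problem))
        dlnp = np.log((1 + rel_step) / (1 - rel_step))
        dcurve = (hi - lo) / dlnp
        out[name] = float(np.sqrt(np.mean(dcurve**2)) / scale)
    return out


def fit_parameters(problem: CalibrationProblem) -> CalibrationResult:
    """Bound-constrained least squares with seeded log-uniform multi-start.

    Start 0 is the problem's initial guess; further starts are drawn
    log-uniformly within the bounds.  The best converged start wins.  An
    empty free set returns the initial parameters and their NRMSE.
    """
    fn, obs, counter = _residual_fn(problem)
    if not problem.free:
        sims = _simulate(problem.initial, problem)
        return CalibrationResult(
            parameters=problem.initial,
            objective=0.5 * float(sum(np.sum((s - o.P11_MPa) ** 2) for s, o in zip(sims, problem.observed))),
            nrmse=[nrmse(s, o.P11_MPa) for s, o in zip(sims, problem.observed)],
            success=True,
            n_evaluations=len(problem.observed),
            weakly_identified=[],
            sensitivities={},
            message="no free parameters",
        )

    bounds = {**DEFAULT_BOUNDS, **problem.bounds}
    lo = np.log([bounds[n][0] for n in problem.free])
    hi = np.log([bounds[n][1] for n in problem.free])
    x0 = np.log([getattr(problem.initial, n) for n in problem.free])
    x0 = np.clip(x0, lo, hi)

    rng = np.random.default_rng(problem.seed)
    starts = [x0]
    for _ in range(max(0, problem.n_starts - 1)):
        if problem.start_spread > 0.0:
            pert = x0 + rng.uniform(
                np.log1p(-problem.start_spread), np.log1p(problem.start_spread), size=x0.size
            )
            starts.append(np.clip(pert, lo, hi))
        else:
            starts.append(rng.uniform(lo, hi))

    best = None
    start_costs: list[float] = []
    messages: list[str] = []
    for xs in starts:
        try:
            sol = least_squares(
                fn,
                xs,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-10,
                max_nfev=problem.max_nfev,
            )
        except Exception as err:  # pragma: no cover - optimizer hard failure
            messages.append(str(err))
            start_costs.append(np.inf)
            continue
        start_costs.append(float(sol.cost))
        messages.append(sol.message)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise CalibrationError(f"all {len(starts)} starts failed: {messages}")

    fitted = _with(problem.initial, problem.free, np.exp(best.x))
    sims = _simulate(fitted, problem)
    sens = curve_sensitivities(fitted, problem)
    weak = [n for n, v in sens.items() if v < WEAK_SENSITIVITY]
    return CalibrationResult(
        parameters=fitted,
        objective=float(best.cost),
        nrmse=[nrmse(s, o.P11_MPa) for s, o in zip(sims, problem.observed)],
        success=bool(best.success),
        n_evaluations=counter["n"],
        weakly_identified=weak,
        sensitivities=sens,
        start_costs=start_costs,
        message="; ".join(dict.fromkeys(messages)),
    )
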