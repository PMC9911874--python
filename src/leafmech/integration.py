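"""Implicit exponential-map time integration of the internal variables.

The evolution equations ``dC_i/dt = f(C, C_i)/tau`` of both Maxwell
branches are integrated with the exponential mapping algorithm

    C_i,n+1 = U_n exp( (dt/tau) U_n^{-1} f_{n+1} U_n^{-1} ) U_n,

with ``U_n = sqrt(C_i,n)`` and the driving force ``f`` evaluated at the
end of the step by damped fixed-point iteration (fully implicit).  The
update is a congruence of a matrix exponential, so the internal variables
remain symmetric positive definite for any step size, and its small-step
expansion reproduces the continuous evolution exactly to first order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import (
    MaterialParameters,
    MaterialState,
    StressBundle,
    branch_force_ani,
    branch_force_iso,
    evaluate,
)
from .kinematics import spd_exp, spd_function, spd_sqrt, sym

__all__ = ["IntegratorSettings", "IntegrationError", "update_state", "simulate_path", "StressHistory"]


@dataclass
class IntegratorSettings:
    """Tolerances and caps of the local constitutive update.

    ``tolerance`` bounds the Frobenius norm of the state increment between
    fixed-point iterates (relative to ``max(1, |C_i|)``); ``max_iterations``
    caps the iterations per attempt and ``max_substeps`` the number of
    step-halvings tried on non-convergence.
    """

    tolerance: float = 1e-10
    max_iterations: int = 50
    max_substeps: int = 10

    def __post_init__(self) -> None:
        if self.tolerance <= 0.0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1 or self.max_substeps < 0:
            raise ValueError("iteration caps must be >= 1")


class IntegrationError(RuntimeError):
    """Local constitutive update failed to converge."""

    def __init__(self, message: str, *, time: float | None = None, dt: float | None = None):
        super().__init__(message)
        self.time = time
        self.dt = dt


def _exp_update(Ci_old: np.ndarray, f_new: np.ndarray, dt_over_tau: float) -> np.ndarray:
    Un = spd_sqrt(Ci_old)
    Un_inv = spd_function(Ci_old, "invsqrt")
    A = dt_over_tau * sym(Un_inv @ f_new @ Un_inv)
    return sym(Un @ spd_exp(A) @ Un)


def _implicit_branch_step(
    C_new: np.ndarray,
    Ci_old: np.ndarray,
    dt: float,
    tau: float,
    force,
    s: IntegratorSettings,
) -> np.ndarray:
    """One implicit exponential-map step of a single branch.

    ``force(Ci)`` returns the driving force at (C_new, Ci).  Damped
    fixed-point iteration on ``Ci``; recursive step-halving on failure.
    """
    # the exact evolution relaxes C_i toward C, so any sane iterate stays
    # within a modest factor of the step's tensors; beyond that the fixed
    # point is spurious (exponential blow-up) and the step is substepped
    norm_cap = 10.0 * (np.linalg.norm(C_new) + np.linalg.norm(Ci_old) + 1.0)

    def attempt(Ci_old: np.ndarray, dt: float) -> np.ndarray | None:
        Ci = Ci_old
        damping = 1.0
        prev_res = np.inf
        for _ in range(s.max_iterations):
            with np.errstate(over="ignore", invalid="ignore"):
                try:
                    target = _exp_update(Ci_old, force(Ci), dt / tau)
                except (ValueError, np.linalg.LinAlgError):
                    return None
            if not np.all(np.isfinite(target)) or np.linalg.norm(target) > norm_cap:
                return None  # step too stiff; caller substeps
            res = np.linalg.norm(target - Ci)
            if res <= s.tolerance * max(1.0, np.linalg.norm(target)):
                return target
            if res > prev_res:
                damping = max(0.25 * damping, 0.05)
            prev_res = res
            Ci = sym(Ci + damping * (target - Ci))
        return None

    def solve(Ci_old: np.ndarray, dt: float, depth: int) -> np.ndarray:
        out = attempt(Ci_old, dt)
        if out is not None:
            return out
        if depth >= s.max_substeps:
            raise IntegrationError(
                f"local update did not converge after {depth} substep halvings", dt=dt
            )
        mid = solve(Ci_old, 0.5 * dt, depth + 1)
        return solve(mid, 0.5 * dt, depth + 1)

    return solve(Ci_old, dt, 0)


def update_state(
    C_new: np.ndarray,
    state_old: MaterialState,
    dt: float,
    p: MaterialParameters,
    s: IntegratorSettings | None = None,
) -> tuple[MaterialState, StressBundle]:
    """Advance the internal variables over one step and evaluate stresses.

    Returns the updated :class:`MaterialState` and the
    :class:`StressBundle` at ``(C_new, state_new)``.  ``dt = 0`` leaves
    the state unchanged exactly.
    """
    if dt < 0.0:
        raise ValueError("dt must be >= 0")
    s = s or IntegratorSettings()
    if dt == 0.0:
        return state_old.copy(), evaluate(C_new, state_old, p)

    Ci_iso, Ci_ani = state_old.Ci_iso, state_old.Ci_ani
    # the two branches are uncoupled given C: each sees only its own C_i
    if p.matrix_branch_active and p.mu_neq_iso > 0.0:
        Ci_iso = _implicit_branch_step(
            C_new, Ci_iso, dt, p.tau_iso, lambda Ci: branch_force_iso(C_new, Ci, p), s
        )
    if p.fiber_branch_active:
        Ci_ani = _implicit_branch_step(
            C_new, Ci_ani, dt, p.tau_ani, lambda Ci: branch_force_ani(C_new, Ci, p), s
        )
    state_new = MaterialState(Ci_iso, Ci_ani)
    return state_new, evaluate(C_new, state_new, p)


I_ANI = np.eye(3)


@dataclass
class StressHistory:
    """Time series of a material-point simulation.

    Full tensors are kept (``F``, ``S``, ``P`` with shape ``(n, 3, 3)``);
    the scalar views used by the uniaxial protocols (``F11``, ``P11``,
    transverse stretch) are exposed as properties.  Serialized as CSV with
    columns ``time_s, F11, lambda_transverse, P11_MPa, S11_MPa,
    dissipation_MPa_per_s``.
    """

    time: np.ndarray
    F: np.ndarray
    S: np.ndarray
    P: np.ndarray
    dissipation: np.ndarray
    states: list = field(default_factory=list)
    energy: np.ndarray | None = None

    @property
    def F11(self) -> np.ndarray:
        return self.F[:, 0, 0]

    @property
    def S11(self) -> np.ndarray:
        return self.S[:, 0, 0]

    @property
    def P11(self) -> np.ndarray:
        return self.P[:, 0, 0]

    @property
    def lambda_transverse(self) -> np.ndarray:
        return self.F[:, 1, 1]

    @property
    def cumulative_dissipation(self) -> np.ndarray:
        """Trapezoidal time integral of the dissipation rate (MPa)."""
        return np.concatenate(
            [[0.0], np.cumsum(0.5 * (self.dissipation[1:] + self.dissipation[:-1]) * np.diff(self.time))]
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "F11": self.F11,
                "lambda_transverse": self.lambda_transverse,
                "P11_MPa": self.P11,
                "S11_MPa": self.S11,
                "dissipation_MPa_per_s": self.dissipation,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_path(
    F_of_t,
    p: MaterialParameters,
    s: IntegratorSettings | None = None,
    initial_state: MaterialState | None = None,
    keep_states: bool = False,
) -> StressHistory:
    """Step a material point through a prescribed deformation history.

    ``F_of_t`` is a sequence of ``(time, F)`` pairs with strictly
    increasing times.  The state starts from the virgin (identity) state
    unless ``initial_state`` is given.
    """
    s = s or IntegratorSettings()
    times = np.array([float(t) for t, _ in F_of_t])
    if times.size == 0:
        raise ValueError("empty deformation history")
    if np.any(np.diff(times) <= 0.0):
        raise ValueError("times must be strictly increasing")
    Fs = np.array([np.asarray(F, dtype=float) for _, F in F_of_t])

    state = (initial_state or MaterialState.identity()).copy()
    n = times.size
    S = np.empty((n, 3, 3))
    P = np.empty((n, 3, 3))
    D = np.empty(n)
    E = np.empty(n)
    states: list[MaterialState] = []

    bundle = evaluate(Fs[0].T @ Fs[0], state, p)
    S[0], D[0], E[0] = bundle.S, bundle.dissipation_rate, bundle.energy
    P[0] = Fs[0] @ bundle.S
    if keep_states:
        states.append(state.copy())
    for k in range(1, n):
        C = sym(Fs[k].T @ Fs[k])
        dt = times[k] - times[k - 1]
        try:
            state, bundle = update_state(C, state, dt, p, s)
        except IntegrationError as err:
            raise IntegrationError(
                f"integration failed at t = {times[k]:g} s: {err}", time=times[k], dt=dt
            ) from err
        S[k], D[k], E[k] = bundle.S, bundle.dissipation_rate, bundle.energy
        P[k] = Fs[k] @ bundle.S
        if keep_states:
            states.append(state.copy())
    return StressHistory(time=times, F=Fs, S=S, P=P, dissipation=D, states=states, energy=E)
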