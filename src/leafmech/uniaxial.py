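"""Cyclic loading programs and the uniaxial material-point driver.

Builds the displacement-driven cyclic ramp-hold-unload programs used for
the tensile and compression experiments (three cycles at increasing
engineering-strain levels), simulates uniaxial tension/compression at a
material point with traction-free lateral faces, and converts raw
time/displacement/force records to strain/stress via

    F11 = (u + l0)/l0,        P11 = R/A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, root

from .constitutive import MaterialParameters, MaterialState
from .integration import IntegratorSettings, StressHistory, update_state

__all__ = [
    "LoadingProtocol",
    "ProtocolError",
    "DriverError",
    "ExperimentRecord",
    "build_protocol",
    "strain_to_F11",
    "force_to_P11",
    "uniaxial_response",
    "convert_experiment",
]

#: default grid density: minimum steps per ramp and per hold segment
RAMP_STEPS = 50
HOLD_STEPS = 200


class ProtocolError(ValueError):
    """Invalid loading-program configuration."""


class DriverError(RuntimeError):
    """Lateral-stress solve failed during the uniaxial simulation."""


@dataclass
class LoadingProtocol:
    """Piecewise-linear engineering-strain program.

    ``segments`` is an ordered list of ``(level, rate, hold)`` cycles: ramp
    at ``rate`` (strain/s) from zero to ``level`` (absolute engineering
    strain, positive), hold for ``hold`` seconds, unload to zero at
    ``unload_rate``, then optionally hold at zero for ``zero_hold``
    seconds.  ``sign`` is +1 for tension, -1 for compression; the strain
    magnitude program is identical for both.
    """

    segments: list[tuple[float, float, float]]
    unload_rate: float
    sign: int = 1
    zero_hold: float = 0.0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ProtocolError("sign must be +1 (tension) or -1 (compression)")
        if self.unload_rate <= 0.0:
            raise ProtocolError("unload rate must be > 0")
        for level, rate, hold in self.segments:
            if level <= 0.0 or rate <= 0.0 or hold < 0.0:
                raise ProtocolError("levels and rates must be > 0, holds >= 0")

    @property
    def breakpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Knot times and (unsigned) strains of the piecewise-linear program."""
        t, e = [0.0], [0.0]
        for level, rate, hold in self.segments:
            t.append(t[-1] + level / rate)
            e.append(level)
            if hold > 0.0:
                t.append(t[-1] + hold)
                e.append(level)
            t.append(t[-1] + level / self.unload_rate)
            e.append(0.0)
            if self.zero_hold > 0.0:
                t.append(t[-1] + self.zero_hold)
                e.append(0.0)
        return np.asarray(t), np.asarray(e)

    @property
    def duration(self) -> float:
        return float(self.breakpoints[0][-1])

    def strain_at(self, t) -> np.ndarray:
        """Signed engineering strain at arbitrary times (linear interpolation)."""
        bt, be = self.breakpoints
        return self.sign * np.interp(np.asarray(t, dtype=float), bt, be)

    def time_grid(self, ramp_steps: int = RAMP_STEPS, hold_steps: int = HOLD_STEPS) -> np.ndarray:
        """Simulation grid resolving each ramp/hold with the given step counts."""
        bt, _ = self.breakpoints
        pieces = [np.array([0.0])]
        for a, b in zip(bt[:-1], bt[1:]):
            is_hold = abs(self.strain_at(b) - self.strain_at(a)) < 1e-15
            n = hold_steps if is_hold else ramp_steps
            pieces.append(np.linspace(a, b, n + 1)[1:])
        return np.concatenate(pieces)


def build_protocol(
    levels,
    rate: float,
    hold: float = 300.0,
    unload_rate: float | None = None,
    sign: int = 1,
    zero_hold: float = 0.0,
    name: str | None = None,
) -> LoadingProtocol:
    """Cyclic ramp-hold-unload program over increasing strain levels.

    ``levels`` are absolute engineering strains (e.g. ``(0.005, 0.01,
    0.02)`` for the 0.5/1/2 % cycles), ``rate`` the loading rate in
    strain/s; the unload rate defaults to the loading rate.
    """
    levels = [float(x) for x in levels]
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ProtocolError("strain levels must be strictly increasing")
    if rate <= 0.0:
        raise ProtocolError("rate must be > 0")
    return LoadingProtocol(
        segments=[(lv, rate, float(hold)) for lv in levels],
        unload_rate=float(unload_rate if unload_rate is not None else rate),
        sign=sign,
        zero_hold=zero_hold,
        name=name,
    )


def strain_to_F11(u, l0: float):
    """Axial deformation-gradient component F11 = (u + l0)/l0."""
    if l0 <= 0.0:
        raise ValueError("initial length l0 must be > 0")
    return (np.asarray(u, dtype=float) + l0) / l0


def force_to_P11(R, A: float):
    """First Piola-Kirchhoff stress P11 = R/A in MPa (N/mm^2)."""
    if A <= 0.0:
        raise ValueError("cross-section area A must be > 0")
    return np.asarray(R, dtype=float) / A


def _lateral_residual(lam_ax, lam_t, state, dt, p, settings):
    F = np.diag([lam_ax, lam_t, lam_t])
    state_new, bundle = update_state(F.T @ F, state, dt, p, settings)
    return state_new, bundle, bundle.S[1, 1]


def _solve_lateral(lam_ax, lam_t0, state, dt, p, settings, tol=1e-9):
    """Secant iteration on S22(lambda_t) = 0 with a brentq fallback."""
    x0 = lam_t0
    out0 = _lateral_residual(lam_ax, x0, state, dt, p, settings)
    if abs(out0[2]) < tol:
        return x0, out0[0], out0[1]
    r0 = out0[2]
    x1 = x0 * (1.0 - 1e-6) if r0 > 0 else x0 * (1.0 + 1e-6)
    out1 = _lateral_residual(lam_ax, x1, state, dt, p, settings)
    r1 = out1[2]
    for _ in range(60):
        if abs(r1) < tol:
            return x1, out1[0], out1[1]
        if r1 == r0:
            break
        x2 = x1 - r1 * (x1 - x0) / (r1 - r0)
        if not (0.2 < x2 < 5.0):
            break
        x0, r0, x1 = x1, r1, x2
        out1 = _lateral_residual(lam_ax, x1, state, dt, p, settings)
        r1 = out1[2]
    # safeguard: bracket around the initial guess and bisect
    lo, hi = lam_t0 * 0.9, lam_t0 * 1.1
    flo = _lateral_residual(lam_ax, lo, state, dt, p, settings)[2]
    fhi = _lateral_residual(lam_ax, hi, state, dt, p, settings)[2]
    for _ in range(20):
        if flo * fhi <= 0.0:
            break
        lo *= 0.95
        hi *= 1.05
        flo = _lateral_residual(lam_ax, lo, state, dt, p, settings)[2]
        fhi = _lateral_residual(lam_ax, hi, state, dt, p, settings)[2]
    else:
        raise DriverError(f"could not bracket the lateral stretch at lambda_ax={lam_ax:g}")
    x = brentq(
        lambda lt: _lateral_residual(lam_ax, lt, state, dt, p, settings)[2],
        lo,
        hi,
        xtol=1e-14,
        rtol=8.9e-16,
    )
    state_new, bundle, res = _lateral_residual(lam_ax, x, state, dt, p, settings)
    if abs(res) > tol:
        raise DriverError(f"lateral stress residual {res:g} MPa above tolerance at lambda_ax={lam_ax:g}")
    return x, state_new, bundle


def _solve_lateral_pair(lam_ax, lt0, state, dt, p, settings, tol=1e-9):
    """Two-unknown lateral solve (S22 = S33 = 0) for oblique fibers."""

    def res(x):
        F = np.diag([lam_ax, x[0], x[1]])
        _, bundle = update_state(F.T @ F, state, dt, p, settings)
        return [bundle.S[1, 1], bundle.S[2, 2]]

    sol = root(res, x0=[lt0[0], lt0[1]], method="hybr", tol=1e-12)
    if not sol.success or max(abs(np.asarray(res(sol.x)))) > tol:
        raise DriverError(f"two-unknown lateral solve failed at lambda_ax={lam_ax:g}: {sol.message}")
    F = np.diag([lam_ax, sol.x[0], sol.x[1]])
    state_new, bundle = update_state(F.T @ F, state, dt, p, settings)
    return sol.x, state_new, bundle


def uniaxial_response(
    protocol: LoadingProtocol,
    p: MaterialParameters,
    settings: IntegratorSettings | None = None,
    times: np.ndarray | None = None,
    ramp_steps: int = RAMP_STEPS,
    hold_steps: int = HOLD_STEPS,
    initial_state: MaterialState | None = None,
    keep_states: bool = False,
) -> StressHistory:
    """Simulate uniaxial loading with traction-free lateral faces.

    The axial stretch is prescribed by the protocol
    (``F11 = 1 + strain``); the transverse stretch is solved at every step
    so the lateral second Piola-Kirchhoff stresses vanish (|S22| below
    1e-9 MPa).  With the fiber along the loading axis the deformation
    stays diagonal with equal transverse stretches; for oblique fibers
    the two lateral stretches are solved independently.
    """
    settings = settings or IntegratorSettings()
    if times is None:
        times = protocol.time_grid(ramp_steps, hold_steps)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0.0):
        raise DriverError("simulation times must be strictly increasing")
    eps = protocol.strain_at(times)
    lam_ax = 1.0 + eps

    axis_aligned = abs(abs(p.fiber_direction[0]) - 1.0) < 1e-12
    state = (initial_state or MaterialState.identity()).copy()
    n = times.size
    F = np.empty((n, 3, 3))
    S = np.empty((n, 3, 3))
    P = np.empty((n, 3, 3))
    D = np.empty(n)
    E = np.empty(n)
    states: list[MaterialState] = []
    lt = np.array([1.0, 1.0])
    t_prev = times[0]
    for k in range(n):
        dt = times[k] - t_prev if k > 0 else 0.0
        try:
            if axis_aligned:
                x, state, bundle = _solve_lateral(lam_ax[k], lt[0], state, dt, p, settings)
                lt = np.array([x, x])
            else:
                lt, state, bundle = _solve_lateral_pair(lam_ax[k], lt, state, dt, p, settings)
        except DriverError as err:
            raise DriverError(f"step {k} (t = {times[k]:g} s): {err}") from err
        F[k] = np.diag([lam_ax[k], lt[0], lt[1]])
        S[k] = bundle.S
        P[k] = F[k] @ bundle.S
        D[k] = bundle.dissipation_rate
        E[k] = bundle.energy
        if keep_states:
            states.append(state.copy())
        t_prev = times[k]
    return StressHistory(time=times, F=F, S=S, P=P, dissipation=D, states=states, energy=E)


@dataclass
class ExperimentRecord:
    """Raw time/displacement/force record with sample geometry.

    ``l0_mm`` is the free (clamping) length, ``area_mm2`` the initial
    cross-section; forces in N, displacements in mm, times in s.
    """

    time_s: np.ndarray
    displacement_mm: np.ndarray
    force_N: np.ndarray
    l0_mm: float
    area_mm2: float
    tissue: str = ""
    rate_label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        if self.l0_mm <= 0.0 or self.area_mm2 <= 0.0:
            raise ValueError("l0_mm and area_mm2 must be > 0")
        if np.any(np.diff(self.time_s) <= 0.0):
            raise ValueError("record times must be strictly increasing")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_s": self.time_s, "displacement_mm": self.displacement_mm, "force_N": self.force_N}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, l0_mm: float, area_mm2: float, **labels) -> "ExperimentRecord":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            time_s=df["time_s"].to_numpy(),
            displacement_mm=df["displacement_mm"].to_numpy(),
            force_N=df["force_N"].to_numpy(),
            l0_mm=l0_mm,
            area_mm2=area_mm2,
            **labels,
        )


def convert_experiment(
    rec: ExperimentRecord, subtract_preload: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert a raw record to ``(time, F11, P11)`` series.

    ``subtract_preload`` removes the first force sample as a baseline
    (the straightening pre-load); off by default.
    """
    R = rec.force_N - (rec.force_N[0] if subtract_preload else 0.0)
    return rec.time_s, strain_to_F11(rec.displacement_mm, rec.l0_mm), force_to_P11(R, rec.area_mm2)
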