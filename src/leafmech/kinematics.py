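"""Symmetric 3x3 tensor algebra and finite-strain kinematic maps.

All second-order tensors are plain ``(3, 3)`` numpy arrays.  Symmetric
tensors may be packed into six-component Voigt vectors with the fixed
component order ``(11, 22, 33, 12, 13, 23)``; shear components are stored
as-is (engineering shears are *not* doubled).

The viscous (inelastic) part of the deformation gradient is taken
rotation-free, ``F_i = U_i = sqrt(C_i)``, so the inelastic right
Cauchy-Green tensor ``C_i`` is the only stored internal variable and all
maps between the reference and intermediate configurations are built from
symmetric matrix functions of ``C_i``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "InvalidDeformationError",
    "DegenerateTensorError",
    "to_voigt",
    "from_voigt",
    "sym",
    "dev",
    "is_spd",
    "right_cauchy_green",
    "elastic_cg",
    "structure_tensor",
    "pushforward_structure",
    "spd_function",
    "spd_sqrt",
    "spd_inv",
    "spd_exp",
    "spd_log",
    "random_rotation",
    "random_spd",
]

I3 = np.eye(3)

#: relative eigenvalue floor below which a tensor is treated as non-SPD
SPD_RTOL = 1e-12

VOIGT_INDICES = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


class InvalidDeformationError(ValueError):
    """Deformation gradient with non-positive determinant."""


class DegenerateTensorError(ValueError):
    """Singular or non-SPD tensor where an SPD one is required."""


def to_voigt(A: np.ndarray) -> np.ndarray:
    """Pack a symmetric tensor into the six-vector (11,22,33,12,13,23)."""
    A = np.asarray(A, dtype=float)
    return np.array([A[i, j] for i, j in VOIGT_INDICES])


def from_voigt(v: np.ndarray) -> np.ndarray:
    """Unpack a six-vector (11,22,33,12,13,23) into a symmetric tensor."""
    v = np.asarray(v, dtype=float)
    A = np.empty((3, 3))
    for k, (i, j) in enumerate(VOIGT_INDICES):
        A[i, j] = v[k]
        A[j, i] = v[k]
    return A


def sym(A: np.ndarray) -> np.ndarray:
    return 0.5 * (A + A.T)


def dev(A: np.ndarray) -> np.ndarray:
    return A - (np.trace(A) / 3.0) * I3


def is_spd(A: np.ndarray, rtol: float = SPD_RTOL) -> bool:
    """Check symmetry and positive-definiteness via eigenvalues."""
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, rtol=0.0, atol=1e-10 * max(1.0, abs(A).max())):
        return False
    w = np.linalg.eigvalsh(sym(A))
    return bool(w[0] > rtol * max(w[-1], 0.0)) and w[0] > 0.0


def right_cauchy_green(F: np.ndarray) -> np.ndarray:
    """Right Cauchy-Green tensor C = F^T F.

    Raises :class:`InvalidDeformationError` if ``det F <= 0``.
    """
    F = np.asarray(F, dtype=float)
    if np.linalg.det(F) <= 0.0:
        raise InvalidDeformationError(
            f"deformation gradient has det F = {np.linalg.det(F):g} <= 0"
        )
    return F.T @ F


def elastic_cg(C: np.ndarray, Ci: np.ndarray) -> np.ndarray:
    """Elastic right Cauchy-Green tensor of a Maxwell branch.

    With the rotation-free choice ``F_i = U_i = sqrt(C_i)`` the elastic
    tensor is ``C_e = U_i^{-1} C U_i^{-1}``; it is symmetrized to remove
    round-off asymmetry.
    """
    Ui_inv = spd_function(Ci, "invsqrt")
    return sym(Ui_inv @ C @ Ui_inv)


def structure_tensor(N: np.ndarray) -> np.ndarray:
    """Rank-one structural tensor M = N (x) N of a unit fiber direction."""
    N = np.asarray(N, dtype=float)
    nrm = np.linalg.norm(N)
    if nrm == 0.0:
        raise DegenerateTensorError("fiber direction must be a non-zero vector")
    N = N / nrm
    return np.outer(N, N)


def pushforward_structure(Ci_ani: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Structural tensor in the intermediate configuration.

    ``M_tilde = (U_i M U_i) / (C_i : M)`` with ``U_i = sqrt(C_i)``.  The
    normalization by ``C_i : M = |U_i N|^2`` makes ``M_tilde`` again a
    rank-one projector ``N_tilde (x) N_tilde`` with unit trace.
    """
    denom = float(np.tensordot(Ci_ani, M))
    if denom <= 0.0:
        raise DegenerateTensorError(
            f"C_i : M = {denom:g} <= 0; inelastic tensor not SPD along the fiber"
        )
    Ui = spd_sqrt(Ci_ani)
    return sym(Ui @ M @ Ui) / denom


def _eig_apply(A: np.ndarray, fn, name: str, positive_required: bool) -> np.ndarray:
    A = sym(np.asarray(A, dtype=float))
    # exact-diagonal fast path: the uniaxial driver keeps every tensor
    # diagonal, where the spectral decomposition is trivial
    off = A[0, 1], A[0, 2], A[1, 2]
    if off == (0.0, 0.0, 0.0):
        d = np.diagonal(A).copy()
        if positive_required and d.min() <= SPD_RTOL * max(d.max(), 0.0):
            raise DegenerateTensorError(f"{name}: input is not SPD (diag {d})")
        return np.diag(fn(d))
    w, V = np.linalg.eigh(A)
    if positive_required and w[0] <= SPD_RTOL * max(w[-1], 0.0):
        raise DegenerateTensorError(f"{name}: input is not SPD (eigenvalues {w})")
    return sym((V * fn(w)) @ V.T)


_SPD_FUNCS = {
    "exp": (np.exp, False),
    "log": (np.log, True),
    "sqrt": (np.sqrt, True),
    "inv": (lambda w: 1.0 / w, True),
    "invsqrt": (lambda w: 1.0 / np.sqrt(w), True),
}


def spd_function(A: np.ndarray, which: str) -> np.ndarray:
    """Matrix function of a symmetric tensor via spectral decomposition.

    ``which`` is one of ``exp``, ``log``, ``sqrt``, ``inv``, ``invsqrt``.
    ``exp`` accepts any symmetric input; the others require SPD.
    """
    try:
        fn, pos = _SPD_FUNCS[which]
    except KeyError:
        raise ValueError(f"unknown matrix function {which!r}") from None
    return _eig_apply(A, fn, which, pos)


def spd_sqrt(A: np.ndarray) -> np.ndarray:
    return spd_function(A, "sqrt")


def spd_inv(A: np.ndarray) -> np.ndarray:
    return spd_function(A, "inv")


def spd_exp(A: np.ndarray) -> np.ndarray:
    return spd_function(A, "exp")


def spd_log(A: np.ndarray) -> np.ndarray:
    return spd_function(A, "log")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform proper rotation (QR of a Gaussian matrix, det fixed)."""
    Q, R = np.linalg.qr(rng.standard_normal((3, 3)))
    Q = Q * np.sign(np.diagonal(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def random_spd(rng: np.random.Generator, spread: float = 0.3) -> np.ndarray:
    """Random SPD tensor with eigenvalues ~ exp(N(0, spread))."""
    Q = random_rotation(rng)
    w = np.exp(rng.normal(0.0, spread, size=3))
    return sym((Q * w) @ Q.T)
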