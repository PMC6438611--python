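"""Neo-Hookean tissue mechanics: constitutive law and elastic moduli.

The acinar septal tissue is modelled as a modified (compressible)
Neo-Hookean hyperelastic solid with stored-energy density

    W(F) = K * U(J) + (G/2) * (J^(-2/3) * I_C - 3),
    U(J) = (1/4) * (J^2 - 1 - 2 ln J),

where ``F`` is the deformation gradient, ``J = det F``, ``I_C = tr(F^T F)``
and ``K``, ``G`` are the small-strain bulk and shear moduli obtained from
the equivalent small-strain modulus ``E`` and Poisson ratio ``nu``:

    K = E / (3 (1 - 2 nu)),    G = E / (2 (1 + nu)).

All stresses are in Pa; lengths are non-dimensional in the deformation
gradient so the same functions serve the mm-based geometry downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialNeoHookean",
    "moduli_from_E_nu",
    "strain_energy",
    "first_piola_stress",
    "cauchy_stress",
    "linear_cauchy_stress",
    "plane_stress_c33",
    "membrane_pk2",
]


class InvalidParameterError(ValueError):
    """Raised for non-physical material or geometric parameters."""


class InvertedElementError(ValueError):
    """Raised when a deformation state has det F <= 0."""


def moduli_from_E_nu(E: float, nu: float) -> tuple[float, float]:
    """Bulk and shear moduli (K, G) from Young's modulus and Poisson ratio.

    Raises
    ------
    InvalidParameterError
        If ``E <= 0`` or ``nu`` lies outside ``[0, 0.5)`` (the
        incompressible limit ``nu -> 0.5`` makes K unbounded).
    """
    if E <= 0.0:
        raise InvalidParameterError(f"E must be positive, got {E}")
    if not (0.0 <= nu < 0.5):
        raise InvalidParameterError(
            f"nu must lie in [0, 0.5); nu={nu} reaches the incompressible limit"
        )
    K = E / (3.0 * (1.0 - 2.0 * nu))
    G = E / (2.0 * (1.0 + nu))
    return K, G


@dataclass(frozen=True)
class MaterialNeoHookean:
    """Compressible Neo-Hookean material parameterized by (E, nu)."""

    E: float
    nu: float
    K: float = field(init=False)
    G: float = field(init=False)

    def __post_init__(self) -> None:
        K, G = moduli_from_E_nu(self.E, self.nu)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "G", G)


def _check_F(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] != (3, 3):
        raise ValueError("F must have shape (..., 3, 3)")
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise InvertedElementError("det F <= 0: element inversion")
    return F


def strain_energy(F: np.ndarray, mat: MaterialNeoHookean) -> np.ndarray:
    """Stored energy density W(F) in Pa. Vectorized over leading axes."""
    F = _check_F(F)
    J = np.linalg.det(F)
    I_C = np.einsum("...ij,...ij->...", F, F)
    U = 0.25 * (J**2 - 1.0 - 2.0 * np.log(J))
    W = mat.K * U + 0.5 * mat.G * (J ** (-2.0 / 3.0) * I_C - 3.0)
    return W


def first_piola_stress(F: np.ndarray, mat: MaterialNeoHookean) -> np.ndarray:
    """First Piola-Kirchhoff stress P = dW/dF (Pa)."""
    F = _check_F(F)
    J = np.linalg.det(F)[..., None, None]
    Finv = np.linalg.inv(F)
    FinvT = np.swapaxes(Finv, -1, -2)
    I_C = np.einsum("...ij,...ij->...", F, F)[..., None, None]
    Uprime = 0.5 * (J - 1.0 / J)
    P = mat.K * Uprime * J * FinvT + mat.G * J ** (-2.0 / 3.0) * (
        F - (I_C / 3.0) * FinvT
    )
    return P


def cauchy_stress(F: np.ndarray, mat: MaterialNeoHookean) -> np.ndarray:
    """Cauchy stress sigma = J^-1 P F^T (Pa); symmetric by construction."""
    F = _check_F(F)
    J = np.linalg.det(F)[..., None, None]
    P = first_piola_stress(F, mat)
    sigma = np.einsum("...ik,...jk->...ij", P, F) / J
    # symmetrize away floating-point asymmetry
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))


def linear_cauchy_stress(eps: np.ndarray, mat: MaterialNeoHookean) -> np.ndarray:
    """Small-strain Hooke stress sigma = lambda tr(eps) I + 2 mu eps.

    This is the infinitesimal-strain special case of the hyperelastic law,
    kept as a verified limit (the membrane and bulk solvers use the finite
    law).
    """
    eps = np.asarray(eps, dtype=float)
    lam = mat.K - 2.0 * mat.G / 3.0
    tr = np.einsum("...ii->...", eps)[..., None, None]
    return lam * tr * np.eye(3) + 2.0 * mat.G * eps


def plane_stress_c33(
    c11: np.ndarray,
    c12: np.ndarray,
    c22: np.ndarray,
    mat: MaterialNeoHookean,
    c33_init: np.ndarray | None = None,
    tol: float = 1e-13,
    max_iter: int = 60,
) -> np.ndarray:
    """Thickness stretch squared c33 enforcing S33 = 0 (plane stress).

    Solves, per element,  K U'(J) J + G J^(-2/3) (c33 - I1/3) = 0  with
    J^2 = det(C2) * c33 and I1 = tr(C2) + c33, by a damped Newton iteration
    on log(c33). Vectorized over arrays.
    """
    c11 = np.asarray(c11, float)
    det2 = c11 * c22 - c12**2
    if np.any(det2 <= 0.0):
        raise InvertedElementError("surface metric not positive definite")
    tr2 = c11 + c22
    x = np.log(c33_init if c33_init is not None else np.ones_like(c11))
    K, G = mat.K, mat.G
    for _ in range(max_iter):
        c33 = np.exp(x)
        J = np.sqrt(det2 * c33)
        I1 = tr2 + c33
        f = K * 0.5 * (J - 1.0 / J) * J + G * J ** (-2.0 / 3.0) * (c33 - I1 / 3.0)
        # df/dx with x = log c33 ; dJ/dx = J/2, dI1/dx = c33
        dJ = 0.5 * J
        dUterm = K * (J * dJ)  # d/dx of K/2 (J^2 - 1) ; note f's first term = K/2 (J^2-1)
        diso = G * (
            -(2.0 / 3.0) * J ** (-5.0 / 3.0) * dJ * (c33 - I1 / 3.0)
            + J ** (-2.0 / 3.0) * (c33 - c33 / 3.0)
        )
        df = dUterm + diso
        step = f / df
        step = np.clip(step, -1.0, 1.0)
        x = x - step
        if np.max(np.abs(step)) < tol:
            break
    return np.exp(x)


def membrane_pk2(
    C2: np.ndarray, mat: MaterialNeoHookean, c33_init: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-plane 2nd Piola-Kirchhoff stress for a plane-stress membrane.

    Parameters
    ----------
    C2 : (..., 2, 2) right Cauchy-Green surface metric.

    Returns
    -------
    S2 : (..., 2, 2) in-plane PK2 stress (Pa).
    c33 : (...,) thickness stretch squared.
    J : (...,) volumetric Jacobian det F.
    """
    C2 = np.asarray(C2, float)
    c11, c12, c22 = C2[..., 0, 0], C2[..., 0, 1], C2[..., 1, 1]
    c33 = plane_stress_c33(c11, c12, c22, mat, c33_init=c33_init)
    det2 = c11 * c22 - c12**2
    J = np.sqrt(det2 * c33)
    I1 = c11 + c22 + c33
    C2inv = np.empty_like(C2)
    C2inv[..., 0, 0] = c22 / det2
    C2inv[..., 1, 1] = c11 / det2
    C2inv[..., 0, 1] = -c12 / det2
    C2inv[..., 1, 0] = -c12 / det2
    I2 = np.zeros_like(C2)
    I2[..., 0, 0] = 1.0
    I2[..., 1, 1] = 1.0
    Uprime = 0.5 * (J - 1.0 / J)
    S2 = (mat.K * Uprime * J)[..., None, None] * C2inv + (
        mat.G * J ** (-2.0 / 3.0)
    )[..., None, None] * (I2 - (I1 / 3.0)[..., None, None] * C2inv)
    return S2, c33, J
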