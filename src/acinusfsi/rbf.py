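"""Radial-basis-function transfer between non-matching interface meshes.

Displacements are interpolated from the solid interface point cloud to the
fluid one with a Wendland C2 kernel plus linear polynomial augmentation
(exact reproduction of constant and linear fields); tractions travel the
adjoint route (transpose operator), which conserves the total interface
force component-wise because the forward map reproduces constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InterfaceMap", "build_interface_map", "transfer_displacement", "transfer_traction"]


def _wendland_c2(r: np.ndarray) -> np.ndarray:
    """phi(r) = (1 - r)^4 (4 r + 1) for r in [0, 1], 0 beyond."""
    x = np.clip(1.0 - r, 0.0, None)
    return x**4 * (4.0 * r + 1.0)


@dataclass
class InterfaceMap:
    """Dense displacement-transfer operator H and its adjoint.

    ``H @ values_on_source`` evaluates on the target points; ``H.T`` pulls
    nodal forces back conservatively.
    """

    source: np.ndarray
    target: np.ndarray
    H: np.ndarray
    support_radius: float

    def forward(self, values: np.ndarray) -> np.ndarray:
        return self.H @ values

    def adjoint(self, forces: np.ndarray) -> np.ndarray:
        return self.H.T @ forces


def build_interface_map(
    source_points: np.ndarray,
    target_points: np.ndarray,
    support_radius: float | None = None,
    regularization: float = 1e-12,
) -> InterfaceMap:
    """RBF interpolation operator between two point clouds on one surface.

    The compact support radius defaults to 3x the largest source
    nearest-neighbour spacing (every kernel sees a well-filled
    neighbourhood). A tiny Tikhonov term guards the kernel block against
    near-duplicate points; the polynomial block keeps linear fields exact.
    """
    from scipy.spatial import cKDTree

    X = np.asarray(source_points, float)
    Y = np.asarray(target_points, float)
    if X.ndim != 2 or X.shape[1] != 3 or len(X) < 4:
        raise ValueError("source must be (n>=4, 3) points")
    if support_radius is None:
        tree = cKDTree(X)
        d, _ = tree.query(X, k=2)
        support_radius = 3.0 * float(d[:, 1].max())
        if support_radius <= 0:
            raise ValueError("degenerate source point set")
    # scale coordinates for conditioning of the polynomial block
    c = X.mean(axis=0)
    s = max(float(np.abs(X - c).max()), 1e-30)
    Xs, Ys = (X - c) / s, (Y - c) / s
    eps = support_radius / s

    def kernel(A, B):
        r = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2) / eps
        return _wendland_c2(r)

    n = len(Xs)
    Phi = kernel(Xs, Xs) + regularization * np.eye(n)
    P = np.hstack([np.ones((n, 1)), Xs])
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = Phi
    A[:n, n:] = P
    A[n:, :n] = P.T
    B = np.hstack([kernel(Ys, Xs), np.ones((len(Ys), 1)), Ys])
    try:
        H = np.linalg.solve(A.T, B.T).T[:, :n]
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"ill-conditioned RBF system: {exc}") from exc
    return InterfaceMap(source=X, target=Y, H=H, support_radius=support_radius)


def transfer_displacement(imap: InterfaceMap, displacement: np.ndarray) -> np.ndarray:
    """Solid-interface displacement -> fluid-boundary displacement."""
    d = np.asarray(displacement, float)
    if len(d) != len(imap.source):
        raise ValueError("displacement must be given on the source points")
    return imap.forward(d)


def transfer_traction(imap: InterfaceMap, nodal_forces: np.ndarray) -> np.ndarray:
    """Fluid nodal forces -> solid nodal loads (conservative adjoint)."""
    f = np.asarray(nodal_forces, float)
    if len(f) != len(imap.target):
        raise ValueError("forces must be given on the target points")
    return imap.adjoint(f)
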