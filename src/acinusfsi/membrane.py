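"""Quasi-static Neo-Hookean membrane finite elements.

The septal tissue is thin (0.025-0.050 mm) compared with the acinus scale
(~1 mm), so the reduced solid mode treats the load-bearing surface as a
plane-stress Neo-Hookean membrane discretized with constant-strain
triangles. Pressure acts as a follower load normal to the deformed
surface. Inertia is dropped: breathing at 0.25 Hz with tissue densities of
order 1e3 kg/m^3 produces inertial stresses many orders of magnitude below
the elastic stresses, so each time instant is a Newton-iterated
equilibrium.

Units: lengths mm, pressures/stresses Pa, forces Pa*mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import InvertedElementError, MaterialNeoHookean, membrane_pk2

__all__ = ["MembraneModel", "MembraneState", "NewtonDivergenceError", "enclosed_volume"]


class NewtonDivergenceError(RuntimeError):
    """Newton failed to converge; carries the last residual norm."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def enclosed_volume(nodes: np.ndarray, tris: np.ndarray, cap: bool = True) -> float:
    """Signed volume enclosed by a triangulated surface (divergence theorem).

    If the surface has one open ring and ``cap`` is true, the hole is closed
    by a fan to the ring centroid so the result is the volume of the capped
    solid. Orientation must be outward for a positive result.
    """
    x = nodes[tris]
    vol = np.einsum("ij,ij->", x[:, 0], np.cross(x[:, 1], x[:, 2])) / 6.0
    if cap:
        edges = {}
        for t in tris:
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                key = (min(a, b), max(a, b))
                if key in edges:
                    edges.pop(key)
                else:
                    edges[key] = (a, b)
        # group boundary edges into closed rings; fan each ring to its own
        # centroid (exact for planar rings such as the duct mouth)
        succ = {a: b for a, b in edges.values()}
        visited = set()
        for start in list(succ):
            if start in visited:
                continue
            ring = [start]
            visited.add(start)
            nxt = succ[start]
            while nxt != start:
                ring.append(nxt)
                visited.add(nxt)
                nxt = succ[nxt]
            c = nodes[ring].mean(axis=0)
            for i, a in enumerate(ring):
                b = ring[(i + 1) % len(ring)]
                # boundary edges run counter to triangle orientation
                vol += np.dot(nodes[b], np.cross(nodes[a], c)) / 6.0
    return float(vol)


@dataclass
class MembraneState:
    """Converged membrane equilibrium.

    Attributes
    ----------
    u : (n, 3) nodal displacements (mm).
    cauchy : (m, 3, 3) in-plane Cauchy stress pushed to 3D axes (Pa).
    J : (m,) volumetric Jacobian per element.
    residual : final relative residual norm.
    """

    u: np.ndarray
    cauchy: np.ndarray
    J: np.ndarray
    residual: float
    n_iter: int


class MembraneModel:
    """CST membrane over a triangulated surface with per-element thickness.

    Parameters
    ----------
    nodes, tris : reference surface mesh (outward-oriented triangles).
    thickness : scalar or (m,) element thicknesses (mm).
    material : Neo-Hookean material.
    fixed_nodes : node indices with all displacement dofs clamped
        (e.g. the duct-mouth ring).
    """

    def __init__(
        self,
        nodes: np.ndarray,
        tris: np.ndarray,
        thickness: float | np.ndarray,
        material: MaterialNeoHookean,
        fixed_nodes: np.ndarray | None = None,
        fixed_dofs: np.ndarray | None = None,
    ):
        self.nodes = np.asarray(nodes, float)
        self.tris = np.asarray(tris, int)
        m = len(self.tris)
        self.thickness = np.broadcast_to(np.asarray(thickness, float), (m,)).copy()
        self.material = material
        self.fixed_nodes = np.asarray(
            fixed_nodes if fixed_nodes is not None else [], int
        )
        n = len(self.nodes)
        mask = np.ones(3 * n, bool)
        if len(self.fixed_nodes):
            mask[(3 * self.fixed_nodes[:, None] + np.arange(3)).ravel()] = False
        if fixed_dofs is not None and len(fixed_dofs):
            mask[np.asarray(fixed_dofs, int)] = False
        self.free = np.flatnonzero(mask)
        self._setup_reference()
        self._setup_indices()
        self._setup_bending()
        self._lu = None
        self._c33 = np.ones(m)

    # -- reference geometry -------------------------------------------------
    def _setup_reference(self) -> None:
        X = self.nodes[self.tris]
        e1 = X[:, 1] - X[:, 0]
        e2 = X[:, 2] - X[:, 0]
        nrm = np.cross(e1, e2)
        a2 = np.linalg.norm(nrm, axis=1)
        if np.any(a2 <= 0):
            raise ValueError("degenerate reference triangle")
        self.area0 = 0.5 * a2
        E1 = e1 / np.linalg.norm(e1, axis=1)[:, None]
        nhat = nrm / a2[:, None]
        E2 = np.cross(nhat, E1)
        # 2x2 reference edge matrix and its inverse
        Dm = np.empty((len(self.tris), 2, 2))
        Dm[:, 0, 0] = np.einsum("ij,ij->i", e1, E1)
        Dm[:, 0, 1] = np.einsum("ij,ij->i", e2, E1)
        Dm[:, 1, 0] = np.einsum("ij,ij->i", e1, E2)
        Dm[:, 1, 1] = np.einsum("ij,ij->i", e2, E2)
        det = Dm[:, 0, 0] * Dm[:, 1, 1] - Dm[:, 0, 1] * Dm[:, 1, 0]
        Bm = np.empty_like(Dm)
        Bm[:, 0, 0] = Dm[:, 1, 1] / det
        Bm[:, 1, 1] = Dm[:, 0, 0] / det
        Bm[:, 0, 1] = -Dm[:, 0, 1] / det
        Bm[:, 1, 0] = -Dm[:, 1, 0] / det
        self.Bm = Bm
        # Newton step cap: soft (near-inextensional) modes of a faceted
        # membrane can produce huge first steps; cap at a few edge lengths
        self.step_cap = 3.0 * float(np.median(np.linalg.norm(e1, axis=1)))

    def _setup_indices(self) -> None:
        # global dof indices for the 9 element dofs; sparsity of K
        dofs = (3 * self.tris[:, :, None] + np.arange(3)).reshape(-1, 9)
        self.elem_dofs = dofs
        self.rows = np.repeat(dofs, 9, axis=1).ravel()
        self.cols = np.tile(dofs, (1, 9)).ravel()

    # -- discrete-shell bending ----------------------------------------------
    def _setup_bending(self) -> None:
        """Hinge elements over interior edges (discrete-shell bending).

        A pure CST membrane on a creased surface has zero-energy
        inextensional modes; the physical wall bending stiffness
        k_b = E t^3 / (12 (1 - nu^2)) regularizes them and carries the
        crease response. Hinge stiffness follows the discrete-shells
        construction: k_h = k_b |e0| / h_bar, rest angle = reference
        dihedral.
        """
        directed: dict[tuple[int, int], tuple[int, int]] = {}
        for ti, (p, q, r) in enumerate(self.tris):
            for a, b, opp in ((p, q, r), (q, r, p), (r, p, q)):
                directed[(int(a), int(b))] = (ti, int(opp))
        hinges = []
        tpair = []
        for (a, b), (ti, k) in directed.items():
            if a < b and (b, a) in directed:
                tj, l = directed[(b, a)]
                hinges.append((a, b, k, l))
                tpair.append((ti, tj))
        self.hinges = np.array(hinges, int).reshape(-1, 4)
        nh = len(self.hinges)
        if nh == 0:
            self.k_hinge = np.zeros(0)
            self.theta0 = np.zeros(0)
            self.hinge_dofs = np.zeros((0, 12), int)
            self.h_rows = np.zeros(0, int)
            self.h_cols = np.zeros(0, int)
            return
        tpair = np.array(tpair, int)
        E, nu = self.material.E, self.material.nu
        t_h = 0.5 * (self.thickness[tpair[:, 0]] + self.thickness[tpair[:, 1]])
        kb = E * t_h**3 / (12.0 * (1.0 - nu**2))
        xe = self.nodes[self.hinges]
        e0 = np.linalg.norm(xe[:, 1] - xe[:, 0], axis=1)
        A = self.area0[tpair[:, 0]] + self.area0[tpair[:, 1]]
        hbar = A / (3.0 * e0)
        self.k_hinge = kb * e0 / hbar
        self.theta0 = self._hinge_theta(xe)
        dofs = (3 * self.hinges[:, :, None] + np.arange(3)).reshape(-1, 12)
        self.hinge_dofs = dofs
        self.h_rows = np.repeat(dofs, 12, axis=1).ravel()
        self.h_cols = np.tile(dofs, (1, 12)).ravel()

    @staticmethod
    def _hinge_theta(xe: np.ndarray) -> np.ndarray:
        """Signed dihedral angle per hinge; xe (..., nh, 4, 3)."""
        x0, x1, x2, x3 = xe[..., 0, :], xe[..., 1, :], xe[..., 2, :], xe[..., 3, :]
        e = x1 - x0
        n1 = np.cross(x1 - x0, x2 - x0)
        n2 = np.cross(x3 - x0, x1 - x0)
        le = np.linalg.norm(e, axis=-1)
        s = np.einsum("...i,...i->...", np.cross(n1, n2), e) / le
        c = np.einsum("...i,...i->...", n1, n2)
        return np.arctan2(s, c)

    def _hinge_forces(self, xe: np.ndarray) -> np.ndarray:
        """Nodal bending forces per hinge, (..., nh, 12)."""
        x0, x1, x2, x3 = xe[..., 0, :], xe[..., 1, :], xe[..., 2, :], xe[..., 3, :]
        e = x1 - x0
        le = np.linalg.norm(e, axis=-1)[..., None]
        n1 = np.cross(x1 - x0, x2 - x0)
        n2 = np.cross(x3 - x0, x1 - x0)
        in1 = 1.0 / np.einsum("...i,...i->...", n1, n1)[..., None]
        in2 = 1.0 / np.einsum("...i,...i->...", n2, n2)[..., None]
        th = self._hinge_theta(xe)
        g2 = -le * n1 * in1
        g3 = -le * n2 * in2
        d21 = np.einsum("...i,...i->...", e, x2 - x1)[..., None]
        d31 = np.einsum("...i,...i->...", e, x3 - x1)[..., None]
        d02 = np.einsum("...i,...i->...", e, x0 - x2)[..., None]
        d03 = np.einsum("...i,...i->...", e, x0 - x3)[..., None]
        g0 = -(d21 / le) * n1 * in1 - (d31 / le) * n2 * in2
        g1 = -(d02 / le) * n1 * in1 - (d03 / le) * n2 * in2
        coef = (2.0 * self.k_hinge * (th - self.theta0))[..., None]
        f = np.concatenate([coef * g0, coef * g1, coef * g2, coef * g3], axis=-1)
        return f

    # -- element forces ------------------------------------------------------
    def _element_forces(self, xe: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Internal minus external nodal forces for element coords.

        xe : (..., m, 3, 3) current coordinates (node, xyz).
        p : (m,) transmural pressure (positive = outward follower load).
        Returns (..., m, 9).
        """
        d1 = xe[..., 1, :] - xe[..., 0, :]
        d2 = xe[..., 2, :] - xe[..., 0, :]
        Bm = self.Bm
        # F_hat = [d1 d2] @ Bm : (..., m, 3, 2)
        F1 = d1 * Bm[:, 0, 0][:, None] + d2 * Bm[:, 1, 0][:, None]
        F2 = d1 * Bm[:, 0, 1][:, None] + d2 * Bm[:, 1, 1][:, None]
        C2 = np.empty(xe.shape[:-2] + (2, 2))
        C2[..., 0, 0] = np.einsum("...i,...i->...", F1, F1)
        C2[..., 1, 1] = np.einsum("...i,...i->...", F2, F2)
        c12 = np.einsum("...i,...i->...", F1, F2)
        C2[..., 0, 1] = c12
        C2[..., 1, 0] = c12
        S2, c33, J = membrane_pk2(
            C2, self.material, c33_init=np.broadcast_to(self._c33, C2.shape[:-2])
        )
        # PK1 (3x2): P = F_hat S2 ; nodal force scatter via Bm^T
        P1 = F1 * S2[..., 0, 0][..., None] + F2 * S2[..., 1, 0][..., None]
        P2 = F1 * S2[..., 0, 1][..., None] + F2 * S2[..., 1, 1][..., None]
        g1 = P1 * Bm[:, 0, 0][:, None] + P2 * Bm[:, 0, 1][:, None]
        g2 = P1 * Bm[:, 1, 0][:, None] + P2 * Bm[:, 1, 1][:, None]
        At = (self.area0 * self.thickness)[:, None]
        f = np.empty(xe.shape[:-2] + (9,))
        f[..., 3:6] = At * g1
        f[..., 6:9] = At * g2
        f[..., 0:3] = -At * (g1 + g2)
        # follower pressure: -(p/3) * area-normal on each node
        an = 0.5 * np.cross(d1, d2)
        fp = (p[:, None] / 3.0) * an
        f[..., 0:3] -= fp
        f[..., 3:6] -= fp
        f[..., 6:9] -= fp
        return f, C2, S2, c33, J

    def _residual(self, u: np.ndarray, p: np.ndarray):
        x = self.nodes + u
        f, C2, S2, c33, J = self._element_forces(x[self.tris], p)
        R = np.zeros(3 * len(self.nodes))
        np.add.at(R, self.elem_dofs.ravel(), f.ravel())
        if len(self.hinges):
            fh = self._hinge_forces(x[self.hinges])
            np.add.at(R, self.hinge_dofs.ravel(), fh.ravel())
        self._c33 = c33  # warm start for the plane-stress iteration
        return R, (C2, S2, c33, J)

    def _tangent(self, u: np.ndarray, p: np.ndarray) -> sp.csc_matrix:
        """Forward-difference consistent tangent assembled element-wise."""
        x = self.nodes + u
        xe = x[self.tris]
        f0, *_ = self._element_forces(xe, p)
        h = 1e-7 * max(1.0, float(np.abs(self.nodes).max()))
        pert = np.broadcast_to(xe, (9,) + xe.shape).copy()
        for j in range(9):
            pert[j, :, j // 3, j % 3] += h
        fj, *_ = self._element_forces(pert, p)
        Ke = (fj - f0[None]) / h  # (9, m, 9): column j
        data = np.transpose(Ke, (1, 2, 0)).ravel()  # row-major (m, 9row, 9col)
        rows, cols = self.rows, self.cols
        if len(self.hinges):
            xh = x[self.hinges]
            f0h = self._hinge_forces(xh)
            perth = np.broadcast_to(xh, (12,) + xh.shape).copy()
            for j in range(12):
                perth[j, :, j // 3, j % 3] += h
            fjh = self._hinge_forces(perth)
            Kh = (fjh - f0h[None]) / h
            data = np.concatenate([data, np.transpose(Kh, (1, 2, 0)).ravel()])
            rows = np.concatenate([rows, self.h_rows])
            cols = np.concatenate([cols, self.h_cols])
        n = 3 * len(self.nodes)
        K = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsc()
        return K[self.free][:, self.free]

    # -- solver ---------------------------------------------------------------
    def solve(
        self,
        pressure: float | np.ndarray,
        u0: np.ndarray | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-12,
        max_iter: int = 25,
        max_substeps: int = 64,
        reuse_tangent: bool = False,
    ) -> MembraneState:
        """Newton-iterated equilibrium under a follower pressure load.

        ``pressure`` is the transmural pressure per element (or scalar),
        positive outward. On divergence the load increment is sub-stepped.
        ``reuse_tangent`` keeps the previously factorized stiffness (modified
        Newton) which is efficient for the small per-time-step load
        increments of a breathing cycle.
        """
        m = len(self.tris)
        p_target = np.broadcast_to(np.asarray(pressure, float), (m,)).copy()
        u = np.zeros((len(self.nodes), 3)) if u0 is None else u0.copy()
        p_ref = max(float(np.abs(p_target).max()), 1.0)
        fscale = p_ref * float((self.area0.sum()))
        state_extra = None
        n_total = 0

        def newton(p, u, allow_reuse):
            nonlocal state_extra, n_total
            R, extra = self._residual(u, p)
            state_extra = extra
            rnorm = np.linalg.norm(R[self.free])
            for it in range(max_iter):
                if rnorm <= max(rtol * fscale, atol):
                    return u, rnorm, it
                if self._lu is None or not allow_reuse or it >= 6:
                    K = self._tangent(u, p)
                    self._lu = spla.splu(K)
                    allow_reuse = True
                du = self._lu.solve(-R[self.free])
                # cap over-long steps along soft modes, backtrack on inversion
                s = min(1.0, self.step_cap / max(np.abs(du).max(), 1e-30))
                for _ in range(8):
                    unew = u.copy()
                    unew.reshape(-1)[self.free] += s * du
                    try:
                        Rn, extra = self._residual(unew, p)
                        break
                    except InvertedElementError:
                        s *= 0.5
                else:
                    raise NewtonDivergenceError(
                        "backtracking failed (element inversion)", rnorm
                    )
                u, R, state_extra = unew, Rn, extra
                rnorm = np.linalg.norm(R[self.free])
                n_total += 1
            if rnorm <= max(rtol * fscale, atol):
                return u, rnorm, max_iter
            raise NewtonDivergenceError(
                f"Newton stalled at residual {rnorm:.3e}", rnorm
            )

        # load continuation: start with the full load, sub-step on failure
        n_sub = 1
        # pressure already equilibrated with u0 (warm start) => try directly
        p_start = np.zeros(m)
        while True:
            try:
                ucur = u.copy()
                for k in range(1, n_sub + 1):
                    p = p_start + (p_target - p_start) * (k / n_sub)
                    ucur, rnorm, nit = newton(p, ucur, reuse_tangent and n_sub == 1)
                u = ucur
                break
            except NewtonDivergenceError:
                self._lu = None
                n_sub *= 2
                if n_sub > max_substeps:
                    raise
        C2, S2, c33, J = state_extra
        cauchy = self._push_forward(u, S2, c33, J)
        return MembraneState(u=u, cauchy=cauchy, J=J, residual=rnorm, n_iter=n_total)

    def _push_forward(self, u, S2, c33, J) -> np.ndarray:
        xe = (self.nodes + u)[self.tris]
        d1 = xe[:, 1] - xe[:, 0]
        d2 = xe[:, 2] - xe[:, 0]
        Bm = self.Bm
        F1 = d1 * Bm[:, 0, 0][:, None] + d2 * Bm[:, 1, 0][:, None]
        F2 = d1 * Bm[:, 0, 1][:, None] + d2 * Bm[:, 1, 1][:, None]
        Fh = np.stack([F1, F2], axis=-1)  # (m, 3, 2)
        sig = np.einsum("mia,mab,mjb->mij", Fh, S2, Fh) / J[:, None, None]
        return 0.5 * (sig + np.swapaxes(sig, 1, 2))

    # -- post-processing ------------------------------------------------------
    def deformed_volume(self, u: np.ndarray) -> float:
        """Volume enclosed by the deformed surface (mouth hole capped)."""
        return enclosed_volume(self.nodes + u, self.tris, cap=True)


def max_principal_stress(
    cauchy: np.ndarray, regions: np.ndarray | None = None
) -> dict:
    """Largest principal Cauchy stress per element and per region.

    Parameters
    ----------
    cauchy : (m, 3, 3) symmetric stress tensors (Pa).
    regions : optional (m,) string/int labels (e.g. primary vs secondary
        septa); per-region maxima are reported for each label.

    Returns
    -------
    dict with ``per_element`` (m,), ``max`` and optionally
    ``per_region`` mapping label -> max (Pa).
    """
    w = np.linalg.eigvalsh(np.asarray(cauchy, float))
    per_elem = w[..., -1]
    out = {"per_element": per_elem, "max": float(per_elem.max(initial=0.0))}
    if regions is not None:
        regions = np.asarray(regions)
        out["per_region"] = {
            str(lab): float(per_elem[regions == lab].max(initial=0.0))
            for lab in np.unique(regions)
        }
    return out
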