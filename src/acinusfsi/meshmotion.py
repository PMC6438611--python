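"""Fluid-mesh motion by elliptic (graph-Laplacian) smoothing.

Boundary displacements from the coupling step are propagated into the
fluid volume by solving a Laplace problem per displacement component on
the tet-mesh node graph; interior nodes therefore follow the walls
smoothly. Element inversion is detected and reported so the caller can
sub-step the interface motion.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import VolumeMesh

__all__ = ["move_fluid_mesh", "MeshInversionError"]


class MeshInversionError(RuntimeError):
    """Mesh motion produced inverted elements; carries their indices."""

    def __init__(self, elements: np.ndarray):
        super().__init__(
            f"mesh motion inverted {len(elements)} elements; reduce the step"
        )
        self.elements = elements


def move_fluid_mesh(
    mesh: VolumeMesh, boundary_nodes: np.ndarray, boundary_disp: np.ndarray
) -> VolumeMesh:
    """Return a new mesh with boundary displacements diffused inward.

    ``boundary_nodes``: node indices with prescribed displacement
    ``boundary_disp`` (k, 3). Raises :class:`MeshInversionError` if the
    motion inverts any tetrahedron.
    """
    boundary_nodes = np.asarray(boundary_nodes, int)
    boundary_disp = np.asarray(boundary_disp, float)
    n = len(mesh.nodes)
    pairs = np.vstack([
        mesh.tets[:, [0, 1]], mesh.tets[:, [0, 2]], mesh.tets[:, [0, 3]],
        mesh.tets[:, [1, 2]], mesh.tets[:, [1, 3]], mesh.tets[:, [2, 3]],
    ])
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    i, j = pairs[:, 0], pairs[:, 1]
    w = np.ones(len(pairs))
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([j, i, i, j])
    data = np.concatenate([-w, -w, w, w])
    L = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()

    fixed = np.zeros(n, bool)
    fixed[boundary_nodes] = True
    free = np.flatnonzero(~fixed)
    u = np.zeros((n, 3))
    u[boundary_nodes] = boundary_disp
    if len(free):
        Lff = L[free][:, free].tocsc()
        rhs = -L[free][:, boundary_nodes] @ boundary_disp
        u[free] = spla.splu(Lff).solve(np.asarray(rhs))
    moved = VolumeMesh(
        nodes=mesh.nodes + u,
        tets=mesh.tets.copy(),
        boundary_tris=mesh.boundary_tris.copy(),
        boundary_labels=mesh.boundary_labels.copy(),
    )
    vols = moved.tet_volumes()
    if np.any(vols <= 0):
        raise MeshInversionError(np.flatnonzero(vols <= 0))
    return moved
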