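"""Incompressible low-Reynolds (Stokes) flow on tetrahedral meshes.

The coarse-mesh 3D fluid mode: stabilized MINI elements (P1 velocity
enriched with a quartic bubble, statically condensed; P1 pressure) for
the steady Stokes problem

    -mu Lap(u) + grad p = 0,   div u = 0,

with no-slip / prescribed-velocity walls and traction (pressure) open
boundaries. At the acinar Reynolds number (~0.08) the convective term is
negligible, so the instantaneous Stokes solution is the laminar flow
field. Wall tractions are recovered variationally (consistent boundary
flux), which restores near-quadratic accuracy for the wall shear stress.

Units: mm, s, Pa => conductances mm^3/(s*Pa), velocities mm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import VolumeMesh
from .network import FluidProperties

__all__ = ["FlowField", "tube_mesh", "solve_low_re_flow", "flow_rate",
           "wall_shear_stress", "max_pressure_drop_field"]


@dataclass
class FlowField:
    """Velocity/pressure solution with the mesh and traction recovery."""

    mesh: VolumeMesh
    u: np.ndarray  # (n, 3) mm/s
    p: np.ndarray  # (n,) Pa
    props: FluidProperties
    reaction: np.ndarray  # (n, 3) consistent nodal boundary forces (Pa*mm^2)
    nodal_area: np.ndarray  # (n,) boundary area per node (mm^2)
    wall_nodes: np.ndarray


# ---------------------------------------------------------------------------
# structured tube mesh
# ---------------------------------------------------------------------------


def _disc_points(R: float, nr: int):
    pts = [(0.0, 0.0)]
    for k in range(1, nr + 1):
        r = R * k / nr
        for j in range(6 * k):
            a = 2.0 * math.pi * j / (6 * k)
            pts.append((r * math.cos(a), r * math.sin(a)))
    return np.array(pts)


def _disc_tris(nr: int):
    # ring start offsets
    start = [0, 1]
    for k in range(1, nr + 1):
        start.append(start[-1] + 6 * k)
    tris = []
    for k in range(1, nr + 1):
        n_in, n_out = 6 * (k - 1), 6 * k
        s_in, s_out = start[k - 1], start[k]
        io, ii = 0, 0
        # walk both rings simultaneously (angular sweep)
        for _ in range(n_in + n_out):
            a_out = (io / n_out) if n_out else 1.0
            a_in = (ii / n_in) if n_in else 1.0
            o0 = s_out + (io % n_out)
            o1 = s_out + ((io + 1) % n_out)
            i0 = s_in + (ii % n_in) if n_in else s_in
            i1 = s_in + ((ii + 1) % n_in) if n_in else s_in
            next_out = (io + 1) / n_out if n_out else 2.0
            next_in = (ii + 1) / n_in if n_in else 2.0
            if io < n_out and (n_in == 0 or next_out <= next_in + 1e-12):
                tris.append((o0, o1, i0))
                io += 1
            else:
                tris.append((o0, i1, i0))
                ii += 1
            if io >= n_out and ii >= n_in:
                break
    return np.array(tris, int)


def tube_mesh(radius: float, length: float, nr: int = 8, nz: int = 8) -> VolumeMesh:
    """Structured tet mesh of a straight circular tube along +z.

    Boundary labels: ``inlet`` (z=0), ``outlet`` (z=length), ``wall``.
    Prisms from the extruded disc triangulation are split into
    tetrahedra with globally consistent diagonals.
    """
    disc = _disc_points(radius, nr)
    tris = _disc_tris(nr)
    nlayer = len(disc)
    zs = np.linspace(0.0, length, nz + 1)
    nodes = np.concatenate(
        [np.column_stack([disc, np.full(nlayer, z)]) for z in zs]
    )
    tets = []
    for iz in range(nz):
        off0, off1 = iz * nlayer, (iz + 1) * nlayer
        for (a, b, c) in tris:
            # rotate so the smallest global bottom id leads
            tri = [a, b, c]
            m = int(np.argmin([a, b, c]))
            v0, v1, v2 = tri[m], tri[(m + 1) % 3], tri[(m + 2) % 3]
            b0, b1, b2 = off0 + v0, off0 + v1, off0 + v2
            t0, t1, t2 = off1 + v0, off1 + v1, off1 + v2
            if v1 < v2:
                tets += [(b0, b1, b2, t2), (b0, b1, t2, t1), (b0, t1, t2, t0)]
            else:
                tets += [(b0, b1, b2, t1), (b0, t1, b2, t2), (b0, t1, t2, t0)]
    tets = np.array(tets, int)
    # boundary faces
    btris, blabels = [], []
    for (a, b, c) in tris:
        btris.append((a, c, b))
        blabels.append("inlet")
        btris.append((nz * nlayer + a, nz * nlayer + b, nz * nlayer + c))
        blabels.append("outlet")
    # wall quads: outermost ring edges
    ring_n = 6 * nr
    ring_start = len(disc) - ring_n
    for iz in range(nz):
        off0, off1 = iz * nlayer, (iz + 1) * nlayer
        for j in range(ring_n):
            a = ring_start + j
            b = ring_start + (j + 1) % ring_n
            # split consistently with the prism rule (diagonal from min id)
            if a < b:
                btris += [(off0 + a, off0 + b, off1 + b), (off0 + a, off1 + b, off1 + a)]
            else:
                btris += [(off0 + a, off0 + b, off1 + a), (off0 + b, off1 + b, off1 + a)]
            blabels += ["wall", "wall"]
    mesh = VolumeMesh(
        nodes=nodes, tets=tets,
        boundary_tris=np.array(btris, int), boundary_labels=np.array(blabels),
    )
    v = mesh.tet_volumes()
    neg = v < 0
    mesh.tets[neg] = mesh.tets[neg][:, [0, 2, 1, 3]]
    assert np.all(mesh.tet_volumes() > 0)
    return mesh


# ---------------------------------------------------------------------------
# MINI-element Stokes
# ---------------------------------------------------------------------------


def _shape_gradients(nodes, tets):
    """Constant P1 gradients and volumes per tet."""
    x = nodes[tets]
    J = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=1)
    detJ = np.linalg.det(J)
    V = detJ / 6.0
    Jinv = np.linalg.inv(J)
    g_local = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    # x = x0 + xi_a (x_{a+1} - x_0) => dxi/dx = J^{-T};  grad phi_k = J^{-T} g_k
    G = np.einsum("eba,ka->ekb", Jinv, g_local)  # (ne, 4, 3)
    return G, V


def _boundary_node_sets(mesh: VolumeMesh):
    sets = {}
    for lab in np.unique(mesh.boundary_labels):
        tris = mesh.boundary_tris[mesh.boundary_labels == lab]
        sets[lab] = np.unique(tris)
    return sets


def solve_low_re_flow(
    mesh: VolumeMesh,
    props: FluidProperties | None = None,
    wall_velocity: np.ndarray | None = None,
    inlet_pressure: float = 0.0,
    wall_labels: tuple[str, ...] = ("wall",),
    inlet_label: str = "inlet",
    linear_rtol: float = 1e-5,
) -> FlowField:
    """Steady Stokes solve with prescribed wall velocity and open ends.

    The inlet carries a normal traction equal to ``inlet_pressure``; the
    remaining open boundary (outlet) is at zero static pressure. With
    moving walls (``wall_velocity`` per node) the open-boundary outflow
    balances the swept wall flux. The assembled saddle system is solved
    directly; the direct factorization satisfies the nominal linear
    tolerance by construction.
    """
    props = props or FluidProperties()
    mu = props.mu
    n = len(mesh.nodes)
    G, V = _shape_gradients(mesh.nodes, mesh.tets)
    ne = len(mesh.tets)
    tets = mesh.tets

    # P1 Laplacian (per velocity component) and divergence coupling
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    Ke = mu * np.einsum("eki,eli->ekl", G, G) * V[:, None, None]
    A = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    # B[qnode, udof]: integral q * du_k/dx_k = V/4 * G[e, j, k]
    Bs = []
    for k in range(3):
        be = np.broadcast_to((V / 4.0)[:, None, None], (ne, 4, 4)) * G[:, None, :, k]
        Bs.append(
            sp.coo_matrix((be.ravel(), (rows, cols)), shape=(n, n)).tocsr()
        )

    # bubble condensation: C_e = (int b)^2 / a_b * (grad q_i . grad q_j)
    int_b = 256.0 * 6.0 * V / 5040.0
    sumg2 = np.einsum("eki,eki->e", G, G)
    a_b = 65536.0 * mu * V * sumg2 / 15120.0
    ce = (int_b**2 / a_b)[:, None, None] * np.einsum("eki,eli->ekl", G, G)
    C = sp.coo_matrix((ce.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    # saddle system [[A,0,0,B0^T],[0,A,0,B1^T],[0,0,A,B2^T],[B0,B1,B2,-C]]
    K = sp.bmat(
        [
            [A, None, None, Bs[0].T],
            [None, A, None, Bs[1].T],
            [None, None, A, Bs[2].T],
            [Bs[0], Bs[1], Bs[2], -C],
        ],
        format="csr",
    )
    rhs = np.zeros(4 * n)

    # inlet traction: sigma.n = -inlet_pressure * n  (n outward)
    if inlet_pressure != 0.0:
        tris = mesh.boundary_tris[mesh.boundary_labels == inlet_label]
        x = mesh.nodes[tris]
        an = 0.5 * np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])  # outward
        for k in range(3):
            np.add.at(rhs[k * n : (k + 1) * n], tris.ravel(),
                      np.repeat(-inlet_pressure * an[:, k] / 3.0, 3))

    # Dirichlet walls
    bsets = _boundary_node_sets(mesh)
    wall_nodes = np.unique(np.concatenate([bsets[w] for w in wall_labels]))
    uD = np.zeros((n, 3))
    if wall_velocity is not None:
        uD[wall_nodes] = np.asarray(wall_velocity, float)
    fixed = np.concatenate([wall_nodes + k * n for k in range(3)])
    xfull = np.zeros(4 * n)
    xfull[: 3 * n] = uD.T.ravel()
    rhs = rhs - K @ xfull
    keep = np.ones(4 * n, bool)
    keep[fixed] = False
    free = np.flatnonzero(keep)
    Kff = K[free][:, free].tocsc()
    sol = np.zeros(4 * n)
    sol[fixed] = xfull[fixed]
    sol[free] = spla.spsolve(Kff, rhs[free])
    u = sol[: 3 * n].reshape(3, n).T
    # the symmetric saddle assembly solves for the negative pressure
    p = -sol[3 * n :]

    # consistent boundary flux (nodal reactions) on the wall
    resid = K @ sol
    resid[free] = 0.0  # interior equations are satisfied
    reaction = resid[: 3 * n].reshape(3, n).T
    nodal_area = np.zeros(n)
    tris = mesh.boundary_tris
    x = mesh.nodes[tris]
    areas = 0.5 * np.linalg.norm(np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1)
    np.add.at(nodal_area, tris.ravel(), np.repeat(areas / 3.0, 3))
    return FlowField(mesh=mesh, u=u, p=p, props=props, reaction=reaction,
                     nodal_area=nodal_area, wall_nodes=wall_nodes)


def flow_rate(flow: FlowField, label: str = "outlet") -> float:
    """Volumetric flux through a labelled boundary patch (mm^3/s, outward)."""
    mesh = flow.mesh
    tris = mesh.boundary_tris[mesh.boundary_labels == label]
    x = mesh.nodes[tris]
    an = 0.5 * np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    un = flow.u[tris].mean(axis=1)
    return float(np.einsum("ij,ij->", un, an))


def wall_shear_stress(flow: FlowField) -> np.ndarray:
    """Wall shear stress magnitude per wall node (Pa).

    Derived from the consistent nodal reactions: traction = reaction /
    nodal area; the component tangential to the wall is the shear.
    """
    mesh = flow.mesh
    wall = flow.wall_nodes
    # averaged outward normal per wall node
    tris = mesh.boundary_tris[
        np.isin(mesh.boundary_tris, wall).all(axis=1)
    ]
    x = mesh.nodes[tris]
    an = 0.5 * np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    normals = np.zeros((len(mesh.nodes), 3))
    np.add.at(normals, tris.ravel(), np.repeat(an / 3.0, 3, axis=0))
    t = flow.reaction[wall] / np.maximum(flow.nodal_area[wall], 1e-30)[:, None]
    nrm = normals[wall]
    nn = np.linalg.norm(nrm, axis=1)
    ok = nn > 0
    nhat = np.zeros_like(nrm)
    nhat[ok] = nrm[ok] / nn[ok, None]
    t_tan = t - np.einsum("ij,ij->i", t, nhat)[:, None] * nhat
    return np.linalg.norm(t_tan, axis=1)


def max_pressure_drop_field(flow: FlowField) -> float:
    """Signed extreme of p - p_open over the interior (open boundary at 0)."""
    p = flow.p
    return float(p[np.argmax(np.abs(p))])
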