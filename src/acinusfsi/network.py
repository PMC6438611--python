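"""Reduced duct-network airflow: Poiseuille/Sampson impedances at Re << 1.

At acinar Reynolds numbers (~0.08) the airflow is viscous and
instantaneous: the pressure field solves a Kirchhoff problem on the graph
of air compartments. Each opened interconnecting face is a thin-walled
orifice (Sampson resistance 3*mu/r^3); the lumen segments on both sides
contribute Hagen-Poiseuille resistance with the compartment's
volume-equivalent radius. Compartment wall motion enters as volume
sources dV/dt; the mouth node is held at zero (open-boundary) pressure.

Units: mm, s, Pa; flows mm^3/s; conductances mm^3/(s*Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "FluidProperties",
    "DuctNetwork",
    "duct_network_flow",
    "network_from_geometry",
    "wall_shear_stress",
    "peak_velocity",
    "reynolds_number",
    "max_pressure_drop",
]


@dataclass(frozen=True)
class FluidProperties:
    """Air at 37 C, ~100% humidity (alveolar conditions)."""

    rho: float = 1.145  # kg/m^3
    mu: float = 1.86e-5  # Pa*s

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("fluid properties must be positive")


@dataclass
class DuctNetwork:
    """Graph of air compartments with lumped viscous conductances.

    ``edges[k] = (i, j)`` connects nodes i, j with conductance ``g[k]``;
    node 0 is the external (mouth) reference at zero pressure. ``r_orifice``
    and ``r_duct`` per edge support wall-shear and velocity estimates.
    """

    n_nodes: int
    edges: np.ndarray  # (ne, 2) int
    g: np.ndarray  # (ne,) conductance
    r_orifice: np.ndarray
    r_duct: np.ndarray
    props: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self):
        if np.any(self.g <= 0):
            raise ValueError("conductances must be positive")
        # connectivity from the reference node
        adj = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        seen = {0}
        stack = [0]
        while stack:
            for k in adj[stack.pop()]:
                if k not in seen:
                    seen.add(k)
                    stack.append(k)
        if len(seen) != self.n_nodes:
            missing = sorted(set(range(self.n_nodes)) - seen)
            raise ValueError(f"network nodes disconnected from reference: {missing}")

    def laplacian(self) -> sp.csc_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        n = self.n_nodes
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        data = np.concatenate([-self.g, -self.g, self.g, self.g])
        return sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsc()


def duct_network_flow(
    network: DuctNetwork, dVdt: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Node pressures and edge flows for given compartment volume rates.

    ``dVdt[i]`` is the rate of volume gain of interior node i+1 (node 0 is
    the zero-pressure reference; its net outflow balances the total by
    conservation). Returns (pressures (n,), edge flows (ne,)) where edge
    flow is positive from ``edges[k,0]`` toward ``edges[k,1]``.
    """
    dVdt = np.asarray(dVdt, float)
    if len(dVdt) != network.n_nodes - 1:
        raise ValueError("dVdt must have one entry per interior node")
    L = network.laplacian()
    rhs = -np.concatenate([[0.0], dVdt])
    # ground node 0: solve reduced SPD system
    Lr = L[1:, 1:]
    p = np.zeros(network.n_nodes)
    p[1:] = spla.spsolve(Lr.tocsc(), rhs[1:])
    i, j = network.edges[:, 0], network.edges[:, 1]
    q = network.g * (p[i] - p[j])
    return p, q


def network_from_geometry(geom, props: FluidProperties | None = None) -> DuctNetwork:
    """Lumped network of the acinus: node 0 = outside world at the mouth.

    Interior node k (k>=1) is lattice cell k-1. Each opened face
    contributes a Sampson orifice in series with the Poiseuille lumen
    segments of the two adjoining compartments.
    """
    props = props or FluidProperties()
    mu = props.mu
    ncell = len(geom.cell_volumes)
    r_cell = (3.0 * geom.cell_volumes / (4.0 * np.pi)) ** (1.0 / 3.0)

    edges, gs, r_or, r_du = [], [], [], []

    def series_resistance(r_o, segments):
        R = 3.0 * mu / r_o**3  # thin-wall orifice (Sampson)
        for (L, r) in segments:
            R += 8.0 * mu * L / (np.pi * r**4)
        return R

    for (i, j, _area, r, L) in geom.openings:
        Ri = series_resistance(r, [(L / 2.0, r_cell[i]), (L / 2.0, r_cell[j])])
        edges.append((i + 1, j + 1))
        gs.append(1.0 / Ri)
        r_or.append(r)
        r_du.append(0.5 * (r_cell[i] + r_cell[j]))
    # mouth edge: external reference -> parent duct cell
    rm = np.sqrt(geom.mouth_area / np.pi)
    Rm = series_resistance(rm, [(geom.mouth_length, r_cell[geom.mouth[0]])])
    edges.append((0, geom.mouth[0] + 1))
    gs.append(1.0 / Rm)
    r_or.append(rm)
    r_du.append(r_cell[geom.mouth[0]])
    return DuctNetwork(
        n_nodes=ncell + 1,
        edges=np.array(edges, int),
        g=np.array(gs, float),
        r_orifice=np.array(r_or, float),
        r_duct=np.array(r_du, float),
        props=props,
    )


def wall_shear_stress(network: DuctNetwork, q: np.ndarray) -> np.ndarray:
    """Poiseuille wall shear stress per edge: tau = 4 mu |Q| / (pi r^3).

    Evaluated with the orifice radius (the narrowest section, where the
    shear peaks).
    """
    return 4.0 * network.props.mu * np.abs(q) / (np.pi * network.r_orifice**3)


def peak_velocity(network: DuctNetwork, q: np.ndarray) -> float:
    """Maximum centreline velocity (mm/s): 2 Q / (pi r^2) over edges."""
    return float(np.max(2.0 * np.abs(q) / (np.pi * network.r_orifice**2)))


def reynolds_number(u_max_mm_s: float, L_mm: float = 1.0,
                    props: FluidProperties | None = None) -> float:
    """Re = rho u L / mu with the 1 mm alveolar-sac length scale.

    ``u_max_mm_s`` in mm/s and ``L_mm`` in mm are converted to SI.
    """
    props = props or FluidProperties()
    return props.rho * (u_max_mm_s * 1e-3) * (L_mm * 1e-3) / props.mu


def max_pressure_drop(p_history: np.ndarray) -> float:
    """Signed extreme of the interior-to-mouth pressure drop over a cycle.

    ``p_history``: (nt, n_interior) node pressures relative to the zero
    open-boundary pressure. The drop is negative during inspiration (air
    drawn in) and positive during expiration; the value returned is the
    signed entry of largest magnitude.
    """
    p_history = np.atleast_2d(np.asarray(p_history, float))
    if p_history.size == 0:
        return 0.0
    flat = p_history.ravel()
    return float(flat[np.argmax(np.abs(flat))])
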