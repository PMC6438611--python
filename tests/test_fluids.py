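"""Fluid modes: duct network (Kirchhoff/Poiseuille) and 3D Stokes."""

import numpy as np
import pytest

from acinusfsi.network import (
    DuctNetwork,
    FluidProperties,
    duct_network_flow,
    max_pressure_drop,
    network_from_geometry,
    peak_velocity,
    reynolds_number,
    wall_shear_stress,
)
from acinusfsi.stokes import (
    flow_rate,
    max_pressure_drop_field,
    solve_low_re_flow,
    tube_mesh,
    wall_shear_stress as wss_3d,
)


@pytest.fixture(scope="module")
def props():
    return FluidProperties()


class TestNetwork:
    def test_single_edge_ohm(self, props):
        g = 2.5
        net = DuctNetwork(
            n_nodes=2, edges=np.array([[0, 1]]), g=np.array([g]),
            r_orifice=np.array([0.1]), r_duct=np.array([0.1]), props=props,
        )
        p, q = duct_network_flow(net, np.array([0.05]))
        assert q[0] == pytest.approx(0.05)  # flow 0 -> 1 feeds the source
        assert p[1] == pytest.approx(-0.05 / g)

    def test_symmetric_tree_equal_branches(self, props):
        # 0 - 1, then 1 - 2 and 1 - 3 with equal conductances and sources
        net = DuctNetwork(
            n_nodes=4,
            edges=np.array([[0, 1], [1, 2], [1, 3]]),
            g=np.array([1.0, 2.0, 2.0]),
            r_orifice=np.full(3, 0.1), r_duct=np.full(3, 0.1), props=props,
        )
        p, q = duct_network_flow(net, np.array([0.0, 0.01, 0.01]))
        assert q[1] == pytest.approx(q[2])
        assert p[2] == pytest.approx(p[3])
        assert q[0] == pytest.approx(0.02)

    def test_disconnected_node_rejected(self, props):
        with pytest.raises(ValueError, match="disconnected"):
            DuctNetwork(
                n_nodes=3, edges=np.array([[0, 1]]), g=np.array([1.0]),
                r_orifice=np.array([0.1]), r_duct=np.array([0.1]), props=props,
            )

    def test_network_matches_stokes_on_a_tube(self, props):
        """The lumped Poiseuille conductance agrees with the 3D solve."""
        R, L, dp = 0.1, 1.0, 1.0
        mesh = tube_mesh(R, L, nr=8, nz=8)
        f = solve_low_re_flow(mesh, props=props, inlet_pressure=dp)
        Q3d = flow_rate(f, "outlet")
        g = np.pi * R**4 / (8 * props.mu * L)
        assert Q3d == pytest.approx(g * dp, rel=0.10)

    def test_acinus_network_mass_conservation(self, healthy_geom, props):
        net = network_from_geometry(healthy_geom, props)
        rng = np.random.default_rng(3)
        dVdt = rng.standard_normal(net.n_nodes - 1) * 1e-3
        p, q = duct_network_flow(net, dVdt)
        # mouth edge carries the total source flow (conservation)
        assert q[-1] == pytest.approx(dVdt.sum(), rel=1e-10)

    def test_wall_shear_and_velocity_scalings(self, props):
        net = DuctNetwork(
            n_nodes=2, edges=np.array([[0, 1]]), g=np.array([1.0]),
            r_orifice=np.array([0.1]), r_duct=np.array([0.1]), props=props,
        )
        q = np.array([0.05])
        tau = wall_shear_stress(net, q)
        assert tau[0] == pytest.approx(4 * props.mu * 0.05 / (np.pi * 0.1**3))
        assert peak_velocity(net, q) == pytest.approx(2 * 0.05 / (np.pi * 0.01))

    def test_reynolds_number_arithmetic(self, props):
        # u = 1 mm/s over L = 1 mm in body-temperature air
        assert reynolds_number(1.0, 1.0, props) == pytest.approx(
            1.145 * 1e-3 * 1e-3 / 1.86e-5, rel=1e-12
        )

    def test_max_pressure_drop_signed_extreme(self):
        hist = np.array([[0.1, -0.3], [0.2, -0.1]])
        assert max_pressure_drop(hist) == -0.3
        assert max_pressure_drop(np.zeros((3, 2))) == 0.0


class TestStokes:
    def test_zero_forcing_zero_flow(self, props):
        mesh = tube_mesh(0.1, 0.5, nr=4, nz=4)
        f = solve_low_re_flow(mesh, props=props, inlet_pressure=0.0)
        assert np.abs(f.u).max() < 1e-12
        assert np.abs(f.p).max() < 1e-12

    def test_poiseuille_flow_rate(self, props):
        """Q = pi R^4 dp / (8 mu L) within 3%."""
        R, L, dp = 0.1, 1.0, 1.0
        mesh = tube_mesh(R, L, nr=6, nz=6)
        f = solve_low_re_flow(mesh, props=props, inlet_pressure=dp)
        Q = flow_rate(f, "outlet")
        Qex = np.pi * R**4 * dp / (8 * props.mu * L)
        assert Q == pytest.approx(Qex, rel=0.03)
        # inlet inflow balances outlet outflow (mass conservation)
        assert flow_rate(f, "inlet") == pytest.approx(-Q, rel=0.01)
        # interior pressure extreme is the driving pressure (outlet at 0)
        assert max_pressure_drop_field(f) == pytest.approx(dp, rel=0.02)

    def test_grid_convergence_monotone(self, props):
        """Poiseuille error decreases monotonically under refinement."""
        R, L, dp = 0.1, 1.0, 1.0
        Qex = np.pi * R**4 * dp / (8 * props.mu * L)
        errs = []
        for nr, nz in ((4, 4), (6, 6), (8, 8)):
            f = solve_low_re_flow(tube_mesh(R, L, nr=nr, nz=nz), props=props,
                                  inlet_pressure=dp)
            errs.append(abs(flow_rate(f, "outlet") / Qex - 1))
        assert errs[0] > errs[1] > errs[2]

    def test_stokes_linearity(self, props):
        """Doubling the driving pressure exactly doubles the flow field."""
        mesh = tube_mesh(0.1, 0.5, nr=4, nz=4)
        f1 = solve_low_re_flow(mesh, props=props, inlet_pressure=1.0)
        f2 = solve_low_re_flow(mesh, props=props, inlet_pressure=2.0)
        assert np.allclose(f2.u, 2 * f1.u, rtol=1e-9, atol=1e-12)

    def test_wall_shear_poiseuille(self, props):
        """tau_w = 4 mu Q / (pi R^3) within 5% away from the tube ends."""
        R, L, dp = 0.1, 1.0, 1.0
        mesh = tube_mesh(R, L, nr=6, nz=8)
        f = solve_low_re_flow(mesh, props=props, inlet_pressure=dp)
        tau = wss_3d(f)
        z = mesh.nodes[f.wall_nodes][:, 2]
        mid = (z > 0.25 * L) & (z < 0.75 * L)
        Q = flow_rate(f, "outlet")
        tau_ex = 4 * props.mu * Q / (np.pi * R**3)
        assert tau[mid].mean() == pytest.approx(tau_ex, rel=0.05)

    def test_moving_wall_mass_balance(self, props):
        """Uniform radial wall motion: open-boundary outflow = swept flux."""
        R, L = 0.1, 0.5
        mesh = tube_mesh(R, L, nr=6, nz=6)
        r = np.linalg.norm(mesh.nodes[:, :2], axis=1)
        vr = 0.5  # mm/s radial expansion at the wall
        wall = np.unique(
            mesh.boundary_tris[mesh.boundary_labels == "wall"]
        )
        wall_vel = np.zeros((len(wall), 3))
        wall_vel[:, 0] = vr * mesh.nodes[wall, 0] / r[wall]
        wall_vel[:, 1] = vr * mesh.nodes[wall, 1] / r[wall]
        f = solve_low_re_flow(mesh, props=props, wall_velocity=wall_vel)
        Qout = flow_rate(f, "outlet") + flow_rate(f, "inlet")
        # discrete swept flux: integral of the prescribed wall velocity over
        # the discrete wall surface (the quantity the solver conserves)
        wtris = mesh.boundary_tris[mesh.boundary_labels == "wall"]
        x = mesh.nodes[wtris]
        an = 0.5 * np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
        swept = -float(np.einsum("ij,ij->", f.u[wtris].mean(axis=1), an))
        assert swept == pytest.approx(-2 * np.pi * R * L * vr, rel=0.01)
        assert Qout == pytest.approx(swept, rel=0.005)
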