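"""Acinus geometry: truncated octahedra, calibration, scenarios, meshes."""

import math

import numpy as np
import pytest

from acinusfsi.geometry import (
    AcinusTopology,
    GeometryError,
    apply_scenario,
    assemble_acinus,
    build_geometry,
    generate_meshes,
    lumen_volume,
    perturb_scenario,
    scenario_presets,
    truncated_octahedron,
)
from acinusfsi.materials import InvalidParameterError
from acinusfsi.membrane import enclosed_volume


class TestTruncatedOctahedron:
    def test_closed_form_volume(self):
        cell = truncated_octahedron(1.0)
        assert cell.volume == pytest.approx(8 * math.sqrt(2), rel=1e-10)

    def test_cubic_scaling(self):
        assert truncated_octahedron(0.5).volume == pytest.approx(
            8 * math.sqrt(2) * 0.125, rel=1e-10
        )

    def test_topology(self):
        cell = truncated_octahedron(2.0, center=(1.0, -2.0, 0.5))
        assert len(cell.vertices) == 24
        assert len(cell.faces) == 14
        sizes = sorted(len(f) for f in cell.faces)
        assert sizes == [4] * 6 + [6] * 8
        assert cell.euler_characteristic == 2

    def test_faces_planar_and_centered(self):
        cell = truncated_octahedron(1.0, center=(3.0, 0.0, 0.0))
        assert np.allclose(cell.vertices.mean(axis=0), [3, 0, 0])
        for f in cell.faces:
            pts = cell.vertices[list(f)]
            c = pts.mean(axis=0)
            n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            n /= np.linalg.norm(n)
            assert np.abs((pts - c) @ n).max() < 1e-12

    def test_invalid_edge_length(self):
        with pytest.raises(InvalidParameterError):
            truncated_octahedron(-1.0)


class TestPresets:
    def test_tabulated_rows(self):
        p = scenario_presets()
        assert p["healthy"].E == 35714.0
        assert p["healthy"].primary_thickness == 0.025
        assert p["healthy"].target_resting_volume == 0.512
        assert p["NSIP"].primary_thickness == p["NSIP"].secondary_thickness == 0.050
        assert p["NSIP"].target_resting_volume == 0.493
        assert p["IPF"].primary_thickness == 0.050
        assert p["IPF"].secondary_thickness == 0.025
        assert p["IPF"].target_resting_volume == 0.465
        assert all(s.nu == 0.42 for s in p.values())


class TestAssembly:
    def test_topology_layout(self):
        centers, duct_ids, duct_edges, mouth = AcinusTopology().build_cells()
        assert len(centers) == 29  # 1 parent + 2x(sac duct, sac end) + 24 alveoli
        assert len(set(map(tuple, centers))) == 29
        assert len(duct_edges) == 28  # spanning tree of the lumen
        # every alveolus is opened toward exactly one duct/sac cell
        from collections import Counter

        deg = Counter()
        for i, j in duct_edges:
            deg[i] += 1
            deg[j] += 1
        leaves = [k for k, v in deg.items() if v == 1]
        assert len(leaves) == 24

    def test_calibrated_resting_volumes(self):
        """Calibration hits the tabulated resting volumes within 1%."""
        for name, target in (("healthy", 0.512), ("NSIP", 0.493), ("IPF", 0.465)):
            g = build_geometry(name, envelope_level=0)
            assert lumen_volume(g) == pytest.approx(target, rel=0.01)

    def test_volume_conservation_lumen_plus_tissue(self, healthy_geom):
        """Lumen + tissue fills the lattice envelope exactly."""
        g = healthy_geom
        assert g.lumen_volume + g.tissue_volume == pytest.approx(
            g.total_volume, rel=1e-9
        )

    def test_cubic_scaling_of_volumes(self):
        topo = AcinusTopology()
        sc = scenario_presets()["healthy"]
        g1 = assemble_acinus(topo, 0.12, scenario=sc, envelope_level=0)
        # thickness offsets are absolute, so compare against zero-thickness
        # closed form: total lattice volume scales exactly as a^3
        g2 = assemble_acinus(topo, 0.24, scenario=sc, envelope_level=0)
        assert g2.total_volume / g1.total_volume == pytest.approx(8.0, rel=1e-12)

    def test_voxel_volume_oracle(self, healthy_geom):
        """Divergence-theorem lumen volume agrees with a voxel count to 2%."""
        g = healthy_geom
        u = g.edge_length / math.sqrt(2.0)
        lo = g.centers_mm.min(axis=0) - 3 * u
        hi = g.centers_mm.max(axis=0) + 3 * u
        n = 70
        axes = [np.linspace(lo[k], hi[k], n) for k in range(3)]
        X = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        voxel = np.prod((hi - lo) / (n - 1))
        from acinusfsi.geometry import _FACE_DIRS, _face_offsets

        nrm = _FACE_DIRS / np.linalg.norm(_FACE_DIRS, axis=1)[:, None]
        base = np.where(
            np.abs(_FACE_DIRS).sum(axis=1) == 1, 2.0 * u, math.sqrt(3.0) * u
        )
        inside = np.zeros(len(X), bool)
        for ci in range(len(g.centers_mm)):
            d = base - _face_offsets(g.septa, ci)
            y = X - g.centers_mm[ci]
            inside |= np.all(y @ nrm.T <= d + 1e-12, axis=1)
        vox_vol = inside.sum() * voxel
        assert vox_vol == pytest.approx(g.lumen_volume, rel=0.02)

    def test_apply_scenario_idempotent_for_healthy(self, healthy_geom):
        g2 = apply_scenario(healthy_geom, healthy_geom.scenario)
        assert g2.edge_length == pytest.approx(healthy_geom.edge_length, rel=1e-9)
        assert g2.lumen_volume == pytest.approx(healthy_geom.lumen_volume, rel=1e-9)

    def test_apply_scenario_thickens_and_recalibrates(self, healthy_geom):
        nsip = apply_scenario(healthy_geom, scenario_presets()["NSIP"])
        assert nsip.lumen_volume == pytest.approx(0.493, rel=0.01)
        assert nsip.edge_length > healthy_geom.edge_length
        # thickening narrows the duct openings despite the rescale
        r_h = np.sqrt(healthy_geom.mouth_area / np.pi)
        r_n = np.sqrt(nsip.mouth_area / np.pi)
        assert r_n < r_h

    def test_overthickening_raises(self):
        topo = AcinusTopology()
        from acinusfsi.geometry import DiseaseScenario

        sc = DiseaseScenario("bad", 0.2, 0.2, 35714.0, 0.42, 0.512)
        with pytest.raises(GeometryError):
            assemble_acinus(topo, 0.09, scenario=sc, envelope_level=0)

    def test_shell_classes_and_ring(self, healthy_geom):
        sh = healthy_geom.shell
        assert set(np.unique(sh.labels)) == {"primary", "secondary"}
        assert len(sh.ring) > 0
        assert np.all(sh.thickness > 0)
        # outer surface encloses the lattice volume (tissue + lumen)
        vol = enclosed_volume(sh.nodes, sh.outer_tris(), cap=True)
        assert vol == pytest.approx(healthy_geom.total_volume, rel=1e-9)


class TestMeshes:
    def test_fluid_mesh_validity_and_volume(self, healthy_geom):
        fluid, solid = generate_meshes(healthy_geom, resolution=0)
        v = fluid.tet_volumes()
        assert np.all(v > 0)
        assert v.sum() == pytest.approx(healthy_geom.lumen_volume, rel=1e-9)
        assert set(np.unique(fluid.boundary_labels)) == {"open", "septum", "wall"}
        assert len(fluid.tets) <= 5e4

    def test_refinement_preserves_volume_and_validity(self, healthy_geom):
        fluid, _ = generate_meshes(healthy_geom, resolution=1)
        v = fluid.tet_volumes()
        assert np.all(v > 0)
        assert v.sum() == pytest.approx(healthy_geom.lumen_volume, rel=1e-9)

    def test_tube_mesh_volume_converges_monotonically(self):
        """Inscribed polygonal tube volume increases toward pi R^2 L."""
        from acinusfsi.stokes import tube_mesh

        exact = math.pi * 0.1**2 * 1.0
        errs = []
        for nr in (4, 6, 8):
            v = tube_mesh(0.1, 1.0, nr=nr, nz=4).tet_volumes().sum()
            errs.append(exact - v)
        assert errs[0] > errs[1] > errs[2] > 0


class TestPerturbation:
    def test_zero_sd_is_identity(self):
        base = scenario_presets()["healthy"]
        assert perturb_scenario(base, 0.0, seed=1) is base

    def test_deterministic_given_seed(self):
        base = scenario_presets()["healthy"]
        a = perturb_scenario(base, 0.1, seed=42)
        b = perturb_scenario(base, 0.1, seed=42)
        assert a == b
        c = perturb_scenario(base, 0.1, seed=43)
        assert c != a

    def test_mean_preserving_distribution(self):
        """Monte-Carlo mean of perturbed E within 2 SE of the base value."""
        base = scenario_presets()["healthy"]
        sd = 0.1
        draws = np.array(
            [perturb_scenario(base, sd, seed=s).E for s in range(1000)]
        )
        se = base.E * sd / math.sqrt(len(draws))
        assert abs(draws.mean() - base.E) < 3 * se
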