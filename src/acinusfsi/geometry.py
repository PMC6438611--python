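"""Parameterized acinus geometry and the healthy / NSIP / IPF scenarios.

The acinus is built from truncated octahedra (14-hedra: 6 square + 8
hexagonal faces) packed space-fillingly on a body-centred-cubic lattice,
following the classic idealization of alveolar duct trees. One parent
duct cell branches into two alveolar-sac ducts; each sac carries 12
alveolar cells attached through opened interconnecting faces, giving two
duct generations and 24 alveoli. The proximal square face of the parent
duct is the single open (mouth) boundary.

Septal walls are classified as *primary* (facing the acinus exterior) or
*secondary* (partitioning the interior). Disease scenarios thicken septa
inward -- reducing the air lumen -- and the lattice edge length is then
recalibrated so the resting lumen volume matches the scenario target,
with septal thicknesses held at their tabulated absolute values.

All lengths in mm, volumes in mm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import ConvexHull, HalfspaceIntersection

from .materials import InvalidParameterError
from .meshutil import subdivide_triangles

__all__ = [
    "PolyhedralCell",
    "AcinusTopology",
    "DiseaseScenario",
    "SeptalThicknessMap",
    "AcinusGeometry",
    "SurfaceMesh",
    "VolumeMesh",
    "GeometryError",
    "truncated_octahedron",
    "assemble_acinus",
    "apply_scenario",
    "lumen_volume",
    "generate_meshes",
    "scenario_presets",
    "perturb_scenario",
    "build_geometry",
]


class GeometryError(RuntimeError):
    """Raised when a geometric construction is infeasible."""


# ---------------------------------------------------------------------------
# truncated octahedron primitive
# ---------------------------------------------------------------------------

# integer template: vertices are permutations of (0, +-1, +-2) in units of
# u = edge_length / sqrt(2); the lattice is exact in these integer coords.
def _toct_vertices_int() -> np.ndarray:
    verts = set()
    for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
        base = [0, 1, 2]
        for s1 in (1, -1):
            for s2 in (1, -1):
                v = [0, 0, 0]
                v[perm[0]] = 0
                v[perm[1]] = s1 * 1
                v[perm[2]] = s2 * 2
                verts.add(tuple(v))
    return np.array(sorted(verts), int)


_TOCT_VERTS = _toct_vertices_int()  # (24, 3)

# face normals and neighbor offsets (integer): 6 squares, 8 hexagons
_SQUARE_DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], int
)
_HEX_DIRS = np.array(
    [[sx, sy, sz] for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)], int
)


def _face_vertex_ids() -> list[np.ndarray]:
    """Vertex index loops for the 14 faces, ordered CCW about the outward normal."""
    faces = []
    for d in _SQUARE_DIRS:
        ids = np.flatnonzero(_TOCT_VERTS @ d == 2)
        faces.append(_order_loop(ids, d))
    for d in _HEX_DIRS:
        ids = np.flatnonzero(_TOCT_VERTS @ d == 3)
        faces.append(_order_loop(ids, d))
    return faces


def _order_loop(ids: np.ndarray, normal: np.ndarray) -> np.ndarray:
    pts = _TOCT_VERTS[ids].astype(float)
    c = pts.mean(axis=0)
    n = normal / np.linalg.norm(normal)
    a = pts[0] - c
    a = a - (a @ n) * n
    a /= np.linalg.norm(a)
    b = np.cross(n, a)
    ang = np.arctan2((pts - c) @ b, (pts - c) @ a)
    return ids[np.argsort(ang)]


_FACE_LOOPS = _face_vertex_ids()
_FACE_DIRS = np.vstack([_SQUARE_DIRS, _HEX_DIRS])
# neighbor center offsets per face: squares 4*dir, hexes 2*dir
_NEIGHBOR_OFFSETS = np.vstack([4 * _SQUARE_DIRS, 2 * _HEX_DIRS])


@dataclass(frozen=True)
class PolyhedralCell:
    """A single truncated-octahedron alveolar unit.

    ``vertices`` (24, 3) in mm; ``faces`` lists of vertex indices (6 squares
    then 8 hexagons); closed-form volume is 8*sqrt(2)*edge_length^3.
    """

    vertices: np.ndarray
    faces: tuple[tuple[int, ...], ...]
    edge_length: float
    center: np.ndarray

    @property
    def volume(self) -> float:
        return float(ConvexHull(self.vertices).volume)

    @property
    def euler_characteristic(self) -> int:
        nv = len(self.vertices)
        nf = len(self.faces)
        edges = set()
        for f in self.faces:
            for i in range(len(f)):
                e = (min(f[i], f[(i + 1) % len(f)]), max(f[i], f[(i + 1) % len(f)]))
                edges.add(e)
        return nv - len(edges) + nf


def truncated_octahedron(edge_length: float, center=(0.0, 0.0, 0.0)) -> PolyhedralCell:
    """The 24-vertex, 14-face truncated octahedron of given edge length."""
    if edge_length <= 0:
        raise InvalidParameterError(f"edge_length must be positive, got {edge_length}")
    u = edge_length / math.sqrt(2.0)
    verts = _TOCT_VERTS * u + np.asarray(center, float)
    faces = tuple(tuple(int(i) for i in loop) for loop in _FACE_LOOPS)
    return PolyhedralCell(
        vertices=verts, faces=faces, edge_length=edge_length,
        center=np.asarray(center, float),
    )


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcinusTopology:
    """Cell-level connectivity of the model acinus.

    Two duct generations: a parent duct cell and two sac-duct cells, each
    surrounded by ``alveoli_per_sac`` alveolar cells opened toward it. The
    nominal anatomical dimensions (duct diameter, sac length) are retained
    as metadata; the lattice edge length is set by volume calibration.
    """

    generations: int = 2
    alveoli_per_sac: int = 12
    duct_diameter: float = 0.274
    sac_length: float = 1.0

    def __post_init__(self):
        if self.generations != 2:
            raise InvalidParameterError("only two duct generations are modelled")
        if not (1 <= self.alveoli_per_sac <= 13):
            raise InvalidParameterError("alveoli_per_sac must be in [1, 13]")

    def build_cells(self):
        """Deterministic lattice layout.

        The parent duct cell (generation 1) opens into two sac-duct cells
        (generation 2); each alveolar sac is an elongated two-cell lumen
        (sac duct plus distal sac-end cell, ~1 mm long) with its 12 alveoli
        attached along the axis through opened faces.

        Returns (centers, duct_ids, duct_edges, mouth) where ``centers`` is a
        list of integer lattice coordinates, ``duct_edges`` are opened
        cell-cell connections and ``mouth`` = (cell_id, face_idx) of the open
        boundary face.
        """
        parent = (0, 0, 0)
        sac_axes = [
            [(2, 2, 2), (4, 4, 4)],
            [(2, -2, -2), (4, -4, -4)],
        ]
        centers = [parent]
        used = {parent}
        duct_edges = []
        axis_ids = []
        for axis in sac_axes:
            ids = []
            prev = 0
            for cell in axis:
                used.add(cell)
                centers.append(cell)
                ids.append(len(centers) - 1)
                duct_edges.append((prev, len(centers) - 1))
                prev = len(centers) - 1
            axis_ids.append(ids)
        for ids in axis_ids:
            placed = 0
            # hexagonal neighbours first (larger openings), then squares,
            # walking the sac axis proximal to distal
            candidates = []
            for off in 2 * _HEX_DIRS:
                for aid in ids:
                    candidates.append((aid, off))
            for off in 4 * _SQUARE_DIRS:
                for aid in ids:
                    candidates.append((aid, off))
            for aid, off in candidates:
                if placed >= self.alveoli_per_sac:
                    break
                s = centers[aid]
                cand = (s[0] + off[0], s[1] + off[1], s[2] + off[2])
                if cand in used:
                    continue
                used.add(cand)
                centers.append(cand)
                duct_edges.append((aid, len(centers) - 1))
                placed += 1
            if placed < self.alveoli_per_sac:
                raise GeometryError("could not place all alveoli on the lattice")
        # mouth: parent duct's (-1, 1, -1) hexagonal face -- proximal to both
        # sacs (symmetric under the sac-swap symmetry) and wide enough to act
        # as the duct inlet
        mouth = (0, 6 + 5)
        duct_ids = [0] + [i for ids in axis_ids for i in ids]
        return centers, duct_ids, duct_edges, mouth


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseaseScenario:
    """Septal-thickness / stiffness parameter bundle for one condition."""

    name: str
    primary_thickness: float  # mm
    secondary_thickness: float  # mm
    E: float  # Pa, equivalent small-strain modulus
    nu: float  # Poisson ratio
    target_resting_volume: float  # mm^3

    def __post_init__(self):
        if self.primary_thickness <= 0 or self.secondary_thickness <= 0:
            raise InvalidParameterError("septal thicknesses must be positive")
        if self.E <= 0:
            raise InvalidParameterError("E must be positive")
        if not (0 <= self.nu < 0.5):
            raise InvalidParameterError("nu must lie in [0, 0.5)")


def scenario_presets() -> dict[str, DiseaseScenario]:
    """The three tabulated parameter sets (healthy, NSIP, IPF)."""
    return {
        "healthy": DiseaseScenario("healthy", 0.025, 0.025, 35714.0, 0.42, 0.512),
        "NSIP": DiseaseScenario("NSIP", 0.050, 0.050, 35714.0, 0.42, 0.493),
        "IPF": DiseaseScenario("IPF", 0.050, 0.025, 35714.0, 0.42, 0.465),
    }


def perturb_scenario(
    base: DiseaseScenario, relative_sd: float, seed: int
) -> DiseaseScenario:
    """Mean-preserving log-normal perturbation of thicknesses and stiffness.

    Each of (primary thickness, secondary thickness, E) is multiplied by an
    independent factor exp(sigma*z - sigma^2/2) with
    sigma = sqrt(log(1 + relative_sd^2)), so the expectation of every
    perturbed parameter equals the base value. Deterministic given ``seed``.
    """
    if relative_sd < 0:
        raise InvalidParameterError("relative_sd must be >= 0")
    if relative_sd == 0:
        return base
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(relative_sd**2))
    f = np.exp(sigma * rng.standard_normal(3) - 0.5 * sigma**2)
    return replace(
        base,
        name=f"{base.name}-perturbed",
        primary_thickness=base.primary_thickness * f[0],
        secondary_thickness=base.secondary_thickness * f[1],
        E=base.E * f[2],
    )


# ---------------------------------------------------------------------------
# septal thickness map and cell lumina
# ---------------------------------------------------------------------------


@dataclass
class SeptalThicknessMap:
    """Per (cell, face) wall class and thickness.

    ``face_class[cell][face]`` is one of ``open`` / ``primary`` /
    ``secondary``; thickness of an open face is 0 (no tissue).
    """

    face_class: list[list[str]]
    thickness: list[np.ndarray]

    @classmethod
    def from_topology(cls, centers, duct_edges, mouth, scenario: DiseaseScenario):
        index = {c: i for i, c in enumerate(centers)}
        opened = set()
        for i, j in duct_edges:
            opened.add((i, j))
            opened.add((j, i))
        classes, thick = [], []
        for ci, c in enumerate(centers):
            row, trow = [], np.zeros(14)
            for fi in range(14):
                off = _NEIGHBOR_OFFSETS[fi]
                nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
                nj = index.get(nb)
                if (ci, fi) == mouth:
                    row.append("open")
                elif nj is None:
                    row.append("primary")
                    trow[fi] = scenario.primary_thickness
                elif (ci, nj) in opened:
                    row.append("open")
                else:
                    row.append("secondary")
                    trow[fi] = scenario.secondary_thickness
            classes.append(row)
            thick.append(trow)
        return cls(face_class=classes, thickness=thick)


def _cell_lumen(center_mm, u, offsets):
    """Half-space intersection of one cell's lumen.

    ``offsets[fi]`` is the inward plane offset in mm (0 for opened faces,
    t/2 for shared septa, t for exterior septa). Returns (vertices,
    volume, per-face polygon areas).
    """
    n = _FACE_DIRS / np.linalg.norm(_FACE_DIRS, axis=1)[:, None]
    base = np.where(np.abs(_FACE_DIRS).sum(axis=1) == 1, 2.0 * u, math.sqrt(3.0) * u)
    d = base - offsets
    if np.any(d <= 0):
        raise GeometryError("septal thickening closes a cell lumen")
    halfspaces = np.hstack([n, -d[:, None]])
    try:
        hs = HalfspaceIntersection(halfspaces, np.zeros(3))
    except Exception as exc:  # qhull failure => degenerate lumen
        raise GeometryError(f"degenerate lumen: {exc}") from exc
    verts = hs.intersections
    vol = float(ConvexHull(verts).volume)
    areas = np.zeros(14)
    for fi in range(14):
        on = np.abs(verts @ n[fi] - d[fi]) < 1e-9 * max(u, 1.0)
        pts = verts[on]
        if len(pts) >= 3:
            areas[fi] = _polygon_area(pts, n[fi])
    return verts + center_mm, vol, areas


def _polygon_area(pts: np.ndarray, normal: np.ndarray) -> float:
    a = pts[0]
    e1 = None
    for p in pts[1:]:
        v = p - a
        if np.linalg.norm(v) > 1e-14:
            e1 = v / np.linalg.norm(v)
            break
    if e1 is None:
        return 0.0
    e2 = np.cross(normal, e1)
    xy = np.stack([(pts - a) @ e1, (pts - a) @ e2], axis=1)
    hull = ConvexHull(xy)
    return float(hull.volume)  # 2-D hull "volume" is the area


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangle surface mesh with boundary-patch labels per triangle."""

    nodes: np.ndarray
    tris: np.ndarray
    labels: np.ndarray  # str per tri
    ring: np.ndarray = field(default_factory=lambda: np.array([], int))


@dataclass
class ShellMesh(SurfaceMesh):
    """Septal shell complex: every tissue face once, with ownership info.

    ``back_cell``/``front_cell`` give the compartments on either side of a
    triangle (front = -1 is the outside world); the triangle normal points
    from back to front. ``thickness`` is the local septal thickness (mm).
    """

    thickness: np.ndarray = field(default_factory=lambda: np.zeros(0))
    back_cell: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    front_cell: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def outer_tris(self) -> np.ndarray:
        """Triangles on the acinus outer boundary (primary septa)."""
        return self.tris[self.front_cell == -1]


@dataclass
class VolumeMesh:
    """Tetrahedral mesh with labelled boundary faces."""

    nodes: np.ndarray
    tets: np.ndarray
    boundary_tris: np.ndarray
    boundary_labels: np.ndarray

    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        return np.einsum(
            "ij,ij->i", x[:, 1] - x[:, 0],
            np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]),
        ) / 6.0


# ---------------------------------------------------------------------------
# the assembled geometry
# ---------------------------------------------------------------------------


@dataclass
class AcinusGeometry:
    """Calibrated acinus: lattice cells, lumen volumes, openings, envelope."""

    topology: AcinusTopology
    scenario: DiseaseScenario
    edge_length: float
    centers_int: np.ndarray  # (n_cells, 3) lattice integer coords
    centers_mm: np.ndarray
    septa: SeptalThicknessMap
    cell_volumes: np.ndarray  # lumen volume per cell (mm^3)
    openings: list  # (cell_i, cell_j, area_mm2, r_eff_mm, length_mm)
    mouth: tuple  # (cell_id, face_idx)
    mouth_area: float
    mouth_length: float
    shell: ShellMesh

    @property
    def lumen_volume(self) -> float:
        return float(self.cell_volumes.sum())

    @property
    def total_volume(self) -> float:
        """Volume enveloped by the full lattice cells (lumen + tissue)."""
        return len(self.centers_int) * 8.0 * math.sqrt(2.0) * self.edge_length**3

    @property
    def tissue_volume(self) -> float:
        return self.total_volume - self.lumen_volume

    @property
    def resting_volume(self) -> float:
        return self.lumen_volume


def lumen_volume(geom: AcinusGeometry) -> float:
    """Resting air volume of the acinus lumen (mm^3, divergence theorem)."""
    return geom.lumen_volume


def _face_offsets(septa: SeptalThicknessMap, ci: int) -> np.ndarray:
    """Inward lumen offsets: every septum is centred on its lattice
    interface (the tissue mid-surface), so each lumen face recedes by half
    the local wall thickness; opened faces carry no tissue."""
    return 0.5 * septa.thickness[ci]


def _lumen_total(u: float, centers, septa: SeptalThicknessMap, mouth) -> float:
    total = 0.0
    for ci, c in enumerate(centers):
        _, vol, _ = _cell_lumen(np.zeros(3), u, _face_offsets(septa, ci))
        total += vol
    return total


def assemble_acinus(
    topology: AcinusTopology,
    edge_length: float,
    scenario: DiseaseScenario | None = None,
    envelope_level: int = 1,
    calibrate_volume: bool = False,
) -> AcinusGeometry:
    """Build the acinus cell complex at a given lattice edge length.

    With ``calibrate_volume`` the edge length is adjusted (septal
    thicknesses held in absolute mm) until the resting lumen volume matches
    ``scenario.target_resting_volume`` to 0.1%.
    """
    if edge_length <= 0:
        raise InvalidParameterError("edge_length must be positive")
    if scenario is None:
        scenario = scenario_presets()["healthy"]
    centers, duct_ids, duct_edges, mouth = topology.build_cells()
    septa = SeptalThicknessMap.from_topology(centers, duct_edges, mouth, scenario)

    u = edge_length / math.sqrt(2.0)
    tmax = max(scenario.primary_thickness, scenario.secondary_thickness)
    if math.sqrt(3.0) * u <= tmax:
        raise GeometryError(
            f"edge_length {edge_length} mm incompatible with septal thickness {tmax} mm"
        )
    if calibrate_volume:
        target = scenario.target_resting_volume

        def f(uu):
            return _lumen_total(uu, centers, septa, mouth) - target

        lo, hi = 0.55 * u, 2.5 * u
        while f(lo) > 0:
            lo *= 0.8
        while f(hi) < 0:
            hi *= 1.25
        u = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
        edge_length = u * math.sqrt(2.0)

    centers_int = np.array(centers, int)
    centers_mm = centers_int * u
    cell_volumes = np.zeros(len(centers))
    face_areas = []
    for ci in range(len(centers)):
        _, vol, areas = _cell_lumen(centers_mm[ci], u, _face_offsets(septa, ci))
        cell_volumes[ci] = vol
        face_areas.append(areas)

    # openings: narrower of the two adjoining cross-sections governs
    index = {tuple(c): i for i, c in enumerate(centers)}
    openings = []
    for i, j in duct_edges:
        fi = _face_index(centers_int[i], centers_int[j])
        fj = _face_index(centers_int[j], centers_int[i])
        area = min(face_areas[i][fi], face_areas[j][fj])
        if area <= 0:
            raise GeometryError(f"duct opening between cells {i} and {j} closed")
        r = math.sqrt(area / math.pi)
        L = float(np.linalg.norm(centers_mm[i] - centers_mm[j]))
        openings.append((i, j, area, r, L))
    mouth_area = face_areas[mouth[0]][mouth[1]]
    # cell centre to mouth plane (hex faces sit at sqrt(3) u)
    mouth_length = (2.0 if mouth[1] < 6 else math.sqrt(3.0)) * u

    shell = _build_shell(centers_int, septa, mouth, u, level=envelope_level)
    return AcinusGeometry(
        topology=topology, scenario=scenario, edge_length=edge_length,
        centers_int=centers_int, centers_mm=centers_mm, septa=septa,
        cell_volumes=cell_volumes, openings=openings, mouth=mouth,
        mouth_area=mouth_area, mouth_length=mouth_length, shell=shell,
    )


def _face_index(ci: np.ndarray, cj: np.ndarray) -> int:
    off = cj - ci
    hits = np.flatnonzero((_NEIGHBOR_OFFSETS == off).all(axis=1))
    if len(hits) != 1:
        raise GeometryError("cells are not lattice neighbours")
    return int(hits[0])


def _build_shell(centers_int, septa, mouth, u, level) -> ShellMesh:
    """Septal shell complex: the reduced solid mode's tissue surface.

    Every tissue face (primary boundary walls and secondary interior
    septa) is fan-triangulated once at the lattice mid-surface, subdivided
    ``level`` times, and annotated with its thickness and the compartments
    on each side. Opened interconnecting faces and the mouth are holes.
    The mouth rim is the clamped ring (the acinus hangs off its feeding
    bronchiole there).
    """
    index = {tuple(c): i for i, c in enumerate(centers_int)}
    node_ids: dict[tuple, int] = {}
    nodes: list = []

    def nid(coord3):
        key = (int(round(2 * coord3[0])), int(round(2 * coord3[1])),
               int(round(2 * coord3[2])))
        idx = node_ids.get(key)
        if idx is None:
            node_ids[key] = idx = len(nodes)
            nodes.append(np.asarray(coord3, float))
        return idx

    tris, labels, thick, back, front = [], [], [], [], []
    for ci, c in enumerate(centers_int):
        for fi in range(14):
            cls = septa.face_class[ci][fi]
            if cls == "open":
                continue
            off = _NEIGHBOR_OFFSETS[fi]
            nb = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if cls == "secondary" and nb is not None and nb < ci:
                continue  # shared septum already built from the lower cell id
            loop = _FACE_LOOPS[fi]
            pts = _TOCT_VERTS[loop] + c
            cen = pts.mean(axis=0)
            idc = nid(cen)
            ids = [nid(p) for p in pts]
            t_here = septa.thickness[ci][fi]
            fcell = -1 if cls == "primary" else nb
            for k in range(len(ids)):
                tris.append((ids[k], ids[(k + 1) % len(ids)], idc))
                labels.append(cls)
                thick.append(t_here)
                back.append(ci)
                front.append(fcell)
    nodes = np.array(nodes, float) * u
    tris = np.array(tris, int)
    labels = np.array(labels)
    thick = np.array(thick, float)
    back = np.array(back, int)
    front = np.array(front, int)
    if level > 0:
        nodes, tris = subdivide_triangles(nodes, tris, levels=level)
        rep = 4**level
        labels = np.repeat(labels, rep)
        thick = np.repeat(thick, rep)
        back = np.repeat(back, rep)
        front = np.repeat(front, rep)
    ring = _mouth_ring(centers_int, mouth, node_ids, nodes, u, level)
    return ShellMesh(
        nodes=nodes, tris=tris, labels=labels, ring=ring,
        thickness=thick, back_cell=back, front_cell=front,
    )


def _mouth_ring(centers_int, mouth, node_ids, nodes, u, level) -> np.ndarray:
    """Nodes on the mouth-face rim (clamped boundary of the shell)."""
    ci, fi = mouth
    c = centers_int[ci]
    loop = _FACE_LOOPS[fi]
    pts = (_TOCT_VERTS[loop] + c).astype(float)
    ring_pts = []
    nseg = 2**level
    for k in range(len(pts)):
        a, b = pts[k], pts[(k + 1) % len(pts)]
        for s in range(nseg):
            ring_pts.append(a + (b - a) * (s / nseg))
    ring_pts = np.array(ring_pts) * u
    from scipy.spatial import cKDTree

    tree = cKDTree(nodes)
    d, idx = tree.query(ring_pts)
    if np.any(d > 1e-9 * max(u, 1.0)):
        raise GeometryError("mouth ring nodes not found on the shell")
    return np.unique(idx)


def build_geometry(
    scenario: DiseaseScenario | str,
    envelope_level: int = 1,
) -> AcinusGeometry:
    """Calibrated geometry for a preset name or an explicit scenario."""
    if isinstance(scenario, str):
        presets = scenario_presets()
        key = {k.lower(): k for k in presets}
        if scenario.lower() not in key:
            raise InvalidParameterError(f"unknown scenario {scenario!r}")
        scenario = presets[key[scenario.lower()]]
    topo = AcinusTopology()
    # start from the closed-form estimate ignoring wall offsets
    n_cells = 5 + 2 * topo.alveoli_per_sac
    a0 = (scenario.target_resting_volume / (n_cells * 8 * math.sqrt(2))) ** (1 / 3)
    return assemble_acinus(
        topo, 1.3 * a0, scenario=scenario, envelope_level=envelope_level,
        calibrate_volume=True,
    )


def apply_scenario(geom: AcinusGeometry, scenario: DiseaseScenario) -> AcinusGeometry:
    """Re-parameterize the healthy reference geometry for a disease scenario.

    Septa are thickened inward by the scenario's map and the lattice is
    rescaled so the resting lumen volume matches the scenario target
    (thicknesses held in absolute mm). Applying the geometry's own scenario
    returns an identical construction (idempotent).
    """
    return assemble_acinus(
        geom.topology, geom.edge_length, scenario=scenario,
        envelope_level=_shell_level_of(geom), calibrate_volume=True,
    )


def _shell_level_of(geom: AcinusGeometry) -> int:
    # infer the subdivision level used (4^level triangles per base fan tri)
    base = 0
    for ci in range(len(geom.centers_int)):
        for fi in range(14):
            cls = geom.septa.face_class[ci][fi]
            if cls == "open":
                continue
            if cls == "secondary":
                off = _NEIGHBOR_OFFSETS[fi]
                c = geom.centers_int[ci]
                nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
                idx = {tuple(cc): i for i, cc in enumerate(geom.centers_int)}
                if idx.get(nb, 10**9) < ci:
                    continue
            base += 4 if fi < 6 else 6
    return max(0, int(round(math.log(len(geom.shell.tris) / base, 4))))


# ---------------------------------------------------------------------------
# volume meshes
# ---------------------------------------------------------------------------


def generate_meshes(
    geom: AcinusGeometry, resolution: int = 0
) -> tuple[VolumeMesh, SurfaceMesh]:
    """Desk-scale meshes: a conforming fluid tet mesh and the solid shell.

    The fluid mesh cones every lattice face fan to its cell centre, giving
    a watertight, conforming tetrahedralization of the cell complex, then
    scales it so the mesh volume equals the calibrated lumen volume
    (a "hydraulic" mesh: exact per-cell offset lumina are non-conforming at
    shared openings and are used for all volume bookkeeping instead).
    ``resolution`` uniformly subdivides each tetrahedron 8-to-1 per level.
    The solid mesh is the envelope shell (reduced solid mode).
    """
    u = geom.edge_length / math.sqrt(2.0)
    node_ids: dict[tuple, int] = {}
    nodes: list = []

    def nid(coord3):
        key = (int(round(2 * coord3[0])), int(round(2 * coord3[1])),
               int(round(2 * coord3[2])))
        idx = node_ids.get(key)
        if idx is None:
            node_ids[key] = idx = len(nodes)
            nodes.append(np.asarray(coord3, float))
        return idx

    tets = []
    btris, blabels = [], []
    for ci, c in enumerate(geom.centers_int):
        idcell = nid(c)
        for fi in range(14):
            cls = geom.septa.face_class[ci][fi]
            is_mouth = (ci, fi) == geom.mouth
            loop = _FACE_LOOPS[fi]
            pts = _TOCT_VERTS[loop] + c
            cen = pts.mean(axis=0)
            idc = nid(cen)
            ids = [nid(p) for p in pts]
            for k in range(len(ids)):
                a, b = ids[k], ids[(k + 1) % len(ids)]
                tets.append((a, b, idc, idcell))
                if is_mouth:
                    btris.append((a, b, idc))
                    blabels.append("open")
                elif cls == "primary":
                    btris.append((a, b, idc))
                    blabels.append("wall")
                elif cls == "secondary":
                    btris.append((a, b, idc))
                    blabels.append("septum")
    nodes = np.array(nodes, float) * u
    tets = np.array(tets, int)
    # deduplicate interior tets built from both sides of opened faces
    tets = np.unique(np.sort(tets, axis=1), axis=0)
    mesh = VolumeMesh(
        nodes=nodes, tets=tets,
        boundary_tris=np.array(btris, int),
        boundary_labels=np.array(blabels),
    )
    _fix_tet_orientation(mesh)
    for _ in range(resolution):
        mesh = _subdivide_tets(mesh)
    vols = mesh.tet_volumes()
    if np.any(vols <= 0):
        bad = np.flatnonzero(vols <= 0)
        raise GeometryError(f"inverted elements after meshing: {bad[:10].tolist()}")
    scale = (geom.lumen_volume / vols.sum()) ** (1.0 / 3.0)
    c0 = mesh.nodes.mean(axis=0)
    mesh.nodes = c0 + (mesh.nodes - c0) * scale
    solid = ShellMesh(
        nodes=geom.shell.nodes.copy(), tris=geom.shell.tris.copy(),
        labels=geom.shell.labels.copy(), ring=geom.shell.ring.copy(),
        thickness=geom.shell.thickness.copy(),
        back_cell=geom.shell.back_cell.copy(),
        front_cell=geom.shell.front_cell.copy(),
    )
    return mesh, solid


def _fix_tet_orientation(mesh: VolumeMesh) -> None:
    x = mesh.nodes[mesh.tets]
    vol6 = np.einsum(
        "ij,ij->i", x[:, 1] - x[:, 0],
        np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]),
    )
    flip = vol6 < 0
    mesh.tets[flip] = mesh.tets[flip][:, [0, 2, 1, 3]]


def _subdivide_tets(mesh: VolumeMesh) -> VolumeMesh:
    """Uniform 8-to-1 red refinement of a tet mesh (shared-edge welding)."""
    nodes = [mesh.nodes]
    offset = len(mesh.nodes)
    cache: dict[tuple[int, int], int] = {}

    def mid(a, b):
        nonlocal offset
        key = (min(a, b), max(a, b))
        idx = cache.get(key)
        if idx is None:
            cache[key] = idx = offset
            nodes.append(0.5 * (mesh.nodes[a] + mesh.nodes[b])[None])
            offset += 1
        return idx

    new_tets = []
    for t in mesh.tets:
        a, b, c, d = (int(v) for v in t)
        ab, ac, ad = mid(a, b), mid(a, c), mid(a, d)
        bc, bd, cd = mid(b, c), mid(b, d), mid(c, d)
        new_tets += [
            (a, ab, ac, ad), (ab, b, bc, bd), (ac, bc, c, cd), (ad, bd, cd, d),
            (ab, ac, ad, bd), (ab, ac, bd, bc), (ac, ad, bd, cd), (ac, bc, bd, cd),
        ]
    new_btris, new_lbl = [], []
    for tri, lbl in zip(mesh.boundary_tris, mesh.boundary_labels):
        a, b, c = (int(v) for v in tri)
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_btris += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
        new_lbl += [lbl] * 4
    out = VolumeMesh(
        nodes=np.vstack(nodes), tets=np.array(new_tets, int),
        boundary_tris=np.array(new_btris, int),
        boundary_labels=np.array(new_lbl),
    )
    _fix_tet_orientation(out)
    return out
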