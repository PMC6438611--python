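"""Run configuration, scalar-history container, and mesh/field export.

Configs are YAML with a pydantic-validated schema; scalar histories go to
HDF5 with self-describing units attributes (loop data is consumed
tabularly); meshes and fields are exported as ASCII XML VTU so any
standard unstructured-grid reader can open them.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from .coupling import CouplingConfig, StateHistory
from .geometry import (
    AcinusGeometry,
    DiseaseScenario,
    SurfaceMesh,
    VolumeMesh,
    build_geometry,
    scenario_presets,
)
from .waveform import BreathingWaveform

__all__ = [
    "RunConfig",
    "RunManifest",
    "read_config",
    "write_config",
    "write_history",
    "read_history",
    "write_vtu",
]

__version__ = "0.1.0"


class WaveformConfig(BaseModel):
    p0: float = Field(244.0, gt=0, description="pleural amplitude, Pa")
    omega: float = Field(np.pi / 2.0, gt=0, description="circular frequency, 1/s")


class MaterialConfig(BaseModel):
    E: float = Field(35714.0, gt=0, description="small-strain modulus, Pa")
    nu: float = Field(0.42, description="Poisson ratio")

    @field_validator("nu")
    @classmethod
    def _nu_range(cls, v):
        if not (0.0 <= v < 0.5):
            raise ValueError("material.nu must lie in [0, 0.5)")
        return v


class ScenarioConfig(BaseModel):
    name: str = "healthy"
    primary_thickness: float | None = Field(None, gt=0)
    secondary_thickness: float | None = Field(None, gt=0)
    target_resting_volume: float | None = Field(None, gt=0)
    material: MaterialConfig = MaterialConfig()

    def to_scenario(self) -> DiseaseScenario:
        presets = {k.lower(): v for k, v in scenario_presets().items()}
        base = presets.get(self.name.lower())
        if base is None:
            if None in (
                self.primary_thickness,
                self.secondary_thickness,
                self.target_resting_volume,
            ):
                raise ValueError(
                    f"unknown scenario {self.name!r} and no explicit parameters"
                )
            base = DiseaseScenario(
                self.name, self.primary_thickness, self.secondary_thickness,
                self.material.E, self.material.nu, self.target_resting_volume,
            )
            return base
        kw = {}
        if self.primary_thickness is not None:
            kw["primary_thickness"] = self.primary_thickness
        if self.secondary_thickness is not None:
            kw["secondary_thickness"] = self.secondary_thickness
        if self.target_resting_volume is not None:
            kw["target_resting_volume"] = self.target_resting_volume
        kw["E"] = self.material.E
        kw["nu"] = self.material.nu
        from dataclasses import replace

        return replace(base, **kw)


class RunConfig(BaseModel):
    """Schema-validated, round-trippable description of one run."""

    scenario: ScenarioConfig = ScenarioConfig()
    waveform: WaveformConfig = WaveformConfig()
    dt: float = Field(0.01, gt=0, description="time step, s")
    n_cycles: int = Field(2, ge=1)
    fluid_mode: str = "network"
    solid_mode: str = "shell"
    mesh_level: int = Field(1, ge=0, le=3)
    tolerance: float = Field(1e-6, gt=0, description="FSI sub-iteration tol")
    newton_rtol: float = Field(1e-8, gt=0)
    loose_coupling: bool = False
    seed: int = 0
    output_dir: str = "results"

    def coupling_config(self) -> CouplingConfig:
        return CouplingConfig(
            dt=self.dt, n_cycles=self.n_cycles, tolerance=self.tolerance,
            loose_coupling=self.loose_coupling, fluid_mode=self.fluid_mode,
            solid_mode=self.solid_mode, envelope_level=self.mesh_level,
            newton_rtol=self.newton_rtol, seed=self.seed,
        )

    def breathing_waveform(self) -> BreathingWaveform:
        return BreathingWaveform(p0=self.waveform.p0, omega=self.waveform.omega)

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(
            json.loads(self.model_dump_json()), sort_keys=True
        )

    def content_hash(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()[:16]


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(config.canonical_yaml())


# ---------------------------------------------------------------------------
# history container (HDF5)
# ---------------------------------------------------------------------------

_HISTORY_FIELDS = {
    "t": "s",
    "volume": "mm^3",
    "flow_rate": "mm^3/s",
    "pressure_drop": "Pa",
    "p_alv": "Pa",
    "p_ip": "Pa",
    "max_wss": "Pa",
    "u_peak": "mm/s",
    "subiters": "1",
    "residual": "1",
}


def write_history(hist: StateHistory, path: str | Path) -> None:
    """Lossless scalar history to HDF5 with units attributes."""
    with h5py.File(path, "w") as fh:
        g = fh.create_group("history")
        for name, unit in _HISTORY_FIELDS.items():
            d = g.create_dataset(name, data=getattr(hist, name))
            d.attrs["units"] = unit
        g.attrs["resting_volume_mm3"] = hist.resting_volume
        g.attrs["period_s"] = hist.period
        g.attrs["peak_stress_Pa"] = hist.peak_stress
        g.attrs["scenario"] = hist.geom.scenario.name
        fh.create_dataset("config_yaml", data=_config_yaml(hist))
        if hist.final_u is not None:
            fh.create_dataset("final_displacement", data=hist.final_u).attrs[
                "units"
            ] = "mm"


def _config_yaml(hist: StateHistory) -> str:
    cfg = hist.config
    sc = hist.geom.scenario
    rc = RunConfig(
        scenario=ScenarioConfig(
            name=sc.name,
            primary_thickness=sc.primary_thickness,
            secondary_thickness=sc.secondary_thickness,
            target_resting_volume=sc.target_resting_volume,
            material=MaterialConfig(E=sc.E, nu=sc.nu),
        ),
        dt=cfg.dt, n_cycles=cfg.n_cycles, fluid_mode=cfg.fluid_mode,
        solid_mode=cfg.solid_mode, mesh_level=cfg.envelope_level,
        tolerance=cfg.tolerance, newton_rtol=cfg.newton_rtol,
        loose_coupling=cfg.loose_coupling, seed=cfg.seed,
        waveform=WaveformConfig(p0=hist.waveform.p0, omega=hist.waveform.omega),
    )
    return rc.canonical_yaml()


def read_history(path: str | Path) -> tuple[StateHistory, RunConfig]:
    """Read a stored history; returns (history, config).

    The geometry is rebuilt from the stored config so derived metrics
    (resting volume, network) are available.
    """
    with h5py.File(path, "r") as fh:
        cfg = RunConfig.model_validate(
            yaml.safe_load(fh["config_yaml"][()].decode())
        )
        geom = build_geometry(cfg.scenario.to_scenario(), cfg.mesh_level)
        hist = StateHistory(
            geom=geom, config=cfg.coupling_config(),
            waveform=cfg.breathing_waveform(),
        )
        g = fh["history"]
        for name in _HISTORY_FIELDS:
            setattr(hist, name, g[name][()])
        hist.peak_stress = float(g.attrs["peak_stress_Pa"])
        if "final_displacement" in fh:
            hist.final_u = fh["final_displacement"][()]
    return hist, cfg


# ---------------------------------------------------------------------------
# VTU export (ASCII XML unstructured grid)
# ---------------------------------------------------------------------------

_VTK_TET = 10
_VTK_TRI = 5


def write_vtu(
    mesh: VolumeMesh | SurfaceMesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Minimal ASCII VTU writer for tet volume or triangle surface meshes."""
    if isinstance(mesh, VolumeMesh):
        cells, ctype = mesh.tets, _VTK_TET
    else:
        cells, ctype = mesh.tris, _VTK_TRI
    nodes = mesh.nodes
    npts, ncell = len(nodes), len(cells)
    nn = cells.shape[1]

    def arr(a, fmt="%.10g"):
        return " ".join(fmt % v for v in np.asarray(a).ravel())

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ncell}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr(nodes),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        arr(cells, "%d"),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        arr(np.arange(1, ncell + 1) * nn, "%d"),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        arr(np.full(ncell, ctype), "%d"),
        "</DataArray>",
        "</Cells>",
    ]
    parts.append("<PointData>")
    for name, data in (point_data or {}).items():
        data = np.asarray(data, float)
        ncomp = 1 if data.ndim == 1 else data.shape[1]
        parts += [
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">',
            arr(data),
            "</DataArray>",
        ]
    parts.append("</PointData>")
    parts.append("<CellData>")
    for name, data in (cell_data or {}).items():
        data = np.asarray(data, float)
        ncomp = 1 if data.ndim == 1 else data.shape[1]
        parts += [
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">',
            arr(data),
            "</DataArray>",
        ]
    parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


class RunManifest(BaseModel):
    """Provenance record emitted once per run."""

    config_hash: str
    software_version: str = __version__
    wall_time_s: float = 0.0
    n_steps: int = 0
    max_subiters: int = 0
    mean_subiters: float = 0.0
    max_residual: float = 0.0
    outputs: dict[str, str] = {}
    created: str = ""

    @classmethod
    def from_run(cls, config: RunConfig, hist: StateHistory,
                 wall_time: float, outputs: dict[str, str]) -> "RunManifest":
        sub = hist.subiters[1:] if len(hist.subiters) > 1 else np.zeros(1)
        return cls(
            config_hash=config.content_hash(),
            wall_time_s=wall_time,
            n_steps=max(len(hist.t) - 1, 0),
            max_subiters=int(sub.max(initial=0)),
            mean_subiters=float(sub.mean()) if len(sub) else 0.0,
            max_residual=float(hist.residual.max(initial=0.0)),
            outputs=outputs,
            created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
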