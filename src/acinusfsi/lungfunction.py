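"""Physiological metrics extracted from a breathing-cycle history.

Tidal volume, acinar compliance (P-V loop slope), acinar resistance
(driving pressure over flow at peak flow), peak flows, pressure-drop
extrema, Reynolds number and the P-V / F-V loops, plus scenario
comparison tables with the healthy model as reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coupling import StateHistory
from .network import FluidProperties

__all__ = [
    "PVLoop",
    "FVLoop",
    "LungFunctionReport",
    "tidal_volume",
    "compliance",
    "acinus_resistance",
    "loops",
    "peak_flows",
    "reynolds_max",
    "max_pressure_drop",
    "compare_scenarios",
]


class IncompleteCycleError(ValueError):
    """History does not cover a full breathing cycle."""


def _last_cycle(hist: StateHistory):
    if len(hist.t) == 0:
        raise IncompleteCycleError("empty history")
    T = hist.period
    t_end = hist.t[-1]
    if t_end + 1e-9 < T:
        raise IncompleteCycleError(
            f"history covers {t_end:.3f} s < one period ({T:.3f} s)"
        )
    mask = hist.t >= t_end - T - 1e-12
    return mask


def tidal_volume(hist: StateHistory) -> float:
    """Maximum lumen volume minus resting volume on the last cycle (mm^3)."""
    m = _last_cycle(hist)
    return float(hist.volume[m].max() - hist.resting_volume)


def compliance(hist: StateHistory, pressure: str = "driving") -> float:
    """P-V loop slope (mm^3/Pa) over the inspiratory limb.

    ``pressure='driving'`` uses the magnitude of the intrapleural pressure
    (the P-V loop's pressure axis for a quiet-breathing acinus);
    ``'alveolar'`` uses the interior-to-mouth pressure drop instead, which
    for a low-Reynolds acinus is orders of magnitude smaller.
    """
    m = _last_cycle(hist)
    t, V = hist.t[m], hist.volume[m]
    if pressure == "driving":
        p = -hist.p_ip[m]
    elif pressure == "alveolar":
        p = -hist.p_alv[m]
    else:
        raise ValueError("pressure must be 'driving' or 'alveolar'")
    # inspiratory limb: from volume minimum to volume maximum
    i0, i1 = int(np.argmin(V)), int(np.argmax(V))
    if i0 > i1:
        i0, i1 = i1, i0
    ps, Vs = p[i0 : i1 + 1], V[i0 : i1 + 1]
    if ps.max() - ps.min() <= 0:
        raise ValueError("degenerate pressure range on the inspiratory limb")
    A = np.vstack([ps, np.ones_like(ps)]).T
    slope, _ = np.linalg.lstsq(A, Vs, rcond=None)[0]
    return float(slope)


def acinus_resistance(hist: StateHistory) -> float:
    """Driving pressure over airflow rate (Pa*s/mm^3) at peak inspiration.

    The pressure is the deepest interior-to-mouth drop magnitude at the
    instant of peak inspiratory flow on the last cycle.
    """
    m = _last_cycle(hist)
    Q = hist.flow_rate[m]
    drop = hist.pressure_drop[m]
    k = int(np.argmax(Q))
    if abs(Q[k]) <= 1e-12 * hist.resting_volume / hist.period:
        raise ValueError("zero flow: resistance undefined")
    return float(abs(drop[k]) / abs(Q[k]))


def max_pressure_drop(hist: StateHistory) -> float:
    """Signed extreme interior-to-mouth pressure over the last cycle (Pa).

    Negative during inspiration, positive during expiration; the signed
    value of largest magnitude is returned.
    """
    m = _last_cycle(hist)
    d = hist.pressure_drop[m]
    return float(d[np.argmax(np.abs(d))])


def peak_flows(hist: StateHistory) -> tuple[float, float]:
    """(PIF, PEF): peak inspiratory and expiratory flow magnitudes (mm^3/s)."""
    m = _last_cycle(hist)
    Q = hist.flow_rate[m]
    return float(Q.max()), float(-Q.min())


def reynolds_max(
    hist: StateHistory, L_mm: float = 1.0, props: FluidProperties | None = None
) -> float:
    """Maximum Reynolds number on the alveolar-sac length scale.

    The characteristic velocity is the peak flow rate over the nominal
    acinar-duct cross-section (the anatomical duct diameter carried by the
    topology), the conventional scale for a lumped-network model.
    """
    props = props or FluidProperties()
    pif, pef = peak_flows(hist)
    d = hist.geom.topology.duct_diameter
    u = max(pif, pef) / (math.pi * (d / 2.0) ** 2)  # mm/s
    return props.rho * (u * 1e-3) * (L_mm * 1e-3) / props.mu


@dataclass
class PVLoop:
    pressure: np.ndarray  # Pa (driving pressure magnitude)
    volume: np.ndarray  # mm^3


@dataclass
class FVLoop:
    flow: np.ndarray  # mm^3/s
    volume: np.ndarray  # mm^3


def loops(hist: StateHistory) -> tuple[PVLoop, FVLoop]:
    """Closed P-V and F-V loops over the final cycle."""
    m = _last_cycle(hist)
    return (
        PVLoop(pressure=-hist.p_ip[m].copy(), volume=hist.volume[m].copy()),
        FVLoop(flow=hist.flow_rate[m].copy(), volume=hist.volume[m].copy()),
    )


@dataclass
class LungFunctionReport:
    """Scenario-level summary of acinar mechanics and function."""

    scenario: str
    resting_volume: float  # mm^3
    tidal_volume: float  # mm^3
    relative_volume_change: float  # TV / resting
    compliance: float  # mm^3/Pa
    compliance_alveolar: float  # alternative definition (mm^3/Pa)
    resistance: float  # Pa*s/mm^3
    max_pressure_drop: float  # Pa (signed extreme)
    reynolds_max: float
    pif: float  # mm^3/s
    pef: float  # mm^3/s
    peak_stress: float  # Pa
    max_wss: float  # Pa
    dt: float = float("nan")
    n_cycles: int = 0

    @classmethod
    def from_history(cls, hist: StateHistory) -> "LungFunctionReport":
        pif, pef = peak_flows(hist)
        return cls(
            scenario=hist.geom.scenario.name,
            resting_volume=hist.resting_volume,
            tidal_volume=tidal_volume(hist),
            relative_volume_change=tidal_volume(hist) / hist.resting_volume,
            compliance=compliance(hist, "driving"),
            compliance_alveolar=compliance(hist, "alveolar"),
            resistance=acinus_resistance(hist),
            max_pressure_drop=max_pressure_drop(hist),
            reynolds_max=reynolds_max(hist),
            pif=pif,
            pef=pef,
            peak_stress=hist.peak_stress,
            max_wss=float(hist.max_wss.max(initial=0.0)),
            dt=hist.config.dt,
            n_cycles=hist.config.n_cycles,
        )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


_COMPARE_METRICS = (
    "tidal_volume",
    "compliance",
    "resistance",
    "max_pressure_drop",
    "pif",
    "max_wss",
    "peak_stress",
)


def compare_scenarios(reports: dict[str, LungFunctionReport]):
    """Percent differences of every metric against the healthy reference.

    Returns a DataFrame with one row per metric: absolute values per
    scenario, percent change of each diseased scenario versus healthy, and
    the NSIP-versus-IPF contrast (IPF as denominator) when both are
    present. Magnitudes are used for signed metrics (pressure drop).
    """
    import pandas as pd

    if "healthy" not in reports:
        raise ValueError("a 'healthy' reference report is required")
    names = list(reports)
    base = reports["healthy"]
    if any(r.dt != base.dt for r in reports.values()):
        raise ValueError("reports were produced with mismatched configs")
    def pct(val, ref):
        if ref == 0.0:
            return 0.0 if val == 0.0 else float("nan")
        return 100.0 * (val / ref - 1.0)

    rows = []
    for metric in _COMPARE_METRICS:
        row = {"metric": metric}
        for n in names:
            row[n] = abs(getattr(reports[n], metric))
        for n in names:
            if n != "healthy":
                row[f"{n}_vs_healthy_pct"] = pct(row[n], row["healthy"])
        if "NSIP" in reports and "IPF" in reports:
            row["NSIP_vs_IPF_pct"] = pct(row["NSIP"], row["IPF"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")
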