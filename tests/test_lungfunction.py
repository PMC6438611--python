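"""Lung-function metrics on synthetic histories and scenario comparison."""

import numpy as np
import pytest

from acinusfsi.coupling import CouplingConfig, StateHistory
from acinusfsi.lungfunction import (
    IncompleteCycleError,
    LungFunctionReport,
    acinus_resistance,
    compare_scenarios,
    compliance,
    loops,
    max_pressure_drop,
    peak_flows,
    tidal_volume,
)
from acinusfsi.waveform import BreathingWaveform, intrapleural_pressure


def synthetic_history(healthy_geom, C=3e-4, R_net=0.1, n_cycles=2, dt=0.01):
    """Linear-compliance analytic response V = V0 + C * (-p_ip)."""
    w = BreathingWaveform()
    cfg = CouplingConfig(dt=dt, n_cycles=n_cycles, envelope_level=0)
    hist = StateHistory(geom=healthy_geom, config=cfg, waveform=w)
    t = np.arange(0, n_cycles * w.period + dt / 2, dt)
    p_ip = intrapleural_pressure(t, w)
    V = healthy_geom.lumen_volume + C * (-p_ip)
    Q = np.gradient(V, t)
    hist.t = t
    hist.volume = V
    hist.flow_rate = Q
    hist.p_ip = p_ip
    hist.pressure_drop = -R_net * Q
    hist.p_alv = -R_net * Q * 0.8
    hist.max_wss = np.abs(Q)
    hist.u_peak = np.abs(Q)
    hist.subiters = np.ones(len(t), int)
    hist.residual = np.zeros(len(t))
    return hist


@pytest.fixture(scope="module")
def linear_hist(healthy_geom):
    return synthetic_history(healthy_geom)


class TestTidalVolume:
    def test_constant_volume_gives_zero(self, healthy_geom):
        h = synthetic_history(healthy_geom, C=0.0)
        assert tidal_volume(h) == 0.0

    def test_linear_response(self, linear_hist):
        assert tidal_volume(linear_hist) == pytest.approx(3e-4 * 244.0, rel=1e-6)

    def test_incomplete_cycle_rejected(self, healthy_geom):
        h = synthetic_history(healthy_geom)
        keep = h.t < 2.0
        for f in ("t", "volume", "flow_rate", "p_ip", "pressure_drop", "p_alv"):
            setattr(h, f, getattr(h, f)[keep])
        with pytest.raises(IncompleteCycleError):
            tidal_volume(h)


class TestCompliance:
    def test_linear_spring_recovered_exactly(self, linear_hist):
        assert compliance(linear_hist) == pytest.approx(3e-4, rel=1e-9)

    def test_degenerate_pressure_range_rejected(self, healthy_geom):
        h = synthetic_history(healthy_geom)
        h.p_ip = np.zeros_like(h.p_ip)
        with pytest.raises(ValueError):
            compliance(h)


class TestResistance:
    def test_network_value_recovered(self, linear_hist):
        # drop = -R Q by construction -> resistance == R at peak flow
        assert acinus_resistance(linear_hist) == pytest.approx(0.1, rel=1e-9)

    def test_doubled_flow_halves_resistance(self, healthy_geom):
        h1 = synthetic_history(healthy_geom, C=3e-4)
        h2 = synthetic_history(healthy_geom, C=6e-4)
        h2.pressure_drop = h1.pressure_drop[: len(h2.t)] * 1.0
        # same drop at doubled flow -> half the resistance
        assert acinus_resistance(h2) == pytest.approx(
            acinus_resistance(h1) / 2, rel=0.01
        )

    def test_zero_flow_rejected(self, healthy_geom):
        h = synthetic_history(healthy_geom, C=0.0)
        with pytest.raises(ValueError):
            acinus_resistance(h)


class TestLoopsAndPeaks:
    def test_sinusoidal_pif_equals_pef(self, linear_hist):
        pif, pef = peak_flows(linear_hist)
        assert pif == pytest.approx(pef, rel=0.01)
        w = BreathingWaveform()
        assert pif == pytest.approx(3e-4 * 244.0 * w.omega / 2.0, rel=0.01)

    def test_loops_close(self, linear_hist):
        pv, fv = loops(linear_hist)
        tv = tidal_volume(linear_hist)
        assert abs(pv.volume[-1] - pv.volume[0]) < 0.01 * tv
        assert abs(fv.volume[-1] - fv.volume[0]) < 0.01 * tv
        assert pv.volume.min() >= linear_hist.resting_volume - 0.01 * tv
        assert pv.volume.max() <= linear_hist.resting_volume + tv * 1.01

    def test_flow_volume_consistency(self, linear_hist):
        """Reported flow equals the numerical dV/dt of the volume trace."""
        h = linear_hist
        dVdt = np.gradient(h.volume, h.t)
        m = np.abs(dVdt) > 0.1 * np.abs(dVdt).max()
        assert np.abs(h.flow_rate[m] - dVdt[m]).max() <= 0.01 * np.abs(
            dVdt
        ).max()

    def test_signed_pressure_extreme(self, linear_hist):
        d = max_pressure_drop(linear_hist)
        assert abs(d) == pytest.approx(np.abs(linear_hist.pressure_drop).max())


class TestCompare:
    def _report(self, hist, name):
        r = LungFunctionReport.from_history(hist)
        r.scenario = name
        return r

    def test_identical_reports_zero_differences(self, healthy_geom):
        h = synthetic_history(healthy_geom)
        reports = {
            "healthy": self._report(h, "healthy"),
            "NSIP": self._report(h, "NSIP"),
            "IPF": self._report(h, "IPF"),
        }
        table = compare_scenarios(reports)
        assert np.abs(table["NSIP_vs_healthy_pct"]).max() < 1e-9
        assert np.abs(table["NSIP_vs_IPF_pct"]).max() < 1e-9

    def test_halved_compliance_is_fifty_percent_down(self, healthy_geom):
        reports = {
            "healthy": self._report(synthetic_history(healthy_geom, C=3e-4), "healthy"),
            "NSIP": self._report(synthetic_history(healthy_geom, C=1.5e-4), "NSIP"),
            "IPF": self._report(synthetic_history(healthy_geom, C=1.5e-4), "IPF"),
        }
        table = compare_scenarios(reports)
        assert table.loc["compliance", "NSIP_vs_healthy_pct"] == pytest.approx(
            -50.0, abs=0.5
        )

    def test_missing_reference_rejected(self, healthy_geom):
        h = synthetic_history(healthy_geom)
        with pytest.raises(ValueError):
            compare_scenarios({"NSIP": self._report(h, "NSIP")})

    def test_mismatched_configs_rejected(self, healthy_geom):
        a = self._report(synthetic_history(healthy_geom), "healthy")
        b = self._report(synthetic_history(healthy_geom, dt=0.02), "NSIP")
        with pytest.raises(ValueError, match="mismatched"):
            compare_scenarios({"healthy": a, "NSIP": b})
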