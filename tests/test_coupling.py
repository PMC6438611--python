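"""Waveform, coupled stepping, time convergence, determinism."""

import numpy as np
import pytest

from acinusfsi.coupling import (
    AcinusSimulator,
    CouplingConfig,
    run_breathing_cycle,
)
from acinusfsi.waveform import BreathingWaveform, intrapleural_pressure


class TestWaveform:
    def test_tabulated_values(self):
        w = BreathingWaveform()
        assert w.p0 == 244.0
        assert w.period == pytest.approx(4.0)
        assert intrapleural_pressure(0.0, w) == 0.0
        assert intrapleural_pressure(2.0, w) == pytest.approx(-244.0)
        assert intrapleural_pressure(1.0, w) == pytest.approx(-122.0)

    def test_bounds_over_cycle(self):
        w = BreathingWaveform()
        t = np.linspace(0, 8, 500)
        p = intrapleural_pressure(t, w)
        assert p.min() >= -w.p0 - 1e-12
        assert p.max() <= 1e-12

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            intrapleural_pressure(-0.1)


@pytest.fixture(scope="module")
def coarse_cfg():
    return CouplingConfig(dt=0.05, n_cycles=1, envelope_level=0)


@pytest.fixture(scope="module")
def healthy_run(coarse_cfg):
    return run_breathing_cycle("healthy", config=coarse_cfg)


class TestCoupledCycle:
    def test_zero_drive_is_a_fixed_point(self, healthy_geom, coarse_cfg):
        """With p_IP = 0 the state stays at rest."""
        sim = AcinusSimulator(
            healthy_geom, config=coarse_cfg,
            waveform=BreathingWaveform(p0=0.0),
        )
        s = sim.step([sim.v_rest_cells.copy()], coarse_cfg.dt,
                     np.zeros((len(sim.model.nodes), 3)), 0.0)
        assert abs(s.volume - sim.v_rest) < 1e-12 * sim.v_rest
        assert abs(s.flow_rate) < 1e-12

    def test_starts_at_resting_volume_and_inhales(self, healthy_run):
        h = healthy_run
        assert h.volume[0] == pytest.approx(h.resting_volume)
        # inspiration onset: volume rises, air flows in through the mouth
        assert h.volume[1] > h.volume[0]
        assert h.flow_rate[1] > 0

    def test_volume_continuity(self, healthy_run):
        dv = np.abs(np.diff(healthy_run.volume))
        assert dv.max() < 0.05 * healthy_run.resting_volume

    def test_phase_of_peak_flow(self, healthy_run):
        """Peak inflow near mid-inspiration (t ~ 1 s), outflow near t ~ 3 s."""
        h = healthy_run
        assert abs(h.t[np.argmax(h.flow_rate)] - 1.0) <= 0.3
        assert abs(h.t[np.argmin(h.flow_rate)] - 3.0) <= 0.3
        # near-zero flow at the turning points
        for tq in (2.0, 4.0):
            k = np.argmin(np.abs(h.t - tq))
            assert abs(h.flow_rate[k]) < 0.1 * h.flow_rate.max()

    def test_pressure_drop_sign_convention(self, healthy_run):
        """Interior pressure negative during inspiration, positive during
        expiration."""
        h = healthy_run
        insp = (h.t > 0.3) & (h.t < 1.7)
        expi = (h.t > 2.3) & (h.t < 3.7)
        assert np.all(h.pressure_drop[insp] < 0)
        assert np.all(h.pressure_drop[expi] > 0)

    def test_mass_conservation_each_step(self, healthy_run):
        """Open-boundary flux equals the BDF2 volume rate to 0.5%."""
        h = healthy_run
        dt = h.config.dt
        V = h.volume
        for k in range(2, len(V)):
            dVdt = (3 * V[k] - 4 * V[k - 1] + V[k - 2]) / (2 * dt)
            if abs(dVdt) > 1e-4:
                assert h.flow_rate[k] == pytest.approx(dVdt, rel=0.005)

    def test_determinism(self, coarse_cfg, healthy_run):
        """Identical config gives a bit-identical scalar history."""
        h2 = run_breathing_cycle("healthy", config=coarse_cfg)
        assert np.array_equal(h2.volume, healthy_run.volume)
        assert np.array_equal(h2.flow_rate, healthy_run.flow_rate)
        assert np.array_equal(h2.pressure_drop, healthy_run.pressure_drop)

    def test_loose_coupling_close_to_subiterated(self, coarse_cfg, healthy_run):
        """Explicit staggering (one exchange per step) agrees closely with
        the sub-iterated solution at this weak coupling strength."""
        cfg = CouplingConfig(dt=0.05, n_cycles=1, envelope_level=0,
                             loose_coupling=True)
        h2 = run_breathing_cycle("healthy", config=cfg)
        tv1 = healthy_run.volume.max() - healthy_run.resting_volume
        tv2 = h2.volume.max() - h2.resting_volume
        assert tv2 == pytest.approx(tv1, rel=1e-3)

    def test_interface_residual_below_tolerance(self, healthy_run):
        assert healthy_run.residual[1:].max() < healthy_run.config.tolerance

    def test_work_consistency_over_cycle(self, healthy_run):
        """Fluid-side boundary work matches the pressure-volume work of the
        air column to 2% over the cycle (conforming exchange)."""
        h = healthy_run
        # work done by the air on the mouth boundary vs p dV of the alveoli
        w_pdv = float(np.trapezoid(h.p_alv, h.volume))
        w_flux = float(np.trapezoid(h.p_alv * h.flow_rate, h.t))
        assert w_flux == pytest.approx(w_pdv, rel=0.02)


class TestTimeConvergence:
    """BDF2 flow differentiation converges at 2nd order on dt halving.

    The quasi-static tissue makes the nodal volume trajectory
    dt-independent, so the flow-rate error against a fine-dt reference
    must fall by ~4x per halving.
    """

    @pytest.fixture(scope="class")
    @staticmethod
    def dt_study(healthy_geom):
        out = {}
        for dt in (0.02, 0.01, 0.005, 0.00125):
            # solver tolerances well below the truncation error being measured
            cfg = CouplingConfig(dt=dt, n_cycles=1, envelope_level=0,
                                 newton_rtol=1e-11, tolerance=1e-9)
            sim = AcinusSimulator(healthy_geom, config=cfg)
            T = sim.waveform.period
            nsteps = int(round(1.5 / dt))
            hist_V = [sim.v_rest_cells.copy()]
            u = np.zeros((len(sim.model.nodes), 3))
            p_alv = 0.0
            ts, qs = [], []
            for k in range(1, nsteps + 1):
                s = sim.step(hist_V, k * dt, u, p_alv)
                u, p_alv = s.u, s.p_alv
                hist_V.append(s.cell_volumes)
                if len(hist_V) > 2:
                    hist_V.pop(0)
                ts.append(k * dt)
                qs.append(s.flow_rate)
            out[dt] = (np.array(ts), np.array(qs))
        return out

    def test_observed_order_at_least_two(self, dt_study):
        ref_t, ref_q = dt_study[0.00125]
        errs = []
        for dt in (0.02, 0.01, 0.005):
            t, q = dt_study[dt]
            mask = t >= 1.0
            qr = np.interp(t[mask], ref_t, ref_q)
            errs.append(np.max(np.abs(q[mask] - qr)))
        order1 = np.log2(errs[0] / errs[1])
        order2 = np.log2(errs[1] / errs[2])
        assert order1 > 1.8
        assert order2 > 1.8
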