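"""Solver physics oracles: steady-state resistance, equilibrium, linear wave
speed, outlet matching, junction mass conservation, grid convergence, and
the haemodynamic effect of a stenosis."""

import numpy as np
import pytest

from pulsescreen import (
    ConvergenceError,
    DiseaseSpec,
    SolverSettings,
    WaveformSet,
    apply_disease,
    load_network,
    periodicity_residual,
    simulate,
)

from conftest import tube_config, two_vessel_config

RHO = 1.06
MMHG = 1333.22


class TestSteadyState:
    def test_resistance_oracle(self):
        """Constant inflow + RCR outlet: converged inlet pressure equals
        p_out + Q0 (R1 + R2), the closed-form steady state, within 1%."""
        q0, r1, r2, pout = 50.0, 0.15, 0.45, 10.0
        net = load_network(tube_config(q0=q0, r1=r1, r2=r2, comp=0.05, pout=pout))
        ws = simulate(net, SolverSettings(mu=0.0, init_pressure=pout,
                                          tolerance=1e-4, max_cycles=30))
        expected = pout + q0 * (r1 + r2)
        assert ws["P1_R"].mean() == pytest.approx(expected, rel=0.01)
        # flow everywhere equals the prescribed inflow
        assert ws["Q2_R"].mean() == pytest.approx(q0, rel=0.01)

    def test_equilibrium_is_preserved_exactly(self):
        """Zero inflow with the network initialised at the outflow pressure
        stays at that pressure with zero flow."""
        net = load_network(tube_config(q0=0.0, pout=40.0))
        ws = simulate(net, SolverSettings(mu=0.0, init_pressure=40.0))
        np.testing.assert_allclose(ws["P1_R"], 40.0, atol=1e-9)
        np.testing.assert_allclose(ws["Q1_R"], 0.0, atol=1e-12)

    def test_nonconvergence_reports_residual(self):
        net = load_network(tube_config(q0=50.0, r1=1.0, r2=5.0, comp=0.5))
        with pytest.raises(ConvergenceError) as err:
            simulate(net, SolverSettings(max_cycles=2, init_pressure=10.0))
        assert err.value.residual > 0


class TestWavePropagation:
    def test_linear_wave_speed(self):
        """A small inlet pulse travels at c0 = sqrt(beta/(2 rho sqrt(A)))
        (foot-to-foot between two sites) within 5%."""
        area, beta, length = 3.0, 800.0, 60.0
        c0 = np.sqrt(beta * MMHG / (2.0 * RHO * np.sqrt(area)))
        period = 0.8
        t = np.arange(256) / 256
        flow = 2.0 * np.exp(-0.5 * ((t - 0.06) / 0.015) ** 2)  # small pulse
        zc = RHO * c0 / area / MMHG
        cfg = tube_config(length=length, area=area, beta=beta, period=period,
                          r1=zc, r2=100.0 * zc, comp=10.0, pout=0.0,
                          phase=t, flow=flow)
        # sites at 10% and 90% of the tube
        net = load_network(cfg)
        s = SolverSettings(mu=0.0, init_pressure=0.0, dx=0.5, max_cycles=3,
                           tolerance=1e-3, n_samples=512, expansion_loss=0.0)
        try:
            ws = simulate(net, s)
        except ConvergenceError:
            ws = None
        if ws is None:  # convergence is irrelevant here; rerun capturing cycle 2
            s = SolverSettings(mu=0.0, init_pressure=0.0, dx=0.5, max_cycles=2,
                               tolerance=1e9, n_samples=512, expansion_loss=0.0)
            ws = simulate(net, s)
        dt = period / ws.n_samples
        # foot = first crossing of 5% of each site's peak
        times = []
        for key in ("P1_R", "P2_R"):
            p = ws[key] - ws[key][0]
            thresh = 0.05 * p.max()
            times.append(np.argmax(p > thresh) * dt)
        dist = 0.8 * length  # between 10% and 90%
        c_measured = dist / (times[1] - times[0])
        assert c_measured == pytest.approx(c0, rel=0.05)

    def test_matched_outlet_absorbs_pulse(self):
        """With terminal impedance equal to the characteristic impedance the
        pulse leaves without secondary reflections above 2% of its height."""
        area, beta, length = 3.0, 800.0, 40.0
        c0 = np.sqrt(beta * MMHG / (2.0 * RHO * np.sqrt(area)))
        zc = RHO * c0 / area / MMHG
        period = 0.8
        t = np.arange(256) / 256
        flow = 3.0 * np.exp(-0.5 * ((t - 0.05) / 0.012) ** 2)
        cfg = tube_config(length=length, area=area, beta=beta, period=period,
                          r1=zc, r2=1000.0 * zc, comp=50.0, pout=0.0,
                          phase=t, flow=flow)
        net = load_network(cfg)
        s = SolverSettings(mu=0.0, init_pressure=0.0, dx=0.4, max_cycles=2,
                           tolerance=1e9, n_samples=1024, expansion_loss=0.0)
        ws = simulate(net, s)
        p = ws["P1_R"] - ws["P1_R"][0]  # site at 10% of the tube
        peak = p.max()
        # primary pulse passes the site by ~ (0.05 + (4+36+36)/c0) s; after
        # that, everything is reflection
        t_clear = 0.05 + 1.1 * (0.1 * length + 2 * 0.9 * length) / c0
        tail = p[int(t_clear / period * ws.n_samples):]
        assert np.abs(tail).max() < 0.02 * peak

    def test_refinement_convergence(self):
        """Waveform changes shrink consistently under grid halving with an
        observed convergence order of at least 1."""
        cfg = two_vessel_config()
        net = load_network(cfg)
        out = {}
        for dx in (1.0, 0.5, 0.25):
            out[dx] = simulate(net, SolverSettings(
                dx=dx, init_pressure=30.0, tolerance=1e-4, max_cycles=80))
        d_coarse = periodicity_residual(out[1.0], out[0.5])
        d_fine = periodicity_residual(out[0.5], out[0.25])
        assert d_fine < d_coarse
        order = np.log2(d_coarse / d_fine)
        assert order >= 0.9


class TestJunctions:
    def test_mass_conserved_at_junctions(self):
        """Interface star states conserve mass to 1e-6 relative at every
        step (tracked by the junction Newton solves)."""
        net = load_network(two_vessel_config())
        ws = simulate(net, SolverSettings(init_pressure=30.0, max_cycles=40))
        assert ws.junction_residual < 1e-6

    def test_mass_conserved_default_network(self, reference_network):
        ws = simulate(reference_network, SolverSettings())
        assert ws.junction_residual < 1e-6

    def test_stenosis_reduces_chain_flow(self, reference_network):
        """A severe stenosis strictly reduces cycle-mean flow through its
        chain relative to the healthy twin."""
        healthy = simulate(reference_network, SolverSettings())
        spec = DiseaseSpec("stenosis", 0.9, 0.3, 0.7, 0.5, "CA", "right")
        ws = simulate(apply_disease(reference_network, spec),
                      SolverSettings(max_cycles=40))
        assert ws["Q1_R"].mean() < healthy["Q1_R"].mean()
        # contralateral side barely affected
        assert ws["Q1_L"].mean() == pytest.approx(healthy["Q1_L"].mean(), rel=0.1)


class TestPeriodicityResidual:
    def make(self, series, n=64, period=0.8):
        return WaveformSet(series=series, period=period, n_samples=n)

    def test_identical_cycles_give_zero(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 64, endpoint=False)) * 10 + 100
        a = self.make({"P1_R": x})
        b = self.make({"P1_R": x.copy()})
        assert periodicity_residual(a, b) == 0.0

    def test_shift_by_one_percent_of_amplitude(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 64, endpoint=False)) * 10 + 100
        amp = x.max() - x.min()
        a = self.make({"P1_R": x})
        b = self.make({"P1_R": x + 0.01 * amp})
        assert periodicity_residual(a, b) == pytest.approx(0.01)

    def test_random_perturbation_recovered(self):
        rng = np.random.default_rng(0)
        x = np.sin(np.linspace(0, 2 * np.pi, 64, endpoint=False)) * 10 + 100
        pert = rng.uniform(-0.5, 0.5, size=64)
        a = self.make({"P1_R": x})
        b = self.make({"P1_R": x + pert})
        amp = (x + pert).max() - (x + pert).min()
        assert periodicity_residual(a, b) == pytest.approx(
            np.abs(pert).max() / amp)

    def test_grid_mismatch_rejected(self):
        a = self.make({"P1_R": np.ones(64)})
        b = self.make({"P1_R": np.ones(32)}, n=32)
        with pytest.raises(ValueError):
            periodicity_residual(a, b)


class TestSettingsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"cfl": 0.0}, {"cfl": 1.5}, {"tolerance": 0.0}, {"max_cycles": 1},
        {"dx": 0.0},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverSettings(**kwargs)
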