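"""Tests for the Brownian-dynamics gravitational-sweep simulator."""

import numpy as np
import pytest

from fibrilhydro import SolventConditions
from fibrilhydro.auc_sweep_simulator import (
    DetectorTrace,
    SpeciesSpec,
    SweepConfig,
    analytic_crossing_fraction,
    diffusion_from_s,
    front_arrival_time,
    front_time,
    s_at_time,
    simulate_sweep,
    trace_to_s_distribution,
)
from fibrilhydro.constants import BOLTZMANN, SVEDBERG


class TestDiffusionFromS:
    def test_stokes_einstein_closed_form(self, solvent):
        """Pick s so the equivalent sphere is 10 nm at f/f0 = 1; then D
        must equal the bare Stokes-Einstein value for a 10 nm sphere."""
        d_eq = 10e-9
        drho = 1331.6 - 998.2
        s = d_eq**2 * drho / (18 * solvent.viscosity) / SVEDBERG
        spec = SpeciesSpec(s_svedberg=s, frictional_ratio=1.0, density=1331.6)
        oracle = BOLTZMANN * 293.15 / (3 * np.pi * solvent.viscosity * d_eq)
        got = diffusion_from_s(spec, solvent)
        assert got == pytest.approx(oracle, rel=1e-12)
        assert got == pytest.approx(4.28e-11, rel=0.01)

    def test_halved_at_fixed_equivalent_sphere(self, solvent):
        """Doubling f/f0 at fixed equivalent-sphere size (s scales down
        by the same factor) halves D: D = kT / (3 pi eta d_eq (f/f0))."""
        d1 = diffusion_from_s(SpeciesSpec(s_svedberg=20.0, frictional_ratio=1.0), solvent)
        d2 = diffusion_from_s(SpeciesSpec(s_svedberg=10.0, frictional_ratio=2.0), solvent)
        assert d2 == pytest.approx(d1 / 2.0, rel=1e-12)

    @pytest.mark.parametrize("s,ffo", [(4.0, 1.26), (50.0, 1.5), (100.0, 1.5)])
    def test_positive(self, s, ffo, solvent):
        assert diffusion_from_s(SpeciesSpec(s_svedberg=s, frictional_ratio=ffo), solvent) > 0


class TestEqTwoTransform:
    def test_closed_form_anchor(self):
        config = SweepConfig()
        w2 = (30000 * 2 * np.pi / 60.0) ** 2
        t = np.log(6.9 / 5.9) / (w2 * 100e-13)
        assert t == pytest.approx(1586.4, abs=0.5)
        assert float(s_at_time(t, config)) == pytest.approx(100.0, rel=1e-9)
        assert front_time(100.0, config) == pytest.approx(t, rel=1e-12)

    def test_step_trace_recovers_step(self):
        """A perfect step trace at t* maps to a cumulative step at s(t*)."""
        config = SweepConfig()
        t_star = 2000.0
        times = np.arange(0.0, 7200.0, 2.0)
        signal = (times < t_star).astype(float)
        trace = DetectorTrace(
            times=times, signal=signal, species_signal=signal[:, None],
            crossing=None, species_crossing=None, abundances=np.array([1.0]),
        )
        dist = trace_to_s_distribution(trace, config, method="drop", cutoff_svedberg=1.0)
        s_star = float(s_at_time(t_star, config))
        cum = dist.cumulative()
        # all mass concentrated within one time-sample of s(t*)
        s_lo = float(s_at_time(t_star + 2.0, config))
        assert float(np.interp(s_lo * 0.99, dist.grid, cum)) == pytest.approx(0.0, abs=1e-9)
        assert float(np.interp(s_star * 1.01, dist.grid, cum)) == pytest.approx(1.0, abs=1e-9)


class TestSimulator:
    def test_no_field_no_diffusion_trace_constant(self):
        config = SweepConfig(rotor_rpm=0.0, duration_s=100.0, dt_s=0.5,
                             n_particles=5000, seed=1)
        trace = simulate_sweep(config, [SpeciesSpec(s_svedberg=50.0)], diffusionless=True)
        assert np.all(trace.signal == trace.signal[0])
        assert np.all(trace.crossing == trace.crossing[0])

    def test_refuses_coarse_time_step(self):
        config = SweepConfig(duration_s=100.0, dt_s=20.0, n_particles=100,
                             record_interval_s=20.0)
        with pytest.raises(ValueError, match="time step"):
            simulate_sweep(config, [SpeciesSpec(s_svedberg=1000.0)])

    def test_bit_reproducible_for_fixed_seed(self):
        config = SweepConfig(duration_s=300.0, dt_s=1.0, n_particles=2000, seed=77,
                             record_interval_s=2.0)
        species = [SpeciesSpec(s_svedberg=100.0)]
        t1 = simulate_sweep(config, species)
        t2 = simulate_sweep(config, species)
        np.testing.assert_array_equal(t1.signal, t2.signal)
        np.testing.assert_array_equal(t1.crossing, t2.crossing)

    def test_diffusionless_front_arrival_matches_analytic(self):
        """With D = 0 the 100 S front reaches the detector at
        ln(r_fix/r_m)/(w^2 s) ~ 1586 s, within one time step."""
        config = SweepConfig(duration_s=1700.0, dt_s=0.5, n_particles=20000,
                             seed=5, record_interval_s=0.5)
        trace = simulate_sweep(config, [SpeciesSpec(s_svedberg=100.0)],
                               diffusionless=True)
        t_ref = front_time(100.0, config)
        t_arr = front_arrival_time(trace, config, method="crossing")
        assert abs(t_arr - t_ref) <= config.dt_s
        # the half-drop of the thin-bin signal agrees within its
        # counting-noise floor (~1.5 s at 2e4 particles)
        t_sig = front_arrival_time(trace, config, method="signal")
        assert abs(t_sig - t_ref) <= 5.0

    def test_monte_carlo_convergence_root_n(self):
        """Sup-distance of the crossing channel to its analytic
        expectation shrinks like 1/sqrt(N) over three doublings."""
        config_kw = dict(duration_s=1200.0, dt_s=1.0, record_interval_s=4.0)
        species = [SpeciesSpec(s_svedberg=100.0)]
        sizes = [2000, 4000, 8000, 16000]
        sups = []
        for n in sizes:
            errs = []
            for seed in range(6):
                config = SweepConfig(n_particles=n, seed=seed, **config_kw)
                trace = simulate_sweep(config, species)
                d = diffusion_from_s(species[0])
                ref = analytic_crossing_fraction(100.0, d, config, trace.times)
                errs.append(np.max(np.abs(trace.crossing - ref)))
            sups.append(np.mean(errs))
        ratios = np.log2(np.array(sups[:-1]) / np.array(sups[1:]))
        assert 0.25 <= float(np.mean(ratios)) <= 0.75

    def test_crossing_channel_tracks_analytic(self):
        config = SweepConfig(duration_s=2400.0, dt_s=1.0, n_particles=30000,
                             seed=9, record_interval_s=4.0)
        species = [SpeciesSpec(s_svedberg=50.0)]
        trace = simulate_sweep(config, species)
        ref = analytic_crossing_fraction(50.0, diffusion_from_s(species[0]),
                                         config, trace.times)
        assert np.max(np.abs(trace.crossing - ref)) < 0.01


class TestRecovery:
    def test_two_species_recovery_small(self):
        """Scaled-down two-species run: recovered cumulative steps land
        at the right coefficients with the right heights."""
        config = SweepConfig(duration_s=4000.0, dt_s=1.0, n_particles=20000,
                             seed=21, record_interval_s=4.0)
        species = [
            SpeciesSpec(s_svedberg=50.0, abundance=0.5),
            SpeciesSpec(s_svedberg=100.0, abundance=0.5),
        ]
        trace = simulate_sweep(config, species)
        dist = trace_to_s_distribution(trace, config, cutoff_svedberg=10.0)
        cum = dist.cumulative()
        for s0, expect in [(40.0, 0.0), (70.0, 0.5), (130.0, 1.0)]:
            got = float(np.interp(s0, dist.grid, cum))
            assert got == pytest.approx(expect, abs=0.03)

    def test_cutoff_excluding_everything_raises(self):
        config = SweepConfig(duration_s=2000.0, dt_s=1.0, n_particles=5000,
                             seed=3, record_interval_s=4.0)
        trace = simulate_sweep(config, [SpeciesSpec(s_svedberg=100.0)])
        with pytest.raises(ValueError, match="cutoff"):
            trace_to_s_distribution(trace, config, cutoff_svedberg=1e5)


class TestConfigValidation:
    def test_geometry_order_enforced(self):
        with pytest.raises(ValueError, match="meniscus"):
            SweepConfig(meniscus_m=0.07, detector_m=0.06, bottom_m=0.072)

    def test_species_validation(self):
        with pytest.raises(ValueError):
            SpeciesSpec(s_svedberg=-1.0)
        with pytest.raises(ValueError):
            SpeciesSpec(s_svedberg=10.0, frictional_ratio=0.9)
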