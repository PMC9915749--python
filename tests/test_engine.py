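"""Unit tests of minimization, dynamics, and the tensile protocol."""

import numpy as np
import pytest

from fibrilsim import (
    BuildConfig,
    SimConfig,
    System,
    assemble_fibril,
    bond_tension,
    build_system,
    default_forcefield,
    equilibrate_nvt,
    minimize,
    run_dynamics,
    run_tensile_experiment,
    tensile_test,
)
from fibrilsim.units import KB, MVV2E


def make_dimer(r=16.0):
    ff = default_forcefield()
    return System(
        np.array([[0.0, 0, 0], [r, 0, 0]]),
        np.array([[0, 1]]),
        np.array([0], dtype=np.int8),
        ff,
        use_pairs=False,
    )


class TestMinimize:
    def test_dimer_relaxes_to_equilibrium_distance(self):
        system = make_dimer(16.0)
        info = minimize(system)
        r = float(np.linalg.norm(system.x[1] - system.x[0]))
        assert r == pytest.approx(14.00, abs=1e-3)
        assert info["e_final"] <= info["e_initial"]

    def test_energy_sequence_non_increasing(self):
        system = make_dimer(19.0)
        info = minimize(system)
        e = np.array(info["energies"])
        assert (np.diff(e) <= 1e-10).all()

    def test_already_minimal_state_unchanged(self):
        system = make_dimer(14.0)
        x0 = system.x.copy()
        minimize(system)
        assert np.abs(system.x - x0).max() < 1e-6


class TestDynamics:
    def test_zero_temperature_minimized_state_is_static(self, tiny_geometry, forcefield):
        system = build_system(tiny_geometry, [], forcefield)
        minimize(system)
        x0 = system.x.copy()
        run_dynamics(system, 200, dt=10.0, temperature=0.0, damping=1000.0,
                     rng=np.random.default_rng(0))
        # no thermal noise, no net force: positions stay put
        assert np.abs(system.x - x0).max() < 1e-2

    def test_same_seed_gives_bitwise_identical_trajectories(self, tiny_geometry, forcefield):
        res = []
        for _ in range(2):
            system = build_system(tiny_geometry, [], forcefield)
            minimize(system)
            sim = SimConfig(dt=10.0, seed=42)
            equilibrate_nvt(system, sim, duration_fs=2000.0,
                            rng=np.random.default_rng(42))
            res.append(system.x.copy())
        assert np.array_equal(res[0], res[1])

    def test_momentum_conserved_without_clamps(self):
        cfg = BuildConfig(
            fibril_diameter=35.0, n_d_periods=2, d_period=210.0,
            particles_per_molecule=22, n_extension_particles=0, n_clamp_particles=0,
        )
        system = build_system(assemble_fibril(cfg), [], default_forcefield())
        minimize(system)
        rng = np.random.default_rng(5)
        system.seed_velocities(100.0, rng)
        p0 = system.v.sum(axis=0).copy()
        run_dynamics(system, 2000, dt=1.0, damping=None)
        p1 = system.v.sum(axis=0)
        np.testing.assert_allclose(p1, p0, atol=1e-10)

    def test_clamp_separation_follows_kinematics_exactly(self, tiny_geometry, forcefield):
        system = build_system(tiny_geometry, [], forcefield)
        minimize(system)
        sep0 = system.clamp_separation()
        v, dt, n = 1e-3, 10.0, 500
        run_dynamics(system, n, dt=dt, temperature=0.0, damping=1000.0,
                     rng=np.random.default_rng(0), clamp_speed=v)
        assert system.clamp_separation() == pytest.approx(sep0 + v * n * dt, abs=1e-9)


class TestTensile:
    def test_serial_chain_force_matches_bond_law(self):
        """Quasi-static pull of a single molecule reproduces the bond law."""
        n = 10
        ff = default_forcefield()
        coords = np.outer(np.arange(n) * 14.0, [1.0, 0, 0])
        bonds = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
        system = System(
            coords, bonds, np.zeros(n - 1, dtype=np.int8), ff,
            clamp_left=[0], clamp_right=[n - 1], cross_section_area=1.0,
            use_pairs=False,
        )
        sim = SimConfig(dt=10.0, temperature=0.0, damping=200.0,
                        pull_velocity=2e-4, max_strain=0.2, output_stride=50)
        result = tensile_test(system, sim, rng=np.random.default_rng(0))
        ts = result.timeseries
        p = ff.bond_params("tc_core")
        settled = ts[ts["strain"] > 0.02]
        # the recorded force is a stride average; compare at the mid-stride
        # clamp separation
        lag = sim.pull_velocity * sim.dt * (sim.output_stride - 1) / 2.0
        r_chain = 14.0 + (settled["separation"] - lag - result.gauge_length) / (n - 1)
        expected = np.array([bond_tension(r, p) for r in r_chain])
        np.testing.assert_allclose(settled["force"], expected, rtol=0.01)

    def test_strain_column_matches_clamp_kinematics(self):
        # reuse a short tiny pull; strain must equal (sep - L0)/L0 exactly
        geom = assemble_fibril(BuildConfig(
            fibril_diameter=35.0, n_d_periods=2, d_period=210.0,
            particles_per_molecule=22, n_extension_particles=6, n_clamp_particles=3,
        ))
        system = build_system(geom, [], default_forcefield())
        minimize(system)
        sim = SimConfig(dt=10.0, pull_velocity=1e-3, max_strain=0.03, output_stride=20)
        result = tensile_test(system, sim, rng=np.random.default_rng(1))
        ts = result.timeseries
        np.testing.assert_allclose(
            ts["strain"], (ts["separation"] - result.gauge_length) / result.gauge_length,
            atol=1e-12,
        )
        v_t = 1e-3 * ts["time_fs"]
        np.testing.assert_allclose(ts["separation"] - result.gauge_length, v_t, atol=1e-9)

    def test_rate_robustness_of_peak_stress(self):
        """Halving the pull velocity shifts the peak stress by < 15%."""
        peaks = {}
        for v in (1e-3, 5e-4):
            cfg_run = run_tensile_experiment(
                _tiny_with_velocity(v), n_age=2, ecl_pct=25, seed=3,
            )
            peaks[v] = cfg_run.summary.sigma_peak
        assert abs(peaks[5e-4] - peaks[1e-3]) / peaks[1e-3] < 0.15


def _tiny_with_velocity(v):
    from fibrilsim.presets import make_preset

    cfg = make_preset("tiny", seed=3)
    return cfg.model_copy(update={"sim": cfg.sim.model_copy(update={"pull_velocity": v})})


class TestEquilibration:
    def test_mean_temperature_near_target(self, tiny_geometry, forcefield):
        system = build_system(tiny_geometry, [], forcefield)
        minimize(system)
        sim = SimConfig(dt=10.0, temperature=300.0, damping=500.0, seed=7)
        info = equilibrate_nvt(system, sim, duration_fs=30000.0,
                               rng=np.random.default_rng(7))
        # generous envelope here; the acceptance suite does the 3-SE check
        assert abs(info["mean_temperature"] - 300.0) < 30.0

    def test_velocity_seeding_scale(self, tiny_geometry, forcefield):
        system = build_system(tiny_geometry, [], forcefield)
        system.seed_velocities(300.0, np.random.default_rng(0))
        ke = 0.5 * system.mass * MVV2E * float(np.sum(system.v[system.free_mask] ** 2))
        dof = 3 * system.n_free
        assert ke / dof == pytest.approx(0.5 * KB * 300.0, rel=0.05)
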