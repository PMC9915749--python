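"""Run presets: full-scale study conditions plus two reduced desk-scale rigs.

``paper``-scale conditions: fibril diameter 202 A, D-period 670 A, five
gap/overlap zones, 218 particles per molecule, 40 extension particles and
10-particle clamps, 80 ns pre-insertion equilibration at dt = 10 fs, pulling
at 1e-4 A/fs with dt = 1 fs.

The reduced presets keep the native proportions (gap 0.6 D / overlap 0.4 D,
one molecule length plus one gap per stagger window, telopeptide/extension
layout) but shrink the D-period to 210 A (15 particle spacings) and the
cross-section to 19 (`small`) or 7 (`tiny`) molecules, and run a shortened
protocol: picosecond-scale equilibration, pulling at 1e-3 A/fs with
dt = 10 fs.  These are the problem sizes used by the test-suite experiments.
"""

from __future__ import annotations

from .config import BuildConfig, ConfigError, CrosslinkConfig, RunConfig, SimConfig

PRESET_NAMES = ("tiny", "small", "paper")


def make_preset(name: str, seed: int = 0) -> RunConfig:
    """A fully populated run configuration for a named preset."""
    if name == "paper":
        return RunConfig(
            build=BuildConfig(),  # paper-scale defaults
            crosslinks=CrosslinkConfig(seed=seed),
            sim=SimConfig(dt=1.0, pull_velocity=1.0e-4, output_stride=500, damping=5000.0, max_strain=0.8, seed=seed),
            equilibration_time=80.0e6,
            post_crosslink_equilibration_time=10.0e6,
            equilibration_dt=10.0,
            seed=seed,
        )
    if name == "small":
        return RunConfig(
            build=BuildConfig(
                fibril_diameter=67.0,
                n_d_periods=3,
                d_period=210.0,
                particles_per_molecule=37,
                n_extension_particles=6,
                n_clamp_particles=3,
            ),
            crosslinks=CrosslinkConfig(seed=seed),
            sim=SimConfig(dt=10.0, pull_velocity=5.0e-4, output_stride=20, damping=5000.0, max_strain=1.2, seed=seed),
            equilibration_time=10000.0,
            post_crosslink_equilibration_time=5000.0,
            equilibration_dt=10.0,
            seed=seed,
        )
    if name == "tiny":
        return RunConfig(
            build=BuildConfig(
                fibril_diameter=35.0,
                n_d_periods=2,
                d_period=210.0,
                particles_per_molecule=22,
                n_extension_particles=6,
                n_clamp_particles=3,
            ),
            crosslinks=CrosslinkConfig(seed=seed),
            sim=SimConfig(dt=10.0, pull_velocity=5.0e-4, output_stride=20, damping=5000.0, max_strain=1.2, seed=seed),
            equilibration_time=5000.0,
            post_crosslink_equilibration_time=2500.0,
            equilibration_dt=10.0,
            seed=seed,
        )
    raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
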