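"""Validated configuration models for the fibril builder and the simulator.

All models reject unknown keys and check the structural invariants up front
so that a bad run fails at load time, not hours into a simulation.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .units import LJ_MIN_FACTOR

#: Default lateral lattice spacing: the pair-potential equilibrium distance
#: 2^(1/6) * sigma_LJ, i.e. a relaxed hexagonal packing of molecules.
DEFAULT_LATTICE_SPACING = LJ_MIN_FACTOR * 14.72


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration input."""


class BuildConfig(BaseModel):
    """Geometry of the coarse-grained fibril (lengths in angstrom)."""

    model_config = ConfigDict(extra="forbid")

    fibril_diameter: float = 202.0
    lattice_spacing: float = DEFAULT_LATTICE_SPACING
    n_d_periods: int = 5
    d_period: float = 670.0
    gap_fraction: float = 0.6
    overlap_fraction: float = 0.4
    particles_per_molecule: int = 218
    particle_spacing: float = 14.0
    n_extension_particles: int = 40
    n_clamp_particles: int = 10
    molecule_path_mode: Literal["straight", "pdb_spline"] = "straight"
    pdb_path: Optional[str] = None
    #: Truncate molecule copies at the axial window [0, n_d_periods * D).
    #: When False each lattice site carries a single full, staggered molecule.
    truncate: bool = True

    @model_validator(mode="after")
    def _check(self) -> "BuildConfig":
        for name in ("fibril_diameter", "lattice_spacing", "d_period", "particle_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.gap_fraction + self.overlap_fraction - 1.0) > 1e-9:
            raise ValueError("gap_fraction + overlap_fraction must equal 1")
        if self.n_d_periods < 1:
            raise ValueError("n_d_periods must be >= 1")
        if self.particles_per_molecule < 2:
            raise ValueError("particles_per_molecule must be >= 2")
        if self.n_extension_particles < 0 or self.n_clamp_particles < 0:
            raise ValueError("particle counts must be non-negative")
        if self.n_clamp_particles > self.n_extension_particles:
            raise ValueError("n_clamp_particles must not exceed n_extension_particles")
        if self.molecule_path_mode == "pdb_spline" and self.pdb_path is None:
            raise ValueError("pdb_spline mode requires pdb_path")
        return self


class CrosslinkConfig(BaseModel):
    """Densities and placement parameters for cross-link insertion."""

    model_config = ConfigDict(extra="forbid")

    ecl_density_pct: float = 0.0
    ecl_valence: Literal["divalent", "trivalent"] = "divalent"
    age_per_tc: float = 0.0
    seed: int = 0
    #: Maximum formation distance for a cross-link; just above the cross-link
    #: equilibrium distance of 18.52 A so that only adjacent molecules qualify.
    candidate_cutoff: float = 25.0

    @model_validator(mode="after")
    def _check(self) -> "CrosslinkConfig":
        if not (0.0 <= self.ecl_density_pct <= 100.0):
            raise ValueError("ecl_density_pct must lie in [0, 100]")
        if self.age_per_tc < 0:
            raise ValueError("age_per_tc must be non-negative")
        if self.candidate_cutoff <= 0:
            raise ValueError("candidate_cutoff must be positive")
        return self


class SimConfig(BaseModel):
    """Parameters of one dynamics stage (equilibration or pulling)."""

    model_config = ConfigDict(extra="forbid")

    dt: float = 10.0  # fs
    temperature: float = 300.0  # K
    damping: float = 1000.0  # Langevin friction time, fs
    pull_velocity: float = 1.0e-4  # A/fs, total clamp separation rate
    max_strain: float = 0.6
    seed: int = 0
    output_stride: int = 20  # steps between time-series records
    skin: float = 6.0  # Verlet skin, A
    #: Stop pulling once the stride-averaged stress falls below this fraction
    #: of the running peak (total failure), provided the peak has passed.
    stop_fraction: float = 0.05

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.pull_velocity < 0:
            raise ValueError("pull_velocity must be non-negative")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.damping <= 0:
            raise ValueError("damping must be positive")
        if self.output_stride < 1:
            raise ValueError("output_stride must be >= 1")
        return self


class RunConfig(BaseModel):
    """Top-level bundle: geometry + cross-links + protocol + force field."""

    model_config = ConfigDict(extra="forbid")

    build: BuildConfig = Field(default_factory=BuildConfig)
    crosslinks: CrosslinkConfig = Field(default_factory=CrosslinkConfig)
    sim: SimConfig = Field(default_factory=SimConfig)
    #: Durations of the protocol stages, fs.
    equilibration_time: float = 10000.0
    post_crosslink_equilibration_time: float = 5000.0
    equilibration_dt: float = 10.0
    #: Optional overrides of force-field parameters (same layout as
    #: ForceField.to_dict()); empty dict keeps the bundled defaults.
    forcefield: dict = Field(default_factory=dict)
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig(**data)
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def config_hash(cfg: BaseModel | dict) -> str:
    """Stable SHA-256 hash of a configuration (key order independent)."""
    if isinstance(cfg, BaseModel):
        cfg = cfg.model_dump()
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
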