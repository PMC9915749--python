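"""End-to-end tensile experiment: build, relax, cross-link, pull, analyze.

This mirrors the study protocol: the bare fibril is energy-minimized
(steepest descent + conjugate gradient) and equilibrated in the NVT
ensemble with the clamps held fixed; cross-links are then inserted on the
equilibrated configuration; a short post-insertion equilibration follows;
finally the clamps are driven apart at constant velocity until total
failure.  All stage seeds are split deterministically from one root seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import analysis
from .config import RunConfig
from .crosslinks import Crosslink, insert_age, insert_ecl
from .engine import TensileResult, build_system, equilibrate_nvt, minimize, tensile_test
from .forcefield import ForceField, default_forcefield
from .geometry import FibrilGeometry, assemble_fibril
from .presets import make_preset


@dataclass
class ExperimentResult:
    """Everything a tensile experiment produced."""

    geometry: FibrilGeometry
    crosslinks: List[Crosslink]
    tensile: TensileResult
    summary: analysis.MechanicalSummary
    curve: analysis.StressStrainCurve
    census: "pandas.DataFrame"  # noqa: F821
    equilibration: dict = field(default_factory=dict)
    config: Optional[RunConfig] = None


def _stage_rngs(seed: int, n: int = 4) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_tensile_experiment(
    config: RunConfig | str,
    *,
    n_age: Optional[float] = None,
    ecl_pct: Optional[float] = None,
    ecl_valence: Optional[str] = None,
    seed: Optional[int] = None,
    forcefield: Optional[ForceField] = None,
    smoothing_window: int = 9,
) -> ExperimentResult:
    """Run one full tensile experiment.

    ``config`` may be a preset name ("tiny", "small", "paper") or a
    :class:`RunConfig`; the keyword arguments override the cross-link
    densities and the root seed.  The returned summary and failure census
    are computed on the stress-strain curve smoothed with a centered moving
    average of ``smoothing_window`` records (recorded in the curve metadata).
    """
    if isinstance(config, str):
        config = make_preset(config, seed=seed or 0)
    updates = {}
    if n_age is not None:
        updates["age_per_tc"] = n_age
    if ecl_pct is not None:
        updates["ecl_density_pct"] = ecl_pct
    if ecl_valence is not None:
        updates["ecl_valence"] = ecl_valence
    if updates:
        config = config.model_copy(
            update={"crosslinks": config.crosslinks.model_copy(update=updates)}
        )
    if seed is not None:
        config = config.model_copy(update={"seed": seed})

    ff = forcefield or (
        ForceField.from_dict(config.forcefield) if config.forcefield else default_forcefield()
    )
    rng_links, rng_eq, rng_post, rng_pull = _stage_rngs(config.seed)

    geometry = assemble_fibril(config.build)
    system = build_system(geometry, [], ff)
    minimize(system)

    # Equilibration couples strongly to the bath (fast thermalization); the
    # production pull keeps whatever weaker damping the run config sets.
    eq_sim = config.sim.model_copy(
        update={
            "dt": config.equilibration_dt,
            "pull_velocity": 0.0,
            "damping": min(config.sim.damping, 1000.0),
            "seed": config.seed,
        }
    )
    eq_info = equilibrate_nvt(system, eq_sim, config.equilibration_time, rng=rng_eq)

    # Cross-links form on the equilibrated configuration.
    geom_eq = dataclasses.replace(geometry, coords=system.x.copy())
    links = list(insert_ecl(geom_eq, config.crosslinks, rng_links))
    links += insert_age(geom_eq, config.crosslinks, rng_links)

    linked = build_system(geom_eq, links, ff)
    linked.v = system.v.copy()
    nb_old = len(system.bonds)
    np.maximum(linked.rmax[:nb_old], system.rmax, out=linked.rmax[:nb_old])

    post_info = equilibrate_nvt(
        linked, eq_sim, config.post_crosslink_equilibration_time,
        rng=rng_post, seed_velocities=False,
    )

    tensile = tensile_test(linked, config.sim, rng=rng_pull)
    curve = analysis.stress_strain(tensile.timeseries, smoothing_window=smoothing_window)
    summary = analysis.summarize(curve)
    census = analysis.failure_census(tensile)
    return ExperimentResult(
        geometry=geometry,
        crosslinks=links,
        tensile=tensile,
        summary=summary,
        curve=curve,
        census=census,
        equilibration={"pre": eq_info["mean_temperature"], "post": post_info["mean_temperature"]},
        config=config,
    )
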