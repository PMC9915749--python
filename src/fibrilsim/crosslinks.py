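"""Stochastic insertion of enzymatic and AGE cross-links into a fibril.

Enzymatic cross-links (ECLs) are lysyl-oxidase-mediated covalent links at
the telopeptide ends of the TC molecules.  A density of 100% corresponds to
two ECLs per molecule (one per end); at lower densities the cross-linked
ends are drawn at random such that no telopeptide end carries more than one
cross-link.  Each selected end links its terminal particle to the nearest
particle of the nearest distinct molecule (divalent) or of the two nearest
distinct molecules (trivalent, realized as two bonds sharing the hub).

AGE cross-links (glucosepane-parameterized) form between helical-domain
particles of two neighboring molecules; telopeptide ends and the artificial
extension particles are excluded as binding sites.  The total count is
``round(N_AGE * N_molecules)``; below one cross-link per molecule the
originating molecules are drawn without replacement so no selected molecule
hosts more than one.  Exact duplicate particle pairs are rejected and
redrawn; all formation distances respect the candidate cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.spatial import cKDTree

from .config import CrosslinkConfig
from .geometry import REGION_CORE, REGION_EXT, FibrilGeometry


class InsertionError(RuntimeError):
    """Raised when the requested cross-link density cannot be realized."""


@dataclass
class Crosslink:
    """One cross-link bond record (trivalent ECLs contribute two records)."""

    cls: str            # "ecl_divalent", "ecl_trivalent" or "age"
    i: int              # hub (ECL telopeptide terminal) / originating particle
    j: int              # partner particle on a distinct molecule
    mol_i: int
    mol_j: int
    distance: float     # formation distance, A
    group: int          # shared id for the two bonds of one trivalent ECL

    @property
    def pair(self) -> tuple[int, int]:
        return (min(self.i, self.j), max(self.i, self.j))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _nearest_partners(tree, positions, eligible_idx, pos, mol_of, own_mol, cutoff, k=64):
    """Eligible particles near pos, sorted by distance, on distinct molecules.

    Yields (global_index, distance) tuples.
    """
    k = min(k, len(eligible_idx))
    dist, loc = tree.query(pos, k=k, distance_upper_bound=cutoff)
    dist = np.atleast_1d(dist)
    loc = np.atleast_1d(loc)
    for d, l in zip(dist, loc):
        if not np.isfinite(d) or l >= len(eligible_idx):
            break
        g = int(eligible_idx[l])
        if mol_of[g] != own_mol:
            yield g, float(d)


def insert_ecl(
    geometry: FibrilGeometry, config: CrosslinkConfig, rng: np.random.Generator
) -> List[Crosslink]:
    """Insert enzymatic cross-links at randomly selected telopeptide ends."""
    ends = geometry.telo_ends
    if config.ecl_density_pct == 0 or not ends:
        return []
    n_target = _round_half_up(config.ecl_density_pct / 100.0 * len(ends))
    order = rng.permutation(len(ends))[:n_target]

    partner_mask = geometry.region != REGION_EXT
    eligible_idx = np.nonzero(partner_mask)[0]
    tree = cKDTree(geometry.coords[eligible_idx])
    mol_of = geometry.molecule_id

    cls = f"ecl_{config.ecl_valence}"
    n_partners = 2 if config.ecl_valence == "trivalent" else 1
    out: List[Crosslink] = []
    shortfall = 0
    group = 0
    for e in order:
        end = ends[int(e)]
        hub = end.terminal
        chosen: list[tuple[int, float]] = []
        chosen_mols = {mol_of[hub]}
        for g, d in _nearest_partners(
            tree, geometry.coords, eligible_idx, geometry.coords[hub],
            mol_of, mol_of[hub], config.candidate_cutoff,
        ):
            if mol_of[g] in chosen_mols:
                continue
            chosen.append((g, d))
            chosen_mols.add(mol_of[g])
            if len(chosen) == n_partners:
                break
        if len(chosen) < n_partners:
            shortfall += 1
            continue
        for g, d in chosen:
            out.append(
                Crosslink(cls, int(hub), g, int(mol_of[hub]), int(mol_of[g]), d, group)
            )
        group += 1
    if shortfall:
        warnings.warn(
            f"{shortfall} telopeptide end(s) had no eligible partner within "
            f"{config.candidate_cutoff} A and were skipped",
            stacklevel=2,
        )
    return out


def insert_age(
    geometry: FibrilGeometry, config: CrosslinkConfig, rng: np.random.Generator
) -> List[Crosslink]:
    """Insert AGE cross-links between helical-domain particles."""
    n_mol = geometry.n_molecules
    total = _round_half_up(config.age_per_tc * n_mol)
    if total == 0:
        return []

    eligible_mask = geometry.region == REGION_CORE
    eligible_idx = np.nonzero(eligible_mask)[0]
    if len(eligible_idx) == 0:
        raise InsertionError("no eligible AGE binding sites in this geometry")
    tree = cKDTree(geometry.coords[eligible_idx])
    mol_of = geometry.molecule_id

    used_pairs: set[tuple[int, int]] = set()
    out: List[Crosslink] = []
    group = 0

    def try_origin(origin: int) -> bool:
        nonlocal group
        for g, d in _nearest_partners(
            tree, geometry.coords, eligible_idx, geometry.coords[origin],
            mol_of, mol_of[origin], config.candidate_cutoff,
        ):
            pair = (min(origin, g), max(origin, g))
            if pair in used_pairs:
                continue
            used_pairs.add(pair)
            out.append(
                Crosslink("age", int(origin), g, int(mol_of[origin]), int(mol_of[g]), d, group)
            )
            group += 1
            return True
        return False

    if config.age_per_tc < 1.0:
        # One cross-link per randomly selected molecule.
        mols_with_sites = np.unique(mol_of[eligible_idx])
        if total > len(mols_with_sites):
            raise InsertionError(
                f"requested {total} AGE cross-links but only "
                f"{len(mols_with_sites)} molecules have eligible sites"
            )
        mol_order = rng.permutation(mols_with_sites)
        placed = 0
        for mol in mol_order:
            if placed == total:
                break
            sites = eligible_idx[mol_of[eligible_idx] == mol]
            for origin in rng.permutation(sites):
                if try_origin(int(origin)):
                    placed += 1
                    break
        if placed < total:
            raise InsertionError(
                f"could only place {placed} of {total} AGE cross-links "
                f"within the candidate cutoff"
            )
    else:
        max_attempts = 200 + 60 * total
        attempts = 0
        while len(out) < total and attempts < max_attempts:
            attempts += 1
            origin = int(rng.choice(eligible_idx))
            try_origin(origin)
        if len(out) < total:
            raise InsertionError(
                f"could only place {len(out)} of {total} AGE cross-links; "
                f"the achievable maximum at this density/cutoff is about {len(out)}"
            )
    return out


def crosslinks_to_table(links: List[Crosslink]) -> "pandas.DataFrame":  # noqa: F821
    """Cross-link set as a DataFrame (CSV-friendly export)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "class": [l.cls for l in links],
            "particle_i": [l.i for l in links],
            "particle_j": [l.j for l in links],
            "molecule_i": [l.mol_i for l in links],
            "molecule_j": [l.mol_j for l in links],
            "formation_distance": [l.distance for l in links],
            "group": [l.group for l in links],
        }
    )


def crosslinks_from_table(df) -> List[Crosslink]:
    return [
        Crosslink(
            str(r["class"]), int(r["particle_i"]), int(r["particle_j"]),
            int(r["molecule_i"]), int(r["molecule_j"]),
            float(r["formation_distance"]), int(r["group"]),
        )
        for _, r in df.iterrows()
    ]
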