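"""File formats: extended XYZ, LAMMPS data, CSV/JSON outputs, run manifest.

All writes are atomic (write to a temporary sibling, then rename), so a
crashed run never leaves a truncated output behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .config import RunConfig, config_hash
from .crosslinks import Crosslink
from .forcefield import BOND_CLASS_CODES, BOND_CLASSES, ForceField
from .geometry import REGION_CORE, REGION_EXT, REGION_TELO, FibrilGeometry

_REGION_TAGS = {REGION_CORE: "core", REGION_TELO: "telo", REGION_EXT: "ext"}
_REGION_CODES = {v: k for k, v in _REGION_TAGS.items()}
#: Element-like species tag per region for XYZ viewers.
_REGION_ELEMENTS = {REGION_CORE: "C", REGION_TELO: "N", REGION_EXT: "O"}


def _atomic_write(path: Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_xyz(
    path: str | Path,
    coords: np.ndarray,
    molecule_id: Optional[np.ndarray] = None,
    region: Optional[np.ndarray] = None,
    comment: str = "",
) -> None:
    """Extended XYZ: species, x, y, z, molecule id (1-based), region tag."""
    n = len(coords)
    molecule_id = molecule_id if molecule_id is not None else np.zeros(n, dtype=int)
    region = region if region is not None else np.zeros(n, dtype=int)
    lines = [str(n), comment or "fibrilsim geometry (A)"]
    for i in range(n):
        el = _REGION_ELEMENTS.get(int(region[i]), "C")
        tag = _REGION_TAGS.get(int(region[i]), "core")
        x, y, z = coords[i]
        lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f} {int(molecule_id[i]) + 1} {tag}")
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def read_xyz(path: str | Path):
    """Read an extended XYZ written by :func:`write_xyz`.

    Returns (coords, molecule_id (0-based), region codes).
    """
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        coords = np.empty((n, 3))
        mols = np.empty(n, dtype=np.int64)
        regs = np.empty(n, dtype=np.int8)
        for i in range(n):
            parts = fh.readline().split()
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            mols[i] = int(parts[4]) - 1
            regs[i] = _REGION_CODES.get(parts[5], REGION_CORE)
    return coords, mols, regs


def write_lammps_data(
    path: str | Path,
    geometry: FibrilGeometry,
    crosslinks: Sequence[Crosslink] = (),
    forcefield: Optional[ForceField] = None,
    margin: float = 100.0,
) -> None:
    """LAMMPS data file (atom-style full) with per-class bond types.

    Bond types are numbered 1..5 in the canonical class order (TC core,
    TC extension, divalent ECL, trivalent ECL, AGE); a single angle type
    covers all triplets (per-triplet equilibrium angles are not expressible
    in a plain data file and are emitted as a comment).
    """
    from .forcefield import PARTICLE_MASS

    mass = forcefield.mass if forcefield is not None else PARTICLE_MASS
    g = geometry
    n = g.n_particles
    bonds = [(int(c) + 1, int(i) + 1, int(j) + 1) for (i, j), c in zip(g.bonds, g.bond_class)]
    for link in crosslinks:
        bonds.append((BOND_CLASS_CODES[link.cls] + 1, link.i + 1, link.j + 1))
    lo = g.coords.min(axis=0) - margin
    hi = g.coords.max(axis=0) + margin

    out = ["# fibrilsim collagen fibril (units real)", ""]
    out.append(f"{n} atoms")
    out.append(f"{len(bonds)} bonds")
    out.append(f"{len(g.angles)} angles")
    out.append("")
    out.append("1 atom types")
    out.append(f"{len(BOND_CLASSES)} bond types")
    out.append("1 angle types  # per-triplet equilibrium angles set elsewhere")
    out.append("")
    out.append(f"{lo[0]:.4f} {hi[0]:.4f} xlo xhi")
    out.append(f"{lo[1]:.4f} {hi[1]:.4f} ylo yhi")
    out.append(f"{lo[2]:.4f} {hi[2]:.4f} zlo zhi")
    out += ["", "Masses", "", f"1 {mass:.4f}", "", "Atoms # full", ""]
    for i in range(n):
        x, y, z = g.coords[i]
        out.append(f"{i + 1} {int(g.molecule_id[i]) + 1} 1 0.0 {x:.6f} {y:.6f} {z:.6f}")
    out += ["", "Bonds", ""]
    for k, (bt, i, j) in enumerate(bonds, start=1):
        out.append(f"{k} {bt} {i} {j}")
    if len(g.angles):
        out += ["", "Angles", ""]
        for k, (i, j, l) in enumerate(g.angles, start=1):
            out.append(f"{k} 1 {int(i) + 1} {int(j) + 1} {int(l) + 1}")
    _atomic_write(Path(path), "\n".join(out) + "\n")


def read_lammps_data_counts(path: str | Path) -> dict:
    """Counts and sections from a LAMMPS data file (round-trip checking)."""
    counts = {"atoms": 0, "bonds": 0, "angles": 0}
    bonds: List[tuple] = []
    angles: List[tuple] = []
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) == 2 and parts[1] in counts:
                counts[parts[1]] = int(parts[0])
                continue
            if parts[0] in ("Masses", "Atoms", "Bonds", "Angles", "Velocities"):
                section = parts[0]
                continue
            if section == "Bonds" and len(parts) >= 4:
                bonds.append((int(parts[1]), int(parts[2]) - 1, int(parts[3]) - 1))
            elif section == "Angles" and len(parts) >= 5:
                angles.append((int(parts[2]) - 1, int(parts[3]) - 1, int(parts[4]) - 1))
    counts["bond_list"] = bonds
    counts["angle_list"] = angles
    return counts


def write_json(path: str | Path, payload: dict) -> None:
    _atomic_write(Path(path), json.dumps(payload, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_manifest(
    path: str | Path,
    config: RunConfig,
    seed: int,
    outputs: Sequence[str],
    stages: Optional[dict] = None,
) -> dict:
    """Run manifest: config hash, seed, package version, stage timestamps."""
    from . import __version__

    manifest = {
        "package": "fibrilsim",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "created": datetime.now(timezone.utc).isoformat(),
        "stages": stages or {},
        "outputs": sorted(str(o) for o in outputs),
    }
    write_json(path, manifest)
    return manifest


def save_state(path: str | Path, system) -> None:
    """Checkpoint the full mutable simulation state (npz)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        x=system.x, v=system.v, rmax=system.rmax, time_fs=system.time_fs,
        bonds=system.bonds, bond_class_codes=system.bond_class_codes,
    )


def load_state(path: str | Path, system) -> None:
    """Restore a checkpoint into an existing system.

    The checkpoint's bond list may be a prefix of the system's (a state
    saved before cross-link insertion loaded into the cross-linked system);
    the extra bonds start their rupture state from the restored coordinates.
    """
    data = np.load(path)
    nb_saved = len(data["rmax"])
    if (
        data["x"].shape != system.x.shape
        or nb_saved > len(system.rmax)
        or not np.array_equal(data["bonds"], system.bonds[:nb_saved])
    ):
        raise ValueError("checkpoint does not match this system's topology")
    rmax = np.linalg.norm(
        data["x"][system.bonds[:, 1]] - data["x"][system.bonds[:, 0]], axis=1
    ) if len(system.bonds) else np.empty(0)
    rmax[:nb_saved] = np.maximum(rmax[:nb_saved], data["rmax"])
    system.restore_state(
        {"x": data["x"], "v": data["v"], "rmax": rmax, "time_fs": float(data["time_fs"])}
    )
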