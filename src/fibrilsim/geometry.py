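"""Construction of the coarse-grained collagen fibril geometry.

A fibril is a bundle of tropocollagen (TC) molecules, each represented as a
chain of particles 14 A apart.  The cross-section is a triangular lattice of
molecule positions clipped to a circle; along the fibril axis the molecules
are staggered by integer multiples of the D-period (67 nm) in the canonical
five-stagger pattern, which produces the alternating gap (0.6 D) and overlap
(0.4 D) zones of the native fibril.

The modeled system is one axial window of ``n_d_periods * D``.  Molecule
copies are laid on each lattice line with an axial period of one molecule
length plus one gap, and clipped to the window.  Line ends that touch the
window boundary are continued by extension particles (reinforced,
effectively unbreakable bonds) whose outermost particles form the rigid
clamps used by the tensile protocol.  Interior molecule ends are physical
molecule ends: their four outermost particles are the telopeptides, which
host enzymatic cross-links and are excluded as AGE binding sites.

Coordinates are Cartesian angstroms with the fibril axis along +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import BuildConfig

#: Particle region codes.
REGION_CORE = 0   # helical domain, AGE-eligible
REGION_TELO = 1   # telopeptide (4 outermost physiological particles per end)
REGION_EXT = 2    # non-physiological extension particles at the clamped ends

#: Number of particles forming one telopeptide end.
N_TELO_PARTICLES = 4

#: Bond-class codes used by the geometry (force-field codes 0 and 1).
BOND_TC_CORE = 0
BOND_TC_EXT = 1


class ConstructionError(RuntimeError):
    """Raised when the assembled geometry is physically inconsistent."""


@dataclass(frozen=True)
class CrossSection:
    """Triangular-lattice molecule positions within the fibril cross-section."""

    sites: np.ndarray      # (n, 2) y/z coordinates, A
    rows: np.ndarray       # (n,) integer lattice row
    cols: np.ndarray       # (n,) integer lattice column

    def __len__(self) -> int:
        return len(self.sites)

    def stagger_indices(self, n_periods: int) -> np.ndarray:
        """Stagger index per site: (row + 2*col) mod n_periods.

        This assignment spreads the axial offsets cyclically over the lattice
        so the lateral neighbors of any molecule carry the other offsets, as
        in the canonical microfibril packing.
        """
        return (self.rows + 2 * self.cols) % n_periods


def mesh_cross_section(diameter: float, spacing: float) -> CrossSection:
    """Mesh the circular fibril cross-section with a triangular lattice.

    Returns all lattice sites within ``diameter/2`` of the center; one site
    always lies at the center itself.  Deterministic for fixed inputs.
    """
    if diameter <= 0 or spacing <= 0:
        raise ValueError("diameter and spacing must be positive")
    radius = diameter / 2.0
    row_height = spacing * math.sqrt(3.0) / 2.0
    max_row = int(math.floor(radius / row_height)) + 1
    sites, rows, cols = [], [], []
    for row in range(-max_row, max_row + 1):
        y = row * row_height
        if abs(y) > radius:
            continue
        offset = (row % 2) * spacing / 2.0
        half_width = math.sqrt(max(radius * radius - y * y, 0.0))
        cmin = int(math.floor((-half_width - offset) / spacing)) - 1
        cmax = int(math.ceil((half_width - offset) / spacing)) + 1
        for col in range(cmin, cmax + 1):
            z = offset + col * spacing
            if y * y + z * z <= radius * radius + 1e-9:
                sites.append((y, z))
                rows.append(row)
                cols.append(col)
    order = np.lexsort((np.array(cols), np.array(rows)))
    return CrossSection(
        sites=np.asarray(sites, dtype=float)[order],
        rows=np.asarray(rows, dtype=np.int64)[order],
        cols=np.asarray(cols, dtype=np.int64)[order],
    )


@dataclass(frozen=True)
class MoleculePath:
    """Particle positions of one TC molecule, equidistant along its path."""

    coords: np.ndarray          # (n, 3), A; axial direction +x, starts at x=0
    spacing: float

    def __post_init__(self) -> None:
        n = len(self.coords)
        if n < 2:
            raise ValueError("a molecule path needs at least 2 particles")
        d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        if np.max(np.abs(d - self.spacing)) > 1e-6 * self.spacing:
            raise ValueError("consecutive particles must be equidistant at `spacing`")

    @property
    def n_particles(self) -> int:
        return len(self.coords)

    @property
    def equilibrium_angles_deg(self) -> np.ndarray:
        """Angles phi_i at each interior particle (degrees); empty for n < 3."""
        return extract_equilibrium_angles(self.coords)


def build_molecule_path(
    n_particles: int, spacing: float, axis: Sequence[float] = (1.0, 0.0, 0.0)
) -> MoleculePath:
    """Straight molecule path: collinear, equidistant particles along `axis`."""
    if n_particles < 2:
        raise ValueError("n_particles must be >= 2")
    u = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(u)
    if nrm == 0:
        raise ValueError("axis must be a non-zero vector")
    u = u / nrm
    coords = np.outer(np.arange(n_particles) * spacing, u)
    return MoleculePath(coords=coords, spacing=spacing)


def extract_equilibrium_angles(coords: np.ndarray) -> np.ndarray:
    """Angle (degrees, in (0, 180]) at each interior particle of a chain."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        return np.empty(0)
    a = coords[:-2] - coords[1:-1]
    b = coords[2:] - coords[1:-1]
    cosphi = np.einsum("ij,ij->i", a, b) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosphi, -1.0, 1.0)))


def spline_path_from_pdb(pdb_path: str, spacing: float) -> MoleculePath:
    """Derive a molecule path by spline-fitting a TC molecule structure.

    The C-alpha trace of the structure (all chains pooled, ordered along the
    molecule axis) is fitted with a smoothing spline and re-sampled at
    equidistant arc-length intervals of ``spacing``.  The number of particles
    is ``floor(arclength / spacing) + 1``.  The resulting path is recentered
    so it starts at x = 0 with its mean axis along +x.
    """
    from scipy.interpolate import splev, splprep

    ca = _read_ca_coordinates(pdb_path)
    if len(ca) < 4:
        raise ValueError("structure provides fewer than 4 CA atoms")
    # Principal axis; order the trace along it.
    center = ca.mean(axis=0)
    u, s, vt = np.linalg.svd(ca - center, full_matrices=False)
    axis = vt[0]
    proj = (ca - center) @ axis
    order = np.argsort(proj)
    pts = ca[order]
    # Collapse near-duplicate parameter values to keep splprep happy.
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-6
    pts = pts[keep]
    smoothing = len(pts) * 4.0  # A^2-scale smoothing of the helical wiggle
    tck, _ = splprep(pts.T, s=smoothing, k=min(3, len(pts) - 1))
    # Arc length by dense sampling.
    tt = np.linspace(0.0, 1.0, 20 * len(pts))
    dense = np.asarray(splev(tt, tck)).T
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = int(math.floor(total / spacing + 1e-6)) + 1
    targets = np.arange(n) * spacing
    t_at = np.interp(targets, arclen, tt)
    coords = np.asarray(splev(t_at, tck)).T
    # Exact equidistance: project small residuals out by rescaling each step.
    for i in range(1, n):
        d = coords[i] - coords[i - 1]
        coords[i] = coords[i - 1] + d * (spacing / np.linalg.norm(d))
    # Recenter: start at origin, principal axis along +x.
    coords = coords - coords[0]
    u2, s2, vt2 = np.linalg.svd(coords - coords.mean(axis=0), full_matrices=False)
    ax = vt2[0]
    if (coords[-1] - coords[0]) @ ax < 0:
        ax = -ax
    # Build an orthonormal frame with ax -> +x.
    e1 = ax
    tmp = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, tmp)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    coords = coords @ np.stack([e1, e2, e3], axis=1)
    return MoleculePath(coords=coords, spacing=spacing)


def _read_ca_coordinates(pdb_path: str) -> np.ndarray:
    """C-alpha coordinates from a PDB file (plain-text ATOM records)."""
    coords = []
    try:
        with open(pdb_path) as fh:
            for line in fh:
                if line.startswith(("ATOM", "HETATM")) and line[12:16].strip() == "CA":
                    coords.append(
                        (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                    )
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {pdb_path}: {exc}") from exc
    if not coords:
        raise ValueError(f"no CA atoms found in {pdb_path}")
    return np.asarray(coords, dtype=float)


@dataclass
class TelopeptideEnd:
    """One physical molecule end eligible for enzymatic cross-linking."""

    molecule: int
    side: str                 # "left" or "right" (toward -x / +x)
    particles: np.ndarray     # telopeptide particle indices, outermost first
    terminal: int             # the outermost physiological particle


@dataclass
class FibrilGeometry:
    """The assembled coarse-grained fibril."""

    coords: np.ndarray            # (N, 3) A
    molecule_id: np.ndarray       # (N,) int64
    region: np.ndarray            # (N,) int8, REGION_* codes
    bonds: np.ndarray             # (nb, 2) int64
    bond_class: np.ndarray        # (nb,) int8, BOND_TC_* codes
    angles: np.ndarray            # (na, 3) int64, apex in the middle
    angle_phi0_deg: np.ndarray    # (na,)
    clamp_left: np.ndarray        # int64 particle indices
    clamp_right: np.ndarray
    telo_ends: List[TelopeptideEnd]
    cross_section_area: float     # A^2
    gauge_length: float           # A, initial clamp-to-clamp distance
    window_length: float          # A, axial extent of the modeled region
    config: Optional[BuildConfig] = None
    stagger: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_particles(self) -> int:
        return len(self.coords)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_id.max()) + 1 if len(self.molecule_id) else 0

    def molecule_particles(self, mol: int) -> np.ndarray:
        return np.nonzero(self.molecule_id == mol)[0]


def assemble_fibril(config: BuildConfig, path: Optional[MoleculePath] = None) -> FibrilGeometry:
    """Assemble the full fibril geometry from a build configuration.

    If ``path`` is None it is built according to ``config.molecule_path_mode``.
    """
    if path is None:
        if config.molecule_path_mode == "straight":
            path = build_molecule_path(config.particles_per_molecule, config.particle_spacing)
        else:
            path = spline_path_from_pdb(config.pdb_path, config.particle_spacing)

    cs = mesh_cross_section(config.fibril_diameter, config.lattice_spacing)
    stagger = cs.stagger_indices(config.n_d_periods)

    d = config.d_period
    window = config.n_d_periods * d
    px = path.coords[:, 0]
    mol_len = float(px[-1] - px[0])
    gap = config.gap_fraction * d
    period = mol_len + gap
    spacing = config.particle_spacing
    n_path = path.n_particles

    coords: list[np.ndarray] = []
    molecule_id: list[np.ndarray] = []
    region: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    bond_class: list[int] = []
    clamp_left: list[int] = []
    clamp_right: list[int] = []
    telo_ends: list[TelopeptideEnd] = []
    seg_particle_ranges: list[tuple[int, int]] = []  # for angle construction

    n_total = 0
    mol_counter = 0

    for site_idx in range(len(cs)):
        yz = cs.sites[site_idx]
        s = int(stagger[site_idx])
        if config.truncate:
            k_lo = int(math.floor((-mol_len - s * d) / period)) - 1
            k_hi = int(math.ceil((window - s * d) / period)) + 1
            k_range = range(k_lo, k_hi + 1)
        else:
            k_range = range(0, 1)
        for k in k_range:
            x0 = s * d + k * period
            xs = x0 + px
            if config.truncate:
                keep = (xs >= -1e-9) & (xs < window - 1e-9)
            else:
                keep = np.ones(n_path, dtype=bool)
            if keep.sum() < 2:
                continue
            idx = np.nonzero(keep)[0]
            first_path, last_path = idx[0], idx[-1]
            n_seg = len(idx)
            seg_xyz = np.empty((n_seg, 3))
            seg_xyz[:, 0] = xs[idx]
            seg_xyz[:, 1] = yz[0] + path.coords[idx, 1]
            seg_xyz[:, 2] = yz[1] + path.coords[idx, 2]

            left_true = first_path == 0
            right_true = last_path == n_path - 1
            if config.truncate:
                # An end is "at the boundary" when its next particle would
                # fall outside the window (cut ends, or true ends starting
                # within one spacing of the edge).
                tol = 1e-6 * spacing
                left_boundary = seg_xyz[0, 0] < spacing + tol
                right_boundary = seg_xyz[-1, 0] > window - spacing - tol
            else:
                left_boundary = right_boundary = config.n_extension_particles > 0

            seg_region = np.full(n_seg, REGION_CORE, dtype=np.int8)
            if left_true:
                seg_region[: min(N_TELO_PARTICLES, n_seg)] = REGION_TELO
            if right_true:
                seg_region[max(0, n_seg - N_TELO_PARTICLES):] = REGION_TELO

            next_id = n_total
            n_ext = config.n_extension_particles

            # --- left extension ---
            ext_left = np.empty((0, 3))
            if left_boundary and n_ext > 0:
                offs = -spacing * np.arange(n_ext, 0, -1)
                ext_left = np.tile(seg_xyz[0], (n_ext, 1))
                ext_left[:, 0] += offs
            n_left = len(ext_left)

            # --- right extension ---
            ext_right = np.empty((0, 3))
            if right_boundary and n_ext > 0:
                offs = spacing * np.arange(1, n_ext + 1)
                ext_right = np.tile(seg_xyz[-1], (n_ext, 1))
                ext_right[:, 0] += offs
            n_right = len(ext_right)

            all_xyz = np.vstack([ext_left, seg_xyz, ext_right])
            all_region = np.concatenate([
                np.full(n_left, REGION_EXT, dtype=np.int8),
                seg_region,
                np.full(n_right, REGION_EXT, dtype=np.int8),
            ])
            n_all = len(all_xyz)
            gids = next_id + np.arange(n_all)

            coords.append(all_xyz)
            region.append(all_region)
            molecule_id.append(np.full(n_all, mol_counter, dtype=np.int64))
            seg_particle_ranges.append((next_id, next_id + n_all))

            for a_loc in range(n_all - 1):
                i, j = gids[a_loc], gids[a_loc + 1]
                is_ext = all_region[a_loc] == REGION_EXT or all_region[a_loc + 1] == REGION_EXT
                bonds.append((i, j))
                bond_class.append(BOND_TC_EXT if is_ext else BOND_TC_CORE)

            ncl = config.n_clamp_particles
            if n_left > 0 and ncl > 0:
                clamp_left.extend(gids[:ncl].tolist())
            if n_right > 0 and ncl > 0:
                clamp_right.extend(gids[n_all - ncl:].tolist())

            if left_true and not left_boundary:
                npart = min(N_TELO_PARTICLES, n_seg)
                parts = gids[n_left: n_left + npart]
                telo_ends.append(
                    TelopeptideEnd(mol_counter, "left", parts.copy(), int(parts[0]))
                )
            if right_true and not right_boundary:
                npart = min(N_TELO_PARTICLES, n_seg)
                parts = gids[n_left + n_seg - npart: n_left + n_seg][::-1]
                telo_ends.append(
                    TelopeptideEnd(mol_counter, "right", parts.copy(), int(parts[0]))
                )

            n_total += n_all
            mol_counter += 1

    if n_total == 0:
        raise ConstructionError("no particles generated; check the configuration")

    coords_arr = np.vstack(coords)
    region_arr = np.concatenate(region)
    mol_arr = np.concatenate(molecule_id)
    bonds_arr = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    bclass_arr = np.asarray(bond_class, dtype=np.int8)

    # Angles: one per interior particle of each chain (extensions included);
    # the as-built triplet angles serve as the equilibrium angles phi_i.
    ang_list = []
    for lo, hi in seg_particle_ranges:
        n_seg = hi - lo
        if n_seg >= 3:
            base = lo + np.arange(n_seg - 2)
            ang_list.append(np.stack([base, base + 1, base + 2], axis=1))
    if ang_list:
        angles_arr = np.vstack(ang_list).astype(np.int64)
        phi0 = _triplet_angles(coords_arr, angles_arr)
    else:
        angles_arr = np.empty((0, 3), dtype=np.int64)
        phi0 = np.empty(0)

    # Overlap sanity check.
    if n_total > 1:
        tree = cKDTree(coords_arr)
        dmin, _ = tree.query(coords_arr, k=2)
        if float(dmin[:, 1].min()) < 0.5 * spacing:
            raise ConstructionError(
                f"overlapping particles: min distance {dmin[:, 1].min():.3f} A "
                f"< 0.5 * spacing ({0.5 * spacing:.3f} A)"
            )

    clamp_left_arr = np.asarray(sorted(clamp_left), dtype=np.int64)
    clamp_right_arr = np.asarray(sorted(clamp_right), dtype=np.int64)
    if len(clamp_left_arr) and len(clamp_right_arr):
        gauge = float(
            coords_arr[clamp_right_arr, 0].mean() - coords_arr[clamp_left_arr, 0].mean()
        )
    else:
        gauge = float(coords_arr[:, 0].max() - coords_arr[:, 0].min())

    return FibrilGeometry(
        coords=coords_arr,
        molecule_id=mol_arr,
        region=region_arr,
        bonds=bonds_arr,
        bond_class=bclass_arr,
        angles=angles_arr,
        angle_phi0_deg=phi0,
        clamp_left=clamp_left_arr,
        clamp_right=clamp_right_arr,
        telo_ends=telo_ends,
        cross_section_area=math.pi * (config.fibril_diameter / 2.0) ** 2,
        gauge_length=gauge,
        window_length=window if config.truncate else float(
            coords_arr[:, 0].max() - coords_arr[:, 0].min()
        ),
        config=config,
        stagger=stagger,
    )


def _triplet_angles(coords: np.ndarray, angles: np.ndarray) -> np.ndarray:
    a = coords[angles[:, 0]] - coords[angles[:, 1]]
    b = coords[angles[:, 2]] - coords[angles[:, 1]]
    cosphi = np.einsum("ij,ij->i", a, b) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosphi, -1.0, 1.0)))
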