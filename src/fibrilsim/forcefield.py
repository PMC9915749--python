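"""Breakable-bond force field for the coarse-grained collagen fibril model.

Three interaction terms make up the total energy

    E_total = E_bond + E_angle + E_inter

* **Bonds** follow a tri-linear tension law: a soft initial branch of
  stiffness ``k0`` up to the critical hyperelastic distance ``r1``, a stiff
  branch ``k1`` up to the breaking distance ``r_break``, and a short
  regularization ramp of width ``a = z * (r_break - r1)`` over which the
  tension decays to zero.  A bond whose separation has ever exceeded
  ``r_break`` is counted as broken; once the separation has exceeded
  ``r_break + a`` the bond is permanently dead and carries no force.

  The default ("continuous") law is C0-continuous in r, which is what the
  regularization factor z is for.  A literal reading of the published
  piecewise form (second branch ``k1*(r - r0)``, third branch
  ``-z*k1*(r - r0)``) is discontinuous at ``r1`` and ``r_break``; it is kept
  available as ``bond_law="printed"`` for comparison.

* **Angles** are harmonic in the angle itself, ``E = 1/2 k_b (phi - phi_i)^2``
  with per-triplet equilibrium angles ``phi_i`` taken from the molecule path
  (180 degrees for straight chains).  The published force expression carries
  a trailing angle factor that is dimensionally anomalous; it is interpreted
  here as a plain harmonic angle law.

* **Pairs** interact through a 12-6 Lennard-Jones potential with a soft core:
  below ``lambda * sigma`` the force is capped at its value at
  ``lambda * sigma`` so that overlapping particles never see a diverging
  repulsion.  The potential is truncated at a finite cutoff and shifted to
  zero there (cutoff=None disables truncation and recovers the bare law).

Parameter values for the five bond classes (collagen backbone, reinforced
extension bonds at the clamped molecule ends, divalent and trivalent
enzymatic cross-links, AGE cross-links parameterized on glucosepane) are
bundled in :func:`default_forcefield`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .units import LJ_MIN_FACTOR

#: Canonical bond-class names, in kernel code order.
BOND_CLASSES = ("tc_core", "tc_extension", "ecl_divalent", "ecl_trivalent", "age")
BOND_CLASS_CODES = {name: i for i, name in enumerate(BOND_CLASSES)}

#: Mass of one mesoscale particle (amu); roughly 12 residues of all three
#: alpha chains.
PARTICLE_MASS = 1358.7


@dataclass(frozen=True)
class BondParams:
    """Tri-linear breakable bond parameters (lengths in A, k in kcal/mol/A^2)."""

    r0: float
    r1: float
    r_break: float
    k0: float
    k1: float
    z: float = 0.05

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 < self.r_break):
            raise ValueError(
                f"require r0 < r1 < r_break, got {self.r0}, {self.r1}, {self.r_break}"
            )
        if not (self.k1 > self.k0 > 0):
            raise ValueError(f"require k1 > k0 > 0, got k0={self.k0}, k1={self.k1}")
        if not (0 < self.z < 1):
            raise ValueError(f"require 0 < z < 1, got z={self.z}")

    @property
    def a(self) -> float:
        """Width of the post-break regularization ramp, a = z*(r_break - r1)."""
        return self.z * (self.r_break - self.r1)

    @property
    def peak_tension(self) -> float:
        """Tension at the breaking distance (bond strength)."""
        return self.k0 * (self.r1 - self.r0) + self.k1 * (self.r_break - self.r1)


@dataclass(frozen=True)
class AngleParams:
    """Harmonic bending parameters: k_b in kcal/mol/rad^2, angle in degrees."""

    k_b: float
    phi0_deg: float = 180.0

    def __post_init__(self) -> None:
        if self.k_b <= 0:
            raise ValueError("bending stiffness k_b must be positive")


@dataclass(frozen=True)
class PairParams:
    """Soft-core Lennard-Jones parameters.

    cutoff=None means no truncation (bare LJ law); otherwise the energy is
    shifted so it vanishes continuously at the cutoff.
    """

    epsilon: float
    sigma: float
    lam: float = 0.9
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0 < self.lam < 1):
            raise ValueError("soft-core factor lambda must lie in (0, 1)")

    @property
    def r_min(self) -> float:
        """Location of the potential minimum, 2^(1/6) sigma."""
        return LJ_MIN_FACTOR * self.sigma

    def with_cutoff(self, cutoff: Optional[float]) -> "PairParams":
        return PairParams(self.epsilon, self.sigma, self.lam, cutoff)


@dataclass
class ForceField:
    """Complete parameter bundle: per-class bonds, angles, pairs, mass."""

    bonds: dict = field(default_factory=dict)  # class name -> BondParams
    angle: AngleParams = field(default_factory=lambda: AngleParams(k_b=14.98))
    pair: PairParams = field(
        default_factory=lambda: PairParams(epsilon=6.87, sigma=14.72, lam=0.9)
    )
    mass: float = PARTICLE_MASS
    bond_law: str = "continuous"  # or "printed"

    def __post_init__(self) -> None:
        if self.bond_law not in ("continuous", "printed"):
            raise ValueError("bond_law must be 'continuous' or 'printed'")

    def bond_params(self, cls: str) -> BondParams:
        return self.bonds[cls]

    def to_dict(self) -> dict:
        return {
            "bonds": {k: asdict(v) for k, v in self.bonds.items()},
            "angle": asdict(self.angle),
            "pair": asdict(self.pair),
            "mass": self.mass,
            "bond_law": self.bond_law,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForceField":
        return cls(
            bonds={k: BondParams(**v) for k, v in d.get("bonds", {}).items()},
            angle=AngleParams(**d["angle"]) if "angle" in d else AngleParams(k_b=14.98),
            pair=PairParams(**d["pair"]) if "pair" in d else PairParams(6.87, 14.72),
            mass=d.get("mass", PARTICLE_MASS),
            bond_law=d.get("bond_law", "continuous"),
        )


def default_forcefield(bond_law: str = "continuous", pair_cutoff_sigmas: float = 3.0) -> ForceField:
    """The default mesoscale parameter set.

    Collagen backbone bonds and enzymatic cross-links follow the published
    mesoscale collagen force field; AGE cross-links use the glucosepane
    parameterization.  Extension bonds at the clamped ends are collagen bonds
    with the breaking distance pushed out to 70 A, making them effectively
    unbreakable so that force is transmitted smoothly into the clamps.
    """
    pair = PairParams(epsilon=6.87, sigma=14.72, lam=0.9)
    cutoff = pair_cutoff_sigmas * pair.sigma if pair_cutoff_sigmas else None
    return ForceField(
        bonds={
            "tc_core": BondParams(r0=14.00, r1=18.20, r_break=21.00, k0=17.13, k1=97.66),
            "tc_extension": BondParams(r0=14.00, r1=18.20, r_break=70.00, k0=17.13, k1=97.66),
            "ecl_divalent": BondParams(r0=18.52, r1=20.52, r_break=23.20, k0=0.20, k1=41.84),
            "ecl_trivalent": BondParams(r0=18.52, r1=22.12, r_break=24.81, k0=0.20, k1=54.60),
            "age": BondParams(r0=18.52, r1=22.72, r_break=31.72, k0=0.10, k1=8.00),
        },
        angle=AngleParams(k_b=14.98),
        pair=pair.with_cutoff(cutoff),
        mass=PARTICLE_MASS,
        bond_law=bond_law,
    )


# ---------------------------------------------------------------------------
# Scalar/array reference implementations (also used by the analysis layer and
# the test oracles; the simulation engine uses the compiled kernels, which
# implement the same math).
# ---------------------------------------------------------------------------

def bond_tension(r, p: BondParams, law: str = "continuous", r_max=None):
    """Scalar bond tension (positive = resists extension) at separation r.

    ``r_max`` is the maximum separation the bond has ever reached; a bond with
    ``r_max >= r_break + a`` is dead and carries no force.
    """
    r = np.asarray(r, dtype=float)
    a = p.a
    fb = p.peak_tension
    if law == "continuous":
        t = np.where(
            r < p.r1,
            p.k0 * (r - p.r0),
            np.where(
                r < p.r_break,
                p.k0 * (p.r1 - p.r0) + p.k1 * (r - p.r1),
                np.where(r < p.r_break + a, fb * (1.0 - (r - p.r_break) / a), 0.0),
            ),
        )
    elif law == "printed":
        t = np.where(
            r < p.r1,
            p.k0 * (r - p.r0),
            np.where(
                r < p.r_break,
                p.k1 * (r - p.r0),
                np.where(r < p.r_break + a, -p.z * p.k1 * (r - p.r0), 0.0),
            ),
        )
    else:
        raise ValueError(f"unknown bond law {law!r}")
    if r_max is not None:
        t = np.where(np.asarray(r_max) >= p.r_break + a, 0.0, t)
    if t.ndim == 0:
        return float(t)
    return t


def bond_energy(r, p: BondParams, law: str = "continuous", r_max=None):
    """Bond potential energy, the continuous integral of -tension."""
    r = np.asarray(r, dtype=float)
    a = p.a
    d1 = p.r1 - p.r0
    if law == "continuous":
        fb = p.peak_tension
        e1 = 0.5 * p.k0 * (r - p.r0) ** 2
        e_r1 = 0.5 * p.k0 * d1 ** 2
        e2 = e_r1 + p.k0 * d1 * (r - p.r1) + 0.5 * p.k1 * (r - p.r1) ** 2
        e_rb = e_r1 + p.k0 * d1 * (p.r_break - p.r1) + 0.5 * p.k1 * (p.r_break - p.r1) ** 2
        s = r - p.r_break
        e3 = e_rb + fb * s - fb * s ** 2 / (2.0 * a)
        e_plat = e_rb + 0.5 * fb * a
    else:
        e1 = 0.5 * p.k0 * (r - p.r0) ** 2
        e_r1 = 0.5 * p.k0 * d1 ** 2
        e2 = e_r1 + 0.5 * p.k1 * ((r - p.r0) ** 2 - d1 ** 2)
        e_rb = e_r1 + 0.5 * p.k1 * ((p.r_break - p.r0) ** 2 - d1 ** 2)
        e3 = e_rb - 0.5 * p.z * p.k1 * ((r - p.r0) ** 2 - (p.r_break - p.r0) ** 2)
        e_plat = e_rb - 0.5 * p.z * p.k1 * (
            (p.r_break + a - p.r0) ** 2 - (p.r_break - p.r0) ** 2
        )
    e = np.where(
        r < p.r1, e1, np.where(r < p.r_break, e2, np.where(r < p.r_break + a, e3, e_plat))
    )
    if r_max is not None:
        e = np.where(np.asarray(r_max) >= p.r_break + a, e_plat, e)
    if e.ndim == 0:
        return float(e)
    return e


def _lj_force(r, eps, sig):
    # F = -dU/dr for U = 4 eps ((sig/r)^12 - (sig/r)^6); positive = repulsive
    sr6 = (sig / r) ** 6
    return (48.0 * eps * sr6 * sr6 - 24.0 * eps * sr6) / r


def _lj_energy(r, eps, sig):
    sr6 = (sig / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def pair_force(r, p: PairParams):
    """Soft-core LJ force -dU/dr (positive = repulsive), zero beyond cutoff."""
    r = np.asarray(r, dtype=float)
    rsc = p.lam * p.sigma
    f = np.where(r < rsc, _lj_force(rsc, p.epsilon, p.sigma), _lj_force(np.maximum(r, 1e-12), p.epsilon, p.sigma))
    if p.cutoff is not None:
        f = np.where(r >= p.cutoff, 0.0, f)
    if f.ndim == 0:
        return float(f)
    return f


def pair_energy(r, p: PairParams):
    """Soft-core LJ energy, shifted to zero at the cutoff when one is set."""
    r = np.asarray(r, dtype=float)
    rsc = p.lam * p.sigma
    e_core = _lj_energy(rsc, p.epsilon, p.sigma) + _lj_force(rsc, p.epsilon, p.sigma) * (rsc - r)
    e = np.where(r < rsc, e_core, _lj_energy(np.maximum(r, 1e-12), p.epsilon, p.sigma))
    if p.cutoff is not None:
        shift = _lj_energy(p.cutoff, p.epsilon, p.sigma)
        e = np.where(r >= p.cutoff, 0.0, e - shift)
    if e.ndim == 0:
        return float(e)
    return e


def angle_energy(phi_deg, p: AngleParams):
    """Harmonic bending energy, 1/2 k_b (phi - phi0)^2 with phi in radians."""
    dphi = np.deg2rad(np.asarray(phi_deg, dtype=float) - p.phi0_deg)
    e = 0.5 * p.k_b * dphi ** 2
    if e.ndim == 0:
        return float(e)
    return e


def angle_torque(phi_deg, p: AngleParams):
    """Restoring torque magnitude k_b * |phi - phi0| in kcal/mol/rad."""
    dphi = np.deg2rad(np.asarray(phi_deg, dtype=float) - p.phi0_deg)
    t = p.k_b * np.abs(dphi)
    if t.ndim == 0:
        return float(t)
    return t
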