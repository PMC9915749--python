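# Methods

## Model

A collagen fibril is represented as a bundle of coarse-grained tropocollagen
(TC) molecules: chains of mesoscale particles (1358.7 amu each, roughly a
dozen residues of all three alpha chains) spaced at the bond equilibrium
distance r0 = 14 A. The cross-section is a triangular lattice of molecule
positions clipped to a circle; the default lattice constant is the pair
potential's minimum distance 2^(1/6) sigma_LJ = 16.53 A, a relaxed lateral
packing. Along the axis the molecules are staggered by integer multiples of
the D-period (670 A at full scale) with stagger index (row + 2 col) mod n
across the lattice, which reproduces the canonical microfibril packing and
its alternating gap (0.6 D) and overlap (0.4 D) zones.

The modeled region is one axial window of n D-periods. Molecule copies are
laid on each lattice line with a period of one molecule length plus one gap
and clipped to the window. Where a line meets the window boundary it is
continued by extension particles whose bonds use a pushed-out breaking
distance (70 A), making them effectively unbreakable; the outermost
extension particles of every such line form the two rigid clamps. Interior
molecule ends are physiological: their four outermost particles are the
telopeptides, which host enzymatic cross-links (ECLs) and are excluded as
AGE binding sites.

### Interactions

Total energy is E_bond + E_angle + E_inter, all parameters in
kcal/mol/Angstrom units ("real" style).

* **Bonds** (TC backbone, extensions, divalent/trivalent ECLs, AGEs) follow
  a tri-linear breakable tension law: stiffness k0 up to the critical
  hyperelastic distance r1, k1 up to the breaking distance r_break, then a
  regularization ramp of width a = z (r_break - r1) over which the tension
  falls linearly to zero. The printed piecewise form of this law in the
  source literature is discontinuous at r1 and r_break; since its stated
  purpose is to *avoid* discontinuities, the default here is the
  C0-continuous version (the literal form is available as
  `bond_law="printed"`). A bond that has ever stretched past r_break counts
  as broken in the failure census; past r_break + a it is permanently dead.
  Rupture is irreversible.

* **Angles** are harmonic in the angle, E = 1/2 k_b (phi - phi_i)^2 with
  k_b = 14.98 kcal/mol/rad^2 and per-triplet equilibrium angles phi_i taken
  from the as-built chain (180 degrees for straight paths; 170-180 for
  spline-derived paths). The published force expression carries a trailing
  angle factor that is dimensionally anomalous; it is read here as a plain
  harmonic angle law.

* **Pairs** are 12-6 Lennard-Jones (epsilon = 6.87 kcal/mol,
  sigma = 14.72 A) with a soft core: below lambda sigma (lambda = 0.9) the
  force is capped at its value at lambda sigma. The potential is truncated
  at 3 sigma and shifted to zero there. Directly bonded pairs (including
  cross-linked pairs) are excluded, and the exclusion persists after
  rupture.

Peak bond tensions rank TC (345.4) > trivalent ECL (147.6) > divalent ECL
(112.5) > AGE (72.4) kcal/mol/A, so TC molecules are the strongest element
and AGEs the weakest, which is what drives the failure-mode transition.

### Cross-link insertion

ECLs: a density of 100% means two cross-links per molecule (one per
telopeptide end). The target number of cross-linked ends is
round(pct/100 x number of telopeptide ends); ends are drawn without
replacement, so no end carries two cross-links. Each selected end bonds its
terminal particle to the nearest particle of the nearest distinct molecule
(divalent) or of the two nearest distinct molecules (trivalent, two bond
records sharing the telopeptide hub). AGEs: the total is
round(N_AGE x number of molecules); below one per molecule the originating
molecules are drawn without replacement. Endpoints are helical-domain
particles only; the partner is the nearest eligible particle of a distinct
molecule whose pair is not already linked (exact duplicates are redrawn).
Candidates beyond 25 A (just above the cross-link equilibrium distance of
18.52 A) are rejected; insertion happens on the *equilibrated*
configuration.

## Protocol

1. Steepest-descent then conjugate-gradient minimization (clamps frozen).
2. Langevin NVT equilibration at 300 K, dt = 10 fs, friction time 1000 fs,
   clamps held at fixed distance.
3. Cross-link insertion, then a second, shorter equilibration.
4. Steered tensile test: both clamps displaced symmetrically along the
   fibril axis at constant total separation rate. Engineering strain is
   (clamp separation - L0)/L0 with L0 the clamp distance at the start of
   pulling; engineering stress is the stride-averaged axial clamp force
   divided by pi (d/2)^2. The run stops at a maximum strain or when the
   stride-averaged stress falls below 5% of its running peak after the peak
   (total failure).

The integrator is velocity-Verlet with the Langevin friction/noise applied
in the BAOAB splitting; with the thermostat off it reduces exactly to
velocity-Verlet (relative NVE energy drift < 1e-4 over 1e5 steps at
dt = 1 fs on the tiny preset — verified in the acceptance suite). During
pulling the thermostat acts on velocities *relative to the affine streaming
profile* between the clamps. This matters: thermostatting absolute
velocities exerts a spurious drag of order m v_drift / tau per particle on
the imposed drift field, which at reduced scale produces a fictitious
stress plateau that never decays and masks total failure. For the same
reason the production pull couples weakly (tau = 5000 fs) while
equilibration couples strongly (tau = 1000 fs). At zero pull velocity the
two prescriptions coincide.

Neighbor lists are KD-tree candidate lists with a 6 A Verlet skin, rebuilt
when any particle has moved half a skin. All randomness flows from one root
seed split per stage (cross-links, equilibrations, pulling); runs are
bit-reproducible for a fixed seed and the same thread count (the kernels
are single-threaded).

## Presets and scaled study conditions

The `paper` preset carries the full-scale study conditions: fibril diameter
202 A, D = 670 A, five gap/overlap zones, 218 particles per molecule, 40
extension particles, 10-particle clamps, 80 ns pre-insertion equilibration
(dt = 10 fs), pulling at 1e-4 A/fs (10 m/s) with dt = 1 fs. These runs are
~40k particles for tens of millions of steps and are not executed by the
test suite.

The desk-scale rigs keep every proportion of the native geometry (gap and
overlap fractions, telopeptide/extension/clamp layout, commensurate
molecule-plus-gap per stagger window) and shrink the two free scales:

* `small`: 19 molecules in cross-section (d = 67 A), 3 D-periods with
  D = 210 A, 37 particles per molecule (~900 particles);
* `tiny`: 7 molecules, 2 D-periods, 22 particles per molecule
  (~220 particles).

Both run a shortened protocol: 10 ps (5 ps) equilibration, 5 ps (2.5 ps)
post-insertion, pulling at 5e-4 A/fs — five times the full-scale velocity,
chosen as the closest-to-reference rate that keeps a full sweep within
desk-scale runtimes — with dt = 10 fs (the stiffest bond mode has a period
of ~1.1 ps, so 10 fs resolves it ~110-fold). Cross-link densities
(AGEs per molecule 0-40; ECL density 0-100% with 100% = 2 per molecule) are
the full-scale study values.

### What the scaled rig does and does not reproduce

The scaled sweep reproduces the qualitative phenomenology: peak stress
grows monotonically with AGE density; mean force per AGE at matched strain
drops by more than half from 0.5 to 40 AGEs/TC (load sharing over more
links); TC backbone ruptures occur only at high AGE density, where
cross-links inhibit inter-molecular sliding and force the molecules to
carry the deformation; at low density the fibril fails by sliding/pull-out
with cross-link rupture and no TC damage.

Two classes of observable do not transfer quantitatively, for a scaling
reason worth stating. First, with 37-particle molecules the interfacial
shear compliance (friction plus cross-link shear) is comparable to the TC
stretch compliance — their ratio scales roughly as 1/n^2 in the particles
per molecule, i.e. ~35x larger than at 218 particles — so the AGE network
measurably stiffens the fibril already at low strain and the stress-strain
curves do not collapse onto an AGE-independent linear branch below the
critical strain; the secant-stiffness change point is correspondingly
early. Second, only cross-links whose endpoints sit on oppositely
clamp-anchored material can rupture during pull-out; in a 3-stagger window
that is a minority of AGE placements, so the AGE broken fraction at failure
saturates well below the full-scale value. Passing the scaled sweep
therefore demonstrates the mechanism switch, not the full-scale numbers.

The generator also idealizes real fibrils: straight molecule paths by
default (a spline-fitted path from a PDB structure is optional), no fibril
twist or radius variation, no mineral phase, a single AGE parameter class
(glucosepane), and no coexistence of divalent and trivalent ECLs in one
fibril.

## Numerical choices and degenerate inputs

* Stress is reported both in kcal/mol/A^3 and in MPa
  (1 kcal/mol/A^3 = 6947.7 MPa, derived from the thermochemical calorie and
  the Avogadro constant).
* The end of the initial linear regime eps_0 defaults to 0.15; delta_sigma
  = sigma_peak - sigma(eps_0) interpolates sigma linearly at eps_0 and is
  flagged undefined for curves that end before eps_0. The change-point
  detector fits a zero-intercept line over strain 0-0.08 and reports the
  first strain whose secant stiffness deviates by more than 10%.
* Work to failure integrates the (optionally smoothed) curve by the
  trapezoidal rule up to the last recorded strain; the smoothing window is
  recorded in the curve metadata and defaults to 9 records in the pipeline.
* Angle forces use the analytic limit at phi -> 180 degrees (the force
  prefactor (phi - phi_0)/sin phi tends to -1), so straight chains are not
  singular. Chains of fewer than three particles simply have no angles.
* Mean per-class bond forces average over *intact* bonds only and exclude
  the artificial extension bonds from the TC class.
* Cross-link insertion on a geometry where a selected end has no partner
  within the cutoff skips that end with a warning (ECLs) or raises with the
  achievable maximum (AGEs).
* Minimization never advances bond-rupture state; dynamics advances it
  every step. Rupture timing is recorded at the output stride (default 20
  steps, i.e. 0.1 A of clamp travel at the small-preset rate).
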