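# fibrilsim

Coarse-grained steered molecular dynamics of cross-linked collagen fibrils.

Collagen type I fibrils are D-periodic bundles of tropocollagen (TC)
molecules held together by enzymatic cross-links (ECLs) at the telopeptide
ends and, with age and diabetes, by advanced glycation end-product (AGE)
cross-links in the helical regions. How the density of these cross-links
changes fibril stiffness, strength, and failure mode is a question for
people studying bone brittleness and connective-tissue aging at the
nanoscale. `fibrilsim` is a simulator for exactly that experiment in
silico: it builds an idealized D-staggered fibril, decorates it
stochastically with ECLs and AGEs, pulls it apart between rigid clamps, and
reports the mechanics.

## Model in brief

Each TC molecule is a chain of mesoscale particles (spacing r0 = 14 A,
mass 1358.7 amu). The energy is

    E_total = E_bond + E_angle + E_inter

with tri-linear breakable bonds (tension k0 (r - r0) up to r1, then
k0 (r1 - r0) + k1 (r - r1) up to the breaking distance r_break, then a
short regularization ramp of width z (r_break - r1) down to zero; rupture
is irreversible), harmonic bending 1/2 k_b (phi - phi_i)^2 with per-triplet
equilibrium angles, and a soft-core 12-6 Lennard-Jones pair potential whose
force is capped below lambda sigma_LJ. Five bond classes carry their own
parameter blocks: TC backbone, reinforced extension bonds at the clamped
ends, divalent and trivalent ECLs, and AGEs (glucosepane parameterization).
Peak bond strengths order TC > trivalent ECL > divalent ECL > AGE.

Tensile tests are displacement-controlled: the outermost particles of each
end form rigid clamps driven apart at constant velocity under a Langevin
thermostat (applied to velocities relative to the affine streaming profile,
so the imposed drift feels no fictitious bath drag). Engineering stress is
the clamp force over the initial cross-section area; the run ends at total
failure. Analyses include sigma_peak, work to failure W_f = integral of
sigma d-epsilon, the stiffened-regime gain delta_sigma =
sigma_peak - sigma(eps_0) with eps_0 = 0.15, mean force per intact bond
class, the per-class failure census, and the sliding/stretching strain
decomposition delta_eps = eps - eps_TC.

See `docs/methods.md` for the full model description, the scaled
desk-size presets, and their known limitations.

## Worked example

Run a complete experiment (build, relax, cross-link, pull, analyze) on the
7-molecule `tiny` preset with 2 AGEs per molecule and 25% divalent ECLs:

```
$ fibrilsim run --preset tiny --seed 5 --n-age 2 --ecl-pct 25 --output-dir out
done: sigma_peak = 1682 MPa at strain 0.289; W_f = 0.0388; failure strain 0.337
```

The peak engineering stress of this toy fibril is ~1.7 GPa (the mesoscale
force field is known to sit at the stiff end of experimental estimates),
reached at 29% strain; pulling continues until the stress collapses below
5% of the running peak — total failure by molecular pull-out at 34%
strain — and the work to failure is the area under the stress-strain curve
in kcal/mol/A^3 units. `out/` then contains the resolved `config.yaml`,
the geometry (`geometry.xyz`, extended XYZ), the cross-link table
(`crosslinks.csv`), the per-stride mechanics time series
(`timeseries.csv`: strain, stress, per-class mean bond forces and broken
counts), the failure census (`census.csv`), `summary.json`, and a
`manifest.json` with the config hash and seed for reproduction. The same
stages are available as separate subcommands (`build`, `minimize`,
`equilibrate`, `crosslink`, `pull`, `analyze`) sharing one output
directory, and everything is callable as a library:

```python
from fibrilsim import run_tensile_experiment

res = run_tensile_experiment("small", n_age=10, ecl_pct=25, seed=1)
print(res.summary.sigma_peak, res.summary.delta_sigma)
print(res.census.tail(1))
```

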