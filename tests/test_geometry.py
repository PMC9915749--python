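"""Unit tests of the fibril geometry builder."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from fibrilsim import (
    BuildConfig,
    assemble_fibril,
    build_molecule_path,
    extract_equilibrium_angles,
    mesh_cross_section,
    spline_path_from_pdb,
)
from fibrilsim.geometry import REGION_EXT, REGION_TELO


def brute_force_lattice_count(diameter, spacing):
    """Independent enumeration of triangular-lattice points inside the circle."""
    radius = diameter / 2
    row_h = spacing * math.sqrt(3) / 2
    count = 0
    lim = int(radius / min(spacing, row_h)) + 2
    for row in range(-lim, lim + 1):
        for col in range(-lim, lim + 1):
            y = row * row_h
            z = col * spacing + (row % 2) * spacing / 2
            if y * y + z * z <= radius * radius + 1e-9:
                count += 1
    return count


class TestMeshCrossSection:
    def test_circle_smaller_than_one_cell_gives_center_site(self):
        cs = mesh_cross_section(10.0, 20.0)
        assert len(cs) == 1
        np.testing.assert_allclose(cs.sites[0], [0.0, 0.0])

    @pytest.mark.parametrize("diameter,spacing", [(202.0, 16.52), (67.0, 16.52), (90.0, 11.0)])
    def test_count_matches_brute_force_enumeration(self, diameter, spacing):
        cs = mesh_cross_section(diameter, spacing)
        assert len(cs) == brute_force_lattice_count(diameter, spacing)

    @pytest.mark.parametrize("diameter,spacing", [(202.0, 16.52), (120.0, 9.3)])
    def test_minimum_site_distance_is_the_lattice_spacing(self, diameter, spacing):
        cs = mesh_cross_section(diameter, spacing)
        d = cKDTree(cs.sites).query(cs.sites, k=2)[0][:, 1]
        assert d.min() >= spacing - 1e-9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            mesh_cross_section(-5.0, 10.0)
        with pytest.raises(ValueError):
            mesh_cross_section(100.0, 0.0)


class TestMoleculePath:
    def test_end_to_end_length(self):
        path = build_molecule_path(218, 14.0)
        assert np.linalg.norm(path.coords[-1] - path.coords[0]) == pytest.approx(3038.0)

    def test_angle_counts_and_values(self):
        assert len(build_molecule_path(3, 14.0).equilibrium_angles_deg) == 1
        assert build_molecule_path(3, 14.0).equilibrium_angles_deg[0] == pytest.approx(180.0)
        assert len(build_molecule_path(2, 14.0).equilibrium_angles_deg) == 0

    def test_too_few_particles_rejected(self):
        with pytest.raises(ValueError):
            build_molecule_path(1, 14.0)

    def test_right_angle_triplet(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1.0, 0]])
        assert extract_equilibrium_angles(coords)[0] == pytest.approx(90.0)


class TestSplinePath:
    def _write_pdb(self, path, coords):
        lines = []
        for i, (x, y, z) in enumerate(coords, start=1):
            lines.append(
                f"ATOM  {i:5d}  CA  GLY A{i:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        path.write_text("\n".join(lines) + "\n")

    def test_straight_synthetic_structure(self, tmp_path):
        # synthetic straight "molecule" of arclength 280 A
        pdb = tmp_path / "straight_synthetic.pdb"
        t = np.linspace(0.0, 280.0, 81)
        self._write_pdb(pdb, np.stack([t, np.zeros_like(t), np.zeros_like(t)], axis=1))
        path = spline_path_from_pdb(str(pdb), 14.0)
        assert path.n_particles == 21  # floor(280/14) + 1
        d = np.linalg.norm(np.diff(path.coords, axis=0), axis=1)
        assert np.abs(d / 14.0 - 1.0).max() < 0.01

    def test_gently_curved_structure_resamples_equidistantly(self, tmp_path):
        pdb = tmp_path / "curved_synthetic.pdb"
        t = np.linspace(0.0, 300.0, 121)
        coords = np.stack([t, 5.0 * np.sin(t / 60.0), 5.0 * np.cos(t / 60.0)], axis=1)
        self._write_pdb(pdb, coords)
        path = spline_path_from_pdb(str(pdb), 14.0)
        d = np.linalg.norm(np.diff(path.coords, axis=0), axis=1)
        assert np.abs(d / 14.0 - 1.0).max() < 0.01
        # all equilibrium angles close to straight for this gentle helix
        assert (path.equilibrium_angles_deg > 170.0).all()

    def test_unparseable_structure_raises(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("not a structure\n")
        with pytest.raises(ValueError):
            spline_path_from_pdb(str(bad), 14.0)


class TestAssembleFibril:
    def test_stagger_offsets_are_multiples_of_d(self):
        cfg = BuildConfig(
            fibril_diameter=67.0, n_d_periods=5, d_period=670.0,
            particles_per_molecule=218, n_extension_particles=0,
            n_clamp_particles=0, truncate=False,
        )
        geom = assemble_fibril(cfg)
        starts = set()
        for mol in range(geom.n_molecules):
            starts.add(round(float(geom.coords[geom.molecule_particles(mol), 0].min()), 6))
        assert starts <= {0.0, 670.0, 1340.0, 2010.0, 2680.0}
        assert len(starts) == 5  # all five stagger offsets occur in 19 sites

    def test_gap_between_consecutive_molecules_on_a_line(self):
        cfg = BuildConfig(
            fibril_diameter=67.0, n_d_periods=3, d_period=210.0,
            particles_per_molecule=37, n_extension_particles=0, n_clamp_particles=0,
        )
        geom = assemble_fibril(cfg)
        # group molecules by lattice line (y, z) and measure the axial gap
        gaps = []
        lines = {}
        for mol in range(geom.n_molecules):
            idx = geom.molecule_particles(mol)
            key = (round(float(geom.coords[idx[0], 1]), 3), round(float(geom.coords[idx[0], 2]), 3))
            lines.setdefault(key, []).append(
                (float(geom.coords[idx, 0].min()), float(geom.coords[idx, 0].max()))
            )
        for segs in lines.values():
            segs.sort()
            for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
                gaps.append(b0 - a1)
        assert gaps, "expected at least one line with two molecule segments"
        assert all(g == pytest.approx(0.6 * 210.0) for g in gaps)

    def test_single_site_single_molecule(self):
        cfg = BuildConfig(
            fibril_diameter=10.0, lattice_spacing=20.0, n_d_periods=1,
            d_period=670.0, particles_per_molecule=25,
            n_extension_particles=0, n_clamp_particles=0, truncate=False,
        )
        geom = assemble_fibril(cfg)
        assert geom.n_particles == 25
        assert geom.n_molecules == 1

    def test_topology_counts(self, tiny_geometry):
        g = tiny_geometry
        # one bond per consecutive pair, one angle per interior particle
        assert len(g.bonds) == g.n_particles - g.n_molecules
        expected_angles = sum(
            max(len(g.molecule_particles(m)) - 2, 0) for m in range(g.n_molecules)
        )
        assert len(g.angles) == expected_angles

    def test_every_particle_in_exactly_one_molecule(self, tiny_geometry):
        g = tiny_geometry
        assert g.molecule_id.min() == 0
        assert g.molecule_id.max() == g.n_molecules - 1
        for i, j in g.bonds:
            assert g.molecule_id[i] == g.molecule_id[j]

    def test_clamp_sets(self, tiny_geometry):
        g = tiny_geometry
        ncl = g.config.n_clamp_particles
        assert set(g.clamp_left).isdisjoint(set(g.clamp_right))
        assert len(g.clamp_left) % ncl == 0
        assert len(g.clamp_right) % ncl == 0
        # clamp particles are extension particles at the system ends
        assert (g.region[g.clamp_left] == REGION_EXT).all()
        assert (g.region[g.clamp_right] == REGION_EXT).all()

    def test_telopeptide_ends_are_physiological(self, tiny_geometry):
        g = tiny_geometry
        for end in g.telo_ends:
            assert (g.region[end.particles] == REGION_TELO).all()
            assert g.molecule_id[end.terminal] == end.molecule

    def test_deterministic_construction(self):
        cfg = BuildConfig(
            fibril_diameter=35.0, n_d_periods=2, d_period=210.0,
            particles_per_molecule=22, n_extension_particles=6, n_clamp_particles=3,
        )
        g1, g2 = assemble_fibril(cfg), assemble_fibril(cfg)
        assert np.array_equal(g1.coords, g2.coords)
        assert np.array_equal(g1.bonds, g2.bonds)
        assert np.array_equal(g1.angle_phi0_deg, g2.angle_phi0_deg)

    def test_rigid_motion_preserves_internal_geometry(self, tiny_geometry):
        g = tiny_geometry
        theta = 0.3
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        moved = g.coords @ rot.T + np.array([5.0, -3.0, 2.0])
        d0 = np.linalg.norm(g.coords[g.bonds[:, 1]] - g.coords[g.bonds[:, 0]], axis=1)
        d1 = np.linalg.norm(moved[g.bonds[:, 1]] - moved[g.bonds[:, 0]], axis=1)
        np.testing.assert_allclose(d0, d1, rtol=1e-12)

    def test_config_invariants_rejected(self):
        with pytest.raises(ValueError):
            BuildConfig(gap_fraction=0.7, overlap_fraction=0.4)
        with pytest.raises(ValueError):
            BuildConfig(n_clamp_particles=50, n_extension_particles=40)
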