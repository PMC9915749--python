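"""Unit tests of the bond / angle / pair potentials and the compiled kernels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrilsim import (
    AngleParams,
    BondParams,
    PairParams,
    System,
    bond_energy,
    bond_tension,
    default_forcefield,
    pair_energy,
    pair_force,
)
from fibrilsim.forcefield import BOND_CLASSES, angle_energy, angle_torque


@pytest.fixture(scope="module")
def tc():
    return default_forcefield().bond_params("tc_core")


class TestBondLaw:
    def test_zero_tension_at_equilibrium(self, tc):
        assert bond_tension(tc.r0, tc) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "r, expected",
        [
            (18.20, 71.946),            # end of the first branch: k0*(r1-r0)
            (21.00, 345.394),           # peak tension: continuous second branch
            (21.00 + 0.05 * 2.8, 0.0),  # beyond the regularization ramp
            (25.0, 0.0),
        ],
    )
    def test_frozen_values(self, tc, r, expected):
        assert bond_tension(r, tc) == pytest.approx(expected, abs=1e-9)

    def test_continuous_everywhere(self, tc):
        eps = 1e-9
        for r in (tc.r1, tc.r_break, tc.r_break + tc.a):
            left = bond_tension(r - eps, tc)
            right = bond_tension(r + eps, tc)
            assert left == pytest.approx(right, abs=1e-4)

    def test_printed_law_is_the_literal_piecewise_form(self, tc):
        # second branch k1*(r - r0), third branch -z*k1*(r - r0)
        assert bond_tension(20.0, tc, law="printed") == pytest.approx(97.66 * 6.0)
        r3 = tc.r_break + 0.5 * tc.a
        assert bond_tension(r3, tc, law="printed") == pytest.approx(
            -tc.z * tc.k1 * (r3 - tc.r0)
        )
        # and it is genuinely discontinuous at r1, unlike the default law
        jump = bond_tension(tc.r1 + 1e-9, tc, law="printed") - bond_tension(
            tc.r1 - 1e-9, tc, law="printed"
        )
        assert abs(jump) > 100.0

    @pytest.mark.parametrize("law", ["continuous", "printed"])
    def test_force_energy_consistency(self, tc, law):
        """-dE/dr equals the tension on every smooth branch."""
        h = 1e-6
        branches = [
            np.linspace(13.0, tc.r1 - 0.01, 7),
            np.linspace(tc.r1 + 0.01, tc.r_break - 0.01, 7),
            np.linspace(tc.r_break + 0.01 * tc.a, tc.r_break + 0.99 * tc.a, 5),
        ]
        for rr in branches:
            for r in rr:
                dedr = (bond_energy(r + h, tc, law) - bond_energy(r - h, tc, law)) / (2 * h)
                # tension is the derivative of the bond energy w.r.t. length
                assert bond_tension(r, tc, law) == pytest.approx(dedr, rel=1e-5, abs=1e-6)

    def test_dead_bond_carries_no_force(self, tc):
        r_dead = tc.r_break + tc.a + 1.0
        assert bond_tension(18.0, tc, r_max=r_dead) == 0.0

    def test_peak_tension_ordering_matches_bond_strength_ranking(self):
        ff = default_forcefield()
        peaks = {c: ff.bond_params(c).peak_tension for c in BOND_CLASSES}
        assert (
            peaks["tc_core"]
            > peaks["ecl_trivalent"]
            > peaks["ecl_divalent"]
            > peaks["age"]
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BondParams(r0=14.0, r1=13.0, r_break=21.0, k0=1.0, k1=2.0)
        with pytest.raises(ValueError):
            BondParams(r0=14.0, r1=18.0, r_break=21.0, k0=2.0, k1=1.0)


class TestPairLaw:
    @pytest.fixture(scope="class")
    def lj(self):
        return PairParams(epsilon=6.87, sigma=14.72, lam=0.9, cutoff=None)

    def test_zero_energy_at_sigma(self, lj):
        assert pair_energy(lj.sigma, lj) == pytest.approx(0.0, abs=1e-10)

    def test_minimum_location_and_depth(self, lj):
        r_min = 2.0 ** (1.0 / 6.0) * lj.sigma
        assert pair_energy(r_min, lj) == pytest.approx(-6.87, rel=1e-9)
        assert pair_force(r_min, lj) == pytest.approx(0.0, abs=1e-9)

    def test_soft_core_force_plateau(self, lj):
        rsc = lj.lam * lj.sigma
        assert pair_force(0.5 * rsc, lj) == pytest.approx(pair_force(rsc, lj))
        assert pair_force(0.01 * rsc, lj) == pytest.approx(pair_force(rsc, lj))

    def test_cutoff_shift_makes_energy_continuous(self):
        lj = PairParams(6.87, 14.72, 0.9, cutoff=3 * 14.72)
        eps = 1e-7
        assert pair_energy(lj.cutoff - eps, lj) == pytest.approx(0.0, abs=1e-5)
        assert pair_energy(lj.cutoff + eps, lj) == 0.0

    @given(r=st.floats(min_value=5.0, max_value=40.0))
    @settings(max_examples=50, deadline=None)
    def test_force_energy_consistency(self, r):
        lj = PairParams(6.87, 14.72, 0.9, cutoff=None)
        h = 1e-6
        dedr = (pair_energy(r + h, lj) - pair_energy(r - h, lj)) / (2 * h)
        assert pair_force(r, lj) == pytest.approx(-dedr, rel=1e-4, abs=1e-7)


class TestAngleLaw:
    def test_zero_torque_at_equilibrium(self):
        p = AngleParams(k_b=14.98, phi0_deg=180.0)
        assert angle_torque(180.0, p) == 0.0

    def test_harmonic_torque_value(self):
        p = AngleParams(k_b=14.98, phi0_deg=180.0)
        assert angle_torque(170.0, p) == pytest.approx(14.98 * 10 * np.pi / 180, rel=1e-9)
        assert angle_energy(170.0, p) == pytest.approx(
            0.5 * 14.98 * (10 * np.pi / 180) ** 2, rel=1e-9
        )


class TestKernels:
    """The compiled kernels agree with the reference potentials."""

    def _random_chain_system(self, seed, n=12):
        rng = np.random.default_rng(seed)
        ff = default_forcefield()
        coords = np.cumsum(
            14.0 * np.stack([np.ones(n), 0.05 * rng.normal(size=n), 0.05 * rng.normal(size=n)], axis=1),
            axis=0,
        )
        bonds = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
        classes = np.zeros(n - 1, dtype=np.int8)
        angles = np.stack([np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)], axis=1)
        phi0 = np.full(n - 2, 178.0)
        return System(
            coords, bonds, classes, ff, angles=angles, angle_phi0_deg=phi0,
        )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_forces_match_finite_differences(self, seed):
        system = self._random_chain_system(seed)
        f, e = system.compute_forces()
        f = f.copy()  # compute_forces returns a reusable buffer
        rng = np.random.default_rng(seed + 100)
        h = 1e-6
        for _ in range(12):
            i = int(rng.integers(system.n))
            d = int(rng.integers(3))
            x0 = system.x[i, d]
            system.x[i, d] = x0 + h
            ep = system.energy().e_total
            system.x[i, d] = x0 - h
            em = system.energy().e_total
            system.x[i, d] = x0
            assert f[i, d] == pytest.approx(-(ep - em) / (2 * h), rel=1e-5, abs=1e-5)

    def test_bond_kernel_tension_matches_reference(self):
        ff = default_forcefield()
        p = ff.bond_params("tc_core")
        rs = [13.5, 16.0, 19.5, 21.05, 21.1, 22.0]
        coords = np.zeros((2 * len(rs), 3))
        bonds, classes = [], []
        for k, r in enumerate(rs):
            coords[2 * k] = (0, 50.0 * k, 0)
            coords[2 * k + 1] = (r, 50.0 * k, 0)
            bonds.append((2 * k, 2 * k + 1))
            classes.append(0)
        system = System(coords, np.array(bonds), np.array(classes, dtype=np.int8), ff,
                        use_pairs=False)
        system.rmax[:] = np.array(rs)  # state equals current separation
        system.compute_forces()
        expect = [bond_tension(r, p, r_max=r) for r in rs]
        np.testing.assert_allclose(system.tension, expect, rtol=1e-12)

    def test_angle_forces_sum_to_zero_and_are_finite_near_straight(self):
        system = self._random_chain_system(7)
        f, _ = system.compute_forces()
        assert np.isfinite(f).all()
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)

    def test_energy_translation_invariance(self):
        system = self._random_chain_system(3)
        e0 = system.energy()
        system.x += np.array([11.0, -7.0, 3.0])
        system._last_build_x = None
        e1 = system.energy()
        assert e1.e_total == pytest.approx(e0.e_total, rel=1e-12)
        assert e1.e_bond == pytest.approx(e0.e_bond, rel=1e-12)
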