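import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condnet.forcefield import (BeadType, ForceField, debye_huckel_energy,
                                fourier_dihedral_energy, harmonic_angle_energy,
                                harmonic_bond_energy, lj_pair_energy,
                                lj_forcefield, quad_dihedral_energy,
                                BondClass, AngleClass, DihedralClass,
                                QuadDihedralClass)


class TestLJPair:
    def test_zero_crossing_at_sigma(self, lj_ff):
        bt = lj_ff.bead_types["LJ"]
        assert lj_pair_energy(1.0, bt, bt, lj_ff) == pytest.approx(0.0)

    def test_minimum_depth(self, lj_ff):
        bt = lj_ff.bead_types["LJ"]
        assert lj_pair_energy(2 ** (1 / 6), bt, bt, lj_ff) == pytest.approx(-1.0)

    def test_cutoff_truncation(self, lj_ff):
        bt = lj_ff.bead_types["LJ"]
        assert lj_pair_energy(2.6, bt, bt, lj_ff) == 0.0
        assert lj_pair_energy(2.5, bt, bt, lj_ff) == 0.0
        assert lj_pair_energy(2.499, bt, bt, lj_ff) != 0.0

    def test_mixing_rules(self):
        a = BeadType("a", "small", sigma=1.0, epsilon=0.25)
        b = BeadType("b", "large", sigma=3.0, epsilon=4.0)
        ff = ForceField(bead_types={"a": a, "b": b}, units="reduced")
        assert ff.sigma_ij(a, b) == 2.0
        assert ff.epsilon_ij(a, b) == 1.0
        # at r = sigma_ij the mixed pair energy crosses zero
        assert lj_pair_energy(2.0, a, b, ff) == pytest.approx(0.0)

    @given(st.floats(0.3, 5.0), st.floats(0.3, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_mixing_symmetry(self, s1, s2):
        a = BeadType("a", "small", sigma=s1, epsilon=0.7)
        b = BeadType("b", "small", sigma=s2, epsilon=1.3)
        ff = ForceField(bead_types={"a": a, "b": b}, units="reduced")
        for r in (0.9, 1.3, 2.2, 4.0):
            assert lj_pair_energy(r, a, b, ff) == lj_pair_energy(r, b, a, ff)

    def test_nonpositive_distance_rejected(self, lj_ff):
        bt = lj_ff.bead_types["LJ"]
        with pytest.raises(ValueError):
            lj_pair_energy(0.0, bt, bt, lj_ff)

    def test_shifted_variant_zero_at_cutoff(self):
        ff = lj_forcefield(shift=True)
        bt = ff.bead_types["LJ"]
        just_in = lj_pair_energy(2.5 - 1e-9, bt, bt, ff)
        assert abs(just_in) < 1e-6


class TestDebyeHuckel:
    def test_zero_charge(self):
        ff = ForceField(units="real")
        assert debye_huckel_energy(5.0, 0, 1, ff) == 0.0

    def test_coulomb_limit(self):
        ff = ForceField(units="real", kappa=0.0, dielectric=1.0,
                        coulomb_constant=1.0)
        assert debye_huckel_energy(2.0, 1, 1, ff) == pytest.approx(0.5)

    def test_screened_closed_form(self):
        # +1/-1 pair at 10 Å in water-like dielectric with 0.1 /Å screening
        ff = ForceField(units="real", dielectric=80.0, kappa=0.1)
        expected = 332.0637 * (1 * -1) / (80.0 * 10.0) * math.exp(-0.1 * 10.0)
        assert debye_huckel_energy(10.0, 1, -1, ff) == pytest.approx(expected,
                                                                    rel=1e-12)

    def test_cutoff(self):
        ff = ForceField(units="real")
        assert debye_huckel_energy(30.0, 1, -1, ff) == 0.0  # beyond 24.1 Å

    def test_reduced_units_default_constant(self):
        ff = ForceField(units="reduced", dielectric=1.0, kappa=0.0)
        assert ff.C == 1.0
        ffr = ForceField(units="real")
        assert ffr.C == pytest.approx(332.0637)


class TestBonded:
    def test_bond_at_rest_length(self, bonded_ff):
        assert harmonic_bond_energy(1.1, "bb", bonded_ff) == 0.0

    def test_bond_quadratic(self):
        ff = ForceField(bonds={"k1": BondClass(K=1.0, b0=1.0)}, units="reduced")
        assert harmonic_bond_energy(3.0, "k1", ff) == pytest.approx(4.0)

    def test_rigid_domain_bond_scale(self):
        # a domain-anchoring bond of 60,000 kcal/mol-Å² stretched by 0.01 Å
        ff = ForceField(bonds={"od": BondClass(K=60_000.0, b0=25.0)},
                        units="real")
        assert harmonic_bond_energy(25.01, "od", ff) == pytest.approx(6.0)

    def test_unknown_bond_class(self, bonded_ff):
        with pytest.raises(KeyError):
            harmonic_bond_energy(1.0, "nope", bonded_ff)

    def test_angle_at_rest(self, bonded_ff):
        assert harmonic_angle_energy(1.9, "aa", bonded_ff) == 0.0

    def test_angle_quadratic(self):
        ff = ForceField(angles={"a": AngleClass(K=2.0, theta0=1.0)},
                        units="reduced")
        assert harmonic_angle_energy(1.5, "a", ff) == pytest.approx(0.5)

    @given(st.floats(0.05, math.pi - 0.05))
    @settings(max_examples=50, deadline=None)
    def test_angle_closed_form(self, theta):
        ff = ForceField(angles={"a": AngleClass(K=3.3, theta0=2.1)},
                        units="reduced")
        assert harmonic_angle_energy(theta, "a", ff) == pytest.approx(
            3.3 * (theta - 2.1) ** 2)

    def test_angle_domain(self, bonded_ff):
        with pytest.raises(ValueError):
            harmonic_angle_energy(3.5, "aa", bonded_ff)


class TestDihedral:
    def test_zero_when_cosines_align(self):
        # phases chosen so every cosine term is 1 at phi = 0.5
        phi = 0.5
        ff = ForceField(dihedrals={"d": DihedralClass(
            K=(1.0, 2.0, 3.0), phi=(phi, 2 * phi, 3 * phi))}, units="reduced")
        assert fourier_dihedral_energy(phi, "d", ff) == pytest.approx(0.0)

    def test_single_term_maximum(self):
        ff = ForceField(dihedrals={"d": DihedralClass(K=(1.0, 0.0, 0.0),
                                                      phi=(0.0, 0.0, 0.0))},
                        units="reduced")
        assert fourier_dihedral_energy(math.pi, "d", ff) == pytest.approx(2.0)

    def test_three_term_hand_evaluation(self):
        k = (1.2, 0.7, 0.4)
        p = (0.3, -0.5, 1.1)
        phi = math.pi / 3
        expected = sum(k[n] * (1 - math.cos((n + 1) * phi - p[n]))
                       for n in range(3))
        ff = ForceField(dihedrals={"d": DihedralClass(K=k, phi=p)},
                        units="reduced")
        assert fourier_dihedral_energy(phi, "d", ff) == pytest.approx(
            expected, rel=1e-12)

    def test_quad_variant(self):
        ff = ForceField(quad_dihedrals={"q": QuadDihedralClass(K=2.0,
                                                               phi0=0.4)},
                        units="reduced")
        assert quad_dihedral_energy(0.4, "q", ff) == 0.0
        assert quad_dihedral_energy(0.9, "q", ff) == pytest.approx(2 * 0.25)
        # wrap-around: phi - phi0 measured on the circle
        assert quad_dihedral_energy(0.4 + 2 * math.pi, "q", ff) == \
            pytest.approx(0.0, abs=1e-12)

    def test_unknown_class(self, bonded_ff):
        with pytest.raises(KeyError):
            fourier_dihedral_energy(0.1, "nope", bonded_ff)


class TestValidationAndIO:
    def test_bead_type_invariants(self):
        with pytest.raises(ValueError):
            BeadType("x", "small", sigma=-1.0, epsilon=1.0)
        with pytest.raises(ValueError):
            BeadType("x", "small", sigma=1.0, epsilon=1.0, charge=2)
        with pytest.raises(ValueError):
            BeadType("x", "weird", sigma=1.0, epsilon=1.0)
        # the big domain bead may carry any charge state
        BeadType("od", "domain", sigma=53.0, epsilon=0.3, charge=0,
                 mass=47544.8)

    def test_forcefield_invariants(self):
        with pytest.raises(ValueError):
            ForceField(lj_cutoff_factor=0.5)
        with pytest.raises(ValueError):
            ForceField(dielectric=-1.0)
        with pytest.raises(ValueError):
            ForceField(kappa=-0.1)

    def test_json_round_trip(self, bonded_ff, tmp_path):
        p = tmp_path / "ff.json"
        bonded_ff.to_json(p)
        back = ForceField.from_json(p)
        assert back.bead_types == bonded_ff.bead_types
        assert back.bonds == bonded_ff.bonds
        assert back.dihedrals == bonded_ff.dihedrals
        assert back.pair_cutoff_override == bonded_ff.pair_cutoff_override
        a, b = bonded_ff.bead_types["A"], bonded_ff.bead_types["B"]
        assert back.lj_cutoff(a, b) == bonded_ff.lj_cutoff(a, b)

    def test_per_group_elec_cutoffs(self, bonded_ff):
        a, b, c = (bonded_ff.bead_types[k] for k in "ABC")
        assert bonded_ff.elec_cutoff(a, b) == 6.0    # max of the pair
        assert bonded_ff.elec_cutoff(b, c) == 5.0    # falls back to default
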