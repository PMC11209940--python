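"""Energy terms, analytic forces, and the exclusion rule."""

import math

import numpy as np
import pytest

from forcematch import synthetic as syn
from forcematch.model import (
    Conformation, PairParam, Topology, angle_energy_force, bond_energy_force,
    classify_pairs, nonbonded_pair_energy_force, torsion_energy_force,
    total_energy_forces,
)
from forcematch.units import COULOMB_K


class TestClassifyPairs:
    def test_linear_backbone_separations(self):
        # 4-carbon backbone, no hydrogens: 1-4 is nonbonded, 1-3 excluded
        top = Topology.from_bonds(["C3", "C2", "C2", "C3"], ["C"] * 4,
                                  [0] * 4, [(0, 1), (1, 2), (2, 3)])
        nb = classify_pairs(top)
        assert (0, 3) in nb          # separated by 3 bonds
        assert (0, 2) not in nb      # 1-3
        assert (0, 1) not in nb      # 1-2

    def test_intermolecular_always_nonbonded(self):
        top = Topology.from_bonds(["C3", "C3"], ["C", "C"], [0, 1], [])
        assert classify_pairs(top) == [(0, 1)]

    def test_disconnected_molecule_rejected(self):
        top = Topology.from_bonds(["C3", "C2", "C3"], ["C"] * 3, [0] * 3,
                                  [(0, 1)])
        with pytest.raises(ValueError, match="molecule 0"):
            classify_pairs(top)


@pytest.mark.parametrize("r,k,re,e_want,f_want", [
    (1.53, 300.0, 1.53, 0.0, 0.0),
    (1.60, 300.0, 1.53, 1.47, 42.0),
])
def test_bond_term(r, k, re, e_want, f_want):
    e, dedr = bond_energy_force(r, k, re)
    assert e == pytest.approx(e_want, abs=1e-12)
    assert dedr == pytest.approx(f_want, abs=1e-10)


def test_bond_gradient_matches_finite_difference():
    h = 1e-6
    e, dedr = bond_energy_force(1.45, 300.0, 1.53)
    num = (bond_energy_force(1.45 + h, 300.0, 1.53)[0]
           - bond_energy_force(1.45 - h, 300.0, 1.53)[0]) / (2 * h)
    assert dedr == pytest.approx(num, rel=1e-6)


def test_bond_nonpositive_length_rejected():
    with pytest.raises(ValueError):
        bond_energy_force(0.0, 300.0, 1.53)


def test_angle_term_values_and_gradient():
    e, dedt = angle_energy_force(2.0, 60.0, 1.911)
    assert e == pytest.approx(60.0 * (2.0 - 1.911) ** 2)
    assert dedt == pytest.approx(120.0 * (2.0 - 1.911))
    e0, d0 = angle_energy_force(1.911, 60.0, 1.911)
    assert e0 == 0.0 and d0 == 0.0
    for bad in (0.0, math.pi):
        with pytest.raises(ValueError):
            angle_energy_force(bad, 60.0, 1.911)


def test_torsion_term_values():
    e, _ = torsion_energy_force(math.radians(60.0), 1.4, 3, 0.0)
    assert e == pytest.approx(0.0, abs=1e-12)
    e0, _ = torsion_energy_force(0.0, 1.4, 3, 0.0)
    assert e0 == pytest.approx(2.8)
    h = 1e-7
    _, dedp = torsion_energy_force(0.3, 1.4, 3, 0.0)
    num = (torsion_energy_force(0.3 + h, 1.4, 3, 0.0)[0]
           - torsion_energy_force(0.3 - h, 1.4, 3, 0.0)[0]) / (2 * h)
    assert dedp == pytest.approx(num, rel=1e-6)


class TestNonbondedPair:
    def test_all_zero_parameters(self):
        p = PairParam(A=0.0, b=1.0)
        for r in (0.5, 2.0, 10.0):
            e, dedr = nonbonded_pair_energy_force(r, 0.0, 0.0, p)
            assert e == 0.0 and dedr == 0.0

    def test_damping_midpoint_symmetry(self):
        # at r = r_d the rational damping halves the bare C6 term
        p = PairParam(A=0.0, b=1.0, C6=600.0, r_d=3.0)
        e, _ = nonbonded_pair_energy_force(3.0, 0.0, 0.0, p)
        assert e == pytest.approx(-600.0 / (2 * 3.0**6))

    def test_full_term_by_term_and_gradient(self):
        p = PairParam(A=1e4, b=3.5, C6=600.0, C8=6000.0, r_d=3.0)
        r, qi, qj = 4.0, -0.2, 0.1
        e, dedr = nonbonded_pair_energy_force(r, qi, qj, p)
        expect = (COULOMB_K * qi * qj / r + 1e4 * math.exp(-3.5 * r)
                  - 600.0 / (r**6 + 3.0**6) - 6000.0 / (r**8 + 3.0**8))
        assert e == pytest.approx(expect, rel=1e-12)
        h = 1e-6
        num = (nonbonded_pair_energy_force(r + h, qi, qj, p)[0]
               - nonbonded_pair_energy_force(r - h, qi, qj, p)[0]) / (2 * h)
        assert dedr == pytest.approx(num, rel=1e-6)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            nonbonded_pair_energy_force(0.05, 0.0, 0.0, PairParam())

    def test_swap_symmetry(self):
        p = PairParam(A=1e4, b=3.5, C6=600.0, C8=6000.0, r_d=3.0)
        e1, _ = nonbonded_pair_energy_force(4.0, -0.2, 0.1, p)
        e2, _ = nonbonded_pair_energy_force(4.0, 0.1, -0.2, p)
        assert e1 == e2

    def test_coulomb_dominates_asymptotically(self):
        p = PairParam(A=1e5, b=3.2, C6=600.0, C8=6000.0, r_d=3.0)
        r = 50.0
        e, _ = nonbonded_pair_energy_force(r, -0.2, 0.1, p)
        e_coul = COULOMB_K * -0.2 * 0.1 / r
        assert abs(e - e_coul) < 1e-6 * abs(e_coul)


class TestTotalEnergyForces:
    def test_single_atom(self, truth):
        top = Topology.from_bonds(["C2"], ["C"], [0], [])
        e, f, _ = total_energy_forces(Conformation(np.zeros((1, 3))), top,
                                      truth.ff)
        assert e == 0.0
        assert np.all(f == 0.0)

    def test_breakdown_sums_to_total(self, truth, butane_pair):
        top, conf = butane_pair
        e, _, br = total_energy_forces(conf, top, truth.ff)
        assert e == pytest.approx(sum(br.values()), rel=1e-10)

    def test_net_force_and_torque_vanish(self, truth, butane_pair):
        top, conf = butane_pair
        _, f, _ = total_energy_forces(conf, top, truth.ff)
        assert np.abs(f.sum(axis=0)).max() < 1e-8
        assert np.abs(np.cross(conf.coords, f).sum(axis=0)).max() < 1e-8

    def test_forces_match_finite_differences(self, truth, butane_pair,
                                             fd_forces):
        top, conf = butane_pair
        rng = np.random.default_rng(1)
        x = conf.coords + rng.normal(0, 0.02, conf.coords.shape)
        _, f, _ = total_energy_forces(Conformation(x), top, truth.ff)
        num = fd_forces(x, top, truth.ff)
        assert np.abs(num - f).max() < 1e-6 * np.abs(f).max()

    def test_rigid_motion_invariance(self, truth, butane_pair):
        top, conf = butane_pair
        e0, f0, _ = total_energy_forces(conf, top, truth.ff)
        # rotate about z by 0.7 rad and translate
        c, s = math.cos(0.7), math.sin(0.7)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        x = conf.coords @ rot.T + np.array([3.0, -1.0, 2.0])
        e1, f1, _ = total_energy_forces(Conformation(x), top, truth.ff)
        assert e1 == pytest.approx(e0, abs=1e-8)
        assert np.abs(f1 - f0 @ rot.T).max() < 1e-8

    def test_missing_pair_parameters_named(self, truth):
        top = Topology.from_bonds(["XX"], ["C"], [0], [])
        import dataclasses
        from forcematch.model import AtomType, ForceField
        ff = ForceField({"XX": AtomType("XX", "C", 0.0)})
        top2 = Topology.from_bonds(["XX", "XX"], ["C", "C"], [0, 1], [])
        with pytest.raises(KeyError, match="XX"):
            total_energy_forces(
                Conformation(np.array([[0, 0, 0], [4, 0, 0.0]])), top2, ff)

    def test_minimum_image_used_with_box(self, truth):
        top = Topology.from_bonds(["HC", "HC"], ["H", "H"], [0, 1], [])
        box = np.array([10.0, 10.0, 10.0])
        # 9 Å apart in a 10 Å box → image distance 1 Å
        conf = Conformation(np.array([[0.5, 5, 5], [9.5, 5, 5.0]]), box=box)
        e, _, br = total_energy_forces(conf, top, truth.ff)
        p = truth.ff.pairs[("HC", "HC")]
        q = truth.ff.charge("HC")
        assert br["repulsion"] == pytest.approx(p.A * math.exp(-p.b * 1.0))
        assert br["coulomb"] == pytest.approx(truth.ff.k_e * q * q / 1.0)


def test_torsions_with_terminal_hydrogen_rejected():
    with pytest.raises(ValueError, match="hydrogen"):
        Topology(["C2", "C2", "C2", "HC"], ["C", "C", "C", "H"], [0] * 4,
                 [(0, 1), (1, 2), (2, 3)], torsions=[(3, 2, 1, 0)])


def test_charge_neutrality_validation(truth):
    top = syn.make_alkane_topology("n-pentane")
    bad = truth.ff.with_charges({"HC": 0.06, "C2": -0.12, "C3": -0.1})
    with pytest.raises(ValueError, match="net charge"):
        bad.check_neutrality(top)
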