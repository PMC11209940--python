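"""Design-matrix assembly, SVD solve, neutrality constraints, two-pass fit."""

import dataclasses

import numpy as np
import pytest

from forcematch import synthetic as syn
from forcematch.design import (
    LinearSystem, ParameterEntry, ParameterSpec, add_neutrality_constraints,
    build_design_matrix, build_parameter_spec, solve_svd, two_pass_fit,
)
from forcematch.model import ConformationSet, Topology


def _spec_counts(spec, kind):
    return [e for e in spec.entries if e.kind == kind and not e.fixed]


class TestParameterSpec:
    def test_cyclopentane_has_three_charge_products(self, truth):
        top = syn.make_alkane_topology("cyclopentane")
        spec = build_parameter_spec([top], truth.ff)
        assert len(_spec_counts(spec, "charge_product")) == 3

    def test_pentane_has_six_charge_products(self, truth):
        top = syn.make_alkane_topology("n-pentane")
        spec = build_parameter_spec([top], truth.ff)
        assert len(_spec_counts(spec, "charge_product")) == 6

    def test_fixed_charges_leave_no_free_products(self, truth):
        top = syn.make_alkane_topology("n-pentane")
        spec = build_parameter_spec(
            [top], truth.ff, charges={"C2": -0.12, "C3": -0.18, "HC": 0.06})
        assert len(_spec_counts(spec, "charge_product")) == 0

    def test_dispersion_only_on_carbon_pairs(self, truth):
        top = syn.make_alkane_topology("n-pentane")
        spec = build_parameter_spec([top], truth.ff)
        for e in _spec_counts(spec, "C6") + _spec_counts(spec, "C8"):
            assert all(truth.ff.atom_types[t].element == "C" for t in e.key)
        assert len(_spec_counts(spec, "C6")) == 3

    def test_empty_topology_set_rejected(self, truth):
        with pytest.raises(ValueError):
            build_parameter_spec([], truth.ff)

    def test_free_b_refused(self, truth):
        top = syn.make_alkane_topology("n-pentane")
        spec = build_parameter_spec([top], truth.ff)
        entries = [dataclasses.replace(e, fixed=False, fixed_value=None)
                   if e.kind == "repulsion_b" else e for e in spec.entries]
        bad = ParameterSpec(entries)
        with pytest.raises(ValueError, match="outer scan"):
            bad.const("repulsion_b", ("C2", "C2"))


def _truth_param_vector(spec, ff):
    """Ground-truth values for every free entry of a spec."""
    vals = []
    for e in spec.free:
        if e.kind == "charge_product":
            vals.append(ff.charge(e.key[0]) * ff.charge(e.key[1]))
        elif e.kind == "repulsion_A":
            vals.append(ff.pair(*e.key).A)
        elif e.kind == "C6":
            vals.append(ff.pair(*e.key).C6)
        elif e.kind == "C8":
            vals.append(ff.pair(*e.key).C8)
        elif e.kind == "bond_k":
            vals.append(ff.bonded.bonds[e.key][0])
        elif e.kind == "bond_kre":
            k, re = ff.bonded.bonds[e.key]
            vals.append(k * re)
        elif e.kind == "angle_k":
            vals.append(ff.bonded.angles[e.key][0])
        elif e.kind == "angle_kte":
            k, te = ff.bonded.angles[e.key]
            vals.append(k * te)
        elif e.kind == "torsion_A":
            vals.append(ff.bonded.torsions[e.key][0])
    return np.array(vals)


class TestDesignMatrix:
    def test_row_count_is_three_per_atom(self, truth, butane_pair):
        top, conf = butane_pair
        frames = syn.mock_reference_forces([conf], top, truth)
        spec = build_parameter_spec([top], truth.ff)
        system = build_design_matrix(frames, top, spec)
        assert system.matrix.shape[0] == 3 * top.n_atoms

    def test_linear_model_reproduces_forces(self, truth, butane_pair):
        # with every parameter at truth, L·p equals the model forces
        top, conf = butane_pair
        frames = syn.mock_reference_forces([conf], top, truth)
        spec = build_parameter_spec([top], truth.ff)
        system = build_design_matrix(frames, top, spec)
        p = _truth_param_vector(spec, truth.ff)
        model = system.matrix @ p
        assert np.abs(model - frames[0].forces.ravel()).max() < 1e-10 * max(
            1.0, np.abs(model).max())

    def test_columns_match_parameter_finite_differences(self, truth,
                                                        butane_pair):
        # bump one force-field parameter, recompute model forces: the change
        # must equal the corresponding design column (linearity is exact)
        import copy
        from forcematch.model import total_energy_forces

        top, conf = butane_pair
        frames = syn.mock_reference_forces([conf], top, truth)
        spec = build_parameter_spec([top], truth.ff)
        system = build_design_matrix(frames, top, spec)
        col = {(
            e.kind, e.key): system.matrix[:, i]
            for i, e in enumerate(spec.free)}
        h = 1e-3
        ff2 = copy.deepcopy(truth.ff)
        ff2.pairs[("C2", "C3")].A += h
        _, f0, _ = total_energy_forces(conf, top, truth.ff)
        _, f1, _ = total_energy_forces(conf, top, ff2)
        num = (f1 - f0).ravel() / h
        assert np.abs(num - col[("repulsion_A", ("C2", "C3"))]).max() < 1e-6

    def test_missing_forces_rejected(self, truth, butane_pair):
        top, conf = butane_pair
        spec = build_parameter_spec([top], truth.ff)
        with pytest.raises(ValueError, match="forces"):
            build_design_matrix(ConformationSet([conf]), top, spec)


class TestNeutralityConstraints:
    def test_water_like_row(self, truth):
        # 1 O-like + 2 H-like atoms: row for A=O is 1·Q_OO + 2·Q_OH = 0
        from forcematch.model import AtomType, ForceField, PairParam

        from forcematch.model import BondedParams

        ff = ForceField(
            {"OW": AtomType("OW", "O", -0.8), "HW": AtomType("HW", "H", 0.4)},
            bonded=BondedParams(
                bonds={("HW", "OW"): (450.0, 0.96)},
                angles={("HW", "OW", "HW"): (55.0, 1.82)}),
            pairs={k: PairParam(A=100.0, b=3.0) for k in
                   [("OW", "OW"), ("HW", "OW"), ("HW", "HW")]})
        top = Topology.from_bonds(["OW", "HW", "HW"], ["O", "H", "H"],
                                  [0] * 3, [(0, 1), (0, 2)])
        top2 = syn.replicate_topology(top, 2)
        truth_w = syn.GroundTruth(ff)
        rng = np.random.default_rng(0)
        conf = syn.generate_conformations(
            top2, truth_w, 298.0, 1, 1, coords0=np.array(
                [[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0],
                 [5, 0, 0], [5.96, 0, 0], [4.76, 0.93, 0.0]]))
        frames = syn.mock_reference_forces(conf, top2, truth_w)
        spec = build_parameter_spec([top2], ff)
        system = build_design_matrix(frames, top2, spec)
        system = add_neutrality_constraints(system, [top2], weight=1.0)
        qcols = {e.key: i for i, e in enumerate(spec.free)
                 if e.kind == "charge_product"}
        row_o = system.matrix[-2]  # rows sorted by type: HW then OW
        row_h = system.matrix[-1] if row_o[qcols[("OW", "OW")]] else None
        rows = system.matrix[-2:]
        got = {tuple(r[[qcols[("OW", "OW")], qcols[("HW", "OW")],
                        qcols[("HW", "HW")]]]) for r in rows}
        assert (1.0, 2.0, 0.0) in got       # A = O-like
        assert (0.0, 1.0, 2.0) in got       # A = H-like

    def test_neutral_charges_satisfy_rows(self, truth):
        top = syn.make_alkane_topology("n-pentane")
        q = {"C2": -0.12, "C3": -0.18, "HC": 0.06}
        # Σ_B n_B q_A q_B = q_A Σ n_B q_B = 0 for a neutral molecule
        counts = {"C2": 3, "C3": 2, "HC": 12}
        for a in q:
            total = sum(n * q[a] * q[b] for b, n in counts.items())
            assert total == pytest.approx(0.0, abs=1e-15)

    def test_nonpositive_weight_rejected(self, truth, butane_pair):
        top, conf = butane_pair
        frames = syn.mock_reference_forces([conf], top, truth)
        spec = build_parameter_spec([top], truth.ff)
        system = build_design_matrix(frames, top, spec)
        with pytest.raises(ValueError):
            add_neutrality_constraints(system, [top], weight=-1.0)


def _toy_system(L, f):
    spec = ParameterSpec([ParameterEntry("repulsion_A", ("X", str(i)))
                          for i in range(L.shape[1])])
    return LinearSystem(np.asarray(L, float), np.asarray(f, float),
                        np.ones(len(f)), [], spec, len(f))


class TestSolveSVD:
    def test_identity(self):
        f = np.array([1.0, -2.0, 3.0])
        rep = solve_svd(_toy_system(np.eye(3), f))
        assert np.allclose(rep.values, f)
        assert rep.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_rows_consistent(self):
        L = np.array([[2.0, 0.0], [2.0, 0.0], [0.0, 1.0]])
        f = np.array([4.0, 4.0, 5.0])
        rep = solve_svd(_toy_system(L, f))
        assert np.allclose(rep.values, [2.0, 5.0])
        assert rep.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_column_minimum_norm(self):
        L = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        f = np.array([2.0, 4.0, 6.0])
        rep = solve_svd(_toy_system(L, f))
        expect = np.linalg.pinv(L) @ f
        assert np.allclose(rep.values, expect)
        assert rep.rank == 1

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            solve_svd(_toy_system(np.zeros((3, 2)), np.ones(3)))


@pytest.fixture(scope="module")
def pentane_frames(truth, pentane_cluster):
    top, cluster = pentane_cluster
    confs = syn.generate_conformations(top, truth, 298.0, 30, seed=12,
                                       coords0=cluster.coords)
    return top, syn.mock_reference_forces(confs, top, truth)


class TestTwoPassFit:
    def test_noiseless_ground_truth_recovery(self, truth, pentane_frames):
        top, frames = pentane_frames
        disp = {k: (p.C6, p.C8) for k, p in truth.ff.pairs.items()
                if p.C6 or p.C8}
        ff, report = two_pass_fit(frames, top, truth.ff, dispersion=disp)
        for t in ("C2", "C3", "HC"):
            assert ff.charge(t) == pytest.approx(truth.ff.charge(t),
                                                 rel=1e-6)
        assert ff.charge("HC") > 0      # hydrogen-positive sign rule
        for k, p in truth.ff.pairs.items():
            assert ff.pairs[k].A == pytest.approx(p.A, rel=1e-6)
        for k, (kr, re) in truth.ff.bonded.bonds.items():
            if k in ff.bonded.bonds:
                assert ff.bonded.bonds[k][0] == pytest.approx(kr, rel=1e-6)
                assert ff.bonded.bonds[k][1] == pytest.approx(re, rel=1e-6)
        for k, (kt, te) in truth.ff.bonded.angles.items():
            if k in ff.bonded.angles:
                assert ff.bonded.angles[k][0] == pytest.approx(kt, rel=1e-6)
                assert ff.bonded.angles[k][1] == pytest.approx(te, rel=1e-6)

    def test_residual_not_worse_than_truth(self, truth, pentane_frames):
        top, frames = pentane_frames
        spec = build_parameter_spec([top], truth.ff)
        system = build_design_matrix(frames, top, spec)
        rep = solve_svd(system)
        p_truth = _truth_param_vector(spec, truth.ff)
        resid_truth = np.sqrt(np.mean(
            (system.matrix @ p_truth - system.rhs) ** 2))
        assert rep.residual_rms <= resid_truth + 1e-8

    def test_two_type_system_products_consistent(self, truth):
        # cyclopentane has two atom types: pass-1 products already satisfy
        # the consistency relation, CMD is exact
        from forcematch.charges import build_product_matrix, \
            consistency_defect

        top0, xyz = syn.ideal_geometry("cyclopentane", truth.ff)
        top = syn.replicate_topology(top0, 2)
        coords = np.vstack([xyz, xyz + np.array([6.0, 0.5, 0.3])])
        confs = syn.generate_conformations(top, truth, 298.0, 25, seed=5,
                                           coords0=coords)
        frames = syn.mock_reference_forces(confs, top, truth)
        disp = {k: (p.C6, p.C8) for k, p in truth.ff.pairs.items()
                if p.C6 or p.C8}
        ff, report = two_pass_fit(frames, top, truth.ff, dispersion=disp)
        cpm = build_product_matrix(report.products, ["C2", "HC"], ["C", "H"])
        assert consistency_defect(cpm) < 1e-10
        # pass-1 and pass-2 non-Coulombic parameters agree
        for e2, v2 in zip(report.pass2.entries, report.pass2.values):
            if e2.kind == "charge_product":
                continue
            assert v2 == pytest.approx(report.pass1.value(e2.kind, e2.key),
                                       abs=1e-8 * max(1.0, abs(v2)))

    def test_zero_charge_truth_passes_match(self, truth, butane_pair):
        top, cluster = butane_pair
        ff0 = truth.ff.with_charges({"C2": 0.0, "C3": 0.0, "HC": 0.0})
        truth0 = syn.GroundTruth(ff0)
        confs = syn.generate_conformations(top, truth0, 298.0, 20, seed=3,
                                           coords0=cluster.coords)
        frames = syn.mock_reference_forces(confs, top, truth0)
        disp = {k: (p.C6, p.C8) for k, p in ff0.pairs.items() if p.C6 or p.C8}
        ff, report = two_pass_fit(frames, top, ff0, dispersion=disp)
        for e2, v2 in zip(report.pass2.entries, report.pass2.values):
            assert v2 == pytest.approx(report.pass1.value(e2.kind, e2.key),
                                       abs=1e-7 * max(1.0, abs(v2)))

    def test_supplied_non_neutral_charges_rejected(self, truth, butane_pair):
        top, cluster = butane_pair
        confs = syn.generate_conformations(top, truth, 298.0, 3, seed=3,
                                           coords0=cluster.coords)
        frames = syn.mock_reference_forces(confs, top, truth)
        with pytest.raises(ValueError, match="neutrality"):
            two_pass_fit(frames, top, truth.ff,
                         cmd_charges={"C2": -0.12, "C3": -0.18, "HC": 0.1})


def test_noise_error_shrinks_with_more_frames(truth, butane_pair):
    """Parameter error decreases with the training-set size (≈1/√F)."""
    top, cluster = butane_pair
    disp = {k: (p.C6, p.C8) for k, p in truth.ff.pairs.items()
            if p.C6 or p.C8}
    sigma = 0.5

    def rms_err(n_frames, seed):
        confs = syn.generate_conformations(top, truth, 298.0, n_frames,
                                           seed=seed, coords0=cluster.coords)
        noisy = syn.mock_reference_forces(
            confs, top, syn.GroundTruth(truth.ff, sigma_force=sigma,
                                        seed=seed + 1))
        ff, _ = two_pass_fit(noisy, top, truth.ff, dispersion=disp)
        errs = [abs(ff.charge(t) - truth.ff.charge(t)) / 0.06
                for t in ("C2", "C3", "HC")]
        errs += [abs(ff.bonded.bonds[k][0] - v[0]) / v[0]
                 for k, v in truth.ff.bonded.bonds.items()
                 if k in ff.bonded.bonds]
        return np.sqrt(np.mean(np.square(errs)))

    few = np.mean([rms_err(60, s) for s in (1, 2, 3)])
    many = np.mean([rms_err(240, s) for s in (4, 5, 6)])
    assert many < few
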