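"""Linear force-matching system: assembly and SVD solve.

Force matching poses L·p = f_ref, where each row is one Cartesian force
component of one atom in one training frame, each column one fitted
parameter, and the entries are ∂(model force)/∂(parameter).  Every term of
the energy expression is (re)parameterized so that the model forces are
linear in the free parameters:

* Coulomb forces are linear in the charge products Q_ab;
* exp-repulsion forces are linear in A_ab at fixed exponent b;
* damped-dispersion forces are linear in C6/C8 at fixed r_d;
* harmonic bonds use (bond_k, bond_kre) = (k_r, k_r·r_e), giving
  dE/dr = 2·bond_k·r − 2·bond_kre, with r_e recovered as bond_kre/bond_k
  after the solve (angles analogously);
* torsion forces are linear in A_t at fixed multiplicity and phase.

The overdetermined system (forces vastly outnumber parameters) is solved in
the least-squares sense by singular value decomposition, with soft
charge-neutrality constraint rows.  The two-pass protocol solves once with
free charge products, extracts charges by CMD, then solves again with the
Coulomb contribution fixed by the CMD-derived products to obtain the
remaining non-Coulombic parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import charges as cmdmod
from .model import (
    MIN_PAIR_DISTANCE, AtomType, BondedParams, Conformation, ConformationSet,
    ForceField, PairParam, Topology, _angle_geometry, _torsion_geometry,
    canonical_pair, classify_pairs, minimum_image,
)
from .units import COULOMB_K

__all__ = [
    "ParameterEntry", "ParameterSpec", "LinearSystem", "FitReport",
    "build_parameter_spec", "build_design_matrix",
    "add_neutrality_constraints", "solve_svd", "two_pass_fit", "stack_systems",
]

#: parameter kinds whose force contribution is linear (usable as columns)
LINEAR_KINDS = frozenset({
    "charge_product", "repulsion_A", "C6", "C8",
    "bond_k", "bond_kre", "angle_k", "angle_kte", "torsion_A",
})
#: fixed nonlinear constants carried along in the spec
CONST_KINDS = frozenset({"repulsion_b", "damping_rd"})


@dataclass(frozen=True)
class ParameterEntry:
    kind: str
    key: tuple
    fixed: bool = False
    fixed_value: float | None = None
    meta: tuple = ()   # e.g. (m, phi0) for torsions

    def __post_init__(self):
        if self.kind not in LINEAR_KINDS | CONST_KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.fixed and self.fixed_value is None:
            raise ValueError(f"fixed entry {self.kind}{self.key} needs a value")


@dataclass
class ParameterSpec:
    """Ordered list of fit parameters (free and fixed)."""

    entries: list[ParameterEntry]

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            if (e.kind, e.key) in seen:
                raise ValueError(f"duplicate entry {e.kind}{e.key}")
            seen.add((e.kind, e.key))

    @property
    def free(self) -> list[ParameterEntry]:
        return [e for e in self.entries
                if not e.fixed and e.kind in LINEAR_KINDS]

    @property
    def fixed(self) -> list[ParameterEntry]:
        return [e for e in self.entries if e.fixed]

    def const(self, kind: str, key: tuple) -> float:
        for e in self.entries:
            if e.kind == kind and e.key == key:
                if not e.fixed:
                    raise ValueError(
                        f"{kind}{key} is not a linear parameter; it must stay "
                        "fixed (use an outer scan to vary it)")
                return e.fixed_value
        raise KeyError(f"no {kind} constant for {key}")


@dataclass
class LinearSystem:
    """L, f_ref, row weights and row provenance of one assembled fit."""

    matrix: np.ndarray
    rhs: np.ndarray
    weights: np.ndarray
    provenance: list
    spec: ParameterSpec
    n_force_rows: int

    def __post_init__(self):
        if not (np.all(np.isfinite(self.matrix))
                and np.all(np.isfinite(self.rhs))):
            raise ValueError("non-finite entries in the linear system")


@dataclass
class FitReport:
    """Solution of one SVD solve with diagnostics."""

    entries: list[ParameterEntry]
    values: np.ndarray
    singular_values: np.ndarray
    rank: int
    rcond: float
    residual_rms: float
    standard_scores: np.ndarray

    def params(self) -> dict:
        return {(e.kind, e.key): float(v)
                for e, v in zip(self.entries, self.values)}

    def value(self, kind: str, key: tuple) -> float:
        for e, v in zip(self.entries, self.values):
            if e.kind == kind and e.key == key:
                return float(v)
        raise KeyError(f"no fitted parameter {kind}{key}")


# ---------------------------------------------------------------------------
# parameter-spec construction

def build_parameter_spec(topologies, base_ff: ForceField, *,
                         charges: dict | None = None,
                         dispersion: dict | None = None) -> ParameterSpec:
    """Enumerate the fit parameters implied by a set of topologies.

    One charge product and one repulsion prefactor per unordered type pair;
    C6/C8 only for carbon–carbon pairs; composite bonded entries per unique
    type tuple.  ``base_ff`` supplies the fixed exponents b and damping
    distances r_d (and the element of each type).  ``charges`` (type → e)
    fixes all charge products at q_a·q_b; ``dispersion`` (pair → (C6, C8))
    freezes the dispersion coefficients.
    """
    topologies = list(topologies)
    if not topologies:
        raise ValueError("at least one topology is required")
    types = sorted({t for top in topologies for t in top.type_names})
    entries: list[ParameterEntry] = []
    for i, a in enumerate(types):
        for b in types[i:]:
            key = canonical_pair(a, b)
            if charges is not None:
                entries.append(ParameterEntry(
                    "charge_product", key, fixed=True,
                    fixed_value=charges[a] * charges[b]))
            else:
                entries.append(ParameterEntry("charge_product", key))
            entries.append(ParameterEntry("repulsion_A", key))
            entries.append(ParameterEntry(
                "repulsion_b", key, fixed=True,
                fixed_value=base_ff.pair(a, b).b))
            entries.append(ParameterEntry(
                "damping_rd", key, fixed=True,
                fixed_value=base_ff.pair(a, b).r_d))
            carbon = (base_ff.atom_types[a].element == "C"
                      and base_ff.atom_types[b].element == "C")
            if carbon:
                if dispersion is not None:
                    c6, c8 = dispersion[key]
                    entries.append(ParameterEntry("C6", key, True, c6))
                    entries.append(ParameterEntry("C8", key, True, c8))
                else:
                    entries.append(ParameterEntry("C6", key))
                    entries.append(ParameterEntry("C8", key))
    bond_keys, angle_keys, torsion_keys = [], [], []
    for top in topologies:
        for b in top.bonds:
            k = top.bond_type(b)
            if k not in bond_keys:
                bond_keys.append(k)
        for a in top.angles:
            k = top.angle_type(a)
            if k not in angle_keys:
                angle_keys.append(k)
        for t in top.torsions:
            k = top.torsion_type(t)
            if k not in torsion_keys:
                torsion_keys.append(k)
    for k in sorted(bond_keys):
        entries.append(ParameterEntry("bond_k", k))
        entries.append(ParameterEntry("bond_kre", k))
    for k in sorted(angle_keys):
        entries.append(ParameterEntry("angle_k", k))
        entries.append(ParameterEntry("angle_kte", k))
    for k in sorted(torsion_keys):
        m, phi0 = 3, 0.0
        if k in base_ff.bonded.torsions:
            _, m, phi0 = base_ff.bonded.torsions[k]
        entries.append(ParameterEntry("torsion_A", k, meta=(m, phi0)))
    return ParameterSpec(entries)


# ---------------------------------------------------------------------------
# design-matrix assembly

def _topology_tables(top: Topology, spec: ParameterSpec):
    pairs = classify_pairs(top)
    pair_groups: dict[tuple, list[int]] = {}
    for n, (i, j) in enumerate(pairs):
        key = canonical_pair(top.type_names[i], top.type_names[j])
        pair_groups.setdefault(key, []).append(n)
    bond_groups: dict[tuple, list] = {}
    for b in top.bonds:
        bond_groups.setdefault(top.bond_type(b), []).append(b)
    angle_groups: dict[tuple, list] = {}
    for a in top.angles:
        angle_groups.setdefault(top.angle_type(a), []).append(a)
    torsion_groups: dict[tuple, list] = {}
    for t in top.torsions:
        torsion_groups.setdefault(top.torsion_type(t), []).append(t)
    return pairs, pair_groups, bond_groups, angle_groups, torsion_groups


def _entry_force_column(entry, spec, top, conf, tables, k_e=COULOMB_K):
    """Force field of a unit value of one linear parameter: (N, 3) array."""
    pairs, pair_groups, bond_groups, angle_groups, torsion_groups = tables
    coords = conf.coords
    out = np.zeros_like(coords)
    kind, key = entry.kind, entry.key
    if kind in ("charge_product", "repulsion_A", "C6", "C8"):
        sel = pair_groups.get(key, [])
        if not sel:
            return out
        idx = np.array([pairs[n] for n in sel])
        d = coords[idx[:, 0]] - coords[idx[:, 1]]
        d = minimum_image(d, conf.box)
        r = np.linalg.norm(d, axis=1)
        if np.any(r < MIN_PAIR_DISTANCE):
            raise ValueError(f"overlapping atoms in pair group {key}")
        if kind == "charge_product":
            coef = k_e / r**3
        elif kind == "repulsion_A":
            b = spec.const("repulsion_b", key)
            coef = b * np.exp(-b * r) / r
        elif kind == "C6":
            rd = spec.const("damping_rd", key)
            coef = -6.0 * r**4 / (r**6 + rd**6) ** 2
        else:
            rd = spec.const("damping_rd", key)
            coef = -8.0 * r**6 / (r**8 + rd**8) ** 2
        f = coef[:, None] * d
        np.add.at(out, idx[:, 0], f)
        np.subtract.at(out, idx[:, 1], f)
    elif kind in ("bond_k", "bond_kre"):
        for (i, j) in bond_groups.get(key, []):
            d = coords[i] - coords[j]
            r = float(np.linalg.norm(d))
            # dE/dr = 2 r per unit bond_k; −2 per unit bond_kre
            f = (-2.0 * d) if kind == "bond_k" else (2.0 / r * d)
            out[i] += f
            out[j] -= f
    elif kind in ("angle_k", "angle_kte"):
        for (i, j, k) in angle_groups.get(key, []):
            theta, dti, dtj, dtk = _angle_geometry(coords, i, j, k)
            dedt = 2.0 * theta if kind == "angle_k" else -2.0
            out[i] -= dedt * dti
            out[j] -= dedt * dtj
            out[k] -= dedt * dtk
    elif kind == "torsion_A":
        m, phi0 = entry.meta if entry.meta else (3, 0.0)
        for quad in torsion_groups.get(key, []):
            phi, dpi, dpj, dpk, dpl = _torsion_geometry(coords, *quad)
            dedp = -m * math.sin(m * phi - phi0)
            i, j, k, l = quad
            out[i] -= dedp * dpi
            out[j] -= dedp * dpj
            out[k] -= dedp * dpk
            out[l] -= dedp * dpl
    else:
        raise ValueError(f"{kind} is not a linear parameter; hold it fixed "
                         "and vary it in an outer scan if needed")
    return out


def build_design_matrix(conformations: ConformationSet, top: Topology,
                        spec: ParameterSpec) -> LinearSystem:
    """Assemble L and f_ref from training frames carrying reference forces.

    Fixed linear entries (e.g. frozen dispersion, CMD-fixed charge products)
    contribute ``fixed_value ×`` their unit-force column, subtracted from the
    reference forces so the remaining system is homogeneous in the free
    parameters.
    """
    ConformationSet(conformations).require_forces()
    free = spec.free
    if not free:
        raise ValueError("no free parameters in the spec")
    tables = _topology_tables(top, spec)
    n3 = 3 * top.n_atoms
    n_frames = len(conformations)
    L = np.empty((n3 * n_frames, len(free)))
    rhs = np.empty(n3 * n_frames)
    provenance = []
    fixed_linear = [e for e in spec.fixed if e.kind in LINEAR_KINDS]
    for fi, conf in enumerate(conformations):
        if conf.n_atoms != top.n_atoms:
            raise ValueError(f"frame {fi} atom count mismatch")
        sl = slice(fi * n3, (fi + 1) * n3)
        ref = conf.forces.copy()
        for e in fixed_linear:
            if e.fixed_value != 0.0:
                ref -= e.fixed_value * _entry_force_column(
                    e, spec, top, conf, tables)
        rhs[sl] = ref.ravel()
        for col, e in enumerate(free):
            L[sl, col] = _entry_force_column(
                e, spec, top, conf, tables).ravel()
        provenance.extend((fi, a, c) for a in range(top.n_atoms)
                          for c in "xyz")
    return LinearSystem(L, rhs, np.ones(len(rhs)), provenance, spec,
                        n_force_rows=len(rhs))


def stack_systems(systems: list[LinearSystem]) -> LinearSystem:
    """Pool several systems built against the same ParameterSpec."""
    first = systems[0]
    for s in systems[1:]:
        if [(e.kind, e.key) for e in s.spec.free] != \
                [(e.kind, e.key) for e in first.spec.free]:
            raise ValueError("systems have incompatible parameter specs")
    return LinearSystem(
        np.vstack([s.matrix for s in systems]),
        np.concatenate([s.rhs for s in systems]),
        np.concatenate([s.weights for s in systems]),
        sum((s.provenance for s in systems), []),
        first.spec,
        n_force_rows=sum(s.n_force_rows for s in systems),
    )


def _species_type_counts(topologies) -> list[dict]:
    """Distinct per-molecule {type: count} compositions across topologies."""
    species = []
    for top in topologies:
        for mol in sorted(set(top.molecule_ids)):
            counts: dict[str, int] = {}
            for t, m in zip(top.type_names, top.molecule_ids):
                if m == mol:
                    counts[t] = counts.get(t, 0) + 1
            if counts not in species:
                species.append(counts)
    return species


def add_neutrality_constraints(system: LinearSystem, topologies,
                               weight: float | None = None) -> LinearSystem:
    """Append soft rows Σ_B n_B Q_AB = 0 per atom type and molecule species.

    These encode q_A × (molecular neutrality); with them, two-type systems
    satisfy the product-consistency relation automatically.  The default
    weight is 10³ × the median force-row norm.
    """
    if weight is not None and weight <= 0:
        raise ValueError("constraint weight must be positive")
    free = system.spec.free
    qcols = {e.key: c for c, e in enumerate(free)
             if e.kind == "charge_product"}
    if not qcols:
        raise ValueError("no free charge products to constrain")
    if weight is None:
        row_norms = np.linalg.norm(system.matrix[:system.n_force_rows],
                                   axis=1)
        weight = 1e3 * float(np.median(row_norms))
        if weight <= 0:
            weight = 1e3
    rows, prov = [], []
    for counts in _species_type_counts(topologies):
        for a in sorted(counts):
            row = np.zeros(len(free))
            ok = True
            for b, n_b in counts.items():
                key = canonical_pair(a, b)
                if key not in qcols:
                    ok = False
                    break
                row[qcols[key]] += n_b
            if ok:
                rows.append(row)
                prov.append(("neutrality", a, tuple(sorted(counts.items()))))
    if not rows:
        return system
    return LinearSystem(
        np.vstack([system.matrix, np.array(rows)]),
        np.concatenate([system.rhs, np.zeros(len(rows))]),
        np.concatenate([system.weights, np.full(len(rows), weight)]),
        system.provenance + prov,
        system.spec,
        system.n_force_rows,
    )


# ---------------------------------------------------------------------------
# SVD solve

def solve_svd(system: LinearSystem, rcond: float = 1e-10) -> FitReport:
    """Minimum-norm least-squares solution via SVD with column equilibration.

    Columns are scaled to unit norm before the decomposition (the raw basis
    functions differ by many orders of magnitude) and the solution is
    unscaled afterwards; singular values below ``rcond`` × the largest are
    truncated.
    """
    L = system.matrix * system.weights[:, None]
    rhs = system.rhs * system.weights
    if not np.any(L):
        raise ValueError("design matrix is identically zero")
    col_scale = np.linalg.norm(L, axis=0)
    col_scale[col_scale == 0.0] = 1.0
    Ls = L / col_scale
    u, s, vt = np.linalg.svd(Ls, full_matrices=False)
    keep = s > rcond * s[0]
    rank = int(np.count_nonzero(keep))
    sinv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    p_scaled = vt.T @ (sinv * (u.T @ rhs))
    p = p_scaled / col_scale
    resid = system.matrix[:system.n_force_rows] @ p \
        - system.rhs[:system.n_force_rows]
    residual_rms = float(np.sqrt(np.mean(resid**2)))
    dof = max(system.n_force_rows - rank, 1)
    sigma2 = float(resid @ resid) / dof
    # covariance of the scaled parameters, mapped back
    var_scaled = np.einsum("ij,j->i", vt.T**2, sinv**2) * sigma2
    std = np.sqrt(var_scaled) / col_scale
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(std > 0, p / std, np.inf)
    return FitReport(list(system.spec.free), p, s, rank, rcond,
                     residual_rms, scores)


# ---------------------------------------------------------------------------
# two-pass fit with CMD

def _extract_forcefield(report: FitReport, spec: ParameterSpec,
                        base_ff: ForceField, type_charges: dict,
                        dispersion: dict | None) -> ForceField:
    params = report.params()
    for e in spec.fixed:
        params.setdefault((e.kind, e.key), e.fixed_value)
    bonded = BondedParams()
    dropped = []
    keys = {k for (kind, k) in params if kind == "bond_k"}
    for k in keys:
        bk = params[("bond_k", k)]
        if abs(bk) < 1e-8:
            dropped.append(("bond", k))
            continue
        bonded.bonds[k] = (bk, params[("bond_kre", k)] / bk)
    keys = {k for (kind, k) in params if kind == "angle_k"}
    for k in keys:
        ak = params[("angle_k", k)]
        if abs(ak) < 1e-8:
            dropped.append(("angle", k))
            continue
        bonded.angles[k] = (ak, params[("angle_kte", k)] / ak)
    for e in spec.entries:
        if e.kind == "torsion_A":
            m, phi0 = e.meta if e.meta else (3, 0.0)
            bonded.torsions[e.key] = (params[("torsion_A", e.key)], m, phi0)
    if dropped:
        warnings.warn(f"dropped bonded terms with |k| < 1e-8: {dropped}")
    pairs = {}
    for e in spec.entries:
        if e.kind != "repulsion_A":
            continue
        key = e.key
        c6 = c8 = 0.0
        if dispersion is not None and key in dispersion:
            c6, c8 = dispersion[key]
        elif ("C6", key) in params:
            c6 = params[("C6", key)]
            c8 = params[("C8", key)]
        pairs[key] = PairParam(
            A=params[("repulsion_A", key)],
            b=spec.const("repulsion_b", key),
            C6=c6, C8=c8,
            r_d=spec.const("damping_rd", key))
    atom_types = {
        name: AtomType(name, at.element, type_charges.get(name, 0.0))
        for name, at in base_ff.atom_types.items()
    }
    return ForceField(atom_types, bonded, pairs, base_ff.k_e)


@dataclass
class TwoPassReport:
    pass1: FitReport
    pass2: FitReport
    assignment: cmdmod.ChargeAssignment
    products: dict = field(default_factory=dict)


def two_pass_fit(conformations: ConformationSet, top: Topology,
                 base_ff: ForceField, *,
                 dispersion: dict | None = None,
                 cmd_charges: dict | None = None,
                 constraint_weight: float | None = None,
                 rcond: float = 1e-10):
    """CMD-centred two-pass force match.

    Pass 1 fits every charge product as an independent linear parameter
    (with neutrality constraint rows); CMD turns the product matrix into
    atomic charges; pass 2 re-solves with the Coulomb contribution fixed at
    the CMD-derived products to obtain the remaining non-Coulombic
    parameters.  Returns the assembled :class:`ForceField` and a report.

    ``dispersion`` freezes pre-fitted C6/C8 throughout.  ``cmd_charges``
    bypasses the internal CMD (they must be neutral to 1e−6 e per molecule).
    """
    types = sorted(set(top.type_names))
    elements = [base_ff.atom_types[t].element for t in types]
    spec1 = build_parameter_spec([top], base_ff, dispersion=dispersion)
    sys1 = build_design_matrix(conformations, top, spec1)
    sys1 = add_neutrality_constraints(sys1, [top], weight=constraint_weight)
    rep1 = solve_svd(sys1, rcond=rcond)
    products = {e.key: v for e, v in zip(rep1.entries, rep1.values)
                if e.kind == "charge_product"}
    if cmd_charges is None:
        cpm = cmdmod.build_product_matrix(products, types, elements)
        assignment = cmdmod.cmd_decompose(cpm)
        type_charges = dict(assignment.charges)
        species = _species_type_counts([top])
        worst = max(abs(sum(n * type_charges[t] for t, n in cnt.items()))
                    for cnt in species)
        if worst > 1e-6:
            warnings.warn(
                f"CMD charges violate molecular neutrality by {worst:.2e} e; "
                "applying a minimal-norm shift")
            type_charges = cmdmod.neutralize_charges(type_charges, species)
    else:
        type_charges = dict(cmd_charges)
        species = _species_type_counts([top])
        worst = max(abs(sum(n * type_charges[t] for t, n in cnt.items()))
                    for cnt in species)
        if worst > 1e-6:
            raise ValueError(
                f"supplied charges violate molecular neutrality by {worst:.2e} e")
        assignment = cmdmod.ChargeAssignment(
            type_charges, float("nan"), 0.0, "", types)
    spec2 = build_parameter_spec([top], base_ff, charges=type_charges,
                                 dispersion=dispersion)
    sys2 = build_design_matrix(conformations, top, spec2)
    rep2 = solve_svd(sys2, rcond=rcond)
    ff = _extract_forcefield(rep2, spec2, base_ff, type_charges, dispersion)
    return ff, TwoPassReport(rep1, rep2, assignment, products)
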