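"""Force-field data model and energy/force evaluation.

The functional form is a point-charge molecular-mechanics expression with
pair-specific (no combining rules) nonbonded terms:

* bonds:     E = k_r (r − r_e)²               (no ½ prefactor)
* angles:    E = k_θ (θ − θ_e)²
* torsions:  E = A_t (1 + cos(m φ − φ0))
* nonbonded: E = k_e q_i q_j / r + A e^{−b r}
             − C6 / (r⁶ + r_d⁶) − C8 / (r⁸ + r_d⁸)

Nonbonded terms act between atoms separated by more than two covalent bonds
or belonging to different molecules; 1-4 pairs are full strength.  Dispersion
(C6/C8) is carried only by carbon–carbon type pairs.  The rational damping
−C_n/(rⁿ + r_dⁿ) removes the unphysical short-range attraction of the bare
inverse power while keeping the −C_n/rⁿ asymptote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .units import COULOMB_K

__all__ = [
    "AtomType", "Topology", "BondedParams", "PairParam", "ForceField",
    "Conformation", "ConformationSet", "classify_pairs",
    "bond_energy_force", "angle_energy_force", "torsion_energy_force",
    "nonbonded_pair_energy_force", "total_energy_forces",
    "canonical_pair", "canonical_triple", "canonical_quad",
]

MIN_PAIR_DISTANCE = 0.1  # Å; closer approaches are unphysical training data


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def canonical_triple(t: tuple[str, str, str]) -> tuple[str, str, str]:
    return t if t <= t[::-1] else t[::-1]


def canonical_quad(t: tuple[str, str, str, str]) -> tuple[str, str, str, str]:
    return t if t <= t[::-1] else t[::-1]


@dataclass(frozen=True)
class AtomType:
    """An atom type: short label, element, and partial charge (e)."""

    name: str
    element: str
    charge: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.charge):
            raise ValueError(f"charge of type {self.name!r} is not finite")


@dataclass
class Topology:
    """Atoms, typing, molecule membership and the bonded-term lists.

    ``angles`` and ``torsions`` are normally enumerated from the bond graph
    via :meth:`from_bonds`; torsions with a terminal hydrogen are omitted.
    """

    type_names: list[str]
    elements: list[str]
    molecule_ids: list[int]
    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    torsions: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        n = self.n_atoms
        if not (len(self.elements) == len(self.molecule_ids) == n):
            raise ValueError("type/element/molecule arrays differ in length")
        seen = set()
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            if self.molecule_ids[i] != self.molecule_ids[j]:
                raise ValueError(f"bond {key} crosses molecules")
        self.bonds = sorted((min(i, j), max(i, j)) for i, j in self.bonds)
        for t in self.angles + self.torsions:
            if any(not 0 <= k < n for k in t):
                raise ValueError(f"bonded term {t} out of range")
        for a, b, c, d in self.torsions:
            if self.elements[a] == "H" or self.elements[d] == "H":
                raise ValueError(
                    f"torsion ({a},{b},{c},{d}) has a terminal hydrogen")

    @property
    def n_atoms(self) -> int:
        return len(self.type_names)

    @property
    def n_molecules(self) -> int:
        return len(set(self.molecule_ids))

    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    @classmethod
    def from_bonds(cls, type_names, elements, molecule_ids, bonds) -> "Topology":
        """Build a topology, enumerating angles and torsions from the bonds.

        Torsions whose terminal atom is a hydrogen are not generated.
        """
        top = cls(list(type_names), list(elements), list(molecule_ids),
                  [tuple(b) for b in bonds])
        g = top.bond_graph()
        angles = []
        for j in g.nodes:
            nbrs = sorted(g.neighbors(j))
            for a_i in range(len(nbrs)):
                for a_k in range(a_i + 1, len(nbrs)):
                    angles.append((nbrs[a_i], j, nbrs[a_k]))
        torsions = []
        for j, k in g.edges:
            for i in g.neighbors(j):
                if i == k:
                    continue
                for l in g.neighbors(k):
                    if l == j or l == i:
                        continue
                    if top.elements[i] == "H" or top.elements[l] == "H":
                        continue
                    quad = (i, j, k, l)
                    if quad[::-1] not in torsions:
                        torsions.append(quad)
        top.angles = angles
        top.torsions = torsions
        return top

    def bond_type(self, b: tuple[int, int]) -> tuple[str, str]:
        return canonical_pair(self.type_names[b[0]], self.type_names[b[1]])

    def angle_type(self, a: tuple[int, int, int]) -> tuple[str, str, str]:
        return canonical_triple(tuple(self.type_names[i] for i in a))

    def torsion_type(self, t) -> tuple[str, str, str, str]:
        return canonical_quad(tuple(self.type_names[i] for i in t))


@dataclass
class BondedParams:
    """Bonded parameters keyed by canonical type tuples.

    bonds:    (k_r [kcal/mol/Å²], r_e [Å])
    angles:   (k_θ [kcal/mol/rad²], θ_e [rad])
    torsions: (A_t [kcal/mol], m [int], φ0 [rad]); alkane fits use m=3, φ0=0.
    """

    bonds: dict = field(default_factory=dict)
    angles: dict = field(default_factory=dict)
    torsions: dict = field(default_factory=dict)

    def validate(self):
        for key, (k, re_) in self.bonds.items():
            if k <= 0 or re_ <= 0:
                raise ValueError(f"bond {key}: need k_r > 0 and r_e > 0")
        for key, (k, te) in self.angles.items():
            if k <= 0 or not 0 < te < math.pi:
                raise ValueError(f"angle {key}: need k_θ > 0, 0 < θ_e < π")


@dataclass
class PairParam:
    """Nonbonded parameters of one unordered type pair (no combining rules)."""

    A: float = 0.0        # kcal/mol
    b: float = 1.0        # Å⁻¹
    C6: float = 0.0       # kcal·mol⁻¹·Å⁶
    C8: float = 0.0       # kcal·mol⁻¹·Å⁸
    r_d: float = 0.0      # Å, damping distance; never fitted

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("repulsion exponent b must be positive")
        if self.r_d < 0:
            raise ValueError("damping distance r_d must be non-negative")


@dataclass
class ForceField:
    """All parameters of the energy expression, keyed by type and type pair."""

    atom_types: dict  # name -> AtomType
    bonded: BondedParams = field(default_factory=BondedParams)
    pairs: dict = field(default_factory=dict)  # canonical pair -> PairParam
    k_e: float = COULOMB_K

    def charge(self, type_name: str) -> float:
        return self.atom_types[type_name].charge

    def pair(self, a: str, b: str) -> PairParam:
        key = canonical_pair(a, b)
        try:
            return self.pairs[key]
        except KeyError:
            raise KeyError(f"no pair parameters for type pair {key}") from None

    def validate(self, topologies=()):
        self.bonded.validate()
        for (a, b), p in self.pairs.items():
            if (p.C6 != 0.0 or p.C8 != 0.0) and not (
                    self.atom_types[a].element == "C"
                    and self.atom_types[b].element == "C"):
                raise ValueError(
                    f"dispersion on non-carbon pair ({a},{b}); C6/C8 act only "
                    "between pairs of carbon atoms")
        for top in topologies:
            self.check_neutrality(top)
            tset = sorted(set(top.type_names))
            for i in range(len(tset)):
                for j in range(i, len(tset)):
                    self.pair(tset[i], tset[j])

    def check_neutrality(self, top: Topology, tol: float = 1e-8):
        for mol in sorted(set(top.molecule_ids)):
            q = sum(self.charge(t) for t, m in
                    zip(top.type_names, top.molecule_ids) if m == mol)
            if abs(q) > tol:
                raise ValueError(
                    f"molecule {mol} carries net charge {q:.3e} e")

    def with_charges(self, charges: dict) -> "ForceField":
        new_types = {
            name: replace(at, charge=charges.get(name, at.charge))
            for name, at in self.atom_types.items()
        }
        return ForceField(new_types, self.bonded, self.pairs, self.k_e)


@dataclass
class Conformation:
    """Coordinates (Å), optional reference forces (kcal/mol/Å), optional box."""

    coords: np.ndarray
    forces: np.ndarray | None = None
    box: np.ndarray | None = None     # orthorhombic edge lengths (3,)
    label: str = ""
    energy: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coordinates must be N×3")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.coords.shape:
                raise ValueError("force array shape does not match coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


class ConformationSet(list):
    """An ordered collection of :class:`Conformation` frames."""

    def require_forces(self):
        for i, c in enumerate(self):
            if c.forces is None:
                raise ValueError(f"frame {i} carries no reference forces")
        return self


# ---------------------------------------------------------------------------
# pair classification

def classify_pairs(top: Topology) -> list[tuple[int, int]]:
    """Nonbonded atom pairs (i < j) under the exclusion rule.

    Pairs separated by one or two covalent bonds (1-2, 1-3) are excluded;
    everything further apart, and every intermolecular pair, interacts at
    full strength (1-4 pairs are not scaled).
    """
    g = top.bond_graph()
    for mol in sorted(set(top.molecule_ids)):
        members = [i for i, m in enumerate(top.molecule_ids) if m == mol]
        if len(members) > 1:
            sub = g.subgraph(members)
            if not nx.is_connected(sub):
                raise ValueError(
                    f"molecule {mol} has disconnected atoms in its bond graph")
    excluded = set()
    for i in g.nodes:
        for j, d in nx.single_source_shortest_path_length(g, i, cutoff=2).items():
            if 1 <= d <= 2:
                excluded.add((min(i, j), max(i, j)))
    n = top.n_atoms
    return [(i, j) for i in range(n) for j in range(i + 1, n)
            if (i, j) not in excluded]


# ---------------------------------------------------------------------------
# scalar term evaluators (energy, dE/dcoordinate)

def bond_energy_force(r: float, k_r: float, r_e: float):
    """Harmonic bond: E = k_r (r − r_e)², dE/dr = 2 k_r (r − r_e)."""
    if r <= 0:
        raise ValueError("bond length must be positive")
    d = r - r_e
    return k_r * d * d, 2.0 * k_r * d


def angle_energy_force(theta: float, k_theta: float, theta_e: float):
    """Harmonic angle: E = k_θ (θ − θ_e)², dE/dθ = 2 k_θ (θ − θ_e)."""
    if not 0.0 < theta < math.pi:
        raise ValueError("angle must lie strictly between 0 and π")
    d = theta - theta_e
    return k_theta * d * d, 2.0 * k_theta * d


def torsion_energy_force(phi: float, A_t: float, m: int, phi0: float = 0.0):
    """Cosine torsion: E = A_t (1 + cos(mφ − φ0)), dE/dφ = −A_t m sin(mφ − φ0)."""
    if not math.isfinite(phi):
        raise ValueError("torsion angle must be finite")
    arg = m * phi - phi0
    return A_t * (1.0 + math.cos(arg)), -A_t * m * math.sin(arg)


def nonbonded_pair_energy_force(r: float, q_i: float, q_j: float,
                                p: PairParam, k_e: float = COULOMB_K):
    """Nonbonded pair energy and dE/dr at separation r (Å)."""
    if r < MIN_PAIR_DISTANCE:
        raise ValueError(
            f"pair distance {r:.3g} Å below {MIN_PAIR_DISTANCE} Å: unphysical "
            "overlap")
    qq = k_e * q_i * q_j
    e_coul = qq / r
    e_rep = p.A * math.exp(-p.b * r)
    d6 = r**6 + p.r_d**6
    d8 = r**8 + p.r_d**8
    e = e_coul + e_rep - p.C6 / d6 - p.C8 / d8
    dedr = (-qq / r**2 - p.b * e_rep
            + 6.0 * p.C6 * r**5 / d6**2 + 8.0 * p.C8 * r**7 / d8**2)
    return e, dedr


# ---------------------------------------------------------------------------
# geometry helpers (shared with the design-matrix assembly)

def _angle_geometry(coords, i, j, k):
    """θ and ∂θ/∂r for atoms (i, j, k) with j the vertex."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    c = float(np.clip(uh @ vh, -1.0, 1.0))
    theta = math.acos(c)
    s = math.sin(theta)
    if s < 1e-10:
        raise ValueError(f"angle ({i},{j},{k}) is degenerate (θ≈0 or π)")
    dti = (c * uh - vh) / (nu * s)
    dtk = (c * vh - uh) / (nv * s)
    return theta, dti, -(dti + dtk), dtk


def _torsion_geometry(coords, i, j, k, l):
    """φ and ∂φ/∂r for the dihedral i-j-k-l."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    phi = math.atan2(float(np.cross(n1, n2) @ b2) / nb2, float(n1 @ n2))
    sq1 = float(n1 @ n1)
    sq2 = float(n2 @ n2)
    if sq1 < 1e-16 or sq2 < 1e-16:
        raise ValueError(f"torsion ({i},{j},{k},{l}) is collinear")
    dpi = -nb2 / sq1 * n1
    dpl = nb2 / sq2 * n2
    f12 = float(b1 @ b2) / nb2**2
    f32 = float(b3 @ b2) / nb2**2
    # translation invariance: the four gradients sum to zero
    dpj = -(1.0 + f12) * dpi + f32 * dpl
    dpk = f12 * dpi - (1.0 + f32) * dpl
    return phi, dpi, dpj, dpk, dpl


def minimum_image(dvec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return dvec
    return dvec - box * np.round(dvec / box)


def _pair_arrays(conf, top, pairs, box):
    idx = np.asarray(pairs, dtype=int)
    if idx.size == 0:
        return idx, np.zeros((0, 3)), np.zeros(0)
    d = conf.coords[idx[:, 0]] - conf.coords[idx[:, 1]]
    if box is not None:
        d = minimum_image(d, box)
    r = np.linalg.norm(d, axis=1)
    return idx, d, r


def _topology_cache(top: Topology) -> dict:
    """Conformation-independent index tables, cached on the topology.

    Liquid boxes have ~10⁵ nonbonded pairs; per-call Python loops over them
    would dominate the MD cost.
    """
    cache = getattr(top, "_eval_cache", None)
    if cache is not None:
        return cache
    pairs = classify_pairs(top)
    pair_idx = np.asarray(pairs, dtype=int).reshape(-1, 2)
    pkeys = sorted({canonical_pair(top.type_names[i], top.type_names[j])
                    for i, j in pairs})
    pkey_index = {k: n for n, k in enumerate(pkeys)}
    pair_kind = np.array([pkey_index[canonical_pair(top.type_names[i],
                                                    top.type_names[j])]
                          for i, j in pairs], dtype=int)
    cache = {
        "pairs": pairs,
        "pair_idx": pair_idx,
        "pair_keys": pkeys,
        "pair_kind": pair_kind,
        "bond_idx": np.asarray(top.bonds, dtype=int).reshape(-1, 2),
        "bond_keys": [top.bond_type(b) for b in top.bonds],
        "angle_idx": np.asarray(top.angles, dtype=int).reshape(-1, 3),
        "angle_keys": [top.angle_type(a) for a in top.angles],
        "torsion_idx": np.asarray(top.torsions, dtype=int).reshape(-1, 4),
        "torsion_keys": [top.torsion_type(t) for t in top.torsions],
    }
    top._eval_cache = cache
    return cache


def _lookup(table: dict, keys, what: str) -> np.ndarray:
    out = []
    for k in keys:
        if k not in table:
            raise KeyError(f"missing {what} parameters for {k}")
        out.append(table[k])
    return np.array(out, dtype=float)


def total_energy_forces(conf: Conformation, top: Topology, ff: ForceField,
                        cutoff: float | None = None):
    """Total energy, forces (−∇E) and a per-term energy breakdown.

    When the conformation carries box vectors, nonbonded distances use the
    minimum-image convention and ``cutoff`` (if given) truncates them sharply.
    """
    if conf.n_atoms != top.n_atoms:
        raise ValueError("conformation and topology atom counts differ")
    coords = conf.coords
    forces = np.zeros_like(coords)
    breakdown = {"bond": 0.0, "angle": 0.0, "torsion": 0.0,
                 "coulomb": 0.0, "repulsion": 0.0, "dispersion": 0.0}
    tc = _topology_cache(top)

    bidx = tc["bond_idx"]
    if len(bidx):
        par = _lookup(ff.bonded.bonds, tc["bond_keys"], "bond")
        d = coords[bidx[:, 0]] - coords[bidx[:, 1]]
        r = np.linalg.norm(d, axis=1)
        if np.any(r <= 0):
            raise ValueError("zero-length bond")
        dr = r - par[:, 1]
        breakdown["bond"] = float((par[:, 0] * dr * dr).sum())
        fvec = (-2.0 * par[:, 0] * dr / r)[:, None] * d
        np.add.at(forces, bidx[:, 0], fvec)
        np.subtract.at(forces, bidx[:, 1], fvec)

    aidx = tc["angle_idx"]
    if len(aidx):
        par = _lookup(ff.bonded.angles, tc["angle_keys"], "angle")
        u = coords[aidx[:, 0]] - coords[aidx[:, 1]]
        v = coords[aidx[:, 2]] - coords[aidx[:, 1]]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        c = np.clip((uh * vh).sum(axis=1), -1.0, 1.0)
        theta = np.arccos(c)
        s = np.sin(theta)
        if np.any(s < 1e-10):
            raise ValueError("degenerate angle (θ≈0 or π)")
        dt = theta - par[:, 1]
        breakdown["angle"] = float((par[:, 0] * dt * dt).sum())
        dedt = 2.0 * par[:, 0] * dt
        dti = (c[:, None] * uh - vh) / (nu * s)[:, None]
        dtk = (c[:, None] * vh - uh) / (nv * s)[:, None]
        np.subtract.at(forces, aidx[:, 0], dedt[:, None] * dti)
        np.add.at(forces, aidx[:, 1], dedt[:, None] * (dti + dtk))
        np.subtract.at(forces, aidx[:, 2], dedt[:, None] * dtk)

    tidx = tc["torsion_idx"]
    if len(tidx):
        par = _lookup(ff.bonded.torsions, tc["torsion_keys"], "torsion")
        b1 = coords[tidx[:, 1]] - coords[tidx[:, 0]]
        b2 = coords[tidx[:, 2]] - coords[tidx[:, 1]]
        b3 = coords[tidx[:, 3]] - coords[tidx[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        sq1 = (n1 * n1).sum(axis=1)
        sq2 = (n2 * n2).sum(axis=1)
        if np.any(sq1 < 1e-16) or np.any(sq2 < 1e-16):
            raise ValueError("collinear torsion")
        phi = np.arctan2((np.cross(n1, n2) * b2).sum(axis=1) / nb2,
                         (n1 * n2).sum(axis=1))
        arg = par[:, 1] * phi - par[:, 2]
        breakdown["torsion"] = float((par[:, 0] * (1.0 + np.cos(arg))).sum())
        dedp = -par[:, 0] * par[:, 1] * np.sin(arg)
        dpi = (-nb2 / sq1)[:, None] * n1
        dpl = (nb2 / sq2)[:, None] * n2
        f12 = ((b1 * b2).sum(axis=1) / nb2**2)[:, None]
        f32 = ((b3 * b2).sum(axis=1) / nb2**2)[:, None]
        dpj = -(1.0 + f12) * dpi + f32 * dpl
        dpk = f12 * dpi - (1.0 + f32) * dpl
        np.subtract.at(forces, tidx[:, 0], dedp[:, None] * dpi)
        np.subtract.at(forces, tidx[:, 1], dedp[:, None] * dpj)
        np.subtract.at(forces, tidx[:, 2], dedp[:, None] * dpk)
        np.subtract.at(forces, tidx[:, 3], dedp[:, None] * dpl)

    pairs = tc["pairs"]
    if len(pairs):
        idx, dvec, r = _pair_arrays(conf, top, tc["pair_idx"], conf.box)
        if np.any(r < MIN_PAIR_DISTANCE):
            bad = int(np.argmin(r))
            raise ValueError(
                f"atoms {pairs[bad]} overlap at {r[bad]:.3g} Å")
        qtab = np.empty(len(tc["pair_keys"]))
        ptab = np.empty((len(tc["pair_keys"]), 5))
        for n, key in enumerate(tc["pair_keys"]):
            p = ff.pair(*key)
            qtab[n] = ff.k_e * ff.charge(key[0]) * ff.charge(key[1])
            ptab[n] = (p.A, p.b, p.C6, p.C8, p.r_d)
        kind = tc["pair_kind"]
        qq = qtab[kind]
        A, b, C6, C8, rd = (ptab[kind, c] for c in range(5))
        if cutoff is not None:
            mask = r <= cutoff
        else:
            mask = slice(None)
        r = r[mask]
        dvec = dvec[mask]
        idx = idx[mask]
        qq, A, b, C6, C8, rd = (a[mask] for a in (qq, A, b, C6, C8, rd))
        e_coul = qq / r
        e_rep = A * np.exp(-b * r)
        d6 = r**6 + rd**6
        d8 = r**8 + rd**8
        e_disp = -C6 / d6 - C8 / d8
        dedr = (-qq / r**2 - b * e_rep
                + 6.0 * C6 * r**5 / d6**2 + 8.0 * C8 * r**7 / d8**2)
        breakdown["coulomb"] = float(e_coul.sum())
        breakdown["repulsion"] = float(e_rep.sum())
        breakdown["dispersion"] = float(e_disp.sum())
        fpair = (-dedr / r)[:, None] * dvec
        n_at = top.n_atoms
        for c in range(3):
            forces[:, c] += np.bincount(idx[:, 0], weights=fpair[:, c],
                                        minlength=n_at)
            forces[:, c] -= np.bincount(idx[:, 1], weights=fpair[:, c],
                                        minlength=n_at)

    total = float(sum(breakdown.values()))
    return total, forces, breakdown
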