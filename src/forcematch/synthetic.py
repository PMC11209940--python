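"""Synthetic reference data from a known ground truth.

Every fitting stage in this package is validated against data generated
from a fully specified "truth" force field: conformations (perturbed or
MD-sampled), per-atom reference forces standing in for correlated-
wavefunction cluster forces, and per-dimer dispersion energies standing in
for SAPT E² dispersion.  Because the truth shares the model's functional
form, noiseless fits must recover its parameters exactly — the package's
strongest end-to-end check.  The generators are deterministic under a seed.

Alkane topologies follow the three-type scheme: terminal carbons C3,
secondary carbons C2, all hydrogens HC; cyclic alkanes contain only C2 and
HC.  Torsions involving hydrogen are not generated.  Default ground-truth
magnitudes are alkane-plausible (C–C ≈ 1.53 Å, C–C–C ≈ 112°, |q_H| ≤ 0.1 e)
so that sampled geometries are physically reasonable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .dispersion import DimerRecord, dispersion_energy, nearest_atom_distance
from .model import (AtomType, BondedParams, Conformation, ConformationSet,
                    ForceField, PairParam, Topology, canonical_pair,
                    canonical_quad, canonical_triple, total_energy_forces)
from .sampling import SamplingSettings, sample_conformations

__all__ = [
    "SPECIES", "GroundTruth", "make_alkane_topology", "replicate_topology",
    "molecule_subtopology", "ideal_geometry", "default_ground_truth",
    "generate_conformations", "mock_reference_forces", "reference_oracle",
    "make_cluster", "make_liquid_frames", "extract_dimers",
    "mock_dispersion_energy", "make_dimer_dataset",
    "make_liquid_system", "make_training_set", "LIQUID_MOLAR_VOLUME",
]

SPECIES = {
    "n-butane": (4, False),
    "n-pentane": (5, False),
    "n-octane": (8, False),
    "cyclopentane": (5, True),
    "cycloheptane": (7, True),
}

#: liquid molar volumes (Å³ per molecule) at ambient conditions, from the
#: measured liquid densities of the species studied
LIQUID_MOLAR_VOLUME = {
    "n-butane": 160.0,     # 602 g/L at 272 K
    "n-pentane": 191.0,    # 621 g/L at 298 K
    "n-octane": 271.0,     # 699 g/L at 298 K
    "cyclopentane": 156.0,  # 744 g/L at 298 K
    "cycloheptane": 201.0,  # 811 g/L at 298 K
}

_DEG = math.pi / 180.0
_TET = 109.47 * _DEG


@dataclass
class GroundTruth:
    """A designated-truth force field plus noise levels for mock references."""

    ff: ForceField
    sigma_force: float = 0.0    # kcal/mol/Å, i.i.d. Gaussian per component
    sigma_energy: float = 0.0   # kcal/mol, per dimer energy
    seed: int = 0

    def __post_init__(self):
        if self.sigma_force < 0 or self.sigma_energy < 0:
            raise ValueError("noise levels must be non-negative")


# ---------------------------------------------------------------------------
# topology construction

def make_alkane_topology(species, molecule_id: int = 0) -> Topology:
    """Topology of one alkane molecule.

    ``species`` is a name from :data:`SPECIES` or a tuple
    ``(n_carbons, cyclic)``.  Atom order: carbons first (backbone order),
    then hydrogens grouped by parent carbon.
    """
    if isinstance(species, str):
        if species not in SPECIES:
            raise ValueError(f"unknown species {species!r}; know "
                             f"{sorted(SPECIES)}")
        nc, cyclic = SPECIES[species]
    else:
        nc, cyclic = species
    if cyclic and nc < 3:
        raise ValueError("cyclic alkanes need at least 3 carbons")
    if not cyclic and nc < 2:
        raise ValueError("linear alkanes need at least 2 carbons")
    cc_bonds = [(i, (i + 1) % nc) for i in range(nc)] if cyclic else \
        [(i, i + 1) for i in range(nc - 1)]
    heavy_deg = [0] * nc
    for i, j in cc_bonds:
        heavy_deg[i] += 1
        heavy_deg[j] += 1
    types = ["C2" if heavy_deg[i] == 2 else "C3" for i in range(nc)]
    elements = ["C"] * nc
    bonds = list(cc_bonds)
    for ci in range(nc):
        for _ in range(4 - heavy_deg[ci]):
            h = len(types)
            types.append("HC")
            elements.append("H")
            bonds.append((ci, h))
    mol = [molecule_id] * len(types)
    return Topology.from_bonds(types, elements, mol, bonds)


def replicate_topology(top: Topology, n: int) -> Topology:
    """n copies of a (single-molecule) topology with fresh molecule ids."""
    na = top.n_atoms
    types, elements, mols, bonds = [], [], [], []
    for m in range(n):
        types += top.type_names
        elements += top.elements
        mols += [m] * na
        bonds += [(i + m * na, j + m * na) for i, j in top.bonds]
    return Topology.from_bonds(types, elements, mols, bonds)


def molecule_subtopology(top: Topology, mol_id: int):
    """(sub-topology, atom indices) of one molecule."""
    idx = [i for i, m in enumerate(top.molecule_ids) if m == mol_id]
    if not idx:
        raise ValueError(f"no molecule with id {mol_id}")
    remap = {g: l for l, g in enumerate(idx)}
    sub = Topology.from_bonds(
        [top.type_names[i] for i in idx],
        [top.elements[i] for i in idx],
        [0] * len(idx),
        [(remap[i], remap[j]) for i, j in top.bonds
         if i in remap and j in remap])
    return sub, idx


# ---------------------------------------------------------------------------
# idealized geometry

def _unit(v):
    return v / np.linalg.norm(v)


def _place_hydrogens(carbons: np.ndarray, cc_bonds, r_ch: float = 1.09):
    """Complete each carbon to a tetrahedron; returns H coords per carbon."""
    nc = len(carbons)
    nbrs = [[] for _ in range(nc)]
    for i, j in cc_bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    hs: list[list[np.ndarray]] = []
    for ci in range(nc):
        c = carbons[ci]
        heavy = [_unit(carbons[j] - c) for j in nbrs[ci]]
        out = []
        if len(heavy) == 2:
            u, v = heavy
            w = _unit(-(u + v))
            p = _unit(np.cross(u, v))
            beta = _TET / 2.0
            out = [c + r_ch * (math.cos(beta) * w + math.sin(beta) * p),
                   c + r_ch * (math.cos(beta) * w - math.sin(beta) * p)]
        elif len(heavy) == 1:
            u = heavy[0]
            a = np.array([0.0, 0.0, 1.0])
            if abs(u @ a) > 0.9:
                a = np.array([1.0, 0.0, 0.0])
            e1 = _unit(a - (a @ u) * u)
            e2 = np.cross(u, e1)
            for k in range(3):
                ang = 2.0 * math.pi * k / 3.0
                d = (math.cos(_TET) * u
                     + math.sin(_TET) * (math.cos(ang) * e1
                                         + math.sin(ang) * e2))
                out.append(c + r_ch * d)
        else:
            raise ValueError("only CH2/CH3 carbons are supported")
        hs.append(out)
    return hs


def ideal_geometry(species, ff: ForceField | None = None,
                   relax_cyclic: bool = True):
    """(topology, coordinates) of an idealized monomer.

    Linear chains are built in the all-anti zigzag with standard bond
    lengths and angles; rings start from a slightly puckered regular polygon
    and, when a force field is given, are closed by a short geometry
    optimization under it.
    """
    top = make_alkane_topology(species)
    if isinstance(species, str):
        nc, cyclic = SPECIES[species]
    else:
        nc, cyclic = species
    r_cc = 1.53
    if not cyclic:
        alpha = (180.0 - 112.0) / 2.0 * _DEG
        pos = [np.zeros(3)]
        for i in range(nc - 1):
            sign = 1.0 if i % 2 == 0 else -1.0
            d = np.array([math.cos(alpha), 0.0, sign * math.sin(alpha)])
            pos.append(pos[-1] + r_cc * d)
        carbons = np.array(pos)
        cc_bonds = [(i, i + 1) for i in range(nc - 1)]
    else:
        radius = r_cc / (2.0 * math.sin(math.pi / nc))
        carbons = np.array([
            [radius * math.cos(2 * math.pi * i / nc),
             radius * math.sin(2 * math.pi * i / nc),
             0.25 * math.cos(4 * math.pi * i / nc)]  # pucker to break planarity
            for i in range(nc)])
        cc_bonds = [(i, (i + 1) % nc) for i in range(nc)]
    hs = _place_hydrogens(carbons, cc_bonds)
    conf_coords = np.vstack([carbons, np.vstack([h for g in hs for h in g])])
    if cyclic and relax_cyclic and ff is not None:
        conf_coords = _relax(conf_coords, top, ff)
    return top, conf_coords


def _relax(coords, top, ff, maxiter: int = 500):
    def fun(x):
        conf = Conformation(x.reshape(-1, 3))
        e, f, _ = total_energy_forces(conf, top, ff)
        return e, -f.ravel()

    res = minimize(fun, coords.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    return res.x.reshape(-1, 3)


# ---------------------------------------------------------------------------
# default ground truth

_BONDS = {
    ("C2", "C2"): (300.0, 1.530), ("C2", "C3"): (305.0, 1.528),
    ("C3", "C3"): (295.0, 1.531), ("C2", "HC"): (340.0, 1.092),
    ("C3", "HC"): (335.0, 1.090),
}
_ANGLES = {
    ("C2", "C2", "C2"): (63.0, 112.0 * _DEG),
    ("C2", "C2", "C3"): (62.0, 112.5 * _DEG),
    ("C3", "C2", "C3"): (61.0, 113.0 * _DEG),
    ("C2", "C2", "HC"): (45.0, 109.3 * _DEG),
    ("C3", "C2", "HC"): (46.0, 109.1 * _DEG),
    ("HC", "C2", "HC"): (39.0, 107.8 * _DEG),
    ("C2", "C3", "HC"): (44.0, 110.5 * _DEG),
    ("C3", "C3", "HC"): (44.5, 110.3 * _DEG),
    ("HC", "C3", "HC"): (38.0, 107.5 * _DEG),
}
_TORSIONS = {
    ("C3", "C2", "C2", "C3"): 1.40,
    ("C2", "C2", "C2", "C3"): 1.45,
    ("C2", "C2", "C2", "C2"): 1.50,
    ("C2", "C2", "C3", "C3"): 1.42,
    ("C3", "C3", "C2", "C2"): 1.42,
}
_PAIRS = {
    ("C2", "C2"): PairParam(13500.0, 3.20, 560.0, 5200.0, 3.4),
    ("C2", "C3"): PairParam(14500.0, 3.25, 580.0, 5500.0, 3.4),
    ("C3", "C3"): PairParam(15500.0, 3.30, 600.0, 6000.0, 3.4),
    ("C2", "HC"): PairParam(4100.0, 3.45, 0.0, 0.0, 2.9),
    ("C3", "HC"): PairParam(4300.0, 3.50, 0.0, 0.0, 2.9),
    ("HC", "HC"): PairParam(2700.0, 3.65, 0.0, 0.0, 2.4),
}
_CHARGES = {"HC": 0.06, "C2": -0.12, "C3": -0.18}


def default_ground_truth(sigma_force: float = 0.0, sigma_energy: float = 0.0,
                         seed: int = 0) -> GroundTruth:
    """Alkane-plausible truth covering types C2, C3, HC for all species.

    Charges obey q_C2 = −2 q_HC and q_C3 = −3 q_HC, so every CH2/CH3-built
    alkane is exactly neutral; the product matrix is exactly rank one.
    """
    atom_types = {
        "C2": AtomType("C2", "C", _CHARGES["C2"]),
        "C3": AtomType("C3", "C", _CHARGES["C3"]),
        "HC": AtomType("HC", "H", _CHARGES["HC"]),
    }
    bonded = BondedParams(
        bonds=dict(_BONDS),
        angles={canonical_triple(k): v for k, v in _ANGLES.items()},
        torsions={canonical_quad(k): (v, 3, 0.0) for k, v in _TORSIONS.items()},
    )
    ff = ForceField(atom_types, bonded, dict(_PAIRS))
    ff.validate()
    return GroundTruth(ff, sigma_force, sigma_energy, seed)


# ---------------------------------------------------------------------------
# conformation generators

def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _perturb_frame(coords, top, rng, sigma_atom, sigma_trans, sigma_rot):
    out = coords.copy()
    for mol in sorted(set(top.molecule_ids)):
        idx = [i for i, m in enumerate(top.molecule_ids) if m == mol]
        com = out[idx].mean(axis=0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.normal(0.0, sigma_rot)
        k = axis
        c, s = math.cos(ang), math.sin(ang)
        rot = (c * np.eye(3) + s * np.array([[0, -k[2], k[1]],
                                             [k[2], 0, -k[0]],
                                             [-k[1], k[0], 0]])
               + (1 - c) * np.outer(k, k))
        out[idx] = (out[idx] - com) @ rot.T + com \
            + rng.normal(0.0, sigma_trans, size=3)
    out += rng.normal(0.0, sigma_atom, size=out.shape)
    return out


def generate_conformations(top: Topology, truth: GroundTruth, T: float,
                           n: int, seed: int, mode: str = "perturb",
                           coords0: np.ndarray | None = None,
                           box=None, sigma_atom: float = 0.035,
                           sigma_trans: float = 0.35,
                           sigma_rot: float = 0.12) -> ConformationSet:
    """Training conformations, either MD-sampled or Gaussian-perturbed.

    ``perturb`` draws per-molecule rigid-body jitter plus atomic Gaussian
    displacements around ``coords0`` with spreads scaled by √(T/298);
    ``md`` delegates to the Langevin sampler under the truth model.
    """
    if coords0 is None:
        raise ValueError("coords0 (reference geometry) required")
    coords0 = np.asarray(coords0, dtype=float)
    if mode == "md":
        settings = SamplingSettings(coords0=coords0, box=None if box is None
                                    else np.asarray(box, float))
        return sample_conformations(truth.ff, top, T, n, seed, settings)
    if mode != "perturb":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    scale = math.sqrt(T / 298.0)
    frames = ConformationSet()
    for k in range(n):
        x = _perturb_frame(coords0, top, rng, sigma_atom * scale,
                           sigma_trans * scale, sigma_rot * scale)
        frames.append(Conformation(
            x, box=None if box is None else np.asarray(box, float),
            label=f"perturb k={k} T={T}"))
    return frames


def mock_reference_forces(conformations, top: Topology, truth: GroundTruth,
                          seed: int | None = None) -> ConformationSet:
    """Reference forces = truth-model forces (+ optional Gaussian noise)."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    out = ConformationSet()
    for conf in conformations:
        _, f, _ = total_energy_forces(conf, top, truth.ff)
        if truth.sigma_force > 0:
            f = f + rng.normal(0.0, truth.sigma_force, size=f.shape)
        out.append(Conformation(conf.coords, forces=f, box=conf.box,
                                label=conf.label, energy=conf.energy))
    return out


def reference_oracle(truth: GroundTruth, seed: int | None = None):
    """A pluggable reference oracle (the mock stand-in for QM cluster runs)."""
    def oracle(conformations, topology):
        return mock_reference_forces(conformations, topology, truth, seed)
    return oracle


# ---------------------------------------------------------------------------
# multi-molecule assemblies

_OCTAHEDRON = np.array([
    [0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
    [0, 0, 1], [0, 0, -1], [1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0],
], dtype=float)


def make_cluster(species, n_molecules: int, seed: int,
                 contact: float = 2.7):
    """A liquid-density cluster of ``n_molecules`` monomers in contact.

    Emulates the training clusters carved out of liquid-phase frames:
    monomer copies with random orientations on compact sites, contracted
    radially until the smallest intermolecular atom–atom distance equals
    ``contact`` Å (van-der-Waals contact, as in the liquid).  Returns
    (topology, conformation).
    """
    if n_molecules > len(_OCTAHEDRON):
        raise ValueError(f"at most {len(_OCTAHEDRON)} molecules supported")
    mono_top, mono_xyz = ideal_geometry(species)
    mono_xyz = mono_xyz - mono_xyz.mean(axis=0)
    extent = float(cdist(mono_xyz, mono_xyz).max())
    rng = np.random.default_rng(seed)
    sites = _OCTAHEDRON[:n_molecules]
    rots = [_random_rotation(rng) for _ in range(n_molecules)]

    def assemble(scale):
        return [mono_xyz @ rots[m].T + sites[m] * scale
                for m in range(n_molecules)]

    def min_dist(placed):
        return min(cdist(placed[i], placed[j]).min()
                   for i in range(n_molecules) for j in range(i + 1,
                                                              n_molecules))

    lo, hi = 1.0, 2.0 * (extent + contact + 2.0)
    while min_dist(assemble(hi)) < contact:
        hi *= 1.5
    for _ in range(60):   # bisect the uniform contraction to the contact
        mid = 0.5 * (lo + hi)
        if min_dist(assemble(mid)) < contact:
            lo = mid
        else:
            hi = mid
    placed = assemble(hi)
    top = replicate_topology(mono_top, n_molecules)
    return top, Conformation(np.vstack(placed),
                             label=f"cluster n={n_molecules}")


def make_liquid_system(species, n_molecules: int = 27, seed: int = 0,
                       volume_per_molecule: float | None = None,
                       ff: ForceField | None = None,
                       relax: bool = True):
    """A periodic liquid box at the species' liquid density.

    Monomers are placed on a jittered cubic lattice with random
    orientations and, when a force field is given, the packing is
    energy-minimized to remove lattice artifacts and steric clashes.
    Returns (topology, conformation-with-box).
    """
    if volume_per_molecule is None:
        if species not in LIQUID_MOLAR_VOLUME:
            raise ValueError(f"no tabulated molar volume for {species!r}; "
                             "pass volume_per_molecule")
        volume_per_molecule = LIQUID_MOLAR_VOLUME[species]
    mono_top, mono_xyz = ideal_geometry(species, ff)
    mono_xyz = mono_xyz - mono_xyz.mean(axis=0)
    edge = (n_molecules * volume_per_molecule) ** (1.0 / 3.0)
    n_side = math.ceil(n_molecules ** (1.0 / 3.0))
    spacing = edge / n_side
    rng = np.random.default_rng(seed)
    pieces = []
    count = 0
    for i in range(n_side):
        for j in range(n_side):
            for k in range(n_side):
                if count >= n_molecules:
                    break
                site = (np.array([i, j, k], dtype=float) + 0.5) * spacing
                pieces.append(mono_xyz @ _random_rotation(rng).T + site
                              + rng.normal(0.0, 0.3, size=3))
                count += 1
    top = replicate_topology(mono_top, n_molecules)
    box = np.full(3, edge)
    coords = np.vstack(pieces)
    if relax and ff is not None:
        coords = _relax_box(coords, top, ff, box)
    return top, Conformation(coords, box=box,
                             label=f"liquid {species} n={n_molecules}")


def _relax_box(coords, top, ff, box, maxiter: int = 300):
    cutoff = 0.49 * float(box.min())

    def fun(x):
        conf = Conformation(x.reshape(-1, 3), box=box)
        e, f, _ = total_energy_forces(conf, top, ff, cutoff=cutoff)
        return e, -f.ravel()

    res = minimize(fun, coords.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    return res.x.reshape(-1, 3)


def make_training_set(species, truth: GroundTruth, seed: int,
                      n_frames_per_temperature: int = 100,
                      temperatures: tuple = (298.0, 328.0),
                      cluster_size: int = 6, n_molecules: int = 27,
                      stride: int = 25):
    """Training clusters per the cluster-reference protocol.

    Samples the periodic liquid with Langevin MD at each temperature under
    the truth model, then carves one ``cluster_size``-molecule cluster (a
    random seed molecule plus its nearest neighbours, unwrapped) out of
    every saved frame.  Returns (cluster topology, ConformationSet of
    cluster frames, liquid topology, liquid frames).
    """
    from .afm import make_training_cluster

    top, start = make_liquid_system(species, n_molecules, seed, ff=truth.ff)
    cutoff = 0.49 * float(start.box.min())
    liquid_frames = ConformationSet()
    for ti, T in enumerate(temperatures):
        settings = SamplingSettings(coords0=start.coords, box=start.box,
                                    stride=stride, cutoff=cutoff)
        liquid_frames.extend(sample_conformations(
            truth.ff, top, T, n_frames_per_temperature,
            (seed * 613 + 7 * ti) % (2**31), settings))
    clusters = ConformationSet()
    cluster_top = None
    for fi, frame in enumerate(liquid_frames):
        cluster_top, cl, _ = make_training_cluster(
            frame, top, cluster_size, seed=(seed * 31 + fi) % (2**31))
        clusters.append(cl)
    return cluster_top, clusters, top, liquid_frames


def make_liquid_frames(species, n_molecules: int, box_edge: float,
                       n_frames: int, seed: int,
                       jitter: float = 1.0) -> tuple:
    """Liquid-like periodic frames: monomers on a jittered cubic lattice
    with random orientations.  Returns (topology, ConformationSet)."""
    mono_top, mono_xyz = ideal_geometry(species)
    mono_xyz = mono_xyz - mono_xyz.mean(axis=0)
    n_side = math.ceil(n_molecules ** (1.0 / 3.0))
    spacing = box_edge / n_side
    rng = np.random.default_rng(seed)
    top = replicate_topology(mono_top, n_molecules)
    box = np.full(3, box_edge)
    frames = ConformationSet()
    sites = []
    for i in range(n_side):
        for j in range(n_side):
            for k in range(n_side):
                sites.append(((np.array([i, j, k]) + 0.5) * spacing))
    sites = np.array(sites[:n_molecules])
    for f in range(n_frames):
        pieces = []
        for s in sites:
            shift = s + rng.normal(0.0, jitter, size=3)
            pieces.append(mono_xyz @ _random_rotation(rng).T + shift)
        frames.append(Conformation(np.vstack(pieces), box=box,
                                   label=f"liquid frame={f}"))
    return top, frames


def extract_dimers(conformations, top: Topology,
                   window: tuple = (5.0, 12.0), n: int | None = None,
                   seed: int = 0) -> list[DimerRecord]:
    """Molecule pairs whose nearest-atom distance falls in ``window``.

    Periodic frames are unwrapped: the second monomer is shifted by the
    image closest to the first.  At most ``n`` records are drawn (uniformly,
    seeded); fewer may be available.
    """
    lo, hi = window
    if lo >= hi or lo <= 0:
        raise ValueError("invalid dimer distance window")
    mols = sorted(set(top.molecule_ids))
    if len(mols) < 2:
        import warnings
        warnings.warn("frame set has fewer than two molecules; no dimers")
        return []
    subs = {m: molecule_subtopology(top, m) for m in mols}
    candidates = []
    for fi, conf in enumerate(conformations):
        for ai in range(len(mols)):
            for bi in range(ai + 1, len(mols)):
                sub_a, idx_a = subs[mols[ai]]
                sub_b, idx_b = subs[mols[bi]]
                xa = conf.coords[idx_a]
                xb = conf.coords[idx_b].copy()
                if conf.box is not None:
                    delta = xb.mean(axis=0) - xa.mean(axis=0)
                    xb -= conf.box * np.round(delta / conf.box)
                d = float(cdist(xa, xb).min())
                if lo <= d <= hi:
                    candidates.append(DimerRecord(
                        sub_a, xa, sub_b, xb,
                        label=f"frame={fi} mols=({mols[ai]},{mols[bi]})"))
    rng = np.random.default_rng(seed)
    if n is not None and len(candidates) > n:
        pick = rng.choice(len(candidates), size=n, replace=False)
        candidates = [candidates[i] for i in sorted(pick)]
    return candidates


def mock_dispersion_energy(dimer: DimerRecord, truth: GroundTruth,
                           rng=None) -> float:
    """Damped C6/C8 intermolecular dispersion under the truth (+ noise)."""
    e = dispersion_energy(dimer, truth.ff)
    if truth.sigma_energy > 0:
        rng = rng or np.random.default_rng(truth.seed)
        e += float(rng.normal(0.0, truth.sigma_energy))
    return e


def make_dimer_dataset(species_list, truth: GroundTruth,
                       n_per_species: int = 80, seed: int = 0,
                       window: tuple = (5.0, 12.0)) -> list[DimerRecord]:
    """Homodimer records with mock dispersion energies, pooled over species.

    Emulates extracting dimers in the 5–12 Å nearest-atom window from
    liquid-phase configurations of each species and attaching reference
    dispersion energies.
    """
    rng = np.random.default_rng(seed)
    records = []
    for si, species in enumerate(species_list):
        _, xyz = ideal_geometry(species)
        extent = float(cdist(xyz, xyz).max())
        box = 3 * (extent + 8.0)
        top, frames = make_liquid_frames(
            species, 27, box, max(2, n_per_species // 20), seed + 101 * si,
            jitter=1.5)
        dimers = extract_dimers(frames, top, window=window,
                                n=n_per_species, seed=seed + 7 * si)
        for d in dimers:
            d.label = f"{species} {d.label}"
            d.energy = mock_dispersion_energy(d, truth, rng)
        records.extend(dimers)
    return records
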