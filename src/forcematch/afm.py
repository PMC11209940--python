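"""The iterative adaptive-force-matching (AFM) driver.

Each generation: sample conformations with the current force field
(Langevin MD at 298 and 328 K, 100 frames each by default), obtain
reference forces for the training set from a pluggable oracle (here the
synthetic mock; in production a QM cluster code), refit the force field by
the two-pass CMD force match, and track convergence.  Dispersion
coefficients are fitted once beforehand and stay frozen throughout the
iterations.  When the sampled structure stops changing the iteration is
converged and a final global fit pools the conformations of up to the last
four generations.

Convergence is declared when either (a) the refit changes no parameter
beyond ``param_tol`` — the fixed-point case, detectable in the very first
generation — or (b) the carbon–carbon radial distribution functions of two
consecutive generations agree within ``rdf_tol`` (max-abs difference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .design import two_pass_fit
from .model import Conformation, ConformationSet, ForceField, Topology, \
    canonical_pair
from .sampling import RDF, SamplingSettings, compute_rdf, rdf_distance, \
    sample_conformations

__all__ = ["AFMSettings", "GenerationRecord", "AFMResult", "run_afm",
           "make_training_cluster", "parameter_drift"]


@dataclass
class AFMSettings:
    """Controls for :func:`run_afm`."""

    topology: Topology = None
    coords0: np.ndarray = None
    box: np.ndarray | None = None
    temperatures: tuple = (298.0, 328.0)
    n_frames_per_temperature: int = 100
    sampling: SamplingSettings = field(default_factory=SamplingSettings)
    cluster_size: int = 6
    dispersion: dict | None = None
    rdf_tol: float = 0.05
    rdf_r_max: float | None = None
    rdf_bins: int = 40
    param_tol: float = 1e-6
    max_generations: int = 5
    global_fit_window: int = 4
    constraint_weight: float | None = None
    rcond: float = 1e-10
    seed: int = 0


@dataclass
class GenerationRecord:
    index: int
    sampling_forcefield: ForceField
    frames_by_temperature: dict
    training_frames: ConformationSet
    fitted_forcefield: ForceField
    rdfs: dict | None
    convergence_metric: float


@dataclass
class AFMResult:
    forcefield: ForceField
    generations: list[GenerationRecord]
    converged: bool
    status: str


def parameter_drift(old: ForceField, new: ForceField, top: Topology) -> float:
    """Max relative change over all comparable parameters of two models."""
    pairs_old, pairs_new = [], []
    for t in sorted(set(top.type_names)):
        pairs_old.append(old.charge(t))
        pairs_new.append(new.charge(t))
    tset = sorted(set(top.type_names))
    for i, a in enumerate(tset):
        for b in tset[i:]:
            po, pn = old.pair(a, b), new.pair(a, b)
            pairs_old += [po.A, po.C6, po.C8]
            pairs_new += [pn.A, pn.C6, pn.C8]
    for table in ("bonds", "angles"):
        keys = set(getattr(old.bonded, table)) & set(getattr(new.bonded, table))
        for k in sorted(keys):
            ko, xo = getattr(old.bonded, table)[k]
            kn, xn = getattr(new.bonded, table)[k]
            pairs_old += [ko, ko * xo]
            pairs_new += [kn, kn * xn]
    keys = set(old.bonded.torsions) & set(new.bonded.torsions)
    for k in sorted(keys):
        pairs_old.append(old.bonded.torsions[k][0])
        pairs_new.append(new.bonded.torsions[k][0])
    vo = np.array(pairs_old)
    vn = np.array(pairs_new)
    denom = np.maximum(np.maximum(np.abs(vo), np.abs(vn)), 1e-2)
    return float(np.max(np.abs(vn - vo) / denom, initial=0.0))


def make_training_cluster(conf: Conformation, top: Topology,
                          n_molecules: int = 6, seed: int = 0):
    """Extract a compact ``n_molecules`` cluster from a liquid frame.

    A seed molecule is drawn at random; its n−1 nearest neighbours (by
    minimum intermolecular atom distance, minimum-image) are kept, each
    shifted to the periodic image closest to the seed so the cluster is
    unwrapped.  Returns (cluster topology, cluster conformation,
    selected molecule ids).
    """
    from .synthetic import molecule_subtopology, replicate_topology

    mols = sorted(set(top.molecule_ids))
    if len(mols) < n_molecules:
        raise ValueError(
            f"frame has {len(mols)} molecules; {n_molecules} requested")
    rng = np.random.default_rng(seed)
    seed_mol = mols[int(rng.integers(len(mols)))]
    subs = {m: molecule_subtopology(top, m) for m in mols}

    def unwrapped(m, ref_com):
        _, idx = subs[m]
        x = conf.coords[idx].copy()
        if conf.box is not None:
            delta = x.mean(axis=0) - ref_com
            x -= conf.box * np.round(delta / conf.box)
        return x

    ref_com = conf.coords[subs[seed_mol][1]].mean(axis=0)
    xa = unwrapped(seed_mol, ref_com)
    dist = []
    for m in mols:
        if m == seed_mol:
            continue
        dist.append((float(cdist(xa, unwrapped(m, ref_com)).min()), m))
    dist.sort()
    chosen = [seed_mol] + [m for _, m in dist[:n_molecules - 1]]
    pieces = [unwrapped(m, ref_com) for m in chosen]
    mono = subs[seed_mol][0]
    cluster_top = replicate_topology(mono, n_molecules)
    cluster = Conformation(np.vstack(pieces),
                           label=f"cluster from {conf.label!r}")
    return cluster_top, cluster, chosen


def _carbon_pairs(top: Topology, ff: ForceField):
    ctypes = sorted({t for t, e in zip(top.type_names, top.elements)
                     if e == "C"})
    return [canonical_pair(a, b) for i, a in enumerate(ctypes)
            for b in ctypes[i:]]


def _homogeneous(top: Topology) -> bool:
    comps = set()
    for m in sorted(set(top.molecule_ids)):
        comp = tuple(sorted(t for t, mi in zip(top.type_names,
                                               top.molecule_ids) if mi == m))
        comps.add(comp)
    return len(comps) == 1


def run_afm(initial_ff: ForceField, reference, settings: AFMSettings
            ) -> AFMResult:
    """Iterate sample → reference forces → fit until structural convergence,
    then perform the pooled global fit over the last generations.

    ``reference`` is a callable ``(conformations, topology) →
    ConformationSet with forces`` — any force provider with this signature
    can stand in for the QM step.
    """
    top = settings.topology
    if top is None or settings.coords0 is None:
        raise ValueError("settings need a topology and starting coordinates")
    current = initial_ff
    records: list[GenerationRecord] = []
    prev_rdfs = None
    converged = False
    status = "max generations reached without convergence"
    train_top = top
    for gen in range(1, settings.max_generations + 1):
        frames_by_t = {}
        all_frames = ConformationSet()
        for ti, T in enumerate(settings.temperatures):
            s = replace(settings.sampling, coords0=settings.coords0,
                        box=settings.box)
            seed = (settings.seed * 1009 + gen * 131 + ti * 7) % (2**31)
            frames = sample_conformations(
                current, top, T, settings.n_frames_per_temperature, seed, s)
            for f in frames:
                f.label += f" gen={gen}"
            frames_by_t[T] = frames
            all_frames.extend(frames)
        if top.n_molecules > settings.cluster_size and _homogeneous(top):
            train = ConformationSet()
            for fi, f in enumerate(all_frames):
                train_top, cl, _ = make_training_cluster(
                    f, top, settings.cluster_size,
                    seed=(settings.seed * 53 + gen * 17 + fi) % (2**31))
                train.append(cl)
        else:
            train = all_frames
        train = reference(train, train_top)
        fitted, _ = two_pass_fit(
            train, train_top, current, dispersion=settings.dispersion,
            constraint_weight=settings.constraint_weight,
            rcond=settings.rcond)
        rdfs = None
        if settings.box is not None:
            r_max = settings.rdf_r_max or 0.49 * float(np.min(settings.box))
            rdfs = {p: compute_rdf(all_frames, top, p, r_max,
                                   settings.rdf_bins)
                    for p in _carbon_pairs(top, current)}
        drift = parameter_drift(current, fitted, train_top)
        metric = drift
        if prev_rdfs is not None and rdfs is not None:
            metric = max(rdf_distance(rdfs[p], prev_rdfs[p]) for p in rdfs)
        records.append(GenerationRecord(gen, current, frames_by_t, train,
                                        fitted, rdfs, metric))
        current = fitted
        if drift < settings.param_tol:
            converged = True
            status = f"fixed point at generation {gen} (drift {drift:.2e})"
            break
        if prev_rdfs is not None and rdfs is not None and \
                metric < settings.rdf_tol:
            converged = True
            status = f"RDFs stable at generation {gen} (Δg {metric:.3f})"
            break
        prev_rdfs = rdfs
    pool = ConformationSet()
    for rec in records[-settings.global_fit_window:]:
        pool.extend(rec.training_frames)
    final_ff, _ = two_pass_fit(
        pool, train_top, current, dispersion=settings.dispersion,
        constraint_weight=settings.constraint_weight, rcond=settings.rcond)
    return AFMResult(final_ff, records, converged, status)
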