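"""Conformational sampling (Langevin dynamics) and radial distribution
functions.

The sampler is a BAOAB-split Langevin integrator at a 1 fs time step with an
inverse friction constant of 2.0 ps, matching the gas-phase protocol used
for the alkane property runs.  It samples at fixed box (no barostat): the
training data it feeds are finite clusters and pre-built liquid-like frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import Conformation, ConformationSet, ForceField, Topology, \
    minimum_image, total_energy_forces
from .units import ACCEL, ATOMIC_MASS, KB

__all__ = ["SamplingSettings", "sample_conformations", "run_langevin",
           "RDF", "compute_rdf", "rdf_distance"]


@dataclass
class SamplingSettings:
    """Langevin sampling controls (times in fs/ps, lengths in Å)."""

    coords0: np.ndarray | None = None
    box: np.ndarray | None = None
    dt_fs: float = 1.0
    friction_inv_ps: float = 2.0    # γ = 1 / this
    stride: int = 50                # steps between saved frames
    equil_frac: float = 0.2         # discarded leading fraction
    cutoff: float | None = None
    max_energy: float = 1e6         # kcal/mol; divergence guard
    # Caging for gas-phase multi-molecule clusters: each molecular COM is
    # tethered harmonically to its starting site, standing in for the cage
    # of surrounding liquid the cluster was carved from (k = 2 kcal/mol/Å²
    # gives ~0.5 Å COM rattling at room temperature, liquid-like).
    # Sampling-only — never part of the fitted model or reference forces.
    restrain_com: bool = True
    restraint_k: float = 2.0        # kcal/mol/Å²


def _masses(top: Topology) -> np.ndarray:
    return np.array([ATOMIC_MASS[e] for e in top.elements])


class _ComRestraint:
    """Harmonic tether of each molecular COM to its starting site."""

    def __init__(self, top: Topology, masses, coords0, k):
        self.k = k
        self.groups = [np.array([i for i, m in enumerate(top.molecule_ids)
                                 if m == mol])
                       for mol in sorted(set(top.molecule_ids))]
        self.w = [masses[g] / masses[g].sum() for g in self.groups]
        self.sites = [coords0[g].T @ w
                      for g, w in zip(self.groups, self.w)]

    def forces(self, coords):
        f = np.zeros_like(coords)
        for g, w, site in zip(self.groups, self.w, self.sites):
            dv = coords[g].T @ w - site
            f[g] += np.outer(w, -2.0 * self.k * dv)
        return f


def run_langevin(ff: ForceField, top: Topology, coords0, T: float,
                 n_steps: int, seed: int,
                 settings: SamplingSettings | None = None,
                 save_stride: int | None = None):
    """Integrate BAOAB Langevin dynamics; returns (frames, diagnostics).

    Deterministic for a given seed.  Frames are saved every ``save_stride``
    steps (never during the first step).  Diagnostics report the mean
    kinetic temperature over the saved portion.
    """
    s = settings or SamplingSettings()
    rng = np.random.default_rng(seed)
    x = np.array(coords0, dtype=float)
    m = _masses(top)[:, None]
    dt = s.dt_fs * 1e-3                      # ps
    gamma = 1.0 / s.friction_inv_ps          # ps⁻¹
    kT = KB * T
    # velocities in Å/ps; Maxwell–Boltzmann start
    v = rng.normal(size=x.shape) * np.sqrt(ACCEL * kT / m)
    c1 = math.exp(-gamma * dt)
    c2 = np.sqrt(ACCEL * kT / m * (1.0 - c1 * c1))
    restraint = None
    if s.restrain_com and s.box is None and top.n_molecules > 1:
        restraint = _ComRestraint(top, _masses(top), x, s.restraint_k)

    def model_forces(conf):
        e, f, _ = total_energy_forces(conf, top, ff, cutoff=s.cutoff)
        if restraint is not None:
            f = f + restraint.forces(conf.coords)
        return e, f

    conf = Conformation(x, box=s.box)
    e, f = model_forces(conf)
    frames = ConformationSet()
    kin_temps = []
    for step in range(1, n_steps + 1):
        a = ACCEL * f / m
        v += 0.5 * dt * a
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.normal(size=x.shape)
        x += 0.5 * dt * v
        conf = Conformation(x.copy(), box=s.box)
        e, f = model_forces(conf)
        a = ACCEL * f / m
        v += 0.5 * dt * a
        if not math.isfinite(e) or abs(e) > s.max_energy:
            raise RuntimeError(
                f"energy diverged at step {step}: E = {e:.3g} kcal/mol")
        if save_stride and step % save_stride == 0:
            conf.energy = e
            conf.label = f"step={step} T={T}"
            frames.append(conf)
            ke = 0.5 * float((m * v * v).sum()) / ACCEL
            kin_temps.append(2.0 * ke / (3.0 * top.n_atoms * KB))
    diag = {"mean_kinetic_T": float(np.mean(kin_temps)) if kin_temps else
            float("nan"),
            "final_energy": e}
    return frames, diag


def sample_conformations(ff: ForceField, top: Topology, T: float,
                         n_frames: int, seed: int,
                         settings: SamplingSettings) -> ConformationSet:
    """Sample ``n_frames`` conformations at temperature T by Langevin MD.

    Runs an equilibration segment (``equil_frac`` of the production length,
    discarded) followed by ``n_frames × stride`` production steps, saving
    every ``stride``-th frame.  Bitwise reproducible for a given seed.
    """
    if settings.coords0 is None:
        raise ValueError("settings.coords0 (starting coordinates) required")
    production = n_frames * settings.stride
    equil = int(math.ceil(settings.equil_frac / (1.0 - settings.equil_frac)
                          * production)) if settings.equil_frac else 0
    frames, _ = run_langevin(ff, top, settings.coords0, T, equil + production,
                             seed, settings, save_stride=settings.stride)
    return ConformationSet(frames[-n_frames:])


# ---------------------------------------------------------------------------
# radial distribution functions

@dataclass
class RDF:
    """Shell-normalized pair-distance histogram g(r)."""

    pair: tuple
    bin_edges: np.ndarray
    g: np.ndarray
    frame_count: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.g < -1e-12):
            raise ValueError("g(r) must be non-negative")


def compute_rdf(conformations, top: Topology, pair: tuple,
                r_max: float, n_bins: int) -> RDF:
    """Intermolecular site–site g(r) for the given type pair.

    Each frame must carry an (orthorhombic) box; normalization uses the
    frame's own ideal-gas shell expectation, so boxes may differ between
    frames.
    """
    a, b = pair
    conformations = list(conformations)
    if not conformations:
        raise ValueError("need at least one frame")
    sel = [(i, j)
           for i in range(top.n_atoms) for j in range(i + 1, top.n_atoms)
           if top.molecule_ids[i] != top.molecule_ids[j]
           and {top.type_names[i], top.type_names[j]} == {a, b}]
    edges = np.linspace(0.0, r_max, n_bins + 1)
    shell = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    hist = np.zeros(n_bins)
    expected = np.zeros(n_bins)
    idx = np.asarray(sel, dtype=int)
    for fi, conf in enumerate(conformations):
        if conf.box is None:
            raise ValueError(f"frame {fi} has no box; RDF needs one")
        if r_max > float(conf.box.min()) / 2.0:
            raise ValueError(
                f"r_max {r_max} exceeds half the smallest box edge")
        if len(sel):
            d = minimum_image(conf.coords[idx[:, 0]] - conf.coords[idx[:, 1]],
                              conf.box)
            r = np.linalg.norm(d, axis=1)
            hist += np.histogram(r, bins=edges)[0]
        vol = float(np.prod(conf.box))
        expected += len(sel) * shell / vol
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, hist / expected, 0.0)
    return RDF((a, b), edges, g, len(conformations))


def rdf_distance(rdf_a: RDF, rdf_b: RDF) -> float:
    """max over bins of |g_a − g_b| (symmetric; 0 for identical RDFs)."""
    if rdf_a.bin_edges.shape != rdf_b.bin_edges.shape or \
            not np.array_equal(rdf_a.bin_edges, rdf_b.bin_edges):
        raise ValueError("RDFs have mismatched binning")
    return float(np.max(np.abs(rdf_a.g - rdf_b.g), initial=0.0))
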