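"""C6/C8 dispersion fitting to dimer dispersion energies.

Dispersion coefficients are fitted to per-dimer dispersion energies (the
SAPT E² stand-in) rather than forces, before and independently of the
force-matching iterations.  Dimers are kept only when their nearest-atom
distance lies in the closed window [5, 12] Å — exchange-dispersion, which
the model does not contain, is not negligible closer in, and the window
ensures the fitted terms carry the correct asymptotics.  One shared
coefficient set per carbon type pair is fitted jointly across all source
molecules; the damping distances r_d are held at their production values so
the coefficients are self-consistent with the model (the damping correction
is tiny beyond 5 Å).  A C10 term is deliberately not offered: fitted
higher-order terms tend to come out repulsive and destabilize the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .design import (FitReport, LinearSystem, ParameterEntry, ParameterSpec,
                     solve_svd)
from .model import MIN_PAIR_DISTANCE, Conformation, ForceField, Topology, \
    canonical_pair

__all__ = ["DimerRecord", "nearest_atom_distance", "filter_dimers",
           "fit_dispersion", "stability_check", "dispersion_energy"]


@dataclass
class DimerRecord:
    """Two monomers, their topologies, and a reference dispersion energy."""

    topology_a: Topology
    coords_a: np.ndarray
    topology_b: Topology
    coords_b: np.ndarray
    energy: float | None = None   # kcal/mol; ≤ 0 for physical dispersion
    label: str = ""

    def __post_init__(self):
        self.coords_a = np.asarray(self.coords_a, dtype=float)
        self.coords_b = np.asarray(self.coords_b, dtype=float)
        if self.coords_a.shape != (self.topology_a.n_atoms, 3):
            raise ValueError("monomer A coordinates do not match topology")
        if self.coords_b.shape != (self.topology_b.n_atoms, 3):
            raise ValueError("monomer B coordinates do not match topology")


def nearest_atom_distance(dimer: DimerRecord) -> float:
    """Minimum intermolecular atom–atom distance (Å), brute force."""
    if dimer.coords_a.size == 0 or dimer.coords_b.size == 0:
        raise ValueError("empty monomer")
    d = float(cdist(dimer.coords_a, dimer.coords_b).min())
    if d < MIN_PAIR_DISTANCE:
        raise ValueError(f"monomers overlap: nearest distance {d:.3g} Å")
    return d


def filter_dimers(records, d_min: float = 5.0, d_max: float = 12.0):
    """Keep dimers with nearest-atom distance in the closed window."""
    if d_min >= d_max:
        raise ValueError("d_min must be below d_max")
    kept = [r for r in records
            if d_min <= nearest_atom_distance(r) <= d_max]
    if not kept:
        raise ValueError(
            f"no dimers survive the [{d_min}, {d_max}] Å window "
            f"({len(list(records))} candidates)")
    return kept


def _carbon_pair_basis(record: DimerRecord, ff: ForceField):
    """Σ −1/(r⁶+r_d⁶) and Σ −1/(r⁸+r_d⁸) per carbon type pair."""
    ta, tb = record.topology_a, record.topology_b
    ca = [i for i, e in enumerate(ta.elements) if e == "C"]
    cb = [i for i, e in enumerate(tb.elements) if e == "C"]
    basis6: dict[tuple, float] = {}
    basis8: dict[tuple, float] = {}
    if not ca or not cb:
        return basis6, basis8
    r = cdist(record.coords_a[ca], record.coords_b[cb])
    for ii, i in enumerate(ca):
        for jj, j in enumerate(cb):
            key = canonical_pair(ta.type_names[i], tb.type_names[j])
            rd = ff.pair(*key).r_d
            rij = r[ii, jj]
            basis6[key] = basis6.get(key, 0.0) - 1.0 / (rij**6 + rd**6)
            basis8[key] = basis8.get(key, 0.0) - 1.0 / (rij**8 + rd**8)
    return basis6, basis8


def dispersion_energy(record: DimerRecord, ff: ForceField) -> float:
    """Model intermolecular dispersion energy of a dimer (damped C6+C8 only)."""
    basis6, basis8 = _carbon_pair_basis(record, ff)
    e = 0.0
    for key, v in basis6.items():
        e += ff.pair(*key).C6 * v
    for key, v in basis8.items():
        e += ff.pair(*key).C8 * v
    return e


def fit_dispersion(records, ff: ForceField, rcond: float = 1e-10):
    """Joint linear fit of C6/C8 per carbon type pair across all records.

    Returns (coefficients {pair: (C6, C8)}, FitReport, warnings).  Requires
    at least twice as many records as free coefficients.
    """
    records = list(records)
    keys = []
    rows = []
    for rec in records:
        if rec.energy is None:
            raise ValueError(f"dimer {rec.label!r} has no reference energy")
        b6, b8 = _carbon_pair_basis(rec, ff)
        for k in b6:
            if k not in keys:
                keys.append(k)
        rows.append((b6, b8))
    keys = sorted(keys)
    n_coeff = 2 * len(keys)
    if n_coeff == 0:
        raise ValueError("no carbon–carbon pairs in the dimer set")
    if len(records) < 2 * n_coeff:
        raise ValueError(
            f"under-determined dispersion fit: {len(records)} records for "
            f"{n_coeff} coefficients; need at least {2 * n_coeff}")
    entries = [ParameterEntry("C6", k) for k in keys] + \
              [ParameterEntry("C8", k) for k in keys]
    spec = ParameterSpec(entries)
    L = np.zeros((len(records), n_coeff))
    rhs = np.array([r.energy for r in records], dtype=float)
    for n, (b6, b8) in enumerate(rows):
        for c, k in enumerate(keys):
            L[n, c] = b6.get(k, 0.0)
            L[n, len(keys) + c] = b8.get(k, 0.0)
    system = LinearSystem(L, rhs, np.ones(len(records)),
                          [("dimer", r.label) for r in records], spec,
                          n_force_rows=len(records))
    report = solve_svd(system, rcond=rcond)
    coeffs = {k: (report.value("C6", k), report.value("C8", k)) for k in keys}
    return coeffs, report, stability_check(coeffs)


def stability_check(coefficients: dict) -> list[str]:
    """Flag repulsive (negative) dispersion coefficients as instabilities."""
    warnings_ = []
    for key, (c6, c8) in sorted(coefficients.items()):
        if c6 < 0:
            warnings_.append(
                f"unstable dispersion: C6{key} = {c6:.6g} is repulsive")
        if c8 < 0:
            warnings_.append(
                f"unstable dispersion: C8{key} = {c8:.6g} is repulsive")
    return warnings_
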