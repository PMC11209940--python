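"""Readers and writers: extended-XYZ conformations/dimers and the JSON
force-field parameter document.

Extended-XYZ carries per-frame metadata on the comment line (``Lattice``,
``Energy``, ``Label``, ``Properties``) and per-atom columns declared by the
``Properties`` string; reference forces travel as three extra real columns.
The force-field file is a single keyed JSON document with a units header;
values are converted to the internal units (Å, kcal/mol, e, rad) on read.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from pathlib import Path

import numpy as np

from .model import (AtomType, BondedParams, Conformation, ConformationSet,
                    ForceField, PairParam, canonical_pair)
from .units import COULOMB_K

__all__ = ["read_conformations", "write_conformations",
           "read_forcefield", "write_forcefield",
           "read_dimers", "write_dimers"]

_KV = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _fmt(x: float) -> str:
    return f"{x:.17g}"


# ---------------------------------------------------------------------------
# extended XYZ

def _comment_line(conf: Conformation, with_types: bool) -> str:
    props = "species:S:1:pos:R:3"
    if with_types:
        props += ":type:S:1:mol:I:1"
    if conf.forces is not None:
        props += ":forces:R:3"
    parts = [f"Properties={props}"]
    if conf.box is not None:
        lx, ly, lz = conf.box
        parts.append(f'Lattice="{_fmt(lx)} 0 0 0 {_fmt(ly)} 0 0 0 {_fmt(lz)}"')
    if conf.energy is not None:
        parts.append(f"Energy={_fmt(conf.energy)}")
    if conf.label:
        parts.append(f'Label="{conf.label}"')
    return " ".join(parts)


def write_conformations(path, conformations, topology=None):
    """Write frames as extended-XYZ; with a topology, per-atom type and
    molecule-id columns are included."""
    path = Path(path)
    lines = []
    for conf in conformations:
        n = conf.n_atoms
        if topology is not None and topology.n_atoms != n:
            raise ValueError("topology does not match frame atom count")
        lines.append(str(n))
        lines.append(_comment_line(conf, topology is not None))
        for i in range(n):
            if topology is not None:
                el = topology.elements[i]
                extra = f" {topology.type_names[i]} {topology.molecule_ids[i]}"
            else:
                el = getattr(conf, "species", None)
                el = el[i] if el is not None else "X"
                extra = ""
            x, y, z = conf.coords[i]
            row = f"{el} {_fmt(x)} {_fmt(y)} {_fmt(z)}{extra}"
            if conf.forces is not None:
                fx, fy, fz = conf.forces[i]
                row += f" {_fmt(fx)} {_fmt(fy)} {_fmt(fz)}"
            lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def _parse_properties(spec: str):
    fields = spec.split(":")
    if len(fields) % 3:
        raise ValueError(f"malformed Properties string {spec!r}")
    cols = []
    for k in range(0, len(fields), 3):
        cols.append((fields[k], fields[k + 1], int(fields[k + 2])))
    return cols


def read_conformations(path) -> ConformationSet:
    """Read extended-XYZ frames; force columns and type/mol columns, when
    present, populate ``forces`` and the ``species``/``types``/``mol_ids``
    attributes of each frame."""
    path = Path(path)
    raw = path.read_text().splitlines()
    frames = ConformationSet()
    ln = 0
    frame_index = 0
    while ln < len(raw):
        if not raw[ln].strip():
            ln += 1
            continue
        try:
            n = int(raw[ln].strip())
        except ValueError:
            raise ValueError(
                f"line {ln + 1}: malformed atom count {raw[ln]!r}") from None
        if ln + 1 >= len(raw) or ln + 1 + n > len(raw):
            raise ValueError(f"frame {frame_index} is truncated")
        comment = raw[ln + 1]
        kv = {m.group(1): (m.group(2) if m.group(2) is not None else m.group(3))
              for m in _KV.finditer(comment)}
        cols = _parse_properties(kv.get("Properties", "species:S:1:pos:R:3"))
        box = None
        if "Lattice" in kv:
            lat = np.array([float(v) for v in kv["Lattice"].split()])
            box = lat.reshape(3, 3).diagonal().copy()
        energy = float(kv["Energy"]) if "Energy" in kv else None
        label = kv.get("Label", "")
        species, types, mols = [], [], []
        coords = np.empty((n, 3))
        forces = None
        for a in range(n):
            tokens = raw[ln + 2 + a].split()
            want = sum(c[2] for c in cols)
            if len(tokens) != want:
                raise ValueError(
                    f"frame {frame_index}, line {ln + 3 + a}: expected "
                    f"{want} columns, found {len(tokens)}")
            pos = 0
            for name, _, width in cols:
                chunk = tokens[pos:pos + width]
                pos += width
                if name == "species":
                    species.append(chunk[0])
                elif name == "pos":
                    coords[a] = [float(v) for v in chunk]
                elif name == "forces":
                    if forces is None:
                        forces = np.empty((n, 3))
                    forces[a] = [float(v) for v in chunk]
                elif name == "type":
                    types.append(chunk[0])
                elif name == "mol":
                    mols.append(int(chunk[0]))
        conf = Conformation(coords, forces=forces, box=box, label=label,
                            energy=energy)
        conf.species = species
        conf.types = types or None
        conf.mol_ids = mols or None
        frames.append(conf)
        ln += 2 + n
        frame_index += 1
    return frames


def write_dimers(path, records):
    """Dimer records as extended-XYZ: both monomers in one frame with mol
    ids 0/1 and the reference energy on the comment line."""
    frames = ConformationSet()
    tops = []
    for rec in records:
        coords = np.vstack([rec.coords_a, rec.coords_b])
        conf = Conformation(coords, label=rec.label, energy=rec.energy)
        frames.append(conf)
        tops.append(rec)
    path = Path(path)
    lines = []
    for conf, rec in zip(frames, tops):
        n = conf.n_atoms
        lines.append(str(n))
        parts = ["Properties=species:S:1:pos:R:3:type:S:1:mol:I:1"]
        if conf.energy is not None:
            parts.append(f"Energy={_fmt(conf.energy)}")
        if conf.label:
            parts.append(f'Label="{conf.label}"')
        lines.append(" ".join(parts))
        tt = list(zip(rec.topology_a.elements, rec.topology_a.type_names,
                      [0] * rec.topology_a.n_atoms)) + \
            list(zip(rec.topology_b.elements, rec.topology_b.type_names,
                     [1] * rec.topology_b.n_atoms))
        for i in range(n):
            el, ty, mol = tt[i]
            x, y, z = conf.coords[i]
            lines.append(f"{el} {_fmt(x)} {_fmt(y)} {_fmt(z)} {ty} {mol}")
    path.write_text("\n".join(lines) + "\n")


def read_dimers(path):
    """Read dimer frames written by :func:`write_dimers`.

    Monomer topologies are rebuilt without bonds (types and elements only),
    which is all the dispersion fit needs.
    """
    from .dispersion import DimerRecord
    from .model import Topology

    frames = read_conformations(path)
    records = []
    for conf in frames:
        if conf.types is None or conf.mol_ids is None:
            raise ValueError("dimer file lacks type/mol columns")
        ids = np.array(conf.mol_ids)
        recs = []
        for mol in (0, 1):
            sel = np.nonzero(ids == mol)[0]
            top = Topology([conf.types[i] for i in sel],
                           [conf.species[i] for i in sel],
                           [0] * len(sel), [])
            recs.append((top, conf.coords[sel]))
        records.append(DimerRecord(recs[0][0], recs[0][1], recs[1][0],
                                   recs[1][1], energy=conf.energy,
                                   label=conf.label))
    return records


# ---------------------------------------------------------------------------
# force-field parameter document

_CANON_UNITS = {"length": "angstrom", "energy": "kcal/mol", "charge": "e",
                "angle": "rad"}
_LENGTH = {"angstrom": 1.0, "nm": 10.0}
_ENERGY = {"kcal/mol": 1.0, "kj/mol": 1.0 / 4.184}
_ANGLE = {"rad": 1.0, "deg": math.pi / 180.0}
_TOP_KEYS = {"units", "damping", "coulomb_constant", "atom_types", "bonds",
             "angles", "torsions", "pairs"}


def write_forcefield(path, ff: ForceField):
    doc = {
        "units": dict(_CANON_UNITS),
        "damping": "rational",
        "coulomb_constant": ff.k_e,
        "atom_types": {name: {"element": at.element, "charge": at.charge}
                       for name, at in sorted(ff.atom_types.items())},
        "bonds": {" ".join(k): {"k_r": v[0], "r_e": v[1]}
                  for k, v in sorted(ff.bonded.bonds.items())},
        "angles": {" ".join(k): {"k_theta": v[0], "theta_e": v[1]}
                   for k, v in sorted(ff.bonded.angles.items())},
        "torsions": {" ".join(k): {"A_t": v[0], "m": v[1], "phi0": v[2]}
                     for k, v in sorted(ff.bonded.torsions.items())},
        "pairs": {" ".join(k): {"A": p.A, "b": p.b, "C6": p.C6, "C8": p.C8,
                                "r_d": p.r_d}
                  for k, p in sorted(ff.pairs.items())},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _require_keys(section: dict, allowed: set, where: str):
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in {where}")


def read_forcefield(path) -> ForceField:
    doc = json.loads(Path(path).read_text())
    _require_keys(doc, _TOP_KEYS, "force-field document")
    if "units" not in doc:
        raise ValueError("force-field file lacks a units header")
    units = doc["units"]
    _require_keys(units, set(_CANON_UNITS), "units header")
    ul = _LENGTH[units.get("length", "angstrom")]
    ue = _ENERGY[units.get("energy", "kcal/mol")]
    ua = _ANGLE[units.get("angle", "rad")]
    damping = doc.get("damping")
    if damping is None:
        warnings.warn("no damping tag in force-field file; assuming the "
                      "rational −C_n/(r^n + r_d^n) form")
    elif damping != "rational":
        raise ValueError(f"unsupported damping form {damping!r}")
    atom_types = {}
    for name, rec in doc.get("atom_types", {}).items():
        _require_keys(rec, {"element", "charge"}, f"atom type {name}")
        atom_types[name] = AtomType(name, rec["element"],
                                    float(rec.get("charge", 0.0)))
    bonded = BondedParams()
    for key, rec in doc.get("bonds", {}).items():
        _require_keys(rec, {"k_r", "r_e"}, f"bond {key}")
        a, b = key.split()
        bonded.bonds[canonical_pair(a, b)] = (rec["k_r"] * ue / ul**2,
                                              rec["r_e"] * ul)
    for key, rec in doc.get("angles", {}).items():
        _require_keys(rec, {"k_theta", "theta_e"}, f"angle {key}")
        t = tuple(key.split())
        bonded.angles[t] = (rec["k_theta"] * ue / ua**2, rec["theta_e"] * ua)
    for key, rec in doc.get("torsions", {}).items():
        _require_keys(rec, {"A_t", "m", "phi0"}, f"torsion {key}")
        t = tuple(key.split())
        bonded.torsions[t] = (rec["A_t"] * ue, int(rec["m"]),
                              rec["phi0"] * ua)
    pairs = {}
    for key, rec in doc.get("pairs", {}).items():
        _require_keys(rec, {"A", "b", "C6", "C8", "r_d"}, f"pair {key}")
        a, b = key.split()
        pairs[canonical_pair(a, b)] = PairParam(
            A=rec.get("A", 0.0) * ue,
            b=rec.get("b", 1.0) / ul,
            C6=rec.get("C6", 0.0) * ue * ul**6,
            C8=rec.get("C8", 0.0) * ue * ul**8,
            r_d=rec.get("r_d", 0.0) * ul)
    ff = ForceField(atom_types, bonded, pairs,
                    k_e=doc.get("coulomb_constant", COULOMB_K))
    ff.validate()
    return ff
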