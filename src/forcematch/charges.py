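"""Charge Matrix Decomposition (CMD).

Force matching determines Coulomb interactions through charge *products*
Q_AB = q_A q_B, which enter the forces linearly.  Fitted independently, the
products generally violate the consistency relation
Q_AB · Q_CD = Q_AC · Q_BD that holds for genuine products of atomic charges
(it is satisfied automatically only for two atom types under neutrality
constraints).  CMD extracts per-type charges as the scaled dominant
eigenvector of the symmetric product matrix: with λ1 the largest eigenvalue
and v its eigenvector, q_A = √λ1 · v_A — the closest rank-1 approximation in
the Frobenius norm (Eckart–Young).  The eigenvector sign is arbitrary (a
global charge flip changes no product), so it is fixed by requiring the
anchor type — hydrogen if present, else the least electronegative element —
to carry a non-negative charge.  If the matrix has no positive eigenvalue,
all charges are set to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import ELECTRONEGATIVITY

__all__ = [
    "ChargeProductMatrix", "ChargeAssignment", "build_product_matrix",
    "cmd_decompose", "products_from_charges", "consistency_defect",
    "neutralize_charges",
]


@dataclass
class ChargeProductMatrix:
    """Symmetric T×T matrix of type-pair charge products (e²)."""

    labels: list[str]
    elements: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        t = len(self.labels)
        if self.matrix.shape != (t, t):
            raise ValueError("product matrix shape does not match labels")
        if len(self.elements) != t:
            raise ValueError("element list does not match labels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite charge products")
        if not np.allclose(self.matrix, self.matrix.T, rtol=0, atol=0):
            raise ValueError("charge product matrix must be exactly symmetric")

    def product(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


@dataclass
class ChargeAssignment:
    """Per-type charges with CMD diagnostics."""

    charges: dict            # type name -> charge (e)
    lambda1: float
    reconstruction_error: float   # Frobenius ‖Q − λ1 v vᵀ‖
    anchor: str
    labels: list[str] = field(default_factory=list)

    def vector(self) -> np.ndarray:
        return np.array([self.charges[l] for l in self.labels])


def build_product_matrix(products: dict, labels, elements) -> ChargeProductMatrix:
    """Assemble the symmetric matrix from fitted unordered-pair products."""
    labels = list(labels)
    t = len(labels)
    q = np.empty((t, t))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            key = (a, b) if a <= b else (b, a)
            if key not in products:
                raise KeyError(f"missing fitted charge product for pair {key}")
            q[i, j] = products[key]
    return ChargeProductMatrix(labels, list(elements), q)


def _pick_anchor(labels, elements) -> str:
    """Hydrogen if present, else the least electronegative element; ties by label."""
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    for i in order:
        if elements[i] == "H":
            return labels[i]
    best = min(order, key=lambda i: (ELECTRONEGATIVITY.get(elements[i], 2.5),
                                     labels[i]))
    return labels[best]


def cmd_decompose(q: ChargeProductMatrix,
                  sign_anchor: str | None = None) -> ChargeAssignment:
    """Rank-1 decomposition of the charge-product matrix into atomic charges.

    q_A = √λ1 · v_A for the largest eigenvalue λ1; anchor-type charge made
    non-negative; all charges zero when no positive eigenvalue exists (λ1 = 0
    is treated the same way, for continuity of the rule).
    """
    anchor = sign_anchor or _pick_anchor(q.labels, q.elements)
    if anchor not in q.labels:
        raise ValueError(f"sign anchor {anchor!r} is not an atom type")
    evals, evecs = np.linalg.eigh(q.matrix)
    lam1 = float(evals[-1])
    if lam1 <= 0.0:
        charges = {l: 0.0 for l in q.labels}
        err = float(np.linalg.norm(q.matrix))
        return ChargeAssignment(charges, lam1, err, anchor, list(q.labels))
    # near-degenerate top eigenvalue: pick the eigenvector with the largest
    # weight on the anchor type and warn
    close = np.nonzero(evals >= lam1 - 1e-12 * max(1.0, abs(lam1)))[0]
    ia = q.labels.index(anchor)
    if len(close) > 1:
        warnings.warn(
            f"dominant eigenvalue is {len(close)}-fold degenerate; choosing "
            "the eigenvector with the largest anchor component")
        pick = close[int(np.argmax(np.abs(evecs[ia, close])))]
    else:
        pick = close[-1]
    v = evecs[:, pick].copy()
    if v[ia] < 0:
        v = -v
    elif v[ia] == 0.0:
        nz = np.nonzero(v)[0]
        if len(nz) and v[nz[0]] < 0:
            v = -v
    qvec = np.sqrt(lam1) * v
    err = float(np.linalg.norm(q.matrix - lam1 * np.outer(v, v)))
    charges = {l: float(c) for l, c in zip(q.labels, qvec)}
    return ChargeAssignment(charges, lam1, err, anchor, list(q.labels))


def products_from_charges(assignment: ChargeAssignment) -> ChargeProductMatrix:
    """Outer product q qᵀ; satisfies the consistency relation exactly."""
    qvec = assignment.vector()
    labels = assignment.labels
    elements = ["H" if l == assignment.anchor else "" for l in labels]
    return ChargeProductMatrix(labels, elements, np.outer(qvec, qvec))


def consistency_defect(q: ChargeProductMatrix | np.ndarray) -> float:
    """max over quadruples |Q_AB Q_CD − Q_AC Q_BD| — zero iff rank-1 consistent."""
    m = q.matrix if isinstance(q, ChargeProductMatrix) else np.asarray(q, float)
    if not np.allclose(m, m.T, rtol=0, atol=0):
        raise ValueError("charge product matrix must be symmetric")
    d = np.einsum("ab,cd->abcd", m, m) - np.einsum("ac,bd->abcd", m, m)
    return float(np.max(np.abs(d)))


def neutralize_charges(charges: dict, species_counts: list[dict]) -> dict:
    """Minimal-norm shift making every molecular species exactly neutral.

    ``species_counts`` holds one {type: count} dict per distinct molecule.
    """
    labels = sorted(charges)
    n = np.array([[cnt.get(l, 0) for l in labels] for cnt in species_counts],
                 dtype=float)
    qv = np.array([charges[l] for l in labels])
    resid = n @ qv
    if np.max(np.abs(resid), initial=0.0) == 0.0:
        return dict(charges)
    shift = n.T @ np.linalg.lstsq(n @ n.T, resid, rcond=None)[0]
    qv = qv - shift
    return {l: float(v) for l, v in zip(labels, qv)}
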