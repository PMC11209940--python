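"""Long-range tail corrections for 1/r⁶ and 1/r⁸ dispersion, barostat
set-point logic, and simple thermodynamic property formulas.

Truncating the dispersion at a cutoff r_c discards attractive interactions;
assuming g(r) = 1 and the undamped −C6/r⁶ − C8/r⁸ form beyond r_c, the
missing energy and pressure are analytic:

    U_tail = −Σ_ab 2π N_a ρ_b [ C6/(3 r_c³) + C8/(5 r_c⁵) ]
    P_tail = −Σ_ab (2π/3) ρ_a ρ_b [ 6 C6/(3 r_c³) + 8 C8/(5 r_c⁵) ]

(double sum over ordered type pairs).  P_tail is negative: a truncated
simulation overestimates the pressure by |P_tail|, so an NPT run that should
land at P_target once the tail is added back must hold its barostat at
P_target + |P_tail|.  MD engines typically correct only the 1/r⁶ term; the
1/r⁸ part — sizeable for these models (32.2 bar at a 1.0 nm cutoff for the
n-butane parameters, 8.7 bar at 1.3 nm) — must be applied manually.  The
homogeneous-fluid assumption fails for slabs, so slab systems refuse
correction outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import canonical_pair
from .units import KB, KCAL_PER_A3_TO_BAR, KCAL_TO_J, TROUTON_DS_VAP

__all__ = ["TailInput", "tail_energy", "tail_pressure", "barostat_setpoint",
           "heat_of_vaporization", "isothermal_compressibility",
           "trouton_boiling_temperature"]


@dataclass
class TailInput:
    """Per-type composition and pair coefficients for a tail correction.

    counts:   atoms per type in the box; volume in Å³ (so ρ = N/V in Å⁻³).
    pairs:    canonical type pair → (C6, C8) in kcal·mol⁻¹·Å⁶/Å⁸.
    r_c:      cutoff in Å;  r_d_max: largest damping distance, for validity.
    """

    counts: dict
    volume: float
    pairs: dict
    r_c: float
    r_d_max: float = 0.0
    slab: bool = False

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("type counts must be non-negative")
        if self.r_c <= 0:
            raise ValueError("cutoff must be positive")
        if self.r_c <= self.r_d_max:
            raise ValueError(
                f"cutoff {self.r_c} Å must exceed the damping distance "
                f"{self.r_d_max} Å for the undamped tail form to hold")

    def _check_homogeneous(self):
        if self.slab:
            raise ValueError(
                "standard tail corrections assume a homogeneous fluid and "
                "are inappropriate for slab/interfacial systems")

    def _coeffs(self, a, b):
        return self.pairs.get(canonical_pair(a, b), (0.0, 0.0))


def tail_energy(inp: TailInput) -> float:
    """Missing dispersion energy beyond the cutoff, kcal/mol per system."""
    inp._check_homogeneous()
    rc = inp.r_c
    u = 0.0
    for a, n_a in inp.counts.items():
        for b, n_b in inp.counts.items():
            c6, c8 = inp._coeffs(a, b)
            u -= 2.0 * math.pi * n_a * (n_b / inp.volume) * (
                c6 / (3.0 * rc**3) + c8 / (5.0 * rc**5))
    return u


def tail_pressure(inp: TailInput) -> float:
    """Missing virial pressure beyond the cutoff, in bar (negative:
    the truncated run overestimates pressure by the magnitude)."""
    inp._check_homogeneous()
    rc = inp.r_c
    p = 0.0
    for a, n_a in inp.counts.items():
        for b, n_b in inp.counts.items():
            c6, c8 = inp._coeffs(a, b)
            p -= (2.0 * math.pi / 3.0) * (n_a / inp.volume) \
                * (n_b / inp.volume) * (6.0 * c6 / (3.0 * rc**3)
                                        + 8.0 * c8 / (5.0 * rc**5))
    return p * KCAL_PER_A3_TO_BAR


def barostat_setpoint(target_pressure: float,
                      tail_correction_magnitude: float) -> float:
    """Pressure the barostat must hold so the corrected system sits at
    ``target_pressure`` (bar): the truncated run is kept high by the
    magnitude of the attractive tail that will be added back."""
    if not (math.isfinite(target_pressure)
            and math.isfinite(tail_correction_magnitude)):
        raise ValueError("pressures must be finite")
    return target_pressure + abs(tail_correction_magnitude)


def heat_of_vaporization(u_gas: float, u_liquid: float, T: float) -> float:
    """ΔH_vap = U_gas − U_liquid + RT (kcal/mol; U per molecule)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return u_gas - u_liquid + KB * T


def isothermal_compressibility(rho1: float, p1: float,
                               rho2: float, p2: float) -> float:
    """κ_T = (1/ρ)(∂ρ/∂P) by centered finite difference, bar⁻¹."""
    if p1 == p2:
        raise ValueError("state points must differ in pressure")
    return 2.0 / (rho1 + rho2) * (rho2 - rho1) / (p2 - p1)


def trouton_boiling_temperature(dh_vap: float) -> float:
    """T_b = ΔH_vap / ΔS_vap with Trouton's ΔS_vap = 85 J/(mol·K)."""
    if dh_vap <= 0:
        raise ValueError("heat of vaporization must be positive")
    return dh_vap * KCAL_TO_J / TROUTON_DS_VAP
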