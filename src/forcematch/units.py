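"""Internal unit system and physical constants.

Everything in the package is expressed in Å, kcal·mol⁻¹, elementary charge,
radians, atomic mass units (g·mol⁻¹) and picoseconds.  Files declare these
units in their headers; external parameters must be converted on import.
"""

#: Coulomb constant, kcal·Å·mol⁻¹·e⁻².
COULOMB_K = 332.06371

#: Boltzmann / gas constant, kcal·mol⁻¹·K⁻¹.
KB = 0.0019872041

#: Pressure conversion: 1 kcal·mol⁻¹·Å⁻³ in bar.
KCAL_PER_A3_TO_BAR = 69476.95

#: Acceleration conversion: (kcal·mol⁻¹·Å⁻¹) / amu → Å·ps⁻².
ACCEL = 418.4

#: 1 kcal in joules (thermochemical calorie).
KCAL_TO_J = 4184.0

#: Trouton's rule vaporization entropy, J·mol⁻¹·K⁻¹.
TROUTON_DS_VAP = 85.0

#: Atomic masses, g·mol⁻¹.
ATOMIC_MASS = {"H": 1.008, "C": 12.011}

#: Pauling electronegativities for the CMD sign-anchor rule.
ELECTRONEGATIVITY = {
    "H": 2.20, "Li": 0.98, "Be": 1.57, "B": 2.04, "C": 2.55, "N": 3.04,
    "O": 3.44, "F": 3.98, "Na": 0.93, "Mg": 1.31, "Al": 1.61, "Si": 1.90,
    "P": 2.19, "S": 2.58, "Cl": 3.16, "K": 0.82, "Ca": 1.00, "Br": 2.96,
    "I": 2.66,
}
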