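# Methods

## Energy expression and conventions

All quantities are in Å, kcal·mol⁻¹, elementary charges, radians, atomic
mass units and picoseconds; the Coulomb constant is 332.06371
kcal·Å·mol⁻¹·e⁻².  Harmonic terms carry **no ½ prefactor**: E = k(x − x_e)².
Parameters imported from files in other conventions must be converted (the
file reader handles kJ/mol, nm and degrees).

Nonbonded pairs are atoms separated by more than two covalent bonds or in
different molecules; 1-4 interactions are not scaled.  Repulsion is
exponential, A·e^(−b·r), which follows the physics of exchange repulsion
more closely than an r⁻¹² power law.  Dispersion uses damped C6 and C8
terms, −C_n/(rⁿ + r_dⁿ), placed only between carbon pairs.  The rational
damping form was chosen because it removes the unphysical short-range
divergence of the bare inverse power, recovers −C_n/rⁿ asymptotically, and
has a single interpretable scale; the parameter file records
`damping: "rational"` so alternative forms can be added without ambiguity.
The damping distance r_d is configured from van der Waals radii and is never
fitted.  A C10 term is deliberately not offered: in practice fitted
higher-order coefficients tend to come out repulsive and destabilize the
model.  Every type pair carries its own (A, b, C6, C8, r_d) — no combining
rules.

When box vectors are present, nonbonded distances use the orthorhombic
minimum-image convention, with an optional sharp cutoff; finite clusters are
evaluated without periodicity.  There is no Ewald summation: all training
references here are finite clusters or modest periodic boxes, and
long-range electrostatics of neutral nonpolar molecules decays fast.

## The linear force-matching system

The fit solves L·p = f_ref, with one row per Cartesian force component of
each training atom and one column per free parameter.  The model force is
exactly linear in: charge products Q_AB (Coulomb), A (repulsion, at fixed
b), C6/C8 (at fixed r_d), the bond composite (bond_k, bond_kre) =
(k_r, k_r·r_e) with dE/dr = 2·bond_k·r − 2·bond_kre, the analogous angle
composite, and the torsion amplitude A_t (at m = 3, φ0 = 0).  After the
solve, r_e = bond_kre / bond_k; a bonded term whose fitted k falls below
1e−8 is dropped with a warning because its equilibrium value is then
undefined.  The repulsion exponent b is *not* linear and is held fixed per
pair at its value in the initial model; this keeps every solve the same
SVD problem and is the reason the whole pipeline needs no nonlinear
optimizer.

Charge neutrality enters as soft constraint rows Σ_B n_B·Q_AB = 0, one per
(atom type, molecular species), weighted by default at 10³ × the median
force-row norm.  Row weighting of the force rows themselves is uniform.

The solver equilibrates columns to unit norm before the SVD and unscales
the solution afterwards.  This matters: exponential-repulsion basis columns
at liquid distances are ~10⁻⁶ while Coulomb columns are ~10¹, and without
equilibration the recovery accuracy is at the mercy of the raw condition
number.  Singular values below rcond = 1e−10 (relative, configurable) are
truncated; the report carries the spectrum, the effective rank, per-row
residuals and per-parameter standard scores derived from the residual
variance and the pseudoinverse covariance.

## Charge matrix decomposition

Fitted independently, charge products violate the consistency relation
Q_AB·Q_CD = Q_AC·Q_BD (exactly satisfied only for two atom types under
neutrality constraints).  CMD restores a physical charge set as the closest
rank-1 approximation of the symmetric product matrix (Eckart–Young): with
λ1 the largest eigenvalue and v its eigenvector, q_A = √λ1·v_A.  The
eigenvector sign is fixed by requiring the anchor type — hydrogen when
present, otherwise the least electronegative element by Pauling scale, ties
broken by label order — to be non-negative.  λ1 ≤ 0 (including exactly
zero, for continuity) yields all-zero charges.  A degenerate top eigenvalue
is resolved toward the eigenvector with the largest anchor weight, with a
warning.  If the CMD charges violate molecular neutrality by more than
1e−6 e, a minimal-norm shift restores exact neutrality and is logged;
externally supplied charges violating the same bound are rejected instead.

The two-pass protocol: pass 1 fits everything with free products; CMD
extracts charges; pass 2 re-solves with the Coulomb contribution fixed at
the derived products to obtain the final non-Coulombic parameters.  For
two-type systems (the cycloalkanes) the passes agree by construction.

## Dispersion fitting

SAPT-style references provide energies, not forces, so the dispersion fit
is energy-based and runs before, and independently of, the force-matching
loop.  Dimers are kept when their nearest-atom distance lies in the
*closed* interval [5, 12] Å: closer in, exchange-dispersion (absent from
the model) is not negligible; the window guarantees correct asymptotics.
One coefficient set per carbon type pair is shared across all source
molecules and fitted jointly (here: n-butane, n-pentane and n-octane
homodimers pooled).  Damping is active during the fit with the production
r_d so coefficients and damping stay self-consistent; beyond 5 Å the
damping correction is tiny.  The fit requires at least twice as many
records as coefficients, and negative fitted coefficients trigger a
stability warning naming the pair.

## Sampling and the adaptive loop

The sampler is BAOAB-split Langevin dynamics, time step 1 fs, inverse
friction constant 2.0 ps, deterministic under a seed.  Thermalization takes
~2 ps (the energy relaxation time is 1/(2γ) = 1 ps); by default the leading
20 % of each trajectory is discarded.  For gas-phase multi-molecule
clusters each molecular centre of mass is tethered harmonically
(k = 2 kcal·mol⁻¹·Å⁻², ≈0.5 Å rattling at room temperature) to its starting
site: the tether stands in for the cage of surrounding liquid the cluster
was carved from, and without it a weakly bound alkane cluster evaporates
within picoseconds of vacuum dynamics.  The tether acts on sampling only —
reference forces never include it.

Each AFM generation samples at 298 and 328 K (100 frames per temperature by
default), obtains reference forces from the oracle — for frames with more
molecules than the cluster size, a 6-molecule cluster (random seed molecule
plus nearest neighbours, minimum-image unwrapped) is carved from every
frame first — and refits with dispersion frozen.  Convergence is declared
when either the refit moves no parameter beyond 1e−6 relative (the
fixed-point case, detectable in the first generation) or consecutive
generations' carbon–carbon RDFs agree within 0.05 in max-abs difference;
the RDF criterion requires a periodic box and the tolerance is a documented
default, chosen here rather than inherited.  The final model comes from one
global fit pooling the training frames of up to the last four generations,
weighted equally.  The reference oracle is a plain callable
`(frames, topology) → frames with forces`, so a real electronic-structure
back-end can be plugged in; only the synthetic mock ships.

## Tail corrections and property helpers

Assuming g(r) = 1 and undamped −C6/r⁶ − C8/r⁸ beyond the cutoff r_c,

    U_tail = −Σ_ab 2π N_a ρ_b [C6/(3 r_c³) + C8/(5 r_c⁵)]
    P_tail = −Σ_ab (2π/3) ρ_a ρ_b [6 C6/(3 r_c³) + 8 C8/(5 r_c⁵)]

summed over ordered type pairs, with 69476.95 bar per kcal·mol⁻¹·Å⁻³.  Both
formulas are verified against direct numerical quadrature of their defining
integrals to better than 1e−8 relative.  P_tail < 0: a truncated run
overestimates pressure by |P_tail|, so the barostat set-point for target P
is P + |P_tail|.  The correction requires r_c to exceed every r_d (so the
undamped form holds) and refuses slab/interfacial systems, where the
homogeneous-fluid assumption fails.  ΔH_vap = U_gas − U_liquid + RT (the RT
term is a documented choice of the standard ideal-vapor form);
κ_T is a centred finite difference of (1/ρ)(∂ρ/∂P); Trouton's rule inverts
ΔH_vap with ΔS_vap = 85 J·mol⁻¹·K⁻¹.

## Synthetic reference data

The generator's defaults are the study conditions.  The ground truth is an
alkane-plausible parameter set: C–C ≈ 1.53 Å and C–C–C ≈ 112° with harmonic
constants of a few hundred kcal·mol⁻¹·Å⁻², threefold torsion amplitudes
≈1.4 kcal·mol⁻¹, pair-distinct exponential repulsion (A ≈ 3–16·10³
kcal·mol⁻¹, b ≈ 3.2–3.65 Å⁻¹), carbon-only dispersion (C6 ≈ 560–600
kcal·mol⁻¹·Å⁶, C8 ≈ 5200–6000 kcal·mol⁻¹·Å⁸, r_d = 3.4 Å) and charges
q_H = +0.06 e with q_C2 = −2q_H, q_C3 = −3q_H, which makes every
CH2/CH3-built alkane exactly neutral and the product matrix exactly rank
one.  Linear species use three types (C3 terminal, C2 secondary, HC);
cyclic species use two.  Idealized geometries are all-anti zigzags, or
puckered regular polygons closed by a short L-BFGS optimization under the
truth model for rings.

Liquid boxes place molecules at the species' measured liquid molar volume
(e.g. 191 Å³ for n-pentane) on a jittered lattice with random orientations,
energy-minimized to remove clashes, then sampled by Langevin dynamics.
Training clusters are carved from those frames.  This matters for
identifiability: the carbon–carbon repulsion prefactors live entirely in
rare close contacts (C–C below ≈4.5 Å), which a condensed ensemble supplies
and a vacuum-relaxed cluster does not.  Dimer sets are extracted from
low-density multi-molecule frames so nearest-atom distances populate the
5–12 Å window.

What the generator does **not** emulate: real electronic-structure forces
(no exchange-dispersion, no many-body polarization, no basis-set artifacts
— the mock shares the model's functional form, so noiseless recovery is
exact by construction and demonstrates the correctness of the fitting
machinery, not the adequacy of the functional form for real references),
NPT barostatting (boxes are fixed at the target density), and nuclear
quantum effects.  Passing recovery tests therefore validates the solver,
the CMD algebra, the sampling and the bookkeeping — not the physics of any
particular reference method.

## Problem sizes and numerical defaults

The bundled studies use 27-molecule liquid boxes, 200 training frames (100
per temperature, 25 fs apart), 6-molecule clusters, 180 pooled homodimers,
and an rcond of 1e−10; the noisy-recovery study adds Gaussian force noise
with σ = 1 % of the RMS reference force.  With these sizes the full
recovery pipeline runs in a few minutes on one CPU core.  Parameter
standard scores in fit reports are asymptotic (residual-variance ×
pseudoinverse covariance) and are diagnostics, not calibrated uncertainties.

## Known limitations

* Orthorhombic boxes only; no Ewald/PME; no barostat — property MD at scale
  is out of scope, only the analytic corrections that post-process it.
* b is never optimized internally; a deliberately wrong b in the initial
  model propagates into the fit (the fitted A partially compensates).
* RDF-based convergence needs a periodic box; box-free runs rely on the
  parameter-drift fixed-point criterion alone.
* The three-body (Axilrod–Teller–Muto) dispersion contribution is not
  modeled.
* Slab systems are refused by the tail corrections rather than treated.
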