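# forcematch

Force-field parameterization for liquid alkanes by **adaptive force matching
(AFM)**: fitting physics-based molecular-mechanics energy expressions to
reference atomic forces, instead of to experimental observables.

The package is written for method developers who want to map a high-level
potential energy surface (in production use: correlated-wavefunction cluster
forces and SAPT dispersion energies) onto a cheap pairwise model, and to test
every stage of that machinery against a known ground truth before any
expensive reference calculation is run.

## The model and the fit

Bonded terms are harmonic bonds and angles (no ½ prefactor) plus a threefold
cosine torsion on heavy atoms:

    E_bond    = k_r (r − r_e)²
    E_angle   = k_θ (θ − θ_e)²
    E_torsion = A_t (1 + cos 3φ)

Nonbonded interactions act between atoms more than two bonds apart or in
different molecules (1-4 pairs at full strength), with *pair-specific*
parameters — no combining rules:

    E_ij = k_e q_i q_j / r + A e^(−b r) − C6/(r⁶ + r_d⁶) − C8/(r⁸ + r_d⁸)

The exponential models exchange repulsion; the damped C6/C8 terms carry
dispersion and exist only between carbon pairs, with the damping distance
`r_d` fixed from van der Waals radii.  All linear parameters are obtained
from the overdetermined system **L·p = f_ref** — one row per Cartesian force
component per training atom — solved by SVD with soft charge-neutrality
constraints.  Three stages make the whole fit linear:

1. **Dispersion first.** C6/C8 are fitted to per-dimer dispersion energies
   (the SAPT E² stand-in) for dimers whose nearest-atom distance lies in
   5–12 Å, jointly across several alkanes, then frozen.
2. **Charge matrix decomposition (CMD).** Coulomb forces are linear in the
   charge *products* Q_AB, which are fitted freely, assembled into a
   symmetric matrix, and collapsed onto atomic charges via the dominant
   eigenpair: q_A = √λ1·v_A, with the sign chosen so hydrogen is positive
   (all charges are zero if no positive eigenvalue exists).  A second solve
   with the Coulomb part fixed yields the remaining parameters.
3. **The adaptive loop.** Sample conformations with the current model
   (BAOAB Langevin dynamics at 298 and 328 K, 100 frames each), obtain
   reference forces from a pluggable oracle, refit, and repeat until the
   carbon–carbon radial distribution functions stop changing; a final
   global fit pools the conformations of up to the last four generations.

Because truncating the r⁻⁸ dispersion at practical cutoffs biases the
pressure appreciably, `forcematch.tails` provides closed-form 1/r⁶ and 1/r⁸
tail corrections to energy and pressure, and the barostat set-point logic
that goes with them, plus small property helpers (heat of vaporization,
isothermal compressibility, Trouton boiling-point estimate).

The `synthetic` module generates every input from a known ground-truth
parameter set — alkane topologies and geometries (n-butane through n-octane,
cyclopentane, cycloheptane), periodic liquid boxes at liquid density,
6-molecule training clusters carved from liquid frames, dimers with mock
dispersion energies, and mock reference forces with optional Gaussian noise
— so the full pipeline is testable by exact parameter recovery.

## Worked example

```python
from forcematch.tails import TailInput, barostat_setpoint, tail_pressure

# the r^-8 tail-pressure overestimate, anchored at 32.2 bar for a 1.0 nm
# cutoff, rescaled to the production 1.3 nm cutoff
r8 = lambda rc: TailInput({"C": 400}, 40000.0, {("C", "C"): (0.0, 5200.0)}, rc)
scale = 32.2 / abs(tail_pressure(r8(10.0)))
over = abs(tail_pressure(r8(13.0))) * scale
print(over)                          # 8.672396193841523
print(barostat_setpoint(1.0, over))  # 9.672396193841523
```

Truncation at 1.3 nm overestimates the pressure by ≈8.7 bar, so an NPT run
targeting 1 bar must hold its barostat at ≈9.7 bar; adding the analytic tail
back lands the corrected system on target.

The same workflow from the shell, for a concrete box of 500 n-butane
molecules with the bundled synthetic parameters (both r⁻⁶ and r⁻⁸ terms):

```sh
$ forcematch tailcorr --ff truth.json --species n-butane --molecules 500 \
      --box 44.3 --cutoff 13.0 --target-pressure 1.0
{"command": "tailcorr", "tail_energy_kcal_mol": -26.30355313489397,
 "tail_pressure_bar": -42.501531353630334,
 "pressure_overestimate_bar": 42.501531353630334,
 "barostat_setpoint_bar": 43.501531353630334}
```

The negative tail pressure says the truncated simulation runs 42.5 bar too
high; the set-point line is the pressure the barostat must hold.

End-to-end parameter recovery — the package's strongest self-check — in a
few lines:

```python
from forcematch import synthetic as syn
from forcematch.design import two_pass_fit
from forcematch.dispersion import filter_dimers, fit_dispersion

truth = syn.default_ground_truth()
dimers = filter_dimers(syn.make_dimer_dataset(
    ["n-butane", "n-pentane", "n-octane"], truth, 60, seed=21))
dispersion, _, _ = fit_dispersion(dimers, truth.ff)
top, clusters, _, _ = syn.make_training_set("n-pentane", truth, seed=9)
frames = syn.mock_reference_forces(clusters[:40], top, truth)
ff, report = two_pass_fit(frames, top, truth.ff, dispersion=dispersion)
print(ff.charge("HC"), ff.charge("C2"))
# 0.059999999999947706 -0.11999999999989006
```

Every fitted parameter (charges, repulsion prefactors, dispersion
coefficients, bonded constants) matches the ground truth to better than
1 part in 10⁶ on noiseless references.

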