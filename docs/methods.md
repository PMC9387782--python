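# Methods

This note records the models implemented, the defaults and why, what the
synthetic generators do and do not emulate, and the numerical choices a
maintainer would otherwise have to reverse-engineer.

## Unit system

Internal units are Å, amu, ps, kcal/mol, elementary charge, Kelvin.
Wherever a dimensionless ratio is needed (the quasi-harmonic α = ħω/k_BT,
the Schlitter determinant argument) energies are converted to the
mechanical unit amu·Å²/ps² (1 kcal/mol = 418.4 amu·Å²/ps², from CODATA
2018 constants). k_B, ħ and the conversion factor live in
`trajthermo.constants` and are unit-tested against SI round-trips; the
Coulomb constant is fixed at the conventional molecular-mechanics value
332.0636 kcal·Å/(mol·e²).

## Superposition and fluctuations

Rigid-body motion is removed with the Kabsch algorithm (SVD of the
cross-covariance, determinant-corrected to the proper-rotation branch).
The fit is computed on a selection (default: protein Cα atoms) and
applied to all atoms. The fit is unweighted by default — matching the
common trajectory-fitting default — with mass weighting available by
flag. The default reference is the first frame of the analysis window,
so the entropy window (final 20% of frames) is fitted to its own start.
"Backbone" RMSD selections (N/CA/C/O) are expressible through the
selection grammar.

RMSF is √⟨|r_i − ⟨r_i⟩|²⟩ per atom, optionally averaged within residues.
It refuses single-frame input and expects a fitted trajectory (an
internal-fit escape hatch exists for convenience).

## Essential dynamics

The positional covariance uses the biased 1/n normalizer — the ensemble
second moment that the entropy formulas assume — with 1/(n−1) available
via `ddof`. Mass weighting multiplies the covariance by √(m_i m_j) per
coordinate pair (units amu·Å²). Eigenvalues are sorted descending;
projections are v·(x−x̄) in the model's weighting, so the sample variance
of projection i equals eigenvalue i identically on the fitting frames.

The free-energy landscape is a Boltzmann inversion of the 2-D projection
histogram, G = −k_BT·ln(P/P_max); empty bins are +∞ (no regularization —
the landscape is descriptive, not a fit).

Selection conventions: apo-protein covariance uses Cα atoms; ligand
covariance uses all ligand atoms; complex covariance uses protein Cα
plus all ligand atoms. This is the only choice under which the entropy
subtraction ΔS = S_complex − S_apo − S_ligand is dimensionally consistent
(dim complex = dim apo + dim ligand), which the classical estimator
asserts explicitly.

## Quasi-harmonic entropy

Three estimators operate on the covariance eigen-spectrum:

* **Quantum QH (default).** Each mass-weighted eigenvalue λ defines
  ω = √(k_BT/λ); the mode entropy is the quantum harmonic-oscillator
  expression in α = ħω/k_BT. This is the standard QH estimator of the
  trajectory-analysis ecosystem.
* **Schlitter.** (k_B/2)·ln det[1 + (k_BTe²/ħ²)C] over the retained
  subspace; an upper bound on the quantum value (property-tested on
  random spectra).
* **Classical Gaussian.** (k_B/2)·ln((2πe)^d det C). Its absolute value
  depends on units; it is flagged non-absolute and only meaningful
  inside ΔS with matching dimensions.

Modes with eigenvalue ≤ `eig_floor` (default 1e-8 amu·Å²) are discarded
and counted: after rigid-body fitting, six near-exactly-zero modes remain
and would contribute spurious divergences. −TΔS is reported at the
analysis temperature (default 300 K) regardless of any thermostat
metadata.

Both the quantum methods refuse non-mass-weighted covariances rather than
silently misinterpreting Å² as amu·Å².

## MM/PBSA interaction energies

Single-trajectory end-state scheme: complex, receptor and ligand
geometries all come from the same complex snapshot, so the bonded term
cancels identically (ΔE_bonded ≡ 0) and the gas-phase term reduces to the
receptor–ligand pair sums. No nonbonded cutoff is applied — systems at
the scale this package targets make the exact double sum affordable, and
cutoffs belong to the MD engine, which is out of scope.

**SASA** is Shrake–Rupley with a golden-spiral point lattice (default
960 points per atom) on spheres of radius (pb_radius + 1.4 Å). The
isolated sphere is exact by construction; two-sphere accuracy is tested
against the spherical-cap closed form (≈0.5% at 960 points).

**Polar solvation** solves ∇·(ε∇φ) = −4πkρ on a uniform cubic grid by
red-black SOR (ω from the standard optimal-relaxation formula).
Dielectric assignment is per grid link: the fraction of the link inside
any atom sphere sets a harmonic (series) average of ε_in and ε_out. The
smoothing matters — a binary in/out assignment makes the Born-ion error
non-monotone under refinement; with it the error falls 3.0% → 0.6% →
0.1% at 1.0/0.5/0.25 Å spacing. Charges spread to the eight neighboring
nodes trilinearly; boundary conditions are (Debye–Hückel screened)
Coulomb values in the exterior dielectric; ionic strength is zero by
default (κ configurable). ΔG_polar is half the charge-weighted potential
difference between the solvated solve and a uniform-ε_in reference solve
on the *identical* grid, so the grid self-energy of the spread charges
cancels exactly.

Known accuracy limitations: the dielectric boundary is the union of atom
spheres (no reentrant/molecular surface), and because the complex and
its isolated parts are solved on differently-sized grids, the binding
ΔG_polar carries a grid-discretization noise floor of a few tenths of a
kcal/mol at 0.5–1.0 Å spacing. Rigid-motion invariance is exact for the
pairwise terms and for translations by whole grid multiples; SASA and PB
values change by discretization-level amounts under arbitrary rotations
(fixed point lattice, fixed grid axes).

**Nonpolar solvation** is γ·SASA + b per species (γ = 0.00542
kcal/(mol·Å²), b = 0.92 kcal/mol); differencing complex − protein −
ligand leaves a net −b in the binding quantity. The per-residue
decomposition gives each receptor residue its full pair sum against the
ligand (so residue vdW/elec partition the totals exactly), the ½qΔφ
per-atom shares of the PB solves, and γ·ΔSASA of its atoms.

Every emitted record enforces the two assembly identities
(ΔG_PBSA = ΔE_vdW + ΔE_elec + ΔG_polar + ΔG_nonpolar and
ΔG_total = ΔG_PBSA + (−TΔS)) at construction time.

## Coordination and hydrogen bonds

g(r) uses shell normalization 4πr²·Δr (the same discretization the
running-integral formula assumes), minimum-image distances when a box is
present, and ρ = partner count / box volume (a reference density must be
supplied for non-periodic ensembles, where ρ is otherwise undefined).
The coordination number integrates 4πr²ρg(r) by the trapezoid rule;
defaults R1 = 0, R2 = 2.7 Å (first/second-shell boundary) with bin width
0.02 Å so the cutoff is bin-aligned. R1 = R2 is treated as a degenerate
interval (n = 0) rather than an error.

Hydrogen bonds use the geometric criterion conventional in MD analysis:
donor–acceptor distance ≤ 3.5 Å and H–D–A angle ≤ 30° (both exposed as
flags); donor hydrogens are resolved by proximity (< 1.2 Å) in the first
frame, and donors without one are skipped with a warning.

## Synthetic generators

All generators are pure functions of (spec, seed).

* `gen_gaussian_ensemble` — i.i.d. multivariate-normal frames with
  prescribed mean/covariance; the generating law's entropy has the
  Gaussian closed form the estimators must recover.
* `gen_rigid_contaminated` — composes each frame with a random rotation
  (uniform over SO(3) by quaternion sampling when the cap is 180°;
  axis-angle otherwise) about the centroid plus a uniform translation.
  Intra-frame geometry is preserved exactly.
* `gen_ideal_gas` — uniform particles in a box around a pinned central
  probe; the g(r) ≡ 1 reference for RDF/coordination.
* `gen_toy_complex` — bead protein (one-bead residues, name CA) plus a
  bead ligand with explicit charges/LJ/PB parameters; optional isotropic
  Gaussian jitter emulates small-amplitude fluctuation about a bound
  pose.

What these do **not** emulate: real dynamics (no integrator, no time
correlation), anharmonicity and multi-well landscapes (so QH estimates
are exact-in-the-limit here but only upper-bound-ish on real data),
explicit solvent, and conformational coupling between receptor and
ligand beyond what jitter provides. A green test therefore establishes
the *estimators* and *assembly arithmetic*, not force-field accuracy on
real complexes — absolute energies from real 100-ns trajectories are
deliberately out of scope.

The bundled three-ligand fixture states its world once: four receptor
beads (charge −0.2 e each), three ligand beads whose charges fall from
(0.8, 0.4, 0.2) to (0.2, 0.1, 0.05) e across the series with the binding
offset growing 3.8 → 4.5 Å, jitter σ = 0.05 Å, and IC₅₀ values 27, 168,
1200 nM spanning the potency range typical of reported inhibitors of the
motivating enzyme target.

## Pipeline conventions

Energies average over the final 10% of frames and entropies over the
final 20% (both fractions configurable), mirroring common end-state
practice of analyzing the equilibrated tail of a production run. When a
ligand has several literature IC₅₀ values, the flagged selected value is
used, with an averaging option. All pipeline outputs are deterministic
given the configuration; reruns are byte-identical. Stage logging echoes
parameters and seeds.

## Numerical edge cases

* Kabsch: < 3 selected atoms or a collinear selection raises a
  degenerate-fit error; mirror-image inputs get the best *proper*
  rotation (det = +1 enforced).
* Covariance of identical frames is the zero matrix; entropy then raises
  "no retained modes" rather than returning −∞.
* PB solves that exceed the iteration cap raise with the final residual;
  zero total charge short-circuits to exactly 0.
* SASA refuses zero-radius atoms in the selection.
* Tables: two-decimal energies, tab-separated, column order fixed by the
  first row; heterogeneous keys are a validation error.
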