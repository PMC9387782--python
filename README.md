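# trajthermo

Thermodynamic analysis of protein–ligand molecular-dynamics ensembles:
rigid-body-fitted fluctuation analysis (RMSD/RMSF), essential-dynamics
PCA, quasi-harmonic configurational entropy (−TΔS), MM/PBSA-style binding
free-energy assembly with per-residue decomposition, RDF-based metal
coordination numbers, and activity–energy correlation.

## Who this is for

Researchers dissecting why structurally different inhibitors of the same
enzyme (the motivating case is the Zn²⁺-dependent histone deacetylase
HDAC2 and its benzamide/hydroxamate inhibitors) bind with different
affinities. End-state binding free energies alone often rank a congeneric
series well but fail across diverse scaffolds; the configurational
entropy change on binding is a large, ligand-dependent correction. This
package implements the full analysis chain on ordinary Cartesian
trajectory ensembles, with synthetic generators of known ground truth so
every stage is testable without any MD engine.

## The model

**Binding free energy (end-state, single trajectory):**

```
ΔG_binding = ΔE_MM + ΔG_solvation − TΔS
ΔE_MM      = ΔE_bonded + ΔE_vdW + ΔE_elec      (ΔE_bonded ≡ 0, single-trajectory scheme)
ΔG_solv    = ΔG_polar + ΔG_nonpolar
ΔG_nonpolar = γ·SASA + b,   γ = 0.00542 kcal/(mol·Å²), b = 0.92 kcal/mol
```

ΔG_polar comes from a finite-difference Poisson solver (interior
dielectric 1, water 80, probe 1.4 Å, solute spheres from per-atom PB
radii); ΔE_vdW/ΔE_elec are exact Lennard-Jones/Coulomb pair sums with
Lorentz–Berthelot combining and k = 332.0636 kcal·Å/(mol·e²).

**Configurational entropy (quasi-harmonic):** after removing rigid-body
motion by Kabsch fitting, the mass-weighted covariance C of the atomic
fluctuations defines effective harmonic modes ω_i = √(k_B T / λ_i). With
α_i = ħω_i/(k_B T),

```
S_QH        = k_B Σ_i [ α_i/(e^{α_i}−1) − ln(1−e^{−α_i}) ]      (quantum QH)
S_Schlitter = (k_B/2) ln det[ 1 + (k_B T e²/ħ²) C ]              (upper bound)
ΔS          = S_complex − S_apo − S_ligand,  reported as −TΔS
```

**Coordination number:** n = ∫_{R1}^{R2} 4πr²ρ g(r) dr with the
first-shell cutoff R2 = 2.7 Å around a designated center (e.g. the
catalytic Zn²⁺).

## Worked example

Generate the bundled synthetic fixture (three toy bead complexes with
decreasing ligand charge and literature-style IC₅₀ values of 27, 168 and
1200 nM) and run the full pipeline:

```
trajthermo simulate --outdir bundle --seed 1
trajthermo report --config bundle/config.yaml
```

or equivalently in Python:

```python
import trajthermo as tt
cfg_path = tt.generate_fixture_bundle("bundle", seed=1, n_frames=60)
cfg = tt.RunConfig.from_yaml(cfg_path)
report = tt.run_pipeline(cfg)
```

which prints (seed 1):

```
LG1: dG_pbsa =    -3.14  -TdS =  -0.66  dG_total =    -3.79 kcal/mol
LG2: dG_pbsa =    -2.36  -TdS =  -0.94  dG_total =    -3.29 kcal/mol
LG3: dG_pbsa =    -1.61  -TdS =  -0.69  dG_total =    -2.30 kcal/mol
pIC50 vs dG_pbsa: r = -0.999
pIC50 vs dG_total: r = -0.986
```

Reading the rows: the most charged ligand (LG1) binds most favourably —
its gas-phase Coulomb attraction is largely, but not fully, paid back by
polar desolvation, the familiar MM/PBSA compensation pattern. The
negative Pearson r says stronger (more negative) computed binding tracks
higher measured potency (larger pIC₅₀). The report directory additionally
contains per-system RMSD/RMSF profiles, PC1/PC2 projections and the
entropy table, all as TSV.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire computation from scratch: it generates the synthetic
bundle for the given seed, executes the full pipeline (fit → RMSF → PCA →
entropy → MM/PBSA → correlation), and re-derives the two solver
benchmarks — the Born-ion polar solvation energy on a 0.25 Å grid against
the closed form −(k/2)(1−1/80)q²/R, and the ideal-gas first-shell
coordination number against (4/3)πR³ρ — printing each quantity next to
its analytic reference before writing the JSON results file.
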