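"""MM/PBSA-style binding energetics and per-residue decomposition.

Single-trajectory end-state scheme: the complex, receptor and ligand
geometries are all extracted from the same complex snapshot, so the bonded
molecular-mechanics term cancels identically and the gas-phase interaction
reduces to the receptor-ligand pairwise van der Waals and Coulomb sums.
Solvation is a continuum term: a finite-difference Poisson polar
contribution (interior dielectric 1, water 80 by default) plus a nonpolar
term linear in the solvent-accessible surface area,
ΔG_nonpolar = γ·SASA + b with γ = 0.00542 kcal/(mol·Å²) and
b = 0.92 kcal/mol (probe radius 1.4 Å).

The assembled record satisfies, by construction,

    ΔG_PBSA  = ΔE_vdW + ΔE_elec + ΔG_polar + ΔG_nonpolar
    ΔG_total = ΔG_PBSA + (−TΔS)

which are exactly the identities a Table-style MM/PBSA report obeys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants, pb
from .model_io import Frame, Selection, Topology, TrajectoryEnsemble, ValidationError
from .qh_entropy import EntropyResult, ThermoParams

__all__ = [
    "SolvationParams",
    "EnergyBreakdown",
    "pair_nonbonded",
    "sasa",
    "nonpolar_solvation",
    "pb_polar_solvation",
    "binding_breakdown",
    "per_residue_decomposition",
    "assemble_total",
]


@dataclass
class SolvationParams:
    """Continuum-solvation settings (defaults mirror a standard PB setup)."""

    eps_in: float = 1.0
    eps_out: float = 80.0
    gamma: float = 0.00542       # kcal/(mol Å²)
    b_const: float = 0.92        # kcal/mol
    probe_radius: float = 1.4    # Å
    grid_spacing: float = 0.5    # Å
    grid_padding: float = 8.0    # Å
    sor_tolerance: float = 1e-6
    max_iterations: int = 20000
    kappa: float = 0.0           # 1/Å, inverse Debye length (0 = pure Poisson)
    n_sasa_points: int = 960

    def __post_init__(self):
        if not (self.eps_out >= self.eps_in >= 1.0):
            raise ValidationError("need eps_out >= eps_in >= 1")
        if self.probe_radius < 0:
            raise ValidationError("probe_radius must be >= 0")
        if self.grid_spacing <= 0:
            raise ValidationError("grid_spacing must be > 0")


@dataclass
class EnergyBreakdown:
    """One MM/PBSA record (kcal/mol); mirrors a binding-energy table row."""

    dE_vdw: float
    dE_elec: float
    dG_polar: float
    dG_nonpolar: float
    dG_pbsa: float
    dE_bonded: float = 0.0       # identically zero in the single-trajectory scheme
    minus_TdS: float | None = None
    dG_total: float | None = None
    per_residue: dict | None = None
    n_snapshots: int = 1

    def __post_init__(self):
        comp = self.dE_vdw + self.dE_elec + self.dG_polar + self.dG_nonpolar
        if abs(self.dG_pbsa - comp) > 1e-9:
            raise ValidationError(
                f"dG_pbsa {self.dG_pbsa} != component sum {comp}"
            )
        if self.minus_TdS is not None and self.dG_total is not None:
            if abs(self.dG_total - (self.dG_pbsa + self.minus_TdS)) > 1e-9:
                raise ValidationError("dG_total != dG_pbsa + minus_TdS")

    def as_row(self) -> dict:
        row = {
            "dE_vdw": self.dE_vdw, "dE_elec": self.dE_elec,
            "dG_polar": self.dG_polar, "dG_nonpolar": self.dG_nonpolar,
            "dG_pbsa": self.dG_pbsa,
            "minus_TdS": self.minus_TdS if self.minus_TdS is not None else float("nan"),
            "dG_total": self.dG_total if self.dG_total is not None else float("nan"),
        }
        return row


# ---------------------------------------------------------------------------
# pairwise non-bonded terms

def pair_nonbonded(frame: Frame, topo: Topology, group_a: Selection,
                   group_b: Selection,
                   coulomb_k: float = constants.COULOMB_K) -> tuple[float, float]:
    """Inter-group van der Waals and Coulomb energies (kcal/mol).

    E_elec = k Σ q_i q_j / r_ij;  E_vdw = Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶]
    with Lorentz-Berthelot combining (arithmetic σ, geometric ε).  No
    cutoff: exact double sum, intended for desk-scale systems.
    """
    ia, ib = group_a.array(), group_b.array()
    if np.intersect1d(ia, ib).size:
        raise ValidationError("pair_nonbonded groups must be disjoint")
    xa, xb = frame.coords[ia], frame.coords[ib]
    diff = xa[:, None, :] - xb[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=2))
    if r.min() < 1e-6:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise ValidationError(
            f"atoms {ia[i]} and {ib[j]} overlap (r = {r[i, j]:.2e} Å)"
        )
    qa, qb = topo.charges[ia], topo.charges[ib]
    e_elec = float(coulomb_k * (np.outer(qa, qb) / r).sum())

    sig = 0.5 * (topo.lj_sigmas[ia][:, None] + topo.lj_sigmas[ib][None, :])
    eps = np.sqrt(np.outer(topo.lj_epsilons[ia], topo.lj_epsilons[ib]))
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(eps > 0, (sig / r) ** 6, 0.0)
    e_vdw = float((4.0 * eps * (sr6 ** 2 - sr6)).sum())
    return e_vdw, e_elec


def _pair_matrix(frame, topo, group_a, group_b, coulomb_k):
    """Per-pair (vdw, elec) matrices for decomposition."""
    ia, ib = group_a.array(), group_b.array()
    xa, xb = frame.coords[ia], frame.coords[ib]
    diff = xa[:, None, :] - xb[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=2))
    qa, qb = topo.charges[ia], topo.charges[ib]
    elec = coulomb_k * np.outer(qa, qb) / r
    sig = 0.5 * (topo.lj_sigmas[ia][:, None] + topo.lj_sigmas[ib][None, :])
    eps = np.sqrt(np.outer(topo.lj_epsilons[ia], topo.lj_epsilons[ib]))
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(eps > 0, (sig / r) ** 6, 0.0)
    vdw = 4.0 * eps * (sr6 ** 2 - sr6)
    return vdw, elec


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0 ** 0.5) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(frame: Frame, topo: Topology, sel: Selection,
         params: SolvationParams | None = None) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area, Å².

    Per selected atom: the fraction of quasi-uniform sphere points at
    radius (pb_radius + probe) not buried inside any neighbor's expanded
    sphere, times the expanded-sphere area.  Returns (per-atom, total).
    """
    params = params or SolvationParams()
    idx = sel.array()
    radii = topo.pb_radii[idx]
    if np.any(radii <= 0):
        bad = idx[np.where(radii <= 0)[0][0]]
        raise ValidationError(f"atom index {bad} has non-positive pb_radius")
    coords = frame.coords[idx]
    expanded = radii + params.probe_radius
    unit = _fibonacci_sphere(params.n_sasa_points)

    n = idx.size
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        exposed = np.ones(params.n_sasa_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            dij = np.linalg.norm(coords[i] - coords[j])
            if dij >= expanded[i] + expanded[j]:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > expanded[j] ** 2
        areas[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas, float(areas.sum())


def nonpolar_solvation(sasa_total: float,
                       params: SolvationParams | None = None) -> float:
    """ΔG_nonpolar = γ·SASA + b (kcal/mol)."""
    params = params or SolvationParams()
    if sasa_total < 0:
        raise ValidationError("SASA must be >= 0")
    return params.gamma * sasa_total + params.b_const


# ---------------------------------------------------------------------------
# polar solvation via the finite-difference Poisson solver

def pb_polar_solvation(frame: Frame, topo: Topology, sel: Selection,
                       params: SolvationParams | None = None) -> float:
    """ΔG_polar (kcal/mol) of the selected atoms in continuum solvent."""
    params = params or SolvationParams()
    idx = sel.array()
    return pb.polar_solvation_energy(
        frame.coords[idx], topo.charges[idx], topo.pb_radii[idx],
        eps_in=params.eps_in, eps_out=params.eps_out,
        spacing=params.grid_spacing, padding=params.grid_padding,
        kappa=params.kappa, tol=params.sor_tolerance,
        max_iter=params.max_iterations,
    )


def _pb_per_atom(frame, topo, sel, params):
    idx = sel.array()
    return pb.polar_solvation_per_atom(
        frame.coords[idx], topo.charges[idx], topo.pb_radii[idx],
        eps_in=params.eps_in, eps_out=params.eps_out,
        spacing=params.grid_spacing, padding=params.grid_padding,
        kappa=params.kappa, tol=params.sor_tolerance,
        max_iter=params.max_iterations,
    )


# ---------------------------------------------------------------------------
# snapshot-averaged binding breakdown

def _window_frames(traj: TrajectoryEnsemble, window):
    if window is None:
        return traj.frames
    frames = traj.frames[window[0]:window[1]]
    if not frames:
        raise ValidationError(f"empty frame window {window}")
    return frames


def binding_breakdown(traj: TrajectoryEnsemble, protein_sel: Selection,
                      ligand_sel: Selection,
                      params: SolvationParams | None = None,
                      thermo: ThermoParams | None = None,
                      window=None, include_polar: bool = True) -> EnergyBreakdown:
    """Snapshot-averaged single-trajectory MM/PBSA breakdown.

    Per snapshot: receptor-ligand pairwise vdW/Coulomb; ΔG_polar =
    PB(complex) − PB(protein) − PB(ligand) on geometries cut from the same
    frame; ΔG_nonpolar from the SASA difference (the b constant enters
    once per species, leaving a net −b).  Terms are averaged over the
    window frames.
    """
    params = params or SolvationParams()
    thermo = thermo or ThermoParams()
    if np.intersect1d(protein_sel.array(), ligand_sel.array()).size:
        raise ValidationError("protein and ligand selections must be disjoint")
    frames = _window_frames(traj, window)
    topo = traj.topology
    both = Selection(tuple(sorted(set(protein_sel.indices) | set(ligand_sel.indices))),
                     "complex")

    vdw_l, elec_l, polar_l, nonpolar_l = [], [], [], []
    for f in frames:
        ev, ee = pair_nonbonded(f, topo, protein_sel, ligand_sel,
                                thermo.coulomb_k)
        vdw_l.append(ev)
        elec_l.append(ee)
        _, sasa_c = sasa(f, topo, both, params)
        _, sasa_p = sasa(f, topo, protein_sel, params)
        _, sasa_lg = sasa(f, topo, ligand_sel, params)
        np_c = nonpolar_solvation(sasa_c, params)
        np_p = nonpolar_solvation(sasa_p, params)
        np_l = nonpolar_solvation(sasa_lg, params)
        nonpolar_l.append(np_c - np_p - np_l)
        if include_polar:
            g_c = pb_polar_solvation(f, topo, both, params)
            g_p = pb_polar_solvation(f, topo, protein_sel, params)
            g_l = pb_polar_solvation(f, topo, ligand_sel, params)
            polar_l.append(g_c - g_p - g_l)
        else:
            polar_l.append(0.0)

    dE_vdw = float(np.mean(vdw_l))
    dE_elec = float(np.mean(elec_l))
    dG_polar = float(np.mean(polar_l))
    dG_nonpolar = float(np.mean(nonpolar_l))
    return EnergyBreakdown(
        dE_vdw=dE_vdw, dE_elec=dE_elec, dG_polar=dG_polar,
        dG_nonpolar=dG_nonpolar,
        dG_pbsa=dE_vdw + dE_elec + dG_polar + dG_nonpolar,
        n_snapshots=len(frames),
    )


def per_residue_decomposition(traj: TrajectoryEnsemble, protein_sel: Selection,
                              ligand_sel: Selection,
                              params: SolvationParams | None = None,
                              thermo: ThermoParams | None = None,
                              window=None, include_polar: bool = True) -> dict:
    """Per-residue (vdw, elec, polar, nonpolar) contributions, kcal/mol.

    vdW/Coulomb of residue R: the pairwise sums restricted to R's atoms
    against the ligand (so residue terms partition the totals exactly).
    Polar: each atom's ½·q·Δφ share of the complex-vs-parts PB solves.
    Nonpolar: γ times the SASA change attributable to R's atoms.  Ligand
    atoms are reported under their own residue key.
    """
    params = params or SolvationParams()
    thermo = thermo or ThermoParams()
    frames = _window_frames(traj, window)
    topo = traj.topology
    ip, il = protein_sel.array(), ligand_sel.array()
    both = Selection(tuple(sorted(set(protein_sel.indices) | set(ligand_sel.indices))),
                     "complex")
    ib = both.array()
    pos_in_both = {int(a): k for k, a in enumerate(ib)}

    keys = {}
    for a in np.concatenate([ip, il]):
        keys[int(a)] = topo.residue_of_atom(int(a)).key
    acc = {k: np.zeros(4) for k in set(keys.values())}

    for f in frames:
        vdw_m, elec_m = _pair_matrix(f, topo, protein_sel, ligand_sel,
                                     thermo.coulomb_k)
        # each protein residue takes its full pair sum against the ligand,
        # so protein-residue vdw/elec partition the totals exactly; the
        # ligand's own residue row carries only solvation shares
        for r, a in enumerate(ip):
            acc[keys[int(a)]][0] += vdw_m[r].sum()
            acc[keys[int(a)]][1] += elec_m[r].sum()

        per_c, sasa_c = sasa(f, topo, both, params)
        per_p, _ = sasa(f, topo, protein_sel, params)
        per_l, _ = sasa(f, topo, ligand_sel, params)
        dsasa = np.zeros(ib.size)
        for k, a in enumerate(ip):
            dsasa[pos_in_both[int(a)]] -= per_p[k]
        for k, a in enumerate(il):
            dsasa[pos_in_both[int(a)]] -= per_l[k]
        dsasa += per_c
        for k, a in enumerate(ib):
            acc[keys[int(a)]][3] += params.gamma * dsasa[k]

        if include_polar:
            pa_c = _pb_per_atom(f, topo, both, params)
            pa_p = _pb_per_atom(f, topo, protein_sel, params)
            pa_l = _pb_per_atom(f, topo, ligand_sel, params)
            dpol = pa_c.copy()
            for k, a in enumerate(ip):
                dpol[pos_in_both[int(a)]] -= pa_p[k]
            for k, a in enumerate(il):
                dpol[pos_in_both[int(a)]] -= pa_l[k]
            for k, a in enumerate(ib):
                acc[keys[int(a)]][2] += dpol[k]

    nf = len(frames)
    out = {}
    for key, v in acc.items():
        v = v / nf
        out[key] = {"vdw": float(v[0]), "elec": float(v[1]),
                    "polar": float(v[2]), "nonpolar": float(v[3])}
    return out


def assemble_total(breakdown: EnergyBreakdown,
                   entropy: EntropyResult) -> EnergyBreakdown:
    """Fold −TΔS into the breakdown: ΔG_total = ΔG_PBSA + (−TΔS)."""
    if entropy.minus_T_dS is None:
        raise ValidationError(
            "entropy result carries no minus_T_dS (is it a ΔS record?)"
        )
    return EnergyBreakdown(
        dE_vdw=breakdown.dE_vdw, dE_elec=breakdown.dE_elec,
        dG_polar=breakdown.dG_polar, dG_nonpolar=breakdown.dG_nonpolar,
        dG_pbsa=breakdown.dG_pbsa,
        minus_TdS=entropy.minus_T_dS,
        dG_total=breakdown.dG_pbsa + entropy.minus_T_dS,
        per_residue=breakdown.per_residue,
        n_snapshots=breakdown.n_snapshots,
    )
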