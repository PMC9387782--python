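"""Radial distribution functions, running coordination numbers, distance
series and geometric hydrogen-bond detection.

The coordination number around a designated center (typically a catalytic
metal ion such as Zn²⁺) is the first-shell integral of the radial
distribution function,

    n = ∫_{R1}^{R2} 4π r² ρ g(r) dr,

with R1 = 0 and R2 = 2.7 Å by default — the cutoff separating the first
and second coordination shells.  ρ is the partner number density in the
bulk phase (partner count over box volume for periodic frames).

Hydrogen bonds use the geometric donor-acceptor-distance plus
hydrogen-donor-acceptor-angle criterion conventional in MD analysis
(3.5 Å and 30° by default); donor hydrogens are resolved by proximity
(< 1.2 Å) in the first frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_io import Selection, TrajectoryEnsemble, ValidationError

__all__ = ["RDFProfile", "CoordinationResult", "HBond", "rdf",
           "coordination_number", "distance_series", "hbond_detect"]

DEFAULT_SHELL_CUTOFF = 2.7   # Å; boundary between first and second shells
DEFAULT_BIN_WIDTH = 0.02     # Å; aligns the 2.7 Å boundary with a bin edge


@dataclass
class RDFProfile:
    r_centers: np.ndarray     # Å, strictly increasing bin centers
    g_of_r: np.ndarray        # dimensionless
    rho: float                # partner number density, Å⁻³
    bin_width: float
    n_frames: int


@dataclass
class CoordinationResult:
    n: float
    R1: float
    R2: float


def _min_image(diff: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return diff
    return diff - box * np.round(diff / box)


def rdf(traj: TrajectoryEnsemble, center_sel: Selection,
        partner_sel: Selection, bin_width: float = DEFAULT_BIN_WIDTH,
        r_max: float = 6.0, rho: float | None = None) -> RDFProfile:
    """g(r) of partner atoms around a single center atom.

    Distances use the minimum-image convention when frames carry a box.
    The density ρ defaults to partner count over box volume; for
    non-periodic ensembles a reference density must be supplied.
    """
    if len(center_sel) != 1:
        raise ValidationError("center selection must contain exactly one atom")
    center = center_sel.indices[0]
    partners = np.array([i for i in partner_sel.indices if i != center])
    if partners.size == 0:
        raise ValidationError("partner selection is empty after excluding center")
    if bin_width <= 0 or r_max <= 0:
        raise ValidationError("bin_width and r_max must be positive")

    box = traj.frames[0].box
    if box is not None and r_max > box.min() / 2.0:
        raise ValidationError(
            f"r_max {r_max} Å exceeds half the smallest box length "
            f"({box.min() / 2.0:.2f} Å)"
        )
    if rho is None:
        if box is None:
            raise ValidationError(
                "non-periodic ensemble: supply a reference density rho"
            )
        rho = partners.size / float(np.prod(box))

    n_bins = int(np.ceil(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for f in traj.frames:
        diff = _min_image(f.coords[partners] - f.coords[center], f.box)
        r = np.sqrt((diff ** 2).sum(axis=1))
        h, _ = np.histogram(r, bins=edges)
        counts += h
    centers = edges[:-1] + bin_width / 2.0
    shell = 4.0 * np.pi * centers ** 2 * bin_width
    g = counts / (traj.n_frames * shell * rho)
    return RDFProfile(r_centers=centers, g_of_r=g, rho=float(rho),
                      bin_width=bin_width, n_frames=traj.n_frames)


def coordination_number(profile: RDFProfile, R1: float = 0.0,
                        R2: float = DEFAULT_SHELL_CUTOFF) -> CoordinationResult:
    """Trapezoidal first-shell integral n = ∫ 4πr²ρ g(r) dr over [R1, R2]."""
    if R2 < R1:
        raise ValidationError(f"need R2 >= R1, got [{R1}, {R2}]")
    if R1 < 0:
        raise ValidationError("R1 must be >= 0")
    if R2 == R1:
        return CoordinationResult(n=0.0, R1=R1, R2=R2)
    r_hi = profile.r_centers[-1] + profile.bin_width / 2.0
    if R2 > r_hi + 1e-12:
        raise ValidationError(
            f"R2 = {R2} Å beyond profile range ({r_hi:.2f} Å)"
        )
    mask = (profile.r_centers >= R1) & (profile.r_centers <= R2)
    r = profile.r_centers[mask]
    if r.size < 2:
        return CoordinationResult(n=0.0, R1=R1, R2=R2)
    integrand = 4.0 * np.pi * r ** 2 * profile.rho * profile.g_of_r[mask]
    n = float(np.trapezoid(integrand, r))
    return CoordinationResult(n=n, R1=R1, R2=R2)


def distance_series(traj: TrajectoryEnsemble, atom_a: int, atom_b: int):
    """Per-frame distance between two atoms plus (mean, sd), Å."""
    if atom_a == atom_b:
        raise ValidationError("atom_a and atom_b must differ")
    n = traj.n_atoms
    if not (0 <= atom_a < n and 0 <= atom_b < n):
        raise ValidationError("atom index out of range")
    d = []
    for f in traj.frames:
        diff = _min_image(f.coords[atom_b] - f.coords[atom_a], f.box)
        d.append(float(np.linalg.norm(diff)))
    d = np.array(d)
    return d, float(d.mean()), float(d.std())


@dataclass
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    mean_distance: float      # donor-acceptor, Å, over counted frames
    mean_angle: float         # H-D-A, degrees, over counted frames
    occupancy: float          # fraction of frames satisfying both criteria


def _resolve_hydrogens(traj, donors):
    """Hydrogen atoms within 1.2 Å of each donor heavy atom (frame 0)."""
    f0 = traj.frames[0]
    h_idx = [i for i, a in enumerate(traj.topology.atoms)
             if a.element.upper() == "H"]
    mapping = {}
    for d in donors.indices:
        near = []
        for h in h_idx:
            if np.linalg.norm(f0.coords[h] - f0.coords[d]) < 1.2:
                near.append(h)
        if near:
            mapping[d] = near
        else:
            warnings.warn(
                f"donor atom {d} has no hydrogen within 1.2 Å; skipped",
                stacklevel=2,
            )
    return mapping


def hbond_detect(traj: TrajectoryEnsemble, donors: Selection,
                 acceptors: Selection, d_cut: float = 3.5,
                 angle_cut: float = 30.0) -> list[HBond]:
    """Geometric hydrogen-bond detection with per-frame occupancy.

    A frame counts when donor-acceptor distance ≤ d_cut and the
    hydrogen-donor-acceptor angle ≤ angle_cut.  Donors without a
    resolvable hydrogen are skipped with a warning.  Bonds with zero
    occupancy are not reported.
    """
    dh = _resolve_hydrogens(traj, donors)
    out = []
    for d, hs in dh.items():
        for acc in acceptors.indices:
            if acc == d or acc in hs:
                continue
            for h in hs:
                hits, dists, angles = 0, [], []
                for f in traj.frames:
                    v_da = f.coords[acc] - f.coords[d]
                    r_da = np.linalg.norm(v_da)
                    if r_da > d_cut:
                        continue
                    v_dh = f.coords[h] - f.coords[d]
                    cosang = np.dot(v_dh, v_da) / (
                        np.linalg.norm(v_dh) * r_da)
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                    if ang <= angle_cut:
                        hits += 1
                        dists.append(r_da)
                        angles.append(ang)
                if hits:
                    out.append(HBond(
                        donor=d, hydrogen=h, acceptor=int(acc),
                        mean_distance=float(np.mean(dists)),
                        mean_angle=float(np.mean(angles)),
                        occupancy=hits / traj.n_frames,
                    ))
    return out
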