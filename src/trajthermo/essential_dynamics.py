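"""Essential dynamics: positional covariance, principal modes, projections.

The covariance matrix of the Cartesian fluctuations of a selection (after
rigid-body fitting) is diagonalized; eigenvectors are the collective modes
and eigenvalues their mean-square amplitudes.  Projections of the
trajectory onto the two leading modes give the familiar PC1/PC2 plane, and
Boltzmann inversion of its occupancy histogram gives a free-energy
landscape G = -k_B·T·ln(P/P_max).

Covariance uses the biased 1/n normalizer by default (the ensemble second
moment assumed by the quasi-harmonic entropy formulas); pass ``ddof=1``
for the unbiased estimator.  Mass weighting multiplies the covariance by
sqrt(m_i·m_j) per coordinate pair, giving amu·Å² units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .model_io import Selection, TrajectoryEnsemble, ValidationError
from .superposition import fit_trajectory

__all__ = ["CovarianceModel", "ProjectionSet", "LandscapeGrid",
           "covariance_model", "project", "free_energy_landscape"]


@dataclass
class CovarianceModel:
    selection: Selection
    mean_coords: np.ndarray       # 3K, Å (unweighted Cartesian mean)
    covariance: np.ndarray        # 3K x 3K, Å² (amu·Å² if mass-weighted)
    mass_weighted: bool
    eigenvalues: np.ndarray       # descending
    eigenvectors: np.ndarray      # orthonormal columns, matching order
    n_frames_used: int
    masses: np.ndarray | None = None   # per selected atom, amu

    @property
    def n_coords(self) -> int:
        return self.mean_coords.size


def covariance_model(traj: TrajectoryEnsemble, sel: Selection,
                     mass_weighted: bool = False,
                     window: tuple[int, int | None] | None = None,
                     fit: bool = True, ddof: int = 0) -> CovarianceModel:
    """Covariance of the selected coordinates over a frame window.

    Rigid-body motion is removed by fitting every window frame onto the
    window's first frame over ``sel`` (disable with ``fit=False`` for
    ensembles generated without rigid contamination).
    """
    if window is not None:
        traj = traj.window(*window)
    if traj.n_frames < 2:
        raise ValidationError("covariance needs at least 2 frames")
    if fit:
        traj = fit_trajectory(traj, sel)
    idx = sel.array()
    x = traj.coordinate_array()[:, idx, :].reshape(traj.n_frames, -1)
    mean = x.mean(axis=0)
    dev = x - mean
    denom = traj.n_frames - ddof
    cov = dev.T @ dev / denom

    masses = None
    if mass_weighted:
        masses = traj.topology.masses[idx]
        if np.any(~np.isfinite(masses)) or np.any(masses <= 0):
            raise ValidationError("mass-weighted covariance needs positive masses")
        sqrt_m = np.sqrt(np.repeat(masses, 3))
        cov = cov * np.outer(sqrt_m, sqrt_m)

    cov = 0.5 * (cov + cov.T)   # enforce exact symmetry
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return CovarianceModel(
        selection=sel, mean_coords=mean, covariance=cov,
        mass_weighted=mass_weighted, eigenvalues=evals[order],
        eigenvectors=evecs[:, order], n_frames_used=traj.n_frames,
        masses=masses,
    )


@dataclass
class ProjectionSet:
    components: tuple            # eigenvector indices (0-based)
    values: np.ndarray           # n_frames x n_components
    mass_weighted: bool


def project(traj: TrajectoryEnsemble, model: CovarianceModel,
            components=(0, 1), fit: bool = True) -> ProjectionSet:
    """Project frames onto the chosen principal modes.

    value[f, c] = v_c · (x_f - mean) in the model's weighting (the
    deviation is multiplied by sqrt(mass) per coordinate when the model is
    mass-weighted, so projections carry Å·amu^1/2).
    """
    components = tuple(int(c) for c in components)
    d = model.n_coords
    for c in components:
        if c < 0 or c >= d:
            raise ValidationError(f"component index {c} out of range (3K={d})")
    if fit:
        traj = fit_trajectory(traj, model.selection)
    idx = model.selection.array()
    if idx[-1] >= traj.n_atoms:
        raise ValidationError("model selection does not fit trajectory")
    x = traj.coordinate_array()[:, idx, :].reshape(traj.n_frames, -1)
    dev = x - model.mean_coords
    if model.mass_weighted:
        dev = dev * np.sqrt(np.repeat(model.masses, 3))
    vals = dev @ model.eigenvectors[:, list(components)]
    return ProjectionSet(components=components, values=vals,
                         mass_weighted=model.mass_weighted)


@dataclass
class LandscapeGrid:
    axes: tuple                  # two bin-edge arrays
    probability: np.ndarray      # sums to 1
    free_energy: np.ndarray      # kcal/mol; +inf on unoccupied bins
    temperature: float


def free_energy_landscape(proj: ProjectionSet, T: float = constants.DEFAULT_TEMPERATURE,
                          n_bins: int = 32) -> LandscapeGrid:
    """Boltzmann inversion of the 2-D projection histogram.

    G(bin) = -k_B·T·ln(P/P_max); the most occupied bin sits at G = 0 and
    empty bins are reported as +inf.
    """
    if proj.values.ndim != 2 or proj.values.shape[1] != 2:
        raise ValidationError("landscape needs exactly 2 projection components")
    if proj.values.shape[0] < 1:
        raise ValidationError("landscape needs at least one frame")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    hist, xe, ye = np.histogram2d(proj.values[:, 0], proj.values[:, 1],
                                  bins=n_bins)
    prob = hist / hist.sum()
    with np.errstate(divide="ignore"):
        g = -constants.K_B_KCAL * T * np.log(prob / prob.max())
    g[prob == 0] = np.inf
    return LandscapeGrid(axes=(xe, ye), probability=prob, free_energy=g,
                         temperature=float(T))
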