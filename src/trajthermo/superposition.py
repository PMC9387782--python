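"""Rigid-body superposition (Kabsch) and RMSD/RMSF profiles.

Fitting removes overall rotation and translation so that the remaining
coordinate variance reflects internal motion only.  The optimal proper
rotation is obtained from the SVD of the cross-covariance of the selected
atoms (the Kabsch algorithm); the fit is unweighted by default, with an
optional mass-weighted variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import (
    Frame,
    Selection,
    TrajectoryEnsemble,
    ValidationError,
)

__all__ = ["FitResult", "kabsch_fit", "fit_trajectory", "rmsd_series",
           "rmsf_profile", "DegenerateFitError"]


class DegenerateFitError(ValidationError):
    """Fewer than three selected atoms, or a collinear selection."""


@dataclass(frozen=True)
class FitResult:
    rotation: np.ndarray      # 3x3 proper orthonormal
    translation: np.ndarray   # applied after rotation, Å
    rmsd: float               # post-fit RMSD over the fit selection, Å


def _check_selection_geometry(x: np.ndarray):
    if x.shape[0] < 3:
        raise DegenerateFitError(
            f"rigid fit needs >= 3 selected atoms, got {x.shape[0]}"
        )
    centered = x - x.mean(axis=0)
    # rank < 2 means all points lie on a line (or coincide)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError("selected atoms are collinear; fit is degenerate")


def _kabsch_rotation(mobile_c: np.ndarray, ref_c: np.ndarray,
                     weights: np.ndarray | None = None) -> np.ndarray:
    """Optimal proper rotation mapping centered mobile onto centered ref."""
    if weights is None:
        h = mobile_c.T @ ref_c
    else:
        h = (mobile_c * weights[:, None]).T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    # force det=+1: proper rotation branch even for reflection-related inputs
    flip = np.diag([1.0, 1.0, d])
    return (u @ flip @ vt).T


def kabsch_fit(mobile: Frame, reference: Frame, sel: Selection,
               weights: np.ndarray | None = None) -> tuple[FitResult, Frame]:
    """Least-squares fit of ``mobile`` onto ``reference`` over ``sel``.

    The rotation/translation minimizing the selected-atom RMSD is computed
    on ``sel`` and applied to **all** atoms of the mobile frame.  Returns
    the fit summary and the transformed frame.
    """
    idx = sel.array()
    if idx[-1] >= mobile.n_atoms or idx[-1] >= reference.n_atoms:
        raise ValidationError("selection index out of range for frame")
    xm = mobile.coords[idx]
    xr = reference.coords[idx]
    _check_selection_geometry(xm)
    _check_selection_geometry(xr)

    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        w = weights / weights.sum()
        cm = (xm * w[:, None]).sum(axis=0)
        cr = (xr * w[:, None]).sum(axis=0)
    else:
        w = None
        cm = xm.mean(axis=0)
        cr = xr.mean(axis=0)

    rot = _kabsch_rotation(xm - cm, xr - cr, weights)
    translation = cr - rot @ cm

    new_coords = mobile.coords @ rot.T + translation
    diff = new_coords[idx] - xr
    if w is not None:
        rmsd = float(np.sqrt((w[:, None] * diff ** 2).sum()))
    else:
        rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    fitted = Frame(new_coords, mobile.box, mobile.time)
    return FitResult(rotation=rot, translation=translation, rmsd=rmsd), fitted


def fit_trajectory(traj: TrajectoryEnsemble, sel: Selection,
                   reference: Frame | None = None,
                   mass_weighted: bool = False) -> TrajectoryEnsemble:
    """Fit every frame onto the reference (default: first frame)."""
    ref = reference if reference is not None else traj.frames[0]
    weights = None
    if mass_weighted:
        weights = traj.topology.masses[sel.array()]
    fitted = [kabsch_fit(f, ref, sel, weights)[1] for f in traj.frames]
    return TrajectoryEnsemble(traj.topology, fitted)


def rmsd_series(traj: TrajectoryEnsemble, reference: Frame | None = None,
                sel: Selection | None = None) -> np.ndarray:
    """Post-fit RMSD of every frame against the reference over ``sel``."""
    ref = reference if reference is not None else traj.frames[0]
    if sel is None:
        sel = Selection(tuple(range(traj.n_atoms)), "all")
    return np.array([kabsch_fit(f, ref, sel)[0].rmsd for f in traj.frames])


def rmsf_profile(traj: TrajectoryEnsemble, sel: Selection,
                 group_by_residue: bool = False,
                 assume_fitted: bool = True):
    """Root-mean-square fluctuation of each selected atom about its mean.

    RMSF_i = sqrt(<|r_i - <r_i>|^2>) over frames.  The trajectory is
    expected to be rigid-body fitted already; pass ``assume_fitted=False``
    to have the fit applied internally first.

    Returns an array per selected atom, or a dict keyed by residue when
    ``group_by_residue`` (averaging atomic RMSF within each residue).
    """
    if traj.n_frames < 2:
        raise ValidationError("RMSF undefined for a single frame")
    if not assume_fitted:
        traj = fit_trajectory(traj, sel)
    idx = sel.array()
    x = traj.coordinate_array()[:, idx, :]
    mean = x.mean(axis=0)
    rmsf = np.sqrt(((x - mean) ** 2).sum(axis=2).mean(axis=0))
    if not group_by_residue:
        return rmsf
    out: dict = {}
    topo = traj.topology
    for a_local, a_global in enumerate(idx):
        key = topo.residue_of_atom(int(a_global)).key
        out.setdefault(key, []).append(rmsf[a_local])
    return {k: float(np.mean(v)) for k, v in out.items()}
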