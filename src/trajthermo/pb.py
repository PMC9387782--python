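"""Finite-difference Poisson(-Boltzmann) solver for polar solvation energies.

The linearized PB equation at zero ionic strength reduces to the variable-
coefficient Poisson equation ∇·(ε∇φ) = -4π·k·ρ, discretized on a uniform
cubic grid and solved by red-black successive over-relaxation (SOR).  With
distances in Å, charges in e and the Coulomb constant k in
kcal·Å/(mol·e²), the potential φ carries kcal/(mol·e).

Dielectric model: a hard sphere per atom — ε = eps_in at any face midpoint
inside an atom's PB radius, eps_out elsewhere (no reentrant/molecular
surface).  Charges are spread to the eight surrounding nodes by trilinear
weighting.  Dirichlet boundary values come from the (Debye-Hückel screened)
Coulomb potential in the exterior dielectric.

The polar solvation energy is computed as a difference of two solves on
the identical grid — one with the solvent dielectric, one with
ε = eps_in everywhere — so the grid self-energy of the spread charges
cancels:

    ΔG_polar = ½ Σ_i q_i [φ_solvated(r_i) - φ_reference(r_i)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants
from .model_io import ValidationError

__all__ = ["PBGridResult", "solve_grid", "polar_solvation_energy",
           "PBConvergenceError"]


class PBConvergenceError(RuntimeError):
    """SOR failed to reach the requested residual within the iteration cap."""


@dataclass
class PBGridResult:
    phi: np.ndarray           # node potentials, kcal/(mol e)
    origin: np.ndarray        # Å
    spacing: float            # Å
    iterations: int
    residual: float           # final relative residual


def _build_grid(coords: np.ndarray, radii: np.ndarray, spacing: float,
                padding: float):
    lo = (coords - radii[:, None]).min(axis=0) - padding
    hi = (coords + radii[:, None]).max(axis=0) + padding
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    # symmetric extension so the box is an exact multiple of the spacing
    extra = (n - 1) * spacing - (hi - lo)
    origin = lo - extra / 2.0
    return origin, n


def _dielectric_faces(origin, n, spacing, coords, radii, eps_in, eps_out):
    """Face-centered dielectric maps for x-, y-, z-oriented grid links.

    Each link's dielectric is the harmonic average of eps_in/eps_out
    weighted by the fraction of the link inside any atom sphere (series
    dielectrics along the field direction).  The smoothing removes the
    raggedness of a binary in/out assignment and restores monotone
    convergence under grid refinement.
    """
    axes = [origin[d] + spacing * np.arange(n[d]) for d in range(3)]
    eps = []
    for d in range(3):
        shape = [n[0], n[1], n[2]]
        shape[d] -= 1
        frac = np.zeros(shape)   # inside-fraction of each link, max over atoms
        perp = [k for k in range(3) if k != d]
        starts = axes[d][:-1]    # link start coordinate along axis d
        for c, r in zip(coords, radii):
            if r <= 0:
                continue
            p1 = axes[perp[0]] - c[perp[0]]
            p2 = axes[perp[1]] - c[perp[1]]
            rho2 = p1[:, None] ** 2 + p2[None, :] ** 2
            inside = rho2 < r * r
            if not inside.any():
                continue
            s = np.sqrt(np.maximum(r * r - rho2, 0.0))    # chord half-length
            lo = c[d] - s
            hi = c[d] + s
            # overlap of [lo,hi] with each link [x0, x0+h]
            x0 = starts.reshape([-1 if k == d else 1 for k in range(3)])
            lo_b = lo[None, :, :] if d == 0 else (lo[:, None, :] if d == 1 else lo[:, :, None])
            hi_b = hi[None, :, :] if d == 0 else (hi[:, None, :] if d == 1 else hi[:, :, None])
            ov = np.clip(np.minimum(hi_b, x0 + spacing) - np.maximum(lo_b, x0),
                         0.0, spacing) / spacing
            np.maximum(frac, ov, out=frac)
        e = 1.0 / (frac / eps_in + (1.0 - frac) / eps_out)
        eps.append(e)
    return eps


def _spread_charges(origin, n, spacing, coords, charges):
    """Trilinear assignment of point charges to grid nodes (units: e)."""
    q_grid = np.zeros(tuple(n))
    t = (coords - origin) / spacing
    i0 = np.floor(t).astype(int)
    frac = t - i0
    if np.any(i0 < 0) or np.any(i0 + 1 >= n):
        raise ValidationError("charge outside PB grid; increase grid_padding")
    for (ix, iy, iz), (fx, fy, fz), q in zip(i0, frac, charges):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dz, wz in ((0, 1 - fz), (1, fz)):
                    q_grid[ix + dx, iy + dy, iz + dz] += q * wx * wy * wz
    return q_grid


def _boundary_potential(origin, n, spacing, coords, charges, eps, kappa,
                        coulomb_k):
    """Screened-Coulomb Dirichlet values on the six grid faces."""
    phi = np.zeros(tuple(n))
    axes = [origin[d] + spacing * np.arange(n[d]) for d in range(3)]

    def fill(face_slice, pts_shape, xs, ys, zs):
        p = np.zeros(pts_shape)
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        for c, q in zip(coords, charges):
            r = np.sqrt((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2)
            r = np.maximum(r, spacing / 2.0)
            contrib = coulomb_k * q / (eps * r)
            if kappa > 0:
                contrib = contrib * np.exp(-kappa * r)
            p += contrib
        phi[face_slice] = p.reshape(phi[face_slice].shape)

    fill((0, slice(None), slice(None)), (1, n[1], n[2]), axes[0][:1], axes[1], axes[2])
    fill((-1, slice(None), slice(None)), (1, n[1], n[2]), axes[0][-1:], axes[1], axes[2])
    fill((slice(None), 0, slice(None)), (n[0], 1, n[2]), axes[0], axes[1][:1], axes[2])
    fill((slice(None), -1, slice(None)), (n[0], 1, n[2]), axes[0], axes[1][-1:], axes[2])
    fill((slice(None), slice(None), 0), (n[0], n[1], 1), axes[0], axes[1], axes[2][:1])
    fill((slice(None), slice(None), -1), (n[0], n[1], 1), axes[0], axes[1], axes[2][-1:])
    return phi


def _sor_solve(phi, eps_faces, source, spacing, tol, max_iter):
    """Red-black SOR for sum_faces eps*(phi_nb - phi_c) = -source (interior)."""
    ex, ey, ez = eps_faces
    # face arrays adjacent to interior nodes
    exm = ex[:-1, 1:-1, 1:-1]
    exp_ = ex[1:, 1:-1, 1:-1]
    eym = ey[1:-1, :-1, 1:-1]
    eyp = ey[1:-1, 1:, 1:-1]
    ezm = ez[1:-1, 1:-1, :-1]
    ezp = ez[1:-1, 1:-1, 1:]
    diag = exm + exp_ + eym + eyp + ezm + ezp
    b = source[1:-1, 1:-1, 1:-1]

    ni, nj, nk = b.shape
    ii, jj, kk = np.meshgrid(np.arange(ni), np.arange(nj), np.arange(nk),
                             indexing="ij")
    red = ((ii + jj + kk) % 2 == 0)
    black = ~red

    n_min = min(phi.shape)
    omega = 2.0 / (1.0 + math.sin(math.pi / n_min))
    b_norm = np.linalg.norm(b) or 1.0

    def neighbor_sum():
        return (exm * phi[:-2, 1:-1, 1:-1] + exp_ * phi[2:, 1:-1, 1:-1]
                + eym * phi[1:-1, :-2, 1:-1] + eyp * phi[1:-1, 2:, 1:-1]
                + ezm * phi[1:-1, 1:-1, :-2] + ezp * phi[1:-1, 1:-1, 2:])

    residual = np.inf
    for it in range(1, max_iter + 1):
        interior = phi[1:-1, 1:-1, 1:-1]
        for mask in (red, black):
            s = neighbor_sum()
            gs = (s + b) / diag
            interior[mask] += omega * (gs[mask] - interior[mask])
        if it % 10 == 0 or it == max_iter:
            r = neighbor_sum() + b - diag * phi[1:-1, 1:-1, 1:-1]
            residual = float(np.linalg.norm(r) / b_norm)
            if residual < tol:
                return it, residual
    raise PBConvergenceError(
        f"SOR did not converge in {max_iter} iterations "
        f"(relative residual {residual:.3e}, tol {tol:.1e})"
    )


def solve_grid(coords, charges, radii, eps_in, eps_out, spacing, padding,
               kappa=0.0, tol=1e-6, max_iter=20000,
               coulomb_k=constants.COULOMB_K) -> PBGridResult:
    """Solve ∇·(ε∇φ) = -4πkρ for one dielectric configuration."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    charges = np.asarray(charges, dtype=float)
    radii = np.asarray(radii, dtype=float)
    origin, n = _build_grid(coords, radii, spacing, padding)
    eps_faces = _dielectric_faces(origin, n, spacing, coords, radii,
                                  eps_in, eps_out)
    q_grid = _spread_charges(origin, n, spacing, coords, charges)
    # ∑ ε (φ_nb - φ_c)/h² = -4πk q/h³  →  multiply through by h²
    source = constants.FOUR_PI * coulomb_k * q_grid / spacing

    phi = _boundary_potential(origin, n, spacing, coords, charges,
                              eps_out, kappa, coulomb_k)
    # interior initial guess: screened Coulomb from the boundary fill is
    # only on faces; start interior from zero-mean of boundary average
    its, res = _sor_solve(phi, eps_faces, source, spacing, tol, max_iter)
    return PBGridResult(phi=phi, origin=origin, spacing=spacing,
                        iterations=its, residual=res)


def _interp_phi(result: PBGridResult, coords: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of node potentials at atom positions."""
    t = (coords - result.origin) / result.spacing
    i0 = np.floor(t).astype(int)
    frac = t - i0
    phi = result.phi
    out = np.zeros(coords.shape[0])
    for a, ((ix, iy, iz), (fx, fy, fz)) in enumerate(zip(i0, frac)):
        acc = 0.0
        for dx, wx in ((0, 1 - fx), (1, fx)):
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dz, wz in ((0, 1 - fz), (1, fz)):
                    acc += wx * wy * wz * phi[ix + dx, iy + dy, iz + dz]
        out[a] = acc
    return out


def polar_solvation_energy(coords, charges, radii, eps_in=1.0, eps_out=80.0,
                           spacing=0.5, padding=8.0, kappa=0.0, tol=1e-6,
                           max_iter=20000,
                           coulomb_k=constants.COULOMB_K) -> float:
    """ΔG_polar (kcal/mol) of moving the charge set from ε=eps_in vacuum
    into the eps_in/eps_out two-dielectric medium.

    Two solves on the identical grid (solvated and uniform-reference); the
    grid self-energy of the spread charges cancels in the difference.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    charges = np.asarray(charges, dtype=float)
    if np.all(charges == 0.0):
        return 0.0
    if eps_out < eps_in or eps_in < 1.0:
        raise ValidationError("need eps_out >= eps_in >= 1")
    solv = solve_grid(coords, charges, radii, eps_in, eps_out, spacing,
                      padding, kappa, tol, max_iter, coulomb_k)
    ref = solve_grid(coords, charges, radii, eps_in, eps_in, spacing,
                     padding, 0.0, tol, max_iter, coulomb_k)
    dphi = _interp_phi(solv, coords) - _interp_phi(ref, coords)
    return float(0.5 * np.sum(charges * dphi))


def polar_solvation_per_atom(coords, charges, radii, eps_in=1.0, eps_out=80.0,
                             spacing=0.5, padding=8.0, kappa=0.0, tol=1e-6,
                             max_iter=20000,
                             coulomb_k=constants.COULOMB_K) -> np.ndarray:
    """Per-atom shares ½·q_i·Δφ(r_i) of the polar solvation energy."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    charges = np.asarray(charges, dtype=float)
    if np.all(charges == 0.0):
        return np.zeros(coords.shape[0])
    solv = solve_grid(coords, charges, radii, eps_in, eps_out, spacing,
                      padding, kappa, tol, max_iter, coulomb_k)
    ref = solve_grid(coords, charges, radii, eps_in, eps_in, spacing,
                     padding, 0.0, tol, max_iter, coulomb_k)
    dphi = _interp_phi(solv, coords) - _interp_phi(ref, coords)
    return 0.5 * charges * dphi
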