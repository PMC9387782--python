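"""Synthetic ensembles with known statistical and physical ground truth.

Four generators cover everything the analysis stages consume:

* multivariate-Gaussian coordinate ensembles with a prescribed mean and
  covariance (entropy and covariance recovery);
* rigid-body-contaminated copies of an ensemble (superposition removal);
* ideal-gas particle boxes of known number density around a fixed central
  probe (radial distribution and coordination numbers);
* toy bead-model protein-ligand complexes carrying charges and
  Lennard-Jones parameters (interaction-energy terms and their
  decomposition).

Every generator is a pure function of its spec and seed: identical inputs
give identical output ensembles.  These are statistical stand-ins, not
dynamics — no integrator or thermostat is involved, which suffices because
every downstream formula consumes configurations, not time correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import (
    AtomRecord,
    Frame,
    Topology,
    TrajectoryEnsemble,
    ValidationError,
)

__all__ = [
    "GaussianSpec",
    "ToyComplexSpec",
    "gen_gaussian_ensemble",
    "gen_rigid_contaminated",
    "gen_ideal_gas",
    "gen_toy_complex",
    "random_rotation_matrix",
]


@dataclass
class GaussianSpec:
    """Multivariate-normal ensemble of K atoms (3K coordinates, Å/Å²)."""

    mean: np.ndarray          # 3K vector, Å
    covariance: np.ndarray    # 3K x 3K symmetric PSD, Å²
    n_frames: int
    seed: int = 0
    masses: np.ndarray | None = None   # per-atom amu; default 12.011 each

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        d = self.mean.size
        if d % 3 != 0:
            raise ValidationError("mean length must be a multiple of 3")
        if self.covariance.shape != (d, d):
            raise ValidationError("covariance shape must match mean length")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-12):
            raise ValidationError("covariance must be symmetric within 1e-12")
        eig = np.linalg.eigvalsh(self.covariance)
        if eig.min() < -1e-10:
            raise ValidationError(
                f"covariance is not PSD (min eigenvalue {eig.min():.3e})"
            )
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")

    @property
    def n_atoms(self) -> int:
        return self.mean.size // 3


def _bead_topology(n_atoms, masses=None, charges=None, sigmas=None,
                   epsilons=None, radii=None, roles=None, names=None,
                   residue_names=None, elements=None):
    atoms = []
    for i in range(n_atoms):
        atoms.append(AtomRecord(
            serial=i + 1,
            name=(names[i] if names else "CA"),
            element=(elements[i] if elements else "C"),
            residue_name=(residue_names[i] if residue_names else "GLY"),
            residue_seq=i + 1,
            chain_id="A",
            mass=float(masses[i]) if masses is not None else 12.011,
            partial_charge=float(charges[i]) if charges is not None else 0.0,
            lj_sigma=float(sigmas[i]) if sigmas is not None else 0.0,
            lj_epsilon=float(epsilons[i]) if epsilons is not None else 0.0,
            pb_radius=float(radii[i]) if radii is not None else 1.7,
            molecule_role=(roles[i] if roles else "protein"),
        ))
    return Topology(atoms)


def gen_gaussian_ensemble(spec: GaussianSpec) -> TrajectoryEnsemble:
    """Draw i.i.d. frames from N(mean, covariance).

    The differential entropy of the generating law is the Gaussian closed
    form (1/2)·ln((2πe)^d·det Σ) in natural units, which downstream entropy
    estimators must recover in the large-sample limit.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.mean.size
    draws = rng.multivariate_normal(spec.mean, spec.covariance,
                                    size=spec.n_frames, method="svd")
    topo = _bead_topology(spec.n_atoms, masses=spec.masses)
    frames = [Frame(row.reshape(-1, 3), time=float(t))
              for t, row in enumerate(draws)]
    return TrajectoryEnsemble(topo, frames)


def random_rotation_matrix(rng: np.random.Generator,
                           max_angle_deg: float = 180.0) -> np.ndarray:
    """Random proper rotation: uniform over SO(3) when max_angle_deg=180
    (quaternion sampling), otherwise uniform axis with angle ~ U(0, max)."""
    if max_angle_deg >= 180.0:
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def gen_rigid_contaminated(traj: TrajectoryEnsemble, max_rot: float,
                           max_trans: float, seed: int) -> TrajectoryEnsemble:
    """Compose each frame with an independent random rigid motion.

    Rotation about the frame's centroid by at most ``max_rot`` degrees,
    translation components uniform in ±``max_trans`` Å.  Internal geometry
    (all intra-frame pairwise distances) is preserved exactly.
    """
    if max_rot < 0 or max_trans < 0:
        raise ValidationError("max_rot and max_trans must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    for f in traj.frames:
        if max_rot == 0 and max_trans == 0:
            frames.append(f.copy())
            continue
        rot = (np.eye(3) if max_rot == 0
               else random_rotation_matrix(rng, max_rot))
        trans = (np.zeros(3) if max_trans == 0
                 else rng.uniform(-max_trans, max_trans, size=3))
        centroid = f.coords.mean(axis=0)
        coords = (f.coords - centroid) @ rot.T + centroid + trans
        frames.append(Frame(coords, f.box, f.time))
    return TrajectoryEnsemble(traj.topology, frames)


def gen_ideal_gas(n_particles: int, box, n_frames: int,
                  seed: int = 0) -> TrajectoryEnsemble:
    """Uniform i.i.d. particles in an orthorhombic box, plus a fixed probe.

    Atom 0 is a probe pinned at the box center in every frame; atoms
    1..n_particles are the gas.  The gas number density is
    n_particles / V(box), the ideal-gas reference for g(r) = 1.
    """
    if n_particles < 1:
        raise ValidationError("n_particles must be >= 1")
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValidationError("box must be three positive lengths")
    rng = np.random.default_rng(seed)
    center = box / 2.0
    n_total = n_particles + 1
    roles = ["ion"] + ["solvent"] * n_particles
    names = ["ZN"] + ["AR"] * n_particles
    elements = ["ZN"] + ["AR"] * n_particles
    resnames = ["ZN"] + ["HOH"] * n_particles
    topo = _bead_topology(n_total, roles=roles, names=names,
                          elements=elements, residue_names=resnames,
                          masses=[65.38] + [39.948] * n_particles)
    frames = []
    for t in range(n_frames):
        gas = rng.uniform(0.0, 1.0, size=(n_particles, 3)) * box
        coords = np.vstack([center[None, :], gas])
        frames.append(Frame(coords, box=box.copy(), time=float(t)))
    return TrajectoryEnsemble(topo, frames)


@dataclass
class ToyComplexSpec:
    """Bead-model protein-ligand complex with explicit geometry/parameters.

    Protein beads become one-bead residues (name CA, role protein); ligand
    beads form a single LIG residue.  Coordinates in Å, charges in e,
    sigma/radius in Å, epsilon in kcal/mol, masses in amu.
    """

    protein_coords: np.ndarray
    ligand_coords: np.ndarray
    protein_charges: np.ndarray | None = None
    ligand_charges: np.ndarray | None = None
    lj_sigma: float | np.ndarray = 3.4
    lj_epsilon: float | np.ndarray = 0.1
    pb_radius: float | np.ndarray = 1.7
    mass: float | np.ndarray = 12.011
    n_frames: int = 1
    jitter_sigma: float = 0.0     # Å, isotropic Gaussian positional noise
    seed: int = 0

    def __post_init__(self):
        self.protein_coords = np.atleast_2d(np.asarray(self.protein_coords, float))
        self.ligand_coords = np.atleast_2d(np.asarray(self.ligand_coords, float))
        for name in ("protein_charges", "ligand_charges"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        all_xyz = np.vstack([self.protein_coords, self.ligand_coords])
        n = all_xyz.shape[0]
        d = np.linalg.norm(all_xyz[:, None] - all_xyz[None, :], axis=2)
        d[np.diag_indices(n)] = np.inf
        if d.min() < 0.5:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            raise ValidationError(
                f"beads {i} and {j} overlap (separation {d.min():.3f} Å < 0.5 Å)"
            )
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")

    @property
    def n_protein_beads(self) -> int:
        return self.protein_coords.shape[0]

    @property
    def n_ligand_beads(self) -> int:
        return self.ligand_coords.shape[0]


def _per_bead(value, n):
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValidationError(f"per-bead parameter has shape {arr.shape}, expected ({n},)")
    return arr


def gen_toy_complex(spec: ToyComplexSpec) -> TrajectoryEnsemble:
    """Build the bead complex ensemble described by ``spec``.

    With ``jitter_sigma > 0`` and ``n_frames > 1`` the stated geometry is
    the frame-0 mean and every frame adds i.i.d. Gaussian displacements —
    a stand-in for small-amplitude thermal fluctuation about a bound pose.
    """
    np_, nl = spec.n_protein_beads, spec.n_ligand_beads
    n = np_ + nl
    charges = np.concatenate([
        spec.protein_charges if spec.protein_charges is not None else np.zeros(np_),
        spec.ligand_charges if spec.ligand_charges is not None else np.zeros(nl),
    ])
    sigmas = _per_bead(spec.lj_sigma, n)
    epsilons = _per_bead(spec.lj_epsilon, n)
    radii = _per_bead(spec.pb_radius, n)
    masses = _per_bead(spec.mass, n)

    atoms = []
    for i in range(np_):
        atoms.append(AtomRecord(
            serial=i + 1, name="CA", element="C", residue_name="GLY",
            residue_seq=i + 1, chain_id="A", mass=masses[i],
            partial_charge=charges[i], lj_sigma=sigmas[i],
            lj_epsilon=epsilons[i], pb_radius=radii[i],
            molecule_role="protein"))
    for j in range(nl):
        i = np_ + j
        atoms.append(AtomRecord(
            serial=i + 1, name=f"L{j + 1}", element="C", residue_name="LIG",
            residue_seq=np_ + 1, chain_id="B", mass=masses[i],
            partial_charge=charges[i], lj_sigma=sigmas[i],
            lj_epsilon=epsilons[i], pb_radius=radii[i],
            molecule_role="ligand"))
    topo = Topology(atoms)

    base = np.vstack([spec.protein_coords, spec.ligand_coords])
    rng = np.random.default_rng(spec.seed)
    frames = []
    for t in range(spec.n_frames):
        coords = base.copy()
        if spec.jitter_sigma > 0:
            coords = coords + rng.normal(0.0, spec.jitter_sigma, size=coords.shape)
        frames.append(Frame(coords, time=float(t)))
    return TrajectoryEnsemble(topo, frames)
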