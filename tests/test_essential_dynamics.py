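"""Covariance models, principal-mode projections, free-energy landscapes."""

import numpy as np
import pytest

from trajthermo.constants import K_B_KCAL
from trajthermo.essential_dynamics import (
    covariance_model,
    free_energy_landscape,
    project,
)
from trajthermo.model_io import Frame, Selection, TrajectoryEnsemble, ValidationError
from trajthermo.synthetic import (
    GaussianSpec,
    gen_gaussian_ensemble,
    gen_rigid_contaminated,
    _bead_topology,
)

SEL3 = Selection((0, 1, 2))


def _random_psd(d, rng, scale=0.05):
    a = rng.normal(size=(d, d)) * scale
    return a @ a.T + 0.01 * np.eye(d)


class TestCovarianceModel:
    def test_recovers_known_covariance(self):
        rng = np.random.default_rng(20)
        sigma = _random_psd(9, rng)
        spec = GaussianSpec(mean=np.arange(9, dtype=float) * 3,
                            covariance=sigma, n_frames=50_000, seed=21)
        ens = gen_gaussian_ensemble(spec)
        m = covariance_model(ens, SEL3, fit=False)
        rel = np.linalg.norm(m.covariance - sigma) / np.linalg.norm(sigma)
        assert rel < 0.02

    def test_identical_frames_zero_matrix(self):
        f = Frame(np.arange(9, dtype=float).reshape(3, 3))
        traj = TrajectoryEnsemble(_bead_topology(3), [f.copy(), f.copy()])
        m = covariance_model(traj, SEL3, fit=False)
        np.testing.assert_allclose(m.covariance, 0.0, atol=1e-12)
        np.testing.assert_allclose(m.eigenvalues, 0.0, atol=1e-12)

    def test_unit_masses_match_unweighted(self):
        spec = GaussianSpec(mean=np.arange(9, dtype=float) * 3,
                            covariance=0.05 * np.eye(9), n_frames=100, seed=22,
                            masses=np.ones(3))
        ens = gen_gaussian_ensemble(spec)
        mu = covariance_model(ens, SEL3, mass_weighted=False, fit=False)
        mw = covariance_model(ens, SEL3, mass_weighted=True, fit=False)
        np.testing.assert_allclose(mu.covariance, mw.covariance, atol=1e-12)

    def test_too_few_frames(self):
        f = Frame(np.arange(9, dtype=float).reshape(3, 3))
        traj = TrajectoryEnsemble(_bead_topology(3), [f])
        with pytest.raises(ValidationError):
            covariance_model(traj, SEL3, fit=False)

    def test_spectral_invariants(self):
        rng = np.random.default_rng(23)
        spec = GaussianSpec(mean=np.arange(9, dtype=float) * 4,
                            covariance=_random_psd(9, rng), n_frames=500,
                            seed=24)
        m = covariance_model(gen_gaussian_ensemble(spec), SEL3, fit=False)
        assert m.eigenvalues.min() > -1e-8
        assert np.all(np.diff(m.eigenvalues) <= 1e-12)
        assert np.trace(m.covariance) == pytest.approx(m.eigenvalues.sum(),
                                                       rel=1e-8)
        gram = m.eigenvectors.T @ m.eigenvectors
        np.testing.assert_allclose(gram, np.eye(9), atol=1e-8)

    def test_eigenvalues_match_characteristic_polynomial(self):
        # brute-force oracle for K <= 4 atoms: roots of det(C - x I)
        rng = np.random.default_rng(25)
        spec = GaussianSpec(mean=np.zeros(6), covariance=_random_psd(6, rng),
                            n_frames=200, seed=26)
        m = covariance_model(gen_gaussian_ensemble(spec),
                             Selection((0, 1)), fit=False)
        coeffs = np.poly(m.covariance)
        roots = np.sort(np.real(np.roots(coeffs)))[::-1]
        np.testing.assert_allclose(m.eigenvalues, roots, rtol=1e-6, atol=1e-12)

    def test_rigid_contamination_leaves_six_near_zero_modes(self):
        base = np.array([[0, 0, 0], [3.8, 0, 0], [0, 3.8, 0], [0, 0, 3.8],
                         [3.8, 3.8, 3.8]], float)
        spec = GaussianSpec(mean=base.ravel(), covariance=1e-4 * np.eye(15),
                            n_frames=800, seed=27)
        cont = gen_rigid_contaminated(gen_gaussian_ensemble(spec), 180.0,
                                      10.0, seed=28)
        m = covariance_model(cont, Selection(tuple(range(5))), fit=True)
        ev = m.eigenvalues
        assert np.all(ev[-6:] < 1e-6 * ev[0])
        assert ev[8] > 1e-3 * ev[0]   # internal modes survive


class TestProjection:
    @pytest.fixture
    def model_and_traj(self):
        rng = np.random.default_rng(30)
        spec = GaussianSpec(mean=np.arange(9, dtype=float) * 4,
                            covariance=_random_psd(9, rng), n_frames=2000,
                            seed=31)
        traj = gen_gaussian_ensemble(spec)
        return covariance_model(traj, SEL3, fit=False), traj

    def test_projection_variance_equals_eigenvalue(self, model_and_traj):
        model, traj = model_and_traj
        proj = project(traj, model, components=(0, 1, 2), fit=False)
        for c in range(3):
            var = float(np.mean(proj.values[:, c] ** 2))   # biased, mean 0
            assert var == pytest.approx(model.eigenvalues[c], rel=1e-6)

    def test_mean_structure_projects_to_zero(self, model_and_traj):
        model, traj = model_and_traj
        mean_frame = Frame(model.mean_coords.reshape(-1, 3))
        single = TrajectoryEnsemble(traj.topology, [mean_frame])
        proj = project(single, model, components=(0, 1), fit=False)
        np.testing.assert_allclose(proj.values, 0.0, atol=1e-10)

    def test_component_series_uncorrelated(self, model_and_traj):
        model, traj = model_and_traj
        proj = project(traj, model, components=(0, 1), fit=False)
        cov01 = float(np.mean(proj.values[:, 0] * proj.values[:, 1]))
        scale = np.sqrt(model.eigenvalues[0] * model.eigenvalues[1])
        assert abs(cov01) / scale < 1e-8

    def test_component_mean_near_zero(self, model_and_traj):
        model, traj = model_and_traj
        proj = project(traj, model, components=(0,), fit=False)
        sd = proj.values[:, 0].std()
        assert abs(proj.values[:, 0].mean()) < 1e-8 * max(sd, 1.0)

    def test_out_of_range_component(self, model_and_traj):
        model, traj = model_and_traj
        with pytest.raises(ValidationError):
            project(traj, model, components=(9,), fit=False)


class TestLandscape:
    def _proj(self, values):
        from trajthermo.essential_dynamics import ProjectionSet
        return ProjectionSet(components=(0, 1), values=np.asarray(values, float),
                             mass_weighted=False)

    def test_single_occupied_bin(self):
        grid = free_energy_landscape(self._proj([[0.0, 0.0]] * 10), T=300,
                                     n_bins=4)
        finite = np.isfinite(grid.free_energy)
        assert finite.sum() == 1
        assert grid.free_energy[finite][0] == pytest.approx(0.0)
        assert grid.probability.sum() == pytest.approx(1.0, abs=1e-12)

    def test_temperature_linearity(self):
        rng = np.random.default_rng(33)
        vals = rng.normal(size=(500, 2))
        g300 = free_energy_landscape(self._proj(vals), T=300, n_bins=8)
        g600 = free_energy_landscape(self._proj(vals), T=600, n_bins=8)
        m = np.isfinite(g300.free_energy)
        np.testing.assert_allclose(g600.free_energy[m],
                                   2.0 * g300.free_energy[m], atol=1e-12)

    def test_gaussian_projection_quadratic_well(self):
        # Boltzmann inversion of a symmetric Gaussian: minimum central,
        # G grows with |r| along the axes
        rng = np.random.default_rng(34)
        vals = rng.normal(size=(200_000, 2))
        grid = free_energy_landscape(self._proj(vals), T=300, n_bins=21)
        g = grid.free_energy
        center = np.unravel_index(np.nanargmin(np.where(np.isfinite(g), g, np.nan)),
                                  g.shape)
        assert abs(center[0] - 10) <= 1 and abs(center[1] - 10) <= 1
        # monotone increase away from center along the middle row (inner bins)
        row = g[center[0], :]
        inner = row[5:16]
        mid = 10 - 5
        assert np.all(np.diff(inner[:mid + 1]) < 0.3)  # towards min: decreasing
        assert np.all(np.diff(inner[mid:]) > -0.3)     # away: increasing
        # quadratic oracle: G(x) ≈ kT x^2 / 2 at bin centers
        xc = 0.5 * (grid.axes[1][:-1] + grid.axes[1][1:])
        kT = K_B_KCAL * 300
        pred = kT * (xc ** 2 - xc[center[1]] ** 2) / 2.0
        m = np.isfinite(row) & (np.abs(xc) < 2.0)
        np.testing.assert_allclose(row[m], pred[m], atol=0.05)
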