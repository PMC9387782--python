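"""Pairwise non-bonded terms, SASA, nonpolar/polar solvation, breakdown."""

import math

import numpy as np
import pytest

from trajthermo.constants import COULOMB_K
from trajthermo.interaction_energy import (
    EnergyBreakdown,
    SolvationParams,
    assemble_total,
    binding_breakdown,
    nonpolar_solvation,
    pair_nonbonded,
    per_residue_decomposition,
    sasa,
)
from trajthermo.model_io import Frame, Selection, ValidationError
from trajthermo.qh_entropy import EntropyResult
from trajthermo.synthetic import ToyComplexSpec, gen_toy_complex


def brute_force_nonbonded(coords, charges, sigmas, epsilons, ia, ib, k=COULOMB_K):
    """Independent double-loop oracle."""
    ev = ee = 0.0
    for i in ia:
        for j in ib:
            r = math.dist(coords[i], coords[j])
            ee += k * charges[i] * charges[j] / r
            eps = math.sqrt(epsilons[i] * epsilons[j])
            if eps > 0:
                s = 0.5 * (sigmas[i] + sigmas[j])
                ev += 4 * eps * ((s / r) ** 12 - (s / r) ** 6)
    return ev, ee


def _beads(coords, charges=None, sigma=3.4, eps=0.1, radius=1.7, split=None):
    coords = np.asarray(coords, float)
    n = len(coords)
    split = split if split is not None else n // 2
    spec = ToyComplexSpec(
        protein_coords=coords[:split], ligand_coords=coords[split:],
        protein_charges=None if charges is None else np.asarray(charges[:split]),
        ligand_charges=None if charges is None else np.asarray(charges[split:]),
        lj_sigma=sigma, lj_epsilon=eps, pb_radius=radius,
    )
    ens = gen_toy_complex(spec)
    return ens, Selection(tuple(range(split))), Selection(tuple(range(split, n)))


class TestPairNonbonded:
    def test_coulomb_hand_value(self):
        # two +1e charges at 3.32 A: 332.0636/3.32 = 100.019 kcal/mol
        ens, a, b = _beads([[0, 0, 0], [3.32, 0, 0]], charges=[1.0, 1.0], eps=0.0)
        ev, ee = pair_nonbonded(ens.frames[0], ens.topology, a, b)
        assert ee == pytest.approx(100.01915662650603, rel=1e-12)
        assert ev == 0.0

    def test_lj_root_and_minimum(self):
        sigma = 3.4
        ens, a, b = _beads([[0, 0, 0], [sigma, 0, 0]], eps=0.25)
        ev, _ = pair_nonbonded(ens.frames[0], ens.topology, a, b)
        assert ev == pytest.approx(0.0, abs=1e-12)
        ens2, a2, b2 = _beads([[0, 0, 0], [2 ** (1 / 6) * sigma, 0, 0]], eps=0.25)
        ev2, _ = pair_nonbonded(ens2.frames[0], ens2.topology, a2, b2)
        assert ev2 == pytest.approx(-0.25, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 12, size=(8, 3))
        while True:
            d = np.linalg.norm(coords[:, None] - coords[None], axis=2)
            d[np.diag_indices(8)] = np.inf
            if d.min() > 1.0:
                break
            coords = rng.uniform(0, 12, size=(8, 3))
        charges = rng.uniform(-1, 1, size=8)
        ens, a, b = _beads(coords, charges=charges, split=5)
        topo = ens.topology
        ev, ee = pair_nonbonded(ens.frames[0], topo, a, b)
        bev, bee = brute_force_nonbonded(
            ens.frames[0].coords, topo.charges, topo.lj_sigmas,
            topo.lj_epsilons, a.indices, b.indices)
        assert ev == pytest.approx(bev, abs=1e-10)
        assert ee == pytest.approx(bee, abs=1e-10)

    def test_overlap_rejected(self):
        ens, a, b = _beads([[0, 0, 0], [0.6, 0, 0]])
        f = Frame(np.array([[0.0, 0, 0], [0.0, 0, 0]]))
        with pytest.raises(ValidationError, match="overlap"):
            pair_nonbonded(f, ens.topology, a, b)

    def test_disjoint_groups_required(self, toy_complex):
        with pytest.raises(ValidationError):
            pair_nonbonded(toy_complex.frames[0], toy_complex.topology,
                           Selection((0, 1)), Selection((1, 2)))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 10, size=(6, 3))
        charges = rng.uniform(-1, 1, size=6)
        ens, a, b = _beads(coords, charges=charges, split=3)
        e0 = pair_nonbonded(ens.frames[0], ens.topology, a, b)
        th = np.deg2rad(33)
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        f2 = Frame(ens.frames[0].coords @ rot.T + np.array([3.0, -1.0, 7.0]))
        e1 = pair_nonbonded(f2, ens.topology, a, b)
        assert e1[0] == pytest.approx(e0[0], abs=1e-8)
        assert e1[1] == pytest.approx(e0[1], abs=1e-8)


class TestSasa:
    PARAMS = SolvationParams()

    def test_isolated_sphere_exact(self):
        ens, a, _ = _beads([[0, 0, 0], [100, 0, 0]], radius=1.6, split=1)
        per, total = sasa(ens.frames[0], ens.topology, a, self.PARAMS)
        assert total == pytest.approx(4 * math.pi * 3.0 ** 2, rel=1e-12)

    def test_two_distant_spheres_additive(self):
        ens, a, b = _beads([[0, 0, 0], [100, 0, 0]], radius=1.6, split=1)
        both = Selection((0, 1))
        _, total = sasa(ens.frames[0], ens.topology, both, self.PARAMS)
        assert total == pytest.approx(2 * 4 * math.pi * 3.0 ** 2, rel=1e-12)

    @pytest.mark.parametrize("d_frac", [0.999, 0.7, 0.4])
    def test_two_sphere_cap_closed_form(self, d_frac):
        # equal expanded radii R; exposed area = 2*(4πR² − 2πR·h), h = R − d/2
        radius, probe = 1.6, 1.4
        R = radius + probe
        d = d_frac * 2 * R
        ens, _, _ = _beads([[0, 0, 0], [d, 0, 0]], radius=radius, split=1)
        both = Selection((0, 1))
        _, total = sasa(ens.frames[0], ens.topology, both, self.PARAMS)
        h = R - d / 2
        exact = 2 * (4 * math.pi * R ** 2 - 2 * math.pi * R * h)
        assert total == pytest.approx(exact, rel=0.02)

    def test_full_overlap_tends_to_one_sphere(self):
        ens, _, _ = _beads([[0, 0, 0], [0.51, 0, 0]], radius=1.6, split=1)
        both = Selection((0, 1))
        _, total = sasa(ens.frames[0], ens.topology, both, self.PARAMS)
        one = 4 * math.pi * 3.0 ** 2
        # 0.51 A apart: slightly more than a single sphere
        assert one < total < 1.1 * one

    def test_point_count_convergence(self):
        # cap-oracle error shrinks with more sphere points
        radius, probe = 1.6, 1.4
        R = radius + probe
        d = 0.7 * 2 * R
        h = R - d / 2
        exact = 2 * (4 * math.pi * R ** 2 - 2 * math.pi * R * h)
        ens, _, _ = _beads([[0, 0, 0], [d, 0, 0]], radius=radius, split=1)
        both = Selection((0, 1))
        errs = []
        for n in (96, 960, 9600):
            p = SolvationParams(n_sasa_points=n)
            _, total = sasa(ens.frames[0], ens.topology, both, p)
            errs.append(abs(total - exact) / exact)
        assert errs[2] < errs[0]
        assert errs[1] < 0.002 * 10   # within 2% at 960 points

    def test_zero_radius_rejected(self):
        ens, a, _ = _beads([[0, 0, 0], [5, 0, 0]], radius=0.0, split=1)
        with pytest.raises(ValidationError):
            sasa(ens.frames[0], ens.topology, a, self.PARAMS)


class TestNonpolar:
    def test_zero_area_gives_b(self):
        assert nonpolar_solvation(0.0) == pytest.approx(0.92)

    def test_hand_value(self):
        # gamma*SASA + b at the isolated-sphere area
        area = 4 * math.pi * 3.0 ** 2
        assert nonpolar_solvation(area) == pytest.approx(
            0.00542 * area + 0.92, rel=1e-12)
        assert nonpolar_solvation(area) == pytest.approx(1.533, abs=5e-4)

    def test_zero_gamma(self):
        p = SolvationParams(gamma=0.0)
        assert nonpolar_solvation(500.0, p) == pytest.approx(0.92)


class TestBindingBreakdown:
    def test_single_frame_matches_brute_force(self, toy_complex, toy_selections):
        prot, lig = toy_selections
        bd = binding_breakdown(toy_complex, prot, lig, include_polar=False)
        topo = toy_complex.topology
        bev, bee = brute_force_nonbonded(
            toy_complex.frames[0].coords, topo.charges, topo.lj_sigmas,
            topo.lj_epsilons, prot.indices, lig.indices)
        assert bd.dE_vdw == pytest.approx(bev, abs=1e-10)
        assert bd.dE_elec == pytest.approx(bee, abs=1e-10)
        assert bd.dG_pbsa == pytest.approx(
            bd.dE_vdw + bd.dE_elec + bd.dG_polar + bd.dG_nonpolar, abs=1e-9)

    def test_separated_limit(self):
        ens, prot, lig = _beads([[0, 0, 0], [3.5, 0, 0], [500.0, 0, 0]],
                                charges=[1.0, -1.0, 1.0], split=2)
        bd = binding_breakdown(ens, prot, lig, include_polar=False)
        assert abs(bd.dE_vdw) < 1e-4
        assert abs(bd.dE_elec) < 1e-2   # k*q/(500) ~ 0.66*q_net; net q here 0
        # nonpolar difference also vanishes at separation (net -b remains)
        assert bd.dG_nonpolar == pytest.approx(-0.92, abs=1e-6)

    def test_window_average_is_mean_of_snapshots(self):
        spec = ToyComplexSpec(
            protein_coords=np.array([[0.0, 0, 0], [3.5, 0, 0]]),
            ligand_coords=np.array([[1.75, 3.2, 0.0]]),
            protein_charges=np.array([1.0, -1.0]),
            ligand_charges=np.array([1.0]),
            n_frames=10, jitter_sigma=0.05, seed=3,
        )
        ens = gen_toy_complex(spec)
        prot, lig = Selection((0, 1)), Selection((2,))
        bd = binding_breakdown(ens, prot, lig, include_polar=False)
        per = [pair_nonbonded(f, ens.topology, prot, lig) for f in ens.frames]
        assert bd.dE_vdw == pytest.approx(np.mean([p[0] for p in per]), abs=1e-12)
        assert bd.dE_elec == pytest.approx(np.mean([p[1] for p in per]), abs=1e-12)
        assert bd.n_snapshots == 10

    def test_polar_screens_gas_phase_attraction_at_separation(self):
        # at large separation the polar term cancels the residual gas-phase
        # Coulomb interaction (eps_out screening), up to coarse-grid noise
        coarse = SolvationParams(grid_spacing=1.0, grid_padding=6.0)
        ens, prot, lig = _beads([[0, 0, 0], [3.5, 0, 0], [40.0, 0, 0]],
                                charges=[0.5, -0.5, 1.0], split=2)
        bd = binding_breakdown(ens, prot, lig, params=coarse)
        assert abs(bd.dE_vdw) < 1e-4
        assert abs(bd.dE_elec + bd.dG_polar) < 1.0


class TestPerResidue:
    def test_vdw_elec_partition_totals(self, toy_complex, toy_selections):
        prot, lig = toy_selections
        bd = binding_breakdown(toy_complex, prot, lig, include_polar=False)
        dec = per_residue_decomposition(toy_complex, prot, lig,
                                        include_polar=False)
        vdw = sum(v["vdw"] for v in dec.values())
        elec = sum(v["elec"] for v in dec.values())
        assert vdw == pytest.approx(bd.dE_vdw, abs=1e-9)
        assert elec == pytest.approx(bd.dE_elec, abs=1e-9)

    def test_zero_charge_residue_no_elec(self):
        ens, prot, lig = _beads([[0, 0, 0], [3.5, 0, 0], [1.75, 3.2, 0]],
                                charges=[0.0, -1.0, 1.0], split=2)
        dec = per_residue_decomposition(ens, prot, lig, include_polar=False)
        key0 = ens.topology.residues[0].key
        assert dec[key0]["elec"] == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention(self):
        # opposite charges attract (negative), like charges repel (positive)
        ens, prot, lig = _beads([[0, 0, 0], [6.0, 0, 0], [0.0, 3.3, 0]],
                                charges=[-1.0, 1.0, 1.0], split=2)
        dec = per_residue_decomposition(ens, prot, lig, include_polar=False)
        k_opp = ens.topology.residues[0].key   # -1 near +1 ligand
        k_same = ens.topology.residues[1].key  # +1 farther from +1 ligand
        assert dec[k_opp]["elec"] < 0
        assert dec[k_same]["elec"] > 0

    def test_polar_shares_sum_to_total(self, toy_complex, toy_selections):
        prot, lig = toy_selections
        coarse = SolvationParams(grid_spacing=0.8, grid_padding=5.0)
        bd = binding_breakdown(toy_complex, prot, lig, params=coarse)
        dec = per_residue_decomposition(toy_complex, prot, lig, params=coarse)
        polar = sum(v["polar"] for v in dec.values())
        assert polar == pytest.approx(bd.dG_polar, abs=1e-6)


class TestAssembleTotal:
    def _entropy(self, minus_T_dS):
        return EntropyResult(method="andricioaei_karplus", S=-minus_T_dS / 300.0,
                             temperature=300.0, n_modes_retained=1,
                             discarded_modes=0, minus_T_dS=minus_T_dS)

    def _bd(self, vdw, elec, polar, nonpolar):
        return EnergyBreakdown(dE_vdw=vdw, dE_elec=elec, dG_polar=polar,
                               dG_nonpolar=nonpolar,
                               dG_pbsa=vdw + elec + polar + nonpolar)

    @pytest.mark.parametrize("pbsa,tds,total", [
        (-70.08, 5.84, -64.24),
        (-53.46, 7.60, -45.86),
    ])
    def test_benchmark_rows(self, pbsa, tds, total):
        # worked examples of the assembly arithmetic on table-style rows
        bd = self._bd(pbsa, 0.0, 0.0, 0.0)
        out = assemble_total(bd, self._entropy(tds))
        assert out.dG_total == pytest.approx(total, abs=1e-9)

    def test_component_sum_reproduces_pbsa(self):
        # rows whose four printed components sum exactly to the printed total
        bd = self._bd(-42.82, -101.46, 79.20, -4.36)
        assert bd.dG_pbsa == pytest.approx(-69.44, abs=1e-9)
        bd2 = self._bd(-35.80, -95.61, 73.21, -3.80)
        assert bd2.dG_pbsa == pytest.approx(-62.00, abs=1e-9)

    def test_zero_entropy_term(self):
        bd = self._bd(-1.0, -2.0, 3.0, -0.5)
        out = assemble_total(bd, self._entropy(0.0))
        assert out.dG_total == pytest.approx(bd.dG_pbsa, abs=1e-12)

    def test_missing_minus_TdS_rejected(self):
        bd = self._bd(-1.0, -2.0, 3.0, -0.5)
        plain = EntropyResult(method="andricioaei_karplus", S=0.1,
                              temperature=300.0, n_modes_retained=1,
                              discarded_modes=0)
        with pytest.raises(ValidationError):
            assemble_total(bd, plain)

    def test_identity_enforced_on_construction(self):
        with pytest.raises(ValidationError):
            EnergyBreakdown(dE_vdw=-1.0, dE_elec=-2.0, dG_polar=3.0,
                            dG_nonpolar=-0.5, dG_pbsa=0.0)
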