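"""Bond/angle/planarity losses: values, outlier logic, gradients,
invariances."""

import numpy as np
import pytest

import gmmrefine as g
from gmmrefine.geom_scores import (bond_angle_loss, bond_length_loss,
                                   dihedrals_with_grad, planarity_loss)
from gmmrefine.model_io import CompiledTopology

from conftest import rigid_transform


def _mini_topo(n_atoms, bonds=None, bond_mean=None, bond_std=None,
               angles=None, angle_mean=None, angle_std=None,
               planars=None, planar_class=None):
    z = np.zeros
    return CompiledTopology(
        bond_idx=np.array(bonds or [], int).reshape(-1, 2),
        bond_mean=np.asarray(bond_mean if bond_mean is not None else [],
                             float),
        bond_std=np.asarray(bond_std if bond_std is not None else [],
                            float),
        angle_idx=np.array(angles or [], int).reshape(-1, 3),
        angle_mean=np.asarray(angle_mean if angle_mean is not None else [],
                              float),
        angle_std=np.asarray(angle_std if angle_std is not None else [],
                             float),
        planar_idx=np.array(planars or [], int).reshape(-1, 4),
        planar_class=np.asarray(planar_class or [], dtype=object),
        phi_idx=z((0, 4), int), psi_idx=z((0, 4), int),
        omega_prev_idx=z((0, 4), int), rama_residues=z(0, int),
        rama_class=np.asarray([], object), chi_idx=[],
        chi_residues=z(0, int), chi_rotating=[],
        suite_idx=z((0, 7, 4), int), suite_residues=z(0, int),
        exclusion_pairs=z((0, 2), int), bond_graph=[[] for _ in
                                                    range(n_atoms)])


def _quad_with_dihedral(angle_deg):
    """Four points whose dihedral is exactly angle_deg."""
    a = np.radians(angle_deg)
    return np.array([[1.0, 0.0, -1.0], [0, 0, -1], [0, 0, 0],
                     [np.cos(a), np.sin(a), 0.0]])


class TestBondLoss:
    def test_ideal_bonds_zero(self, helix, helix_topo):
        rep = bond_length_loss(helix.coords, helix_topo)
        assert rep.likelihood < 1e-6
        assert rep.outlier_count == 0

    def test_five_sigma_bond_is_outlier_and_penalized(self):
        topo = _mini_topo(2, bonds=[[0, 1]], bond_mean=[1.5],
                          bond_std=[0.02])
        coords = np.array([[0.0, 0, 0], [1.5 + 5.2 * 0.02, 0, 0]])
        rep = bond_length_loss(coords, topo)
        assert rep.outlier_count == 1        # 5-sigma reporting threshold
        assert rep.outlier_penalty > 0       # 4.5-sigma penalty threshold
        # between the two thresholds: penalized but not reported
        coords2 = np.array([[0.0, 0, 0], [1.5 + 4.8 * 0.02, 0, 0]])
        rep2 = bond_length_loss(coords2, topo)
        assert rep2.outlier_count == 0 and rep2.outlier_penalty > 0

    def test_vectorized_equals_scalar_loop(self):
        rng = np.random.default_rng(0)
        n = 51
        coords = rng.normal(scale=4, size=(n, 3))
        bonds = [[i, i + 1] for i in range(50)]
        means = rng.uniform(1.2, 1.6, 50)
        stds = np.full(50, 0.02)
        topo = _mini_topo(n, bonds=bonds, bond_mean=means, bond_std=stds)
        rep = bond_length_loss(coords, topo)
        acc = 0.0
        for (i, j), mu, sd in zip(bonds, means, stds):
            z = (np.linalg.norm(coords[i] - coords[j]) - mu) / sd
            acc += z * z / 2 + max(abs(z) - 4.5, 0) ** 2
        assert rep.loss == pytest.approx(acc / 50, abs=1e-10)

    def test_coincident_atoms_guarded(self):
        topo = _mini_topo(2, bonds=[[0, 1]], bond_mean=[1.5],
                          bond_std=[0.02])
        coords = np.zeros((2, 3))
        rep = bond_length_loss(coords, topo)
        assert np.isfinite(rep.loss) and rep.degenerate == 1

    def test_monotone_under_uniform_stretch(self, helix, helix_topo):
        last = bond_length_loss(helix.coords, helix_topo).loss
        center = helix.coords.mean(axis=0)
        for eps in (0.05, 0.1, 0.2):
            coords = center + (helix.coords - center) * (1 + eps)
            cur = bond_length_loss(coords, helix_topo).loss
            assert cur > last
            last = cur


class TestAngleLoss:
    def test_ideal_angles_near_zero(self, helix, helix_topo):
        rep = bond_angle_loss(helix.coords, helix_topo)
        assert rep.outlier_count == 0

    def test_collinear_guarded(self):
        topo = _mini_topo(3, angles=[[0, 1, 2]], angle_mean=[109.5],
                          angle_std=[2.0])
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        rep = bond_angle_loss(coords, topo)
        assert np.isfinite(rep.loss) and np.all(np.isfinite(rep.grad))

    def test_gradient_matches_finite_differences(self):
        topo = _mini_topo(3, angles=[[0, 1, 2]], angle_mean=[100.0],
                          angle_std=[2.0])
        rng = np.random.default_rng(1)
        coords = rng.normal(scale=2, size=(3, 3))
        rep = bond_angle_loss(coords, topo)
        for a in range(3):
            for k in range(3):
                p = coords.copy()
                p[a, k] += 1e-6
                lp = bond_angle_loss(p, topo).loss
                p[a, k] -= 2e-6
                lm = bond_angle_loss(p, topo).loss
                fd = (lp - lm) / 2e-6
                if abs(fd) > 1e-6:
                    assert abs(fd - rep.grad[a, k]) / abs(fd) < 1e-3


class TestPlanarity:
    def test_trans_peptide_zero(self, helix, helix_topo):
        rep = planarity_loss(helix.coords, helix_topo)
        assert rep.loss == 0.0 and rep.outlier_count == 0

    @pytest.mark.parametrize("omega,expect_penalty",
                             [(145.0, True), (155.0, False)])
    def test_peptide_30_degree_threshold(self, omega, expect_penalty):
        topo = _mini_topo(4, planars=[[0, 1, 2, 3]],
                          planar_class=["peptide"])
        rep = planarity_loss(_quad_with_dihedral(omega), topo)
        assert (rep.loss > 0) == expect_penalty

    @pytest.mark.parametrize("dev,expect_penalty",
                             [(12.0, True), (8.0, False)])
    def test_other_planar_10_degree_threshold(self, dev, expect_penalty):
        topo = _mini_topo(4, planars=[[0, 1, 2, 3]],
                          planar_class=["other"])
        rep = planarity_loss(_quad_with_dihedral(180.0 - dev), topo)
        assert (rep.loss > 0) == expect_penalty


class TestInvariances:
    def test_rigid_invariance_of_all_losses(self, helix, helix_topo):
        moved = rigid_transform(helix.coords, seed=3)
        for fn in (bond_length_loss, bond_angle_loss, planarity_loss):
            a = fn(helix.coords, helix_topo).loss
            b = fn(moved, helix_topo).loss
            assert abs(a - b) < 1e-9

    def test_dihedral_matches_independent_implementation(self):
        import biotite.structure as struc

        rng = np.random.default_rng(11)
        for _ in range(20):
            pts = rng.normal(scale=3, size=(4, 3))
            mine = dihedrals_with_grad(pts, np.array([[0, 1, 2, 3]]))[0][0]
            ref = np.degrees(struc.dihedral(pts[0], pts[1], pts[2],
                                            pts[3]))
            # biotite computes in float32; agree to its precision
            assert abs((mine - ref + 180) % 360 - 180) < 1e-4
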