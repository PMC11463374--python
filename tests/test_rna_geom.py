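"""RNA backbone suite vectors, assignment and loss."""

import numpy as np
import pytest

import gmmrefine as g
from gmmrefine.geom_scores import wrap_angle
from gmmrefine.rna_geom import (assign_suites, compute_suite_vectors,
                                suite_loss, suite_loss_on_coords)


class TestSuiteVectors:
    def test_two_residue_single_vector(self):
        rna = g.make_rna(2)
        topo = g.compile_topology(rna)
        vec, _ = compute_suite_vectors(rna.coords, topo)
        assert vec.shape == (1, 7)

    def test_chain_of_n_gives_n_minus_one(self, rna5, rna5_topo):
        vec, _ = compute_suite_vectors(rna5.coords, rna5_topo)
        assert vec.shape == (4, 7)

    def test_angles_match_independent_dihedral_oracle(self, rna5,
                                                      rna5_topo):
        def oracle(p0, p1, p2, p3):
            # projection-plane formulation, independent of the
            # cross-product/atan2 route used by the implementation
            b = p2 - p1
            b = b / np.linalg.norm(b)
            u = (p0 - p1) - np.dot(p0 - p1, b) * b
            v = (p3 - p2) - np.dot(p3 - p2, b) * b
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            return np.sign(np.dot(np.cross(u, v), b)) * ang

        vec, _ = compute_suite_vectors(rna5.coords, rna5_topo)
        for s, quads in enumerate(rna5_topo.suite_idx):
            for k, quad in enumerate(quads):
                ref = oracle(*[rna5.coords[q] for q in quad])
                assert abs(wrap_angle(vec[s, k] - ref)) < 1e-6


class TestAssignment:
    def test_vector_at_center_scores_one(self, suite_library):
        v = suite_library.centers[7].reshape(1, 7)
        asg = assign_suites(v, suite_library)
        assert asg.nearest[0] == 7
        assert asg.suiteness[0] == pytest.approx(1.0, abs=1e-12)
        rep = suite_loss(v, suite_library)
        assert rep.loss < 1e-12

    def test_far_vector_is_outlier_but_contributes_gradient(
            self, suite_library):
        v = suite_library.centers[0] + np.array([90, 120, 100, 110, 95,
                                                 100, 90.0])
        rep = suite_loss(v.reshape(1, 7), suite_library)
        assert rep.assignment.suiteness[0] < suite_library.score_floor
        assert rep.assignment.outlier[0]
        assert np.abs(rep.dvectors).max() > 0     # still trains

    def test_argmin_matches_brute_force(self, suite_library):
        rng = np.random.default_rng(5)
        vecs = rng.uniform(-180, 180, size=(40, 7))
        asg = assign_suites(vecs, suite_library)
        for v, got in zip(vecs, asg.nearest):
            d = [np.sqrt(np.mean((wrap_angle(v - c)
                                  / suite_library.widths) ** 2))
                 for c in suite_library.centers]
            assert int(np.argmin(d)) == got

    def test_periodicity(self, suite_library):
        rng = np.random.default_rng(6)
        v = rng.uniform(-180, 180, size=(1, 7))
        a = assign_suites(v, suite_library)
        b = assign_suites(v + 360.0, suite_library)
        assert a.nearest[0] == b.nearest[0]
        assert a.suiteness[0] == pytest.approx(b.suiteness[0], abs=1e-12)

    def test_reported_mean_excludes_outliers(self, suite_library):
        near = suite_library.centers[3] + 5.0
        far = suite_library.centers[3] + 120.0
        rep = suite_loss(np.vstack([near, far]), suite_library)
        solo = suite_loss(near.reshape(1, 7), suite_library)
        assert rep.mean_score == pytest.approx(solo.mean_score, abs=1e-12)

    def test_mean_score_improves_toward_center(self, suite_library):
        c = suite_library.centers[2]
        a = suite_loss((c + 12.0).reshape(1, 7), suite_library)
        b = suite_loss((c + 6.0).reshape(1, 7), suite_library)
        assert b.mean_score > a.mean_score


class TestLossOnCoords:
    def test_gradient_matches_finite_differences(self, rna5, rna5_topo,
                                                 suite_library):
        rep = suite_loss_on_coords(rna5.coords, rna5_topo, suite_library)
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(10):
            a = rng.integers(0, rna5.n_atoms)
            k = rng.integers(0, 3)
            p = rna5.coords.copy()
            p[a, k] += 1e-5
            lp = suite_loss_on_coords(p, rna5_topo, suite_library).loss
            p[a, k] -= 2e-5
            lm = suite_loss_on_coords(p, rna5_topo, suite_library).loss
            fd = (lp - lm) / 2e-5
            if abs(fd) > 1e-8:
                assert abs(fd - rep.grad[a, k]) / abs(fd) < 1e-3
                checked += 1
        assert checked > 0

    def test_library_has_46_distinct_centers(self, suite_library):
        assert len(suite_library.names) == 46
        assert len(set(suite_library.names)) == 46
        d = np.linalg.norm(wrap_angle(
            suite_library.centers[:, None] - suite_library.centers[None]),
            axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 1.0
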