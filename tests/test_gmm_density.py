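"""Projections, FRC properties, and the map-model similarity machinery."""

import numpy as np
import pytest

import gmmrefine as g
from gmmrefine.gmm_density import (FRCSpec, GaussianMixture, ProjectionImage,
                                   euler_to_matrix, frc_score,
                                   frc_score_with_grad, project_gmm,
                                   project_gmm_with_grad, project_map,
                                   voxelize_gmm)

RNG = np.random.default_rng(7)


def _random_gmm(n=10, lo=8, hi=24, sigma=1.8):
    return GaussianMixture(RNG.uniform(lo, hi, size=(n, 3)), np.ones(n),
                           np.full(n, sigma))


class TestProjectGmm:
    def test_single_gaussian_symmetry_and_mass(self):
        # at the rotation center, so any orientation leaves it in place
        gmm = GaussianMixture([[15.5, 15.5, 15.5]], [2.0], [2.0])
        img = project_gmm(gmm, euler_to_matrix((0.3, 0.7, 0.1)), None, 32,
                          1.0, origin=np.zeros(3))
        assert np.allclose(img.data, img.data.T, atol=1e-12)
        total = img.data.sum()
        expected = 2.0 * (2 * np.pi) ** 1.5 * 2.0 ** 3
        assert abs(total - expected) / expected < 0.01

    def test_z_stack_additivity(self):
        a = GaussianMixture([[16, 16, 10], [16, 16, 22]], [1.0, 1.0],
                            [1.5, 1.5])
        b = GaussianMixture([[16, 16, 16]], [2.0], [1.5])
        ia = project_gmm(a, np.eye(3), None, 32, 1.0, origin=np.zeros(3))
        ib = project_gmm(b, np.eye(3), None, 32, 1.0, origin=np.zeros(3))
        assert np.allclose(ia.data, ib.data, atol=1e-9)

    def test_matches_voxelized_oracle(self):
        gmm = _random_gmm()
        img = project_gmm(gmm, np.eye(3), None, 32, 1.0,
                          origin=np.zeros(3))
        oracle = voxelize_gmm(gmm, 32, 1.0, origin=np.zeros(3)) \
            .data.sum(axis=2)
        rmse = np.sqrt(np.mean((img.data - oracle) ** 2))
        assert rmse < 0.01 * oracle.max()


class TestProjectMap:
    def test_identity_is_axis_sum(self):
        data = RNG.normal(size=(16, 16, 16))
        dmap = g.DensityMap(data, 1.0)
        img = project_map(dmap, np.eye(3))
        assert np.allclose(img.data, data.sum(axis=2), atol=1e-9)

    def test_zero_map_zero_projection(self):
        dmap = g.DensityMap(np.zeros((16, 16, 16)), 1.0)
        img = project_map(dmap, euler_to_matrix((0.5, 0.4, 0.3)))
        assert np.all(img.data == 0)

    def test_rotation_composition(self):
        gmm = _random_gmm(n=6, lo=10, hi=22, sigma=2.5)
        dmap = voxelize_gmm(gmm, 32, 1.0, origin=np.zeros(3))
        R0 = euler_to_matrix((0.4, 0.3, 0.0))
        R1 = euler_to_matrix((0.0, 0.5, 0.2))
        # oracle: rotate the mixture itself, voxelize, project at R1
        cen = dmap.center
        rot_gmm = GaussianMixture((gmm.centers - cen) @ R0.T + cen,
                                  gmm.amplitudes, gmm.widths)
        rot_map = voxelize_gmm(rot_gmm, 32, 1.0, origin=np.zeros(3))
        a = project_map(rot_map, R1)
        b = project_map(dmap, R1 @ R0)
        err = np.sqrt(np.mean((a.data - b.data) ** 2))
        assert err < 0.02 * np.abs(a.data).max()


class TestFRC:
    spec = FRCSpec(cutoff_res=2.5)

    def _img(self, data):
        return ProjectionImage(np.asarray(data, float), np.eye(3),
                               np.zeros(2), 1.0)

    def test_identity(self):
        x = self._img(RNG.normal(size=(32, 32)))
        assert frc_score(x, x, self.spec) == pytest.approx(1.0, abs=1e-12)

    def test_scale_and_offset_invariance(self):
        x = RNG.normal(size=(32, 32))
        a = self._img(x)
        b = self._img(2.0 * x + 3.0)
        assert frc_score(a, b, self.spec) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        a = self._img(RNG.normal(size=(32, 32)))
        b = self._img(RNG.normal(size=(32, 32)))
        assert abs(frc_score(a, b, self.spec)
                   - frc_score(b, a, self.spec)) < 1e-12

    def test_common_inplane_rotation_invariance(self):
        x = RNG.normal(size=(32, 32))
        y = RNG.normal(size=(32, 32))
        s0 = frc_score(self._img(x), self._img(y), self.spec)
        s1 = frc_score(self._img(np.rot90(x)), self._img(np.rot90(y)),
                       self.spec)
        assert abs(s0 - s1) < 1e-9

    def test_lowpass_invariance_below_cutoff(self):
        """Per-ring normalization makes the score blind to filtering: a
        Gaussian falloff low-pass (sampled at the ring radii, so the
        attenuation is a pure per-ring scaling) leaves the FRC at exactly 1
        below the cutoff."""
        from gmmrefine.gmm_density import _ring_labels

        x = RNG.normal(size=(48, 48))
        spec = FRCSpec(cutoff_res=4.0)
        labels, n_rings = _ring_labels(48, 1.0, spec)
        filt = np.exp(-np.maximum(labels, 0) ** 2 / (2 * 8.0 ** 2))
        y = np.real(np.fft.ifft2(np.fft.fft2(x) * filt))
        s = frc_score(self._img(x), self._img(y), spec)
        assert abs(s - 1.0) < 1e-6

    def test_zero_power_ring_defined_as_zero(self):
        a = self._img(np.zeros((32, 32)))
        b = self._img(RNG.normal(size=(32, 32)))
        s = frc_score(a, b, self.spec)
        assert np.isfinite(s) and s == 0.0

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            FRCSpec(cutoff_res=1.0).validate(pixel_size=1.0)


class TestSelfConsistency:
    def test_gmm_vs_simulated_map_frc(self, helix):
        dmap = g.simulate_map(helix, 4.0, 1.0)
        gmm = g.gmm_from_model(helix, 4.0)
        R = euler_to_matrix((0.3, 0.9, 0.4))
        ig = project_gmm(gmm, R, None, dmap.npix, dmap.voxel_size,
                         origin=dmap.origin, center=dmap.center)
        im = project_map(dmap, R)
        spec = FRCSpec(cutoff_res=1.5 * 2 * dmap.voxel_size)
        curve = g.frc_curve(ig, im, spec)
        assert np.all(curve >= 0.999)
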