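"""Decoder stack, patching, weight balancing and single-model refinement."""

import numpy as np
import pytest

import gmmrefine as g
from gmmrefine.refine_single import (DecoderStack, RefinementConfig,
                                     balance_rule, make_patches, refine,
                                     score_model)


@pytest.fixture(scope="module")
def small_cfg():
    return RefinementConfig(resolution=4.0, patch_count=6,
                            iterations=(80, 60, 80), seed=0, width=32,
                            rebuild_rotamers=False)


def _stack(model, k=6, active=("d1", "d2", "d3"), seed=0):
    heavy = model.heavy_model()
    pa = make_patches(heavy, k, seed)
    st = DecoderStack(heavy.coords, pa, 4, 32, seed)
    st.attach_residues(heavy)
    st.active = set(active)
    return heavy, st


class TestPatches:
    def test_one_patch_per_residue_when_k_equals_n(self, helix):
        pa = make_patches(helix, len(helix.residues), seed=0)
        assert len(set(pa.residue_patch)) == len(helix.residues)

    def test_atoms_follow_their_residue(self, helix):
        pa = make_patches(helix, 4, seed=0)
        for ri, res in enumerate(helix.residues):
            assert np.all(pa.atom_patch[res.atom_idx]
                          == pa.residue_patch[ri])

    def test_patch_sizes_balanced_on_uniform_helix(self):
        m = g.make_peptide(24, kind="helix")
        pa = make_patches(m, 4, seed=0)
        sizes = np.bincount(pa.residue_patch)
        assert sizes.max() <= 3 * sizes.mean()

    def test_k_clamped_to_residue_count(self, helix):
        pa = make_patches(helix, 99, seed=0)
        assert pa.k == len(helix.residues)


class TestDecoderStack:
    def test_zero_output_identity_bit_for_bit(self, helix):
        heavy, st = _stack(helix)
        coords, logamp, logsig, _ = st.emit(np.ones(4))
        assert np.array_equal(coords, heavy.coords)
        assert np.all(logamp == 0) and np.all(logsig == 0)

    def test_patch_transforms_preserve_intra_patch_geometry(self, helix):
        heavy, st = _stack(helix, active=("d1",))
        rng = np.random.default_rng(0)
        st.d1.W[-1][:] = rng.normal(scale=0.1, size=st.d1.W[-1].shape)
        st.d1.b[-1][:] = rng.normal(scale=0.2, size=st.d1.b[-1].shape)
        coords, _, _, _ = st.emit(np.ones(4))
        topo = g.compile_topology(heavy)
        pa = st.patches
        for (i, j), mean in zip(topo.bond_idx, topo.bond_mean):
            if pa.atom_patch[i] == pa.atom_patch[j]:
                before = np.linalg.norm(heavy.coords[i] - heavy.coords[j])
                after = np.linalg.norm(coords[i] - coords[j])
                assert abs(before - after) < 1e-9

    def test_displacement_cap(self, helix):
        heavy, st = _stack(helix, active=("d3",))
        st.d3.b[-1][:] = 10.0
        st.max_displacement = 0.3
        coords, _, _, _ = st.emit(np.ones(4))
        disp = np.linalg.norm(coords - heavy.coords, axis=1)
        assert disp.max() <= 0.3 + 1e-9

    def test_backward_matches_finite_differences(self, helix):
        heavy, st = _stack(helix, k=3, active=("d1",))
        rng = np.random.default_rng(1)
        st.d1.b[-1][:] = rng.normal(scale=0.1, size=st.d1.b[-1].shape)
        conf = np.ones(4)
        target = rng.normal(size=heavy.coords.shape)

        def loss():
            c = st.emit(conf)[0]
            return 0.5 * np.sum((c - target) ** 2)

        coords, _, _, cache = st.emit(conf)
        grads = st.backward(cache, coords - target)
        gb = grads["d1"][len(st.d1.W):][-1]      # last-layer bias gradient
        for idx in rng.choice(len(gb), size=6, replace=False):
            st.d1.b[-1][idx] += 1e-6
            lp = loss()
            st.d1.b[-1][idx] -= 2e-6
            lm = loss()
            st.d1.b[-1][idx] += 1e-6
            fd = (lp - lm) / 2e-6
            if abs(fd) > 1e-8:
                assert abs(fd - gb[idx]) / abs(fd) < 1e-4


class TestBalanceRule:
    def test_reciprocal_arithmetic(self):
        wb = balance_rule(0.10, 0.05)
        assert wb.ratio == pytest.approx(2.0)
        assert wb.geometry_weight == pytest.approx(0.5)
        assert not wb.fallback

    def test_degenerate_falls_back(self):
        wb = balance_rule(0.10, 0.0)
        assert wb.fallback and wb.geometry_weight == 1.0


class TestRefine:
    def test_self_consistency_identity(self, small_cfg):
        """Refining against a map simulated from the model itself must not
        move it or degrade its geometry."""
        m = g.make_peptide(10, kind="helix")
        dmap = g.simulate_map(m, 4.0, 1.0)
        out, rep = refine(m, dmap, small_cfg)
        heavy = m.heavy_model()
        rmsd = np.sqrt(np.mean(np.sum((out.coords - heavy.coords) ** 2,
                                      axis=1)))
        assert rmsd < 0.1
        final = rep["final"]
        assert final["bond_outliers"] == 0
        assert final["angle_outliers"] == 0

    def test_reproducible_under_fixed_seed(self, small_cfg):
        m = g.make_peptide(8, kind="helix")
        dmap = g.simulate_map(m, 4.0, 1.0)
        a, _ = refine(m, dmap, small_cfg)
        b, _ = refine(m, dmap, small_cfg)
        assert np.array_equal(a.coords, b.coords)

    def test_geometry_only_mode_runs_without_map(self, small_cfg):
        m = g.make_peptide(6, kind="helix")
        pert = g.perturb_model(m, sigma=0.05, seed=2)
        cfg = RefinementConfig(resolution=4.0, patch_count=3,
                               iterations=(0, 0, 150), seed=0, width=32,
                               geometry_only=True, rebuild_rotamers=False)
        out, rep = refine(pert, None, cfg)
        before = score_model(pert, None, 4.0)
        after = rep["final"]
        assert after["geometry_loss"] <= before["geometry_loss"]


class TestScoreModel:
    def test_ideal_fixture_all_zero(self, helix):
        metrics = score_model(helix, None, 4.0)
        assert metrics["bond_outliers"] == 0
        assert metrics["angle_outliers"] == 0
        assert metrics["planarity_outliers"] == 0
        assert metrics["rama_outlier_fraction"] == 0.0
        assert metrics["clash_count"] == 0

    def test_compressed_bond_detected(self, helix):
        coords = helix.coords.copy()
        topo = g.compile_topology(helix)
        i, j = topo.bond_idx[0]
        direction = coords[j] - coords[i]
        coords[j] -= 0.2 * direction / np.linalg.norm(direction)
        metrics = score_model(helix.with_coords(coords), None, 4.0)
        assert metrics["bond_outliers"] == 1
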