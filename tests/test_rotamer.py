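"""Rotamer mixture fitting, chi scoring, re-posing and rebuild."""

import numpy as np
import pytest

import gmmrefine as g
from gmmrefine.geom_scores import dihedrals_with_grad, wrap_angle
from gmmrefine.rotamer import (DegenerateHistogramError, OUTLIER_SCORE,
                               attach_chi_res_types, fit_rotamer_gmm,
                               rebuild_rotamers, rotamer_loss, set_chi)


class TestFit:
    def test_2d_three_peak_recovery(self):
        peaks = [([-60.0, 175.0], 12.0, 1.0), ([60.0, -60.0], 12.0, 0.7),
                 ([180.0, 60.0], 12.0, 0.5)]
        hist = g.make_rotamer_histogram("LEU", 2, peaks=peaks)
        gmm = fit_rotamer_gmm(hist, "LEU", n_components=6, n_iter=80)
        top = gmm.centers[np.argsort(-gmm.weights)[:3]]
        for center, _, _ in peaks:
            d = np.min(np.linalg.norm(wrap_angle(top - np.array(center)),
                                      axis=1))
            assert d < 5.0

    def test_1d_single_peak_center(self):
        hist = g.make_rotamer_histogram("SER", 1,
                                        peaks=[([60.0], 14.0, 1.0)])
        gmm = fit_rotamer_gmm(hist, "SER", n_components=2, n_iter=80)
        best = gmm.centers[np.argmax(gmm.weights), 0]
        assert abs(wrap_angle(best - 60.0)) < 2.0

    def test_empty_histogram_degenerate(self):
        hist = g.RotamerHistogram("LEU", 10.0, np.zeros((36, 36)))
        with pytest.raises(DegenerateHistogramError):
            fit_rotamer_gmm(hist, "LEU")

    def test_text_round_trip(self):
        hist = g.make_rotamer_histogram("LEU", 2, step=20.0)
        back = g.RotamerHistogram.from_text(hist.to_text())
        assert back.res_type == "LEU" and back.d == 2
        assert np.allclose(back.values, hist.values, atol=1e-5)


class TestLoss:
    def test_stationary_at_component_center(self, leu_rotamer_gmm):
        _, gmm = leu_rotamer_gmm
        center = gmm.centers[np.argmax(gmm.weights)]
        _, dchis = rotamer_loss([center], ["LEU"], {"LEU": gmm})
        assert np.abs(dchis[0]).max() < 1e-4

    def test_periodicity(self, leu_rotamer_gmm):
        _, gmm = leu_rotamer_gmm
        chi = np.array([-75.0, 160.0])
        r1, _ = rotamer_loss([chi], ["LEU"], {"LEU": gmm})
        r2, _ = rotamer_loss([chi + 360.0], ["LEU"], {"LEU": gmm})
        assert r1.loss == pytest.approx(r2.loss, abs=1e-12)

    def test_outlier_count_matches_lookup(self, leu_rotamer_gmm):
        hist, gmm = leu_rotamer_gmm
        rng = np.random.default_rng(9)
        chis = rng.uniform(-180, 180, size=(50, 2))
        rep, _ = rotamer_loss(list(chis), ["LEU"] * 50, {"LEU": gmm})
        oracle = hist.lookup(chis) < OUTLIER_SCORE
        mine = rep.scores < OUTLIER_SCORE
        # disagreement only in boundary cells where the two representations
        # straddle the threshold
        mismatch = mine != oracle
        assert mismatch.mean() <= 0.06
        for i in np.flatnonzero(mismatch):
            assert min(rep.scores[i], hist.lookup(chis[i])[0]) \
                < 5 * OUTLIER_SCORE

    def test_missing_sidechain_excluded(self, leu_rotamer_gmm):
        _, gmm = leu_rotamer_gmm
        rep, dchis = rotamer_loss([None, np.array([-60.0, 180.0])],
                                  ["LEU", "LEU"], {"LEU": gmm})
        assert rep.n_residues == 1 and dchis[0] is None


class TestReposing:
    def test_set_chi_round_trip(self):
        m = g.make_peptide(3, sequence=["ALA", "LEU", "ALA"])
        topo = g.compile_topology(m)
        target = np.array([-72.0, 155.0])
        coords = set_chi(m.coords, topo, 0, target)
        got = dihedrals_with_grad(coords, topo.chi_idx[0])[0]
        assert np.allclose(wrap_angle(got - target), 0.0, atol=1e-8)

    def test_set_chi_preserves_bonds(self):
        m = g.make_peptide(3, sequence=["ALA", "LEU", "ALA"])
        topo = g.compile_topology(m)
        from gmmrefine.geom_scores import bond_vectors
        _, r0 = bond_vectors(m.coords, topo.bond_idx)
        coords = set_chi(m.coords, topo, 0, np.array([55.0, -60.0]))
        _, r1 = bond_vectors(coords, topo.bond_idx)
        assert np.allclose(r0, r1, atol=1e-9)

    def test_chi_sign_convention_vs_independent_oracle(self):
        import biotite.structure as struc

        rng = np.random.default_rng(2)
        m = g.make_peptide(3, sequence=["ALA", "LEU", "ALA"])
        topo = g.compile_topology(m)
        for seed in range(20):
            coords = m.coords + rng.normal(scale=0.05,
                                           size=m.coords.shape)
            chi = dihedrals_with_grad(coords, topo.chi_idx[0])[0]
            for j, quad in enumerate(topo.chi_idx[0]):
                ref = np.degrees(struc.dihedral(*[coords[q] for q in
                                                  quad]))
                # biotite computes in float32
                assert abs(wrap_angle(chi[j] - ref)) < 1e-4


class TestRebuild:
    def test_flat_map_falls_back_to_library_peak(self, leu_rotamer_gmm):
        _, gmm = leu_rotamer_gmm
        m = g.make_peptide(3, sequence=["ALA", "LEU", "ALA"])
        topo = g.compile_topology(m)
        attach_chi_res_types(topo, m)
        start = m.with_coords(set_chi(m.coords, topo, 0,
                                      np.array([-100.0, 100.0])))
        flat = g.DensityMap(np.zeros((16, 16, 16)), 1.0)
        out, _ = rebuild_rotamers(start, flat, {"LEU": gmm}, topo=topo)
        chi = dihedrals_with_grad(out.coords, topo.chi_idx[0])[0]
        peaks = gmm.peak_centers()
        dmin = min(np.abs(wrap_angle(chi - p)).max() for p in peaks)
        assert dmin < 1.0

    def test_no_chi_residues_untouched(self, leu_rotamer_gmm):
        _, gmm = leu_rotamer_gmm
        m = g.make_peptide(3, sequence=["ALA", "GLY", "ALA"])
        topo = g.compile_topology(m)
        attach_chi_res_types(topo, m)
        flat = g.DensityMap(np.zeros((16, 16, 16)), 1.0)
        out, info = rebuild_rotamers(m, flat, {"LEU": gmm}, topo=topo)
        assert np.array_equal(out.coords, m.coords)
        assert info == []

    def test_rebuild_never_emits_outlier_chi(self, leu_rotamer_gmm):
        _, gmm = leu_rotamer_gmm
        m = g.make_peptide(3, sequence=["ALA", "LEU", "ALA"])
        topo = g.compile_topology(m)
        attach_chi_res_types(topo, m)
        truth = set_chi(m.coords, topo, 0, gmm.peak_centers()[0])
        dmap = g.simulate_map(m.with_coords(truth), 2.5, 0.7)
        start = m.with_coords(set_chi(m.coords, topo, 0,
                                      np.array([-100.0, 100.0])))
        out, _ = rebuild_rotamers(start, dmap, {"LEU": gmm}, topo=topo)
        chi = dihedrals_with_grad(out.coords, topo.chi_idx[0])[0]
        assert gmm.score(chi.reshape(1, -1))[0] >= gmm.outlier_score
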