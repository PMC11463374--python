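"""Steric clash detection: thresholds, H-bond relaxation, neighbor lists."""

import numpy as np
import pytest

import gmmrefine as g
from gmmrefine.clash import (all_pairs_clash_loss, build_neighbor_list,
                             clash_loss, NeighborList)
from gmmrefine.model_io import MolecularModel, CompiledTopology


def _two_atom_model(elements, dist):
    return MolecularModel(elements, ["X1", "X2"], ["UNK", "UNK"], [1, 2],
                          ["A", "A"],
                          [[0, 0, 0], [dist, 0, 0]],
                          is_hydrogen=[e == "H" for e in elements])


def _empty_topo(n):
    z = np.zeros
    return CompiledTopology(
        bond_idx=z((0, 2), int), bond_mean=z(0), bond_std=z(0),
        angle_idx=z((0, 3), int), angle_mean=z(0), angle_std=z(0),
        planar_idx=z((0, 4), int), planar_class=np.asarray([], object),
        phi_idx=z((0, 4), int), psi_idx=z((0, 4), int),
        omega_prev_idx=z((0, 4), int), rama_residues=z(0, int),
        rama_class=np.asarray([], object), chi_idx=[],
        chi_residues=z(0, int), chi_rotating=[],
        suite_idx=z((0, 7, 4), int), suite_residues=z(0, int),
        exclusion_pairs=z((0, 2), int), bond_graph=[[] for _ in range(n)])


class TestNeighborList:
    def test_unbonded_pair_listed(self):
        m = _two_atom_model(["C", "C"], 3.0)
        nl = build_neighbor_list(m.coords, _empty_topo(2))
        assert len(nl.pairs) == 1

    def test_bonded_pair_excluded(self, helix, helix_topo):
        nl = build_neighbor_list(helix.coords, helix_topo)
        listed = {(int(i), int(j)) for i, j in nl.pairs}
        for i, j in helix_topo.bond_idx:
            key = (min(int(i), int(j)), max(int(i), int(j)))
            assert key not in listed

    def test_matches_brute_force_on_random_packing(self):
        rng = np.random.default_rng(0)
        n = 300
        coords = rng.uniform(0, 20, size=(n, 3))
        topo = _empty_topo(n)
        nl = build_neighbor_list(coords, topo, cutoff=6.0)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        ii, jj = np.triu_indices(n, k=1)
        brute = {(int(i), int(j)) for i, j in zip(ii, jj)
                 if d[i, j] <= 6.0}
        assert {(int(i), int(j)) for i, j in nl.pairs} == brute


class TestClashThresholds:
    def test_carbon_pair_around_threshold(self):
        # two carbons: threshold 1.70 + 1.70 - 0.4 = 3.0 A
        topo = _empty_topo(2)
        near = _two_atom_model(["C", "C"], 3.01)
        nl = build_neighbor_list(near.coords, topo)
        assert clash_loss(near.coords, nl, near, topo).clash_count == 0
        over = _two_atom_model(["C", "C"], 2.99)
        rep = clash_loss(over.coords, nl, over, topo)
        assert rep.clash_count == 1
        assert rep.overlaps[0] == pytest.approx(0.01, abs=1e-9)

    def test_hbond_relaxation(self):
        # H...O threshold without relaxation: 1.17 + 1.40 - 0.4 = 2.17;
        # relaxed by another 0.4 to 1.77.  An 0.2 A would-be overlap is
        # therefore not a clash for the H-bond pairing.
        topo = _empty_topo(2)
        m = _two_atom_model(["H", "O"], 2.17 - 0.2)
        nl = build_neighbor_list(m.coords, topo)
        rep = clash_loss(m.coords, nl, m, topo)
        assert rep.clash_count == 0
        # same geometry for H...C is a clash (threshold 1.17+1.70-0.4=2.47)
        m2 = _two_atom_model(["H", "C"], 2.47 - 0.2)
        rep2 = clash_loss(m2.coords, build_neighbor_list(m2.coords, topo),
                          m2, topo)
        assert rep2.clash_count == 1

    def test_penalty_monotone_in_distance(self):
        topo = _empty_topo(2)
        last = None
        for dist in (3.2, 3.0, 2.8, 2.6, 2.4):
            m = _two_atom_model(["C", "C"], dist)
            nl = build_neighbor_list(m.coords, topo)
            p = clash_loss(m.coords, nl, m, topo).penalty
            if last is not None:
                assert p > last
            last = p


class TestOracleEquivalence:
    def test_neighbor_list_equals_all_pairs(self, helix_h):
        topo = g.compile_topology(helix_h)
        nl = build_neighbor_list(helix_h.coords, topo)
        a = clash_loss(helix_h.coords, nl, helix_h, topo)
        b = all_pairs_clash_loss(helix_h.coords, helix_h, topo)
        assert a.penalty == pytest.approx(b.penalty, abs=1e-9)
        assert a.clash_count == b.clash_count

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        n = 20
        coords = rng.uniform(0, 8, size=(n, 3))
        m = MolecularModel(["C"] * n, [f"C{i}" for i in range(n)],
                           ["UNK"] * n, list(range(n)), ["A"] * n, coords)
        topo = _empty_topo(n)
        nl = build_neighbor_list(coords, topo)
        rep = clash_loss(coords, nl, m, topo)
        checked = 0
        for _ in range(10):
            a, k = rng.integers(0, n), rng.integers(0, 3)
            p = coords.copy()
            p[a, k] += 1e-6
            lp = clash_loss(p, nl, m, topo).penalty
            p[a, k] -= 2e-6
            lm = clash_loss(p, nl, m, topo).penalty
            fd = (lp - lm) / 2e-6
            if abs(fd) > 1e-6:
                assert abs(fd - rep.grad[a, k]) / abs(fd) < 1e-3
                checked += 1
        assert checked > 0
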