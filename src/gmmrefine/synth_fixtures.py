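"""Synthetic test inputs at toy scale: ideal-geometry peptides and RNA,
perturbed variants, simulated density maps, synthetic Ramachandran/rotamer
histograms, and two-state conformational series.

Backbones are built by internal-coordinate chaining (NeRF) using exactly
the ideal bond lengths and angles the geometry dictionary restrains, and
sidechains/bases are grafted on by rigid superposition of the ideal
component coordinates, so freshly generated models score zero geometry
outliers by construction.  All randomness is controlled by explicit seeds
and generation is pure: the same spec always yields the same atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gmm_density import DensityMap, gmm_from_model, voxelize_gmm
from .model_io import (GeometryDictionary, MolecularModel,
                       default_dictionary, place_from_internal)
from .rama import RamaHistogram
from .rotamer import RotamerHistogram

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)
#: link torsions (epsilon, zeta, alpha) for the RNA fixture; near A-form
#: values, adjusted so the ideal-component sugar conformation chains into a
#: clash-free strand
A_FORM_EZA = (-148.0, -90.0, -90.0)


@dataclass
class FixtureSpec:
    kind: str = "helix"          # helix | strand | mixed-peptide | rna |
                                 # rna-duplex | two-state-series
    n_residues: int = 12
    sequence: list | None = None
    perturb_sigma: float = 0.0
    hinge_residue: int | None = None
    hinge_rotation: float = 8.0  # degrees between the two end states
    map_resolution: float = 4.0
    voxel_size: float = 1.0
    seed: int = 0


def make_fixture(spec: FixtureSpec):
    if spec.kind in ("helix", "strand", "mixed-peptide"):
        return make_peptide(spec.n_residues, kind=spec.kind,
                            sequence=spec.sequence, seed=spec.seed)
    if spec.kind in ("rna", "rna-duplex"):
        return make_rna(spec.n_residues,
                        n_strands=2 if spec.kind == "rna-duplex" else 1)
    if spec.kind == "two-state-series":
        return make_two_state(spec)
    raise ValueError(f"unsupported fixture kind: {spec.kind}")


# ---------------------------------------------------------------------------
# peptides
# ---------------------------------------------------------------------------

def _kabsch(P, Q):
    """Rigid transform (R, t) minimizing |R P + t - Q|."""
    Pc, Qc = P.mean(0), Q.mean(0)
    H = (P - Pc).T @ (Q - Qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, Qc - R @ Pc


def _bond_len(chem, a, b):
    for x, y, mean in chem.heavy_bonds:
        if {x, y} == {a, b}:
            return mean
    raise KeyError(f"no bond {a}-{b}")


def _angle_mean(chem, a, b, c):
    for x, y, z, mean in chem.heavy_angles:
        if y == b and {x, z} == {a, c}:
            return mean
    raise KeyError(f"no angle {a}-{b}-{c}")


def make_peptide(n_residues: int, kind: str = "helix",
                 sequence: list | None = None, seed: int = 0,
                 phi_psi: tuple | None = None, chain_id: str = "A",
                 gdict: GeometryDictionary | None = None) -> MolecularModel:
    """Ideal-geometry peptide with canonical backbone dihedrals.

    Default sequence is polyalanine; ``kind='mixed-peptide'`` cycles through
    a small set of residue types exercising sidechain chemistry.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    if gdict is None:
        gdict = default_dictionary()
    if sequence is None:
        if kind == "mixed-peptide":
            pool = ["ALA", "LEU", "SER", "GLY", "VAL", "PHE"]
            sequence = [pool[i % len(pool)] for i in range(n_residues)]
        else:
            sequence = ["ALA"] * n_residues
    for rt in sequence:
        chem = gdict.chem(rt)
        if chem is None or not {"N", "CA", "C", "O"} <= set(chem.neighbors):
            raise ValueError(f"unsupported residue type {rt}")
    if phi_psi is None:
        # mixed sequences use the extended backbone so bulky sidechains at
        # ideal component conformations stay clash-free
        phi_psi = HELIX_PHI_PSI if kind == "helix" else STRAND_PHI_PSI
    phi0, psi0 = phi_psi
    lk = gdict.links["peptide"]
    len_cn = lk["bond"][2]
    ang_cacn = lk["angles"][0][3]
    ang_cnca = lk["angles"][2][3]

    element, name, res_type, res_index, coords = [], [], [], [], []
    prev = None                    # (N, CA, C) coordinates of residue i-1
    for i, rt in enumerate(sequence):
        chem = gdict.chem(rt)
        n_ca = _bond_len(chem, "N", "CA")
        ca_c = _bond_len(chem, "CA", "C")
        ang_ncac = _angle_mean(chem, "N", "CA", "C")
        if prev is None:
            N = np.zeros(3)
            CA = N + np.array([n_ca, 0.0, 0.0])
            th = np.radians(180.0 - ang_ncac)
            C = CA + ca_c * np.array([np.cos(th), np.sin(th), 0.0])
        else:
            pN, pCA, pC = prev
            N = place_from_internal(pN, pCA, pC, len_cn, ang_cacn, psi0)
            CA = place_from_internal(pCA, pC, N, n_ca, ang_cnca, 180.0)
            C = place_from_internal(pC, N, CA, ca_c, ang_ncac, phi0)
        # carbonyl O: anti to the next amide nitrogen
        chem_o = _bond_len(chem, "C", "O")
        ang_caco = _angle_mean(chem, "CA", "C", "O")
        O = place_from_internal(N, CA, C, chem_o, ang_caco, psi0 + 180.0)
        res_atoms = [("N", "N", N), ("CA", "C", CA), ("C", "C", C),
                     ("O", "O", O)]
        # graft the sidechain by rigid superposition on (N, CA, C)
        ideal = chem.ideal_coords
        R, t = _kabsch(np.array([ideal["N"], ideal["CA"], ideal["C"]]),
                       np.array([N, CA, C]))
        for an in chem.atom_names:
            if an in ("N", "CA", "C", "O", "OXT") or chem.elements[an] == "H":
                continue
            res_atoms.append((an, chem.elements[an], R @ ideal[an] + t))
        for an, el, pos in res_atoms:
            element.append(el)
            name.append(an)
            res_type.append(rt)
            res_index.append(i + 1)
            coords.append(pos)
        prev = (N, CA, C)
    model = MolecularModel(element, name, res_type, res_index,
                           [chain_id] * len(name), np.array(coords))
    return _pose_canonical_rotamers(model, gdict)


#: canonical sidechain rotamers used by the generator (degrees)
_CANONICAL_CHI = {"LEU": (-70.0, 160.0), "VAL": (175.0,),
                  "ILE": (-60.0, 170.0), "PHE": (-65.0, 85.0),
                  "TYR": (-65.0, 85.0), "TRP": (-65.0, 95.0),
                  "SER": (-65.0,), "THR": (60.0,), "CYS": (-65.0,)}
_DEFAULT_CHI = (-65.0, 175.0, -65.0, 175.0)


def _pose_canonical_rotamers(model: MolecularModel,
                             gdict: GeometryDictionary) -> MolecularModel:
    from .model_io import compile_topology
    from .rotamer import set_chi

    if not any(r.res_type in gdict.chi_defs for r in model.residues):
        return model
    topo = compile_topology(model, gdict)
    coords = model.coords
    for k, ri in enumerate(topo.chi_residues):
        rt = model.residues[ri].res_type
        if rt == "PRO":
            continue            # ring chi fixed by the sugar-like ring
        target = _CANONICAL_CHI.get(rt, _DEFAULT_CHI)
        d = len(topo.chi_idx[k])
        coords = set_chi(coords, topo, k, np.asarray(target[:d]))
    return model.with_coords(coords)


# ---------------------------------------------------------------------------
# RNA
# ---------------------------------------------------------------------------

def make_rna(n_residues: int, sequence: list | None = None,
             n_strands: int = 1, chain_id: str = "A",
             torsions: tuple = A_FORM_EZA,
             gdict: GeometryDictionary | None = None) -> MolecularModel:
    """Ideal A-form-like RNA strand(s) chained by internal coordinates.

    Each nucleotide keeps the ideal component geometry; successive residues
    are attached through the phosphodiester link using the given
    (epsilon, zeta, alpha) torsions.
    """
    if gdict is None:
        gdict = default_dictionary()
    if sequence is None:
        pool = ["A", "U", "G", "C"]
        sequence = [pool[i % 4] for i in range(n_residues)]
    eps, zeta, alpha = torsions
    lk = gdict.links["rna"]
    len_o3p = lk["bond"][2]
    ang_c3o3p = lk["angles"][0][3]
    ang_o3po5 = lk["angles"][1][3]

    element, name, res_type, res_index, chain, coords = [], [], [], [], [], []
    for strand in range(n_strands):
        cid = chr(ord(chain_id) + strand)
        prev = None          # dict of placed coords for residue i-1
        for i, rt in enumerate(sequence):
            chem = gdict.chem(rt)
            if chem is None:
                raise ValueError(f"unsupported nucleotide {rt}")
            ideal = chem.ideal_coords
            if prev is None:
                R, t = np.eye(3), np.array([strand * 18.0, 0.0, 0.0])
            else:
                P = place_from_internal(prev["C4'"], prev["C3'"],
                                        prev["O3'"], len_o3p, ang_c3o3p, eps)
                len_po5 = _bond_len(chem, "P", "O5'")
                O5 = place_from_internal(prev["C3'"], prev["O3'"], P,
                                         len_po5, ang_o3po5, zeta)
                len_o5c5 = _bond_len(chem, "O5'", "C5'")
                ang_po5c5 = _angle_mean(chem, "P", "O5'", "C5'")
                C5 = place_from_internal(prev["O3'"], P, O5, len_o5c5,
                                         ang_po5c5, alpha)
                R, t = _kabsch(np.array([ideal["P"], ideal["O5'"],
                                         ideal["C5'"]]),
                               np.array([P, O5, C5]))
            placed = {}
            for an in chem.atom_names:
                if chem.elements[an] == "H" or an == "OP3":
                    continue
                placed[an] = R @ ideal[an] + t
            if prev is not None:
                # rebuild the free phosphate oxygens around the P tetrahedron
                # so they stay clear of the incoming O3' ester direction
                from .geom_scores import dihedral_angles
                q = np.array([prev["O3'"], placed["P"], placed["O5'"],
                              placed["C5'"]])
                tau0 = dihedral_angles(
                    q[::-1], np.array([[0, 1, 2, 3]]))[0]
                for an2, dtau in (("OP1", 120.0), ("OP2", -120.0)):
                    placed[an2] = place_from_internal(
                        placed["C5'"], placed["O5'"], placed["P"],
                        _bond_len(chem, "P", an2),
                        _angle_mean(chem, "O5'", "P", an2), tau0 + dtau)
            for an, pos in placed.items():
                element.append(chem.elements[an])
                name.append(an)
                res_type.append(rt)
                res_index.append(i + 1)
                chain.append(cid)
                coords.append(pos)
            prev = placed
    return MolecularModel(element, name, res_type, res_index, chain,
                          np.array(coords))


# ---------------------------------------------------------------------------
# perturbations and two-state series
# ---------------------------------------------------------------------------

def perturb_model(model: MolecularModel, sigma: float = 0.3, seed: int = 0,
                  domain_shift: np.ndarray | None = None,
                  domain_start: int | None = None) -> MolecularModel:
    """Add per-atom Gaussian noise, optionally shifting a whole domain
    (all residues from ``domain_start`` on) coherently."""
    rng = np.random.default_rng(seed)
    coords = model.coords + rng.normal(scale=sigma, size=model.coords.shape)
    if domain_shift is not None and domain_start is not None:
        sel = model.res_index >= domain_start
        coords[sel] += np.asarray(domain_shift, float)
    return model.with_coords(coords)


def _rotation_about(axis, point, angle_deg):
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
    return R, point


def hinge_rotate(model: MolecularModel, hinge_residue: int,
                 angle_deg: float, ramp: int = 2) -> MolecularModel:
    """Rotate the domain beyond the hinge residue about an axis through the
    hinge CA, with a smooth per-residue ramp so local geometry stays within
    restraint tolerances."""
    ca = model.find_atom(model.chain_id[0], hinge_residue, "CA")
    if ca is None:
        raise ValueError("hinge residue has no CA")
    point = model.coords[ca]
    chain_dir = model.coords[-1] - model.coords[0]
    chain_dir /= np.linalg.norm(chain_dir)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(chain_dir, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    axis = np.cross(chain_dir, ref)
    axis /= np.linalg.norm(axis)
    coords = model.coords.copy()
    for res in model.residues:
        frac = np.clip((res.res_index - hinge_residue + ramp)
                       / (2.0 * ramp), 0.0, 1.0)
        if frac <= 0:
            continue
        R, p = _rotation_about(axis, point, angle_deg * frac)
        coords[res.atom_idx] = (coords[res.atom_idx] - p) @ R.T + p
    return model.with_coords(coords)


def make_two_state(spec: FixtureSpec):
    """Two-state hinge fixture: returns (state_a, state_b) models related by
    a smooth hinge rotation of ``hinge_rotation`` degrees."""
    base = make_peptide(spec.n_residues, kind="helix",
                        sequence=spec.sequence, seed=spec.seed)
    hinge = spec.hinge_residue or spec.n_residues // 2
    a = hinge_rotate(base, hinge, -spec.hinge_rotation / 2.0)
    b = hinge_rotate(base, hinge, +spec.hinge_rotation / 2.0)
    return a, b


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------

def simulate_map(model: MolecularModel, resolution: float,
                 voxel_size: float = 1.0, npix: int | None = None,
                 origin: np.ndarray | None = None, pad: float = 6.0
                 ) -> DensityMap:
    """Voxelized mixture density at the stated resolution.

    Resolution enters through the Gaussian width of the rendered atoms
    (which band-limits the map); no separate filter is applied because the
    per-ring normalization of the FRC makes any radial filter irrelevant.
    Consistent with the projection conventions, so the self-FRC of a model
    against its own simulated map is ~1 below the cutoff.
    """
    if resolution < 2 * voxel_size:
        raise ValueError("resolution finer than Nyquist for this voxel size")
    mask = model.refinable
    if not mask.any():
        n = npix or 16
        return DensityMap(np.zeros((n, n, n)), voxel_size,
                          origin if origin is not None else np.zeros(3))
    gmm = gmm_from_model(model, resolution)
    if npix is None or origin is None:
        lo = model.coords[mask].min(0) - pad
        hi = model.coords[mask].max(0) + pad
        if npix is None:
            npix = int(np.ceil((hi - lo).max() / voxel_size))
            npix += npix % 2
        if origin is None:
            center = (lo + hi) / 2.0
            origin = center - voxel_size * (npix - 1) / 2.0
    return voxelize_gmm(gmm, npix, voxel_size, origin)


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def make_rama_histogram(peaks=None, step: float = 4.0, floor: float = 1e-6,
                        residue_class: str = "General") -> RamaHistogram:
    """Periodic 2D histogram from a known Gaussian mixture plus a uniform
    floor, max-normalized to 1.  ``peaks`` is a list of
    (phi, psi, sigma_deg, weight); the default emulates the alpha/beta/
    left-handed regions."""
    if peaks is None:
        peaks = [(-63.0, -43.0, 12.0, 1.0), (-120.0, 130.0, 18.0, 0.8),
                 (-150.0, 155.0, 14.0, 0.5), (57.0, 40.0, 10.0, 0.25),
                 (-90.0, -10.0, 11.0, 0.3)]
    n = int(round(360.0 / step))
    ax = -180.0 + step * np.arange(n)
    P, Q = np.meshgrid(ax, ax, indexing="ij")
    vals = np.full((n, n), floor)
    for (p0, q0, s, w) in peaks:
        dp = (P - p0 + 180.0) % 360.0 - 180.0
        dq = (Q - q0 + 180.0) % 360.0 - 180.0
        vals += w * np.exp(-(dp ** 2 + dq ** 2) / (2 * s * s))
    vals /= vals.max()
    return RamaHistogram(residue_class, step, vals)


def make_rotamer_histogram(res_type: str, d: int, peaks=None,
                           step: float = 10.0, floor: float = 1e-7
                           ) -> RotamerHistogram:
    """Periodic d-dimensional chi histogram from well-separated peaks.

    ``peaks`` is a list of (center_d_vector, sigma_deg, weight); defaults
    place the canonical gauche+/trans/gauche- staggered conformers."""
    if peaks is None:
        singles = [(-60.0, 1.0), (180.0, 0.7), (60.0, 0.35)]
        peaks = []
        import itertools
        for combo in itertools.product(singles, repeat=d):
            center = [c[0] for c in combo]
            weight = float(np.prod([c[1] for c in combo]))
            peaks.append((center, 12.0, weight))
        peaks = sorted(peaks, key=lambda p: -p[2])[:3 ** d]
    n = int(round(360.0 / step))
    ax = -180.0 + step * np.arange(n)
    mesh = np.meshgrid(*([ax] * d), indexing="ij")
    vals = np.full(mesh[0].shape, floor)
    for center, s, w in peaks:
        d2 = np.zeros_like(vals)
        for dim in range(d):
            dd = (mesh[dim] - center[dim] + 180.0) % 360.0 - 180.0
            d2 += dd ** 2
        vals += w * np.exp(-d2 / (2 * s * s))
    vals /= vals.max()
    return RotamerHistogram(res_type, step, vals)
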