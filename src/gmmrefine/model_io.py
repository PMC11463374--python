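"""Atomic model I/O, chemical reference tables, and topology compilation.

Models are read and written with gemmi (PDB and mmCIF).  Ideal intra-residue
bond lengths and angles are derived from the chemical-component ideal
coordinates bundled with biotite, combined with a small shipped table of
restraint standard deviations and inter-residue link geometry.  Before any
scoring, the per-model connectivity is compiled once into flat numpy index
arrays (bond pairs, angle triples, dihedral quads, chi quads, RNA suite quads
and the within-3-bonds exclusion set) so that all geometry terms can be
evaluated vectorized during refinement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

logger = logging.getLogger("gmmrefine")

# residue-type sets
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
RNA_BASES = {"A", "C", "G", "U"}
DNA_BASES = {"DA", "DC", "DG", "DT"}

#: chain-break thresholds (Angstrom) for the peptide C-N and RNA O3'-P links
PEPTIDE_BREAK = 2.5
PHOSPHO_BREAK = 2.5

#: default std-multiple beyond which a restraint is flagged as an outlier in
#: the differentiable penalty (reports use the 5.0-sigma validation threshold)
DEFAULT_OUTLIER_SIGMA = 4.5
REPORT_OUTLIER_SIGMA = 5.0

_RAMA_CLASSES = ("General", "Gly", "transPro", "cisPro", "prePro", "Ile")


def _data_text(name: str) -> str:
    return resources.files("gmmrefine.data").joinpath(name).read_text()


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom; a convenience view into :class:`MolecularModel` arrays."""

    element: str
    name: str
    res_type: str
    res_index: int
    chain_id: str
    coords: np.ndarray
    is_hydrogen: bool = False


@dataclass
class Residue:
    chain_id: str
    res_index: int
    res_type: str
    atom_idx: np.ndarray          # indices into the model's atom arrays
    polymer_type: str             # "protein" | "RNA" | "other"

    def index_of(self, atom_name: str, names: np.ndarray) -> int | None:
        hits = self.atom_idx[names[self.atom_idx] == atom_name]
        return int(hits[0]) if hits.size else None


class MolecularModel:
    """Ordered atoms grouped into residues; the object being refined.

    Hydrogens may be present but are flagged and excluded from the refinable
    set (one Gaussian is placed per non-H atom).
    """

    def __init__(self, element, name, res_type, res_index, chain_id, coords,
                 is_hydrogen=None):
        n = len(name)
        self.element = np.asarray(element, dtype=object)
        self.name = np.asarray(name, dtype=object)
        self.res_type = np.asarray(res_type, dtype=object)
        self.res_index = np.asarray(res_index, dtype=int)
        self.chain_id = np.asarray(chain_id, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        if is_hydrogen is None:
            is_hydrogen = np.array([e == "H" for e in self.element])
        self.is_hydrogen = np.asarray(is_hydrogen, dtype=bool)
        if n and not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        self.residues = self._group_residues()
        self.h_recipe = None      # filled by add_hydrogens

    # -- construction helpers ------------------------------------------------
    def _group_residues(self) -> list[Residue]:
        residues = []
        start = 0
        n = len(self.name)
        for i in range(1, n + 1):
            if i == n or (self.chain_id[i] != self.chain_id[start]
                          or self.res_index[i] != self.res_index[start]):
                idx = np.arange(start, i)
                rt = self.res_type[start]
                if rt in AMINO_ACIDS:
                    ptype = "protein"
                elif rt in RNA_BASES:
                    ptype = "RNA"
                else:
                    ptype = "other"
                residues.append(Residue(self.chain_id[start],
                                        int(self.res_index[start]),
                                        rt, idx, ptype))
                start = i
        return residues

    # -- basic views ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.name)

    @property
    def refinable(self) -> np.ndarray:
        """Boolean mask of refinable (non-hydrogen) atoms."""
        return ~self.is_hydrogen

    def atom(self, i: int) -> Atom:
        return Atom(self.element[i], self.name[i], self.res_type[i],
                    int(self.res_index[i]), self.chain_id[i],
                    self.coords[i], bool(self.is_hydrogen[i]))

    def heavy_model(self) -> "MolecularModel":
        """Copy containing only the refinable (non-H) atoms."""
        m = self.refinable
        return MolecularModel(self.element[m], self.name[m], self.res_type[m],
                              self.res_index[m], self.chain_id[m],
                              self.coords[m])

    def with_coords(self, coords: np.ndarray) -> "MolecularModel":
        out = MolecularModel(self.element, self.name, self.res_type,
                             self.res_index, self.chain_id, coords,
                             self.is_hydrogen)
        out.h_recipe = self.h_recipe
        return out

    def find_atom(self, chain_id, res_index, atom_name) -> int | None:
        hit = np.flatnonzero((self.chain_id == chain_id)
                             & (self.res_index == res_index)
                             & (self.name == atom_name))
        return int(hit[0]) if hit.size else None


# ---------------------------------------------------------------------------
# geometry dictionary
# ---------------------------------------------------------------------------

def _ccd_residue(res_type: str):
    import biotite.structure.info as strucinfo
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return strucinfo.residue(res_type)
    except Exception:
        return None


@dataclass
class _ResidueChem:
    """Per-residue-type chemistry derived from ideal component coordinates."""
    atom_names: list[str]
    elements: dict[str, str]
    heavy_bonds: list[tuple[str, str, float]]          # (a, b, ideal length)
    heavy_angles: list[tuple[str, str, str, float]]    # (a, b, c, ideal deg)
    h_parents: dict[str, str]                          # H name -> parent heavy
    ideal_coords: dict[str, np.ndarray]
    neighbors: dict[str, list[str]]                    # heavy-atom graph


class GeometryDictionary:
    """Chemical reference tables: ideal bonds/angles, planarity, VdW radii,
    chi definitions, hydrogen construction geometry and link restraints."""

    def __init__(self, bond_std: float | None = None,
                 angle_std: float | None = None):
        stds = {}
        for line in _data_text("restraint_stds.txt").splitlines():
            line = line.split("#")[0].strip()
            if line:
                k, v = line.split()
                stds[k] = float(v)
        self.bond_std = bond_std if bond_std is not None else stds["bond_std"]
        self.angle_std = angle_std if angle_std is not None else stds["angle_std"]
        self._chem: dict[str, _ResidueChem | None] = {}
        self.vdw = self._load_vdw()
        self.links = self._load_links()
        self.planarity = self._load_planarity()
        self.chi_defs = self._load_chi()
        #: angular thresholds (degrees) for planar dihedral classes
        self.planar_thresholds = {"peptide": 30.0, "other": 10.0}

    @staticmethod
    def _load_vdw() -> dict[str, float]:
        table = {}
        for line in _data_text("vdw_radii.txt").splitlines():
            line = line.split("#")[0].strip()
            if line:
                el, r = line.split()
                table[el.upper()] = float(r)
        return table

    @staticmethod
    def _load_links():
        links = {"peptide": {"bond": None, "angles": []},
                 "rna": {"bond": None, "angles": []}}
        for line in _data_text("link_geometry.txt").splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            kind, what = parts[0], parts[1]
            if what == "bond":
                links[kind]["bond"] = (parts[2], parts[3],
                                       float(parts[4]), float(parts[5]))
            else:
                links[kind]["angles"].append(
                    (parts[2], parts[3], parts[4],
                     float(parts[5]), float(parts[6])))
        return links

    @staticmethod
    def _load_planarity():
        groups: dict[str, list[tuple[str, ...]]] = {}
        for line in _data_text("planarity_groups.txt").splitlines():
            line = line.split("#")[0].strip()
            if line:
                parts = line.split()
                groups.setdefault(parts[0], []).append(tuple(parts[1:5]))
        return groups

    @staticmethod
    def _load_chi():
        defs: dict[str, list[tuple[str, ...]]] = {}
        for line in _data_text("chi_definitions.txt").splitlines():
            line = line.split("#")[0].strip()
            if line:
                parts = line.split()
                defs.setdefault(parts[0], []).append(tuple(parts[2:6]))
        return defs

    def vdw_radius(self, element: str) -> float:
        return self.vdw.get(element.upper(), 1.7)

    # -- per-residue chemistry -----------------------------------------------
    def chem(self, res_type: str) -> _ResidueChem | None:
        if res_type not in self._chem:
            self._chem[res_type] = self._build_chem(res_type)
        return self._chem[res_type]

    def _build_chem(self, res_type: str) -> _ResidueChem | None:
        ref = _ccd_residue(res_type)
        if ref is None:
            return None
        names = [str(n) for n in ref.atom_name]
        elements = {n: str(e).upper() for n, e in zip(names, ref.element)}
        coords = {n: np.array(c, dtype=float)
                  for n, c in zip(names, ref.coord)}
        adj: dict[str, set[str]] = {n: set() for n in names}
        for i, j, _ in ref.bonds.as_array():
            adj[names[i]].add(names[j])
            adj[names[j]].add(names[i])
        heavy = [n for n in names if elements[n] != "H"]
        heavy_set = set(heavy)
        bonds, angles = [], []
        for a in heavy:
            for b in sorted(adj[a] & heavy_set):
                if a < b:
                    bonds.append((a, b, float(np.linalg.norm(coords[a]
                                                             - coords[b]))))
        for b in heavy:
            nbrs = sorted(adj[b] & heavy_set)
            for i in range(len(nbrs)):
                for j in range(i + 1, len(nbrs)):
                    a, c = nbrs[i], nbrs[j]
                    u = coords[a] - coords[b]
                    v = coords[c] - coords[b]
                    cosang = np.dot(u, v) / (np.linalg.norm(u)
                                             * np.linalg.norm(v))
                    angles.append((a, b, c,
                                   float(np.degrees(np.arccos(
                                       np.clip(cosang, -1, 1))))))
        h_parents = {}
        for n in names:
            if elements[n] == "H":
                parents = [p for p in adj[n] if elements[p] != "H"]
                if parents:
                    h_parents[n] = parents[0]
        neighbors = {a: sorted(adj[a] & heavy_set) for a in heavy}
        return _ResidueChem(names, elements, bonds, angles, h_parents,
                            coords, neighbors)


_DEFAULT_DICT: GeometryDictionary | None = None


def default_dictionary() -> GeometryDictionary:
    global _DEFAULT_DICT
    if _DEFAULT_DICT is None:
        _DEFAULT_DICT = GeometryDictionary()
    return _DEFAULT_DICT


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_model(path, format: str = "auto") -> MolecularModel:
    """Read a PDB or mmCIF file into a :class:`MolecularModel`.

    Only the first model of a multi-model file is read; for atoms with
    alternate locations the highest-occupancy conformer is kept.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path))
    except Exception as exc:            # pragma: no cover - gemmi error text
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise ValueError(f"{path}: no atoms found")
    element, name, res_type, res_index, chain_id, coords = [], [], [], [], [], []
    for chain in st[0]:
        for res in chain:
            best: dict[str, object] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in res:
                if best.get(atom.name) is not atom:
                    continue
                element.append(atom.element.name.upper())
                name.append(atom.name)
                res_type.append(res.name)
                res_index.append(res.seqid.num)
                chain_id.append(chain.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    model = MolecularModel(element, name, res_type, res_index, chain_id,
                           coords)
    unknown = {r.res_type for r in model.residues if r.polymer_type == "other"}
    if unknown:
        logger.warning("residue types without geometry dictionary entries "
                       "(excluded from geometry losses): %s",
                       ", ".join(sorted(unknown)))
    return model


def write_model(models, path, format: str = "auto") -> None:
    """Write one model (or a list, as a multi-model series) to PDB/mmCIF."""
    import gemmi

    if isinstance(models, MolecularModel):
        models = [models]
    path = Path(path)
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = gemmi.Structure()
    st.name = path.stem
    for mi, model in enumerate(models):
        gm = gemmi.Model(mi + 1)
        for res in model.residues:
            cname = str(res.chain_id)
            if gm.find_chain(cname) is None:
                gm.add_chain(gemmi.Chain(cname))
            chain = gm.find_chain(cname)
            gr = gemmi.Residue()
            gr.name = str(res.res_type)
            gr.seqid = gemmi.SeqId(res.res_index, " ")
            for i in res.atom_idx:
                ga = gemmi.Atom()
                ga.name = str(model.name[i])
                ga.element = gemmi.Element(str(model.element[i]).capitalize())
                x, y, z = model.coords[i]
                ga.pos = gemmi.Position(x, y, z)
                gr.add_atom(ga)
            chain.add_residue(gr)
        st.add_model(gm)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))


# ---------------------------------------------------------------------------
# compiled topology
# ---------------------------------------------------------------------------

@dataclass
class CompiledTopology:
    """Flat index arrays bridging chemistry tables to vectorized losses.

    All indices refer to the atom order of the model the topology was
    compiled for (heavy atoms; the exclusion set additionally covers placed
    hydrogens when compiled after :func:`add_hydrogens`).
    """

    bond_idx: np.ndarray          # (B, 2)
    bond_mean: np.ndarray
    bond_std: np.ndarray
    angle_idx: np.ndarray         # (A, 3)
    angle_mean: np.ndarray
    angle_std: np.ndarray
    planar_idx: np.ndarray        # (P, 4)
    planar_class: np.ndarray      # (P,) "peptide" | "other"
    phi_idx: np.ndarray           # (R, 4) or empty; -1 where undefined
    psi_idx: np.ndarray
    omega_prev_idx: np.ndarray    # omega quad preceding each residue
    rama_residues: np.ndarray     # residue list indices with full phi+psi
    rama_class: np.ndarray        # static class; Pro cis/trans resolved later
    chi_idx: list                 # per residue: (d, 4) int array (may be empty)
    chi_residues: np.ndarray      # residue list indices owning chi_idx entries
    chi_rotating: list            # per residue: list of d index arrays
    suite_idx: np.ndarray         # (S, 7, 4)
    suite_residues: np.ndarray
    exclusion_pairs: np.ndarray   # (E, 2), i < j, bonded or within 3 bonds
    bond_graph: list              # adjacency lists over all atoms (incl. H)

    @property
    def n_bonds(self) -> int:
        return len(self.bond_idx)

    def exclusion_set(self) -> set:
        return {(int(i), int(j)) for i, j in self.exclusion_pairs}


def _residue_atom_map(model: MolecularModel, res: Residue) -> dict[str, int]:
    return {str(model.name[i]): int(i) for i in res.atom_idx}


def _link_partner(model, res_a, res_b, kind):
    """Return (i, j) atom indices of the inter-residue link bond, or None."""
    amap, bmap = _residue_atom_map(model, res_a), _residue_atom_map(model, res_b)
    if kind == "peptide":
        i, j = amap.get("C"), bmap.get("N")
        thr = PEPTIDE_BREAK
    else:
        i, j = amap.get("O3'"), bmap.get("P")
        thr = PHOSPHO_BREAK
    if i is None or j is None:
        return None
    if np.linalg.norm(model.coords[i] - model.coords[j]) > thr:
        return None
    return i, j


def compile_topology(model: MolecularModel,
                     gdict: GeometryDictionary | None = None
                     ) -> CompiledTopology:
    """Pre-compile all geometry index arrays for a model.

    Unknown residue types are skipped with a warning; chain breaks (residue
    gaps or over-stretched link bonds) produce no inter-residue entries.
    """
    if gdict is None:
        gdict = default_dictionary()
    names = model.name
    n_atoms = model.n_atoms
    bonds, bmean = [], []
    angles, amean = [], []
    planars, pclass = [], []
    adjacency: list[set[int]] = [set() for _ in range(n_atoms)]

    def add_bond(i, j, mean):
        bonds.append((i, j))
        bmean.append(mean)

    def add_angle(i, j, k, mean):
        angles.append((i, j, k))
        amean.append(mean)

    # intra-residue terms
    for res in model.residues:
        chem = gdict.chem(res.res_type) if res.polymer_type != "other" else None
        amap = _residue_atom_map(model, res)
        if chem is None:
            if res.polymer_type != "other":
                logger.warning("no chemistry for residue %s", res.res_type)
            continue
        for a, b, mean in chem.heavy_bonds:
            if a in amap and b in amap:
                add_bond(amap[a], amap[b], mean)
        for a, b, c, mean in chem.heavy_angles:
            if a in amap and b in amap and c in amap:
                add_angle(amap[a], amap[b], amap[c], mean)
        for quad in gdict.planarity.get(res.res_type, []):
            if all(q in amap for q in quad):
                planars.append(tuple(amap[q] for q in quad))
                pclass.append("other")
        # bond graph includes hydrogens
        for h, parent in chem.h_parents.items():
            if h in amap and parent in amap:
                adjacency[amap[h]].add(amap[parent])
                adjacency[amap[parent]].add(amap[h])

    for (i, j) in bonds:
        adjacency[i].add(j)
        adjacency[j].add(i)

    # inter-residue links, phi/psi/omega, suites
    res_list = model.residues
    linked_next: dict[int, bool] = {}
    phi = np.full((len(res_list), 4), -1, int)
    psi = np.full((len(res_list), 4), -1, int)
    omega_prev = np.full((len(res_list), 4), -1, int)
    suite_quads, suite_res = [], []
    for ri in range(len(res_list) - 1):
        ra, rb = res_list[ri], res_list[ri + 1]
        if ra.chain_id != rb.chain_id:
            continue
        if ra.polymer_type == rb.polymer_type == "protein":
            kind = "peptide"
        elif ra.polymer_type == rb.polymer_type == "RNA":
            kind = "rna"
        else:
            continue
        link = _link_partner(model, ra, rb, kind)
        if link is None:
            continue
        i, j = link
        linked_next[ri] = True
        lk = gdict.links[kind]
        _, _, mean, std = lk["bond"]
        bonds.append((i, j))
        bmean.append(mean)
        adjacency[i].add(j)
        adjacency[j].add(i)
        amap, bmap = _residue_atom_map(model, ra), _residue_atom_map(model, rb)
        both = {**{k: v for k, v in amap.items()},
                **{k + "+": v for k, v in bmap.items()}}
        if kind == "peptide":
            link_angle_atoms = [("CA", "C", "N+"), ("O", "C", "N+"),
                                ("C", "N+", "CA+")]
        else:
            link_angle_atoms = [("C3'", "O3'", "P+"), ("O3'", "P+", "O5'+"),
                                ("O3'", "P+", "OP1+"), ("O3'", "P+", "OP2+")]
        for (a, b, c), (_, _, _, mean_a, std_a) in zip(link_angle_atoms,
                                                       lk["angles"]):
            if a in both and b in both and c in both:
                angles.append((both[a], both[b], both[c]))
                amean.append(mean_a)
        if kind == "peptide":
            quad = [amap.get("CA"), amap.get("C"), bmap.get("N"),
                    bmap.get("CA")]
            if None not in quad:
                planars.append(tuple(quad))
                pclass.append("peptide")
                omega_prev[ri + 1] = quad
            cq = [amap.get("CA"), amap.get("C"), amap.get("O"), bmap.get("N")]
            if None not in cq:
                planars.append(tuple(cq))
                pclass.append("other")
            if None not in (amap.get("C"), bmap.get("N"), bmap.get("CA"),
                            bmap.get("C")):
                phi[ri + 1] = [amap["C"], bmap["N"], bmap["CA"], bmap["C"]]
            if None not in (amap.get("N"), amap.get("CA"), amap.get("C"),
                            bmap.get("N")):
                psi[ri] = [amap["N"], amap["CA"], amap["C"], bmap["N"]]
        else:
            suite_names = [("C5'", "C4'", "C3'", "O3'"),
                           ("C4'", "C3'", "O3'", "P+"),
                           ("C3'", "O3'", "P+", "O5'+"),
                           ("O3'", "P+", "O5'+", "C5'+"),
                           ("P+", "O5'+", "C5'+", "C4'+"),
                           ("O5'+", "C5'+", "C4'+", "C3'+"),
                           ("C5'+", "C4'+", "C3'+", "O3'+")]
            quads = []
            ok = True
            for sn in suite_names:
                q = [both.get(a) for a in sn]
                if None in q:
                    ok = False
                    break
                quads.append(q)
            if ok:
                suite_quads.append(quads)
                suite_res.append(ri + 1)
            else:
                logger.warning("missing backbone atom in RNA step %s%d",
                               rb.chain_id, rb.res_index)

    # Ramachandran residue list and static class
    rama_res, rama_cls = [], []
    for ri, res in enumerate(res_list):
        if res.polymer_type != "protein":
            continue
        if phi[ri, 0] < 0 or psi[ri, 0] < 0:
            continue
        if res.res_type == "PRO":
            cls = "transPro"          # cis/trans resolved from omega at score time
        elif res.res_type == "GLY":
            cls = "Gly"
        elif ri + 1 < len(res_list) and res_list[ri + 1].res_type == "PRO" \
                and linked_next.get(ri):
            cls = "prePro"
        elif res.res_type == "ILE":
            cls = "Ile"
        else:
            cls = "General"
        rama_res.append(ri)
        rama_cls.append(cls)

    # chi quads and rotating sets
    chi_idx, chi_res, chi_rot = [], [], []
    for ri, res in enumerate(res_list):
        quads = gdict.chi_defs.get(res.res_type)
        if not quads:
            continue
        amap = _residue_atom_map(model, res)
        qarr, rots = [], []
        for quad in quads:
            if not all(q in amap for q in quad):
                break
            idx4 = [amap[q] for q in quad]
            rotating = _distal_atoms(adjacency, idx4[1], idx4[2],
                                     set(res.atom_idx.tolist()))
            qarr.append(idx4)
            rots.append(np.array(sorted(rotating), dtype=int))
        if qarr:
            chi_idx.append(np.array(qarr, dtype=int))
            chi_res.append(ri)
            chi_rot.append(rots)

    exclusions = _exclusion_pairs(adjacency)
    bond_std = np.full(len(bonds), gdict.bond_std)
    angle_std = np.full(len(angles), gdict.angle_std)
    # link-specific stds
    return CompiledTopology(
        bond_idx=np.array(bonds, int).reshape(-1, 2),
        bond_mean=np.array(bmean, float),
        bond_std=bond_std,
        angle_idx=np.array(angles, int).reshape(-1, 3),
        angle_mean=np.array(amean, float),
        angle_std=angle_std,
        planar_idx=np.array(planars, int).reshape(-1, 4),
        planar_class=np.array(pclass, dtype=object),
        phi_idx=phi, psi_idx=psi, omega_prev_idx=omega_prev,
        rama_residues=np.array(rama_res, int),
        rama_class=np.array(rama_cls, dtype=object),
        chi_idx=chi_idx,
        chi_residues=np.array(chi_res, int),
        chi_rotating=chi_rot,
        suite_idx=np.array(suite_quads, int).reshape(-1, 7, 4),
        suite_residues=np.array(suite_res, int),
        exclusion_pairs=exclusions,
        bond_graph=[sorted(s) for s in adjacency],
    )


def _distal_atoms(adjacency, axis_b, axis_c, allowed) -> set:
    """Atoms on the c-side of the b-c bond (the set a chi rotation moves)."""
    seen = {axis_b, axis_c}
    stack = [axis_c]
    out = set()
    while stack:
        cur = stack.pop()
        for nb in adjacency[cur]:
            if nb not in seen and nb in allowed:
                seen.add(nb)
                out.add(nb)
                stack.append(nb)
    return out


def _exclusion_pairs(adjacency) -> np.ndarray:
    """All atom pairs connected within 3 bonds (symmetric, stored i < j)."""
    pairs = set()
    for start in range(len(adjacency)):
        frontier = {start}
        seen = {start}
        for _ in range(3):
            nxt = set()
            for a in frontier:
                for b in adjacency[a]:
                    if b not in seen:
                        nxt.add(b)
            for b in nxt:
                pairs.add((start, b) if start < b else (b, start))
            seen |= nxt
            frontier = nxt
    if not pairs:
        return np.empty((0, 2), int)
    return np.array(sorted(pairs), int)


# ---------------------------------------------------------------------------
# hydrogen placement
# ---------------------------------------------------------------------------

@dataclass
class HydrogenRecipe:
    """Deterministic construction rules for riding hydrogens.

    ``frame`` hydrogens are rebuilt from a local orthonormal frame of three
    heavy atoms; ``rotor`` hydrogens (CH3/OH/NH3 and chain-terminal amines)
    are rebuilt by internal coordinates at the zero-degree torsion; ``amide``
    backbone hydrogens sit on the external bisector of C(i-1)-N-CA.
    """
    kinds: list = field(default_factory=list)
    params: list = field(default_factory=list)
    h_names: list = field(default_factory=list)
    h_elements: list = field(default_factory=list)
    h_res: list = field(default_factory=list)       # residue list index


def _frame(p, a, b):
    """Orthonormal frame at p from directions to a and b."""
    e1 = a - p
    e1 = e1 / np.linalg.norm(e1)
    v = b - p
    e2 = v - np.dot(v, e1) * e1
    n = np.linalg.norm(e2)
    if n < 1e-8:
        # degenerate: pick any perpendicular
        ref = np.array([1.0, 0, 0]) if abs(e1[0]) < 0.9 else np.array([0, 1.0, 0])
        e2 = np.cross(e1, ref)
        n = np.linalg.norm(e2)
    e2 = e2 / n
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3])


def place_from_internal(a, b, c, length, angle_deg, torsion_deg):
    """NeRF placement: position d with |cd| = length, angle(b,c,d) and
    torsion(a,b,c,d) given in degrees."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-8:
        ref = np.array([1.0, 0, 0]) if abs(bc[0]) < 0.9 else np.array([0, 1.0, 0])
        n = np.cross(bc, ref)
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([-length * np.cos(ang),
                        length * np.sin(ang) * np.cos(tor),
                        length * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def add_hydrogens(model: MolecularModel,
                  gdict: GeometryDictionary | None = None) -> MolecularModel:
    """Return a copy of the model with riding hydrogens appended.

    Hydrogen positions are deterministic functions of the heavy-atom
    coordinates; torsionally free groups are placed at the zero-degree
    torsion so repeated placement is idempotent.
    """
    if gdict is None:
        gdict = default_dictionary()
    heavy = model.heavy_model()
    recipe = HydrogenRecipe()
    res_list = heavy.residues
    for rii, res in enumerate(res_list):
        chem = gdict.chem(res.res_type) if res.polymer_type != "other" else None
        if chem is None:
            continue
        amap = _residue_atom_map(heavy, res)
        # O3' esterified to the next residue's phosphate carries no H
        o3_linked = False
        if res.polymer_type == "RNA" and rii + 1 < len(res_list):
            nxt = res_list[rii + 1]
            if nxt.chain_id == res.chain_id and "O3'" in amap:
                nmap = _residue_atom_map(heavy, nxt)
                if "P" in nmap and np.linalg.norm(
                        heavy.coords[amap["O3'"]] - heavy.coords[nmap["P"]]) \
                        <= PHOSPHO_BREAK:
                    o3_linked = True
        # group CCD hydrogens by parent heavy atom
        by_parent: dict[str, list[str]] = {}
        for h, parent in chem.h_parents.items():
            if parent in ("OP1", "OP2", "OP3"):
                continue            # phosphates kept unprotonated
            if parent == "O3'" and o3_linked:
                continue
            by_parent.setdefault(parent, []).append(h)
        for parent, hs in sorted(by_parent.items()):
            if parent not in amap:
                if parent not in ("OXT", "P", "OP3", "O3'", "O2'"):
                    logger.warning("missing parent %s for H in %s", parent,
                                   res.res_type)
                continue
            hs = sorted(hs)
            present_nbrs = [n for n in chem.neighbors[parent] if n in amap]
            p_idx = amap[parent]
            if parent == "N" and res.polymer_type == "protein":
                # backbone amide H: external bisector of C(i-1)-N-CA;
                # requires the preceding residue -- otherwise treated below
                prev = res_list[rii - 1] if rii > 0 else None
                prev_c = None
                if prev is not None and prev.chain_id == res.chain_id \
                        and prev.polymer_type == "protein":
                    pmap = _residue_atom_map(heavy, prev)
                    if "C" in pmap and np.linalg.norm(
                            heavy.coords[pmap["C"]] - heavy.coords[p_idx]) \
                            <= PEPTIDE_BREAK:
                        prev_c = pmap["C"]
                if res.res_type != "PRO" and prev_c is not None \
                        and "CA" in amap and "H" in hs:
                    recipe.kinds.append("amide")
                    recipe.params.append((p_idx, amap["CA"], prev_c, 1.0))
                    recipe.h_names.append("H")
                    recipe.h_elements.append("H")
                    recipe.h_res.append(rii)
                continue    # no N-terminal protonation beyond the amide H
            if len(present_nbrs) >= 2:
                # frame hydrogens: store ideal local coordinates
                F = _frame(chem.ideal_coords[parent],
                           chem.ideal_coords[present_nbrs[0]],
                           chem.ideal_coords[present_nbrs[1]])
                for h in hs:
                    if h not in chem.ideal_coords:
                        continue
                    local = F @ (chem.ideal_coords[h]
                                 - chem.ideal_coords[parent])
                    recipe.kinds.append("frame")
                    recipe.params.append((p_idx, amap[present_nbrs[0]],
                                          amap[present_nbrs[1]], local))
                    recipe.h_names.append(h)
                    recipe.h_elements.append("H")
                    recipe.h_res.append(rii)
            elif len(present_nbrs) == 1:
                # rotor group: zero-degree torsion about parent-neighbor bond
                nb = present_nbrs[0]
                if nb not in amap:
                    continue
                gp_candidates = [g for g in chem.neighbors[nb]
                                 if g != parent and g in amap]
                if not gp_candidates:
                    continue
                gp = gp_candidates[0]
                ideal_len = float(np.linalg.norm(
                    chem.ideal_coords[hs[0]] - chem.ideal_coords[parent]))
                ideal_ang = 109.5 if len(hs) != 1 else _ideal_h_angle(chem,
                                                                      parent,
                                                                      nb, hs[0])
                if len(hs) > 1:
                    ideal_ang = _ideal_h_angle(chem, parent, nb, hs[0])
                # default rotor conformation: first H anti to the reference
                # heavy atom, siblings evenly spaced (staggered for CH3)
                for k, h in enumerate(hs):
                    recipe.kinds.append("rotor")
                    recipe.params.append((p_idx, amap[nb], amap[gp],
                                          ideal_len, ideal_ang,
                                          180.0 + k * 360.0
                                          / max(len(hs), 1)))
                    recipe.h_names.append(h)
                    recipe.h_elements.append("H")
                    recipe.h_res.append(rii)
    h_coords = place_hydrogens(recipe, heavy.coords)
    res_of = res_list
    element = np.concatenate([heavy.element,
                              np.array(recipe.h_elements, object)])
    name = np.concatenate([heavy.name, np.array(recipe.h_names, object)])
    res_type = np.concatenate(
        [heavy.res_type,
         np.array([res_of[r].res_type for r in recipe.h_res], object)])
    res_index = np.concatenate(
        [heavy.res_index,
         np.array([res_of[r].res_index for r in recipe.h_res], int)])
    chain_id = np.concatenate(
        [heavy.chain_id,
         np.array([res_of[r].chain_id for r in recipe.h_res], object)])
    coords = np.vstack([heavy.coords, h_coords.reshape(-1, 3)])
    is_h = np.concatenate([np.zeros(heavy.n_atoms, bool),
                           np.ones(len(recipe.h_names), bool)])
    # hydrogens must be grouped with their residues for residue bookkeeping;
    # re-sort atoms by (chain, residue) preserving heavy-atom order first
    order = _stable_residue_order(chain_id, res_index, is_h)
    out = MolecularModel(element[order], name[order], res_type[order],
                         res_index[order], chain_id[order], coords[order],
                         is_h[order])
    inv = np.empty(len(order), int)
    inv[order] = np.arange(len(order))
    out.h_recipe = _remap_recipe(recipe, inv, heavy.n_atoms)
    return out


def _ideal_h_angle(chem, parent, nb, h):
    u = chem.ideal_coords[h] - chem.ideal_coords[parent]
    v = chem.ideal_coords[nb] - chem.ideal_coords[parent]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1, 1))))


def _stable_residue_order(chain_id, res_index, is_h):
    keys = [(str(c), int(r)) for c, r in zip(chain_id, res_index)]
    uniq = []
    seen = set()
    for k in keys:
        if k not in seen:
            seen.add(k)
            uniq.append(k)
    rank = {k: i for i, k in enumerate(uniq)}
    return np.argsort([rank[k] * 2 + (1 if h else 0)
                       for k, h in zip(keys, is_h)], kind="stable")


def _remap_recipe(recipe: HydrogenRecipe, inv: np.ndarray, n_heavy: int
                  ) -> HydrogenRecipe:
    """Remap recipe heavy-atom indices and record each H's new atom index."""
    out = HydrogenRecipe()
    out.kinds = list(recipe.kinds)
    out.h_names = list(recipe.h_names)
    out.h_elements = list(recipe.h_elements)
    out.h_res = list(recipe.h_res)
    for kind, p in zip(recipe.kinds, recipe.params):
        if kind == "frame":
            out.params.append((int(inv[p[0]]), int(inv[p[1]]),
                               int(inv[p[2]]), p[3]))
        elif kind == "rotor":
            out.params.append((int(inv[p[0]]), int(inv[p[1]]),
                               int(inv[p[2]]), p[3], p[4], p[5]))
        else:
            out.params.append((int(inv[p[0]]), int(inv[p[1]]),
                               int(inv[p[2]]), p[3]))
    out.h_atom_idx = inv[np.arange(n_heavy, n_heavy + len(recipe.kinds))]
    out.heavy_atom_idx = inv[np.arange(n_heavy)]
    return out


def place_hydrogens(recipe: HydrogenRecipe, heavy_coords: np.ndarray
                    ) -> np.ndarray:
    """Rebuild all hydrogen positions from heavy-atom coordinates.

    ``heavy_coords`` is indexed with the recipe's stored heavy-atom indices,
    so it must be the coordinate array the recipe was built against (either
    the heavy-only array or the full mixed array).
    """
    out = np.zeros((len(recipe.kinds), 3))
    for i, (kind, p) in enumerate(zip(recipe.kinds, recipe.params)):
        if kind == "frame":
            pi, a, b, local = p
            F = _frame(heavy_coords[pi], heavy_coords[a], heavy_coords[b])
            out[i] = heavy_coords[pi] + F.T @ local
        elif kind == "rotor":
            pi, nb, gp, length, ang, tor = p
            out[i] = place_from_internal(heavy_coords[gp], heavy_coords[nb],
                                         heavy_coords[pi], length, ang, tor)
        else:                       # amide
            pi, ca, cprev, length = p
            u = heavy_coords[pi] - heavy_coords[ca]
            v = heavy_coords[pi] - heavy_coords[cprev]
            d = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            d = d / np.linalg.norm(d)
            out[i] = heavy_coords[pi] + length * d
    return out


def update_hydrogens(model: MolecularModel) -> None:
    """Recompute riding-H coordinates of a hydrogenated model in place."""
    r = model.h_recipe
    if r is None:
        return
    h = place_hydrogens(r, model.coords)
    model.coords[np.asarray(r.h_atom_idx, int)] = h
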