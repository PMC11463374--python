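"""Five-stage single-model refinement.

The refinement follows a coarse-to-fine schedule driven by three decoder
networks whose outputs are added on top of the Gaussian mixture built from
the input model: D1 emits rigid per-patch transforms (large-scale
morphing), D2 per-residue transforms, D3 per-atom offsets plus
amplitude/width deltas.  A conformation vector (constant ones for a single
model) feeds all three.  Stages:

1. pre-compile topology and score tables;
2. train D1 against the FRC map loss only, at coarse resolution;
3. train D1+D2 jointly, adding bond/angle/clash constraints;
4. optional rotamer rebuild + direct chi optimization (high-resolution maps);
5. train D3 (with D1+D2 frozen-in) under the full set of stereochemical
   losses at the target resolution.

The relative weight of geometry vs map terms is calibrated from the data:
two geometry-free iterations measure how much geometry degrades per unit of
map-score gain, and the geometry weight is set to the reciprocal of that
ratio before training restarts from re-initialized networks.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import clash as clash_mod
from .geom_scores import (bond_angle_loss, bond_length_loss, planarity_loss)
from .gmm_density import (FRCSpec, GaussianMixture, frc_score,
                          frc_score_with_grad, gmm_from_model, project_gmm,
                          project_gmm_with_grad, project_map,
                          sample_orientations)
from .model_io import add_hydrogens, compile_topology, place_hydrogens
from .nn import MLP, Adam, euler_zyx_with_grad
from .rama import fit_rama_gmm, rama_loss_on_coords, RAMA_CLASSES
from .rna_geom import SuiteLibrary, suite_loss_on_coords
from .rotamer import (attach_chi_res_types, fit_rotamer_gmm,
                      rebuild_rotamers, rotamer_loss_on_coords)
from .synth_fixtures import make_rama_histogram, make_rotamer_histogram

logger = logging.getLogger("gmmrefine")


@dataclass
class RefinementConfig:
    """Tunables of the five-stage refinement."""

    resolution: float = 4.0          # target resolution, Angstrom
    patch_count: int = 64
    conf_dim: int = 4                # conformation input (constant ones here)
    batch_size: int = 4              # projections per iteration
    n_orientations: int = 24         # fixed quasi-uniform projection set
    iterations: tuple = (300, 200, 300)   # stages 2, 3, 5
    learning_rate: float = 1e-2
    width: int = 64                  # hidden width of the 4-layer decoders
    seed: int = 0
    outlier_sigma: float = 4.5
    geometry_weight: float | None = None  # None -> auto-balance
    #: clamp on the auto-balanced weight; keeps both loss terms active for
    #: heavily distorted inputs whose geometry scale dwarfs the FRC scale
    geometry_weight_bounds: tuple = (0.01, 10.0)
    #: per-iteration cap on |weighted geometry gradient| / |map gradient|
    geometry_gradient_cap: float = 2.0
    invert_geometry: bool = False
    #: proximal weight keeping the adversarial search local (per A^2)
    adversarial_disp_penalty: float = 0.5
    geometry_only: bool = False
    rebuild_rotamers: bool | None = None  # None -> auto (res <= 3.5 A)
    rebuild_resolution_gate: float = 3.5
    max_displacement: float | None = None  # trust radius (invert mode: 0.3)
    neighbor_refresh: int = 100
    geom_term_weights: tuple = (1.0, 1.0, 1.0)  # bond : angle : planarity
    libraries: dict | None = None    # {'rama':…, 'rotamer':…, 'suite':…}

    def stage_resolution(self, stage: int) -> float:
        if stage == 2:
            return max(self.resolution, 10.0)
        if stage == 3:
            return max(self.resolution, 6.0)
        return self.resolution


@dataclass
class PatchAssignment:
    residue_patch: np.ndarray        # (R,)
    atom_patch: np.ndarray           # (N,)
    k: int


def make_patches(model, k: int, seed: int = 0) -> PatchAssignment:
    """K-means on residue centers-of-geometry; every atom of a residue
    shares its residue's patch."""
    from sklearn.cluster import KMeans

    res_centers = np.array([model.coords[r.atom_idx].mean(axis=0)
                            for r in model.residues])
    n_res = len(res_centers)
    if k > n_res:
        logger.warning("patch count %d > residue count %d; clamping", k,
                       n_res)
        k = n_res
    km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    res_patch = km.fit_predict(res_centers)
    atom_patch = np.zeros(model.n_atoms, int)
    for ri, r in enumerate(model.residues):
        atom_patch[r.atom_idx] = res_patch[ri]
    return PatchAssignment(res_patch, atom_patch, k)


@dataclass
class WeightBalance:
    ratio: float
    geometry_weight: float
    fallback: bool = False


# ---------------------------------------------------------------------------
# score libraries (fitted histogram GMMs + suite table)
# ---------------------------------------------------------------------------

_LIB_CACHE: dict = {}

_ROTAMER_GRID_STEP = {1: 6.0, 2: 10.0, 3: 24.0, 4: 30.0}


def default_score_libraries(res_types=(), seed: int = 0) -> dict:
    """Synthetic stand-in score tables fitted on demand and cached.

    Real reference histograms (Phenix-distributed) can be substituted by
    passing user histograms through :func:`gmmrefine.rama.fit_rama_gmm` /
    :func:`gmmrefine.rotamer.fit_rotamer_gmm`.
    """
    from .model_io import default_dictionary

    if "rama" not in _LIB_CACHE:
        hist = make_rama_histogram(step=4.0)
        gmm = fit_rama_gmm(hist, n_components=600, n_rounds=2, seed=seed,
                           rmsd_tol=0.05)
        _LIB_CACHE["rama"] = {cls: gmm for cls in RAMA_CLASSES}
    if "suite" not in _LIB_CACHE:
        _LIB_CACHE["suite"] = SuiteLibrary.default()
    rot = _LIB_CACHE.setdefault("rotamer", {})
    gdict = default_dictionary()
    for rt in res_types:
        if rt in rot:
            continue
        d = len(gdict.chi_defs.get(rt, ()))
        if d == 0:
            continue
        hist = make_rotamer_histogram(rt, d, step=_ROTAMER_GRID_STEP[d])
        rot[rt] = fit_rotamer_gmm(hist, rt, seed=seed,
                                  n_components=min(3 ** d + 1, 30),
                                  n_iter=60)
    return {"rama": _LIB_CACHE["rama"], "rotamer": rot,
            "suite": _LIB_CACHE["suite"]}


# ---------------------------------------------------------------------------
# decoder stack
# ---------------------------------------------------------------------------

class DecoderStack:
    """Three decoders whose outputs add on top of the input-model GMM.

    At zero network output (the initial state: zero-initialized last
    layers) the emitted coordinates equal the input coordinates exactly.
    """

    ROT_SCALE = 0.15           # radians per unit network output
    TRANS_SCALE = 2.0          # Angstrom
    OFFSET_SCALE = 0.5         # Angstrom
    LOGAMP_SCALE = 0.1

    def __init__(self, x0, patches: PatchAssignment, conf_dim: int,
                 width: int, seed: int):
        self.x0 = np.asarray(x0, float)
        self.patches = patches
        n_atoms = len(self.x0)
        self.n_res = int(patches.residue_patch.size)
        self.k = patches.k
        # per-residue atom lists from the patch assignment's residue ids
        self.res_of_atom = np.zeros(n_atoms, int)
        self.d1 = MLP(conf_dim, self.k * 6, width, 4, seed)
        self.d2 = MLP(conf_dim, self.n_res * 6, width, 4, seed + 1)
        self.d3 = MLP(conf_dim, n_atoms * 5, width, 4, seed + 2)
        self.active = {"d1"}
        self.conf_dim = conf_dim
        self.width = width
        self.seed = seed
        self.max_displacement = None

    def attach_residues(self, model) -> None:
        for ri, r in enumerate(model.residues):
            self.res_of_atom[r.atom_idx] = ri
        self.patch_centroid = np.array(
            [self.x0[self.patches.atom_patch == p].mean(axis=0)
             for p in range(self.k)])
        self.res_centroid = np.array(
            [self.x0[self.res_of_atom == ri].mean(axis=0)
             for ri in range(self.n_res)])

    def reinitialize(self) -> None:
        n_atoms = len(self.x0)
        self.d1 = MLP(self.conf_dim, self.k * 6, self.width, 4, self.seed)
        self.d2 = MLP(self.conf_dim, self.n_res * 6, self.width, 4,
                      self.seed + 1)
        self.d3 = MLP(self.conf_dim, n_atoms * 5, self.width, 4,
                      self.seed + 2)

    # -- forward ------------------------------------------------------------
    def emit(self, conf):
        """Coordinates (and log-amplitude/width deltas) for one conformation
        vector; caches everything needed for backward()."""
        x0 = self.x0
        n = len(x0)
        delta = np.zeros((n, 3))
        cache = {"conf": conf}
        if "d1" in self.active:
            out1 = self.d1.forward(conf)[0]
            delta += self._rigid_delta(out1, self.patches.atom_patch,
                                       self.patch_centroid, cache, "d1")
        if "d2" in self.active:
            out2 = self.d2.forward(conf)[0]
            delta += self._rigid_delta(out2, self.res_of_atom,
                                       self.res_centroid, cache, "d2")
        logamp = np.zeros(n)
        logsig = np.zeros(n)
        if "d3" in self.active:
            out3 = self.d3.forward(conf)[0].reshape(n, 5)
            delta += self.OFFSET_SCALE * out3[:, :3]
            logamp = self.LOGAMP_SCALE * out3[:, 3]
            logsig = self.LOGAMP_SCALE * out3[:, 4]
        scale = None
        if self.max_displacement is not None:
            norm = np.linalg.norm(delta, axis=1)
            scale = np.minimum(1.0, self.max_displacement
                               / np.maximum(norm, 1e-9))
            delta = delta * scale[:, None]
        cache["disp_scale"] = scale
        return x0 + delta, logamp, logsig, cache

    def _rigid_delta(self, out, group_of_atom, centroids, cache, key):
        ngroups = len(centroids)
        out = out.reshape(ngroups, 6)
        angles = self.ROT_SCALE * out[:, :3]
        trans = self.TRANS_SCALE * out[:, 3:]
        Rs, dRs = [], []
        for gi in range(ngroups):
            R, dR = euler_zyx_with_grad(angles[gi])
            Rs.append(R)
            dRs.append(dR)
        Rs = np.array(Rs)
        rel = self.x0 - centroids[group_of_atom]
        rotated = np.einsum("nij,nj->ni", Rs[group_of_atom], rel)
        # (R - I) @ rel + t: exactly zero at zero network output
        delta = (rotated - rel) + trans[group_of_atom]
        cache[key] = (group_of_atom, centroids, dRs, rel)
        return delta

    # -- backward -----------------------------------------------------------
    def backward(self, cache, dcoords, dlogamp=None, dlogsig=None):
        """Parameter gradients for every active decoder."""
        if cache["disp_scale"] is not None:
            dcoords = dcoords * cache["disp_scale"][:, None]
        grads = {}
        for key, net in (("d1", self.d1), ("d2", self.d2)):
            if key not in self.active:
                continue
            group_of_atom, centroids, dRs, rel = cache[key]
            ngroups = len(centroids)
            dout = np.zeros((ngroups, 6))
            for gi in range(ngroups):
                sel = group_of_atom == gi
                if not np.any(sel):
                    continue
                dc = dcoords[sel]
                for a in range(3):
                    dout[gi, a] = self.ROT_SCALE * np.sum(
                        dc * (rel[sel] @ dRs[gi][a].T))
                dout[gi, 3:] = self.TRANS_SCALE * dc.sum(axis=0)
            grads[key] = net.backward(dout.reshape(1, -1))
        if "d3" in self.active:
            n = len(self.x0)
            dout3 = np.zeros((n, 5))
            dout3[:, :3] = self.OFFSET_SCALE * dcoords
            if dlogamp is not None:
                dout3[:, 3] = self.LOGAMP_SCALE * dlogamp
            if dlogsig is not None:
                dout3[:, 4] = self.LOGAMP_SCALE * dlogsig
            grads["d3"] = self.d3.backward(dout3.reshape(1, -1))
        return grads


# ---------------------------------------------------------------------------
# geometry bundle used during training
# ---------------------------------------------------------------------------

class AdversarialBundle:
    """Saturating outlier-count surrogate for the inverted-loss experiment.

    Validation metrics are counts: once a restraint crosses the outlier
    threshold, pushing it further gains nothing.  Maximizing a smooth count
    (sigmoids on the z-scores) therefore degrades every metric while atoms
    stop moving as soon as their restraints are outliers -- the mechanism
    behind tiny displacements producing extreme validation scores.
    """

    def __init__(self, geometry: "GeometryBundle", z_target: float = 5.5,
                 tau: float = 0.5):
        self.geom = geometry
        self.z_target = z_target
        self.tau = tau

    def __call__(self, coords):
        from .geom_scores import (angles_with_grad, bond_vectors,
                                  dihedrals_with_grad, wrap_angle)

        g = self.geom
        topo = g.topo
        loss = 0.0
        grad = np.zeros_like(coords)
        # smooth outlier counts for bonds and angles: sigmoid((|z|-z*)/tau)
        for kind in ("bond", "angle"):
            if kind == "bond":
                idx = topo.bond_idx
                if not len(idx):
                    continue
                d, r = bond_vectors(coords, idx)
                z = (r - topo.bond_mean) / topo.bond_std
            else:
                idx = topo.angle_idx
                if not len(idx):
                    continue
                theta, dtheta = angles_with_grad(coords, idx)
                z = (theta - topo.angle_mean) / topo.angle_std
            s = 1.0 / (1.0 + np.exp(-(np.abs(z) - self.z_target)
                                    / self.tau))
            loss += float(s.mean())
            dz = s * (1 - s) / self.tau * np.sign(z) / len(z)
            if kind == "bond":
                dd = (dz / topo.bond_std / r)[:, None] * d
                np.add.at(grad, idx[:, 1], dd)
                np.add.at(grad, idx[:, 0], -dd)
            else:
                contrib = (dz / topo.angle_std)[:, None, None] * dtheta
                np.add.at(grad, idx.ravel(), contrib.reshape(-1, 3))
        # planarity: smooth count of quads beyond threshold + 2 degrees
        if len(topo.planar_idx):
            phi, dphi = dihedrals_with_grad(coords, topo.planar_idx)
            w = wrap_angle(phi)
            d0 = np.abs(w)
            dev = np.minimum(d0, 180.0 - d0)
            thr = np.array([{"peptide": 30.0, "other": 10.0}[c]
                            for c in topo.planar_class])
            s = 1.0 / (1.0 + np.exp(-(dev - thr - 2.0) / 1.0))
            loss += float(s.mean())
            sign = np.where(d0 <= 180.0 - d0, np.sign(w), -np.sign(w))
            dp = s * (1 - s) * sign / len(s)
            contrib = dp[:, None, None] * dphi
            np.add.at(grad, topo.planar_idx.ravel(), contrib.reshape(-1, 3))
        # Ramachandran surrogate is already a saturating outlier fraction
        if len(topo.rama_residues):
            rep = rama_loss_on_coords(coords, topo, g.libs["rama"])
            loss += rep.loss
            grad += rep.grad
        # clash: smooth count of pairs with meaningful overlap
        g.mixed[g.heavy_idx] = coords
        g.mixed[g.h_idx] = place_hydrogens(g.recipe, g.mixed)
        if g.nlist is None:
            g.nlist = clash_mod.build_neighbor_list(g.mixed, g.topo_h)
        pairs = g.nlist.pairs
        if len(pairs):
            from .clash import _thresholds
            from .model_io import default_dictionary
            t, _ = _thresholds(g.model_h, default_dictionary(), pairs)
            delta = g.mixed[pairs[:, 0]] - g.mixed[pairs[:, 1]]
            dist = np.maximum(np.linalg.norm(delta, axis=1), 1e-8)
            s = 1.0 / (1.0 + np.exp(-((t - dist) - 0.1) / 0.05))
            loss += float(s.sum()) / max(len(coords), 1)
            dd = (-s * (1 - s) / 0.05 / dist / max(len(coords), 1))[:, None] \
                * delta
            gm = np.zeros_like(g.mixed)
            np.add.at(gm, pairs[:, 0], dd)
            np.add.at(gm, pairs[:, 1], -dd)
            parents = np.array([p[0] for p in g.recipe.params], int)
            np.add.at(gm, parents, gm[g.h_idx])
            grad += gm[g.heavy_idx]
        return loss, grad, {"adversarial_surrogate": loss}


class GeometryBundle:
    """Evaluates the active geometry losses and their coordinate gradient,
    including riding-hydrogen clash handling."""

    def __init__(self, model, config: RefinementConfig, terms=("bond",
                 "angle")):
        self.model = model            # heavy-atom model
        self.cfg = config
        self.terms = set(terms)
        self.topo = compile_topology(model)
        attach_chi_res_types(self.topo, model)
        self.libs = config.libraries
        if self.libs is None:
            res_types = {r.res_type for r in model.residues}
            self.libs = default_score_libraries(sorted(res_types),
                                                config.seed)
        self.model_h = add_hydrogens(model)
        self.topo_h = compile_topology(self.model_h)
        self.recipe = self.model_h.h_recipe
        self.heavy_idx = np.asarray(self.recipe.heavy_atom_idx, int)
        self.h_idx = np.asarray(self.recipe.h_atom_idx, int)
        self.mixed = self.model_h.coords.copy()
        self.nlist = None
        self._iter = 0

    def __call__(self, coords):
        cfg = self.cfg
        loss = 0.0
        grad = np.zeros_like(coords)
        metrics = {}
        wb, wa, wp = cfg.geom_term_weights
        if "bond" in self.terms:
            rep = bond_length_loss(coords, self.topo, cfg.outlier_sigma)
            loss += wb * rep.loss
            grad += wb * rep.grad
            metrics["bond_outliers"] = rep.outlier_count
            metrics["bond_loss"] = rep.loss
        if "angle" in self.terms:
            rep = bond_angle_loss(coords, self.topo, cfg.outlier_sigma)
            loss += wa * rep.loss
            grad += wa * rep.grad
            metrics["angle_outliers"] = rep.outlier_count
        if "planarity" in self.terms:
            rep = planarity_loss(coords, self.topo)
            loss += wp * rep.loss
            grad += wp * rep.grad
            metrics["planarity_outliers"] = rep.outlier_count
        if "rama" in self.terms and len(self.topo.rama_residues):
            rep = rama_loss_on_coords(coords, self.topo, self.libs["rama"])
            loss += rep.loss
            grad += rep.grad
            metrics["rama_outlier_fraction"] = rep.outlier_fraction
        if "rotamer" in self.terms and len(self.topo.chi_idx):
            rep = rotamer_loss_on_coords(coords, self.topo,
                                         self.libs["rotamer"])
            loss += rep.loss
            grad += rep.grad
            metrics["rotamer_outliers"] = rep.outlier_count
        if "suite" in self.terms and len(self.topo.suite_idx):
            rep = suite_loss_on_coords(coords, self.topo, self.libs["suite"])
            loss += rep.loss
            grad += rep.grad
            metrics["suite_mean"] = rep.mean_score
        if "clash" in self.terms:
            self.mixed[self.heavy_idx] = coords
            self.mixed[self.h_idx] = place_hydrogens(self.recipe,
                                                     self.mixed)
            if self.nlist is None or \
                    self._iter - self.nlist.built_at >= cfg.neighbor_refresh:
                self.nlist = clash_mod.build_neighbor_list(
                    self.mixed, self.topo_h, iteration=self._iter)
            rep = clash_mod.clash_loss(self.mixed, self.nlist, self.model_h,
                                       self.topo_h)
            loss += rep.penalty
            grad += rep.grad[self.heavy_idx]
            metrics["clash_count"] = rep.clash_count
        self._iter += 1
        metrics["geometry_loss"] = loss
        return loss, grad, metrics


# ---------------------------------------------------------------------------
# training stages
# ---------------------------------------------------------------------------

class _MapLoss:
    """FRC map loss over a fixed quasi-uniform orientation set, with
    per-orientation cached map projections."""

    def __init__(self, dmap, config: RefinementConfig):
        self.dmap = dmap
        self.cfg = config
        self.rotations = sample_orientations(config.n_orientations,
                                             config.seed + 17)
        self.map_projs = [project_map(dmap, R) for R in self.rotations]
        self.npix = dmap.npix
        self.apix = dmap.voxel_size

    def spec(self, resolution):
        return FRCSpec(cutoff_res=max(resolution, 2 * self.apix + 1e-6))

    def score_and_grad(self, gmm, batch_ids, resolution):
        spec = self.spec(resolution)
        total = 0.0
        dc = np.zeros_like(gmm.centers)
        da = np.zeros(len(gmm.centers))
        ds = np.zeros(len(gmm.centers))
        for bi in batch_ids:
            img, back = project_gmm_with_grad(
                gmm, self.rotations[bi], None, self.npix, self.apix,
                origin=self.dmap.origin, center=self.dmap.center)
            s, gimg = frc_score_with_grad(img, self.map_projs[bi], spec)
            total += s
            c, a, w = back(gimg)
            dc += c
            da += a
            ds += w
        b = len(batch_ids)
        return total / b, dc / b, da / b, ds / b

    def mean_frc(self, gmm, resolution):
        spec = self.spec(resolution)
        vals = [frc_score(project_gmm(gmm, R, None, self.npix, self.apix,
                                      origin=self.dmap.origin,
                                      center=self.dmap.center), mp, spec)
                for R, mp in zip(self.rotations, self.map_projs)]
        return float(np.mean(vals))


def _base_gmm(model, resolution):
    return gmm_from_model(model, resolution)


def _train_stage(stack: DecoderStack, geometry: GeometryBundle | None,
                 maploss: _MapLoss | None, config: RefinementConfig,
                 n_iter: int, resolution: float, geom_weight: float,
                 conf: np.ndarray, base_gmm: GaussianMixture | None,
                 invert: bool = False, stage_name: str = "",
                 lr: float | None = None, eval_interval: int = 25):
    """Shared training loop; returns (final coords, history dict).

    Every ``eval_interval`` iterations the stage objective is evaluated on
    the full orientation set and the decoder parameters are checkpointed;
    the best checkpoint is restored at stage end so a stage can never make
    the model worse than its best visited state (the stage-boundary guard).
    """
    import copy as _copy

    optimizers = {k: Adam(getattr(stack, k).params,
                          lr=lr or config.learning_rate)
                  for k in stack.active}
    history = {"map_score": [], "geometry_loss": [], "metrics": []}
    best = {"obj": np.inf, "coords": stack.x0.copy()}

    def full_objective():
        # checkpoints are judged at the target resolution even when the
        # stage trains at a coarser one: few coarse rings are degenerate
        # and training can wander without the fine-ring anchor noticing
        coords, logamp, logsig, _ = stack.emit(conf)
        obj = 0.0
        if maploss is not None and base_gmm is not None:
            gmm = GaussianMixture(coords,
                                  base_gmm.amplitudes * np.exp(logamp),
                                  base_gmm.widths * np.exp(logsig))
            obj += 1.0 - maploss.mean_frc(gmm, config.resolution)
        if geometry is not None:
            obj += sign * geom_weight * geometry(coords)[0]
        return obj, coords

    def checkpoint():
        obj, coords = full_objective()
        if obj < best["obj"]:
            best["obj"] = obj
            best["coords"] = coords.copy()
            best["params"] = {k: _copy.deepcopy(getattr(stack, k))
                              for k in stack.active}

    sign = -1.0 if invert else 1.0
    for it in range(n_iter):
        coords, logamp, logsig, cache = stack.emit(conf)
        total = 0.0
        dcoords = np.zeros_like(coords)
        dlogamp = dlogsig = None
        if maploss is not None and base_gmm is not None:
            gmm = GaussianMixture(coords,
                                  base_gmm.amplitudes * np.exp(logamp),
                                  base_gmm.widths * np.exp(logsig))
            bsz = config.batch_size
            start = (it * bsz) % config.n_orientations
            batch = [(start + j) % config.n_orientations
                     for j in range(bsz)]
            s, dc, da, dw = maploss.score_and_grad(gmm, batch, resolution)
            total += 1.0 - s
            dcoords += -dc
            dlogamp = -da * gmm.amplitudes
            dlogsig = -dw * gmm.widths
            history["map_score"].append(s)
        if geometry is not None:
            gl, gg, metrics = geometry(coords)
            total += sign * geom_weight * gl
            gg_w = sign * geom_weight * gg
            if maploss is not None and base_gmm is not None:
                # keep the weighted geometry pull comparable to the map
                # pull so neither term goes silent
                nmap = np.linalg.norm(dcoords)
                ngeom = np.linalg.norm(gg_w)
                cap = config.geometry_gradient_cap
                if nmap > 1e-12 and ngeom > cap * nmap:
                    gg_w *= cap * nmap / ngeom
            dcoords += gg_w
            history["geometry_loss"].append(gl)
            history["metrics"].append(metrics)
        if invert:
            # proximal term: the adversarial search stays local, atoms stop
            # moving once their restraints have saturated as outliers
            lam = config.adversarial_disp_penalty
            disp = coords - stack.x0
            total += lam * float(np.sum(disp ** 2))
            dcoords += 2.0 * lam * disp
        if not np.isfinite(total):
            logger.warning("%s: non-finite loss at iteration %d; "
                           "restoring best checkpoint", stage_name, it)
            break
        grads = stack.backward(cache, dcoords, dlogamp, dlogsig)
        for k, g in grads.items():
            optimizers[k].step(g)
        if (it + 1) % eval_interval == 0 and not invert:
            checkpoint()
        if it % 50 == 0:
            logger.info("%s it %d: loss %.5f", stage_name, it, total)
    if not invert:
        checkpoint()
        if "params" in best:
            for k, net in best["params"].items():
                setattr(stack, k, net)
    coords = stack.emit(conf)[0]
    return coords, history, best


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def balance_weights(model, dmap, config: RefinementConfig) -> WeightBalance:
    """Measure the map-gain / geometry-degradation ratio over two
    geometry-free iterations and return its reciprocal as the geometry
    weight; the decoders are re-initialized afterwards."""
    heavy = model.heavy_model()
    patches = make_patches(heavy, min(config.patch_count,
                                      len(heavy.residues)), config.seed)
    stack = DecoderStack(heavy.coords, patches, config.conf_dim,
                         config.width, config.seed)
    stack.attach_residues(heavy)
    stack.active = {"d1", "d2"}
    geometry = GeometryBundle(heavy, config, terms=("bond", "angle",
                                                    "clash"))
    maploss = _MapLoss(dmap, config)
    return _balance(stack, geometry, maploss, config,
                    np.ones(config.conf_dim), heavy)


def _balance(stack, geometry, maploss, config, conf, heavy,
             resolution=None):
    resolution = resolution or config.stage_resolution(3)
    base = _base_gmm(heavy, resolution)
    g0 = geometry(stack.x0)[0]
    m0 = maploss.mean_frc(GaussianMixture(stack.x0, base.amplitudes,
                                          base.widths), resolution)
    # the ratio of first-order changes is step-size invariant; a larger
    # balancing step just makes both deltas measurable above noise
    lr_bal = max(0.03, 3 * config.learning_rate)
    opt = {k: Adam(getattr(stack, k).params, lr=lr_bal)
           for k in stack.active}
    coords = stack.x0
    for it in range(2):
        coords, logamp, logsig, cache = stack.emit(conf)
        gmm = GaussianMixture(coords, base.amplitudes * np.exp(logamp),
                              base.widths * np.exp(logsig))
        batch = [(it * config.batch_size + j) % config.n_orientations
                 for j in range(config.batch_size)]
        s, dc, da, dw = maploss.score_and_grad(gmm, batch, resolution)
        grads = stack.backward(cache, -dc, -da * gmm.amplitudes,
                               -dw * gmm.widths)
        for k, g in grads.items():
            opt[k].step(g)
    coords = stack.emit(conf)[0]
    g1 = geometry(coords)[0]
    m1 = maploss.mean_frc(GaussianMixture(coords, base.amplitudes,
                                          base.widths), resolution)
    stack.reinitialize()
    return balance_rule(m1 - m0, g1 - g0)


def balance_rule(dmap_delta: float, dgeom_delta: float,
                 default_weight: float = 1.0) -> WeightBalance:
    """Reciprocal rule: ratio = |map gain| / |geometry degradation|;
    geometry weight = 1/ratio.  Degenerate deltas fall back to the default
    weight with a warning."""
    if abs(dgeom_delta) < 1e-9 or abs(dmap_delta) < 1e-6:
        logger.warning("weight balancing degenerate (dmap=%.3g dgeom=%.3g);"
                       " using default weight %.3g", dmap_delta,
                       dgeom_delta, default_weight)
        return WeightBalance(np.inf, default_weight, fallback=True)
    ratio = abs(dmap_delta) / abs(dgeom_delta)
    return WeightBalance(ratio, 1.0 / ratio)


def refine(model, dmap, config: RefinementConfig):
    """Run the five-stage refinement; returns (refined model, reports).

    The returned model contains heavy atoms only (hydrogens used for clash
    scoring are a deterministic function of it).
    """
    t_start = time.time()
    heavy = model.heavy_model()
    reports = {"stages": {}}
    # stage 1: topology + score tables
    patches = make_patches(heavy, min(config.patch_count,
                                      len(heavy.residues)), config.seed)
    stack = DecoderStack(heavy.coords, patches, config.conf_dim,
                         config.width, config.seed)
    stack.attach_residues(heavy)
    conf = np.ones(config.conf_dim)
    geometry_basic = GeometryBundle(heavy, config,
                                    terms=("bond", "angle", "clash"))
    geometry_full = GeometryBundle(heavy, config,
                                   terms=("bond", "angle", "planarity",
                                          "rama", "rotamer", "suite",
                                          "clash"))
    maploss = None if (dmap is None or config.geometry_only) \
        else _MapLoss(dmap, config)
    reports["stages"]["compile"] = {
        "n_bonds": geometry_basic.topo.n_bonds,
        "n_patches": patches.k,
    }

    geom_weight = config.geometry_weight
    if geom_weight is None and maploss is not None:
        stack.active = {"d1", "d2"}
        wb = _balance(stack, geometry_basic, maploss, config, conf, heavy)
        lo, hi = config.geometry_weight_bounds
        geom_weight = float(np.clip(wb.geometry_weight, lo, hi))
        reports["balance"] = {"ratio": wb.ratio, "weight": geom_weight,
                              "raw_weight": wb.geometry_weight,
                              "fallback": wb.fallback}
    elif geom_weight is None:
        geom_weight = 1.0

    if maploss is not None:
        # stage 2: large-scale morphing, map only
        stack.active = {"d1"}
        res2 = config.stage_resolution(2)
        base2 = _base_gmm(heavy, res2)
        coords, hist, _ = _train_stage(stack, None, maploss, config,
                                       config.iterations[0], res2,
                                       0.0, conf, base2, stage_name="stage2")
        reports["stages"]["morph"] = _stage_summary(hist)
        # stage 3: residue-level, basic geometry on
        stack.active = {"d1", "d2"}
        res3 = config.stage_resolution(3)
        base3 = _base_gmm(heavy, res3)
        coords, hist, _ = _train_stage(stack, geometry_basic, maploss,
                                       config, config.iterations[1], res3,
                                       geom_weight, conf, base3,
                                       stage_name="stage3")
        reports["stages"]["residue"] = _stage_summary(hist)
        # stage 4: rotamer rebuild (gated by resolution)
        do_rebuild = config.rebuild_rotamers
        if do_rebuild is None:
            do_rebuild = config.resolution \
                <= config.rebuild_resolution_gate
        if do_rebuild and len(geometry_full.topo.chi_idx):
            interim = heavy.with_coords(coords)
            rebuilt, info = rebuild_rotamers(
                interim, dmap, geometry_full.libs["rotamer"],
                topo=geometry_full.topo)
            # fold the chi changes into the stack's reference coordinates
            stack.x0 = rebuilt.coords.copy()
            stack.attach_residues(heavy)
            stack.reinitialize()
            stack.active = {"d1", "d2"}
            reports["stages"]["rotamer_rebuild"] = {
                "n_rebuilt": len(info)}
    # stage 5: full-atom with every constraint
    stack.active = {"d1", "d2", "d3"} if maploss is not None else {"d3"}
    res5 = config.resolution
    base5 = _base_gmm(heavy, res5)
    invert = config.invert_geometry
    if invert:
        stack.active = {"d3"}
        stack.max_displacement = config.max_displacement or 0.3
        map5 = None
        geometry5 = AdversarialBundle(geometry_full)
        weight5 = 1.0
    else:
        stack.max_displacement = config.max_displacement
        map5 = maploss
        geometry5 = geometry_full
        weight5 = geom_weight
    coords, hist, best = _train_stage(stack, geometry5, map5, config,
                                      config.iterations[2], res5,
                                      weight5, conf, base5,
                                      invert=invert, stage_name="stage5")
    final = coords
    reports["stages"]["full_atom"] = _stage_summary(hist)
    out = heavy.with_coords(final)
    reports["final"] = score_model(out, dmap, config.resolution,
                                   geometry_full)
    reports["runtime_s"] = time.time() - t_start
    return out, reports


def _stage_summary(history):
    out = {}
    if history["map_score"]:
        out["map_score_first"] = history["map_score"][0]
        out["map_score_last"] = history["map_score"][-1]
    if history["geometry_loss"]:
        out["geometry_loss_first"] = history["geometry_loss"][0]
        out["geometry_loss_last"] = history["geometry_loss"][-1]
    if history["metrics"]:
        out["metrics_last"] = history["metrics"][-1]
    return out


def score_model(model, dmap=None, resolution: float = 4.0,
                geometry: GeometryBundle | None = None,
                config: RefinementConfig | None = None) -> dict:
    """Validation-style report matching the per-module scores exactly."""
    heavy = model.heavy_model()
    if geometry is None:
        cfg = config or RefinementConfig(resolution=resolution)
        geometry = GeometryBundle(heavy, cfg,
                                  terms=("bond", "angle", "planarity",
                                         "rama", "rotamer", "suite",
                                         "clash"))
    geometry.nlist = None          # fresh neighbor list for scoring
    _, _, metrics = geometry(heavy.coords)
    out = dict(metrics)
    if dmap is not None:
        ml = _MapLoss(dmap, config or RefinementConfig(
            resolution=resolution))
        out["map_frc"] = ml.mean_frc(_base_gmm(heavy, resolution),
                                     resolution)
    return out
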