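"""Conformation-conditioned model series refinement.

Input: a stack of 3D reconstructions with their latent conformation
coordinates (produced by any heterogeneity analysis).  The decoder stack of
the single-model refinement is trained with the sample's latent coordinate
(plus a small Gaussian jitter, as in variational autoencoders) as the
conformation input, pairing each training batch with projections of that
sample's map.  After the map-driven phase, additional geometry-only rounds
run at latents drawn uniformly along the trajectory so that frames *between*
the sampled conformations also keep valid stereochemistry.  The result is a
continuous series of models parameterized by the latent coordinate.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .gmm_density import DensityMap, GaussianMixture
from .refine_single import (DecoderStack, GeometryBundle, RefinementConfig,
                            _MapLoss, _balance, _base_gmm, make_patches,
                            score_model)
from .nn import Adam

logger = logging.getLogger("gmmrefine")


@dataclass
class ConformationSample:
    """A latent conformation coordinate paired with its reconstruction."""

    latent: np.ndarray
    dmap: DensityMap
    weight: float = 1.0

    def __post_init__(self):
        self.latent = np.atleast_1d(np.asarray(self.latent, float))


@dataclass
class TrajectorySpec:
    """Path through latent space along which frames are emitted."""

    points: np.ndarray           # (P, d) ordered latent waypoints
    n_frames: int = 10
    noise_sigma: float | None = None   # default: 5% of the path length
    seed: int = 0
    closed: bool = False

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        if self.n_frames < 2:
            raise ValueError("need at least two frames")

    @property
    def path_length(self) -> float:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    def frame_latents(self) -> np.ndarray:
        """n_frames latents spaced evenly in arc length along the path."""
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1] if cum[-1] > 0 else 1.0
        ts = np.linspace(0.0, total, self.n_frames,
                         endpoint=not self.closed)
        out = []
        for t in ts:
            i = min(np.searchsorted(cum, t, side="right") - 1,
                    len(seg) - 1) if len(seg) else 0
            if len(seg) == 0 or seg[i] == 0:
                out.append(pts[0])
            else:
                f = (t - cum[i]) / seg[i]
                out.append(pts[i] * (1 - f) + pts[i + 1] * f)
        return np.array(out)

    def sample_latents(self, n: int, rng) -> np.ndarray:
        """Uniformly distributed latents along the trajectory."""
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1] if cum[-1] > 0 else 1.0
        ts = rng.uniform(0, total, n)
        out = []
        for t in ts:
            i = min(np.searchsorted(cum, t, side="right") - 1,
                    len(seg) - 1) if len(seg) else 0
            if len(seg) == 0 or seg[i] == 0:
                out.append(pts[0])
            else:
                f = (t - cum[i]) / seg[i]
                out.append(pts[i] * (1 - f) + pts[i + 1] * f)
        return np.array(out)


def refine_series(base_model, samples: list, traj: TrajectorySpec,
                  config: RefinementConfig,
                  geometry_rounds: int = 200,
                  trust_radius: float = 1.0):
    """Train the decoder stack against the map stack and emit the series.

    ``base_model`` should already be refined against the consensus map.
    Returns (list of MolecularModel frames, reports dict).
    """
    if not samples:
        raise ValueError("no conformation samples")
    d = len(samples[0].latent)
    for s in samples:
        if len(s.latent) != d:
            raise ValueError("mismatched latent dimensionality")
    if traj.points.shape[1] != d:
        raise ValueError("trajectory dimensionality does not match samples")
    if len(samples) == 1:
        logger.warning("single conformation sample: series refinement "
                       "degenerates to single-model refinement")
    rng = np.random.default_rng(config.seed)
    noise = traj.noise_sigma
    if noise is None:
        noise = 0.05 * max(traj.path_length, 1e-12)

    heavy = base_model.heavy_model()
    patches = make_patches(heavy, min(config.patch_count,
                                      len(heavy.residues)), config.seed)
    stack = DecoderStack(heavy.coords, patches, d, config.width,
                         config.seed)
    stack.attach_residues(heavy)
    geometry_basic = GeometryBundle(heavy, config,
                                    terms=("bond", "angle", "clash"))
    geometry_full = GeometryBundle(heavy, config,
                                   terms=("bond", "angle", "planarity",
                                          "rama", "rotamer", "suite",
                                          "clash"))
    maplosses = [_MapLoss(s.dmap, config) for s in samples]
    weights = np.array([s.weight for s in samples], float)
    weights = weights / weights.sum()
    reports = {"stages": {}}

    geom_weight = config.geometry_weight
    if geom_weight is None:
        stack.active = {"d1", "d2"}
        wb = _balance(stack, geometry_basic, maplosses[0], config,
                      samples[0].latent, heavy)
        lo, hi = config.geometry_weight_bounds
        geom_weight = float(np.clip(wb.geometry_weight, lo, hi))
        reports["balance"] = {"ratio": wb.ratio, "weight": geom_weight,
                              "raw_weight": wb.geometry_weight}

    def train_phase(active, geometry, n_iter, resolution, name):
        stack.active = active
        base = _base_gmm(heavy, resolution)
        optim = {k: Adam(getattr(stack, k).params,
                         lr=config.learning_rate) for k in active}
        hist = {"map_score": [], "geometry_loss": []}
        for it in range(n_iter):
            si = rng.choice(len(samples), p=weights)
            conf = samples[si].latent + rng.normal(scale=noise, size=d)
            coords, logamp, logsig, cache = stack.emit(conf)
            gmm = GaussianMixture(coords,
                                  base.amplitudes * np.exp(logamp),
                                  base.widths * np.exp(logsig))
            bsz = config.batch_size
            batch = [(it * bsz + j) % config.n_orientations
                     for j in range(bsz)]
            s, dc, da, dw = maplosses[si].score_and_grad(gmm, batch,
                                                         resolution)
            dcoords = -dc
            dlogamp = -da * gmm.amplitudes
            dlogsig = -dw * gmm.widths
            hist["map_score"].append(s)
            if geometry is not None:
                gl, gg, _ = geometry(coords)
                gg_w = geom_weight * gg
                nmap = np.linalg.norm(dcoords)
                ngeom = np.linalg.norm(gg_w)
                cap = config.geometry_gradient_cap
                if nmap > 1e-12 and ngeom > cap * nmap:
                    gg_w *= cap * nmap / ngeom
                dcoords = dcoords + gg_w
                hist["geometry_loss"].append(gl)
            grads = stack.backward(cache, dcoords, dlogamp, dlogsig)
            for k, g in grads.items():
                optim[k].step(g)
            if it % 50 == 0:
                logger.info("series %s it %d: map %.4f", name, it, s)
        reports["stages"][name] = {
            "map_first": hist["map_score"][0],
            "map_last": hist["map_score"][-1],
        }

    it2, it3, it5 = config.iterations
    train_phase({"d1"}, None, it2, config.stage_resolution(2), "morph")
    train_phase({"d1", "d2"}, geometry_basic, it3,
                config.stage_resolution(3), "residue")
    train_phase({"d1", "d2", "d3"}, geometry_full, it5, config.resolution,
                "full_atom")

    # geometry-only polishing along the trajectory (D3 only), with a trust
    # radius guarding against drift away from the map-trained series
    stack.active = {"d1", "d2", "d3"}
    probe = traj.frame_latents()
    pre = [stack.emit(lat)[0] for lat in probe]
    d3_backup = copy.deepcopy(stack.d3)
    optim = Adam(stack.d3.params, lr=config.learning_rate)
    reverted = False
    for it in range(geometry_rounds):
        # batch the geometry gradient over every emission latent plus a
        # uniformly-sampled one, so frame corrections do not fight each
        # other through the shared network weights
        lats = list(probe) + [traj.sample_latents(1, rng)[0]]
        acc = None
        for lat in lats:
            coords, _, _, cache = stack.emit(lat)
            gl, gg, _ = geometry_full(coords)
            stack.active = {"d3"}
            grads = stack.backward(cache, geom_weight * gg / len(lats))
            stack.active = {"d1", "d2", "d3"}
            if acc is None:
                acc = grads["d3"]
            else:
                acc = [a + b for a, b in zip(acc, grads["d3"])]
        optim.step(acc)
        if it % 20 == 19:
            disp = max(np.abs(stack.emit(l)[0] - p).max()
                       for l, p in zip(probe, pre))
            if disp > trust_radius:
                stack.d3 = d3_backup
                logger.warning("geometry polishing exceeded trust radius "
                               "(%.2f A); round reverted", disp)
                reverted = True
                break
    reports["stages"]["polish"] = {"rounds": geometry_rounds,
                                   "reverted": reverted}

    frames = []
    for lat in traj.frame_latents():
        coords = stack.emit(lat)[0]
        frames.append(heavy.with_coords(coords.copy()))
    reports["frame_latents"] = traj.frame_latents()
    return frames, reports


def series_report(series: list, resolution: float = 8.0,
                  config: RefinementConfig | None = None):
    """Per-frame geometry metrics table (pandas DataFrame).

    Metrics per frame equal single-model scoring of that frame in
    isolation.
    """
    import pandas as pd

    if not series:
        raise ValueError("empty series")
    rows = []
    for fi, frame in enumerate(series):
        metrics = score_model(frame, None, resolution, config=config)
        row = {"frame": fi}
        row.update({k: v for k, v in metrics.items()})
        rows.append(row)
    return pd.DataFrame(rows)
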