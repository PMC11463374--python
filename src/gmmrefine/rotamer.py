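"""Differentiable sidechain-rotamer scoring and map-driven rotamer rebuild.

Chi-angle histograms (1-4 dimensional depending on residue chemistry) are
fitted with periodic Gaussian mixtures on the log-score scale; components
are seeded at detected histogram peaks and optimized locally.  The fitted
mixtures give a likelihood term and an outlier hinge penalty, both
differentiable through the chi dihedrals back to atom coordinates.

The rebuild procedure enumerates library peaks for each residue, re-poses
the sidechain at each candidate (ideal internal geometry, only chi varies),
selects the candidate with the best local real-space map agreement, and
then polishes all chi angles jointly with Adam against a composite
map + rotamer - clash objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geom_scores import dihedrals_with_grad, wrap_angle

logger = logging.getLogger("gmmrefine")

LOG_C = -10.0
C_CONST = float(np.exp(LOG_C))
#: outlier threshold on the original score scale (assumed, configurable)
OUTLIER_SCORE = 0.003
#: mixture component counts per chi dimensionality
COMPONENT_COUNT = {1: 4, 2: 25, 3: 64, 4: 160}


class DegenerateHistogramError(ValueError):
    """Raised for histograms with no detectable peaks."""


@dataclass
class RotamerHistogram:
    """Periodic d-dimensional chi histogram, max-normalized to 1."""

    res_type: str
    step: float
    values: np.ndarray           # shape (g,) * d

    def __post_init__(self):
        self.values = np.asarray(self.values, float)

    @property
    def d(self) -> int:
        return self.values.ndim

    @property
    def axis(self) -> np.ndarray:
        return -180.0 + self.step * np.arange(self.values.shape[0])

    def grid_points(self) -> np.ndarray:
        axes = [self.axis] * self.d
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def lookup(self, chi) -> np.ndarray:
        chi = np.atleast_2d(np.asarray(chi, float))
        g = self.values.shape[0]
        idx = np.round((wrap_angle(chi) + 180.0) / self.step).astype(int) % g
        return self.values[tuple(idx.T)]

    @classmethod
    def from_text(cls, text: str) -> "RotamerHistogram":
        lines = [ln for ln in text.splitlines()
                 if ln.strip() and not ln.startswith("#")]
        res_type, d = lines[0].split()
        step = float(lines[1])
        flat = np.array([float(v) for ln in lines[2:] for v in ln.split()])
        g = int(round(flat.size ** (1.0 / int(d))))
        return cls(res_type, step, flat.reshape((g,) * int(d)))

    def to_text(self) -> str:
        flat = self.values.ravel()
        rows = "\n".join(" ".join(f"{v:.6g}" for v in flat[i:i + 16])
                         for i in range(0, flat.size, 16))
        return f"{self.res_type} {self.d}\n{self.step}\n{rows}\n"


def _wrap(a):
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


@dataclass
class RotamerGMM:
    """Fitted periodic mixture over chi-space (log-score scale)."""

    res_type: str
    centers: np.ndarray          # (K, d)
    widths: np.ndarray           # (K,)
    weights: np.ndarray          # (K,)
    base: float = LOG_C
    outlier_score: float = OUTLIER_SCORE
    fit_rmsd: float = np.nan

    @property
    def d(self) -> int:
        return self.centers.shape[1]

    def evaluate_with_grad(self, chi):
        chi = np.atleast_2d(np.asarray(chi, float))
        dx = _wrap(chi[:, None, :] - self.centers[None, :, :])
        s2 = self.widths[None, :] ** 2
        g = np.exp(-np.sum(dx ** 2, axis=2) / (2 * s2))
        y = self.base + g @ self.weights
        wg = (g * self.weights[None, :])[:, :, None]
        dy = np.sum(wg * (-dx / s2[:, :, None]), axis=1)
        return y, dy

    def evaluate(self, chi):
        return self.evaluate_with_grad(chi)[0]

    def score(self, chi):
        return np.maximum(np.exp(self.evaluate(chi)) - C_CONST, 0.0)

    def peak_centers(self, rel_weight: float = 0.01) -> np.ndarray:
        """Library peaks: component centers with weight above 1% of max."""
        wmax = self.weights.max()
        return self.centers[self.weights > rel_weight * wmax]

    def to_hdf5(self, group) -> None:
        group.attrs["res_type"] = self.res_type
        group.attrs["fit_rmsd"] = self.fit_rmsd
        for k in ("centers", "widths", "weights"):
            group.create_dataset(k, data=getattr(self, k))

    @classmethod
    def from_hdf5(cls, group) -> "RotamerGMM":
        return cls(str(group.attrs["res_type"]), group["centers"][...],
                   group["widths"][...], group["weights"][...],
                   fit_rmsd=float(group.attrs["fit_rmsd"]))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _find_peaks(hist: RotamerHistogram, min_height: float = 0.05):
    from scipy.ndimage import maximum_filter

    v = hist.values
    mx = maximum_filter(v, size=3, mode="wrap")
    peaks = np.argwhere((v == mx) & (v >= min_height * v.max()
                                     if v.max() > 0 else False))
    heights = v[tuple(peaks.T)] if len(peaks) else np.zeros(0)
    order = np.argsort(-heights)
    return peaks[order], heights[order]


def fit_rotamer_gmm(hist: RotamerHistogram, res_type: str | None = None,
                    seed: int = 0, n_components: int | None = None,
                    n_iter: int = 150, lr: float = 0.5) -> RotamerGMM:
    """Fit the chi-space mixture: components seeded at histogram peaks,
    surplus components placed at the largest-residual cells, then local
    full-batch Adam on the log-transformed target."""
    if hist.values.max() <= 0:
        raise DegenerateHistogramError(
            f"histogram for {res_type or hist.res_type} has no mass")
    res_type = res_type or hist.res_type
    d = hist.d
    K = n_components or COMPONENT_COUNT.get(d, 4 ** d)
    peaks, heights = _find_peaks(hist)
    if len(peaks) == 0:
        raise DegenerateHistogramError("no peaks detected")
    pts = hist.grid_points()
    y = np.log(hist.values.ravel() + C_CONST) - LOG_C
    centers = (-180.0 + hist.step * peaks[:K]).astype(float)
    sigma0 = max(hist.step * 1.5, 8.0)
    if len(centers) < K:
        # surplus components at largest-residual locations
        tmp = RotamerGMM(res_type, centers, np.full(len(centers), sigma0),
                         np.maximum(np.log(heights[:len(centers)]
                                           + C_CONST) - LOG_C, 0.1))
        resid = np.abs(tmp.evaluate(pts) - LOG_C - y)
        order = np.argsort(-resid)
        extra = []
        taken = list(centers)
        for p in order:
            if len(centers) + len(extra) >= K:
                break
            cand = pts[p]
            if all(np.linalg.norm(_wrap(cand - t)) > 2 * hist.step
                   for t in taken[-50:]):
                extra.append(cand)
                taken.append(cand)
        if extra:
            centers = np.vstack([centers, extra])
    K = len(centers)
    widths = np.full(K, sigma0)
    # initial weights: ridge least squares on the basis
    dx = _wrap(pts[:, None, :] - centers[None, :, :])
    B = np.exp(-np.sum(dx ** 2, axis=2) / (2 * widths[None, :] ** 2))
    ata = B.T @ B
    ata[np.diag_indices_from(ata)] += 1e-4 * len(pts) / K
    w = np.linalg.solve(ata, B.T @ y)
    # local Adam refinement of all parameters; centers stay anchored near
    # their detected peaks (the optimization is local by construction)
    init_centers = centers.copy()
    max_shift = 0.15 * hist.step
    log_s = np.log(widths)
    params = [w, centers, log_s]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    steps = [lr, lr * 4, lr * 0.05]
    b1, b2, eps = 0.9, 0.999, 1e-8
    P = len(pts)
    for it in range(n_iter):
        sig = np.exp(log_s)
        dx = _wrap(pts[:, None, :] - centers[None, :, :])
        s2 = sig[None, :] ** 2
        B = np.exp(-np.sum(dx ** 2, axis=2) / (2 * s2))
        r = B @ w - y
        gy = 2 * r / P
        gw = B.T @ gy
        common = gy[:, None] * B * w[None, :]
        gc = np.einsum("pk,pkd->kd", common / s2[:, :], dx)
        gs = np.sum(common * np.sum(dx ** 2, axis=2) / s2, axis=0)
        for g, mm, vv, p, st in zip((gw, gc, gs), m, v, params, steps):
            t = it + 1
            mm[...] = b1 * mm + (1 - b1) * g
            vv[...] = b2 * vv + (1 - b2) * g * g
            p -= st * (mm / (1 - b1 ** t)) / (np.sqrt(vv / (1 - b2 ** t))
                                              + eps)
        np.clip(log_s, np.log(3.0), np.log(60.0), out=log_s)
        drift = _wrap(centers - init_centers)
        centers[...] = init_centers + np.clip(drift, -max_shift, max_shift)
    sig = np.exp(log_s)
    dx = _wrap(pts[:, None, :] - centers[None, :, :])
    B = np.exp(-np.sum(dx ** 2, axis=2) / (2 * sig[None, :] ** 2))
    rmsd = float(np.sqrt(np.mean((B @ w - y) ** 2)))
    return RotamerGMM(res_type, centers, sig, w, fit_rmsd=rmsd)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class RotamerReport:
    scores: np.ndarray
    outlier_count: int
    loss: float
    grad: np.ndarray = None
    n_residues: int = 0


def rotamer_loss(chi_list, res_types, gmms: dict,
                 likelihood_weight: float = 0.1, tau: float = 0.5):
    """Negative log mixture density plus a smooth hinge below the outlier
    threshold; returns the report and per-residue d(loss)/d(chi)."""
    n = len(chi_list)
    scores = np.full(n, np.nan)
    dchis = [None] * n
    loss = 0.0
    counted = 0
    for i, (chi, rt) in enumerate(zip(chi_list, res_types)):
        gmm = gmms.get(rt)
        if gmm is None or chi is None or len(chi) != gmm.d:
            continue
        y, dy = gmm.evaluate_with_grad(np.asarray(chi).reshape(1, -1))
        y = float(y[0])
        thr = np.log(gmm.outlier_score + C_CONST)
        scores[i] = max(np.exp(y) - C_CONST, 0.0)
        hinge = max(thr - y, 0.0)
        loss += likelihood_weight * (-y) + hinge ** 2
        dl_dy = -likelihood_weight - 2 * hinge
        dchis[i] = dl_dy * dy[0]
        counted += 1
    if counted:
        loss /= counted
        dchis = [None if d is None else d / counted for d in dchis]
    valid = ~np.isnan(scores)
    outliers = int(np.sum(scores[valid] < OUTLIER_SCORE))
    return RotamerReport(scores, outliers, loss, n_residues=counted), dchis


def chi_angles(coords, topo):
    """Per chi-residue chi vectors (degrees) from current coordinates."""
    out = []
    for qarr in topo.chi_idx:
        chi, _ = dihedrals_with_grad(coords, qarr)
        out.append(chi)
    return out


def rotamer_loss_on_coords(coords, topo, gmms: dict,
                           likelihood_weight: float = 0.1) -> RotamerReport:
    n_atoms = len(coords)
    res_types = [None] * len(topo.chi_residues)
    chis, grads = [], []
    # residue types come from the model residue list index
    for k, qarr in enumerate(topo.chi_idx):
        chi, dchi = dihedrals_with_grad(coords, qarr)
        chis.append(chi)
        grads.append((qarr, dchi))
    rts = [topo_res_type(topo, k) for k in range(len(topo.chi_idx))]
    report, dchis = rotamer_loss(chis, rts, gmms, likelihood_weight)
    grad = np.zeros((n_atoms, 3))
    for (qarr, dchi), dl in zip(grads, dchis):
        if dl is None:
            continue
        np.add.at(grad, qarr.ravel(),
                  (dl[:, None, None] * dchi).reshape(-1, 3))
    report.grad = grad
    return report


def topo_res_type(topo, k):
    # stored at compile time on first use
    if not hasattr(topo, "chi_res_types"):
        return None
    return topo.chi_res_types[k]


def attach_chi_res_types(topo, model) -> None:
    topo.chi_res_types = [model.residues[ri].res_type
                          for ri in topo.chi_residues]


# ---------------------------------------------------------------------------
# chi re-posing and rebuild
# ---------------------------------------------------------------------------

def _rotation_about_axis(axis, angle_rad):
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K \
        + (1 - np.cos(angle_rad)) * (K @ K)


def set_chi(coords, topo, k: int, chi_target) -> np.ndarray:
    """Return coordinates with residue k's chi vector rotated to the target
    (bond lengths/angles untouched; only the distal sets rotate)."""
    coords = coords.copy()
    qarr = topo.chi_idx[k]
    rot_sets = topo.chi_rotating[k]
    for j in range(len(qarr)):
        cur = dihedrals_with_grad(coords, qarr[j:j + 1])[0][0]
        delta = np.radians(wrap_angle(chi_target[j] - cur))
        b, c = qarr[j, 1], qarr[j, 2]
        axis = coords[c] - coords[b]
        R = _rotation_about_axis(axis, delta)
        sel = rot_sets[j]
        coords[sel] = (coords[sel] - coords[c]) @ R.T + coords[c]
    return coords


def _interp_map(dmap, pos):
    """Trilinear map value and gradient (per Angstrom) at positions."""
    from scipy.ndimage import map_coordinates

    vox = (np.asarray(pos) - dmap.origin) / dmap.voxel_size
    val = map_coordinates(dmap.data, vox.T, order=1, mode="constant")
    if not hasattr(dmap, "_grad_cache"):
        dmap._grad_cache = np.gradient(dmap.data, dmap.voxel_size)
    grad = np.stack([map_coordinates(g, vox.T, order=1, mode="constant")
                     for g in dmap._grad_cache], axis=1)
    return val, grad


def _local_map_correlation(dmap, atom_pos, sigma, radius=3.0):
    """Real-space correlation between the map and a Gaussian model density
    within ``radius`` of the given atoms."""
    vs = dmap.voxel_size
    lo = np.floor((atom_pos.min(0) - radius - dmap.origin) / vs).astype(int)
    hi = np.ceil((atom_pos.max(0) + radius - dmap.origin) / vs).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(dmap.data.shape) - 1)
    if np.any(hi <= lo):
        return 0.0
    axes = [dmap.origin[i] + vs * np.arange(lo[i], hi[i] + 1)
            for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    d2 = np.min(np.sum((pts[..., None, :] - atom_pos[None, None, None, :, :])
                       ** 2, axis=-1), axis=-1)
    mask = d2 <= radius ** 2
    if mask.sum() < 8:
        return 0.0
    model = np.zeros(mask.sum())
    sel = pts[mask]
    for p in atom_pos:
        model += np.exp(-np.sum((sel - p) ** 2, axis=1) / (2 * sigma ** 2))
    mvals = dmap.data[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1,
                      lo[2]:hi[2] + 1][mask]
    if mvals.std() < 1e-12 or model.std() < 1e-12:
        return 0.0
    return float(np.corrcoef(mvals, model)[0, 1])


def rebuild_rotamers(model, dmap, gmms: dict, topo=None,
                     map_weight: float = 1.0, rotamer_weight: float = 0.3,
                     clash_weight: float = 1.0, sigma: float = 1.0,
                     n_iter: int = 60, lr: float = 3.0):
    """Enumerate library peaks per residue, select the best-matching one
    against the map, then jointly polish all chi angles with Adam.

    Returns (model with replaced chi, per-residue info list).
    """
    from . import clash as clash_mod
    from .model_io import compile_topology

    if topo is None:
        topo = compile_topology(model)
    if not hasattr(topo, "chi_res_types"):
        attach_chi_res_types(topo, model)
    coords = model.coords.copy()
    info = []
    flat_map = dmap is None or float(np.ptp(dmap.data)) < 1e-12
    for k, ri in enumerate(topo.chi_residues):
        rt = topo.chi_res_types[k]
        gmm = gmms.get(rt)
        if gmm is None or gmm.d != len(topo.chi_idx[k]):
            continue
        peaks = gmm.peak_centers()
        side_atoms = sorted({a for s in topo.chi_rotating[k] for a in s}
                            | set(topo.chi_idx[k][:, 3].tolist()))
        best, best_score = None, -np.inf
        for peak in peaks:
            cand = set_chi(coords, topo, k, peak)
            rot_y = float(gmm.evaluate(peak.reshape(1, -1))[0])
            if flat_map:
                score = rot_y
            else:
                corr = _local_map_correlation(dmap, cand[side_atoms], sigma)
                score = map_weight * corr + 0.05 * rot_y
            if score > best_score:
                best_score, best = score, peak
        if best is not None:
            coords = set_chi(coords, topo, k, best)
            info.append({"residue": int(ri), "res_type": rt,
                         "chi": best.copy(), "score": best_score})
    # joint local chi optimization (Adam directly on the chi angles)
    if not flat_map:
        coords = _optimize_chis(coords, topo, gmms, dmap, map_weight,
                                rotamer_weight, clash_weight, model,
                                n_iter, lr)
    # post-condition: no chi vector may be an outlier
    for k in range(len(topo.chi_idx)):
        rt = topo.chi_res_types[k]
        gmm = gmms.get(rt)
        if gmm is None or gmm.d != len(topo.chi_idx[k]):
            continue
        chi = dihedrals_with_grad(coords, topo.chi_idx[k])[0]
        if gmm.score(chi.reshape(1, -1))[0] < gmm.outlier_score:
            # revert to nearest library peak
            peaks = gmm.peak_centers()
            dists = np.linalg.norm(_wrap(peaks - chi), axis=1)
            coords = set_chi(coords, topo, k, peaks[np.argmin(dists)])
    out = model.with_coords(coords)
    return out, info


def _optimize_chis(coords, topo, gmms, dmap, map_w, rot_w, clash_w, model,
                   n_iter, lr):
    from . import clash as clash_mod

    ks = [k for k in range(len(topo.chi_idx))
          if gmms.get(topo.chi_res_types[k]) is not None
          and gmms[topo.chi_res_types[k]].d == len(topo.chi_idx[k])]
    if not ks:
        return coords
    chis = {k: dihedrals_with_grad(coords, topo.chi_idx[k])[0] for k in ks}
    radii = np.array([1.7 if not h else 1.17 for h in model.is_hydrogen])
    nlist = clash_mod.build_neighbor_list(coords, topo)

    def objective_and_grad(c):
        total = 0.0
        gatom = np.zeros_like(c)
        mv, mg = _interp_map(dmap, c)
        total += map_w * float(mv.mean())
        gatom += map_w * mg / len(c)
        rep = clash_mod.clash_loss(c, nlist, model, topo)
        total -= clash_w * rep.penalty
        gatom -= clash_w * rep.grad
        rep_r = rotamer_loss_on_coords(c, topo, gmms)
        total -= rot_w * rep_r.loss
        gatom -= rot_w * rep_r.grad
        return total, gatom

    m = {k: np.zeros(len(chis[k])) for k in ks}
    v = {k: np.zeros(len(chis[k])) for k in ks}
    best_obj, best_coords = -np.inf, coords.copy()
    b1, b2, eps = 0.9, 0.999, 1e-8
    for it in range(n_iter):
        obj, gatom = objective_and_grad(coords)
        if obj > best_obj:
            best_obj, best_coords = obj, coords.copy()
        for k in ks:
            qarr = topo.chi_idx[k]
            g = np.zeros(len(qarr))
            for j in range(len(qarr)):
                b, cx = qarr[j, 1], qarr[j, 2]
                axis = coords[cx] - coords[b]
                axis = axis / np.linalg.norm(axis)
                sel = topo.chi_rotating[k][j]
                arm = coords[sel] - coords[cx]
                dpos = np.cross(axis[None, :], arm)     # per radian
                g[j] = np.sum(dpos * gatom[sel]) * np.pi / 180.0
            t = it + 1
            m[k][...] = b1 * m[k] + (1 - b1) * g
            v[k][...] = b2 * v[k] + (1 - b2) * g * g
            step = lr * (m[k] / (1 - b1 ** t)) \
                / (np.sqrt(v[k] / (1 - b2 ** t)) + eps)
            chis[k] = chis[k] + step                     # ascent
            coords = set_chi(coords, topo, k, chis[k])
    obj, _ = objective_and_grad(coords)
    if obj < best_obj:
        coords = best_coords
    return coords
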