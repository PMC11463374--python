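"""Differentiable Ramachandran scoring.

Discrete (phi, psi) histograms (six residue classes: General, Gly,
trans-Pro, cis-Pro, pre-Pro, Ile) are converted into smooth periodic 2D
Gaussian mixtures fitted to the log-transformed score ln(R + C) with
C = e^-10.  Extra penalty weight is placed on histogram cells below the
outlier threshold (R < 0.0005) so that every histogram outlier remains an
outlier under the mixture representation.  The fitted surface provides
scores and analytic gradients with respect to the backbone dihedrals, which
chain back to atom coordinates through the dihedral gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geom_scores import dihedrals_with_grad, wrap_angle

logger = logging.getLogger("gmmrefine")

LOG_C = -10.0
C_CONST = float(np.exp(LOG_C))
OUTLIER_R = 0.0005
#: favored/allowed boundary (MolProbity convention)
FAVORED_R = 0.02

RAMA_CLASSES = ("General", "Gly", "transPro", "cisPro", "prePro", "Ile")


@dataclass
class RamaHistogram:
    """Periodic (phi, psi) histogram, max-normalized to 1.

    ``values[i, j]`` is the score at phi = -180 + i*step, psi = -180 + j*step.
    """

    residue_class: str
    step: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.min() < 0:
            raise ValueError("histogram values must be non-negative")

    @property
    def axis(self) -> np.ndarray:
        return -180.0 + self.step * np.arange(self.values.shape[0])

    def grid_points(self) -> np.ndarray:
        p, q = np.meshgrid(self.axis, self.axis, indexing="ij")
        return np.stack([p.ravel(), q.ravel()], axis=1)

    def lookup(self, phi, psi) -> np.ndarray:
        """Nearest-cell histogram lookup (the non-differentiable oracle)."""
        i = np.round((wrap_angle(phi) + 180.0) / self.step).astype(int) \
            % self.values.shape[0]
        j = np.round((wrap_angle(psi) + 180.0) / self.step).astype(int) \
            % self.values.shape[1]
        return self.values[i, j]

    @classmethod
    def from_text(cls, text: str) -> "RamaHistogram":
        """Parse the documented plain-text grid format:
        line 1: class name, line 2: step, then row-major values."""
        lines = [ln for ln in text.splitlines()
                 if ln.strip() and not ln.startswith("#")]
        name = lines[0].strip()
        step = float(lines[1])
        vals = np.array([[float(v) for v in ln.split()] for ln in lines[2:]])
        return cls(name, step, vals)

    def to_text(self) -> str:
        rows = "\n".join(" ".join(f"{v:.6g}" for v in row)
                         for row in self.values)
        return f"{self.residue_class}\n{self.step}\n{rows}\n"


def _wrap(a):
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


@dataclass
class Histogram2DGMM:
    """Fitted periodic mixture surface over the (phi, psi) torus.

    Evaluation returns the log-score Y; the original-scale score is
    R = exp(Y) - C clipped at zero.  Periodicity is handled by minimum-image
    angle differences (component widths are capped well below 90 deg, which
    makes this identical to replicating components across torus images).
    """

    residue_class: str
    centers: np.ndarray          # (K, 2) degrees
    widths: np.ndarray           # (K,) isotropic sigma, degrees
    weights: np.ndarray          # (K,) signed
    base: float = LOG_C          # constant offset of the fitted surface
    outlier_r: float = OUTLIER_R
    favored_r: float = FAVORED_R
    fit_rmsd: float = np.nan
    converged: bool = True

    def evaluate(self, phi, psi) -> np.ndarray:
        return self._eval(np.asarray(phi, float), np.asarray(psi, float))[0]

    def evaluate_with_grad(self, phi, psi):
        return self._eval(np.asarray(phi, float), np.asarray(psi, float))

    def _eval(self, phi, psi):
        dphi = _wrap(phi.reshape(-1, 1) - self.centers[None, :, 0])
        dpsi = _wrap(psi.reshape(-1, 1) - self.centers[None, :, 1])
        s2 = self.widths[None, :] ** 2
        g = np.exp(-(dphi ** 2 + dpsi ** 2) / (2 * s2))
        y = self.base + g @ self.weights
        wg = g * self.weights[None, :]
        dy_dphi = np.sum(wg * (-dphi / s2), axis=1)
        dy_dpsi = np.sum(wg * (-dpsi / s2), axis=1)
        return y, dy_dphi, dy_dpsi

    def score(self, phi, psi) -> np.ndarray:
        """Original-scale score R >= 0."""
        return np.maximum(np.exp(self.evaluate(phi, psi)) - C_CONST, 0.0)

    # -- persistence --------------------------------------------------------
    def to_hdf5(self, group) -> None:
        group.attrs["residue_class"] = self.residue_class
        group.attrs["base"] = self.base
        group.attrs["fit_rmsd"] = self.fit_rmsd
        for k in ("centers", "widths", "weights"):
            group.create_dataset(k, data=getattr(self, k))

    @classmethod
    def from_hdf5(cls, group) -> "Histogram2DGMM":
        return cls(str(group.attrs["residue_class"]),
                   group["centers"][...], group["widths"][...],
                   group["weights"][...], float(group.attrs["base"]),
                   fit_rmsd=float(group.attrs["fit_rmsd"]))


def _log_target(hist: RamaHistogram) -> np.ndarray:
    return np.log(hist.values + C_CONST)


#: decreasing (width, min separation) schedule in degrees for the adaptive
#: placement rounds; widths are floored at 1.2 grid steps against aliasing
_ADAPTIVE_SCHEDULE = ((8.0, 6.0), (6.0, 4.0), (4.5, 3.0), (3.5, 2.5),
                      (2.8, 2.2), (2.4, 2.0))


def fit_rama_gmm(hist: RamaHistogram, n_components: int = 2500,
                 boundary_penalty_weight: float = 5.0, seed: int = 0,
                 rmsd_tol: float = 1e-3, margin: float = 0.1,
                 n_rounds: int | None = None) -> Histogram2DGMM:
    """Fit a periodic 2D mixture to the log-transformed histogram.

    About 40% of the components sit on a uniform torus grid and are solved
    by ridge least squares; the remaining budget is spent in rounds of
    decreasing component width that place components at the cells with the
    largest residual (re-solving after each round), concentrating capacity
    where the log-surface has structure.  A final iteratively-reweighted
    pass adds a one-sided penalty on histogram-outlier cells whose fitted
    score creeps above the outlier contour, so that every histogram outlier
    is also an outlier under the mixture representation.
    """
    rng = np.random.default_rng(seed)
    K = n_components
    pts = hist.grid_points()
    y = _log_target(hist).ravel() - LOG_C
    thr_y = float(np.log(OUTLIER_R + C_CONST)) - LOG_C
    out_cells = hist.values.ravel() < OUTLIER_R

    side = max(int(np.sqrt(0.4 * K)), 2)
    g1 = -180.0 + 360.0 * (np.arange(side) + 0.5) / side
    cp, cq = np.meshgrid(g1, g1, indexing="ij")
    centers = np.stack([cp.ravel(), cq.ravel()], axis=1)
    if seed:
        centers = _wrap(centers + rng.uniform(-0.05, 0.05, centers.shape)
                        * 360.0 / side)
    sigmas = np.full(len(centers), 360.0 / side)

    def basis(c, s):
        dp = _wrap(pts[:, 0:1] - c[None, :, 0])
        dq = _wrap(pts[:, 1:2] - c[None, :, 1])
        g = np.exp(-(dp * dp + dq * dq) / (2 * s[None, :] ** 2))
        # explicit intercept column: flat surfaces are represented exactly
        # and the floor level is absorbed into the mixture's base offset
        return np.hstack([g, np.ones((len(pts), 1))])

    def solve(A, wgt=None, target=None, ridge=1e-8):
        t = y if target is None else target
        if wgt is None:
            ata = A.T @ A
            aty = A.T @ t
        else:
            Aw = A * wgt[:, None]
            ata = A.T @ Aw
            aty = Aw.T @ t
        ata[np.diag_indices_from(ata)] += ridge
        return np.linalg.solve(ata, aty)

    A = basis(centers, sigmas)
    w = solve(A)
    r = A @ w - y
    sched = [(max(s, 1.2 * hist.step), max(sep, hist.step))
             for (s, sep) in _ADAPTIVE_SCHEDULE]
    if n_rounds is not None:
        sched = sched[:max(n_rounds, 1)]
    n_rounds = len(sched)
    per_round = max((K - len(centers)) // n_rounds, 1)
    for rd, (sig_rd, sep_rd) in enumerate(sched):
        n_new = per_round if rd < n_rounds - 1 else K - len(centers)
        if n_new <= 0 or np.abs(r).max() < 1e-4:
            break       # residual already negligible; extra components
                        # would only add ripple
        order = np.argsort(-np.abs(r))
        extra = []
        for p in order:
            if len(extra) >= n_new:
                break
            cand = pts[p]
            if all(max(abs(_wrap(cand[0] - e[0])),
                       abs(_wrap(cand[1] - e[1]))) > sep_rd
                   for e in extra):
                extra.append(cand)
        centers = np.vstack([centers, extra])
        sigmas = np.concatenate([sigmas, np.full(len(extra), sig_rd)])
        A = basis(centers, sigmas)
        w = solve(A)
        r = A @ w - y
    # boundary pass: histogram outliers must stay outliers under the fit
    wgt = np.ones(len(pts))
    target = y.copy()
    for _ in range(10):
        yfit = A @ w
        viol = out_cells & (yfit > thr_y - 1e-6)
        if not viol.any():
            break
        wgt[viol] += boundary_penalty_weight
        target[viol] = np.minimum(target[viol], thr_y - margin)
        w = solve(A, wgt, target)
    yfit = A @ w
    rmsd = float(np.sqrt(np.mean((yfit - y) ** 2)))
    gmm = Histogram2DGMM(hist.residue_class, centers, sigmas, w[:-1],
                         base=LOG_C + float(w[-1]), fit_rmsd=rmsd)
    if rmsd > rmsd_tol:
        gmm.converged = False
        logger.warning("rama GMM fit RMSD %.4g above tolerance %.4g",
                       rmsd, rmsd_tol)
    return gmm


def _full_basis(pts, centers, sigma, chunk):
    cols = []
    for lo in range(0, len(centers), chunk):
        hi = min(lo + chunk, len(centers))
        dp = _wrap(pts[:, 0:1] - centers[None, lo:hi, 0])
        dq = _wrap(pts[:, 1:2] - centers[None, lo:hi, 1])
        s2 = sigma[None, lo:hi] ** 2
        cols.append(np.exp(-(dp * dp + dq * dq) / (2 * s2)))
    return np.concatenate(cols, axis=1)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class RamaReport:
    scores: np.ndarray           # per-residue R
    classes: list
    outlier_fraction: float
    allowed_fraction: float
    loss: float
    grad: np.ndarray = None      # (n_atoms, 3) when computed from coords
    n_residues: int = 0

    @property
    def outlier_count(self) -> int:
        return int(np.sum(self.scores < OUTLIER_R))


def rama_score(phi_psi: np.ndarray, classes, gmms: dict,
               tau: float = 0.5, allowed_weight: float = 0.1):
    """Score (phi, psi) pairs against per-class fitted surfaces.

    Returns a :class:`RamaReport` plus the d(loss)/d(phi, psi) array used to
    chain the gradient back to coordinates.
    """
    phi_psi = np.asarray(phi_psi, float).reshape(-1, 2)
    n = len(phi_psi)
    scores = np.zeros(n)
    dangles = np.zeros((n, 2))
    loss = 0.0
    thr_out = np.log(OUTLIER_R + C_CONST)
    thr_fav = np.log(FAVORED_R + C_CONST)
    for cls in set(classes):
        gmm = gmms[cls]
        sel = np.array([c == cls for c in classes])
        y, dyp, dys = gmm.evaluate_with_grad(phi_psi[sel, 0],
                                             phi_psi[sel, 1])
        scores[sel] = np.maximum(np.exp(y) - C_CONST, 0.0)
        so = 1.0 / (1.0 + np.exp(-(thr_out - y) / tau))
        sf = 1.0 / (1.0 + np.exp(-(thr_fav - y) / tau))
        loss += float(np.sum(so) + allowed_weight * np.sum(sf)) / max(n, 1)
        dl_dy = (-so * (1 - so) / tau
                 - allowed_weight * sf * (1 - sf) / tau) / max(n, 1)
        dangles[sel, 0] = dl_dy * dyp
        dangles[sel, 1] = dl_dy * dys
    outlier_fraction = float(np.mean(scores < OUTLIER_R)) if n else 0.0
    allowed_fraction = float(np.mean(scores >= FAVORED_R)) if n else 0.0
    report = RamaReport(scores, list(classes), outlier_fraction,
                        allowed_fraction, loss, n_residues=n)
    return report, dangles


def resolve_classes(coords, topo) -> list:
    """Static classes with Pro cis/trans resolved from the preceding omega."""
    classes = []
    for k, ri in enumerate(topo.rama_residues):
        cls = topo.rama_class[k]
        if cls in ("transPro", "cisPro"):
            oq = topo.omega_prev_idx[ri]
            if oq[0] >= 0:
                omega = dihedrals_with_grad(coords, oq.reshape(1, 4))[0][0]
                cls = "cisPro" if abs(wrap_angle(omega)) < 30.0 else "transPro"
            else:
                cls = "transPro"
        classes.append(cls)
    return classes


def rama_loss_on_coords(coords, topo, gmms, tau: float = 0.5,
                        allowed_weight: float = 0.1) -> RamaReport:
    """Full chain: coordinates -> (phi, psi) -> mixture surface -> loss."""
    n_atoms = len(coords)
    if len(topo.rama_residues) == 0:
        return RamaReport(np.zeros(0), [], 0.0, 0.0, 0.0,
                          np.zeros((n_atoms, 3)), 0)
    phi_q = topo.phi_idx[topo.rama_residues]
    psi_q = topo.psi_idx[topo.rama_residues]
    phi, dphi = dihedrals_with_grad(coords, phi_q)
    psi, dpsi = dihedrals_with_grad(coords, psi_q)
    classes = resolve_classes(coords, topo)
    report, dangles = rama_score(np.stack([phi, psi], axis=1), classes, gmms,
                                 tau, allowed_weight)
    grad = np.zeros((n_atoms, 3))
    np.add.at(grad, phi_q.ravel(),
              (dangles[:, 0:1, None] * dphi).reshape(-1, 3))
    np.add.at(grad, psi_q.ravel(),
              (dangles[:, 1:2, None] * dpsi).reshape(-1, 3))
    report.grad = grad
    return report
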