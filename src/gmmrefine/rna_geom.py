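"""RNA backbone suite scoring.

Each base step is described by seven consecutive backbone dihedrals
(delta-1, epsilon-1, zeta-1, alpha, beta, gamma, delta).  The 7-angle
vector is assigned to the nearest of 46 suite cluster centers under a
per-dimension scaled circular distance.  Suiteness follows the suitename
convention ((cos(pi*d) + 1)/2)^3 for scaled distance d < 1, zero beyond.
The reported mean skips bases with suiteness below 0.001 (validation
convention) whereas the differentiable training loss is a pseudo-Huber
function of the distance to the assigned center summed over *all* bases,
so outlier bases keep a nonzero gradient and cannot be silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geom_scores import dihedrals_with_grad, wrap_angle

SUITE_FLOOR = 0.001
SUITE_ANGLE_NAMES = ("delta-1", "epsilon-1", "zeta-1", "alpha", "beta",
                     "gamma", "delta")


@dataclass
class SuiteLibrary:
    """46 named cluster centers in 7D dihedral space with metric widths."""

    names: list
    centers: np.ndarray          # (46, 7) degrees
    widths: np.ndarray           # (7,) per-dimension scaling, degrees
    score_floor: float = SUITE_FLOOR

    def __post_init__(self):
        self.centers = np.asarray(self.centers, float)
        self.widths = np.asarray(self.widths, float)
        if self.centers.shape != (len(self.names), 7):
            raise ValueError("suite centers must be (n_names, 7)")

    @classmethod
    def default(cls) -> "SuiteLibrary":
        text = resources.files("gmmrefine.data") \
            .joinpath("suite_centers_synthetic.txt").read_text()
        names, centers, widths = [], [], None
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "widths":
                widths = [float(v) for v in parts[1:8]]
            else:
                names.append(parts[0])
                centers.append([float(v) for v in parts[1:8]])
        return cls(names, np.array(centers), np.array(widths))


@dataclass
class SuiteAssignment:
    vectors: np.ndarray          # (S, 7)
    nearest: np.ndarray          # (S,) center index (argmin even for outliers)
    distance: np.ndarray         # (S,) scaled distance to assigned center
    suiteness: np.ndarray        # (S,) in [0, 1]
    outlier: np.ndarray          # (S,) bool, suiteness < floor


def compute_suite_vectors(coords, topo):
    """Per-step 7-angle vectors (degrees) and per-angle gradients."""
    S = len(topo.suite_idx)
    if S == 0:
        return np.zeros((0, 7)), np.zeros((0, 7, 4, 3))
    quads = topo.suite_idx.reshape(-1, 4)
    ang, grad = dihedrals_with_grad(coords, quads)
    return ang.reshape(S, 7), grad.reshape(S, 7, 4, 3)


def assign_suites(vectors, library: SuiteLibrary) -> SuiteAssignment:
    """Nearest-center assignment under the scaled circular metric."""
    vectors = np.asarray(vectors, float).reshape(-1, 7)
    delta = wrap_angle(vectors[:, None, :] - library.centers[None, :, :])
    scaled = delta / library.widths[None, None, :]
    d = np.sqrt(np.mean(scaled ** 2, axis=2))        # (S, 46)
    nearest = np.argmin(d, axis=1)
    dmin = d[np.arange(len(vectors)), nearest]
    suiteness = np.where(dmin < 1.0,
                         ((np.cos(np.pi * np.minimum(dmin, 1.0)) + 1) / 2)
                         ** 3, 0.0)
    return SuiteAssignment(vectors, nearest, dmin, suiteness,
                           suiteness < library.score_floor)


@dataclass
class SuiteReport:
    assignment: SuiteAssignment
    mean_score: float            # validation-style mean over assigned bases
    loss: float                  # training loss including outliers
    grad: np.ndarray = None      # (n_atoms, 3) when computed from coords
    dvectors: np.ndarray = None  # (S, 7) d(loss)/d(angle)


def suite_loss(vectors, library: SuiteLibrary) -> SuiteReport:
    """Reported mean suiteness (assigned bases only) plus the smooth
    pseudo-Huber training loss over all bases."""
    asg = assign_suites(vectors, library)
    member = ~asg.outlier
    mean_score = float(asg.suiteness[member].mean()) if member.any() else 0.0
    if len(asg.vectors) == 0:
        return SuiteReport(asg, mean_score, 0.0,
                           dvectors=np.zeros((0, 7)))
    delta = wrap_angle(asg.vectors
                       - library.centers[asg.nearest])     # (S, 7)
    scaled = delta / library.widths[None, :]
    d2 = np.mean(scaled ** 2, axis=1)
    hub = np.sqrt(1.0 + d2) - 1.0
    loss = float(hub.mean())
    # d(loss)/d(angle_k) = scaled_k / (7 * widths_k * sqrt(1+d2)) / S
    S = len(asg.vectors)
    dvec = scaled / library.widths[None, :] / 7.0 \
        / np.sqrt(1.0 + d2)[:, None] / S
    return SuiteReport(asg, mean_score, loss, dvectors=dvec)


def suite_loss_on_coords(coords, topo, library: SuiteLibrary) -> SuiteReport:
    n_atoms = len(coords)
    vectors, dgrads = compute_suite_vectors(coords, topo)
    report = suite_loss(vectors, library)
    grad = np.zeros((n_atoms, 3))
    if len(vectors):
        contrib = report.dvectors[:, :, None, None] * dgrads   # (S,7,4,3)
        np.add.at(grad, topo.suite_idx.ravel(), contrib.reshape(-1, 3))
    report.grad = grad
    return report
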