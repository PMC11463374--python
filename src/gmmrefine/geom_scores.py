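"""Differentiable bond-length, bond-angle and planar-dihedral losses.

Each restraint contributes a Gaussian negative log-likelihood term
z^2/2 with z = (value - mean)/std, plus a smooth squared-hinge penalty that
activates beyond ``outlier_sigma`` (default 4.5) standard deviations.
Reported outlier counts use the 5-sigma validation convention, deliberately
looser than the penalty threshold, mirroring the safety margin between the
refinement target and the validation report.

This module also owns the vectorized dihedral/angle computations (values in
degrees, analytic gradients in degrees per Angstrom) reused by the
Ramachandran, rotamer and RNA-suite scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import (CompiledTopology, DEFAULT_OUTLIER_SIGMA,
                       REPORT_OUTLIER_SIGMA)

_EPS = 1e-12


@dataclass
class GeomLossReport:
    """Scores and gradient for one class of geometry restraints."""

    loss: float
    likelihood: float
    outlier_penalty: float
    z: np.ndarray
    outlier_count: int
    grad: np.ndarray                     # (n_atoms, 3)
    n_terms: int
    degenerate: int = 0
    kind: str = ""

    def worst_offenders(self, n: int = 10) -> list[tuple[int, float]]:
        order = np.argsort(-np.abs(self.z))[:n]
        return [(int(i), float(self.z[i])) for i in order]

    def to_text(self, n: int = 10) -> str:
        lines = [f"# {self.kind}: loss={self.loss:.6g} "
                 f"outliers={self.outlier_count}/{self.n_terms}",
                 "term_index\tz"]
        lines += [f"{i}\t{z:+.3f}" for i, z in self.worst_offenders(n)]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# internal-coordinate primitives with analytic gradients
# ---------------------------------------------------------------------------

def bond_vectors(coords, idx):
    d = coords[idx[:, 1]] - coords[idx[:, 0]]
    r = np.sqrt(np.maximum(np.einsum("ij,ij->i", d, d), _EPS))
    return d, r


def angles_with_grad(coords, idx):
    """Bond angles (degrees) for index triples and gradients (deg/A) with
    shape (n, 3, 3): gradient for atoms a, b, c of each triple."""
    a, b, c = coords[idx[:, 0]], coords[idx[:, 1]], coords[idx[:, 2]]
    u, v = a - b, c - b
    nu = np.sqrt(np.maximum(np.einsum("ij,ij->i", u, u), _EPS))
    nv = np.sqrt(np.maximum(np.einsum("ij,ij->i", v, v), _EPS))
    uh, vh = u / nu[:, None], v / nv[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    sin = np.sqrt(np.maximum(1 - cosang ** 2, 1e-12))
    # guarded at collinear triples: gradient magnitude capped by sin floor
    da = (cosang[:, None] * uh - vh) / (nu * sin)[:, None]
    dc = (cosang[:, None] * vh - uh) / (nv * sin)[:, None]
    db = -da - dc
    grad = np.degrees(np.stack([da, db, dc], axis=1))
    return theta, grad


def dihedrals_with_grad(coords, quads):
    """IUPAC-signed dihedral angles (degrees) for (n, 4) index quads and
    gradients (deg/A) of shape (n, 4, 3)."""
    quads = np.asarray(quads, int).reshape(-1, 4)
    p0, p1, p2, p3 = (coords[quads[:, k]] for k in range(4))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.sqrt(np.maximum(np.einsum("ij,ij->i", b2, b2), _EPS))
    m = np.cross(b2 / nb2[:, None], n1)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    phi = np.degrees(np.arctan2(y, x))
    sn1 = np.maximum(np.einsum("ij,ij->i", n1, n1), _EPS)
    sn2 = np.maximum(np.einsum("ij,ij->i", n2, n2), _EPS)
    dp0 = -(nb2 / sn1)[:, None] * n1
    dp3 = (nb2 / sn2)[:, None] * n2
    t = np.einsum("ij,ij->i", b1, b2) / (nb2 ** 2)
    s = np.einsum("ij,ij->i", b3, b2) / (nb2 ** 2)
    dp1 = -(1 + t)[:, None] * dp0 + s[:, None] * dp3
    dp2 = t[:, None] * dp0 - (1 + s)[:, None] * dp3
    grad = np.degrees(np.stack([dp0, dp1, dp2, dp3], axis=1))
    return phi, grad


def dihedral_angles(coords, quads) -> np.ndarray:
    return dihedrals_with_grad(coords, quads)[0]


def wrap_angle(a):
    """Wrap degrees to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def scatter_grad(grad, idx, contrib, n_atoms):
    """Accumulate per-term atom gradients into a (n_atoms, 3) array."""
    np.add.at(grad, idx.ravel(), contrib.reshape(-1, 3))
    return grad


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _z_loss(z, outlier_sigma, penalty_weight=1.0):
    """Likelihood + hinge pieces of the z-score loss and d(loss)/dz."""
    n = max(len(z), 1)
    likelihood = float(np.sum(z ** 2) / (2 * n))
    excess = np.maximum(np.abs(z) - outlier_sigma, 0.0)
    penalty = penalty_weight * float(np.sum(excess ** 2) / n)
    dz = z / n + penalty_weight * 2 * excess * np.sign(z) / n
    return likelihood, penalty, dz


def bond_length_loss(coords, topo: CompiledTopology,
                     outlier_sigma: float = DEFAULT_OUTLIER_SIGMA,
                     penalty_weight: float = 1.0) -> GeomLossReport:
    """Mean z^2/2 over bonds plus the squared-hinge outlier penalty."""
    n_atoms = len(coords)
    idx = topo.bond_idx
    grad = np.zeros((n_atoms, 3))
    if len(idx) == 0:
        return GeomLossReport(0.0, 0.0, 0.0, np.zeros(0), 0, grad, 0,
                              kind="bond")
    d, r = bond_vectors(coords, idx)
    degenerate = int(np.sum(r < 1e-4))
    z = (r - topo.bond_mean) / topo.bond_std
    likelihood, penalty, dz = _z_loss(z, outlier_sigma, penalty_weight)
    # dr/dx_j = d/r ; dz/dr = 1/std
    dd = (dz / topo.bond_std / r)[:, None] * d
    np.add.at(grad, idx[:, 1], dd)
    np.add.at(grad, idx[:, 0], -dd)
    outliers = int(np.sum(np.abs(z) > REPORT_OUTLIER_SIGMA))
    return GeomLossReport(likelihood + penalty, likelihood, penalty, z,
                          outliers, grad, len(idx), degenerate, "bond")


def bond_angle_loss(coords, topo: CompiledTopology,
                    outlier_sigma: float = DEFAULT_OUTLIER_SIGMA,
                    penalty_weight: float = 1.0) -> GeomLossReport:
    n_atoms = len(coords)
    idx = topo.angle_idx
    grad = np.zeros((n_atoms, 3))
    if len(idx) == 0:
        return GeomLossReport(0.0, 0.0, 0.0, np.zeros(0), 0, grad, 0,
                              kind="angle")
    theta, dtheta = angles_with_grad(coords, idx)
    z = (theta - topo.angle_mean) / topo.angle_std
    likelihood, penalty, dz = _z_loss(z, outlier_sigma, penalty_weight)
    contrib = (dz / topo.angle_std)[:, None, None] * dtheta
    scatter_grad(grad, idx, contrib, n_atoms)
    outliers = int(np.sum(np.abs(z) > REPORT_OUTLIER_SIGMA))
    return GeomLossReport(likelihood + penalty, likelihood, penalty, z,
                          outliers, grad, len(idx), 0, "angle")


def planarity_loss(coords, topo: CompiledTopology,
                   thresholds: dict | None = None) -> GeomLossReport:
    """Squared-hinge penalty on the deviation of each planar dihedral from
    its nearest planar value (0 or 180 degrees); zero below the class
    threshold (30 deg for peptide omega, 10 deg for other planar groups)."""
    if thresholds is None:
        thresholds = {"peptide": 30.0, "other": 10.0}
    n_atoms = len(coords)
    idx = topo.planar_idx
    grad = np.zeros((n_atoms, 3))
    if len(idx) == 0:
        return GeomLossReport(0.0, 0.0, 0.0, np.zeros(0), 0, grad, 0,
                              kind="planarity")
    phi, dphi = dihedrals_with_grad(coords, idx)
    w = wrap_angle(phi)
    d0 = np.abs(w)
    dev = np.minimum(d0, 180.0 - d0)
    thr = np.array([thresholds[c] for c in topo.planar_class])
    excess = np.maximum(dev - thr, 0.0)
    n = len(idx)
    penalty = float(np.sum(excess ** 2) / n)
    # d(dev)/d(phi): +sign(w) on the 0-side, -sign(w) on the 180-side
    sign = np.where(d0 <= 180.0 - d0, np.sign(w), -np.sign(w))
    dpen = 2 * excess * sign / n
    contrib = dpen[:, None, None] * dphi
    scatter_grad(grad, idx, contrib, n_atoms)
    outliers = int(np.sum(excess > 0))
    z = dev / np.maximum(thr, 1e-9)
    return GeomLossReport(penalty, 0.0, penalty, z, outliers, grad, n, 0,
                          "planarity")


@dataclass
class GeometryScores:
    """Bundle of all basic geometry reports with a combined loss/gradient."""
    bond: GeomLossReport
    angle: GeomLossReport
    planarity: GeomLossReport
    weights: tuple = (1.0, 1.0, 1.0)

    @property
    def loss(self) -> float:
        return (self.weights[0] * self.bond.loss
                + self.weights[1] * self.angle.loss
                + self.weights[2] * self.planarity.loss)

    @property
    def grad(self) -> np.ndarray:
        return (self.weights[0] * self.bond.grad
                + self.weights[1] * self.angle.grad
                + self.weights[2] * self.planarity.grad)


def basic_geometry(coords, topo: CompiledTopology,
                   outlier_sigma: float = DEFAULT_OUTLIER_SIGMA,
                   weights=(1.0, 1.0, 1.0)) -> GeometryScores:
    return GeometryScores(bond_length_loss(coords, topo, outlier_sigma),
                          bond_angle_loss(coords, topo, outlier_sigma),
                          planarity_loss(coords, topo), weights)
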