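"""2D fiber-orientation tensors and the strength-of-alignment index.

The planar orientation state of a fiber population is summarized by the
length-weighted second-moment tensor

    Omega = sum_i l_i [cos^2 t_i, cos t_i sin t_i; cos t_i sin t_i, sin^2 t_i]
            / sum_i l_i

where ``t_i`` is the angle fiber ``i`` makes with the horizontal axis and
``l_i`` its (projected) length.  Omega is symmetric positive semi-definite
with unit trace; its eigenvalues ``w1 <= w2`` give the strength of alignment

    alpha = 1 - w1 / w2

which is 0 for an isotropic population and 1 for perfectly parallel fibers.
The eigenvector of ``w2`` is the principal direction of alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OrientationResult", "tensor_from_angles", "orientation_from_tensor"]


@dataclass(frozen=True)
class OrientationResult:
    """Planar orientation tensor with its eigen-decomposition.

    Attributes
    ----------
    tensor : (2, 2) ndarray
        Symmetric unit-trace orientation tensor Omega.
    w1, w2 : float
        Eigenvalues, ``w1 <= w2``.
    alpha : float
        Strength of alignment, ``1 - w1/w2`` in [0, 1].
    angle : float
        Principal direction (eigenvector of ``w2``) in radians, reduced to
        ``[0, pi)`` measured from the +x axis.
    """

    tensor: np.ndarray
    w1: float
    w2: float
    alpha: float
    angle: float


def tensor_from_angles(angles, weights=None) -> np.ndarray:
    """Length-weighted 2D orientation tensor of a set of fiber angles."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one fiber angle")
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("total fiber weight must be positive")
    c, s = np.cos(angles), np.sin(angles)
    omega = np.array(
        [
            [np.sum(weights * c * c), np.sum(weights * c * s)],
            [np.sum(weights * c * s), np.sum(weights * s * s)],
        ]
    )
    return omega / wsum


def orientation_from_tensor(omega: np.ndarray) -> OrientationResult:
    """Eigen-decompose an orientation tensor into (w1, w2, alpha, angle)."""
    omega = np.asarray(omega, dtype=float)
    omega = 0.5 * (omega + omega.T)
    evals, evecs = np.linalg.eigh(omega)
    w1, w2 = float(evals[0]), float(evals[1])
    if w2 <= 0:
        raise ValueError("degenerate orientation tensor (zero trace)")
    alpha = 1.0 - w1 / w2
    principal = evecs[:, 1]
    angle = float(np.arctan2(principal[1], principal[0])) % np.pi
    return OrientationResult(tensor=omega, w1=w1, w2=w2, alpha=alpha, angle=angle)
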