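"""Ground-truth synthetic fixtures: bead image sequences and fiber textures.

The generators emulate the two kinds of raw data the image operators
consume, with exact ground truth co-emitted so every operator can be
validated end to end:

* bead-seeded time-lapse frames — Gaussian-profile microspheres on a dark
  background, advected by a prescribed displacement field (uniform drift,
  radial contraction toward a point, or a displacement field exported from
  a gel simulation), optionally with additive Gaussian noise;
* fibrous textures — anti-aliased straight fibers whose orientations are
  drawn from a von Mises distribution (on the doubled angle, the natural
  axial distribution), for which the orientation tensor has the closed form
  eigenvalues (1 +/- R)/2 with R = I1(kappa)/I0(kappa), hence
  alpha = 2R / (1 + R).

Everything is a deterministic function of the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import iv
from skimage.draw import line_aa

from .field_analysis import Trajectory
from .image_analysis import ImageSequence
from .orientation import OrientationResult, orientation_from_tensor, tensor_from_angles

__all__ = [
    "SceneSpec",
    "TextureSpec",
    "uniform_field",
    "radial_contraction_field",
    "simulation_field",
    "render_bead_sequence",
    "render_fiber_texture",
    "von_mises_alpha",
]


# ---------------------------------------------------------------------------
# displacement fields: u(x, y, t) in pixels, t = frame index
# ---------------------------------------------------------------------------


def uniform_field(ux: float, uy: float):
    """Uniform drift of (ux, uy) px per frame."""

    def u(x, y, t):
        return np.full_like(x, ux * t), np.full_like(y, uy * t)

    return u


def radial_contraction_field(center, rate: float):
    """Radial contraction toward ``center``: per-frame fractional step.

    After t frames a point at radius r sits at r (1 - rate)^t — mimics
    matrix being drawn toward a compacting explant.
    """
    cx, cy = center

    def u(x, y, t):
        f = (1.0 - rate) ** t - 1.0
        return f * (x - cx), f * (y - cy)

    return u


def simulation_field(mesh, displacements, pixel_size_mm: float, scale: float = 1.0):
    """Displacement field interpolated from a gel-simulation top surface.

    ``displacements``: (n_steps, n_nodes, 3) history in mm;
    frame t samples history step t (clamped to the last step).  Returns
    pixel-space displacements; ``scale`` magnifies them for tracking tests.
    """
    from scipy.interpolate import LinearNDInterpolator

    top = np.flatnonzero(np.abs(mesh.coords[:, 2] - mesh.Lz) < 1e-9)
    pts = mesh.coords[top][:, :2]
    n_steps = len(displacements)

    interps = [
        LinearNDInterpolator(pts, displacements[t][top][:, :2], fill_value=0.0)
        for t in range(n_steps)
    ]

    def u(x, y, t):
        ti = min(int(t), n_steps - 1)
        mm_xy = np.column_stack([x.ravel(), y.ravel()]) * pixel_size_mm
        d = interps[ti](mm_xy) * scale / pixel_size_mm
        return d[:, 0].reshape(x.shape), d[:, 1].reshape(y.shape)

    return u


# ---------------------------------------------------------------------------
# bead scenes
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Bead-seeded scene description (all randomness from ``seed``)."""

    shape: tuple[int, int] = (256, 256)  # (H, W)
    n_beads: int = 30
    bead_radius: float = 3.0  # px
    n_frames: int = 10
    displacement_field: object = field(default_factory=lambda: uniform_field(0, 0))
    noise_sigma: float = 2.0  # 8-bit counts
    background: float = 20.0
    amplitude: float = 200.0
    pixel_size: float = 1.0  # um/px
    frame_interval: float = 15.0  # min
    margin: int = 24  # keep initial beads away from the edges
    seed: int = 0


def _render_frame(shape, centers, radius, background, amplitude):
    h, w = shape
    img = np.full((h, w), float(background))
    sigma = radius / 2.0
    half = int(np.ceil(4 * sigma))
    for cx, cy in centers:
        i0, j0 = int(np.floor(cy)) - half, int(np.floor(cx)) - half
        i1, j1 = i0 + 2 * half + 1, j0 + 2 * half + 1
        i0c, j0c = max(i0, 0), max(j0, 0)
        i1c, j1c = min(i1, h), min(j1, w)
        if i0c >= i1c or j0c >= j1c:
            continue
        yy, xx = np.mgrid[i0c:i1c, j0c:j1c]
        img[i0c:i1c, j0c:j1c] += amplitude * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)
        )
    return img


def render_bead_sequence(spec: SceneSpec):
    """Render a bead sequence and its ground-truth trajectories.

    Returns ``(ImageSequence, truth)`` where ``truth`` is a long-format
    DataFrame (bead, frame, x, y, clipped); beads advected within
    ``2 * bead_radius`` of the frame edge are flagged clipped (and a warning
    is emitted) since their appearance is truncated.
    """
    import warnings

    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    m = spec.margin
    x0 = rng.uniform(m, w - m, spec.n_beads)
    y0 = rng.uniform(m, h - m, spec.n_beads)
    frames = []
    rows = []
    any_clipped = False
    for t in range(spec.n_frames):
        ux, uy = spec.displacement_field(x0, y0, t)
        xs, ys = x0 + ux, y0 + uy
        edge = 2 * spec.bead_radius
        clipped = (xs < edge) | (xs > w - edge) | (ys < edge) | (ys > h - edge)
        any_clipped |= bool(np.any(clipped))
        img = _render_frame(
            spec.shape, np.column_stack([xs, ys]), spec.bead_radius,
            spec.background, spec.amplitude,
        )
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        frames.append(np.clip(img, 0, 255).astype(np.uint8))
        for b in range(spec.n_beads):
            rows.append((b, t, xs[b], ys[b], bool(clipped[b])))
    if any_clipped:
        warnings.warn("some beads were advected into the frame margin", stacklevel=2)
    seq = ImageSequence(
        np.stack(frames), pixel_size=spec.pixel_size,
        frame_interval=spec.frame_interval,
    )
    truth = pd.DataFrame(rows, columns=["bead", "frame", "x", "y", "clipped"])
    return seq, truth


def truth_trajectories(truth: pd.DataFrame, frame_interval=15.0) -> list[Trajectory]:
    """Ground-truth table -> Trajectory objects (pixel units)."""
    out = []
    for bead, grp in truth.groupby("bead"):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                id=int(bead),
                positions=grp[["x", "y"]].to_numpy(),
                frame_interval=frame_interval,
            )
        )
    return out


# ---------------------------------------------------------------------------
# fiber textures
# ---------------------------------------------------------------------------


@dataclass
class TextureSpec:
    """Fibrous-texture description (all randomness from ``seed``)."""

    shape: tuple[int, int] = (256, 256)
    n_fibers: int = 400
    mean_length: float = 60.0  # px
    sd_length: float = 8.0
    mean_angle: float = 0.0  # radians, from +x toward +y (image convention)
    kappa: float = 0.0  # von Mises concentration; 0 = uniform
    intensity: float = 110.0
    background: float = 15.0
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


def von_mises_alpha(kappa: float) -> float:
    """Closed-form alignment strength of a von Mises fiber population.

    With doubled angles 2t ~ VM(2 mu, kappa), the orientation tensor has
    eigenvalues (1 +/- R)/2, R = I1(kappa)/I0(kappa), so
    alpha = 1 - (1-R)/(1+R) = 2R/(1+R).
    """
    if kappa == 0:
        return 0.0
    r = iv(1, kappa) / iv(0, kappa)
    return 2.0 * r / (1.0 + r)


def render_fiber_texture(spec: TextureSpec):
    """Render a fiber texture plus the exact tensor of the sampled angles.

    Returns ``(image, truth, angles)``: ``truth`` is the
    :class:`OrientationResult` of the sampled fiber angles (equal weights),
    the Monte-Carlo realization whose expectation is
    :func:`von_mises_alpha` of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    if spec.kappa == 0:
        angles = rng.uniform(0.0, np.pi, spec.n_fibers)
    else:
        angles = (rng.vonmises(2.0 * spec.mean_angle, spec.kappa,
                               spec.n_fibers) % (2 * np.pi)) / 2.0
    lengths = np.clip(
        rng.normal(spec.mean_length, spec.sd_length, spec.n_fibers), 4.0, None
    )
    img = np.full((h, w), float(spec.background))
    cx = rng.uniform(0, w, spec.n_fibers)
    cy = rng.uniform(0, h, spec.n_fibers)
    for x, y, ang, L in zip(cx, cy, angles, lengths):
        dx, dy = 0.5 * L * np.cos(ang), 0.5 * L * np.sin(ang)
        r0, c0 = int(round(y - dy)), int(round(x - dx))
        r1, c1 = int(round(y + dy)), int(round(x + dx))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        img[rr[keep], cc[keep]] += spec.intensity * val[keep]
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    truth = orientation_from_tensor(tensor_from_angles(angles))
    return img, truth, angles
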