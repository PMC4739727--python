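"""Image operators: bead tracking and FFT fiber-alignment analysis.

Two operators quantify gel remodeling from 8-bit grayscale time-lapse
images:

* :func:`track_beads` — sequential template matching.  For every bead a
  template around its current position is cross-correlated (normalized
  cross-correlation, so the match is invariant to intensity gain and offset)
  against a search window in the next frame; the correlation peak, refined
  to sub-pixel precision by quadratic interpolation, gives the new position.
  The template is re-sampled from each new frame at the found position.
  Beads whose peak correlation falls below a threshold are marked lost from
  that frame (out-of-focus exclusions).

* :func:`fft_alignment` — fiber orientation from the power spectrum.  The
  windowed tile's spectral energy is distributed over orientation bins
  (band-limited, DC removed); because spectral energy of an oriented texture
  concentrates perpendicular to the fibers, the distribution is rotated 90
  degrees before forming the orientation tensor and the alignment strength
  ``alpha = 1 - w1/w2``.

Image coordinates: positions are (x, y) = (column, row), angles are measured
from the +x axis toward +y (i.e. clockwise on screen with the row axis
pointing down).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .field_analysis import Trajectory
from .orientation import OrientationResult, orientation_from_tensor

__all__ = [
    "ImageSequence",
    "track_beads",
    "fft_alignment",
    "tile_alignment",
    "alignment_overlay",
]


@dataclass
class ImageSequence:
    """8-bit grayscale time-lapse stack with physical calibration."""

    frames: np.ndarray  # (n_frames, H, W) uint8
    pixel_size: float = 1.0  # micrometres per pixel
    frame_interval: float = 15.0  # minutes

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) stack")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.uint8),
                         photometric="minisblack")

    @classmethod
    def from_tiff(cls, path, pixel_size=1.0, frame_interval=15.0):
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames, pixel_size, frame_interval)


def _ncc_peak(window: np.ndarray, template: np.ndarray):
    """Normalized cross-correlation peak of a template inside a window.

    Returns (row, col) of the template center at the best match, with
    quadratic sub-pixel refinement, and the peak correlation score.
    """
    from skimage.feature import match_template

    corr = match_template(window.astype(float), template.astype(float))
    ij = np.unravel_index(np.argmax(corr), corr.shape)
    score = float(corr[ij])
    sub = np.array(ij, dtype=float)
    for axis in range(2):
        i = ij[axis]
        if 0 < i < corr.shape[axis] - 1:
            idx = list(ij)
            idx[axis] = i - 1
            ym = corr[tuple(idx)]
            idx[axis] = i + 1
            yp = corr[tuple(idx)]
            y0 = corr[ij]
            denom = ym - 2.0 * y0 + yp
            if denom < 0:
                sub[axis] += 0.5 * (ym - yp) / denom
    half = (np.array(template.shape) - 1) / 2.0
    return sub + half, score


def track_beads(
    seq: ImageSequence,
    initial_positions,
    template_halfwidth: int = 10,
    search_halfwidth: int = 20,
    min_correlation: float = 0.5,
) -> list[Trajectory]:
    """Track beads through a sequence by NCC template matching.

    ``initial_positions``: (n, 2) array of (x, y) pixel positions in frame 0,
    each at least ``template_halfwidth`` away from the frame edge.  Positions
    are returned in pixels; multiply by ``seq.pixel_size`` for micrometres.
    A bead whose best correlation drops below ``min_correlation`` keeps its
    last position and is marked lost from that frame on.
    """
    initial_positions = np.atleast_2d(np.asarray(initial_positions, dtype=float))
    h, w = seq.shape
    thw, shw = int(template_halfwidth), int(search_halfwidth)
    if shw <= thw:
        raise ValueError("search halfwidth must exceed template halfwidth")
    for x, y in initial_positions:
        if not (thw <= x < w - thw and thw <= y < h - thw):
            raise ValueError(f"initial position ({x}, {y}) too close to frame edge")

    trajectories = []
    for bead_id, (x0, y0) in enumerate(initial_positions):
        pos = [(x0, y0)]
        scores = []
        lost_from = None
        x, y = x0, y0
        for f in range(1, seq.n_frames):
            if lost_from is not None:
                pos.append((x, y))
                scores.append(np.nan)
                continue
            ci, cj = int(round(y)), int(round(x))
            t0 = seq.frames[f - 1][
                max(ci - thw, 0): ci + thw + 1, max(cj - thw, 0): cj + thw + 1
            ]
            wi_lo, wi_hi = max(ci - shw, 0), min(ci + shw + 1, h)
            wj_lo, wj_hi = max(cj - shw, 0), min(cj + shw + 1, w)
            window = seq.frames[f][wi_lo:wi_hi, wj_lo:wj_hi]
            if min(t0.shape) < 3 or min(window.shape) <= max(t0.shape):
                lost_from = f
                pos.append((x, y))
                scores.append(np.nan)
                continue
            (pi, pj), score = _ncc_peak(window, t0)
            scores.append(score)
            if score < min_correlation:
                lost_from = f
                pos.append((x, y))
                continue
            # template center offset within the window -> new position
            new_y = wi_lo + pi + (y - ci)
            new_x = wj_lo + pj + (x - cj)
            x, y = new_x, new_y
            pos.append((x, y))
        trajectories.append(
            Trajectory(
                id=bead_id,
                positions=np.array(pos),
                frame_interval=seq.frame_interval,
                scores=np.array(scores),
                lost_from=lost_from,
            )
        )
    return trajectories


def fft_alignment(
    tile: np.ndarray,
    band: tuple[float, float] = (0.02, 0.4),
    n_bins: int = 180,
) -> OrientationResult:
    """Fiber orientation statistics of one image tile via its power spectrum.

    A Hann window suppresses edge artifacts; spectral energy inside the
    annular frequency band (cycles/pixel) is binned by orientation over
    [0, pi), rotated a quarter turn into fiber space, and condensed into the
    orientation tensor.  A featureless (constant) tile is returned as
    isotropic with ``alpha = 0``.
    """
    tile = np.asarray(tile, dtype=float)
    if tile.ndim != 2:
        raise ValueError("tile must be a 2D image")
    if min(tile.shape) < 64:
        raise ValueError("tile must be at least 64 px on each side")
    if np.ptp(tile) == 0:
        return OrientationResult(
            tensor=np.eye(2) / 2, w1=0.5, w2=0.5, alpha=0.0, angle=0.0
        )
    h, w = tile.shape
    win = np.outer(np.hanning(h), np.hanning(w))
    spec = np.abs(np.fft.fftshift(np.fft.fft2((tile - tile.mean()) * win))) ** 2
    fy = np.fft.fftshift(np.fft.fftfreq(h))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(w))[None, :]
    freq = np.hypot(fx, fy)
    mask = (freq >= band[0]) & (freq <= band[1])
    energy = spec[mask]
    if energy.sum() == 0:
        return OrientationResult(
            tensor=np.eye(2) / 2, w1=0.5, w2=0.5, alpha=0.0, angle=0.0
        )
    # spectral angle; +pi/2 rotation into image-space fiber direction
    theta = np.arctan2(np.broadcast_to(fy, spec.shape)[mask],
                       np.broadcast_to(fx, spec.shape)[mask])
    phi = theta + np.pi / 2.0
    bins = np.floor(((phi % np.pi) / np.pi) * n_bins).astype(int) % n_bins
    dist = np.bincount(bins, weights=energy, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) * np.pi / n_bins
    c, s = np.cos(centers), np.sin(centers)
    omega = np.array(
        [
            [np.sum(dist * c * c), np.sum(dist * c * s)],
            [np.sum(dist * c * s), np.sum(dist * s * s)],
        ]
    ) / dist.sum()
    return orientation_from_tensor(omega)


def tile_alignment(
    image: np.ndarray, tile_size: int = 128, **kwargs
) -> list[tuple[int, int, OrientationResult]]:
    """FFT alignment over a grid of tiles; returns (row0, col0, result)."""
    image = np.asarray(image)
    out = []
    for r0 in range(0, image.shape[0] - tile_size + 1, tile_size):
        for c0 in range(0, image.shape[1] - tile_size + 1, tile_size):
            res = fft_alignment(image[r0: r0 + tile_size, c0: c0 + tile_size],
                                **kwargs)
            out.append((r0, c0, res))
    return out


def alignment_overlay(image, tiles, path, tile_size=128) -> None:
    """Save an ellipse-glyph overlay of per-tile alignment for visual QC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(image, cmap="gray")
    for r0, c0, res in tiles:
        cx, cy = c0 + tile_size / 2, r0 + tile_size / 2
        width = tile_size * 0.8 * res.w2
        height = tile_size * 0.8 * max(res.w1, 0.02)
        # screen angle: y axis points down
        e = Ellipse(
            (cx, cy), 2 * width, 2 * height,
            angle=np.degrees(res.angle), fill=False, color="yellow", lw=1.2,
        )
        ax.add_patch(e)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
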