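"""Image-plane stage: render synthetic bright-field frames and track the bead centroid.

Lets the pipeline start from pixels instead of positions. The spot model
is a radially symmetric 2-D Gaussian (real bead images show ring
structure, but thresholded centroiding is insensitive to that at the
tested signal-to-noise ratios); tracking is the intensity-weighted
centroid of pixels above a fraction of the frame maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .tpm import Trajectory

__all__ = [
    "FrameStack",
    "TrackedPositions",
    "render_bead_frames",
    "track_centroid",
    "read_frame_stack",
    "write_frame_stack",
]


@dataclass
class FrameStack:
    """A stack of 2-D intensity frames with pixel and time calibration."""

    frames: np.ndarray  # (n_frames, height, width)
    pixel_size: float  # nm per pixel
    frame_rate: float = 25.0  # Hz

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class TrackedPositions:
    """Tracked centroid positions; frames with no spot are NaN and listed."""

    t: np.ndarray  # s
    x: np.ndarray  # nm
    y: np.ndarray  # nm
    missing: list[int] = field(default_factory=list)

    def to_trajectory(self, bead_id: str = "tracked") -> Trajectory:
        if self.missing:
            raise ValueError(f"{len(self.missing)} frames have no trackable spot")
        return Trajectory(t=self.t, x=self.x, y=self.y, bead_id=bead_id)


def render_bead_frames(
    positions: Trajectory,
    psf_width: float = 2.0,
    snr: float = 20.0,
    pixel_size: float = 100.0,
    shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> FrameStack:
    """Render one Gaussian spot per frame at the trajectory's positions.

    Positions (nm) are mapped to pixels at ``pixel_size`` nm/px around the
    frame center; the spot has peak intensity 1 and width ``psf_width``
    px, plus white pixel noise of standard deviation ``1/snr``
    (``snr=inf`` for noiseless frames). The frame must enclose every
    position with a margin of at least ``3*psf_width``.
    """
    margin = 3.0 * psf_width
    px = positions.x / pixel_size
    py = positions.y / pixel_size
    half_w = float(np.max(np.abs(px))) + margin
    half_h = float(np.max(np.abs(py))) + margin
    if shape is None:
        shape = (2 * int(np.ceil(half_h)) + 1, 2 * int(np.ceil(half_w)) + 1)
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    if np.any(px + cx < margin) or np.any(px + cx > w - 1 - margin) or np.any(
        py + cy < margin
    ) or np.any(py + cy > h - 1 - margin):
        raise ValueError("bead leaves the frame (margin 3*psf_width violated)")

    rng = np.random.default_rng(seed)
    cols = np.arange(w)
    rows = np.arange(h)
    frames = np.empty((len(positions), h, w))
    inv2s2 = 1.0 / (2.0 * psf_width**2)
    for i in range(len(positions)):
        gx = np.exp(-((cols - (px[i] + cx)) ** 2) * inv2s2)
        gy = np.exp(-((rows - (py[i] + cy)) ** 2) * inv2s2)
        frames[i] = np.outer(gy, gx)
    if np.isfinite(snr):
        frames += rng.normal(0.0, 1.0 / snr, frames.shape)
    return FrameStack(frames=frames, pixel_size=pixel_size,
                      frame_rate=positions.sample_rate)


def track_centroid(
    stack: FrameStack,
    threshold_fraction: float = 0.5,
    max_spot_fraction: float = 0.25,
) -> TrackedPositions:
    """Intensity-weighted centroid of the above-threshold spot, frame by frame.

    Pixels above ``threshold_fraction`` of the frame maximum contribute,
    weighted by their intensity minus the threshold (local background
    subtraction, which suppresses the sub-pixel bias of a hard mask).
    Frames whose above-threshold region covers more than
    ``max_spot_fraction`` of the image (no dominant spot) or whose maximum
    is non-positive are flagged missing. Output is in nm relative to the
    frame center, timestamped from the frame rate.
    """
    n, h, w = stack.frames.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    cols = np.arange(w)
    rows = np.arange(h)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    missing: list[int] = []
    for i, frame in enumerate(stack.frames):
        peak = frame.max()
        if peak <= 0:
            missing.append(i)
            continue
        thr = threshold_fraction * peak
        mask = frame >= thr
        if mask.sum() > max_spot_fraction * frame.size:
            missing.append(i)
            continue
        wgt = np.where(mask, frame - thr, 0.0)
        total = wgt.sum()
        if total <= 0:
            missing.append(i)
            continue
        x[i] = (wgt.sum(axis=0) @ cols) / total - cx
        y[i] = (wgt.sum(axis=1) @ rows) / total - cy
    t = np.arange(n) / stack.frame_rate
    return TrackedPositions(
        t=t, x=x * stack.pixel_size, y=y * stack.pixel_size, missing=missing
    )


def write_frame_stack(stack: FrameStack, path: str | Path) -> None:
    """Store a stack as a multi-page float32 TIFF with calibration metadata."""
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        photometric="minisblack",
        metadata={"pixel_size_nm": stack.pixel_size,
                  "frame_rate_hz": stack.frame_rate},
    )


def read_frame_stack(
    path: str | Path, pixel_size: float | None = None, frame_rate: float | None = None
) -> FrameStack:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return FrameStack(
        frames=np.atleast_3d(frames) if frames.ndim == 2 else frames,
        pixel_size=pixel_size or float(meta.get("pixel_size_nm", 100.0)),
        frame_rate=frame_rate or float(meta.get("frame_rate_hz", 25.0)),
    )
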