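"""Motion-energy analysis (MEA): frame differencing within a region of interest.

Movement intensity is read off a video as the number of ROI pixels whose
grayscale value changes by at least a threshold (default 12 of 256 levels)
between consecutive frames. Counts are standardized by ROI size to percent
(0 = no motion, 100 = entire ROI activated) and smoothed with a centered
moving median (default bandwidth five frames).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.ndimage import median_filter

from .datatypes import FrameStack, MotionEnergySeries, ROIMask

__all__ = [
    "compute_motion_energy",
    "standardize_series",
    "smooth_series",
    "mea_pipeline",
    "load_frame_dir",
    "load_roi_mask",
]

GRAYSCALE_THRESHOLD = 12


def compute_motion_energy(stack: FrameStack, roi: ROIMask,
                          threshold: int = GRAYSCALE_THRESHOLD,
                          inclusive: bool = True) -> MotionEnergySeries:
    """Changed-pixel counts inside the ROI for every frame step.

    ``values[t]`` counts ROI pixels with ``|I(t+1) - I(t)| >= threshold``
    (``>`` when ``inclusive=False``); the series has ``n_frames - 1`` steps.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least two frames")
    if roi.mask.shape != stack.shape:
        raise ValueError(f"ROI shape {roi.mask.shape} != frame shape {stack.shape}")
    frames = stack.frames.astype(np.int16)
    diff = np.abs(np.diff(frames, axis=0))
    changed = diff >= threshold if inclusive else diff > threshold
    counts = changed[:, roi.mask].sum(axis=1).astype(float)
    return MotionEnergySeries(counts, fps=stack.fps, kind="raw-count")


def standardize_series(raw: MotionEnergySeries, roi_size: int) -> MotionEnergySeries:
    """Convert counts to percent of ROI: ``100 * count / roi_size``."""
    if roi_size <= 0:
        raise ValueError("roi_size must be positive")
    return raw.with_values(100.0 * raw.values / roi_size, kind="standardized")


def smooth_series(series: MotionEnergySeries, bandwidth: int = 5) -> MotionEnergySeries:
    """Centered moving median.

    The window shrinks symmetrically at the series ends (value at position i
    uses the frames within ``min(i, len-1-i, bandwidth//2)`` of i), so the
    output has the same length as the input.
    """
    if bandwidth < 1 or bandwidth % 2 == 0:
        raise ValueError("bandwidth must be odd and >= 1")
    if len(series) < bandwidth:
        raise ValueError("series shorter than bandwidth")
    x = series.values
    out = median_filter(x, size=bandwidth, mode="nearest")
    # symmetric shrink at the edges (median_filter pads instead)
    half = bandwidth // 2
    n = x.size
    for i in range(half):
        out[i] = np.median(x[: 2 * i + 1])
        out[n - 1 - i] = np.median(x[n - 2 * i - 1:])
    return series.with_values(out, kind="smoothed")


def mea_pipeline(stack: FrameStack, roi: ROIMask, threshold: int = GRAYSCALE_THRESHOLD,
                 bandwidth: int = 5) -> MotionEnergySeries:
    """Full preprocessing chain: count, standardize by ROI size, smooth."""
    raw = compute_motion_energy(stack, roi, threshold=threshold)
    return smooth_series(standardize_series(raw, roi.size), bandwidth=bandwidth)


def load_frame_dir(path: str | Path, fps: int = 25) -> FrameStack:
    """Read a directory of grayscale PNG/TIFF frames (sorted by filename)."""
    import imageio.v3 as iio

    files = sorted(p for p in Path(path).iterdir()
                   if p.suffix.lower() in {".png", ".tif", ".tiff"})
    if not files:
        raise ValueError(f"no PNG/TIFF frames in {path}")
    frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    if frames.ndim == 4:  # collapse RGB storage of grayscale data
        frames = frames[..., 0]
    return FrameStack(frames, fps=fps)


def load_roi_mask(path: str | Path) -> ROIMask:
    """ROI from a PNG (nonzero = inside) or a run-length JSON
    ``{"shape": [h, w], "runs": [[row, col_start, col_end], ...]}``."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        spec = json.loads(path.read_text())
        mask = np.zeros(tuple(spec["shape"]), dtype=bool)
        for row, c0, c1 in spec["runs"]:
            mask[row, c0:c1] = True
        return ROIMask(mask)
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return ROIMask(img != 0)
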