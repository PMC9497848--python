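"""Core containers shared by every stage of the pipeline.

The unit of analysis is a *dyad*: two people filmed during a conversation,
each represented by a motion-energy time series (percentage of their region
of interest whose pixels changed between consecutive frames, sampled at the
video frame rate). Synthetic dyads additionally carry their ground-truth
coupling schedule, so detection stages can be scored against what was
actually injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

DEFAULT_FPS = 25

#: measure columns of the cohort table, in canonical order
MEASURE_COLUMNS = (
    "cc_raw", "cc_abs", "cc_z", "cc_r2",
    "rmea_wcc", "rmea_wclc",
    "susy_es_abs", "susy_es_noabs",
    "suco_co", "suco_es_abs", "suco_es_co",
    "wclc_pp_f", "wclc_pp_r2", "wclr_pp_f", "wclr_pp_r2",
    "mi_raw", "mi_cor", "mi_z",
    "wincrqa_rr", "wincrqa_det", "wincrqa_entr",
)


@dataclass(frozen=True)
class MotionEnergySeries:
    """One interactant's motion intensity per frame step.

    ``kind`` tracks the preprocessing stage: ``raw-count`` (changed-pixel
    counts), ``standardized`` (percent of ROI, in [0, 100]) or ``smoothed``
    (after the moving median).
    """

    values: np.ndarray
    fps: int = DEFAULT_FPS
    kind: str = "standardized"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("motion-energy series must be one-dimensional")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "MotionEnergySeries":
        return replace(self, values=np.asarray(values, dtype=float),
                       kind=self.kind if kind is None else kind)


@dataclass(frozen=True)
class CouplingInterval:
    """Ground-truth synchronization interval of the simulator.

    Within ``[start_frame, end_frame)`` the follower copies the driver's
    motion with time lag ``lag_tau`` (frames; positive means the second
    member follows the first), coupling strength ``strength_beta`` >= 0 and
    ``sign`` +1 (in-phase) or -1 (anti-phase).
    """

    start_frame: int
    end_frame: int
    lag_tau: int
    strength_beta: float
    sign: int = 1

    def __post_init__(self) -> None:
        if self.start_frame < 0 or self.end_frame <= self.start_frame:
            raise ValueError("require 0 <= start_frame < end_frame")
        if self.strength_beta < 0:
            raise ValueError("strength_beta must be non-negative")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class DyadTimeSeries:
    """Aligned pair of motion-energy series plus metadata.

    ``schedule`` is the ground-truth list of coupling intervals for
    synthetic dyads (``None`` for observed data).
    """

    a: np.ndarray
    b: np.ndarray
    fps: int = DEFAULT_FPS
    dyad_id: str = "dyad"
    schedule: list[CouplingInterval] | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("dyad members must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.a.size

    @property
    def duration_s(self) -> float:
        return self.a.size / self.fps


@dataclass(frozen=True)
class FrameStack:
    """Grayscale video frames (n_frames, height, width), intensities 0-255."""

    frames: np.ndarray
    fps: int = DEFAULT_FPS

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class ROIMask:
    """Boolean region-of-interest mask; motion counts are standardized by its size."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("ROI mask must be two-dimensional")
        if not mask.any():
            raise ValueError("ROI mask is empty")
        object.__setattr__(self, "mask", mask)

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Split one global seed into ``n`` independent child seeds.

    The splitting rule is ``np.random.SeedSequence(seed).spawn(n)``: child i
    is fully determined by (seed, i), so whole cohorts are reproducible from
    a single integer.
    """
    return np.random.SeedSequence(seed).spawn(n)
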