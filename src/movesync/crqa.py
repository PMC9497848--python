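"""Windowed cross-recurrence quantification analysis (WinCRQA).

Both series are rescaled to the unit interval and delay-embedded (dimension
3, delay 1 frame by default). Within each 60 s window (1500 frames, 50 %
overlap) the cross-recurrence matrix marks time pairs (i, j) whose embedded
states lie within Euclidean radius eps = 0.05, restricted to the diagonal
band |i - j| <= 125 frames — the same +-5 s lag range as the correlation
methods. Per window:

* RR   — percent of band cells that are recurrent;
* DET  — percent of recurrent points lying on diagonal runs of length >=
         the minimum line (2), i.e. stretches where the two trajectories
         shadow each other; undefined (NaN) when RR = 0;
* ENTR — Shannon entropy of the diagonal run-length distribution,
         normalized by the log of the number of distinct observed lengths
         (0 when fewer than 2 distinct lengths occur).

The conversation-level measure averages the window values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import DyadTimeSeries, MotionEnergySeries

__all__ = [
    "CrqaParams",
    "CrqaWindowResult",
    "unit_rescale",
    "embed",
    "cross_recurrence_window",
    "wincrqa",
]


@dataclass(frozen=True)
class CrqaParams:
    radius_eps: float = 0.05
    embedding_dim: int = 3
    embedding_delay: int = 1
    window_frames: int = 1500
    window_overlap: int = 750
    lag_band: int = 125          # diagonal band half-width; None = full matrix
    min_diag_line: int = 2

    def __post_init__(self) -> None:
        if self.radius_eps <= 0:
            raise ValueError("radius must be positive")
        if self.window_overlap >= self.window_frames:
            raise ValueError("overlap must be smaller than the window")
        span = (self.embedding_dim - 1) * self.embedding_delay + 1
        if self.window_frames <= span:
            raise ValueError("window shorter than the embedding span")


@dataclass(frozen=True)
class CrqaWindowResult:
    rr: float      # percent
    det: float     # percent, NaN when rr == 0
    entr: float    # normalized to [0, 1]
    entr_raw: float
    n_recurrent: int
    n_cells: int


def unit_rescale(series: MotionEnergySeries | np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 1]; errors on constant input."""
    x = series.values if isinstance(series, MotionEnergySeries) else np.asarray(series, float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant series cannot be rescaled")
    return (x - lo) / (hi - lo)


def embed(x: np.ndarray, dim: int = 3, delay: int = 1) -> np.ndarray:
    """Delay embedding: row k = (x_k, x_{k+delay}, ..., x_{k+(dim-1)delay})."""
    x = np.asarray(x, dtype=float)
    span = (dim - 1) * delay
    if x.size <= span:
        raise ValueError("series too short for this embedding")
    n = x.size - span
    return np.stack([x[i * delay: i * delay + n] for i in range(dim)], axis=1)


def cross_recurrence_window(emb_a: np.ndarray, emb_b: np.ndarray,
                            params: CrqaParams) -> CrqaWindowResult:
    """Recurrence measures of one window pair of embedded trajectories."""
    na, nb = emb_a.shape[0], emb_b.shape[0]
    band = params.lag_band
    offsets = (range(-(na - 1), nb) if band is None
               else range(-min(band, na - 1), min(band, nb - 1) + 1))
    eps2 = params.radius_eps ** 2
    n_cells = 0
    n_rec = 0
    run_lengths: list[int] = []
    det_points = 0
    for d in offsets:
        i0 = max(0, -d)
        i1 = min(na, nb - d)
        if i1 <= i0:
            continue
        diff = emb_a[i0:i1] - emb_b[i0 + d:i1 + d]
        rec = (diff * diff).sum(axis=1) < eps2
        n_cells += rec.size
        n_rec += int(rec.sum())
        for length in _run_lengths(rec):
            run_lengths.append(length)
            if length >= params.min_diag_line:
                det_points += length
    if n_cells == 0:
        raise ValueError("no cells in the diagonal band")
    rr = 100.0 * n_rec / n_cells
    det = 100.0 * det_points / n_rec if n_rec else float("nan")
    lines = np.array([l for l in run_lengths if l >= params.min_diag_line])
    entr_raw, entr = 0.0, 0.0
    if lines.size:
        lengths, counts = np.unique(lines, return_counts=True)
        p = counts / counts.sum()
        entr_raw = float(-(p * np.log(p)).sum())
        entr = entr_raw / np.log(lengths.size) if lengths.size > 1 else 0.0
    return CrqaWindowResult(rr=rr, det=det, entr=entr, entr_raw=entr_raw,
                            n_recurrent=n_rec, n_cells=n_cells)


def _run_lengths(mask: np.ndarray) -> list[int]:
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return (edges[1::2] - edges[::2]).tolist()


def wincrqa(dyad: DyadTimeSeries, params: CrqaParams = CrqaParams()
            ) -> CrqaWindowResult:
    """Window-averaged cross-recurrence measures for a whole dyad.

    Windows of ``window_frames`` step by ``window_frames - window_overlap``;
    fields are averaged with NaN-aware means (DET is undefined in windows
    without recurrences).
    """
    if len(dyad) < params.window_frames:
        raise ValueError("series shorter than one CRQA window")
    a = unit_rescale(dyad.a)
    b = unit_rescale(dyad.b)
    step = params.window_frames - params.window_overlap
    results = []
    for start in range(0, len(dyad) - params.window_frames + 1, step):
        sl = slice(start, start + params.window_frames)
        emb_a = embed(a[sl], params.embedding_dim, params.embedding_delay)
        emb_b = embed(b[sl], params.embedding_dim, params.embedding_delay)
        results.append(cross_recurrence_window(emb_a, emb_b, params))
    with np.errstate(invalid="ignore"):
        return CrqaWindowResult(
            rr=float(np.mean([r.rr for r in results])),
            det=float(np.nanmean([r.det for r in results])),
            entr=float(np.mean([r.entr for r in results])),
            entr_raw=float(np.mean([r.entr_raw for r in results])),
            n_recurrent=int(sum(r.n_recurrent for r in results)),
            n_cells=int(sum(r.n_cells for r in results)),
        )
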