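"""Synchronization-interval detection: WCLC-PP and WCLR-PP.

The model behind this stage: phases of strong lagged linear coupling
(synchronization intervals) alternate with phases of independence. Local
association is evaluated for every window start t (increment one frame,
window b = 125 frames) and every lag tau in +-125 frames, producing an
*R-square matrix*:

* WCLC mode: the squared windowed cross-lagged Pearson correlation between
  the window of A at t and the window of B at t + tau.
* WCLR mode: the autocorrelation-adjusted increment
  Delta R^2 = R^2(follower window ~ own past + partner window)
            - R^2(follower window ~ own past),
  i.e. the share of the follower's variance explained by the partner beyond
  what the follower's own lag-tau autocorrelation explains. Cells whose
  incremental F test is not significant at alpha = 0.001 are set to zero.

Positive lag means the second member (B) follows the first (A); for
negative lags the member roles are mirrored. Peak picking then selects
per-row local maxima over lags, chains same-lag maxima over consecutive
rows into candidate intervals, resolves row-sharing conflicts in favor of
the interval with the larger mean, and keeps intervals whose mean strength
exceeds the cutoff (default 0.25). Summary measures: the fraction of rows
covered by intervals (PP-F) and the mean strength inside intervals (PP-R2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._stats import sliding_corr_same_start
from .datatypes import DyadTimeSeries

__all__ = [
    "RSquareMatrix",
    "SynchronizationInterval",
    "LOSI",
    "wclc_rsq_matrix",
    "wclr_rsq_matrix",
    "peak_picking",
    "sync_frequency",
    "sync_mean_r2",
]

DEFAULT_WINDOW = 125
DEFAULT_TAU_MAX = 125
DEFAULT_ALPHA = 0.001
DEFAULT_R2_CUTOFF = 0.25


@dataclass(frozen=True)
class RSquareMatrix:
    """Window-start x lag grid of R^2 (WCLC) or Delta R^2 (WCLR) values.

    Rows are window starts 0..L-b at unit increment; NaN cells mark lagged
    windows that fall off the series or degenerate variance.
    """

    values: np.ndarray
    lags: np.ndarray
    mode: str                    # "wclc" | "wclr"
    window: int
    length: int
    alpha: float | None = None   # significance filter applied, None = off

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SynchronizationInterval:
    row_start: int
    row_end: int        # inclusive
    lag: int
    mean_strength: float

    @property
    def n_rows(self) -> int:
        return self.row_end - self.row_start + 1


@dataclass(frozen=True)
class LOSI:
    """List of synchronization intervals; no row belongs to two intervals."""

    intervals: tuple[SynchronizationInterval, ...]
    n_rows: int
    window: int
    r2_cutoff: float = DEFAULT_R2_CUTOFF


def _lagged_corr_fields(a: np.ndarray, b: np.ndarray, bw: int,
                        tau_max: int) -> dict[str, np.ndarray]:
    """All windowed correlation fields needed by both matrix modes.

    Each field is (n_rows, n_lags) with n_rows = L - bw + 1. ``r_ab``:
    corr(A@t, B@t+tau). ``auto``: lag-|tau| autocorrelation of the follower
    (B for tau>0, A for tau<0) between its windows at t and t+|tau|.
    ``cross``: corr(leader@t, follower@(t+|tau|)) — identical to r_ab up to
    which member leads.
    """
    L = a.size
    n_rows = L - bw + 1
    lags = np.arange(-tau_max, tau_max + 1)
    r_ab = np.full((n_rows, lags.size), np.nan)
    auto = np.full((n_rows, lags.size), np.nan)
    r12 = np.full((n_rows, lags.size), np.nan)
    r0 = sliding_corr_same_start(a, b, bw)  # corr(A@t, B@t)
    for j, tau in enumerate(lags):
        k = abs(int(tau))
        if n_rows - k < 1:
            continue
        if tau >= 0:
            r = sliding_corr_same_start(a[:L - k], b[k:], bw)
            ac = sliding_corr_same_start(b[:L - k], b[k:], bw)
            rows = slice(0, n_rows - k)
        else:
            r = sliding_corr_same_start(a[k:], b[:L - k], bw)
            ac = sliding_corr_same_start(a[:L - k], a[k:], bw)
            rows = slice(k, n_rows)
        src = slice(0, n_rows - k)
        r_ab[rows, j] = r[src]
        auto[rows, j] = ac[src]
        # predictors both live at the *earlier* window position
        r12[rows, j] = r0[src] if tau < 0 else r0[rows]
    return {"lags": lags, "r_ab": r_ab, "auto": auto, "r12": r12}


def wclc_rsq_matrix(dyad: DyadTimeSeries, b: int = DEFAULT_WINDOW,
                    tau_max: int = DEFAULT_TAU_MAX,
                    alpha: float | None = DEFAULT_ALPHA) -> RSquareMatrix:
    """Squared windowed cross-lagged correlations.

    With the significance filter on (default), cells whose correlation is
    not significant at ``alpha`` (F test with 1 and b-2 df) are set to 0.
    """
    L = len(dyad)
    if L < b + tau_max:
        raise ValueError("series shorter than window + maximum lag")
    fields = _lagged_corr_fields(dyad.a, dyad.b, b, tau_max)
    r2 = fields["r_ab"] ** 2
    if alpha is not None:
        f_crit = stats.f.isf(alpha, 1, b - 2)
        r2_crit = f_crit / (f_crit + b - 2)
        r2[r2 < r2_crit] = 0.0
    return RSquareMatrix(values=r2, lags=fields["lags"], mode="wclc",
                         window=b, length=L, alpha=alpha)


def wclr_rsq_matrix(dyad: DyadTimeSeries, b: int = DEFAULT_WINDOW,
                    tau_max: int = DEFAULT_TAU_MAX,
                    alpha: float | None = DEFAULT_ALPHA) -> RSquareMatrix:
    """Autocorrelation-adjusted Delta R^2 matrix.

    Per cell two least-squares models predict the follower window at
    t + |tau|: model 1 from the follower's own window at t, model 2 adds
    the leader's window at t. Delta R^2 = R^2_M2 - R^2_M1, floored at 0;
    non-significant increments (incremental F with 1 and b-3 df at
    ``alpha``) are set to 0. R^2_M2 follows from the pairwise correlations:
    R^2_M2 = (r_y1^2 + r_y2^2 - 2 r_y1 r_y2 r_12) / (1 - r_12^2).
    """
    L = len(dyad)
    if L < b + tau_max:
        raise ValueError("series shorter than window + maximum lag")
    fields = _lagged_corr_fields(dyad.a, dyad.b, b, tau_max)
    lags = fields["lags"]
    r_y2 = fields["r_ab"]          # corr(leader past window, follower window)
    r_y1 = fields["auto"]          # follower autocorrelation
    r_12 = fields["r12"]           # corr between the two predictor windows
    denom = 1.0 - r_12 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2_m2 = (r_y1 ** 2 + r_y2 ** 2 - 2.0 * r_y1 * r_y2 * r_12) / denom
    r2_m1 = r_y1 ** 2
    delta = r2_m2 - r2_m1
    collinear = ~np.isfinite(denom) | (np.abs(denom) < 1e-10) | ~np.isfinite(delta)
    missing = np.isnan(r_y2) | np.isnan(r_y1) | np.isnan(r_12)
    delta[collinear & ~missing] = 0.0
    np.clip(delta, 0.0, 1.0, out=delta)
    if alpha is not None:
        f_crit = stats.f.isf(alpha, 1, b - 3)
        with np.errstate(invalid="ignore"):
            thresh = f_crit * (1.0 - np.minimum(r2_m2, 1.0)) / (b - 3)
        delta[delta < thresh] = 0.0
    delta[missing] = np.nan
    return RSquareMatrix(values=delta, lags=lags, mode="wclr",
                         window=b, length=L, alpha=alpha)


def _plateau_local_maxima(values: np.ndarray) -> np.ndarray:
    """Boolean mask of per-row local maxima along the lag axis.

    A maximal plateau (run of equal values strictly greater than the
    nearest distinct values on both sides, missing sides counting as -inf)
    contributes one maximum: its cell of smallest |lag| (ties towards
    negative lag). NaN cells never qualify.
    """
    n_rows, n_lags = values.shape
    v = np.where(np.isnan(values), -np.inf, values)
    left = np.empty_like(v)
    right = np.empty_like(v)
    start = np.empty((n_rows, n_lags), dtype=np.int64)
    end = np.empty((n_rows, n_lags), dtype=np.int64)
    left[:, 0] = -np.inf
    start[:, 0] = 0
    for j in range(1, n_lags):
        same = v[:, j] == v[:, j - 1]
        left[:, j] = np.where(same, left[:, j - 1], v[:, j - 1])
        start[:, j] = np.where(same, start[:, j - 1], j)
    right[:, -1] = -np.inf
    end[:, -1] = n_lags - 1
    for j in range(n_lags - 2, -1, -1):
        same = v[:, j] == v[:, j + 1]
        right[:, j] = np.where(same, right[:, j + 1], v[:, j + 1])
        end[:, j] = np.where(same, end[:, j + 1], j)
    qualifies = (v > left) & (v > right) & np.isfinite(v)
    center = (n_lags - 1) // 2  # index of lag 0
    rep = np.clip(center, start, end)  # smallest-|lag| index inside the plateau
    cols = np.arange(n_lags)[None, :]
    return qualifies & (cols == rep)


def peak_picking(matrix: RSquareMatrix,
                 r2_cutoff: float = DEFAULT_R2_CUTOFF) -> LOSI:
    """Detect synchronization intervals in an R-square matrix.

    Per-row local maxima over lags are chained over directly consecutive
    rows at equal lag into candidate intervals. When intervals share a row,
    the one with the larger mean strength is kept and the loser discarded
    entirely (ties broken towards earlier start, then smaller |lag|).
    Intervals with mean strength <= ``r2_cutoff`` are dropped.
    """
    V = matrix.values
    maxima = _plateau_local_maxima(V)
    candidates: list[SynchronizationInterval] = []
    for j in range(maxima.shape[1]):
        rows = np.flatnonzero(maxima[:, j])
        if rows.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(rows) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [rows.size - 1]))
        lag = int(matrix.lags[j])
        for s, e in zip(run_starts, run_ends):
            r0, r1 = int(rows[s]), int(rows[e])
            mean = float(V[r0:r1 + 1, j].mean())
            candidates.append(SynchronizationInterval(r0, r1, lag, mean))
    candidates.sort(key=lambda iv: (-iv.mean_strength, iv.row_start,
                                    abs(iv.lag), iv.lag))
    occupied = np.zeros(matrix.n_rows, dtype=bool)
    kept = []
    for iv in candidates:
        span = occupied[iv.row_start:iv.row_end + 1]
        if span.any():
            continue
        span[:] = True
        kept.append(iv)
    kept = [iv for iv in kept if iv.mean_strength > r2_cutoff]
    kept.sort(key=lambda iv: iv.row_start)
    return LOSI(intervals=tuple(kept), n_rows=matrix.n_rows,
                window=matrix.window, r2_cutoff=r2_cutoff)


def sync_frequency(losi: LOSI) -> float:
    """Fraction of window-start rows covered by synchronization intervals."""
    covered = sum(iv.n_rows for iv in losi.intervals)
    return covered / losi.n_rows if losi.n_rows else 0.0


def sync_frequency_frames(losi: LOSI) -> float:
    """Alternative convention: fraction of *frames* covered, counting each
    interval as [row_start, row_end + window) on the frame axis."""
    if not losi.intervals:
        return 0.0
    total_frames = losi.n_rows + losi.window - 1
    covered = np.zeros(total_frames, dtype=bool)
    for iv in losi.intervals:
        covered[iv.row_start:iv.row_end + losi.window] = True
    return float(covered.mean())


def sync_mean_r2(losi: LOSI, matrix: RSquareMatrix) -> float:
    """Mean matrix value over all (row, lag) members of retained intervals.

    NaN (with a warning left to the caller) when the LOSI is empty.
    """
    if not losi.intervals:
        return float("nan")
    cells = []
    lag_index = {int(l): j for j, l in enumerate(matrix.lags)}
    for iv in losi.intervals:
        j = lag_index[iv.lag]
        cells.append(matrix.values[iv.row_start:iv.row_end + 1, j])
    return float(np.concatenate(cells).mean())
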