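"""Surrogate-referenced synchrony: SUSY and SUCO.

Both methods cut the dyad into non-overlapping segments (default 30 s) and
express synchrony relative to *segment-shuffled* surrogates, i.e. pairings
of an A-segment with a non-matching B-segment. With n segments there are
exactly n(n-1) ordered non-identical pairings, and the full ensemble is
enumerated, so the surrogate reference is deterministic.

SUSY scores a segment by the mean Fisher-Z cross-correlation over all
integer-frame lags within +-5 s, either sign-free (Z_abs) or signed
(Z_noabs); the dyad value is the mean of segment scores, and the effect
size standardizes it against the surrogate ensemble:
ES = (Z - mean_surrogate) / SD(surrogate).

SUCO works on local slopes (least-squares slope in 3 s windows stepped by
1 s): per segment the slope sequences of A and B are Pearson-correlated
(r_i), aggregated sign-free into Z'_abs, and summarized by the concordance
index CO = ln(sum of positive r_i / |sum of negative r_i|). ES_abs uses
the pairwise surrogate ensemble; ES-CO standardizes CO against full
cyclic-shift surrogate dyads, since a concordance index needs a whole set
of segment correlations rather than a single pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import fisher_z
from .datatypes import DyadTimeSeries

__all__ = ["SusyResult", "SucoResult", "susy", "suco"]


@dataclass(frozen=True)
class SusyResult:
    z_abs: float
    z_noabs: float
    es_abs: float
    es_noabs: float
    n_segments: int
    n_surrogates: int


@dataclass(frozen=True)
class SucoResult:
    z_abs_prime: float
    co: float               # NaN when all r_i share one sign
    es_abs: float
    es_co: float
    segment_correlations: np.ndarray
    n_segments: int
    co_defined: bool


def _pair_lag_scores(a: np.ndarray, b: np.ndarray, seg: int, n_seg: int,
                     lag_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Segment-pair score matrices (abs, noabs).

    Entry (i, j): mean over available lags of the Fisher-Z cross-correlation
    between A-segment i and the lag-shifted window of B anchored at segment
    j. Lagged windows may read past the segment edge into B's neighboring
    frames; lags that would leave the series are skipped.
    """
    L = b.size
    lags = np.arange(-lag_max, lag_max + 1)
    cb = np.concatenate(([0.0], np.cumsum(b)))
    cb2 = np.concatenate(([0.0], np.cumsum(b * b)))
    score_abs = np.full((n_seg, n_seg), np.nan)
    score_noabs = np.full((n_seg, n_seg), np.nan)
    a_segs = [a[i * seg:(i + 1) * seg] for i in range(n_seg)]
    a_sums = np.array([s.sum() for s in a_segs])
    a_vars = np.array([(s * s).sum() - s.sum() ** 2 / seg for s in a_segs])
    a_ss = np.array([(s * s).sum() for s in a_segs])
    for j in range(n_seg):
        base = j * seg
        lo = max(0, base - lag_max)
        hi = min(L, base + seg + lag_max)
        bseg = b[lo:hi]
        valid = (base + lags >= 0) & (base + lags + seg <= L)
        starts = base + lags[valid]
        s_b = cb[starts + seg] - cb[starts]
        s_b2 = cb2[starts + seg] - cb2[starts]
        var_b = s_b2 - s_b * s_b / seg
        for i in range(n_seg):
            if a_vars[i] <= 1e-12 * max(a_ss[i], 1.0):
                continue
            cross = np.correlate(bseg, a_segs[i], mode="valid")
            s_ab = cross[starts - lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (s_ab - a_sums[i] * s_b / seg) / np.sqrt(a_vars[i] * var_b)
            r = r[var_b > 1e-12 * np.maximum(s_b2, 1.0)]
            if r.size == 0:
                continue
            z = fisher_z(np.clip(r, -1.0, 1.0))
            score_abs[i, j] = np.abs(z).mean()
            score_noabs[i, j] = z.mean()
    return score_abs, score_noabs


def _es(real: float, surrogate: np.ndarray) -> float:
    surrogate = surrogate[np.isfinite(surrogate)]
    if surrogate.size < 2:
        return float("nan")
    sd = surrogate.std(ddof=1)
    return float((real - surrogate.mean()) / sd) if sd > 0 else float("nan")


def susy(dyad: DyadTimeSeries, segment_s: float = 30.0,
         lag_max_s: float = 5.0) -> SusyResult:
    """Surrogate synchrony with the exhaustive n(n-1) segment-pair ensemble."""
    seg = int(round(segment_s * dyad.fps))
    lag_max = int(round(lag_max_s * dyad.fps))
    n_seg = len(dyad) // seg
    if n_seg < 2:
        raise ValueError("need at least 2 full segments")
    s_abs, s_noabs = _pair_lag_scores(dyad.a, dyad.b, seg, n_seg, lag_max)
    diag = np.eye(n_seg, dtype=bool)
    real_abs = float(np.nanmean(s_abs[diag]))
    real_noabs = float(np.nanmean(s_noabs[diag]))
    surr_abs = s_abs[~diag]
    surr_noabs = s_noabs[~diag]
    if np.isfinite(s_abs[diag]).sum() < 2:
        raise ValueError("fewer than 2 valid segments")
    return SusyResult(
        z_abs=real_abs, z_noabs=real_noabs,
        es_abs=_es(real_abs, surr_abs), es_noabs=_es(real_noabs, surr_noabs),
        n_segments=n_seg, n_surrogates=int(np.isfinite(surr_abs).sum()))


def segment_slopes(x: np.ndarray, seg: int, n_seg: int, win: int,
                   incr: int) -> list[np.ndarray]:
    """Least-squares slopes in overlapping windows, per segment.

    Windows are aligned to segment starts and stepped by ``incr``; a window
    belongs to the segment it starts in and must fit inside the series, so
    it may read past the segment edge.
    """
    c = (win - 1) / 2.0
    kernel = np.arange(win) - c
    denom = (kernel * kernel).sum()
    slopes_all = np.correlate(x, kernel, mode="valid") / denom  # start -> slope
    out = []
    for i in range(n_seg):
        starts = np.arange(i * seg, (i + 1) * seg, incr)
        starts = starts[starts + win <= x.size]
        out.append(slopes_all[starts])
    return out


def suco(dyad: DyadTimeSeries, slope_window_s: float = 3.0,
         slope_increment_s: float = 1.0, segment_s: float = 30.0) -> SucoResult:
    """Surrogate concordance of local slopes."""
    fps = dyad.fps
    seg = int(round(segment_s * fps))
    win = int(round(slope_window_s * fps))
    incr = max(1, int(round(slope_increment_s * fps)))
    n_seg = len(dyad) // seg
    if n_seg < 2:
        raise ValueError("need at least 2 full segments")
    if seg < 3 * win:
        raise ValueError("segment too short for 3 slope windows")
    sa = segment_slopes(dyad.a, seg, n_seg, win, incr)
    sb = segment_slopes(dyad.b, seg, n_seg, win, incr)

    def corr(i: int, j: int) -> float:
        x, y = sa[i], sb[j]
        m = min(x.size, y.size)
        xr, yr = x[:m], y[:m]
        xc, yc = xr - xr.mean(), yr - yr.mean()
        vx, vy = (xc * xc).sum(), (yc * yc).sum()
        # relative guard: constant slopes up to rounding noise are degenerate
        if m < 3 or vx <= 1e-12 * (xr * xr).sum() or vy <= 1e-12 * (yr * yr).sum():
            return float("nan")
        return float(np.clip((xc * yc).sum() / np.sqrt(vx * vy), -1.0, 1.0))

    pair_r = np.array([[corr(i, j) for j in range(n_seg)] for i in range(n_seg)])
    r_i = np.diagonal(pair_r)
    valid = np.isfinite(r_i)
    if valid.sum() < 2:
        raise ValueError("fewer than 2 segments with defined slope correlation")
    z_abs_prime = float(fisher_z(np.abs(r_i[valid])).mean())
    co = _concordance(r_i[valid])
    off = ~np.eye(n_seg, dtype=bool)
    es_abs = _es(z_abs_prime, fisher_z(np.abs(pair_r[off])))
    # full cyclic-shift surrogate dyads for the concordance index
    co_surr = np.array([
        _concordance(np.array([pair_r[i, (i + k) % n_seg] for i in range(n_seg)
                               if np.isfinite(pair_r[i, (i + k) % n_seg])]))
        for k in range(1, n_seg)
    ])
    es_co = _es(co, co_surr) if np.isfinite(co) else float("nan")
    return SucoResult(z_abs_prime=z_abs_prime, co=co, es_abs=es_abs, es_co=es_co,
                      segment_correlations=r_i, n_segments=n_seg,
                      co_defined=bool(np.isfinite(co)))


def _concordance(r: np.ndarray) -> float:
    """ln(sum of positive r / |sum of negative r|); NaN if either side empty."""
    pos = r[r > 0].sum()
    neg = r[r < 0].sum()
    if pos <= 0 or neg >= 0:
        return float("nan")
    return float(np.log(pos / abs(neg)))
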