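"""Small numeric helpers shared across measure modules."""

from __future__ import annotations

import numpy as np

#: |r| is capped at 1 - FISHER_CLAMP_EPS before atanh so perfect
#: correlations (common in noiseless fixtures) stay finite.
FISHER_CLAMP_EPS = 1e-7
_CLAMP = 1.0 - FISHER_CLAMP_EPS


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher's Z transform atanh(r), with |r| clamped away from 1."""
    r = np.clip(r, -_CLAMP, _CLAMP)
    return np.arctanh(r)


def windowed_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson r of two equal-length windows; NaN when degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def sliding_corr_same_start(x: np.ndarray, y: np.ndarray, b: int) -> np.ndarray:
    """Pearson r of aligned length-``b`` windows at every start position.

    Returns an array of length ``len(x) - b + 1``; degenerate windows give
    NaN. Implemented with cumulative sums so the whole row of window starts
    costs O(L).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size - b + 1
    if n < 1:
        return np.empty(0)
    sx = _winsum(x, b)
    sy = _winsum(y, b)
    sxx = _winsum(x * x, b)
    syy = _winsum(y * y, b)
    sxy = _winsum(x * y, b)
    cov = sxy - sx * sy / b
    vx = sxx - sx * sx / b
    vy = syy - sy * sy / b
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    # guard tiny negative variances from cancellation
    bad = (vx <= 1e-12 * np.maximum(sxx, 1.0)) | (vy <= 1e-12 * np.maximum(syy, 1.0))
    r[bad] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def _winsum(x: np.ndarray, b: int) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(x)))
    return c[b:] - c[:-b]


def hedges_g(x: np.ndarray, y: np.ndarray) -> float:
    """Hedges g: pooled-SD standardized mean difference of x minus y,
    times the small-sample correction 1 - 3/(4(n1+n2) - 9)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        return float("nan")
    correction = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float((x.mean() - y.mean()) / np.sqrt(s2) * correction)
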