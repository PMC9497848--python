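"""Windowed cross-lagged correlation (rMEA style) with pseudo-synchrony test.

The series is scanned with a reference window (default 60 s) stepped by a
fixed increment (default 30 s); for every step the partner's window is
shifted through all integer-frame lags up to +-5 s. Each cell of the
resulting matrix is the Fisher-Z of the *absolute* Pearson correlation of
the two windows, so cells are non-negative. Two summary measures are read
off the matrix: the mean of the lag-0 column (WCC) and the grand mean over
all lags (WCLC).

Because noise and non-stationarity alone produce non-zero windowed
correlations, the measures are referenced against *pseudo-synchrony*: the
same computation on artificial dyads that pair person A of one dyad with
person B of another (person shuffling), giving a per-dyad z score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import fisher_z
from .datatypes import DyadTimeSeries

__all__ = [
    "WCLCMatrix",
    "SurrogateDistribution",
    "wclc_matrix",
    "rmea_wcc",
    "rmea_wclc",
    "person_shuffle_test",
]


@dataclass(frozen=True)
class WCLCMatrix:
    """Window-start x lag grid of Fisher-Z absolute cross-correlations.

    ``values[i, j]`` is atanh(|r|) for the reference window starting at
    ``row_starts[i]`` (0-based frame index) against the partner window
    starting at ``row_starts[i] + lags[j]``; NaN marks cells whose lagged
    window does not fit in the series or whose variance is degenerate.
    """

    values: np.ndarray
    row_starts: np.ndarray
    lags: np.ndarray
    window: int
    length: int


@dataclass(frozen=True)
class SurrogateDistribution:
    values: np.ndarray
    scheme: str  # "person-shuffle" | "segment-shuffle"

    @property
    def n_surrogates(self) -> int:
        return self.values.size


def _lagged_corr_row(a: np.ndarray, b: np.ndarray, t: int, b_width: int,
                     lags: np.ndarray) -> np.ndarray:
    """Pearson r between A[t:t+b] and B[t+lag : t+lag+b] for every lag.

    One np.correlate call provides all lagged cross sums; window sums of B
    come from cumulative sums. Out-of-range or degenerate cells are NaN.
    """
    L = a.size
    aw = a[t:t + b_width]
    lo = max(0, t + lags[0])
    hi = min(L, t + lags[-1] + b_width)
    valid = (t + lags >= 0) & (t + lags + b_width <= L)
    out = np.full(lags.size, np.nan)
    if not valid.any():
        return out
    bseg = b[lo:hi]
    cross_all = np.correlate(bseg, aw, mode="valid")  # index k -> B start lo+k
    cb = np.concatenate(([0.0], np.cumsum(bseg)))
    cb2 = np.concatenate(([0.0], np.cumsum(bseg * bseg)))
    starts = t + lags[valid] - lo
    s_ab = cross_all[starts]
    s_b = cb[starts + b_width] - cb[starts]
    s_b2 = cb2[starts + b_width] - cb2[starts]
    s_a = aw.sum()
    var_a = (aw * aw).sum() - s_a * s_a / b_width
    var_b = s_b2 - s_b * s_b / b_width
    cov = s_ab - s_a * s_b / b_width
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var_a * var_b)
    tol = 1e-12
    r[(var_b <= tol * np.maximum(s_b2, 1.0)) | (var_a <= tol)] = np.nan
    out[valid] = np.clip(r, -1.0, 1.0)
    return out


def wclc_matrix(dyad: DyadTimeSeries, window_s: float = 60.0, lag_max_s: float = 5.0,
                increment_s: float = 30.0) -> WCLCMatrix:
    """Windowed cross-lagged correlation matrix, Fisher-Z of absolute r.

    Positive lag means the second member's window starts later, i.e. B
    follows A. Rows where the reference window does not fit are dropped;
    lagged windows falling off either end leave the cell missing.
    """
    fps = dyad.fps
    b_width = int(round(window_s * fps))
    tau_max = int(round(lag_max_s * fps))
    increment = max(1, int(round(increment_s * fps)))
    L = len(dyad)
    if L < b_width + tau_max:
        raise ValueError("series shorter than window + maximum lag")
    lags = np.arange(-tau_max, tau_max + 1)
    row_starts = np.arange(0, L - b_width + 1, increment)
    values = np.empty((row_starts.size, lags.size))
    for i, t in enumerate(row_starts):
        r = _lagged_corr_row(dyad.a, dyad.b, int(t), b_width, lags)
        values[i] = fisher_z(np.abs(r))
    return WCLCMatrix(values=values, row_starts=row_starts, lags=lags,
                      window=b_width, length=L)


def rmea_wcc(matrix: WCLCMatrix) -> float:
    """Mean of the lag-0 column over non-missing rows."""
    col = matrix.values[:, matrix.lags == 0].ravel()
    if np.isnan(col).all():
        raise ValueError("no valid lag-0 entries")
    return float(np.nanmean(col))


def rmea_wclc(matrix: WCLCMatrix) -> float:
    """Grand mean over all non-missing cells (all lags)."""
    if np.isnan(matrix.values).all():
        raise ValueError("no valid entries")
    return float(np.nanmean(matrix.values))


def person_shuffle_test(cohort: list[DyadTimeSeries], measure: str = "wclc",
                        n_shuffles: int = 100, seed: int = 0,
                        window_s: float = 60.0, lag_max_s: float = 5.0,
                        increment_s: float = 30.0) -> pd.DataFrame:
    """Pseudo-synchrony z for every dyad of a cohort.

    For each dyad, ``n_shuffles`` surrogate dyads pair its A series with the
    B series of another dyad drawn uniformly with replacement (truncating
    the pair to the shorter length); the requested measure (``"wcc"`` or
    ``"wclc"``) is computed on each surrogate, and
    ``z = (real - mean_surrogate) / sd_surrogate``. Returns one row per
    dyad with columns real, surr_mean, surr_sd, z, p (two-sided normal).
    """
    if len(cohort) < 2:
        raise ValueError("person shuffling needs at least 2 dyads")
    if measure not in ("wcc", "wclc"):
        raise ValueError("measure must be 'wcc' or 'wclc'")
    summarize = rmea_wcc if measure == "wcc" else rmea_wclc
    rng = np.random.default_rng(seed)

    def pair_value(a_dyad: DyadTimeSeries, b_dyad: DyadTimeSeries) -> float:
        n = min(len(a_dyad), len(b_dyad))
        pair = DyadTimeSeries(a=a_dyad.a[:n], b=b_dyad.b[:n], fps=a_dyad.fps)
        return summarize(wclc_matrix(pair, window_s, lag_max_s, increment_s))

    cache: dict[tuple[int, int], float] = {}
    rows = []
    for i, dyad in enumerate(cohort):
        real = summarize(wclc_matrix(dyad, window_s, lag_max_s, increment_s))
        others = [j for j in range(len(cohort)) if j != i]
        draws = rng.choice(others, size=n_shuffles, replace=True)
        surr = np.empty(n_shuffles)
        for k, j in enumerate(draws):
            key = (i, int(j))
            if key not in cache:
                cache[key] = pair_value(dyad, cohort[j])
            surr[k] = cache[key]
        mu, sd = surr.mean(), surr.std(ddof=1)
        z = (real - mu) / sd if sd > 0 else np.nan
        rows.append({"dyad_id": dyad.dyad_id, "real": real, "surr_mean": mu,
                     "surr_sd": sd, "z": z,
                     "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan})
    return pd.DataFrame(rows)
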