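"""Independent brute-force reference implementations.

Everything here is written in the most literal style possible — explicit
loops, np.corrcoef / np.linalg.lstsq per window — deliberately sharing no
code with the package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np

CLAMP = 1.0 - 1e-7


def fisher(r: float) -> float:
    return float(np.arctanh(np.clip(r, -CLAMP, CLAMP)))


def moving_median_oracle(x: np.ndarray, bandwidth: int) -> np.ndarray:
    """Centered moving median, window shrinking symmetrically at the ends."""
    half = bandwidth // 2
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        k = min(i, n - 1 - i, half)
        window = sorted(x[i - k:i + k + 1])
        m = len(window)
        out[i] = (window[m // 2] if m % 2 == 1
                  else 0.5 * (window[m // 2 - 1] + window[m // 2]))
    return out


def motion_energy_oracle(frames: np.ndarray, mask: np.ndarray,
                         threshold: int) -> np.ndarray:
    """Double-loop pixel comparison."""
    n, h, w = frames.shape
    out = np.zeros(n - 1)
    for t in range(n - 1):
        count = 0
        for i in range(h):
            for j in range(w):
                if mask[i, j] and abs(int(frames[t + 1, i, j]) - int(frames[t, i, j])) >= threshold:
                    count += 1
        out[t] = count
    return out


def corr_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def wclc_matrix_oracle(a: np.ndarray, b: np.ndarray, window: int, tau_max: int,
                       increment: int) -> np.ndarray:
    """Fisher-Z |r| grid, rows at the given increment."""
    L = len(a)
    starts = list(range(0, L - window + 1, increment))
    lags = list(range(-tau_max, tau_max + 1))
    out = np.full((len(starts), len(lags)), np.nan)
    for i, t in enumerate(starts):
        for j, tau in enumerate(lags):
            s = t + tau
            if s < 0 or s + window > L:
                continue
            r = corr_or_nan(a[t:t + window], b[s:s + window])
            if not np.isnan(r):
                out[i, j] = fisher(abs(r))
    return out


def wclc_rsq_oracle(a: np.ndarray, b: np.ndarray, window: int, tau_max: int,
                    alpha: float | None) -> np.ndarray:
    """Squared lagged window correlations with the F significance filter."""
    from scipy import stats

    L = len(a)
    rows = L - window + 1
    lags = list(range(-tau_max, tau_max + 1))
    out = np.full((rows, len(lags)), np.nan)
    r2_crit = 0.0
    if alpha is not None:
        f_crit = stats.f.isf(alpha, 1, window - 2)
        r2_crit = f_crit / (f_crit + window - 2)
    for t in range(rows):
        for j, tau in enumerate(lags):
            s = t + tau
            if s < 0 or s + window > L:
                continue
            r = corr_or_nan(a[t:t + window], b[s:s + window])
            if np.isnan(r):
                continue
            r2 = r * r
            out[t, j] = 0.0 if (alpha is not None and r2 < r2_crit) else r2
    return out


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    sst = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (resid ** 2).sum() / sst)


def wclr_rsq_oracle(a: np.ndarray, b: np.ndarray, window: int, tau_max: int,
                    alpha: float | None) -> np.ndarray:
    """Two-regression Delta R^2 per cell, positive lag = B follows A."""
    from scipy import stats

    L = len(a)
    rows = L - window + 1
    lags = list(range(-tau_max, tau_max + 1))
    out = np.full((rows, len(lags)), np.nan)
    f_crit = stats.f.isf(alpha, 1, window - 3) if alpha is not None else None
    for t in range(rows):
        for j, tau in enumerate(lags):
            k = abs(tau)
            if tau >= 0:
                if t + k + window > L:
                    continue
                y = b[t + k:t + k + window]
                x_auto = b[t:t + window]
                x_cross = a[t:t + window]
            else:
                if t - k < 0:
                    continue
                y = a[t:t + window]
                x_auto = a[t - k:t - k + window]
                x_cross = b[t - k:t - k + window]
            if np.std(y) == 0 or np.std(x_auto) == 0 or np.std(x_cross) == 0:
                continue
            r12 = np.corrcoef(x_auto, x_cross)[0, 1]
            if abs(1.0 - r12 * r12) < 1e-10:
                out[t, j] = 0.0
                continue
            r2_m1 = _ols_r2(y, x_auto[:, None])
            r2_m2 = _ols_r2(y, np.column_stack([x_auto, x_cross]))
            delta = max(0.0, min(1.0, r2_m2 - r2_m1))
            if f_crit is not None and 1.0 - r2_m2 > 1e-12:
                f = (r2_m2 - r2_m1) / ((1.0 - r2_m2) / (window - 3))
                if f < f_crit:
                    delta = 0.0
            out[t, j] = delta
    return out


def peak_picking_oracle(values: np.ndarray, lags: np.ndarray,
                        cutoff: float) -> list[tuple[int, int, int, float]]:
    """Literal enumeration of the selection rule.

    Returns retained intervals as (row_start, row_end, lag, mean_strength).
    """
    n_rows, n_lags = values.shape
    v = np.where(np.isnan(values), -np.inf, values)
    maxima = np.zeros((n_rows, n_lags), dtype=bool)
    for t in range(n_rows):
        j = 0
        while j < n_lags:
            e = j
            while e + 1 < n_lags and v[t, e + 1] == v[t, j]:
                e += 1
            left = v[t, j - 1] if j > 0 else -np.inf
            right = v[t, e + 1] if e + 1 < n_lags else -np.inf
            if np.isfinite(v[t, j]) and v[t, j] > left and v[t, j] > right:
                rep = min(range(j, e + 1), key=lambda c: (abs(int(lags[c])), int(lags[c])))
                maxima[t, rep] = True
            j = e + 1
    candidates = []
    for j in range(n_lags):
        t = 0
        while t < n_rows:
            if maxima[t, j]:
                e = t
                while e + 1 < n_rows and maxima[e + 1, j]:
                    e += 1
                mean = float(values[t:e + 1, j].mean())
                candidates.append((t, e, int(lags[j]), mean))
                t = e + 1
            else:
                t += 1
    # repeatedly select the best remaining candidate, discard overlaps
    kept = []
    remaining = list(candidates)
    while remaining:
        best = min(remaining,
                   key=lambda c: (-c[3], c[0], abs(c[2]), c[2]))
        kept.append(best)
        remaining = [c for c in remaining
                     if c is not best and (c[1] < best[0] or c[0] > best[1])]
    kept = [c for c in kept if c[3] > cutoff]
    return sorted(kept)


def susy_oracle(a: np.ndarray, b: np.ndarray, seg: int, lag_max: int):
    """Segment-pair score matrices and SUSY summary, all via loops."""
    L = len(a)
    n_seg = L // seg
    lags = list(range(-lag_max, lag_max + 1))
    score_abs = np.full((n_seg, n_seg), np.nan)
    score_noabs = np.full((n_seg, n_seg), np.nan)
    for i in range(n_seg):
        aw = a[i * seg:(i + 1) * seg]
        if np.std(aw) == 0:
            continue
        for j in range(n_seg):
            zs = []
            for lag in lags:
                s = j * seg + lag
                if s < 0 or s + seg > L:
                    continue
                bw = b[s:s + seg]
                if np.std(bw) == 0:
                    continue
                zs.append(fisher(np.corrcoef(aw, bw)[0, 1]))
            if zs:
                score_abs[i, j] = np.mean(np.abs(zs))
                score_noabs[i, j] = np.mean(zs)
    z_abs = np.nanmean([score_abs[i, i] for i in range(n_seg)])
    surr = [score_abs[i, j] for i in range(n_seg) for j in range(n_seg)
            if i != j and np.isfinite(score_abs[i, j])]
    es_abs = (z_abs - np.mean(surr)) / np.std(surr, ddof=1)
    return score_abs, score_noabs, z_abs, es_abs


def suco_slopes_oracle(x: np.ndarray, seg: int, n_seg: int, win: int,
                       incr: int) -> list[np.ndarray]:
    """Per-segment window slopes via np.polyfit."""
    out = []
    for i in range(n_seg):
        slopes = []
        for s in range(i * seg, (i + 1) * seg, incr):
            if s + win > len(x):
                break
            slopes.append(np.polyfit(np.arange(win), x[s:s + win], 1)[0])
        out.append(np.array(slopes))
    return out


def concordance_oracle(r: np.ndarray) -> float:
    pos = sum(v for v in r if v > 0)
    neg = sum(v for v in r if v < 0)
    if pos <= 0 or neg >= 0:
        return float("nan")
    return float(np.log(pos / abs(neg)))


def crqa_window_oracle(emb_a: np.ndarray, emb_b: np.ndarray, eps: float,
                       band: int | None, min_line: int):
    """Double-loop recurrence matrix plus diagonal run scan."""
    na, nb = len(emb_a), len(emb_b)
    rec = {}
    n_cells = 0
    for i in range(na):
        for j in range(nb):
            if band is not None and abs(i - j) > band:
                continue
            n_cells += 1
            dist = np.sqrt(((emb_a[i] - emb_b[j]) ** 2).sum())
            rec[(i, j)] = dist < eps
    n_rec = sum(rec.values())
    rr = 100.0 * n_rec / n_cells
    # diagonal runs
    run_lengths = []
    offsets = range(-(na - 1), nb) if band is None else range(-band, band + 1)
    for d in offsets:
        run = 0
        for i in range(na):
            j = i + d
            if (i, j) in rec and rec[(i, j)]:
                run += 1
            else:
                if run:
                    run_lengths.append(run)
                run = 0
        if run:
            run_lengths.append(run)
    det_points = sum(l for l in run_lengths if l >= min_line)
    det = 100.0 * det_points / n_rec if n_rec else float("nan")
    lines = [l for l in run_lengths if l >= min_line]
    entr = 0.0
    if lines:
        uniq = sorted(set(lines))
        p = np.array([lines.count(u) for u in uniq], dtype=float)
        p /= p.sum()
        raw = float(-(p * np.log(p)).sum())
        entr = raw / np.log(len(uniq)) if len(uniq) > 1 else 0.0
    return rr, det, entr


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook product-moment formula."""
    n = len(x)
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = np.sqrt(n * (x * x).sum() - x.sum() ** 2) * np.sqrt(n * (y * y).sum() - y.sum() ** 2)
    return float(num / den)


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranks."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r
    return pearson_oracle(ranks(x), ranks(y))
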