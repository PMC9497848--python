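"""Convergent- and predictive-validity statistics over the cohort table.

Convergent validity: if the 21 measures quantify one construct they should
correlate; the battery is summarized by a Pearson/Spearman correlation
matrix (Pearson below the diagonal, Spearman above, the field's standard
triangle layout) and by an exploratory factor analysis — maximum
likelihood extraction on the Pearson correlation matrix with an oblique
(oblimin/quartimin) rotation, the number of factors chosen by a parallel
test with bootstrap reference eigenvalues. Fit is judged by RMSEA (< 0.08
acceptable), TLI (> 0.9) and the RMSR of residual correlations.

Predictive validity: group contrasts (Kruskal-Wallis p, Hedges g with
small-sample correction, patient minus control) and Pearson/Spearman
correlations of each measure with PHQ9 and GAD7 symptom sums.

No multiplicity adjustment is applied by default (unadjusted p < 0.05
stars); Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import hedges_g
from .datatypes import MEASURE_COLUMNS

__all__ = [
    "CorrelationMatrixResult",
    "FactorSolution",
    "correlation_matrix",
    "parallel_analysis",
    "efa_ml",
    "group_comparison",
    "symptom_correlations",
    "effect_size_label",
]

log = logging.getLogger(__name__)

_MIN_PAIRS = 4


def _measure_cols(table: pd.DataFrame, columns=None) -> list[str]:
    if columns is not None:
        return list(columns)
    return [c for c in MEASURE_COLUMNS if c in table.columns]


@dataclass(frozen=True)
class CorrelationMatrixResult:
    """Pearson (lower triangle) / Spearman (upper triangle) matrix."""

    combined: pd.DataFrame
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    pearson_p: pd.DataFrame
    spearman_p: pd.DataFrame

    def formatted(self, star_alpha: float = 0.05) -> str:
        """Human-readable triangle layout with significance stars."""
        cols = self.combined.columns
        out = pd.DataFrame("", index=cols, columns=cols)
        for i, ri in enumerate(cols):
            out.loc[ri, ri] = "1"
            for j, cj in enumerate(cols):
                if i == j:
                    continue
                src, p = ((self.pearson, self.pearson_p) if i > j
                          else (self.spearman, self.spearman_p))
                r, pv = src.loc[ri, cj], p.loc[ri, cj]
                if np.isnan(r):
                    out.loc[ri, cj] = "--"
                else:
                    star = " *" if pv < star_alpha else ""
                    out.loc[ri, cj] = f"{r:.2f}{star}"
        return out.to_string()


def _pairwise_corr(x: np.ndarray, y: np.ndarray,
                   method: str) -> tuple[float, float]:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < _MIN_PAIRS:
        return np.nan, np.nan
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return np.nan, np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "pearson":
            r, p = stats.pearsonr(xs, ys)
        else:
            r, p = stats.spearmanr(xs, ys)
    return float(r), float(p)


def correlation_matrix(table: pd.DataFrame, columns=None) -> CorrelationMatrixResult:
    """All pairwise measure correlations with pairwise deletion.

    ``combined`` carries Pearson r below the diagonal and Spearman rho
    above it; the *_p frames hold two-sided p-values.
    """
    cols = _measure_cols(table, columns)
    k = len(cols)
    pearson = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    spearman = pearson.copy()
    pearson_p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    spearman_p = pearson_p.copy()
    data = table[cols].to_numpy(dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            r, p = _pairwise_corr(data[:, i], data[:, j], "pearson")
            pearson.iloc[i, j] = pearson.iloc[j, i] = r
            pearson_p.iloc[i, j] = pearson_p.iloc[j, i] = p
            r, p = _pairwise_corr(data[:, i], data[:, j], "spearman")
            spearman.iloc[i, j] = spearman.iloc[j, i] = r
            spearman_p.iloc[i, j] = spearman_p.iloc[j, i] = p
    combined = pearson.copy()
    iu = np.triu_indices(k, 1)
    combined.values[iu] = spearman.values[iu]
    return CorrelationMatrixResult(combined=combined, pearson=pearson,
                                   spearman=spearman, pearson_p=pearson_p,
                                   spearman_p=spearman_p)


def parallel_analysis(table: pd.DataFrame, n_boot: int = 100, seed: int = 0,
                      columns=None, percentile: float = 95.0,
                      method: str = "bootstrap") -> int:
    """Parallel test for the number of factors.

    Observed eigenvalues of the correlation matrix are compared against the
    ``percentile`` of eigenvalues from ``n_boot`` reference data sets:
    either per-column independent bootstrap resamples of the observed data
    (``method="bootstrap"``, which keeps the marginals but destroys the
    dependence) or standard-normal draws (``method="normal"``). Returns the
    count of observed eigenvalues above their reference quantile.
    """
    cols = _measure_cols(table, columns)
    data = table[cols].dropna().to_numpy(dtype=float)
    n, k = data.shape
    if n < 10:
        raise ValueError("need at least 10 complete rows")
    if method not in ("bootstrap", "normal"):
        raise ValueError("method must be 'bootstrap' or 'normal'")
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(data, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    ref = np.empty((n_boot, k))
    for b in range(n_boot):
        if method == "bootstrap":
            sim = np.column_stack([rng.choice(data[:, j], size=n, replace=True)
                                   for j in range(k)])
        else:
            sim = rng.standard_normal((n, k))
        ref[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(sim, rowvar=False)))[::-1]
    threshold = np.percentile(ref, percentile, axis=0)
    above = obs > threshold
    # factors must be leading: stop at the first eigenvalue below threshold
    n_factors = 0
    for flag in above:
        if not flag:
            break
        n_factors += 1
    return n_factors


@dataclass(frozen=True)
class FactorSolution:
    loadings: pd.DataFrame          # measures x factors, oblique-rotated
    factor_correlation: np.ndarray  # factors x factors
    uniqueness: pd.Series
    rmsr: float
    rmsea: float
    tli: float
    n_factors: int
    variance_explained: np.ndarray  # per factor, from rotated loadings
    heywood: bool
    n_obs: int


def efa_ml(table: pd.DataFrame, n_factors: int, columns=None,
           rotation: str = "quartimin") -> FactorSolution:
    """Maximum-likelihood EFA with oblique rotation on the Pearson matrix.

    ``quartimin`` is the oblimin family member with gamma = 0, the common
    default for correlated factors. With few rows and many measures the
    correlation matrix is near-singular; the fit is attempted anyway, a
    warning is logged, and Heywood cases (zero/negative uniqueness) are
    flagged but still returned.
    """
    from statsmodels.multivariate.factor import Factor
    from statsmodels.multivariate.factor_rotation import rotate_factors

    cols = _measure_cols(table, columns)
    data = table[cols].dropna().to_numpy(dtype=float)
    n, p = data.shape
    if n <= n_factors:
        raise ValueError("more factors than observations")
    if n < p:
        log.warning("EFA with %d rows and %d measures: correlation matrix "
                    "is ill-conditioned; interpret fit indices cautiously", n, p)
    R = np.corrcoef(data, rowvar=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = Factor(corr=R, n_factor=n_factors, method="ml", nobs=n).fit()
    L = np.asarray(fit.loadings)
    psi = 1.0 - (L * L).sum(axis=1)
    heywood = bool((psi <= 1e-6).any())
    if n_factors > 1:
        L_rot, T = rotate_factors(L, rotation)
        phi = T.T @ T
    else:
        L_rot, phi = L, np.eye(1)
    sigma = L @ L.T + np.diag(np.clip(psi, 1e-8, None))
    resid = R - sigma
    off = ~np.eye(p, dtype=bool)
    rmsr = float(np.sqrt((resid[off] ** 2).mean()))
    rmsea, tli = _ml_fit_indices(R, sigma, n, p, n_factors)
    var_expl = (L_rot * L_rot).sum(axis=0)
    return FactorSolution(
        loadings=pd.DataFrame(L_rot, index=cols,
                              columns=[f"F{i+1}" for i in range(n_factors)]),
        factor_correlation=phi, uniqueness=pd.Series(psi, index=cols),
        rmsr=rmsr, rmsea=rmsea, tli=tli, n_factors=n_factors,
        variance_explained=var_expl, heywood=heywood, n_obs=n)


def _ml_fit_indices(R: np.ndarray, sigma: np.ndarray, n: int, p: int,
                    k: int) -> tuple[float, float]:
    """RMSEA and TLI from the ML discrepancy with Bartlett's correction."""
    sign_r, logdet_r = np.linalg.slogdet(R)
    sign_s, logdet_s = np.linalg.slogdet(sigma)
    if sign_r <= 0 or sign_s <= 0:
        return float("nan"), float("nan")
    f_min = logdet_s + np.trace(R @ np.linalg.inv(sigma)) - logdet_r - p
    f_min = max(f_min, 0.0)
    df = ((p - k) ** 2 - (p + k)) / 2.0
    c = n - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0
    chi2 = c * f_min
    f0 = -logdet_r
    df0 = p * (p - 1) / 2.0
    chi0 = (n - 1 - (2 * p + 5) / 6.0) * f0
    if df <= 0:
        return 0.0, 1.0
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    denom = chi0 / df0 - 1.0
    tli = float((chi0 / df0 - chi2 / df) / denom) if denom != 0 else float("nan")
    return rmsea, tli


def group_comparison(table: pd.DataFrame, group_col: str = "group",
                     patient_label: str = "patient",
                     columns=None) -> pd.DataFrame:
    """Kruskal-Wallis p and Hedges g (patient minus control) per measure."""
    cols = _measure_cols(table, columns)
    groups = table[group_col].unique()
    if len(groups) != 2:
        raise ValueError("group comparison expects exactly two groups")
    control_label = [g for g in groups if g != patient_label][0]
    rows = []
    for c in cols:
        pat = table.loc[table[group_col] == patient_label, c].dropna().to_numpy()
        ctl = table.loc[table[group_col] == control_label, c].dropna().to_numpy()
        row = {"measure": c,
               "mean_patient": pat.mean() if pat.size else np.nan,
               "sd_patient": pat.std(ddof=1) if pat.size > 1 else np.nan,
               "mean_control": ctl.mean() if ctl.size else np.nan,
               "sd_control": ctl.std(ddof=1) if ctl.size > 1 else np.nan}
        if pat.size >= 2 and ctl.size >= 2:
            try:
                _, p = stats.kruskal(pat, ctl)
            except ValueError:  # all values identical
                p = 1.0
            row["kw_p"] = p
            row["hedges_g"] = hedges_g(pat, ctl)
        else:
            row["kw_p"] = np.nan
            row["hedges_g"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("measure")


def symptom_correlations(table: pd.DataFrame,
                         symptom_cols: tuple[str, ...] = ("phq9", "gad7"),
                         columns=None) -> pd.DataFrame:
    """Pearson and Spearman correlation of each measure with symptom sums."""
    cols = _measure_cols(table, columns)
    rows = []
    for c in cols:
        row: dict[str, float | str] = {"measure": c}
        for s in symptom_cols:
            x = table[c].to_numpy(dtype=float)
            y = table[s].to_numpy(dtype=float)
            for method in ("pearson", "spearman"):
                r, p = _pairwise_corr(x, y, method)
                row[f"{s}_{method}_r"] = r
                row[f"{s}_{method}_p"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("measure")


def effect_size_label(value: float, kind: str = "r") -> str:
    """Cohen's verbal labels for |r| (0.1/0.3/0.5) and |g| (0.2/0.5/0.8)."""
    cuts = (0.1, 0.3, 0.5) if kind == "r" else (0.2, 0.5, 0.8)
    v = abs(value)
    if np.isnan(v):
        return "undefined"
    if v <= cuts[0]:
        return "negligible"
    if v <= cuts[1]:
        return "small"
    if v <= cuts[2]:
        return "moderate"
    return "large"
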