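"""Statistical battery for participant-factor vs signal-quality analyses.

Three families of analysis are implemented:

1. Equal-width binning with two-sided Mann-Whitney U tests between the first
   and last bins, Benjamini-Hochberg corrected, significance at 0.01.
2. Spearman rank correlation (BH corrected) plus a robust linear fit on the
   log10-scale response, summarized as a signed fold change between the
   model's predictions at the 1st and 99th percentiles of the factor.
3. Robust multiple regression after a |r| > 0.5 multicollinearity screen,
   reporting per-predictor estimate, SE, t, p, Cohen's f² and VIF.

Robust fitting is iteratively reweighted least squares with Tukey bisquare
weights (tuning constant 4.685, ~95% Gaussian efficiency), the convention of
mainstream statistical toolboxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.robust.norms import TukeyBiweight
from statsmodels.stats.multitest import multipletests

__all__ = [
    "equal_width_bins",
    "mann_whitney_first_last",
    "bh_adjust",
    "spearman",
    "robust_linfit",
    "FoldChangeResult",
    "fold_change",
    "multicollinearity_screen",
    "vif",
    "RegressionReport",
    "robust_multiple_regression",
    "cohens_f2",
    "F2_BANDS",
    "SIGNIFICANCE_ALPHA",
    "BISQUARE_C",
]

SIGNIFICANCE_ALPHA = 0.01
BISQUARE_C = 4.685
F2_BANDS = {"small": 0.02, "medium": 0.15, "large": 0.35}


def equal_width_bins(x, k: int = 4) -> np.ndarray:
    """Assign 1..k equal-width bins over [min(x), max(x)].

    Bins are right-half-open except the last, which is closed so the maximum
    maps to bin k.  Used for visualization and first-vs-last bin tests only;
    correlation/regression analyses use the continuous values.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("x is constant; bins are undefined")
    edges = np.linspace(lo, hi, k + 1)
    ids = np.digitize(x, edges[1:-1], right=False) + 1
    return ids


def mann_whitney_first_last(y, bins) -> dict:
    """Two-sided Mann-Whitney U test between the first and last bins.

    Exact p-value for small tie-free groups (both n <= 20), normal
    approximation with tie correction otherwise.
    """
    y = np.asarray(y, dtype=float)
    bins = np.asarray(bins)
    first, last = bins.min(), bins.max()
    g1, g2 = y[bins == first], y[bins == last]
    if g1.size == 0 or g2.size == 0:
        raise ValueError("first/last bin is empty")
    has_ties = np.unique(np.concatenate([g1, g2])).size < g1.size + g2.size
    method = "exact" if (g1.size <= 20 and g2.size <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue),
            "n1": int(g1.size), "n2": int(g2.size), "method": method}


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> dict:
    """Spearman rank correlation with average ranks for ties; p from the
    t approximation.  Constant input is flagged with NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": float("nan"), "p": float("nan")}
    res = stats.spearmanr(x, y)
    return {"rho": float(res.statistic), "p": float(res.pvalue)}


def _design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x])


def _rlm_fit(X: np.ndarray, y: np.ndarray, maxiter: int = 50,
             tol: float = 1e-8):
    """IRLS bisquare fit; falls back to OLS for (near-)perfect fits where the
    robust scale estimate degenerates."""
    ols = sm.OLS(y, X).fit()
    resid_scale = np.max(np.abs(ols.resid)) if len(y) else 0.0
    y_scale = max(np.max(np.abs(y)), 1.0)
    if resid_scale <= 1e-10 * y_scale:
        return ols, np.ones_like(y), True
    rlm = sm.RLM(y, X, M=TukeyBiweight(c=BISQUARE_C))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = rlm.fit(maxiter=maxiter, tol=tol, conv="coefs")
    converged = len(fit.fit_history["params"]) < maxiter
    return fit, np.asarray(fit.weights), converged


def robust_linfit(x, y) -> dict:
    """Robust simple linear regression of y on x (IRLS, bisquare 4.685).

    Returns slope, intercept and a convergence flag; non-convergence returns
    the last iterate, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    fit, _, converged = _rlm_fit(_design(x), y)
    intercept, slope = fit.params
    return {"slope": float(slope), "intercept": float(intercept),
            "converged": bool(converged)}


@dataclass
class FoldChangeResult:
    """Signed fold change of the unlogged response between the 1st- and
    99th-percentile predictor values under a log10-scale linear fit."""

    L: float
    U: float
    fold_change: float
    slope: float
    intercept: float
    x_low: float
    x_high: float


def fold_change(fit: dict, x, percentiles: tuple[float, float] = (1.0, 99.0)
                ) -> FoldChangeResult:
    """Evaluate a log10-scale fit at the 1st/99th percentiles of x, unlog,
    and apply the sign rule: U/L if U >= L else -L/U.

    Percentiles use linear interpolation between order statistics.
    """
    x = np.asarray(x, dtype=float)
    x_low, x_high = np.percentile(x, percentiles, method="linear")
    slope, intercept = fit["slope"], fit["intercept"]
    L = 10.0 ** (intercept + slope * x_low)
    U = 10.0 ** (intercept + slope * x_high)
    if not (np.isfinite(L) and np.isfinite(U)):
        raise ValueError("non-finite fold-change endpoints")
    fc = U / L if U >= L else -L / U
    return FoldChangeResult(L=float(L), U=float(U), fold_change=float(fc),
                            slope=float(slope), intercept=float(intercept),
                            x_low=float(x_low), x_high=float(x_high))


def multicollinearity_screen(X: pd.DataFrame, r_threshold: float = 0.5,
                             priority: list[str] | None = None) -> list[str]:
    """Drop one predictor from every |Pearson r| > threshold pair.

    Pairs are processed in descending |r|; within a pair the predictor that
    appears *later* in ``priority`` (default: column order) is dropped, and
    pairs involving already-dropped predictors are skipped, which makes the
    rule deterministic for correlation chains.
    """
    cols = list(X.columns)
    priority = priority or cols
    rank = {c: priority.index(c) if c in priority else len(priority) + i
            for i, c in enumerate(cols)}
    corr = X.corr().abs()
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if corr.loc[a, b] > r_threshold:
                pairs.append((corr.loc[a, b], a, b))
    pairs.sort(key=lambda t: -t[0])
    dropped: set[str] = set()
    for _, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        dropped.add(a if rank[a] > rank[b] else b)
    return [c for c in cols if c not in dropped]


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R²_j) from
    regressing predictor j on the others (with intercept).

    Rank-deficient predictors are flagged with +inf.  Bands: <5 low,
    5-10 moderate, >10 high.
    """
    cols = list(X.columns)
    out = {}
    Xv = X.to_numpy(dtype=float)
    for j, c in enumerate(cols):
        yj = Xv[:, j]
        others = np.delete(Xv, j, axis=1)
        if others.shape[1] == 0:
            out[c] = 1.0
            continue
        Z = np.column_stack([np.ones(len(yj)), others])
        beta, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def _weighted_r2(y: np.ndarray, fitted: np.ndarray, w: np.ndarray) -> float:
    """R² analogue from weighted sums of squares at the converged IRLS
    weights."""
    ybar = np.average(y, weights=w)
    ss_res = np.sum(w * (y - fitted) ** 2)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


@dataclass
class RegressionReport:
    """Per-predictor robust regression summary (Tables-style layout)."""

    table: pd.DataFrame          # estimate, se, t, p, f2, vif per predictor
    r_squared: float
    n: int
    converged: bool
    retained: list[str]

    def effect_band(self, predictor: str) -> str:
        f2 = self.table.loc[predictor, "f2"]
        if f2 >= F2_BANDS["large"]:
            return "large"
        if f2 >= F2_BANDS["medium"]:
            return "medium"
        if f2 >= F2_BANDS["small"]:
            return "small"
        return "negligible"


def _fit_r2(X: pd.DataFrame, y: np.ndarray) -> float:
    Z = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])
    fit, w, _ = _rlm_fit(Z, y)
    return _weighted_r2(y, Z @ fit.params, w)


def cohens_f2(X: pd.DataFrame, y, predictor: str,
              r2_full: float | None = None) -> float:
    """Partial Cohen's f² for one predictor in the robust model:
    (R²_full - R²_without_j) / (1 - R²_full), floored at 0.

    R² is the weighted-sum-of-squares analogue at the converged robust
    weights.  Bands: 0.02 small, 0.15 medium, 0.35 large.
    """
    if predictor not in X.columns:
        raise ValueError(f"{predictor!r} not in model")
    y = np.asarray(y, dtype=float)
    if r2_full is None:
        r2_full = _fit_r2(X, y)
    if r2_full >= 1.0 - 1e-12:
        return float("inf")
    r2_red = _fit_r2(X.drop(columns=[predictor]), y) if X.shape[1] > 1 else 0.0
    return float(max(0.0, (r2_full - r2_red) / (1.0 - r2_full)))


def robust_multiple_regression(X: pd.DataFrame, y,
                               compute_f2: bool = True) -> RegressionReport:
    """Robust multiple regression of y on the (screened) predictors.

    IRLS bisquare fit; SEs from the robust covariance estimate; t =
    estimate/SE with two-sided p from the t distribution on n - p - 1
    degrees of freedom; per-predictor partial f² and VIF attached.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    Z = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("rank-deficient design; screen predictors first")
    fit, w, converged = _rlm_fit(Z, y)
    params = np.asarray(fit.params)
    se = np.asarray(fit.bse)
    df = n - p - 1
    tvals = params / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    r2 = _weighted_r2(y, Z @ params, w)
    vifs = vif(X)
    rows = {}
    for j, c in enumerate(X.columns, start=1):
        f2 = cohens_f2(X, y, c, r2_full=r2) if compute_f2 else np.nan
        rows[c] = {"estimate": params[j], "se": se[j], "t": tvals[j],
                   "p": pvals[j], "f2": f2, "vif": vifs[c]}
    table = pd.DataFrame(rows).T[["estimate", "se", "t", "p", "f2", "vif"]]
    return RegressionReport(table=table, r_squared=float(r2), n=int(n),
                            converged=bool(converged),
                            retained=list(X.columns))
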