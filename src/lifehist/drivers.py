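"""Statistical attribution of trait variation to environmental drivers.

Group contrasts by a random-intercept linear mixed model (ecosystem fixed,
site random), PC1 composite nutrient parameters, Spearman correlation,
all-subsets OLS ranked by AIC, and hierarchical partitioning of explained
variance over the best model's predictors.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

MAX_SUBSET_PREDICTORS = 12
MAX_PARTITION_PREDICTORS = 10


@dataclass
class LmmResult:
    fixed_effect_estimate: float  # treatment - reference group mean difference
    se: float
    p: float
    site_variance: float
    residual_variance: float
    method: str = field(default="reml")  # "reml" | "ols"


@dataclass
class ModelSelectionResult:
    models: pd.DataFrame  # columns: predictors (tuple), k, aic, r2; AIC-ascending
    best: tuple[str, ...]


@dataclass
class PartitionResult:
    independent_effects: pd.Series  # per-predictor fraction of variance
    total_r2: float


def zscore(df: pd.DataFrame) -> pd.DataFrame:
    """Standardise each column to mean 0, sample SD 1 (ddof=1)."""
    sd = df.std(ddof=1)
    constant = sd[~(sd > 0)].index.tolist()
    if constant:
        raise ValueError(f"constant variables cannot be z-scored: {constant}")
    return (df - df.mean()) / sd


def pc1_composite(df: pd.DataFrame) -> tuple[pd.Series, float, pd.Series]:
    """First-principal-component scores of a standardized variable set.

    Returns (scores, explained-variance fraction, loadings). The sign is
    fixed so the first listed variable loads positively, making the
    composite's direction reproducible.
    """
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise ValueError("need >= 2 variables and >= 3 samples")
    x = df.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[0] == 0:
        raise ValueError("rank-0 input")
    loadings = vt[0]
    if loadings[0] < 0:
        loadings = -loadings
    scores = x @ loadings
    explained = float(s[0] ** 2 / (s**2).sum())
    return (
        pd.Series(scores, index=df.index, name="PC1"),
        explained,
        pd.Series(loadings, index=df.columns, name="loading"),
    )


def lmm_group_effect(
    y, ecosystem, site, treatment: str | None = None
) -> LmmResult:
    """Ecosystem contrast from a random-intercept mixed model.

    Fits y = b0 + b1 * [ecosystem == treatment] + u_site + eps by REML;
    b1 is the treatment-minus-reference difference in means. ``treatment``
    defaults to ``"cropland"`` when that label is present (the usual
    cropland-minus-pristine contrast), otherwise to the alphabetically
    last label. Wald z inference on b1. With fewer than 2 sites the model
    degenerates and an OLS fit is returned with a warning.
    """
    y = np.asarray(y, dtype=float)
    eco = pd.Series(list(ecosystem))
    site = pd.Series(list(site))
    labels = sorted(eco.unique())
    if len(labels) != 2:
        raise ValueError("exactly two ecosystem labels required")
    if treatment is None:
        treatment = "cropland" if "cropland" in labels else labels[1]
    x = (eco == treatment).to_numpy(dtype=float)
    X = sm.add_constant(x)

    if site.nunique() < 2:
        warnings.warn("fewer than 2 sites; falling back to OLS")
        return _ols_contrast(y, X)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = MixedLM(y, X, groups=site.to_numpy()).fit(reml=True)
        except Exception:
            return _ols_contrast(y, X)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    site_var = float(np.asarray(fit.cov_re)[0, 0])
    resid_var = float(fit.scale)
    if not math.isfinite(se) or se == 0:
        return _ols_contrast(y, X)
    if site_var < 1e-3 * resid_var:
        # singular fit: variance component at the zero boundary, where the
        # mixed model is exactly OLS
        return _ols_contrast(y, X)
    p = 2 * stats.norm.sf(abs(beta / se))
    return LmmResult(beta, se, p, max(site_var, 0.0), resid_var, method="reml")


def _ols_contrast(y: np.ndarray, X: np.ndarray) -> LmmResult:
    fit = sm.OLS(y, X).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else 1.0
    return LmmResult(beta, se, p, 0.0, float(fit.mse_resid), method="ols")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    P-value from the t approximation on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4 or len(x) != len(y):
        raise ValueError("need paired vectors of length >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _subset_rss_r2(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...]) -> tuple[float, float]:
    n = len(y)
    if cols:
        A = np.column_stack([np.ones(n), X[:, cols]])
    else:
        A = np.ones((n, 1))
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    return rss, r2


def all_subsets_aic(y, X: pd.DataFrame, aicc: bool = False) -> ModelSelectionResult:
    """Exhaustive OLS over every predictor subset, ranked by AIC.

    AIC uses the Gaussian profile form n*ln(RSS/n) + 2*(k+2), counting k
    slopes, the intercept and the error variance. Ties break toward the
    smaller model, then lexicographically. ``aicc`` adds the small-sample
    correction 2*m*(m+1)/(n-m-1) with m = k+2.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    k_total = len(names)
    if k_total > MAX_SUBSET_PREDICTORS:
        raise ValueError(f"refusing all-subsets with > {MAX_SUBSET_PREDICTORS} predictors")
    n = len(y)
    if n <= k_total + 2:
        raise ValueError("need n > max subset size + 2")
    Xv = X.to_numpy(dtype=float)
    rows = []
    for r in range(k_total + 1):
        for cols in itertools.combinations(range(k_total), r):
            rss, r2 = _subset_rss_r2(y, Xv, cols)
            m = r + 2
            aic = n * math.log(max(rss, 1e-300) / n) + 2 * m
            if aicc:
                aic += 2 * m * (m + 1) / (n - m - 1)
            rows.append(
                {
                    "predictors": tuple(names[c] for c in cols),
                    "k": r,
                    "aic": aic,
                    "r2": r2,
                }
            )
    models = pd.DataFrame(rows).sort_values(
        by=["aic", "k", "predictors"], kind="stable", ignore_index=True
    )
    return ModelSelectionResult(models, tuple(models.loc[0, "predictors"]))


def hierarchical_partition(y, X: pd.DataFrame) -> PartitionResult:
    """Average R^2 increment of each predictor over all entry orders.

    Computed from the 2^k subset-R^2 table with the combinatorial
    weights s!(k-s-1)!/k!, so the per-predictor independent effects sum
    exactly to the full-model R^2 (Shapley decomposition of explained
    variance).
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    k = len(names)
    if k > MAX_PARTITION_PREDICTORS:
        raise ValueError(f"refusing partition with > {MAX_PARTITION_PREDICTORS} predictors")
    if k == 0:
        raise ValueError("need at least one predictor")
    if len(y) <= k + 2:
        raise ValueError("need n > k + 2")
    Xv = X.to_numpy(dtype=float)
    r2 = {}
    for r in range(k + 1):
        for cols in itertools.combinations(range(k), r):
            r2[cols] = _subset_rss_r2(y, Xv, cols)[1]
    fact = [math.factorial(i) for i in range(k + 1)]
    effects = np.zeros(k)
    for i in range(k):
        others = [j for j in range(k) if j != i]
        for r in range(k):
            w = fact[r] * fact[k - r - 1] / fact[k]
            for cols in itertools.combinations(others, r):
                with_i = tuple(sorted(cols + (i,)))
                effects[i] += w * (r2[with_i] - r2[cols])
    return PartitionResult(
        pd.Series(effects, index=names, name="independent_effect"),
        r2[tuple(range(k))],
    )
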