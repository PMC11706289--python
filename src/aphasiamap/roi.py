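"""Region-of-interest lesion-symptom regression.

Each dimension score is regressed on lesion volume (cm³) within the four
ROIs by ordinary least squares; per-ROI inference uses two-tailed t-tests
at alpha = 0.05 (unadjusted, with optional Holm correction), local effect
sizes are Cohen's f² = (R²_full - R²_reduced) / (1 - R²_full), and a
per-ROI Pillai's-trace MANOVA tests each ROI against all four dimension
scores simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionFit",
    "EffectSize",
    "ManovaResult",
    "fit_roi_model",
    "cohens_f2",
    "pillai_trace",
    "effect_size_label",
    "roi_table",
]


@dataclass
class RegressionFit:
    """OLS fit of one dimension score on the ROI lesion volumes."""

    predictors: list[str]
    beta: np.ndarray  # intercept first
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: float
    f_stat: float
    df1: int
    df2: int
    model_p: float
    significant: np.ndarray  # per predictor (excl. intercept order preserved)


def effect_size_label(f2: float) -> str:
    """Cohen's f² bins: small [0.02, 0.15), medium [0.15, 0.35), large >= 0.35."""
    if f2 >= 0.35:
        return "large"
    if f2 >= 0.15:
        return "medium"
    if f2 >= 0.02:
        return "small"
    return "negligible"


@dataclass
class EffectSize:
    f2: float
    label: str


@dataclass
class ManovaResult:
    predictors: list[str]
    pillai: np.ndarray
    approx_f: np.ndarray
    df1: np.ndarray
    df2: np.ndarray
    p: np.ndarray


def _design(volumes: np.ndarray) -> np.ndarray:
    X = np.asarray(volumes, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def fit_roi_model(
    scores: np.ndarray,
    volumes: np.ndarray,
    predictor_names: list[str] | None = None,
    alpha: float = 0.05,
    holm: bool = False,
) -> RegressionFit:
    """OLS of one dimension's scores on per-participant ROI lesion volumes.

    Rejects rank-deficient designs (reported with the condition number).
    Significance flags are per-predictor two-tailed t-tests at ``alpha``,
    optionally Holm-adjusted across the non-intercept predictors.
    """
    y = np.asarray(scores, dtype=float)
    X = _design(volumes)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > {p} observations for {p - 1} predictors")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values are not supported")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            "rank-deficient design (condition number "
            f"{np.linalg.cond(X):.3g}); drop collinear predictors"
        )
    names = predictor_names or [f"x{i}" for i in range(1, p)]
    res = sm.OLS(y, X).fit()
    pvals = res.pvalues[1:]
    if holm:
        flags = _holm(pvals, alpha)
    else:
        flags = pvals < alpha
    return RegressionFit(
        predictors=list(names),
        beta=res.params,
        se=res.bse,
        t=res.tvalues,
        p=res.pvalues,
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        df1=int(res.df_model),
        df2=int(res.df_resid),
        model_p=float(res.f_pvalue),
        significant=np.asarray(flags, dtype=bool),
    )


def _holm(pvals: np.ndarray, alpha: float) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags


def cohens_f2(scores: np.ndarray, volumes: np.ndarray, predictor_index: int) -> EffectSize:
    """Local effect size of one ROI: (R²_full - R²_reduced) / (1 - R²_full)."""
    y = np.asarray(scores, dtype=float)
    X = np.asarray(volumes, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    full = sm.OLS(y, _design(X)).fit()
    if full.rsquared >= 1.0 - 1e-12:
        raise ValueError("R² of the full model is 1; f² undefined")
    reduced = sm.OLS(y, _design(np.delete(X, predictor_index, axis=1))).fit()
    f2 = (full.rsquared - reduced.rsquared) / (1.0 - full.rsquared)
    f2 = max(float(f2), 0.0)
    return EffectSize(f2, effect_size_label(f2))


def pillai_trace(
    score_matrix: np.ndarray,
    volumes: np.ndarray,
    predictor_names: list[str] | None = None,
) -> ManovaResult:
    """Per-predictor Pillai's trace across all outcome dimensions.

    For each (non-intercept) predictor the single-coefficient hypothesis
    L B = 0 is tested against the multivariate outcome: H = (L B̂)'
    [L (X'X)⁻¹ L']⁻¹ (L B̂), E = residual SSCP, V = tr(H (H+E)⁻¹), with the
    standard F approximation.
    """
    Y = np.asarray(score_matrix, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = _design(volumes)
    n, r = X.shape
    m = Y.shape[1]
    if n <= r + m:
        raise ValueError("need n > n_outcomes + n_predictors + 1")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    E = Y.T @ Y - B.T @ X.T @ Y
    if np.linalg.matrix_rank(E) < m:
        raise ValueError("singular residual covariance across outcomes")
    v_err = n - r
    names = predictor_names or [f"x{i}" for i in range(1, r)]
    pillai = np.empty(r - 1)
    fs = np.empty(r - 1)
    df1s = np.empty(r - 1)
    df2s = np.empty(r - 1)
    ps = np.empty(r - 1)
    for j in range(1, r):
        Lb = B[j][None, :]  # 1 x m
        H = Lb.T @ Lb / XtX_inv[j, j]
        V = float(np.trace(H @ np.linalg.inv(H + E)))
        # s = min(m, q) with q = 1 hypothesis df
        df1 = m
        df2 = v_err - m + 1
        F = (df2 / df1) * V / (1.0 - V)
        pillai[j - 1] = V
        fs[j - 1] = F
        df1s[j - 1] = df1
        df2s[j - 1] = df2
        ps[j - 1] = stats.f.sf(F, df1, df2)
    return ManovaResult(list(names), pillai, fs, df1s.astype(int), df2s.astype(int), ps)


def roi_table(
    scores: pd.DataFrame,
    volumes: pd.DataFrame,
    alpha: float = 0.05,
    holm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit one model per dimension; return tidy coefficient and effect-size tables.

    ``scores``: participants x dimensions; ``volumes``: participants x ROIs
    (cm³), index-aligned. The coefficient table mirrors the per-dimension
    beta / SE / t / P layout with a model-fit footer row per dimension.
    """
    vols = volumes.loc[scores.index]
    rows = []
    eff = []
    for dim in scores.columns:
        fit = fit_roi_model(scores[dim].to_numpy(), vols.to_numpy(),
                            list(vols.columns), alpha=alpha, holm=holm)
        rows.append({"dimension": dim, "term": "(Intercept)", "beta": fit.beta[0],
                     "se": fit.se[0], "t": fit.t[0], "p": fit.p[0]})
        for i, roi in enumerate(fit.predictors, start=1):
            rows.append({"dimension": dim, "term": roi, "beta": fit.beta[i],
                         "se": fit.se[i], "t": fit.t[i], "p": fit.p[i]})
        rows.append({"dimension": dim, "term": "model",
                     "beta": np.nan, "se": np.nan, "t": fit.f_stat, "p": fit.model_p,
                     "r2": fit.r2, "df1": fit.df1, "df2": fit.df2})
        for i, roi in enumerate(vols.columns):
            es = cohens_f2(scores[dim].to_numpy(), vols.to_numpy(), i)
            eff.append({"dimension": dim, "roi": roi, "f2": es.f2, "label": es.label})
    return pd.DataFrame(rows), pd.DataFrame(eff)
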