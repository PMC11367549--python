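"""Longitudinal log2-ratio mixed-effects engine.

Both serum analytes and transcripts are analysed the same way: the response
is each subject's log2 ratio to their own baseline at every post-baseline
week; fixed effects are the week x arm cell means (plus the centred baseline
value as a covariate and optional between-subject factors such as responder
status); a subject-level random intercept absorbs repeated-measures
correlation.

Fitting uses REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.
When the random-intercept variance is estimated at (numerically) zero, or
when each subject contributes a single post-baseline observation so the
variance component is unidentifiable, the fit falls back to ordinary least
squares — in the one-visit case the model is then exactly a per-week ANCOVA.

Wald tests use a between-within degrees-of-freedom approximation:
between-subject contrasts (arm differences, responder effects) are tested on
``n_subjects - p_between`` df, within-subject cell means on
``n_obs - n_subjects - p_within`` df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["RatioModelFit", "fit_ratio_model"]


@dataclass
class RatioModelFit:
    """Fixed-effect estimates from one response's longitudinal fit.

    ``cell_effects`` holds the adjusted mean log2 ratio per (arm, week);
    ``contrasts`` the between-arm difference per week (second sorted arm
    minus first); ``factor_effects`` any extra between-subject factor
    coefficients. All tables carry estimate, se, df, p columns.
    """

    cell_effects: pd.DataFrame
    contrasts: pd.DataFrame
    factor_effects: pd.DataFrame
    method: str  # "mixedlm" or "ols"
    re_var: float


def _design(df: pd.DataFrame, weeks: List[int], arms: List[str],
            extra_factors: List[str]) -> tuple[np.ndarray, List[str]]:
    """Cell-mean design: one column per (week, arm) cell, centred baseline
    covariate, treatment-coded extra factors (first level reference)."""
    cols, names = [], []
    for w in weeks:
        for a in arms:
            cols.append(((df["week"] == w) & (df["arm"] == a)).to_numpy(float))
            names.append(f"cell[w{w}:{a}]")
    cols.append(df["baseline_c"].to_numpy(float))
    names.append("baseline_c")
    for f in extra_factors:
        levels = sorted(df[f].unique())
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} has a single level; contrast undefined")
        for lev in levels[1:]:
            cols.append((df[f] == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
    return np.column_stack(cols), names


def fit_ratio_model(
    df: pd.DataFrame,
    extra_factors: Optional[List[str]] = None,
) -> RatioModelFit:
    """Fit the longitudinal log2-ratio model for a single response.

    ``df`` needs columns ``subject_id, arm, week, ratio, baseline`` with one
    row per subject x post-baseline week. Raises ``ValueError`` when a
    (week, arm) design cell is empty or the design is rank deficient.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    extra_factors = list(extra_factors or [])
    df = df.copy()
    required = {"subject_id", "arm", "week", "ratio", "baseline"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df["ratio"].isna().any():
        df = df.dropna(subset=["ratio"])
    weeks = sorted(df["week"].unique())
    arms = sorted(df["arm"].unique())
    for w in weeks:
        for a in arms:
            n_cell = ((df["week"] == w) & (df["arm"] == a)).sum()
            if n_cell < 2:
                raise ValueError(f"design cell week={w}, arm={a} has {n_cell} < 2 observations")
    df["baseline_c"] = df["baseline"] - df["baseline"].mean()

    X, names = _design(df, weeks, arms, extra_factors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear factors)")
    y = df["ratio"].to_numpy(float)
    groups = df["subject_id"].to_numpy()
    n_obs = len(df)
    n_subj = df["subject_id"].nunique()
    n_extra = sum(len(sorted(df[f].unique())) - 1 for f in extra_factors)
    p_between = len(arms) + 1 + n_extra  # arm means + baseline covariate + factors
    df_between = max(n_subj - p_between, 1)
    df_within = max(n_obs - n_subj - (X.shape[1] - p_between), 1)

    max_per_subject = df.groupby("subject_id").size().max()
    method = "mixedlm"
    re_var = 0.0
    if max_per_subject <= 1:
        method = "ols"
    if method == "mixedlm":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = MixedLM(y, X, groups=groups).fit(reml=True)
                re_var = float(np.asarray(fit.cov_re).ravel()[0])
            except Exception as exc:  # singular fits, convergence failures
                logger.warning("mixed model failed (%s); falling back to OLS", exc)
                method = "ols"
        if method == "mixedlm" and (re_var < 1e-8 or not np.isfinite(re_var)):
            logger.warning("random-intercept variance ~ 0; falling back to OLS")
            method = "ols"
    if method == "mixedlm":
        beta = np.asarray(fit.fe_params, float)
        cov = np.asarray(fit.cov_params())[: len(beta), : len(beta)]
    else:
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n_obs - X.shape[1]
        if dof < 1:
            raise ValueError("not enough observations for OLS fall-back")
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        re_var = 0.0
        df_within = df_between = dof  # classical ANCOVA df

    def wald(L: np.ndarray, dof: float):
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        if se == 0:
            return est, se, dof, 1.0 if est == 0 else 0.0
        t = est / se
        return est, se, dof, float(2.0 * sps.t.sf(abs(t), dof))

    idx = {name: i for i, name in enumerate(names)}
    cell_rows, contrast_rows, factor_rows = [], [], []
    for w in weeks:
        for a in arms:
            L = np.zeros(len(names))
            L[idx[f"cell[w{w}:{a}]"]] = 1.0
            est, se, dof, p = wald(L, df_within)
            cell_rows.append((a, w, est, se, dof, p))
        if len(arms) == 2:
            L = np.zeros(len(names))
            L[idx[f"cell[w{w}:{arms[1]}]"]] = 1.0
            L[idx[f"cell[w{w}:{arms[0]}]"]] = -1.0
            est, se, dof, p = wald(L, df_between)
            contrast_rows.append((f"{arms[1]}-{arms[0]}", w, est, se, dof, p))
    for f in extra_factors:
        levels = sorted(df[f].unique())
        for lev in levels[1:]:
            L = np.zeros(len(names))
            L[idx[f"{f}[{lev}]"]] = 1.0
            est, se, dof, p = wald(L, df_between)
            factor_rows.append((f, str(lev), est, se, dof, p))

    cols = ["estimate", "se", "df", "p"]
    return RatioModelFit(
        cell_effects=pd.DataFrame(cell_rows, columns=["arm", "week", *cols]),
        contrasts=pd.DataFrame(contrast_rows, columns=["contrast", "week", *cols]),
        factor_effects=pd.DataFrame(factor_rows, columns=["factor", "level", *cols]),
        method=method,
        re_var=re_var,
    )
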