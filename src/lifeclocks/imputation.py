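"""Multiple imputation by chained equations with predictive mean matching,
and Rubin's-rules pooling.

Continuous fields: Bayesian linear regression with predictive mean matching
(imputed values are always observed donor values).  Binary fields: logistic
regression draws.  Categorical fields: multinomial regression draws.  The
predictor matrix defaults to every other analysis variable, including the
study outcomes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, softmax


def _is_binary(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return col.dtype == bool or str(col.dtype) == "boolean" or (len(vals) <= 2 and set(vals) <= {0, 1, 0.0, 1.0, True, False})


def _encode_predictors(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """Numeric design matrix from all columns except the target."""
    parts = [np.ones(len(df))]
    for c in df.columns:
        if c == exclude:
            continue
        col = df[c]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            dummies = pd.get_dummies(col, drop_first=True)
            for d in dummies.columns:
                parts.append(dummies[d].astype(float).to_numpy())
        else:
            parts.append(col.astype(float).to_numpy())
    X = np.column_stack(parts)
    # drop constant / duplicate columns to keep the design full rank
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) > 0:
            keep.append(j)
    X = X[:, keep]
    q, r = np.linalg.qr(X)
    indep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r).max())
    return X[:, indep]


def _bayes_ols_draw(X, y, rng):
    """Posterior-style draw of (beta, sigma) under the flat-prior normal model."""
    n, k = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ X.T @ y
    resid = y - X @ beta_hat
    dof = max(n - k, 1)
    sigma2 = (resid @ resid) / rng.chisquare(dof)
    L = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(k))
    beta_star = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(k))
    return beta_hat, beta_star


def _pmm_column(X, y_obs_mask, y, k_donors, rng):
    """Predictive-mean-matching draw for the missing entries of one column."""
    obs, mis = y_obs_mask, ~y_obs_mask
    beta_hat, beta_star = _bayes_ols_draw(X[obs], y[obs], rng)
    pred_obs = X[obs] @ beta_hat
    pred_mis = X[mis] @ beta_star
    donors_y = y[obs]
    k = min(k_donors, len(donors_y))
    d = np.abs(pred_mis[:, None] - pred_obs[None, :])
    nearest = np.argpartition(d, k - 1, axis=1)[:, :k]
    pick = nearest[np.arange(len(pred_mis)), rng.integers(0, k, size=len(pred_mis))]
    return donors_y[pick]


def _logistic_column(X, y_obs_mask, y, rng):
    import statsmodels.api as sm

    obs, mis = y_obs_mask, ~y_obs_mask
    yo = y[obs].astype(float)
    try:
        res = sm.Logit(yo, X[obs]).fit(disp=0, maxiter=100)
        beta = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        beta_star = rng.multivariate_normal(beta, cov, method="svd")
    except Exception:
        # fall back to an observed-frequency draw when the fit is unstable
        p = yo.mean()
        return rng.random(int(mis.sum())) < p
    p = expit(X[mis] @ beta_star)
    return rng.random(len(p)) < p


def _multinomial_column(X, y_obs_mask, y_codes, n_cat, rng):
    import statsmodels.api as sm

    obs, mis = y_obs_mask, ~y_obs_mask
    try:
        res = sm.MNLogit(y_codes[obs], X[obs]).fit(disp=0, maxiter=100, method="newton")
        params = np.asarray(res.params)  # k x (n_cat-1)
        cov = np.asarray(res.cov_params())
        flat = rng.multivariate_normal(params.ravel(order="F"), cov, method="svd")
        params_star = flat.reshape(params.shape, order="F")
        eta = np.column_stack([np.zeros(int(mis.sum())), X[mis] @ params_star])
        p = softmax(eta, axis=1)
    except Exception:
        freq = np.bincount(y_codes[obs], minlength=n_cat).astype(float)
        p = np.tile(freq / freq.sum(), (int(mis.sum()), 1))
    cum = p.cumsum(axis=1)
    u = rng.random(len(p))[:, None]
    return (u > cum[:, :-1]).sum(axis=1)


def impute_pmm(
    table: pd.DataFrame,
    m: int = 5,
    iterations: int = 10,
    k_donors: int = 5,
    seed: int = 0,
    predictors: list[str] | None = None,
) -> list[pd.DataFrame]:
    """Chained-equations multiple imputation; returns ``m`` completed tables.

    Columns are visited in ascending order of missingness each iteration.
    Identifier-like (object, non-categorical) columns are carried through
    untouched.  A column with no observed values is an error.
    """
    if m < 2:
        raise ValueError(f"need m >= 2 imputations, got {m}")
    work_cols = predictors if predictors is not None else [
        c for c in table.columns if not (table[c].dtype == object and not table[c].isna().any())
    ]
    base = table[work_cols]
    miss_frac = base.isna().mean()
    targets = list(miss_frac[miss_frac > 0].sort_values().index)
    if not targets:
        return [table.copy() for _ in range(m)]
    for c in targets:
        if base[c].notna().sum() == 0:
            raise ValueError(f"column {c!r} has no observed values")

    completed = []
    for chain, ss in enumerate(np.random.SeedSequence(seed).spawn(m)):
        rng = np.random.default_rng(ss)
        filled = base.copy()
        for c in targets:  # initialize from observed draws
            mis = filled[c].isna()
            obs_vals = filled.loc[~mis, c].to_numpy()
            filled.loc[mis, c] = rng.choice(obs_vals, size=int(mis.sum()))

        for _ in range(iterations):
            for c in targets:
                mis = base[c].isna().to_numpy()
                obs = ~mis
                X = _encode_predictors(filled, exclude=c)
                col = base[c]
                if isinstance(col.dtype, pd.CategoricalDtype) or (col.dtype == object and not _is_binary(col)):
                    cats = pd.Categorical(filled[c])
                    codes = cats.codes.copy()
                    new = _multinomial_column(X, obs, codes, len(cats.categories), rng)
                    vals = pd.Categorical.from_codes(new, cats.categories)
                    filled[c] = filled[c].astype(cats.dtype)
                    filled.loc[mis, c] = vals
                elif _is_binary(col):
                    new = _logistic_column(X, obs, filled[c].astype(float).to_numpy(), rng)
                    filled.loc[mis, c] = pd.array(new, dtype=filled[c].dtype if str(filled[c].dtype) == "boolean" else None)
                else:
                    y = filled[c].astype(float).to_numpy()
                    filled.loc[mis, c] = _pmm_column(X, obs, y, k_donors, rng)
        out = table.copy()
        for c in work_cols:
            out[c] = filled[c]
        completed.append(out)
    return completed


@dataclass
class PooledEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    df: float
    within_var: float
    between_var: float
    total_var: float
    m: int


def pool_rubin(estimates, variances, complete_df: float | None = None) -> PooledEstimate:
    """Rubin's-rules pooling of per-imputation estimates and variances.

    Total variance = mean within-imputation variance + (1 + 1/m) x
    between-imputation variance; degrees of freedom use the Barnard-Rubin
    small-sample adjustment when a complete-data df is supplied, otherwise
    the classical large-sample formula.
    """
    q = np.asarray(estimates, float)
    u = np.asarray(variances, float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be 1-d arrays of equal length")
    m = len(q)
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    qbar = q.mean()
    ubar = u.mean()
    b = q.var(ddof=1)
    t = ubar + (1.0 + 1.0 / m) * b
    if b == 0:
        df = np.inf
    else:
        r = (1.0 + 1.0 / m) * b / ubar
        df_old = (m - 1) * (1.0 + 1.0 / r) ** 2
        if complete_df is not None:
            lam = (1.0 + 1.0 / m) * b / t
            df_obs = (complete_df + 1.0) / (complete_df + 3.0) * complete_df * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    from scipy import stats

    crit = stats.t.ppf(0.975, df) if np.isfinite(df) else 1.959963984540054
    se = float(np.sqrt(t))
    return PooledEstimate(float(qbar), se, float(qbar - crit * se), float(qbar + crit * se),
                         float(df), float(ubar), float(b), float(t), m)
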