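"""Proteome-wide analyses: differential abundance, cross-timepoint
consistency, elastic-net Cox longevity modelling and decile biomarkers.

Proteins are log10-transformed and z-scored before modelling.  Differential
abundance against a continuous score uses vectorized OLS; against mortality
it uses per-protein Cox models.  The longevity model is an elastic-net
penalized Cox regression (mixing parameter fixed, penalty chosen by
cross-validated concordance).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .clocks import ProteinMatrix
from .exposures import adjust_bh
from .survival import fit_cox


def _standardized_log10(matrix: ProteinMatrix, ids: pd.Index, subset: str | None = None):
    """log10 + z-score; returns (values, protein ids, skipped-constant ids)."""
    cols = list(matrix.abundance.columns)
    if subset is not None:
        keep = set(matrix.annotations.index[matrix.annotations["organ"] == subset])
        cols = [c for c in cols if c in keep]
    X = np.log10(matrix.abundance.loc[ids, cols].to_numpy(float))
    sd = X.std(axis=0, ddof=1)
    skipped = [c for c, s in zip(cols, sd) if s == 0]
    ok = sd > 0
    Z = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    return Z, [c for c, o in zip(cols, ok) if o], skipped


def differential_abundance(
    matrix: ProteinMatrix,
    cohort: pd.DataFrame,
    outcome: str = "pfs_linear",
    score: pd.Series | None = None,
    subset: str | None = None,
    adjusted: bool = True,
) -> pd.DataFrame:
    """Per-protein association with a score (linear) or mortality (Cox).

    ``outcome='pfs_linear'`` regresses each standardized protein on the
    supplied score (plus sex and age when ``adjusted``); ``'mortality_cox'``
    fits one Cox model per protein.  BH adjustment is applied across all
    tested proteins; zero-variance proteins are skipped with a note.
    """
    ids = pd.Index(cohort["participant_id"])
    Z, proteins, skipped = _standardized_log10(matrix, ids, subset)
    if skipped:
        warnings.warn(f"skipped zero-variance proteins: {skipped[:5]}{'...' if len(skipped) > 5 else ''}")
    n = len(ids)
    male = (cohort["sex"] == "male").astype(float).to_numpy()
    age = cohort["chron_age"].to_numpy(float)

    if outcome == "pfs_linear":
        if score is None:
            raise ValueError("pfs_linear needs a score series")
        s = score.reindex(ids).to_numpy(float)
        cols = [np.ones(n), s] + ([male, age] if adjusted else [])
        X = np.column_stack(cols)
        XtX_inv = np.linalg.inv(X.T @ X)
        B = XtX_inv @ X.T @ Z  # coefficients x proteins
        resid = Z - X @ B
        dof = n - X.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        beta = B[1]
        tstat = beta / se
        p = 2 * stats.t.sf(np.abs(tstat), dof)
        out = pd.DataFrame({"protein_id": proteins, "beta": beta, "se": se, "p": p})
    elif outcome == "mortality_cox":
        times = cohort["followup_years"].to_numpy(float)
        events = cohort["died"].to_numpy(bool)
        rows = []
        for j, pid in enumerate(proteins):
            cols = {"protein": Z[:, j]}
            if adjusted:
                cols.update({"male": male, "chron_age": age})
            fit = fit_cox(times, events, pd.DataFrame(cols))[0]
            rows.append({"protein_id": pid, "beta": fit.coef, "se": fit.se, "p": fit.p})
        out = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    out["adj_p"] = adjust_bh(out["p"].to_numpy())
    out["significant"] = out["adj_p"] < 0.05
    return out


def cross_timepoint_consistency(results: list[pd.DataFrame], k: int = 2, alpha: float = 0.05) -> pd.DataFrame:
    """Proteins BH-significant in at least ``k`` of the per-timepoint results."""
    if k > len(results):
        raise ValueError(f"k={k} exceeds the {len(results)} result sets provided")
    counts: dict[str, int] = {}
    for res in results:
        for pid in res.loc[res["adj_p"] < alpha, "protein_id"]:
            counts[pid] = counts.get(pid, 0) + 1
    out = pd.DataFrame({"protein_id": list(counts), "n_timepoints": list(counts.values())})
    return out.loc[out["n_timepoints"] >= k].sort_values(
        ["n_timepoints", "protein_id"], ascending=[False, True]
    ).reset_index(drop=True)


@dataclass
class ElasticNetCoxResult:
    selected: list[str]
    coefficients: pd.Series
    alpha_mixing: float
    lambda_chosen: float
    lambda_path: np.ndarray
    cv_cindex: float
    cv_cindex_path: np.ndarray
    fold_assignments: np.ndarray
    seed: int


def elastic_net_cox(
    matrix: ProteinMatrix,
    cohort: pd.DataFrame,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
) -> ElasticNetCoxResult:
    """Elastic-net penalized Cox model with CV-chosen penalty.

    The mixing parameter is fixed (0.5 by default); the penalty path is 100
    log-spaced values; folds are stratified by event status; the penalty
    maximizing the mean cross-validated concordance index is selected, and
    proteins with nonzero coefficients at that penalty are reported.
    """
    ids = pd.Index(cohort["participant_id"])
    events = cohort["died"].to_numpy(bool)
    times = cohort["followup_years"].to_numpy(float)
    if events.sum() < n_folds:
        raise ValueError("need at least as many events as folds")
    Z, proteins, _ = _standardized_log10(matrix, ids)
    y = Surv.from_arrays(event=events, time=times)

    path_fit = CoxnetSurvivalAnalysis(l1_ratio=alpha, n_alphas=n_lambdas, alpha_min_ratio=0.01, normalize=False)
    path_fit.fit(Z, y)
    lambdas = np.asarray(path_fit.alphas_)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.zeros(len(ids), int)
    cindex = np.full((n_folds, len(lambdas)), np.nan)
    for f, (tr, te) in enumerate(skf.split(Z, events.astype(int))):
        folds[te] = f
        est = CoxnetSurvivalAnalysis(l1_ratio=alpha, alphas=lambdas, normalize=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            est.fit(Z[tr], y[tr])
        for i, lam in enumerate(lambdas):
            try:
                risk = est.predict(Z[te], alpha=lam)
            except ValueError:
                continue
            cindex[f, i] = concordance_index_censored(events[te], times[te], risk)[0]
    mean_c = np.nanmean(cindex, axis=0)
    best = int(np.nanargmax(mean_c))
    coefs = pd.Series(path_fit.coef_[:, best], index=proteins)
    selected = list(coefs.index[coefs != 0])
    return ElasticNetCoxResult(
        selected=selected,
        coefficients=coefs,
        alpha_mixing=alpha,
        lambda_chosen=float(lambdas[best]),
        lambda_path=lambdas,
        cv_cindex=float(mean_c[best]),
        cv_cindex_path=mean_c,
        fold_assignments=folds,
        seed=seed,
    )


def nested_cv_cindex(
    matrix: ProteinMatrix,
    cohort: pd.DataFrame,
    alpha: float = 0.5,
    outer_folds: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 100,
) -> float:
    """Honest concordance estimate for the whole penalty-selection procedure.

    The concordance at the CV-maximizing penalty is optimistically biased
    (the maximum of noisy curves), so model *performance* is estimated by
    nested cross-validation: each outer training set chooses its own penalty
    by inner CV, and concordance is scored on the held-out outer fold.
    """
    ids = pd.Index(cohort["participant_id"])
    events = cohort["died"].to_numpy(bool)
    times = cohort["followup_years"].to_numpy(float)
    Z, _, _ = _standardized_log10(matrix, ids)
    y = Surv.from_arrays(event=events, time=times)
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in outer.split(Z, events.astype(int)):
        path = CoxnetSurvivalAnalysis(l1_ratio=alpha, n_alphas=n_lambdas, alpha_min_ratio=0.01, normalize=False)
        path.fit(Z[tr], y[tr])
        lams = np.asarray(path.alphas_)
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed + 1)
        cmat = np.full((inner_folds, len(lams)), np.nan)
        for f, (itr, ite) in enumerate(inner.split(Z[tr], events[tr].astype(int))):
            est = CoxnetSurvivalAnalysis(l1_ratio=alpha, alphas=lams, normalize=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                est.fit(Z[tr][itr], y[tr][itr])
            for i, lam in enumerate(lams):
                risk = est.predict(Z[tr][ite], alpha=lam)
                cmat[f, i] = concordance_index_censored(events[tr][ite], times[tr][ite], risk)[0]
        best = int(np.nanargmax(np.nanmean(cmat, axis=0)))
        risk = path.predict(Z[te], alpha=lams[best])
        scores.append(concordance_index_censored(events[te], times[te], risk)[0])
    return float(np.mean(scores))


def decile_biomarker_risk(
    matrix: ProteinMatrix,
    protein_id: str,
    cohort: pd.DataFrame,
    tail: str = "bottom",
    comparator: pd.Series | None = None,
):
    """Odds of death for the tail decile of one protein's abundance.

    Flags the bottom (or top) decile, fits ``death ~ flag + sex + age`` by
    logistic regression, and optionally reports a comparator binary
    covariate (e.g. >= 15 pack-years vs never smoking) side by side.
    """
    import statsmodels.api as sm

    from .pfs import OddsRatioFit

    if tail not in {"bottom", "top"}:
        raise ValueError(f"tail must be 'bottom' or 'top', got {tail!r}")
    ids = pd.Index(cohort["participant_id"])
    x = matrix.abundance.loc[ids, protein_id].to_numpy(float)
    q = np.quantile(x, 0.1 if tail == "bottom" else 0.9)
    flag = (x <= q) if tail == "bottom" else (x >= q)
    if flag.mean() > 0.2:
        raise ValueError("degenerate decile: ties span more than 20% of samples")
    male = (cohort["sex"] == "male").astype(float).to_numpy()
    age = cohort["chron_age"].to_numpy(float)
    y = cohort["died"].astype(int).to_numpy()
    X = pd.DataFrame({"const": 1.0, "tail_decile": flag.astype(float), "male": male, "chron_age": age})
    res = sm.Logit(y, X).fit(disp=0)
    out = {
        "decile": OddsRatioFit.from_fit(f"{tail}_decile_{protein_id}", "death", res.params["tail_decile"],
                                        res.bse["tail_decile"], res.pvalues["tail_decile"], int(res.nobs))
    }
    if comparator is not None:
        comp = comparator.reindex(ids)
        keep = comp.notna().to_numpy()
        Xc = pd.DataFrame(
            {"const": 1.0, "comparator": comp[keep].astype(float).to_numpy(), "male": male[keep], "chron_age": age[keep]}
        )
        resc = sm.Logit(y[keep], Xc).fit(disp=0)
        out["comparator"] = OddsRatioFit.from_fit("comparator", "death", resc.params["comparator"],
                                                  resc.bse["comparator"], resc.pvalues["comparator"], int(resc.nobs))
    return out


def exposure_profile_of_protein(
    matrix: ProteinMatrix,
    protein_id: str,
    cohort: pd.DataFrame,
    exposures=("ses_high", "education_high", "pack_years", "activity_sustained", "adversity_periods",
               "adolescent_overweight", "alcohol_units_mean", "birthweight_kg"),
) -> pd.DataFrame:
    """Multivariable exposure profile of one protein (standardized outcome)."""
    import statsmodels.api as sm

    from .exposures import _design

    ids = pd.Index(cohort["participant_id"])
    x = np.log10(matrix.abundance.loc[ids, protein_id].to_numpy(float))
    if x.std(ddof=1) == 0:
        raise ValueError(f"protein {protein_id} has zero variance")
    z = (x - x.mean()) / x.std(ddof=1)
    X = _design(cohort, list(exposures) + ["sex", "chron_age"])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("aliased exposures in profile model")
    res = sm.OLS(z, X).fit()
    return pd.DataFrame(
        {
            "term": list(exposures),
            "beta": [float(res.params[e]) for e in exposures],
            "se": [float(res.bse[e]) for e in exposures],
            "p": [float(res.pvalues[e]) for e in exposures],
        }
    )
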