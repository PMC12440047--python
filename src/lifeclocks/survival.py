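"""Kaplan-Meier curves and Cox models linking extreme ageing to mortality."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .clocks import AgeGapProfile


@dataclass
class SurvivalFit:
    """One fitted Cox term: log-hazard, HR with Wald CI, p, event counts."""

    term: str
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    ties: str

    @classmethod
    def from_row(cls, term, coef, se, p, n, n_events, ties):
        return cls(
            term=term,
            coef=float(coef),
            se=float(se),
            hr=float(np.exp(coef)),
            ci_low=float(np.exp(coef - 1.959963984540054 * se)),
            ci_high=float(np.exp(coef + 1.959963984540054 * se)),
            p=float(p),
            n=int(n),
            n_events=int(n_events),
            ties=ties,
        )


def kaplan_meier(times, events, groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimates, optionally per group.

    Returns ``{label: DataFrame(time, survival, at_risk)}`` with one row per
    distinct event/censoring time; right-censoring is honoured.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    labels = np.asarray(["all"] * len(times)) if groups is None else np.asarray(groups)
    out = {}
    for label in pd.unique(labels):
        m = labels == label
        kmf = KaplanMeierFitter().fit(times[m], events[m])
        tab = kmf.event_table
        out[str(label)] = pd.DataFrame(
            {
                "time": tab.index.to_numpy(float),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tab["at_risk"].to_numpy(int),
            }
        )
    return out


def _breslow_newton(times, events, X, max_iter=100, tol=1e-10):
    """Newton-Raphson maximization of the Breslow-ties partial likelihood."""
    n, k = X.shape
    order = np.argsort(-times)  # descending: risk set = prefix
    t, d, Xs = times[order], events[order], X[order]
    beta = np.zeros(k)
    for _ in range(max_iter):
        if np.any(np.abs(beta) > 50):
            raise ConvergenceError("monotone partial likelihood (separation?) in Breslow fit")
        eta = Xs @ beta
        w = np.exp(eta)
        cum_w = np.cumsum(w)
        cum_wx = np.cumsum(w[:, None] * Xs, axis=0)
        cum_wxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
        # risk set for event at time t_i: all with time >= t_i -> largest
        # prefix index with the same time value
        idx = np.searchsorted(-t, -t, side="right") - 1
        grad = np.zeros(k)
        hess = np.zeros((k, k))
        ev = np.where(d)[0]
        for i in ev:
            j = idx[i]
            s0 = cum_w[j]
            s1 = cum_wx[j]
            s2 = cum_wxx[j]
            mu = s1 / s0
            grad += Xs[i] - mu
            hess += s2 / s0 - np.outer(mu, mu)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise ConvergenceError("Breslow Newton did not converge")
    if np.any(np.abs(beta) > 50):
        raise ConvergenceError("monotone partial likelihood (separation?) in Breslow fit")
    cov = np.linalg.inv(hess)
    return beta, np.sqrt(np.diag(cov))


def fit_cox(times, events, covariates: pd.DataFrame, ties: str = "efron") -> list[SurvivalFit]:
    """Cox proportional-hazards fit returning one :class:`SurvivalFit` per term.

    Efron tie handling (the default, via lifelines) suits month-resolution
    death dates; a Breslow Newton solver is provided for comparison.
    Complete separation / monotone likelihood raises rather than returning a
    silent estimate.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if events.sum() < 1:
        raise ValueError("need at least one event to fit a Cox model")
    X = covariates.astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("covariates are collinear (rank-deficient design)")
    n, n_events = len(times), int(events.sum())
    if ties == "efron":
        df = X.copy()
        df["_time"], df["_event"] = times, events.astype(int)
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # damp the Newton step on retry: with heavy month-resolution ties
            # the undamped step can overshoot
            for options in (None, {"step_size": 0.5}, {"step_size": 0.1}):
                try:
                    cph.fit(df, duration_col="_time", event_col="_event", fit_options=options)
                    break
                except ConvergenceError:
                    if options == {"step_size": 0.1}:
                        raise
        s = cph.summary
        return [
            SurvivalFit.from_row(term, s.loc[term, "coef"], s.loc[term, "se(coef)"], s.loc[term, "p"], n, n_events, ties)
            for term in X.columns
        ]
    if ties == "breslow":
        beta, se = _breslow_newton(times, events, X.to_numpy())
        from scipy import stats as sps

        return [
            SurvivalFit.from_row(term, b, s, 2 * sps.norm.sf(abs(b / s)), n, n_events, ties)
            for term, b, s in zip(X.columns, beta, se)
        ]
    raise ValueError(f"unknown ties method {ties!r}")


def _adjusters(cohort: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {"male": (cohort["sex"] == "male").astype(float).to_numpy(), "chron_age": cohort["chron_age"].to_numpy(float)},
        index=cohort["participant_id"],
    )


def extreme_ager_hazard(profile: AgeGapProfile, cohort: pd.DataFrame, ties: str = "efron") -> pd.DataFrame:
    """Mortality models for extreme ageing, adjusted for sex and age.

    One extreme-vs-rest Cox model per clock, plus one model with
    extreme-organ-count categories (1, 2, 3, >=4 vs 0).  Returns a tidy
    table of hazard ratios; empty count categories are dropped with a
    warning.
    """
    if profile.flags is None:
        raise ValueError("run flag_extreme_agers first")
    adj = _adjusters(cohort)
    times = cohort["followup_years"].to_numpy(float)
    events = cohort["died"].to_numpy(bool)
    rows = []
    for clock in profile.clocks:
        X = adj.copy()
        X.insert(0, "extreme", profile.flags[clock].reindex(adj.index).astype(float))
        fit = fit_cox(times, events, X, ties=ties)[0]
        rows.append({"model": clock, "term": "extreme", **fit.__dict__})

    if profile.n_extreme is None:
        from .profiles import count_extreme_organs

        count_extreme_organs(profile)
    counts = profile.n_extreme.reindex(adj.index).clip(upper=4)
    X = adj.copy()
    levels = []
    for k in (1, 2, 3, 4):
        name = f"extreme_{k}" if k < 4 else "extreme_4plus"
        col = (counts == k).astype(float)
        if col.sum() == 0:
            warnings.warn(f"no participants with {k} extreme organs; category dropped")
            continue
        X.insert(len(levels), name, col)
        levels.append(name)
    for term, fit in zip(levels, fit_cox(times, events, X, ties=ties)):
        rows.append({"model": "organ_count", "term": term, **fit.__dict__})
    out = pd.DataFrame(rows)
    return out.drop(columns=["term"]).rename(columns={"model": "model"}).assign(term=out["term"])[
        ["model", "term", "coef", "se", "hr", "ci_low", "ci_high", "p", "n", "n_events", "ties"]
    ]
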