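"""Life-course exposure -> age-gap association models.

Primary models regress a clock's age gap on one exposure (expressed on its
reporting unit) adjusted for sex, chronological age and childhood
socio-economic status, with Benjamini-Hochberg correction across the eight
clocks per exposure family.  Sensitivity scenarios reproduce the published
follow-up analyses (adult-overweight adjustment, education subgroups,
activity dose-response, smoking cessation, per-timepoint and dose-binned
alcohol models) and the adversity-component multivariable model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .clocks import AgeGapProfile
from .config import ADVERSITY_COMPONENTS, CLOCKS, TIMEPOINT_AGES, UNIT_SCALES

DEFAULT_COVARIATES = ("sex", "chron_age", "ses_high")


@dataclass
class AssociationResult:
    """One exposure-clock regression coefficient in years per unit."""

    exposure: str
    clock: str
    beta: float
    se: float
    p: float
    n: int
    covariates: tuple[str, ...]
    adj_p: float | None = None
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)

    def __post_init__(self):
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - 1.959963984540054 * self.se
            self.ci_high = self.beta + 1.959963984540054 * self.se


def _as_numeric(col: pd.Series) -> np.ndarray:
    if col.dtype == bool or str(col.dtype) == "boolean":
        return col.astype(float).to_numpy()
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        if set(col.unique()) <= {"male", "female"}:
            return (col == "male").astype(float).to_numpy()
        raise ValueError(f"cannot coerce column {col.name!r} to numeric")
    return pd.to_numeric(col).to_numpy(float)


def _design(cohort: pd.DataFrame, columns) -> pd.DataFrame:
    X = pd.DataFrame({c: _as_numeric(cohort[c]) for c in columns}, index=cohort.index)
    return sm.add_constant(X, has_constant="add")


def fit_exposure_association(
    cohort: pd.DataFrame,
    profile: AgeGapProfile,
    exposure: str,
    clock: str,
    covariates=DEFAULT_COVARIATES,
    extra_covariates=(),
) -> AssociationResult:
    """OLS of one clock's age gap on one exposure, on its reporting unit.

    When childhood SES is itself the exposure it is dropped from the
    covariate list (it would otherwise self-adjust).
    """
    covs = [c for c in covariates if not (exposure in {"ses_high", "childhood_ses"} and c == "ses_high")]
    covs += [c for c in extra_covariates if c not in covs and c != exposure]
    y = profile.age_gap[clock].reindex(cohort["participant_id"]).to_numpy(float)
    x = _as_numeric(cohort[exposure]) / UNIT_SCALES.get(exposure, 1.0)
    X = _design(cohort, covs)
    X.insert(1, exposure, x)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear covariates in exposure model")
    res = sm.OLS(y, X).fit()
    return AssociationResult(
        exposure=exposure,
        clock=clock,
        beta=float(res.params[exposure]),
        se=float(res.bse[exposure]),
        p=float(res.pvalues[exposure]),
        n=int(res.nobs),
        covariates=tuple(covs),
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one family."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def family_associations(
    cohort: pd.DataFrame,
    profile: AgeGapProfile,
    exposure: str,
    clocks=None,
    covariates=DEFAULT_COVARIATES,
    extra_covariates=(),
) -> list[AssociationResult]:
    """One exposure tested across the eight clocks, BH-adjusted as a family."""
    clocks = list(clocks) if clocks is not None else [c for c in CLOCKS if c in profile.clocks]
    results = [
        fit_exposure_association(cohort, profile, exposure, c, covariates, extra_covariates) for c in clocks
    ]
    for r, adj in zip(results, adjust_bh([r.p for r in results])):
        r.adj_p = float(adj)
    return results


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


SCENARIOS = (
    "overweight_adult_adjusted",
    "education_subgroups",
    "activity_dose",
    "smoking_cessation",
    "alcohol_timepoints",
    "alcohol_dose",
)


def fit_sensitivity_scenario(
    scenario: str,
    cohort: pd.DataFrame,
    profile: AgeGapProfile,
    clock: str | None = None,
) -> list[AssociationResult]:
    """Published sensitivity analyses as coefficient sets.

    - ``overweight_adult_adjusted``: adolescent overweight with additional
      adjustment for early-, mid- and late-adulthood overweight (Conventional).
    - ``education_subgroups``: education effect split by university degree.
    - ``activity_dose``: age gap by number of active timepoints (1-4 vs 0).
    - ``smoking_cessation``: ceased-by-43 and continued smokers vs never.
    - ``alcohol_timepoints``: brain gap on each timepoint's intake with the
      extended confounder set.
    - ``alcohol_dose``: brain gap by weekly-intake dose band vs none/low.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    out: list[AssociationResult] = []

    if scenario == "overweight_adult_adjusted":
        clock = clock or "Conventional"
        out.append(fit_exposure_association(cohort, profile, "adolescent_overweight", clock))
        for extra in (("adult_overweight_early",), ("adult_overweight_early", "adult_overweight_mid"),
                      ("adult_overweight_early", "adult_overweight_mid", "adult_overweight_late")):
            r = fit_exposure_association(cohort, profile, "adolescent_overweight", clock, extra_covariates=extra)
            r.exposure = f"adolescent_overweight|{'+'.join(e.split('_')[-1] for e in extra)}"
            out.append(r)

    elif scenario == "education_subgroups":
        clock = clock or "Conventional"
        base = cohort.copy()
        for label, mask in (
            ("education_no_degree", ~cohort["university_degree"].astype(bool)),
            ("education_with_degree", cohort["university_degree"].astype(bool) | ~cohort["education_high"].astype(bool)),
        ):
            sub = base.loc[mask.to_numpy()]
            r = fit_exposure_association(sub, profile, "education_high", clock)
            r.exposure = label
            out.append(r)

    elif scenario == "activity_dose":
        clock = clock or "Conventional"
        work = cohort.copy()
        for k in (1, 2, 3, 4):
            work[f"active_{k}"] = (cohort["active_timepoints"] == k)
        X_cols = [f"active_{k}" for k in (1, 2, 3, 4)]
        y = profile.age_gap[clock].reindex(cohort["participant_id"]).to_numpy(float)
        X = _design(work, list(DEFAULT_COVARIATES))
        for i, c in enumerate(X_cols):
            X.insert(1 + i, c, work[c].astype(float).to_numpy())
        res = sm.OLS(y, X).fit()
        for c in X_cols:
            out.append(
                AssociationResult(c, clock, float(res.params[c]), float(res.bse[c]), float(res.pvalues[c]),
                                  int(res.nobs), tuple(DEFAULT_COVARIATES))
            )

    elif scenario == "smoking_cessation":
        clock = clock or "Conventional"
        work = cohort.copy()
        work["ceased_by_43"] = cohort["smoking_status"] == "ceased_by_43"
        work["continued"] = cohort["smoking_status"] == "continued"
        y = profile.age_gap[clock].reindex(cohort["participant_id"]).to_numpy(float)
        X = _design(work, list(DEFAULT_COVARIATES))
        X.insert(1, "ceased_by_43", work["ceased_by_43"].astype(float).to_numpy())
        X.insert(2, "continued", work["continued"].astype(float).to_numpy())
        res = sm.OLS(y, X).fit()
        for c in ("ceased_by_43", "continued"):
            out.append(
                AssociationResult(c, clock, float(res.params[c]), float(res.bse[c]), float(res.pvalues[c]),
                                  int(res.nobs), tuple(DEFAULT_COVARIATES))
            )

    elif scenario == "alcohol_timepoints":
        clock = clock or "Brain"
        confounders = ("sex", "chron_age", "ses_high", "adult_ses_high", "education_high",
                       "social_support", "adult_overweight_mid", "activity_sustained")
        for age in TIMEPOINT_AGES:
            r = fit_exposure_association(cohort, profile, f"alcohol_units_{age}", clock, covariates=confounders)
            out.append(r)

    elif scenario == "alcohol_dose":
        clock = clock or "Brain"
        units = cohort["alcohol_units_mean"].to_numpy(float)
        bands = {"alcohol_7_21": (7.0, 21.0), "alcohol_21_35": (21.0, 35.0), "alcohol_over_35": (35.0, np.inf)}
        work = cohort.copy()
        for name, (lo, hi) in bands.items():
            work[name] = (units >= lo) & (units < hi)
        y = profile.age_gap[clock].reindex(cohort["participant_id"]).to_numpy(float)
        X = _design(work, list(DEFAULT_COVARIATES))
        for i, name in enumerate(bands):
            X.insert(1 + i, name, work[name].astype(float).to_numpy())
        res = sm.OLS(y, X).fit()
        for name in bands:
            out.append(
                AssociationResult(name, clock, float(res.params[name]), float(res.bse[name]),
                                  float(res.pvalues[name]), int(res.nobs), tuple(DEFAULT_COVARIATES))
            )
    return out


def adversity_component_model(
    cohort: pd.DataFrame,
    profile: AgeGapProfile,
    clock: str = "Conventional",
) -> list[AssociationResult]:
    """All adversity components entered simultaneously (plus sex/age/SES)."""
    components = [c for period in ADVERSITY_COMPONENTS.values() for c in period]
    y = profile.age_gap[clock].reindex(cohort["participant_id"]).to_numpy(float)
    X = _design(cohort, list(DEFAULT_COVARIATES))
    for i, comp in enumerate(components):
        X.insert(1 + i, comp, cohort[comp].astype(float).to_numpy())
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("adversity components are perfectly collinear (aliased)")
    res = sm.OLS(y, X).fit()
    return [
        AssociationResult(comp, clock, float(res.params[comp]), float(res.bse[comp]),
                          float(res.pvalues[comp]), int(res.nobs), tuple(DEFAULT_COVARIATES))
        for comp in components
    ]
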