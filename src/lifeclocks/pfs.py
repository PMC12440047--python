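"""Protective factor score (PFS): construction and outcome models.

The PFS counts eight favourable life-course factors: normal birthweight
(>= 2.5 kg), higher childhood socio-economic status, healthy adolescent BMI
(below the sex-specific overweight cut-off), secondary-education
qualifications, never smoking, moderate alcohol intake (7-21 units/week
inclusive), activity at two or more of four adult timepoints and adversity
in fewer than three of four life periods.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .clocks import AgeGapProfile
from .config import BMI_CUTOFF, SES_HIGH_LEVELS

FACTORS = (
    "normal_birthweight",
    "higher_ses",
    "healthy_adolescent_bmi",
    "higher_education",
    "non_smoking",
    "moderate_alcohol",
    "sustained_activity",
    "low_adversity",
)

#: PFS group cut-points: <=3 / 4 / 5 / 6 / >=7
PFS_GROUPS = ("le3", "4", "5", "6", "ge7")


@dataclass
class OddsRatioFit:
    term: str
    outcome: str
    log_or: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n: int

    @classmethod
    def from_fit(cls, term, outcome, coef, se, p, n):
        z = 1.959963984540054
        return cls(term, outcome, float(coef), float(se), float(np.exp(coef)),
                   float(np.exp(coef - z * se)), float(np.exp(coef + z * se)), float(p), int(n))


def score_protective_factors(cohort: pd.DataFrame) -> pd.DataFrame:
    """Eight protective-factor booleans plus the PFS per participant.

    Boundary conventions: BMI at or above the cut-off counts as overweight;
    the moderate-alcohol band [7, 21] units/week is inclusive; non-smoking
    means zero lifetime pack-years.
    """
    needed = ["birthweight_kg", "childhood_ses", "adolescent_bmi", "education_high",
              "pack_years", "alcohol_units_mean", "active_timepoints", "adversity_periods", "sex"]
    na = [c for c in needed if cohort[c].isna().any()]
    if na:
        raise ValueError(f"cannot score PFS with missing values in {na}; impute first")
    cutoff = cohort["sex"].map(BMI_CUTOFF).astype(float)
    out = pd.DataFrame(index=pd.Index(cohort["participant_id"], name="participant_id"))
    out["normal_birthweight"] = (cohort["birthweight_kg"] >= 2.5).to_numpy()
    out["higher_ses"] = cohort["childhood_ses"].isin(SES_HIGH_LEVELS).to_numpy()
    out["healthy_adolescent_bmi"] = (cohort["adolescent_bmi"] < cutoff).to_numpy()
    out["higher_education"] = cohort["education_high"].astype(bool).to_numpy()
    out["non_smoking"] = (cohort["pack_years"] == 0).to_numpy()
    alc = cohort["alcohol_units_mean"].to_numpy(float)
    out["moderate_alcohol"] = (alc >= 7.0) & (alc <= 21.0)
    out["sustained_activity"] = (cohort["active_timepoints"] >= 2).to_numpy()
    out["low_adversity"] = (cohort["adversity_periods"] < 3).to_numpy()
    out["pfs"] = out[list(FACTORS)].sum(axis=1).astype(int)
    out["pfs_group"] = pd.Categorical(
        np.select([out["pfs"] <= 3, out["pfs"] == 4, out["pfs"] == 5, out["pfs"] == 6], PFS_GROUPS[:4], "ge7"),
        categories=PFS_GROUPS, ordered=True,
    )
    return out


def _outcome_vector(outcome: str, cohort: pd.DataFrame, profile: AgeGapProfile | None) -> pd.Series:
    ids = pd.Index(cohort["participant_id"])
    if outcome == "death":
        return pd.Series(cohort["died"].astype(int).to_numpy(), index=ids)
    if profile is None or profile.flags is None:
        raise ValueError(f"outcome {outcome!r} needs a flagged AgeGapProfile")
    if outcome == "extreme_conventional":
        return profile.flags["Conventional"].reindex(ids).astype(int)
    if outcome == "multiorgan_extreme":
        if profile.n_extreme is None:
            from .profiles import count_extreme_organs

            count_extreme_organs(profile)
        return (profile.n_extreme.reindex(ids) >= 2).astype(int)
    raise ValueError(f"unknown outcome {outcome!r}")


def _logit(y: np.ndarray, X: pd.DataFrame):
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; logistic model undefined")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as e:
        raise ValueError(f"logistic fit failed (separation or singular design): {e}")
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge (possible separation)")
    return res


def _adjusted_design(cohort: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(
        {"male": (cohort["sex"] == "male").astype(float).to_numpy(), "chron_age": cohort["chron_age"].to_numpy(float)},
        index=cohort.index,
    )
    return sm.add_constant(X, has_constant="add")


def pfs_outcome_model(
    pfs: pd.DataFrame,
    outcome: str,
    cohort: pd.DataFrame,
    profile: AgeGapProfile | None = None,
) -> dict[str, OddsRatioFit]:
    """Logistic models of an outcome on the PFS, adjusted for sex and age.

    Returns the per-unit odds ratio and the top-vs-bottom group contrast
    (>= 7 vs <= 3 protective factors).
    """
    y = _outcome_vector(outcome, cohort, profile).to_numpy()
    X = _adjusted_design(cohort)
    X.insert(1, "pfs", pfs["pfs"].reindex(cohort["participant_id"]).to_numpy(float))
    res = _logit(y, X)
    out = {"per_unit": OddsRatioFit.from_fit("pfs", outcome, res.params["pfs"], res.bse["pfs"],
                                             res.pvalues["pfs"], int(res.nobs))}

    groups = pfs["pfs_group"].reindex(cohort["participant_id"]).to_numpy()
    keep = np.isin(groups, ["le3", "ge7"])
    y2 = y[keep]
    X2 = _adjusted_design(cohort.loc[keep.nonzero()[0]].reset_index(drop=True))
    X2.insert(1, "top_group", (groups[keep] == "ge7").astype(float))
    res2 = _logit(y2, X2)
    out["top_vs_bottom"] = OddsRatioFit.from_fit("pfs_ge7_vs_le3", outcome, res2.params["top_group"],
                                                 res2.bse["top_group"], res2.pvalues["top_group"], int(res2.nobs))
    return out


def pfs_factor_decomposition(
    cohort: pd.DataFrame,
    profile: AgeGapProfile | None,
    outcome: str,
    pfs: pd.DataFrame | None = None,
) -> list[OddsRatioFit]:
    """Mutually adjusted odds ratios for all eight factors simultaneously."""
    pfs = pfs if pfs is not None else score_protective_factors(cohort)
    y = _outcome_vector(outcome, cohort, profile).to_numpy()
    X = _adjusted_design(cohort)
    F = pfs[list(FACTORS)].reindex(cohort["participant_id"]).astype(float)
    for i, f in enumerate(FACTORS):
        X.insert(1 + i, f, F[f].to_numpy())
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("protective factors are aliased (perfectly collinear)")
    res = _logit(y, X)
    return [
        OddsRatioFit.from_fit(f, outcome, res.params[f], res.bse[f], res.pvalues[f], int(res.nobs))
        for f in FACTORS
    ]
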