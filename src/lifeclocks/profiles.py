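"""Extreme-ager classification and multi-organ ageing heterogeneity."""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .clocks import AgeGapProfile
from .config import ORGAN_CLOCKS


def flag_extreme_agers(profile: AgeGapProfile, quantile: float = 0.9) -> AgeGapProfile:
    """Flag the oldest decile of each clock's age-gap distribution.

    The threshold is the type-7 (linear interpolation) empirical quantile;
    gaps >= threshold are flagged, so ties at the threshold are included.
    A degenerate (constant) gap distribution yields a warning and no flags.
    """
    if len(profile.age_gap) < 10:
        raise ValueError("need at least 10 participants to define a decile")
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    flags, thresholds = {}, {}
    for clock in profile.clocks:
        g = profile.age_gap[clock].to_numpy(float)
        if np.ptp(g) == 0.0:
            warnings.warn(f"clock {clock}: degenerate age-gap distribution; no extreme agers flagged")
            flags[clock] = np.zeros(len(g), bool)
            thresholds[clock] = np.nan
            continue
        thr = float(np.quantile(g, quantile))  # type-7
        flags[clock] = g >= thr
        thresholds[clock] = thr
    return profile.with_flags(
        pd.DataFrame(flags, index=profile.age_gap.index),
        pd.Series(thresholds, name="threshold"),
    )


def count_extreme_organs(profile: AgeGapProfile, cap: int = 4) -> tuple[pd.Series, pd.DataFrame]:
    """Per-participant extreme-organ counts and a >=k prevalence table.

    Counts run over the seven organ clocks only (the Conventional clock is
    reported separately).  The prevalence table gives the fraction of
    participants with >= 1 ... >= ``cap`` extremely aged organs.
    """
    if profile.flags is None:
        raise ValueError("run flag_extreme_agers first")
    organ_cols = [c for c in profile.flags.columns if c in ORGAN_CLOCKS]
    missing = [c for c in ORGAN_CLOCKS if c in profile.clocks and c not in organ_cols]
    if missing:
        raise ValueError(f"missing flags for organ clocks: {missing}")
    counts = profile.flags[organ_cols].sum(axis=1).astype(int)
    counts.name = "n_extreme_organs"
    profile.n_extreme = counts
    prev = pd.DataFrame(
        {"k": range(1, cap + 1), "prevalence": [(counts >= k).mean() for k in range(1, cap + 1)]}
    ).set_index("k")
    return counts, prev


def age_gap_correlations(profile: AgeGapProfile) -> pd.DataFrame:
    """Pearson correlation matrix of age gaps across clocks."""
    if len(profile.age_gap) < 3:
        raise ValueError("need at least 3 participants for correlations")
    sd = profile.age_gap.std()
    zero = list(sd.index[sd == 0])
    if zero:
        raise ValueError(f"zero-variance clocks: {zero}")
    return profile.age_gap.corr(method="pearson")


def cooccurrence_combinations(profile: AgeGapProfile, min_organs: int = 2, top: int = 5) -> pd.DataFrame:
    """Most frequent exact organ sets showing concurrent extreme ageing.

    Considers participants flagged on >= ``min_organs`` organ clocks and
    counts each exact flagged-organ combination; returns the ``top`` most
    frequent, ties broken alphabetically.
    """
    if min_organs < 2:
        raise ValueError(f"min_organs must be >= 2, got {min_organs}")
    if profile.flags is None:
        raise ValueError("run flag_extreme_agers first")
    organ_cols = [c for c in profile.flags.columns if c in ORGAN_CLOCKS]
    f = profile.flags[organ_cols]
    eligible = f.sum(axis=1) >= min_organs
    combos: dict[tuple[str, ...], int] = {}
    for _, row in f.loc[eligible].iterrows():
        key = tuple(sorted(c for c in organ_cols if row[c]))
        combos[key] = combos.get(key, 0) + 1
    out = pd.DataFrame(
        [{"organs": " + ".join(k), "n_organs": len(k), "count": v} for k, v in combos.items()]
    )
    if out.empty:
        return pd.DataFrame(columns=["organs", "n_organs", "count"])
    return out.sort_values(["count", "organs"], ascending=[False, True]).head(top).reset_index(drop=True)
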