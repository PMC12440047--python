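"""Linear proteomic ageing clocks: scaling, QC, z-scoring, age prediction.

A clock is a linear model on reference-z-scored, transformed (log10 by
default) protein abundances: ``predicted age = intercept + sum_j w_j *
(t(x_j) - mean_j) / sd_j``.  Age gaps are predicted minus chronological age;
positive gaps mean biologically older.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

VALID_ORGANS = {"brain", "heart", "lung", "liver", "kidney", "immune", "artery", "organismal", "none"}
TRANSFORMS = {"log10": np.log10, "identity": lambda x: x}


@dataclass
class ProteinMatrix:
    """Samples x proteins RFU abundances with panel annotations.

    ``annotations`` is indexed by protein id with columns ``organ`` and
    ``scaling_factor``; ``qc_flag`` marks assay-failed samples.
    """

    abundance: pd.DataFrame
    annotations: pd.DataFrame
    qc_flag: pd.Series

    def __post_init__(self):
        self.qc_flag = self.qc_flag.reindex(self.abundance.index).fillna(False).astype(bool)

    def validate(self) -> None:
        if (self.abundance.to_numpy() <= 0).any():
            raise ValueError("abundances must be strictly positive RFU")
        missing = self.abundance.columns.difference(self.annotations.index)
        if len(missing):
            raise ValueError(f"proteins without annotations: {list(missing)[:5]}")
        bad = set(self.annotations["organ"]) - VALID_ORGANS
        if bad:
            raise ValueError(f"unknown organ labels: {sorted(bad)}")
        if (self.annotations["scaling_factor"] <= 0).any():
            raise ValueError("scaling factors must be strictly positive")

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundance.index

    def proteins_for_organ(self, organ: str) -> list[str]:
        ids = self.annotations.index[self.annotations["organ"] == organ]
        return [p for p in self.abundance.columns if p in set(ids)]


@dataclass
class ClockModel:
    """One linear clock: protein subset, reference stats, weights, intercept."""

    name: str
    proteins: list[str]
    weights: pd.Series
    ref_mean: pd.Series
    ref_sd: pd.Series
    intercept: float
    transform: str = "log10"

    def __post_init__(self):
        for attr in ("weights", "ref_mean", "ref_sd"):
            s = getattr(self, attr)
            if not isinstance(s, pd.Series):
                setattr(self, attr, pd.Series(np.asarray(s, float), index=self.proteins))
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if (self.ref_sd <= 0).any():
            raise ValueError(f"clock {self.name}: reference SDs must be positive")
        extra = set(self.weights.index) - set(self.proteins)
        if extra:
            raise ValueError(f"clock {self.name}: weighted proteins outside subset: {sorted(extra)[:5]}")


def apply_scaling_factors(matrix: ProteinMatrix) -> ProteinMatrix:
    """Multiply each protein column by its assay-version scaling factor."""
    factors = matrix.annotations["scaling_factor"].reindex(matrix.abundance.columns)
    if factors.isna().any():
        missing = list(factors.index[factors.isna()])[:5]
        raise ValueError(f"missing scaling factor for proteins: {missing}")
    scaled = matrix.abundance * factors
    return ProteinMatrix(abundance=scaled, annotations=matrix.annotations, qc_flag=matrix.qc_flag)


def qc_filter_samples(matrix: ProteinMatrix) -> tuple[ProteinMatrix, list[str]]:
    """Drop assay-flagged samples; return the filtered matrix and removed ids."""
    flagged = matrix.qc_flag.reindex(matrix.abundance.index).fillna(False)
    if flagged.all():
        raise ValueError("all samples are QC-flagged; nothing left to analyse")
    removed = list(matrix.abundance.index[flagged])
    kept = matrix.abundance.loc[~flagged]
    return ProteinMatrix(abundance=kept, annotations=matrix.annotations, qc_flag=matrix.qc_flag.loc[~flagged]), removed


def estimate_biological_age(matrix: ProteinMatrix, clock: ClockModel) -> pd.Series:
    """Predicted biological age in years for every sample in the matrix."""
    missing = [p for p in clock.proteins if p not in matrix.abundance.columns]
    if missing:
        raise ValueError(f"clock {clock.name}: proteins absent from matrix: {missing[:5]}")
    x = matrix.abundance[clock.proteins].to_numpy(float)
    t = TRANSFORMS[clock.transform](x)
    z = (t - clock.ref_mean[clock.proteins].to_numpy()) / clock.ref_sd[clock.proteins].to_numpy()
    pred = clock.intercept + z @ clock.weights[clock.proteins].to_numpy()
    return pd.Series(pred, index=matrix.abundance.index, name=clock.name)


@dataclass
class AgeGapProfile:
    """Per-participant, per-clock predicted ages and age gaps.

    ``flags``/``thresholds``/``n_extreme`` are filled by
    :func:`lifeclocks.profiles.flag_extreme_agers` and
    :func:`lifeclocks.profiles.count_extreme_organs`.
    """

    predicted_age: pd.DataFrame
    age_gap: pd.DataFrame
    chron_age: pd.Series
    flags: pd.DataFrame | None = None
    thresholds: pd.Series | None = None
    n_extreme: pd.Series | None = None

    @property
    def clocks(self) -> list[str]:
        return list(self.age_gap.columns)

    def summary(self) -> pd.DataFrame:
        """Mean/SD/min/max of each clock's age-gap distribution."""
        g = self.age_gap
        return pd.DataFrame({"mean": g.mean(), "sd": g.std(), "min": g.min(), "max": g.max()})

    def with_flags(self, flags: pd.DataFrame, thresholds: pd.Series) -> "AgeGapProfile":
        return replace(self, flags=flags, thresholds=thresholds)


def compute_age_gaps(
    predicted: pd.DataFrame | pd.Series | dict,
    cohort: pd.DataFrame,
    center: bool = False,
) -> AgeGapProfile:
    """Age gaps (predicted minus chronological age) aligned to the cohort.

    ``center=True`` subtracts each clock's cohort-mean gap (in this
    near-constant-age cohort the usual age-trend correction reduces to a
    constant shift); raw gaps are the default.
    """
    if isinstance(predicted, pd.Series):
        predicted = predicted.to_frame()
    elif isinstance(predicted, dict):
        predicted = pd.DataFrame(predicted)
    chron = cohort.set_index("participant_id")["chron_age"]
    if not predicted.index.equals(chron.index):
        if set(predicted.index) != set(chron.index):
            raise ValueError("sample ids of predictions do not match the cohort")
        predicted = predicted.reindex(chron.index)
    gaps = predicted.sub(chron, axis=0)
    if center:
        gaps = gaps - gaps.mean()
    return AgeGapProfile(predicted_age=predicted, age_gap=gaps, chron_age=chron)
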