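"""Feature importance for biological ageing (FIBA).

Permutation importance for the proteins of one organ clock with respect to
an exposure <-> age-gap association: each clock protein's column is permuted
across participants, age gaps are recomputed, the association is refitted
and the drop in the regression coefficient (original minus permuted) is the
protein's FIBA coefficient, averaged over randomisations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clocks import ClockModel, ProteinMatrix, TRANSFORMS
from .config import UNIT_SCALES
from .exposures import DEFAULT_COVARIATES, _as_numeric, _design


@dataclass
class FIBAResult:
    protein_id: str
    fiba_coefficient: float
    per_randomisation: np.ndarray
    clock_weight_abs: float
    n_randomisations: int
    seed: int


def fiba_scores(
    matrix: ProteinMatrix,
    clock: ClockModel,
    cohort: pd.DataFrame,
    exposure: str,
    covariates=DEFAULT_COVARIATES,
    n_rand: int = 5,
    seed: int = 0,
) -> tuple[list[FIBAResult], float]:
    """FIBA coefficients for every clock protein, plus the baseline beta.

    Sign convention: ``beta_orig - mean(beta_permuted)``, so for a positive
    association a positive FIBA means the protein supports it.  Zero-weight
    proteins contribute nothing to the clock, so their FIBA is exactly zero
    for every seed.  Per-protein sub-seeds are derived from the master seed
    and the protein index, keeping every randomisation reproducible.
    """
    if n_rand < 1:
        raise ValueError(f"n_rand must be >= 1, got {n_rand}")
    x_exp = _as_numeric(cohort[exposure]) / UNIT_SCALES.get(exposure, 1.0)
    if np.ptp(x_exp) == 0:
        raise ValueError("exposure is constant; association undefined")

    ids = pd.Index(cohort["participant_id"])
    sub = ProteinMatrix(
        abundance=matrix.abundance.loc[ids], annotations=matrix.annotations, qc_flag=matrix.qc_flag.loc[ids]
    )
    t = TRANSFORMS[clock.transform](sub.abundance[clock.proteins].to_numpy(float))
    mu = clock.ref_mean[clock.proteins].to_numpy()
    sd = clock.ref_sd[clock.proteins].to_numpy()
    w = clock.weights[clock.proteins].to_numpy()
    z = (t - mu) / sd
    contrib = z * w  # per-protein contribution to the predicted age
    gap = clock.intercept + contrib.sum(axis=1) - cohort["chron_age"].to_numpy(float)

    # the association refit reduces to one inner product: beta = h @ y
    covs = [c for c in covariates if c != exposure]
    X = _design(cohort, covs)
    X.insert(1, exposure, x_exp)
    Xv = X.to_numpy(float)
    h = np.linalg.pinv(Xv)[1]
    beta_orig = float(h @ gap)

    n = len(cohort)
    results = []
    for j, pid in enumerate(clock.proteins):
        if w[j] == 0.0:
            results.append(FIBAResult(pid, 0.0, np.zeros(n_rand), 0.0, n_rand, seed))
            continue
        rng = np.random.default_rng([seed, j])
        vals = np.empty(n_rand)
        for r in range(n_rand):
            perm = rng.permutation(n)
            gap_perm = gap + (contrib[perm, j] - contrib[:, j])
            vals[r] = beta_orig - float(h @ gap_perm)
        results.append(FIBAResult(pid, float(vals.mean()), vals, float(abs(w[j])), n_rand, seed))
    return results, beta_orig


def fiba_table(results: list[FIBAResult], beta_orig: float) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "fiba_coefficient": [r.fiba_coefficient for r in results],
            "clock_weight_abs": [r.clock_weight_abs for r in results],
        }
    )
    df["beta_orig"] = beta_orig
    return df.sort_values("fiba_coefficient", key=np.abs, ascending=False).reset_index(drop=True)
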