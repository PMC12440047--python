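"""Synthetic birth-cohort generator with fully recorded ground truth.

Generates (i) a life-course exposure table whose marginals match the study
cohort, (ii) latent organ biological ages with planted exposure effects,
(iii) an organ-enriched protein matrix whose true clocks invert the latent
ages, (iv) a proportional-hazards mortality process, and (v) configurable
missingness.  Every random draw flows from a single integer seed, so any
dataset is exactly regenerable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .clocks import ClockModel, ProteinMatrix
from .config import (
    ACTIVITY_LEVELS,
    ADVERSITY_COMPONENTS,
    ADVERSITY_PERIODS,
    BMI_CUTOFF,
    CLOCKS,
    CLOCK_ORGAN_LABEL,
    PROTECTED_FIELDS,
    SES_HIGH_LEVELS,
    SES_LEVELS,
    TIMEPOINT_AGES,
    UNIT_SCALES,
    CohortConfig,
    EffectConfig,
    HazardConfig,
    PanelConfig,
)


@dataclass
class GroundTruth:
    """Planted parameters recorded for downstream recovery tests."""

    exposure_effects: dict[tuple[str, str], float]
    frailty_sd: float
    organ_noise_sd: float
    triad_sd: float = 0.0
    triad_organs: tuple[str, ...] = ()
    seeds: dict[str, int] = field(default_factory=dict)
    hazard: HazardConfig | None = None
    hazard_intercept: float | None = None
    clock_truth: dict[str, ClockModel] = field(default_factory=dict)
    mediation_structure: dict[str, float] = field(default_factory=dict)

    def effects_for_clock(self, clock: str) -> dict[str, float]:
        return {e: b for (e, c), b in self.exposure_effects.items() if c == clock}


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _copula_uniforms(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    """Equicorrelated Gaussian copula via a single shared factor."""
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"copula_rho must be in [0, 1), got {rho}")
    f = rng.standard_normal(n)[:, None]
    z = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * rng.standard_normal((n, k))
    return stats.norm.cdf(z)


def _count_from_probs(u: np.ndarray, probs: Iterable[float], reverse: bool = False) -> np.ndarray:
    """Map copula uniforms to an ordinal count with the given probabilities.

    With ``reverse=True`` larger uniforms (more disadvantage) map to smaller
    counts (e.g. fewer active timepoints).
    """
    p = np.asarray(list(probs), float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=0.05):
        raise ValueError("category probabilities must be non-negative and sum to 1")
    p = p / p.sum()
    edges = np.cumsum(p[:-1])
    idx = np.searchsorted(edges, u, side="right")
    return (len(p) - 1 - idx) if reverse else idx


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one cohort table plus its planted ground truth.

    Returns a participant table (one row per person: demographics,
    time-resolved life-course exposures, empty survival columns) and the
    :class:`GroundTruth` carrying every planted parameter.  Survival fields
    are filled by :func:`simulate_mortality`.
    """
    cfg = config or CohortConfig()
    if cfg.n <= 0:
        raise ValueError(f"cohort size must be positive, got {cfg.n}")
    for name in ("p_male", "p_education", "p_never_smoker", "p_quit_by_43"):
        p = getattr(cfg, name)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability, got {p}")
    n = cfg.n
    rng_cop, rng_misc = _spawn(seed, 2)

    # disadvantage-aligned copula: ses, education, birthweight, BMI,
    # smoking, alcohol, activity, adversity
    u = _copula_uniforms(rng_cop, n, 8, cfg.copula_rho)
    u_ses, u_edu, u_bw, u_bmi, u_smk, u_alc, u_act, u_adv = u.T

    df = pd.DataFrame(index=pd.RangeIndex(n))
    df["participant_id"] = [f"NS{i + 1:05d}" for i in range(n)]
    df["sex"] = np.where(rng_misc.random(n) < cfg.p_male, "male", "female")
    df["chron_age"] = cfg.age_mean + cfg.age_sd * rng_misc.standard_normal(n)

    # childhood factors -------------------------------------------------
    df["birthweight_kg"] = cfg.birthweight_mean - cfg.birthweight_sd * stats.norm.ppf(u_bw)
    ses_idx = _count_from_probs(u_ses, cfg.ses_probs)
    df["childhood_ses"] = pd.Categorical.from_codes(ses_idx, SES_LEVELS, ordered=True)
    df["ses_high"] = df["childhood_ses"].isin(SES_HIGH_LEVELS)
    df["education_high"] = u_edu <= cfg.p_education
    bmi_mean = np.where(df["sex"] == "female", cfg.bmi_mean_female, cfg.bmi_mean_male)
    df["adolescent_bmi"] = bmi_mean + cfg.bmi_sd * stats.norm.ppf(u_bmi)
    cutoff = df["sex"].map(BMI_CUTOFF).astype(float)
    df["adolescent_overweight"] = df["adolescent_bmi"] >= cutoff

    # smoking -----------------------------------------------------------
    smoker = u_smk > cfg.p_never_smoker
    quit = smoker & (rng_misc.random(n) < cfg.p_quit_by_43)
    pack = np.zeros(n)
    for mask, mean, sd in (
        (quit, cfg.quit_pack_years_mean, cfg.quit_pack_years_sd),
        (smoker & ~quit, cfg.cont_pack_years_mean, cfg.cont_pack_years_sd),
    ):
        k = int(mask.sum())
        if k:
            shape = (mean / sd) ** 2
            pack[mask] = rng_misc.gamma(shape, mean / shape, size=k)
    df["pack_years"] = pack
    df["smoking_status"] = np.select([~smoker, quit], ["never", "ceased_by_43"], default="continued")

    # alcohol -----------------------------------------------------------
    person = cfg.alcohol_sigma_person * stats.norm.ppf(u_alc)
    for age in TIMEPOINT_AGES:
        visit = cfg.alcohol_sigma_visit * rng_misc.standard_normal(n)
        df[f"alcohol_units_{age}"] = np.exp(cfg.alcohol_log_mu + person + visit)
    df["alcohol_units_mean"] = df[[f"alcohol_units_{a}" for a in TIMEPOINT_AGES]].mean(axis=1)

    # physical activity -------------------------------------------------
    n_active = _count_from_probs(u_act, cfg.activity_probs, reverse=True)
    active_at = np.zeros((n, 4), bool)
    order = np.argsort(rng_misc.random((n, 4)), axis=1)
    for i in range(n):
        active_at[i, order[i, : n_active[i]]] = True
    for j, age in enumerate(TIMEPOINT_AGES):
        level = np.where(active_at[:, j], np.where(rng_misc.random(n) < 0.5, "mild", "moderate_high"), "inactive")
        df[f"activity_cat_{age}"] = pd.Categorical(level, ACTIVITY_LEVELS)
    df["active_timepoints"] = n_active
    df["activity_sustained"] = n_active >= 2

    # adversity ---------------------------------------------------------
    n_adv = _count_from_probs(u_adv, cfg.adversity_probs)
    period_flag = np.zeros((n, 4), bool)
    order = np.argsort(rng_misc.random((n, 4)), axis=1)
    for i in range(n):
        period_flag[i, order[i, : n_adv[i]]] = True
    for j, period in enumerate(ADVERSITY_PERIODS):
        df[f"adversity_{period}"] = period_flag[:, j]
        comps = ADVERSITY_COMPONENTS[period]
        draw = rng_misc.random((n, len(comps))) < cfg.p_component_given_period
        none = ~draw.any(axis=1)
        draw[none, rng_misc.integers(0, len(comps), size=int(none.sum()))] = True
        draw &= period_flag[:, j][:, None]
        for c, comp in enumerate(comps):
            df[comp] = draw[:, c]
    df["adversity_periods"] = n_adv

    # auxiliary adult variables for sensitivity scenarios ----------------
    df["university_degree"] = df["education_high"] & (rng_misc.random(n) < cfg.p_university_given_education)
    z_bmi = stats.norm.ppf(u_bmi)
    for logit0, period in zip(cfg.adult_overweight_base_logit, ("early", "mid", "late")):
        lp = logit0 + cfg.adult_overweight_adolescent_logodds * df["adolescent_overweight"] + 0.3 * z_bmi
        df[f"adult_overweight_{period}"] = rng_misc.random(n) < 1.0 / (1.0 + np.exp(-lp))
    df["social_support"] = rng_misc.random(n) < cfg.p_social_support
    df["adult_ses_high"] = rng_misc.random(n) < cfg.p_adult_ses_high

    # survival placeholders (filled by simulate_mortality)
    df["followup_years"] = np.nan
    df["died"] = False
    df["censored"] = False

    eff = EffectConfig()
    truth = GroundTruth(
        exposure_effects=dict(eff.exposure_effects),
        frailty_sd=eff.frailty_sd,
        organ_noise_sd=eff.organ_noise_sd,
        triad_sd=eff.triad_sd,
        triad_organs=eff.triad_organs,
        seeds={"cohort": seed},
    )
    return df, truth


def _exposure_value(cohort: pd.DataFrame, exposure: str) -> np.ndarray:
    """Exposure on its reporting scale (pack-years / 20, units / 7, ...)."""
    x = cohort[exposure]
    if x.dtype == bool or str(x.dtype) == "boolean":
        v = x.astype(float).to_numpy()
    else:
        v = pd.to_numeric(x).to_numpy(float)
    return v / UNIT_SCALES.get(exposure, 1.0)


def latent_organ_ages(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    seed: int = 0,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Latent biological age per participant and clock.

    latent age = chronological age + planted exposure effects + shared
    frailty + organ noise.  ``noiseless=True`` drops frailty and noise,
    leaving the deterministic exposure signal (used by inversion oracles).
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    chron = cohort["chron_age"].to_numpy(float)
    frailty = 0.0 if noiseless else truth.frailty_sd * rng.standard_normal(n)
    triad = 0.0 if noiseless or not truth.triad_sd else truth.triad_sd * rng.standard_normal(n)
    ages = {}
    for clock in CLOCKS:
        a = chron.copy()
        for exposure, beta in truth.effects_for_clock(clock).items():
            a = a + beta * _exposure_value(cohort, exposure)
        if not noiseless:
            a = a + frailty + truth.organ_noise_sd * rng.standard_normal(n)
            if clock in truth.triad_organs:
                a = a + triad
        ages[clock] = a
    out = pd.DataFrame(ages, index=pd.Index(cohort["participant_id"], name="participant_id"))
    truth.seeds.setdefault("latent", seed)
    return out


def generate_protein_matrix(
    cohort: pd.DataFrame,
    panel: PanelConfig | None = None,
    truth: GroundTruth | None = None,
    seed: int = 0,
    latent_ages: pd.DataFrame | None = None,
) -> tuple[ProteinMatrix, list[ClockModel]]:
    """Simulate an organ-enriched aptamer panel driven by latent organ ages.

    Each protein's log10 abundance is ``baseline + loading * latent_age +
    noise``; the returned true clocks carry weights that invert the loadings,
    so applying them to the (scaled) matrix recovers the latent ages up to
    assay noise.  The raw matrix is returned on the "new assay version"
    scale, i.e. divided by per-protein scaling factors that
    :func:`lifeclocks.clocks.apply_scaling_factors` must re-apply.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    panel = panel or PanelConfig()
    if panel.noise_sd < 0:
        raise ValueError(f"noise SD must be non-negative, got {panel.noise_sd}")
    truth = truth if truth is not None else GroundTruth(exposure_effects={}, frailty_sd=0.0, organ_noise_sd=0.0)
    rng_panel, rng_noise, rng_latent = _spawn(seed, 3)
    if latent_ages is None:
        latent_ages = latent_organ_ages(cohort, truth, seed=int(rng_latent.integers(2**31)))

    per_organ = panel.n_per_organ if isinstance(panel.n_per_organ, Mapping) else {c: panel.n_per_organ for c in CLOCKS}
    sample_ids = list(cohort["participant_id"])
    n = len(sample_ids)

    cols, meta_rows, clock_models = {}, [], []
    for clock in CLOCKS:
        p = int(per_organ.get(clock, 0))
        if p == 0:
            continue
        organ = CLOCK_ORGAN_LABEL[clock]
        ids = [f"{organ[:3].upper()}{j + 1:04d}" for j in range(p)]
        lo, hi = panel.loading_range
        loadings = rng_panel.uniform(lo, hi, size=p)
        n_zero = int(round(panel.zero_loading_fraction * p))
        if n_zero:
            loadings[rng_panel.choice(p, size=n_zero, replace=False)] = 0.0
        baselines = rng_panel.uniform(*panel.baseline_log10_range, size=p)
        factors = rng_panel.uniform(*panel.scaling_factor_range, size=p)

        ages = latent_ages[clock].to_numpy(float)
        log10_scaled = baselines[None, :] + loadings[None, :] * ages[:, None]
        if panel.noise_sd > 0:
            log10_scaled = log10_scaled + panel.noise_sd * rng_noise.standard_normal((n, p))
        raw = 10.0**log10_scaled / factors[None, :]

        ref_mean = baselines + loadings * panel.ref_age_mean
        ref_sd = np.sqrt((loadings * panel.ref_age_sd) ** 2 + panel.noise_sd**2)
        ref_sd[ref_sd == 0] = 1.0
        nz = loadings != 0
        weights = np.zeros(p)
        weights[nz] = ref_sd[nz] / (nz.sum() * loadings[nz])

        for j, pid in enumerate(ids):
            cols[pid] = raw[:, j]
            meta_rows.append((pid, organ, factors[j]))
        clock_models.append(
            ClockModel(
                name=clock,
                proteins=ids,
                weights=pd.Series(weights, index=ids),
                ref_mean=pd.Series(ref_mean, index=ids),
                ref_sd=pd.Series(ref_sd, index=ids),
                intercept=panel.ref_age_mean,
                transform="log10",
            )
        )

    abundance = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    qc = pd.Series(False, index=abundance.index, name="qc_flag")
    if panel.n_qc_extra:
        # extra assay-flagged samples outside the analysis cohort
        extra_ids = [f"QCFAIL{j + 1:03d}" for j in range(panel.n_qc_extra)]
        extra = pd.DataFrame(
            {pid: np.full(panel.n_qc_extra, abundance[pid].median()) for pid in abundance.columns},
            index=pd.Index(extra_ids, name="sample_id"),
        )
        abundance = pd.concat([abundance, extra])
        qc = pd.concat([qc, pd.Series(True, index=extra.index, name="qc_flag")])

    annotations = pd.DataFrame(meta_rows, columns=["protein_id", "organ", "scaling_factor"]).set_index("protein_id")
    matrix = ProteinMatrix(abundance=abundance, annotations=annotations, qc_flag=qc)
    truth.clock_truth = {m.name: m for m in clock_models}
    truth.seeds.setdefault("panel", seed)
    return matrix, clock_models


def _calibrate_intercept(fun, target: float) -> float:
    """Solve fun(intercept) = target death fraction by bisection."""
    lo, hi = -30.0, 10.0
    return float(optimize.brentq(lambda c: fun(c) - target, lo, hi, xtol=1e-10))


def simulate_mortality(
    cohort: pd.DataFrame,
    latent_gaps: pd.DataFrame,
    truth: GroundTruth,
    seed: int = 0,
    hazard: HazardConfig | None = None,
    extreme_counts: pd.Series | None = None,
    pfs: pd.Series | None = None,
) -> pd.DataFrame:
    """Fill survival fields from a proportional-hazards mortality process.

    The linear predictor sums per-clock age-gap terms, an optional
    per-extreme-organ gradient and an optional protective-factor term; the
    baseline (exponential by default, Gompertz optional) is calibrated so
    the expected death fraction matches the configured target.  Event times
    beyond the administrative horizon are censored; observed death times are
    recorded at month resolution.
    """
    hz = hazard or HazardConfig()
    if hz.horizon_years <= 0:
        raise ValueError(f"censoring horizon must be positive, got {hz.horizon_years}")
    rng = np.random.default_rng(seed)
    n = len(cohort)

    lp = np.zeros(n)
    for clock, beta in (hz.gap_coefs or {}).items():
        lp += beta * latent_gaps[clock].to_numpy(float)
    if hz.extreme_count_coef is not None:
        if extreme_counts is None:
            raise ValueError("extreme_count_coef set but no extreme_counts supplied")
        lp += hz.extreme_count_coef * extreme_counts.to_numpy(float)
    if hz.pfs_coef is not None:
        if pfs is None:
            raise ValueError("pfs_coef set but no pfs supplied")
        lp += hz.pfs_coef * pfs.to_numpy(float)

    H = hz.horizon_years
    target = hz.target_death_fraction
    out = cohort.copy()
    if hz.mode == "logistic":
        c0 = (_calibrate_intercept(lambda c: np.mean(1.0 / (1.0 + np.exp(-(c + lp)))), target)
              if target is not None else hz.baseline_log_rate)
        p = 1.0 / (1.0 + np.exp(-(c0 + lp)))
        died = rng.random(n) < p
        t = np.where(died, rng.uniform(0.0, H, size=n), H)
    elif hz.baseline == "exponential":
        c0 = (_calibrate_intercept(lambda c: np.mean(1.0 - np.exp(-np.exp(c + lp) * H)), target)
              if target is not None else hz.baseline_log_rate)
        t = rng.exponential(1.0, size=n) / np.exp(c0 + lp)
        died = t <= H
    elif hz.baseline == "gompertz":
        g = hz.gompertz_shape

        def frac(c):
            return np.mean(1.0 - np.exp(-np.exp(c + lp) * (np.expm1(g * H)) / g))

        c0 = _calibrate_intercept(frac, target) if target is not None else hz.baseline_log_rate
        e = rng.exponential(1.0, size=n)
        t = np.log1p(g * e / np.exp(c0 + lp)) / g
        died = t <= H
    else:
        raise ValueError(f"unknown baseline {hz.baseline!r}")

    if hz.round_to_month and hz.mode != "logistic":
        t = np.where(died, np.minimum(np.ceil(t * 12.0) / 12.0, H), t)
    out["followup_years"] = np.where(died, np.maximum(t, 1.0 / 24.0), H)
    out["died"] = died
    out["censored"] = ~died
    truth.hazard = hz
    truth.hazard_intercept = c0
    truth.seeds.setdefault("mortality", seed)
    return out


def inject_missingness(
    cohort: pd.DataFrame,
    rates: Mapping[str, float],
    mechanism: str = "MCAR",
    seed: int = 0,
    mar_covariate: str = "sex",
    mar_logodds: float = 1.0,
) -> pd.DataFrame:
    """Mask exposure fields at the requested rates.

    MCAR masks uniformly; MAR conditions the masking log-odds on an observed
    covariate (calibrated so the marginal rate still matches).  Outcome,
    survival and demographic fields are protected and may never be masked.
    """
    if mechanism not in {"MCAR", "MAR"}:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for col, rate in rates.items():
        if col in PROTECTED_FIELDS:
            raise ValueError(f"field {col!r} is protected and cannot be masked")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {col!r} must be in [0, 1], got {rate}")
        if rate == 0.0:
            continue
        n = len(out)
        if mechanism == "MCAR":
            mask = rng.random(n) < rate
        else:
            x = out[mar_covariate]
            x = (x == x.unique()[0]).astype(float).to_numpy() if x.dtype == object else pd.to_numeric(x).to_numpy(float)
            x = (x - x.mean()) / (x.std() or 1.0)
            c0 = _calibrate_intercept(lambda c: np.mean(1.0 / (1.0 + np.exp(-(c + mar_logodds * x)))), rate)
            mask = rng.random(n) < 1.0 / (1.0 + np.exp(-(c0 + mar_logodds * x)))
        if out[col].dtype == bool:
            out[col] = out[col].astype("boolean")
        elif pd.api.types.is_integer_dtype(out[col]):
            out[col] = out[col].astype("Float64")
        out.loc[mask, col] = pd.NA
    return out


def generate_hazard_protein_study(
    n: int = 1803,
    n_proteins: int = 500,
    n_hazard: int = 10,
    log_hr_per_sd: float = 0.3,
    seed: int = 0,
    target_death_fraction: float = 0.156,
    horizon: float = 15.1,
) -> tuple[pd.DataFrame, ProteinMatrix, list[str]]:
    """Proteome-wide planted truth: a panel in which a known subset of
    proteins carries a log-linear mortality hazard.

    Returns a minimal cohort with survival fields, the protein matrix and
    the list of planted hazard-protein ids.  ``n_hazard=0`` gives a
    pure-noise panel (no protein is informative).
    """
    rng_z, rng_t, rng_d = _spawn(seed, 3)
    z = rng_z.standard_normal((n, n_proteins))
    coef = np.zeros(n_proteins)
    coef[:n_hazard] = log_hr_per_sd
    lp = z @ coef
    lam0 = -np.log(1.0 - target_death_fraction) / horizon / np.mean(np.exp(lp))
    t = rng_t.exponential(1.0, n) / (lam0 * np.exp(lp))
    died = t <= horizon
    ids = [f"S{i:05d}" for i in range(n)]
    cohort = pd.DataFrame(
        {
            "participant_id": ids,
            "sex": rng_d.choice(["male", "female"], n),
            "chron_age": 63.2 + 1.1 * rng_d.standard_normal(n),
            "followup_years": np.where(died, t, horizon),
            "died": died,
            "censored": ~died,
        }
    )
    prots = [f"P{j:04d}" for j in range(n_proteins)]
    abundance = pd.DataFrame(10.0 ** (3.0 + 0.2 * z), index=pd.Index(ids, name="sample_id"), columns=prots)
    annotations = pd.DataFrame(
        {"organ": "none", "scaling_factor": 1.0}, index=pd.Index(prots, name="protein_id")
    )
    matrix = ProteinMatrix(abundance=abundance, annotations=annotations, qc_flag=pd.Series(False, index=abundance.index))
    return cohort, matrix, prots[:n_hazard]


def simulate_study(
    cohort_config: CohortConfig | None = None,
    panel: PanelConfig | None = None,
    hazard: HazardConfig | None = None,
    seed: int = 0,
):
    """Run the full generator pipeline with one master seed.

    Returns ``(cohort, matrix, clocks, latent_ages, truth)`` where the
    cohort already carries simulated survival fields.
    """
    s_cohort, s_latent, s_panel, s_mort = [int(r.integers(2**31)) for r in _spawn(seed, 4)]
    cohort, truth = generate_cohort(cohort_config, seed=s_cohort)
    latent = latent_organ_ages(cohort, truth, seed=s_latent)
    matrix, clocks = generate_protein_matrix(cohort, panel, truth, seed=s_panel, latent_ages=latent)
    gaps = latent.sub(cohort.set_index("participant_id")["chron_age"], axis=0)
    cohort = simulate_mortality(cohort, gaps, truth, seed=s_mort, hazard=hazard)
    truth.seeds["master"] = seed
    return cohort, matrix, clocks, latent, truth
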