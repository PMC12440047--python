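"""Study conditions for the synthetic 1946 birth-cohort generator.

The defaults describe a same-birth-week cohort of 1,803 adults sampled for
plasma proteomics in late midlife (63.2 +/- 1.1 years) and followed for
mortality over ~15 years with ~15.6% deaths.  Exposure marginals reproduce
the cohort's published demographic table; planted exposure -> organ-ageing
effects default to the published regression magnitudes so that every
downstream estimator has a known truth to recover.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

CLOCKS = ["Conventional", "Brain", "Heart", "Lung", "Liver", "Kidney", "Immune", "Artery"]
ORGAN_CLOCKS = CLOCKS[1:]

#: organ-enrichment label carried by each protein; the Conventional clock is
#: built from non-organ-specific ("organismal") proteins.
CLOCK_ORGAN_LABEL = {
    "Conventional": "organismal",
    "Brain": "brain",
    "Heart": "heart",
    "Lung": "lung",
    "Liver": "liver",
    "Kidney": "kidney",
    "Immune": "immune",
    "Artery": "artery",
}
ORGAN_TO_CLOCK = {v: k for k, v in CLOCK_ORGAN_LABEL.items()}

SES_LEVELS = [
    "professional",
    "intermediate",
    "skilled_nonmanual",
    "skilled_manual",
    "partly_skilled",
    "unskilled",
]
#: father's occupation classes counted as higher childhood socio-economic status
SES_HIGH_LEVELS = SES_LEVELS[:3]

ACTIVITY_LEVELS = ["inactive", "mild", "moderate_high"]
TIMEPOINT_AGES = [36, 43, 53, 63]
ADVERSITY_PERIODS = ["childhood", "early_adult", "mid_adult", "later_adult"]
#: financial / psychosocial adversity sources, by the life period in which
#: they are recorded
ADVERSITY_COMPONENTS = {
    "childhood": ["overcrowding", "childhood_illness"],
    "early_adult": ["unemployment", "divorce"],
    "mid_adult": ["conflict_children", "work_crisis"],
    "later_adult": ["social_isolation", "financial_troubles"],
}

#: denominators that express association coefficients on their reporting
#: units (years per 20 pack-years, per 7 UK units/week, per life period ...)
UNIT_SCALES = {
    "pack_years": 20.0,
    "alcohol_units_mean": 7.0,
    "alcohol_units_36": 7.0,
    "alcohol_units_43": 7.0,
    "alcohol_units_53": 7.0,
    "alcohol_units_63": 7.0,
}

#: fields that are never masked by the missingness injector: outcomes and
#: fixed demographics are observed for everyone
PROTECTED_FIELDS = {"participant_id", "sex", "chron_age", "followup_years", "died", "censored"}

#: adolescent-overweight BMI cut-offs (WHO growth charts at age 15)
BMI_CUTOFF = {"female": 23.5, "male": 22.7}


def default_exposure_effects() -> dict[tuple[str, str], float]:
    """Planted (exposure, clock) -> effect in years per reporting unit.

    Magnitudes follow the published life-course associations: adolescent
    overweight +1.13 y, secondary education -0.52 y, sustained activity
    -0.79 y and smoking +0.59 y per 20 pack-years on the Conventional clock
    and on the three socio-behaviourally sensitive organs (liver, kidney,
    immune); alcohol -0.27 y per 7 units/week on the brain clock only; the
    adversity composite acts through its period-specific components on the
    Conventional clock.
    """
    effects: dict[tuple[str, str], float] = {}
    for clock in ("Conventional", "Liver", "Kidney", "Immune"):
        effects[("adolescent_overweight", clock)] = 1.13
        effects[("education_high", clock)] = -0.52
        effects[("activity_sustained", clock)] = -0.79
        effects[("pack_years", clock)] = 0.59
    effects[("alcohol_units_mean", "Brain")] = -0.27
    for comp, beta in {
        "overcrowding": 0.42,
        "childhood_illness": 0.57,
        "conflict_children": 0.40,
        "work_crisis": 0.43,
        "social_isolation": 0.94,
        "financial_troubles": 0.61,
    }.items():
        effects[(comp, "Conventional")] = beta
    return effects


@dataclass
class CohortConfig:
    """Marginal distributions of the cohort's demographics and exposures."""

    n: int = 1803
    age_mean: float = 63.2
    age_sd: float = 1.1
    p_male: float = 0.494
    # birthweight: Normal with 2.9% below the 2.5 kg low-birthweight line
    birthweight_mean: float = 3.35
    birthweight_sd: float = 0.45
    ses_probs: tuple[float, ...] = (0.077, 0.224, 0.210, 0.292, 0.172, 0.058)
    p_education: float = 0.637
    # adolescent BMI: sex-specific Normals putting 10.5% above the
    # overweight cut-offs (23.5 female / 22.7 male)
    bmi_sd: float = 2.0
    bmi_mean_female: float = 20.99
    bmi_mean_male: float = 20.19
    # smoking: zero-inflated; smokers split into ceased-by-43 and continued,
    # with gamma pack-year intensities giving marginal mean 9.9, SD ~15
    p_never_smoker: float = 0.35
    p_quit_by_43: float = 0.35  # among ever-smokers
    quit_pack_years_mean: float = 4.0
    quit_pack_years_sd: float = 3.0
    cont_pack_years_mean: float = 21.3
    cont_pack_years_sd: float = 17.5
    # alcohol: log-normal units/week at ages 36/43/53/63 with a persistent
    # person effect; marginal mean 16.8, SD 15.0 per timepoint
    alcohol_log_mu: float = 2.53
    alcohol_sigma_person: float = 0.64
    alcohol_sigma_visit: float = 0.42
    # distribution of the number of active timepoints (0..4 of 4)
    activity_probs: tuple[float, ...] = (0.133, 0.200, 0.236, 0.237, 0.194)
    # distribution of the number of life periods with adversity (0..4 of 4)
    adversity_probs: tuple[float, ...] = (0.021, 0.148, 0.285, 0.355, 0.190)
    p_component_given_period: float = 0.6
    # Gaussian-copula equicorrelation clustering disadvantage across exposures
    copula_rho: float = 0.15
    # auxiliary adult variables used by sensitivity scenarios
    p_university_given_education: float = 0.25
    adult_overweight_base_logit: tuple[float, ...] = (-1.1, -0.2, 0.2)  # early/mid/late
    adult_overweight_adolescent_logodds: float = 1.5
    p_social_support: float = 0.8
    p_adult_ses_high: float = 0.6


@dataclass
class EffectConfig:
    """Planted structure shared by the latent organ-age model."""

    exposure_effects: dict[tuple[str, str], float] = field(default_factory=default_exposure_effects)
    #: shared frailty SD in years: induces positive but modest (< 0.4)
    #: pairwise age-gap correlations across organs
    frailty_sd: float = 2.0
    #: organ-specific noise SD in years
    organ_noise_sd: float = 3.5
    #: extra shared factor (years) tying brain, immune and liver ageing --
    #: these organs show the closest coupling and the most frequent
    #: concurrent extreme ageing
    triad_sd: float = 1.2
    triad_organs: tuple[str, ...] = ("Brain", "Immune", "Liver")


@dataclass
class HazardConfig:
    """Proportional-hazards mortality process over the follow-up window."""

    baseline: str = "exponential"  # or "gompertz"
    gompertz_shape: float = 0.09
    horizon_years: float = 15.1
    #: expected death fraction the baseline is calibrated to; None keeps the
    #: fixed baseline_log_rate instead
    target_death_fraction: float | None = 0.156
    baseline_log_rate: float = -4.49  # ~1.12%/yr, 15.6% dead over 15.1 y
    #: log-hazard per year of age gap, by clock
    gap_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"Conventional": 0.07, "Heart": 0.09, "Kidney": 0.05, "Liver": 0.05, "Immune": 0.05}
    )
    #: optional log-hazard per extremely aged organ (graded-risk experiments)
    extreme_count_coef: float | None = None
    #: optional log-hazard (log-odds in logistic mode) per protective factor
    pfs_coef: float | None = None
    #: "times" draws event times from the hazard; "logistic" draws a
    #: death-by-horizon indicator from a logistic model (for odds-ratio truth)
    mode: str = "times"
    round_to_month: bool = True


@dataclass
class PanelConfig:
    """Synthetic aptamer panel layout (scaled down from 201/103 per organ)."""

    n_per_organ: int = 40
    loading_range: tuple[float, float] = (0.004, 0.02)
    zero_loading_fraction: float = 0.0
    baseline_log10_range: tuple[float, float] = (3.0, 4.0)
    noise_sd: float = 0.02  # log10-RFU residual SD
    scaling_factor_range: tuple[float, float] = (0.5, 2.0)
    #: extra non-cohort samples carrying an assay QC flag (mirrors the
    #: 1807 -> 1803 sample exclusion)
    n_qc_extra: int = 4
    ref_age_mean: float = 63.2
    ref_age_sd: float = 4.0  # scale constant for reference z-scoring
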