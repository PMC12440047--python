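"""Exposure association models, BH correction, sensitivity scenarios."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lifeclocks import (
    AgeGapProfile,
    CohortConfig,
    GroundTruth,
    adjust_bh,
    adversity_component_model,
    compute_age_gaps,
    family_associations,
    fit_exposure_association,
    fit_sensitivity_scenario,
    generate_cohort,
    latent_organ_ages,
)


def brute_force_bh(p):
    """Independent step-up implementation used as the BH oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def default_profile(seed=101, n=1803):
    cohort, truth = generate_cohort(CohortConfig(n=n), seed=seed)
    latent = latent_organ_ages(cohort, truth, seed=seed + 1)
    return cohort, truth, compute_age_gaps(latent, cohort)


class TestAssociations:
    def test_three_point_perfect_line(self):
        cohort = pd.DataFrame(
            {"participant_id": list("abc"), "sex": ["female", "male", "female"],
             "chron_age": [63.0, 63.0, 63.0], "x": [0.0, 1.0, 2.0]}
        )
        gaps = pd.DataFrame({"Conventional": [0.0, 1.0, 2.0]}, index=pd.Index(list("abc"), name="participant_id"))
        profile = AgeGapProfile(gaps + 63.0, gaps, cohort.set_index("participant_id")["chron_age"])
        r = fit_exposure_association(cohort, profile, "x", "Conventional", covariates=())
        assert r.beta == pytest.approx(1.0, abs=1e-12)

    def test_independent_exposure_beta_near_zero(self, rng):
        cohort, truth, profile = default_profile(seed=103)
        cohort = cohort.copy()
        cohort["noise_exposure"] = rng.standard_normal(len(cohort))
        r = fit_exposure_association(cohort, profile, "noise_exposure", "Heart")
        assert abs(r.beta) < 3 * r.se

    def test_planted_smoking_effect_recovered_within_ci(self):
        """Planted +0.59 y per 20 pack-years on the Conventional clock is
        covered by the 95% CI of the correctly specified model."""
        cohort, truth, profile = default_profile(seed=104)
        planted = [e for e in truth.effects_for_clock("Conventional")]
        r = fit_exposure_association(cohort, profile, "pack_years", "Conventional",
                                     extra_covariates=[e for e in planted if e != "pack_years"])
        assert r.ci_low < 0.59 < r.ci_high

    def test_unitization_pack_years_per_20(self):
        cohort, truth, profile = default_profile(seed=105)
        r20 = fit_exposure_association(cohort, profile, "pack_years", "Conventional")
        cohort2 = cohort.copy()
        cohort2["raw_pack"] = cohort["pack_years"]
        r_raw = fit_exposure_association(cohort2, profile, "raw_pack", "Conventional")
        assert r20.beta == pytest.approx(20 * r_raw.beta, rel=1e-9)

    def test_ses_exposure_drops_ses_covariate(self):
        cohort, truth, profile = default_profile(seed=106, n=400)
        r = fit_exposure_association(cohort, profile, "ses_high", "Conventional")
        assert "ses_high" not in r.covariates

    def test_adding_independent_covariate_barely_moves_estimate(self, rng):
        cohort, truth, profile = default_profile(seed=107)
        cohort = cohort.copy()
        cohort["junk"] = rng.standard_normal(len(cohort))
        r0 = fit_exposure_association(cohort, profile, "adolescent_overweight", "Conventional")
        r1 = fit_exposure_association(cohort, profile, "adolescent_overweight", "Conventional",
                                      extra_covariates=("junk",))
        assert abs(r0.beta - r1.beta) < 0.1

    def test_family_bh_adjusted_within_eight_clocks(self):
        cohort, truth, profile = default_profile(seed=108)
        res = family_associations(cohort, profile, "adolescent_overweight")
        assert len(res) == 8
        p = np.array([r.p for r in res])
        adj = np.array([r.adj_p for r in res])
        np.testing.assert_allclose(adj, brute_force_bh(p), rtol=1e-12)
        assert (adj >= p - 1e-15).all()

    def test_collinear_covariates_rejected(self):
        cohort, truth, profile = default_profile(seed=109, n=200)
        cohort = cohort.copy()
        cohort["dup"] = cohort["chron_age"]
        with pytest.raises(ValueError, match="collinear"):
            fit_exposure_association(cohort, profile, "pack_years", "Brain", extra_covariates=("dup",))


class TestBH:
    def test_textbook_family(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.123])[0] == pytest.approx(0.123)

    def test_all_ones(self):
        np.testing.assert_array_equal(adjust_bh([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    def test_matches_brute_force_on_random_vectors(self, rng):
        """1000 random p-vectors: package BH equals the step-up oracle."""
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            np.testing.assert_allclose(adjust_bh(p), brute_force_bh(p), rtol=1e-10)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_property_matches_oracle(self, p):
        np.testing.assert_allclose(adjust_bh(p), brute_force_bh(p), rtol=1e-10)


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        cohort, truth, profile = default_profile(seed=110, n=200)
        with pytest.raises(ValueError, match="unknown scenario"):
            fit_sensitivity_scenario("bogus", cohort, profile)

    def test_overweight_robust_to_adult_adjustment(self):
        """Planted adolescent effect persists when adult overweight enters."""
        cohort, truth, profile = default_profile(seed=111)
        res = fit_sensitivity_scenario("overweight_adult_adjusted", cohort, profile)
        assert len(res) == 4
        for r in res:
            assert r.beta > 0.3  # adolescent term stays positive and sizeable

    def test_education_subgroups_equal_within_ci(self):
        """The planted schooling effect is degree-independent, so subgroup
        estimates agree within sampling error."""
        cohort, truth, profile = default_profile(seed=112)
        res = fit_sensitivity_scenario("education_subgroups", cohort, profile)
        a, b = res
        assert abs(a.beta - b.beta) < 2 * np.hypot(a.se, b.se)

    def test_activity_dose_response_monotone_with_linear_planting(self):
        """A planted per-timepoint activity benefit yields monotone dose betas."""
        cohort, _ = generate_cohort(CohortConfig(n=6000), seed=113)
        truth = GroundTruth(exposure_effects={("active_timepoints", "Conventional"): -0.5},
                            frailty_sd=0.0, organ_noise_sd=1.0)
        latent = latent_organ_ages(cohort, truth, seed=114)
        profile = compute_age_gaps(latent, cohort)
        res = fit_sensitivity_scenario("activity_dose", cohort, profile)
        betas = [r.beta for r in res]
        assert all(np.diff(betas) < 0)  # increasingly protective
        assert betas[-1] == pytest.approx(-2.0, abs=0.25)

    def test_quitters_show_no_excess_ageing(self):
        """Smokers who ceased by 43 carry few pack-years, so their contrast
        with never-smokers is null."""
        cohort, truth, profile = default_profile(seed=115)
        res = fit_sensitivity_scenario("smoking_cessation", cohort, profile)
        by_name = {r.exposure: r for r in res}
        quit = by_name["ceased_by_43"]
        assert quit.ci_low < 0 < quit.ci_high or abs(quit.beta) < 0.35
        assert by_name["continued"].beta > quit.beta

    def test_alcohol_timepoints_consistent_direction(self):
        cohort, truth, profile = default_profile(seed=116)
        res = fit_sensitivity_scenario("alcohol_timepoints", cohort, profile, clock="Brain")
        assert len(res) == 4
        assert all(r.beta < 0 for r in res)

    def test_alcohol_dose_bands_increasingly_protective(self):
        cohort, _ = generate_cohort(CohortConfig(n=8000), seed=117)
        truth = GroundTruth(exposure_effects={("alcohol_units_mean", "Brain"): -0.27},
                            frailty_sd=0.0, organ_noise_sd=1.0)
        latent = latent_organ_ages(cohort, truth, seed=118)
        profile = compute_age_gaps(latent, cohort)
        res = fit_sensitivity_scenario("alcohol_dose", cohort, profile, clock="Brain")
        betas = [r.beta for r in res]
        assert all(np.diff(betas) < 0)


class TestAdversityComponents:
    def test_single_planted_component_dominates(self):
        """Only the planted overcrowding effect (+0.42 y) is significant."""
        cohort, _ = generate_cohort(CohortConfig(n=12000), seed=120)
        truth = GroundTruth(exposure_effects={("overcrowding", "Conventional"): 0.42},
                            frailty_sd=0.0, organ_noise_sd=1.0)
        latent = latent_organ_ages(cohort, truth, seed=121)
        profile = compute_age_gaps(latent, cohort)
        res = adversity_component_model(cohort, profile)
        by_name = {r.exposure: r for r in res}
        assert by_name["overcrowding"].p < 1e-6
        assert by_name["overcrowding"].beta == pytest.approx(0.42, abs=0.1)
        others = [r for r in res if r.exposure != "overcrowding"]
        assert sum(r.p < 0.05 for r in others) <= 1  # chance-level only

    def test_no_planting_all_null(self):
        cohort, _ = generate_cohort(CohortConfig(n=4000), seed=122)
        truth = GroundTruth(exposure_effects={}, frailty_sd=0.0, organ_noise_sd=1.0)
        latent = latent_organ_ages(cohort, truth, seed=123)
        profile = compute_age_gaps(latent, cohort)
        res = adversity_component_model(cohort, profile)
        assert all(abs(r.beta) < 4 * r.se for r in res)

    def test_aliased_components_rejected(self):
        cohort, truth, profile = default_profile(seed=124, n=300)
        cohort = cohort.copy()
        cohort["childhood_illness"] = cohort["overcrowding"]  # perfect collinearity
        with pytest.raises(ValueError, match="collinear"):
            adversity_component_model(cohort, profile)
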