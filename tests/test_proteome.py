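"""Proteome-wide analyses: differential abundance with FDR control,
cross-timepoint consistency, elastic-net Cox and decile biomarkers."""
import numpy as np
import pandas as pd
import pytest

from lifeclocks import ProteinMatrix
from lifeclocks.proteome import (
    cross_timepoint_consistency,
    decile_biomarker_risk,
    differential_abundance,
    elastic_net_cox,
    exposure_profile_of_protein,
)

from conftest import make_survival_cohort


def build_matrix(log10_vals, ids, organs="none"):
    p = log10_vals.shape[1]
    prots = [f"P{j}" for j in range(p)]
    ab = pd.DataFrame(10.0**log10_vals, index=pd.Index(ids, name="sample_id"), columns=prots)
    if isinstance(organs, str):
        organs = [organs] * p
    ann = pd.DataFrame({"organ": organs, "scaling_factor": 1.0}, index=pd.Index(prots, name="protein_id"))
    return ProteinMatrix(ab, ann, pd.Series(False, index=ab.index))


class TestDifferentialAbundance:
    def test_planted_score_links_recovered_with_fdr_control(self):
        """50 of 500 proteins track the score: recall > 0.8 with the mean
        false-discovery proportion controlled at <= 0.07 over replicates."""
        n, p, k = 800, 500, 50
        truth = {f"P{j}" for j in range(k)}
        recalls, fdps = [], []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            cohort = make_survival_cohort(n, seed=200 + seed)
            score = rng.integers(0, 9, n).astype(float)
            z = (score - score.mean()) / score.std()
            logs = rng.standard_normal((n, p))
            logs[:, :k] += 0.25 * z[:, None]
            m = build_matrix(logs, cohort["participant_id"])
            res = differential_abundance(m, cohort, "pfs_linear",
                                         score=pd.Series(score, index=pd.Index(cohort["participant_id"])))
            hits = set(res.loc[res["significant"], "protein_id"])
            recalls.append(len(hits & truth) / k)
            fdps.append(len(hits - truth) / max(len(hits), 1))
        assert np.mean(recalls) > 0.8
        assert np.mean(fdps) <= 0.07

    def test_null_proteins_uniform_adjp(self):
        rng = np.random.default_rng(22)
        n, p = 300, 200
        cohort = make_survival_cohort(n, seed=23)
        score = rng.integers(0, 9, n).astype(float)
        m = build_matrix(rng.standard_normal((n, p)), cohort["participant_id"])
        res = differential_abundance(m, cohort, "pfs_linear",
                                     score=pd.Series(score, index=pd.Index(cohort["participant_id"])))
        assert res["significant"].sum() <= 2

    def test_organ_subset_restricts_tests(self):
        rng = np.random.default_rng(24)
        n = 100
        cohort = make_survival_cohort(n, seed=25)
        organs = ["brain"] * 5 + ["liver"] * 5
        m = build_matrix(rng.standard_normal((n, 10)), cohort["participant_id"], organs)
        score = pd.Series(rng.random(n), index=pd.Index(cohort["participant_id"]))
        res = differential_abundance(m, cohort, "pfs_linear", score=score, subset="brain")
        assert set(res["protein_id"]) == {f"P{j}" for j in range(5)}

    def test_zero_variance_protein_skipped_with_note(self):
        rng = np.random.default_rng(26)
        n = 80
        cohort = make_survival_cohort(n, seed=27)
        logs = rng.standard_normal((n, 3))
        logs[:, 1] = 2.0
        m = build_matrix(logs, cohort["participant_id"])
        score = pd.Series(rng.random(n), index=pd.Index(cohort["participant_id"]))
        with pytest.warns(UserWarning, match="zero-variance"):
            res = differential_abundance(m, cohort, "pfs_linear", score=score)
        assert "P1" not in set(res["protein_id"])

    def test_mortality_cox_route_finds_planted_hazard_protein(self):
        rng = np.random.default_rng(28)
        n = 1000
        z = rng.standard_normal(n)
        cohort = make_survival_cohort(n, seed=29, lp=0.8 * z)
        logs = np.column_stack([z, rng.standard_normal(n), rng.standard_normal(n)])
        m = build_matrix(logs, cohort["participant_id"])
        res = differential_abundance(m, cohort, "mortality_cox").set_index("protein_id")
        assert res.loc["P0", "adj_p"] < 1e-6
        assert res.loc["P0", "beta"] == pytest.approx(0.8, abs=3 * res.loc["P0", "se"])


class TestCrossTimepoint:
    def frame(self, sig):
        return pd.DataFrame({"protein_id": list(sig), "adj_p": [0.01 if v else 0.5 for v in sig.values()],
                             "beta": 0.1, "p": 0.01})

    def test_protein_significant_everywhere_included_for_any_k(self):
        results = [self.frame({"A": True, "B": False}) for _ in range(4)]
        for k in (1, 2, 3, 4):
            out = cross_timepoint_consistency(results, k=k)
            assert "A" in set(out["protein_id"])

    def test_nothing_significant_gives_empty(self):
        results = [self.frame({"A": False}) for _ in range(3)]
        assert cross_timepoint_consistency(results, 2).empty

    def test_persistent_signal_enriched_over_one_off(self):
        results = [self.frame({"persistent": True, "oneoff": t == 0}) for t in range(4)]
        out = cross_timepoint_consistency(results, 2)
        assert set(out["protein_id"]) == {"persistent"}

    def test_k_exceeding_timepoints_rejected(self):
        with pytest.raises(ValueError):
            cross_timepoint_consistency([self.frame({"A": True})], 2)


class TestElasticNetCox:
    def test_planted_hazard_proteins_selected_small_scale(self):
        rng = np.random.default_rng(30)
        n, p, k = 600, 80, 5
        logs = rng.standard_normal((n, p))
        lp = logs[:, :k] @ np.full(k, 0.4)
        cohort = make_survival_cohort(n, seed=31, lp=lp)
        m = build_matrix(logs, cohort["participant_id"])
        res = elastic_net_cox(m, cohort, n_folds=5, seed=32)
        assert set(f"P{j}" for j in range(k)) <= set(res.selected)
        assert res.cv_cindex > 0.6
        assert res.alpha_mixing == 0.5

    def test_seed_fixed_reproducible(self):
        rng = np.random.default_rng(33)
        n, p = 300, 40
        logs = rng.standard_normal((n, p))
        cohort = make_survival_cohort(n, seed=34, lp=0.5 * logs[:, 0])
        m = build_matrix(logs, cohort["participant_id"])
        r1 = elastic_net_cox(m, cohort, n_folds=4, seed=35)
        r2 = elastic_net_cox(m, cohort, n_folds=4, seed=35)
        assert r1.selected == r2.selected
        assert r1.lambda_chosen == r2.lambda_chosen
        assert r1.cv_cindex == r2.cv_cindex
        np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)

    def test_path_sparsity_monotone_in_lambda(self):
        rng = np.random.default_rng(36)
        n, p = 400, 60
        logs = rng.standard_normal((n, p))
        cohort = make_survival_cohort(n, seed=37, lp=0.5 * logs[:, 0] + 0.4 * logs[:, 1])
        m = build_matrix(logs, cohort["participant_id"])
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        ids = pd.Index(cohort["participant_id"])
        Z = np.log10(m.abundance.loc[ids].to_numpy())
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        y = Surv.from_arrays(event=cohort["died"].to_numpy(bool), time=cohort["followup_years"].to_numpy())
        fit = CoxnetSurvivalAnalysis(l1_ratio=0.5, n_alphas=50, normalize=False).fit(Z, y)
        nnz = (fit.coef_ != 0).sum(axis=0)  # alphas_ descend, sparsity relaxes
        assert (np.diff(nnz) >= 0).mean() > 0.9

    def test_too_few_events_rejected(self):
        rng = np.random.default_rng(38)
        cohort = make_survival_cohort(30, seed=39, target=0.1)
        m = build_matrix(rng.standard_normal((30, 5)), cohort["participant_id"])
        cohort["died"] = False
        cohort.loc[0, "died"] = True
        with pytest.raises(ValueError):
            elastic_net_cox(m, cohort, n_folds=10)


class TestDecileBiomarker:
    def test_decile_size_is_ceil_tenth(self, rng):
        n = 505
        cohort = make_survival_cohort(n, seed=40)
        m = build_matrix(rng.standard_normal((n, 2)), cohort["participant_id"])
        x = m.abundance["P0"].to_numpy()
        q = np.quantile(x, 0.1)
        assert (x <= q).sum() == int(np.ceil(0.1 * n))

    def test_planted_double_odds_recovered(self):
        """Bottom-decile membership planted at log-OR log(2) is covered."""
        rng = np.random.default_rng(41)
        n = 4000
        logs = rng.standard_normal((n, 2))
        flag = logs[:, 0] <= np.quantile(logs[:, 0], 0.1)
        p = 1.0 / (1.0 + np.exp(-(-1.9 + np.log(2.0) * flag)))
        cohort = make_survival_cohort(n, seed=42)
        cohort["died"] = rng.random(n) < p
        m = build_matrix(logs, cohort["participant_id"])
        fit = decile_biomarker_risk(m, "P0", cohort, tail="bottom")["decile"]
        assert fit.ci_low < 2.0 < fit.ci_high

    def test_null_protein_odds_near_one(self, rng):
        n = 3000
        cohort = make_survival_cohort(n, seed=43)
        m = build_matrix(rng.standard_normal((n, 1)), cohort["participant_id"])
        fit = decile_biomarker_risk(m, "P0", cohort)["decile"]
        assert fit.ci_low < 1.0 < fit.ci_high

    def test_comparator_reported_side_by_side(self, rng):
        n = 500
        cohort = make_survival_cohort(n, seed=44)
        m = build_matrix(rng.standard_normal((n, 1)), cohort["participant_id"])
        comp = pd.Series(rng.random(n) < 0.3, index=pd.Index(cohort["participant_id"]))
        out = decile_biomarker_risk(m, "P0", cohort, comparator=comp)
        assert "comparator" in out

    def test_tied_decile_rejected(self):
        n = 100
        cohort = make_survival_cohort(n, seed=45)
        logs = np.zeros((n, 1))  # all tied
        m = build_matrix(logs, cohort["participant_id"])
        with pytest.raises(ValueError, match="degenerate"):
            decile_biomarker_risk(m, "P0", cohort)


class TestExposureProfile:
    def test_planted_links_significant_others_null(self):
        from lifeclocks import CohortConfig, generate_cohort

        cohort, _ = generate_cohort(CohortConfig(n=8000), seed=46)
        rng = np.random.default_rng(47)
        z = (0.5 * cohort["education_high"].astype(float).to_numpy()
             + 0.5 * cohort["activity_sustained"].astype(float).to_numpy()
             + rng.standard_normal(len(cohort)))
        m = build_matrix(z[:, None] * 0.2, cohort["participant_id"])
        res = exposure_profile_of_protein(m, "P0", cohort).set_index("term")
        assert res.loc["education_high", "p"] < 1e-6
        assert res.loc["activity_sustained", "p"] < 1e-6
        assert res.loc["adolescent_overweight", "p"] > 0.001
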