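"""PheWAS engine: case/control rules, logistic oracle checks, multiplicity,
positive controls, skewness, stratification, concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from predscan import (
    PhecodeDefinition,
    PositiveControlSpec,
    adjust_multiplicity,
    assemble_case_control,
    compute_skewness,
    direction_concordance,
    evaluate_positive_controls,
    fit_logistic,
    run_phewas,
    simulate_covariates,
    stratified_association,
)
from predscan.phewas import PhenotypeRejected, _assign_ranks
from predscan.projection import ScoreVector

from conftest import make_result


def occurrences(rows):
    return pd.DataFrame(rows, columns=["sample_id", "phecode", "count"])


@pytest.fixture(scope="module")
def cohort_cov():
    return simulate_covariates([f"S{i}" for i in range(2000)], seed=50, n_sites=2)


class TestAssembleCaseControl:
    def setup_method(self):
        self.defn = PhecodeDefinition("401", "hypertension", ("401.1",))

    def test_single_occurrence_makes_a_case(self, cohort_cov):
        occ = occurrences([(f"S{i}", "401", 1) for i in range(400)])
        a = assemble_case_control(occ, self.defn, cohort_cov, min_cases=300,
                                  min_site_cases=0)
        assert a.status.loc["S0"] == "case"
        assert a.n_cases == 400

    def test_exclusion_code_only_carrier_is_excluded(self, cohort_cov):
        occ = occurrences(
            [(f"S{i}", "401", 1) for i in range(400)] + [("S1500", "401.1", 1)]
        )
        a = assemble_case_control(occ, self.defn, cohort_cov, min_cases=300,
                                  min_site_cases=0)
        assert a.status.loc["S1500"] == "excluded"

    def test_case_with_exclusion_code_stays_a_case(self, cohort_cov):
        occ = occurrences([(f"S{i}", "401", 1) for i in range(400)]
                          + [("S0", "401.1", 1)])
        a = assemble_case_control(occ, self.defn, cohort_cov, min_cases=300,
                                  min_site_cases=0)
        assert a.status.loc["S0"] == "case"

    def test_below_min_cases_rejected(self, cohort_cov):
        occ = occurrences([(f"S{i}", "401", 1) for i in range(299)])
        with pytest.raises(PhenotypeRejected, match="299 cases"):
            assemble_case_control(occ, self.defn, cohort_cov, min_cases=300,
                                  min_site_cases=0)

    def test_single_gender_phenotype_rejected(self, cohort_cov):
        defn = PhecodeDefinition("635", "", (), sex_restriction="female")
        occ = occurrences([(f"S{i}", "635", 1) for i in range(400)])
        with pytest.raises(PhenotypeRejected, match="single-gender"):
            assemble_case_control(occ, defn, cohort_cov)

    def test_low_case_site_excluded_wholesale(self, cohort_cov):
        site = cohort_cov["site"]
        site0 = cohort_cov.index[site == "site_0"]
        site1 = cohort_cov.index[site == "site_1"]
        occ = occurrences(
            [(s, "401", 1) for s in site0[:400]] + [(s, "401", 1) for s in site1[:5]]
        )
        a = assemble_case_control(occ, self.defn, cohort_cov, min_cases=300,
                                  min_site_cases=10)
        assert a.excluded_sites == ("site_1",)
        assert (a.status.loc[site1] == "excluded").all()
        assert a.n_cases == 400

    def test_controls_outside_case_birth_decades_excluded(self):
        cov = simulate_covariates([f"S{i}" for i in range(1200)], seed=51,
                                  n_sites=1)
        young = cov["birth_decade"] >= 1950
        case_ids = cov.index[young][:400]
        occ = occurrences([(s, "401", 1) for s in case_ids])
        a = assemble_case_control(occ, self.defn, cov, min_cases=300,
                                  min_site_cases=0)
        old_controls = cov.index[(cov["birth_decade"] < 1950)]
        assert (a.status.loc[old_controls] != "control").all()
        lo, hi = a.case_birth_decades
        ctrl_dec = cov.loc[a.control_ids(), "birth_decade"]
        assert ctrl_dec.between(lo, hi).all()

    def test_case_and_control_sets_disjoint(self, cohort_cov):
        occ = occurrences([(f"S{i}", "401", 1) for i in range(400)])
        a = assemble_case_control(occ, self.defn, cohort_cov, min_cases=300,
                                  min_site_cases=0)
        assert not set(a.case_ids()) & set(a.control_ids())
        assert a.n_cases + a.n_controls + (a.status == "excluded").sum() == 2000

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assemble_case_control(occurrences([]), self.defn,
                                  pd.DataFrame(columns=["sample_id"]))


class TestFitLogistic:
    def test_matches_contingency_table_log_odds(self):
        # 2x2 oracle: status vs dichotomized score without covariates
        n = np.array([[300, 100], [200, 400]])  # rows: x=0/1, cols: ctrl/case
        y = np.concatenate([np.zeros(300), np.ones(100), np.zeros(200), np.ones(400)])
        x = np.concatenate([np.zeros(400), np.ones(600)])
        expected = np.log(n[1, 1] * n[0, 0] / (n[1, 0] * n[0, 1]))
        fit = fit_logistic(y, x)
        assert fit.converged
        assert fit.beta == pytest.approx(expected, abs=1e-6)

    def test_permuted_score_pvalues_are_uniform(self):
        rng = np.random.default_rng(60)
        n = 300
        y = (rng.random(n) < 0.3).astype(float)
        x = rng.standard_normal(n)
        pvals = []
        for _ in range(500):
            fit = fit_logistic(y, rng.permutation(x))
            pvals.append(fit.p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_perfect_separation_flagged_not_fatal(self):
        y = np.array([0.0] * 20 + [1.0] * 20)
        x = np.concatenate([np.linspace(-2, -1, 20), np.linspace(1, 2, 20)])
        fit = fit_logistic(y, x)
        assert not fit.converged
        assert np.isnan(fit.beta)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones(10), np.arange(10.0))

    def test_beta_invariant_to_raw_score_rescaling(self, cohort_cov):
        # the per-SD convention: standardized input, so doubling the raw
        # scale then re-standardizing changes nothing
        rng = np.random.default_rng(61)
        raw = rng.standard_normal(2000)
        y = (rng.random(2000) < 0.2).astype(float)
        s1 = (raw - raw.mean()) / raw.std()
        raw2 = raw * 2.0
        s2 = (raw2 - raw2.mean()) / raw2.std()
        f1 = fit_logistic(y, s1, cohort_cov)
        f2 = fit_logistic(y, s2, cohort_cov)
        assert f1.beta == pytest.approx(f2.beta, abs=1e-8)


class TestAdjustMultiplicity:
    def test_experiment_wide_bonferroni_threshold(self):
        results = [make_result(p=1e-8)]
        _, th = adjust_multiplicity(results, n_biomarkers=53, n_phenotypes=1139)
        assert th["bonferroni_threshold"] == pytest.approx(8.28e-7, rel=5e-3)

    def test_bh_stepup_arithmetic(self):
        results = [make_result(phecode=str(i), p=p)
                   for i, p in enumerate([0.01, 0.02, 0.03, 0.04])]
        results, _ = adjust_multiplicity(results, 1, 4)
        assert all(r.q == pytest.approx(0.04, abs=1e-12) for r in results)

    def test_all_unit_pvalues_give_unit_q_no_flags(self):
        results = [make_result(phecode=str(i), p=1.0) for i in range(5)]
        results, _ = adjust_multiplicity(results, 1, 5)
        assert all(r.q == 1.0 for r in results)
        assert not any(r.fdr_significant or r.bonferroni_significant for r in results)

    @staticmethod
    def bh_oracle(pvals):
        # brute-force step-up: q_i = min over j with p_j >= p_i of m*p_j/rank_j
        m = len(pvals)
        order = np.argsort(pvals, kind="stable")
        q = np.empty(m)
        running = np.inf
        for rank_from_top in range(m, 0, -1):
            idx = order[rank_from_top - 1]
            running = min(running, m * pvals[idx] / rank_from_top)
            q[idx] = min(running, 1.0)
        return q

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=20))
    def test_bh_matches_brute_force_oracle(self, pvals):
        results = [make_result(phecode=str(i), p=p) for i, p in enumerate(pvals)]
        results, _ = adjust_multiplicity(results, 1, len(pvals))
        expected = self.bh_oracle(np.array(pvals))
        got = np.array([r.q for r in results])
        np.testing.assert_allclose(got, expected, atol=1e-12)
        # q monotone non-decreasing in p-rank
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(got[order]) >= -1e-12)

    def test_q_never_below_p_within_family(self):
        rng = np.random.default_rng(62)
        results = [make_result(phecode=str(i), p=p)
                   for i, p in enumerate(rng.random(15))]
        results, _ = adjust_multiplicity(results, 1, 15)
        assert all(r.q >= r.p - 1e-12 for r in results)

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError, match="no results"):
            adjust_multiplicity([], 1, 1)

    def test_per_biomarker_vs_global_family(self):
        results = [make_result(biomarker="a", phecode="1", p=0.001),
                   make_result(biomarker="a", phecode="2", p=0.5),
                   make_result(biomarker="b", phecode="1", p=0.04)]
        per, _ = adjust_multiplicity(results, 2, 2, fdr_family="per_biomarker")
        assert per[2].q == pytest.approx(0.04)
        results2 = [make_result(biomarker="a", phecode="1", p=0.001),
                    make_result(biomarker="a", phecode="2", p=0.5),
                    make_result(biomarker="b", phecode="1", p=0.04)]
        glob, _ = adjust_multiplicity(results2, 2, 2, fdr_family="global")
        assert glob[2].q == pytest.approx(3 * 0.04 / 2)


class TestPositiveControls:
    def make_results(self):
        results = [make_result(phecode=str(i), p=0.5 / (i + 1)) for i in range(10)]
        _assign_ranks(results)
        results, _ = adjust_multiplicity(results, 1, 10)
        return results

    def test_top_rank_category_detected(self):
        results = self.make_results()
        best = min(results, key=lambda r: r.rank)
        specs = [PositiveControlSpec("bm", (best.phecode,))]
        cats, summary = evaluate_positive_controls(results, specs)
        assert "top_rank" in cats["bm"]
        assert summary["pct_top_rank"] == 100.0

    def test_unresolvable_control_is_untestable(self):
        results = self.make_results()
        specs = [PositiveControlSpec("bm", ("nonexistent",))]
        cats, summary = evaluate_positive_controls(results, specs)
        assert "bm" not in cats
        assert summary["n_untestable"] == 1

    def test_bonferroni_implies_fdr_at_default_thresholds(self):
        results = [make_result(phecode="1", p=1e-9),
                   make_result(phecode="2", p=0.8)]
        _assign_ranks(results)
        results, _ = adjust_multiplicity(results, 1, 2)
        cats, _ = evaluate_positive_controls(
            results, [PositiveControlSpec("bm", ("1",))]
        )
        assert {"bonferroni", "fdr"} <= cats["bm"]

    def test_no_category_reported_as_none(self):
        results = [make_result(phecode=str(i), p=0.9, rank=float(i + 6))
                   for i in range(3)]
        for r in results:
            r.q = 0.9
        cats, summary = evaluate_positive_controls(
            results, [PositiveControlSpec("bm", ("0",))]
        )
        assert cats["bm"] == {"none"}

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_positive_controls(self.make_results(), [])


class TestSkewness:
    def results_from_betas(self, betas, n_cases=500):
        return [make_result(phecode=str(i), beta=b, q=0.5, n_cases=n_cases)
                for i, b in enumerate(betas)]

    def test_symmetric_betas_give_zero(self):
        assert compute_skewness(self.results_from_betas([-0.4, 0.0, 0.4])) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_constant_positive_betas_give_one(self):
        assert compute_skewness(self.results_from_betas([0.3] * 5)) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_negating_betas_negates_statistic(self):
        betas = [0.1, 0.5, -0.2, 0.3, 0.05]
        s1 = compute_skewness(self.results_from_betas(betas))
        s2 = compute_skewness(self.results_from_betas([-b for b in betas]))
        assert s2 == pytest.approx(-s1, abs=1e-12)

    def test_scale_invariance(self):
        betas = [0.1, 0.5, -0.2, 0.3, 0.05]
        s1 = compute_skewness(self.results_from_betas(betas))
        s2 = compute_skewness(self.results_from_betas([7.3 * b for b in betas]))
        assert s2 == pytest.approx(s1, abs=1e-10)

    def test_low_case_and_fdr_significant_results_filtered(self):
        kept = self.results_from_betas([0.2, 0.2, 0.2])
        low = self.results_from_betas([5.0], n_cases=10)
        sig = self.results_from_betas([-5.0])
        sig[0].q = 0.01
        assert compute_skewness(kept + low + sig) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_retained_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            compute_skewness(self.results_from_betas([0.1, 0.2]))

    def test_all_zero_betas_flagged_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = compute_skewness(self.results_from_betas([0.0] * 5))
        assert np.isnan(out)


class TestConcordance:
    def test_identical_results_fully_concordant(self):
        res = [make_result(phecode=str(i), beta=0.2, p=0.01) for i in range(5)]
        frac, n = direction_concordance(res, res)
        assert frac == 1.0 and n == 5

    def test_negated_betas_fully_discordant(self):
        a = [make_result(phecode=str(i), beta=0.2, p=0.01) for i in range(5)]
        b = [make_result(phecode=str(i), beta=-0.2, p=0.01) for i in range(5)]
        assert direction_concordance(a, b)[0] == 0.0

    def test_pairs_failing_p_filter_leave_denominator(self):
        a = [make_result(phecode=str(i), beta=0.2, p=0.01) for i in range(4)]
        b = [make_result(phecode="0", beta=0.2, p=0.05),
             make_result(phecode="1", beta=-0.2, p=0.5),
             make_result(phecode="2", beta=0.2, p=0.09),
             make_result(phecode="3", beta=-0.2, p=0.95)]
        frac, n = direction_concordance(a, b, p_filter=0.1)
        assert n == 2 and frac == 1.0

    def test_empty_join_flagged_undefined(self):
        a = [make_result(phecode="0", p=0.01)]
        b = [make_result(phecode="0", p=0.9)]
        with pytest.warns(UserWarning, match="undefined"):
            frac, n = direction_concordance(a, b)
        assert np.isnan(frac) and n == 0


class TestStratifiedAndScan:
    def make_scan(self, seed, planted_log_or=0.6, n=3000):
        rng = np.random.default_rng(seed)
        cov = simulate_covariates([f"S{i}" for i in range(n)], seed=seed,
                                  n_sites=1, n_platforms=1)
        score = rng.standard_normal(n)
        score = (score - score.mean()) / score.std()
        sv = ScoreVector(samples=list(cov["sample_id"]), raw=score,
                         standardized=score, biomarker="bm")
        from scipy.special import expit

        prob = expit(np.log(0.15 / 0.85) + planted_log_or * score)
        status = pd.Series(
            np.where(rng.random(n) < prob, "case", "control"),
            index=cov.index,
        )
        from predscan.phewas import CaseControlAssignment

        a = CaseControlAssignment(
            phecode="250", status=status,
            n_cases=int((status == "case").sum()),
            n_controls=int((status == "control").sum()),
        )
        return sv, a, cov

    def test_duplicate_phecode_rejected(self):
        sv, a, cov = self.make_scan(70)
        with pytest.raises(ValueError, match="duplicate"):
            run_phewas(sv, [a, a], cov)

    def test_nonconverged_results_excluded_from_ranking(self):
        results = [make_result(phecode="1", p=0.5),
                   make_result(phecode="2", p=0.01),
                   make_result(phecode="3", p=np.nan, converged=False)]
        _assign_ranks(results)
        assert results[1].rank == 1.0
        assert np.isnan(results[2].rank)

    def test_homogeneous_effect_similar_across_strata(self):
        # under a shared effect the stratum estimates must agree: Wald test
        # of equality non-significant in >= 90% of seeds (CI *containment*
        # of one point estimate in the other stratum's interval only holds
        # ~83% of the time even under perfect homogeneity, since the
        # difference carries both standard errors)
        hits = 0
        for seed in range(10):
            sv, a, cov = self.make_scan(700 + seed, n=8000)
            strat = pd.Series(
                np.random.default_rng(seed).integers(0, 2, len(cov)),
                index=cov.index,
            )
            out = stratified_association(sv, a, cov, strat)
            r0, r1 = out["0"], out["1"]
            if r0 is None or r1 is None:
                continue
            z = (r1.beta - r0.beta) / np.hypot(r0.se, r1.se)
            hits += abs(z) < 1.96
        assert hits >= 9

    def test_stratum_specific_effect_detected_only_in_affected_stratum(self):
        from scipy.special import expit

        detected, null_sig = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(800 + seed)
            n = 8000
            cov = simulate_covariates([f"S{i}" for i in range(n)], seed=seed,
                                      n_sites=1, n_platforms=1)
            score = rng.standard_normal(n)
            strat = pd.Series(rng.integers(0, 2, n), index=cov.index)
            log_or = np.where(strat == 1, 0.5, 0.0)
            prob = expit(np.log(0.15 / 0.85) + log_or * score)
            status = pd.Series(np.where(rng.random(n) < prob, "case", "control"),
                               index=cov.index)
            from predscan.phewas import CaseControlAssignment

            a = CaseControlAssignment("250", status,
                                      int((status == "case").sum()),
                                      int((status == "control").sum()))
            sv = ScoreVector(list(cov["sample_id"]), score,
                             (score - score.mean()) / score.std(), "bm")
            out = stratified_association(sv, a, cov, strat)
            detected += out["1"].p < 0.05
            null_sig += out["0"].p < 0.05
        assert detected >= 8
        assert null_sig <= 3

    def test_constant_stratifier_rejected(self):
        sv, a, cov = self.make_scan(71)
        strat = pd.Series(np.zeros(len(cov)), index=cov.index)
        with pytest.raises(ValueError, match="constant"):
            stratified_association(sv, a, cov, strat)
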