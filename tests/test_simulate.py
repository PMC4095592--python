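"""Cohort generator and risk-set sampling tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bcrisk import published
from bcrisk.simulate import (
    CohortParams,
    MatchingSpec,
    SnpSpec,
    matched_sets_frame,
    sample_nested_case_control,
    simulate_cohort,
    simulate_published_studies,
)

DAYS = 365.25


def null_params(n=4000, hazard=0.01, seed=0, **kw):
    """Cohort with no SNP or covariate effects: pure exponential survival."""
    panel = [SnpSpec(f"rs{i}", "A", 0.3, 0.0) for i in range(5)]
    return CohortParams(
        n_subjects=n,
        baseline_hazard=hazard,
        snp_panel=panel,
        covariate_effects={},
        genotype_missing_rate=0.0,
        seed=seed,
        **kw,
    )


def matching_predicates_hold(cohort, sets, spec=MatchingSpec()):
    """Independent checker: every control matches its case on every rule."""
    c = cohort.set_index("subject_id")
    diag_cal = c["enrollment_date"] + c["diagnosis_time"] * DAYS
    for s in sets:
        case = c.loc[s.case_id]
        case_diag = diag_cal.loc[s.case_id]
        for cid in s.control_ids:
            ctrl = c.loc[cid]
            if abs(ctrl.age_at_enrollment - case.age_at_enrollment) > spec.age_caliper_years:
                return False
            if abs(ctrl.enrollment_date - case.enrollment_date) > spec.enrollment_caliper_days:
                return False
            if abs(ctrl.blood_draw_date - case.blood_draw_date) > spec.blood_draw_caliper_days:
                return False
            if ctrl.dialect != case.dialect or ctrl.menopausal_status != case.menopausal_status:
                return False
            if not np.isnan(diag_cal.loc[cid]) and diag_cal.loc[cid] <= case_diag:
                return False
    return True


class TestSimulateCohort:
    def test_null_case_proportion_matches_exponential_survival(self):
        params = null_params()
        cohort, _ = simulate_cohort(params)
        expected = 1 - np.exp(-params.baseline_hazard * params.followup_years)
        observed = (cohort.case_status == "case").mean()
        se = np.sqrt(expected * (1 - expected) / params.n_subjects)
        assert abs(observed - expected) < 4 * se

    def test_deterministic_under_fixed_seed(self):
        c1, g1 = simulate_cohort(null_params(n=500, seed=7))
        c2, g2 = simulate_cohort(null_params(n=500, seed=7))
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_case_enrichment_matches_genotype_class_enumeration(self):
        """A log(2) SNP enriches the risk allele in cases by the amount an
        independent enumeration over the three genotype classes predicts."""
        beta, raf, lam, t = np.log(2), 0.3, 0.01, 15.0
        panel = [SnpSpec("rs1", "A", raf, beta)]
        params = CohortParams(
            n_subjects=40000,
            baseline_hazard=lam,
            snp_panel=panel,
            covariate_effects={},
            genotype_missing_rate=0.0,
            seed=11,
        )
        cohort, geno = simulate_cohort(params)
        case = cohort.case_status.to_numpy() == "case"
        raf_cases = geno["rs1"][case].mean() / 2
        raf_controls = geno["rs1"][~case].mean() / 2

        # oracle: P(case|g) = 1 - exp(-lam * e^{beta(g - 2 raf)} * t), HWE class weights
        probs = stats.binom.pmf([0, 1, 2], 2, raf)
        p_case = 1 - np.exp(-lam * np.exp(beta * (np.arange(3) - 2 * raf)) * t)
        exp_cases = (np.arange(3) * probs * p_case).sum() / (2 * (probs * p_case).sum())
        exp_controls = (np.arange(3) * probs * (1 - p_case)).sum() / (
            2 * (probs * (1 - p_case)).sum()
        )
        assert raf_cases > raf_controls
        assert raf_cases - raf_controls == pytest.approx(exp_cases - exp_controls, abs=0.01)

    def test_invalid_hazard_rejected(self):
        with pytest.raises(ValueError, match="baseline_hazard"):
            null_params(hazard=-1.0)

    def test_control_genotypes_fit_hardy_weinberg(self):
        """Null-SNP HWE P values in controls are uniform: median near 0.5."""
        from bcrisk.qc import genotype_counts, hwe_chisq_test

        params = null_params(n=3000, seed=5)
        cohort, geno = simulate_cohort(params)
        controls = geno[cohort.case_status.to_numpy() == "control"]
        pvals = [hwe_chisq_test(genotype_counts(controls[c])).p_value for c in geno]
        assert 0.1 < np.median(pvals) < 0.9


class TestRiskSetSampling:
    def test_sets_pass_independent_matching_checker(self):
        cohort, _ = simulate_cohort(null_params(n=4000, hazard=0.02, seed=2))
        sets = sample_nested_case_control(cohort, seed=3)
        assert len(sets) > 0
        assert matching_predicates_hold(cohort, sets)

    def test_saturated_eligibility_gives_full_sets(self):
        """When every non-case matches every case, each set has 3 controls."""
        n = 40
        cohort = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "case_status": ["case"] * 3 + ["control"] * (n - 3),
                "age_at_enrollment": 55.0,
                "dialect": "Hokkien",
                "menopausal_status": "post",
                "enrollment_date": 100,
                "blood_draw_date": 400,
                "diagnosis_time": [1.0, 2.0, 3.0] + [np.nan] * (n - 3),
            }
        )
        sets = sample_nested_case_control(cohort, seed=0)
        assert len(sets) == 3
        assert all(len(s.control_ids) == 3 for s in sets)

    def test_two_control_sets_retained_and_prior_cases_excluded(self):
        """A case with exactly two eligible controls keeps its set; a subject
        already diagnosed by the index date is never selected."""
        cohort = pd.DataFrame(
            {
                "subject_id": ["case1", "early_case", "c1", "c2"],
                "case_status": ["case", "case", "control", "control"],
                "age_at_enrollment": 55.0,
                "dialect": "Hokkien",
                "menopausal_status": "post",
                "enrollment_date": 100,
                "blood_draw_date": 400,
                "diagnosis_time": [5.0, 1.0, np.nan, np.nan],
            }
        )
        sets = sample_nested_case_control(cohort, seed=0)
        by_case = {s.case_id: s for s in sets}
        # the subject diagnosed at year 1 is never a control at year 5 ...
        assert set(by_case["case1"].control_ids) == {"c1", "c2"}
        # ... but the year-5 case is a legitimate risk-set control at year 1
        assert "case1" in by_case["early_case"].control_ids

    def test_cases_with_too_few_controls_dropped(self, caplog):
        cohort = pd.DataFrame(
            {
                "subject_id": ["case1", "c1"],
                "case_status": ["case", "control"],
                "age_at_enrollment": 55.0,
                "dialect": "Hokkien",
                "menopausal_status": "post",
                "enrollment_date": 100,
                "blood_draw_date": 400,
                "diagnosis_time": [5.0, np.nan],
            }
        )
        with caplog.at_level("WARNING"):
            sets = sample_nested_case_control(cohort, seed=0)
        assert sets == []
        assert "dropped" in caplog.text

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            sample_nested_case_control(pd.DataFrame(columns=["case_status"]))

    def test_membership_frame_layout(self):
        cohort, _ = simulate_cohort(null_params(n=2000, hazard=0.02, seed=9))
        sets = sample_nested_case_control(cohort, seed=1)
        frame = matched_sets_frame(sets)
        assert list(frame.columns) == ["set_id", "subject_id", "role"]
        assert (frame.groupby("set_id")["role"].apply(lambda r: (r == "case").sum()) == 1).all()


class TestSimulatedStudies:
    def test_zero_spread_gives_identical_effects(self):
        panel = [SnpSpec("rs1", "A", 0.3, 0.1), SnpSpec("rs2", "A", 0.4, -0.05)]
        studies = simulate_published_studies(panel, k_studies=4, seed=0)
        assert (studies.groupby("rsid")["beta"].nunique() == 1).all()

    def test_single_study_pools_to_itself(self):
        from bcrisk.meta import pool_studies

        panel = [SnpSpec("rs1", "A", 0.3, 0.12)]
        studies = simulate_published_studies(panel, k_studies=1, seed=0)
        pooled = pool_studies(studies)
        assert pooled.pooled_beta.iloc[0] == pytest.approx(0.12)
        assert pooled.pooled_se.iloc[0] == pytest.approx(studies.se.iloc[0])

    def test_heterogeneous_snp_flagged_with_monte_carlo_power(self):
        """A SNP with large between-study spread triggers the heterogeneity
        rule with the power a direct Monte-Carlo oracle predicts."""
        from bcrisk.meta import cochran_q, fixed_effects_pool

        panel = [SnpSpec("rs_het", "A", 0.3, 0.1)]
        hits = 0
        reps = 200
        for r in range(reps):
            studies = simulate_published_studies(
                panel, k_studies=3, heterogeneous_snps=("rs_het",),
                seed=r, heterogeneity_sd=0.3,
            )
            pb, _ = fixed_effects_pool(studies.beta, studies.se)
            _, _, p = cochran_q(studies.beta, studies.se, pb)
            hits += p < 0.007

        # oracle: same mechanism simulated directly from its definition
        rng = np.random.default_rng(12345)
        oracle_hits = 0
        for _ in range(2000):
            betas = 0.1 + rng.normal(0, 0.3, 3)
            ses = rng.uniform(0.03, 0.08, 3)
            w = 1 / ses**2
            pb = (w * betas).sum() / w.sum()
            q = (w * (betas - pb) ** 2).sum()
            oracle_hits += stats.chi2.sf(q, 2) < 0.007
        power = oracle_hits / 2000
        assert hits / reps == pytest.approx(power, abs=0.1)

    def test_unknown_heterogeneous_snp_rejected(self):
        panel = [SnpSpec("rs1", "A", 0.3, 0.1)]
        with pytest.raises(ValueError, match="not in panel"):
            simulate_published_studies(panel, 2, heterogeneous_snps=("rsX",))
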