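"""Meta-analysis pooling, heterogeneity, FDR and the genetic risk score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bcrisk import published
from bcrisk.meta import (
    bh_fdr,
    cochran_q,
    compute_grs,
    fixed_effects_pool,
    grs_quartiles,
    pool_studies,
    select_grs_snps,
)


class TestPooling:
    def test_single_study_identity(self):
        assert fixed_effects_pool([0.1], [0.2]) == pytest.approx((0.1, 0.2))

    def test_equal_se_symmetry(self):
        pb, _ = fixed_effects_pool([0.1, 0.3], [0.15, 0.15])
        assert pb == pytest.approx(0.2)

    def test_hand_arithmetic_oracle(self):
        # three studies, w = 1/se^2 = 100, 25, 4
        betas, ses = [0.10, 0.30, -0.20], [0.1, 0.2, 0.5]
        w = np.array([100.0, 25.0, 4.0])
        expected_beta = (w * betas).sum() / w.sum()  # = (10+7.5-0.8)/129
        expected_se = w.sum() ** -0.5
        pb, pse = fixed_effects_pool(betas, ses)
        assert pb == pytest.approx(expected_beta)
        assert pse == pytest.approx(expected_se)

    def test_pooled_se_never_exceeds_best_study(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ses = rng.uniform(0.05, 0.5, rng.integers(1, 6))
            _, pse = fixed_effects_pool(np.zeros(len(ses)), ses)
            assert pse <= ses.min() + 1e-12

    def test_zero_studies_rejected(self):
        with pytest.raises(ValueError):
            fixed_effects_pool([], [])


class TestCochranQ:
    def test_identical_effects_zero_q(self):
        q, _, p = cochran_q([0.2, 0.2, 0.2], [0.1, 0.1, 0.1], 0.2)
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic_oracle(self):
        # k=2, betas (0, 0.2), se 0.1 each -> w=100; Q = 100*0.01 + 100*0.01 = 2
        pb, _ = fixed_effects_pool([0.0, 0.2], [0.1, 0.1])
        q, df, p = cochran_q([0.0, 0.2], [0.1, 0.1], pb)
        assert q == pytest.approx(2.0)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_single_study_convention(self):
        assert cochran_q([0.1], [0.2], 0.1) == (0.0, 0, 1.0)

    def test_null_q_follows_chi_square(self):
        """Under homogeneity Q ~ chi2(k-1): QQ agreement over 10,000 draws."""
        rng = np.random.default_rng(123)
        k = 3
        qs = []
        for _ in range(10000):
            ses = rng.uniform(0.05, 0.3, k)
            betas = rng.normal(0, ses)
            pb, _ = fixed_effects_pool(betas, ses)
            qs.append(cochran_q(betas, ses, pb)[0])
        u = stats.chi2.cdf(qs, k - 1)
        d, p = stats.kstest(u, "uniform")
        assert p > 0.001


class TestBhFdr:
    def test_step_up_forces_equal_adjusted(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.4])[0] == pytest.approx(0.4)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10))
    def test_matches_brute_force_definition(self, pvals):
        adjusted = bh_fdr(pvals)
        m = len(pvals)
        order = np.argsort(pvals, kind="stable")
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(1, m + 1)
        for i in range(m):
            # brute force: min over j with rank >= rank_i of m*p_j/rank_j
            candidates = [
                m * pvals[j] / ranks[j] for j in range(m) if ranks[j] >= ranks[i]
            ]
            assert adjusted[i] == pytest.approx(min(1.0, min(candidates)))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        np.testing.assert_allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


class TestSelection:
    def make_pooled(self, p_het_fdr):
        return pd.DataFrame(
            {
                "rsid": [f"rs{i}" for i in range(len(p_het_fdr))],
                "pooled_beta": 0.1,
                "pooled_se": 0.05,
                "k": 3,
                "q": 1.0,
                "p_het": p_het_fdr,
                "p_het_fdr": p_het_fdr,
            }
        )

    def test_no_heterogeneity_all_included(self):
        out = select_grs_snps(self.make_pooled([1.0] * 5))
        assert out.included_in_grs.all()

    def test_four_of_fiftyfive_excluded(self):
        """A 55-SNP panel with 4 heterogeneous SNPs keeps exactly 51."""
        p = [1.0] * 55
        for i in (3, 17, 30, 54):
            p[i] = 0.001
        out = select_grs_snps(self.make_pooled(p))
        assert out.included_in_grs.sum() == 51
        assert set(out.loc[~out.included_in_grs, "rsid"]) == {"rs3", "rs17", "rs30", "rs54"}

    def test_override_keeps_snp_with_local_weight(self):
        out = select_grs_snps(self.make_pooled([0.001, 1.0]), overrides=("rs0",))
        row = out.set_index("rsid").loc["rs0"]
        assert row.included_in_grs
        assert row.weight_source == "local_only"

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            select_grs_snps(self.make_pooled([1.0]), overrides=("rsX",))


def panel_effects():
    panel = published.snp_panel()
    return pd.DataFrame(
        {
            "rsid": panel.rsid,
            "pooled_beta": np.log(panel.or_pooled),
            "included_in_grs": True,
            "weight_source": np.where(panel.or_pooled.isna(), "local_only", "pooled"),
        }
    ), pd.Series(np.log(panel.or_local.to_numpy()), index=panel.rsid)


class TestGrs:
    def small_genotypes(self, n=50, seed=0):
        panel = published.snp_panel()
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.binomial(2, panel.raf_controls.to_numpy(), size=(n, 51)).astype(float),
            index=pd.Index([f"S{i}" for i in range(n)], name="subject_id"),
            columns=panel.rsid,
        )

    def test_zero_oriented_dosage_zero_score(self):
        effects, local = panel_effects()
        g = self.small_genotypes()
        pb = effects.set_index("rsid").pooled_beta.fillna(local)
        # put every subject at dosage 0 after orientation
        for rsid in g.columns:
            g[rsid] = 2.0 if pb[rsid] < 0 else 0.0
        res = compute_grs(g, effects, local)
        np.testing.assert_allclose(res.scores.raw_score, 0.0)
        np.testing.assert_allclose(res.scores.normalized_score, 0.0)

    def test_equal_weights_give_allele_count(self):
        rng = np.random.default_rng(1)
        g = pd.DataFrame(
            rng.binomial(2, 0.4, size=(30, 6)).astype(float),
            index=pd.Index([f"S{i}" for i in range(30)], name="subject_id"),
            columns=[f"rs{i}" for i in range(6)],
        )
        effects = pd.DataFrame(
            {"rsid": g.columns, "pooled_beta": 0.17, "included_in_grs": True,
             "weight_source": "pooled"}
        )
        res = compute_grs(g, effects)
        np.testing.assert_allclose(res.scores.normalized_score, g.sum(axis=1))

    def test_invariant_under_snp_permutation_and_orientation_flip(self):
        effects, local = panel_effects()
        g = self.small_genotypes(seed=2)
        base = compute_grs(g, effects, local).scores.normalized_score

        perm = list(np.random.default_rng(3).permutation(g.columns))
        permuted = compute_grs(g[perm], effects, local).scores.normalized_score
        np.testing.assert_allclose(base, permuted)

        # flip the coding of one input SNP and negate its effect: same score
        rsid = "rs2046210"
        g2 = g.copy()
        g2[rsid] = 2 - g2[rsid]
        effects2 = effects.copy()
        effects2.loc[effects2.rsid == rsid, "pooled_beta"] *= -1
        flipped = compute_grs(g2, effects2, local).scores.normalized_score
        np.testing.assert_allclose(base, flipped)

    def test_missing_imputed_with_expected_control_dosage(self):
        effects, local = panel_effects()
        g = self.small_genotypes(seed=4)
        rsid = g.columns[0]
        expected_fill = g[rsid].iloc[1:].mean()
        g_miss = g.copy()
        g_miss.loc[g_miss.index[0], rsid] = np.nan
        res = compute_grs(g_miss, effects, local)
        w = res.weights
        manual = g.iloc[0].copy()
        manual[rsid] = expected_fill
        pb = effects.set_index("rsid").pooled_beta.fillna(local)
        oriented = np.where(pb[g.columns] < 0, 2 - manual, manual)
        assert res.scores.normalized_score.iloc[0] == pytest.approx(
            float(oriented @ w[g.columns].to_numpy()) / w.mean()
        )

    def test_empty_inclusion_rejected(self):
        effects, local = panel_effects()
        effects["included_in_grs"] = False
        with pytest.raises(ValueError, match="no SNPs"):
            compute_grs(self.small_genotypes(), effects, local)


class TestQuartiles:
    def make_result(self, scores):
        from bcrisk.meta import GrsResult

        return GrsResult(
            scores=pd.DataFrame(
                {"subject_id": [f"S{i}" for i in range(len(scores))],
                 "raw_score": scores, "normalized_score": scores}
            ),
            weights=pd.Series([1.0], index=["rs1"]),
        )

    def test_linear_interpolation_boundaries(self):
        res = grs_quartiles(self.make_result(np.arange(1.0, 9.0)), [f"S{i}" for i in range(8)])
        assert res.quartile_boundaries == pytest.approx((2.75, 4.5, 6.25))

    def test_half_open_interval_assignment(self):
        res = self.make_result(np.r_[np.arange(1.0, 9.0), 2.75, 4.5, 6.25])
        controls = [f"S{i}" for i in range(8)]
        out = grs_quartiles(res, controls)
        q = out.scores.set_index("subject_id").quartile
        # boundary values fall in the upper interval (left-closed)
        assert q["S8"] == 2 and q["S9"] == 3 and q["S10"] == 4

    def test_degenerate_controls_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            grs_quartiles(self.make_result(np.ones(10)), [f"S{i}" for i in range(10)])

    def test_control_occupancy_uniform(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(50, 5, 2000)
        res = grs_quartiles(self.make_result(scores), [f"S{i}" for i in range(2000)])
        occ = res.scores.quartile.value_counts(normalize=True)
        assert occ.min() > 0.24 and occ.max() < 0.26
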