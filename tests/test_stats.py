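"""Statistical layer: KS screening, the paired-contrast ANOVA against
independent oracles, effect sizes, post hocs, rank correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import midrank_oracle, pearson_oracle
from neurowalk.stats import (bonferroni_pairwise, ks_normality,
                             partial_eta_squared, rm_anova_2x2,
                             spearman_correlation)


def make_table(M: np.ndarray) -> pd.DataFrame:
    """Long-format table from an (n_subjects, 4) cell matrix in the order
    (neu, elev), (neu, plank), (neg, elev), (neg, plank)."""
    cells = [("neutral", "elevator"), ("neutral", "plank"),
             ("negative", "elevator"), ("negative", "plank")]
    rows = []
    for s in range(M.shape[0]):
        for ci, (cond, task) in enumerate(cells):
            rows.append((f"S{s:02d}", cond, task, M[s, ci]))
    return pd.DataFrame(rows, columns=["subject", "condition", "task",
                                       "value"])


class TestKsNormality:
    def test_statistic_matches_cdf_gap_oracle(self, rng):
        x = rng.normal(3.0, 2.0, 60)
        d, _ = ks_normality(x, n_reps=100, seed=0)
        xs = np.sort(x)
        cdf = sps.norm.cdf(xs, loc=x.mean(), scale=x.std(ddof=1))
        n = len(x)
        gaps = []
        for i in range(n):
            gaps.append(abs((i + 1) / n - cdf[i]))
            gaps.append(abs(cdf[i] - i / n))
        assert d == pytest.approx(max(gaps), abs=1e-12)

    def test_normal_sample_usually_passes(self, rng):
        hits = 0
        for rep in range(40):
            x = np.random.default_rng(rep).normal(0, 1, 500)
            _, p = ks_normality(x, n_reps=400, seed=rep)
            hits += p > 0.05
        assert hits >= 36  # >= 90% of replicates

    def test_exponential_sample_usually_rejected(self):
        hits = 0
        for rep in range(40):
            x = np.random.default_rng(rep).exponential(1.0, 200)
            _, p = ks_normality(x, n_reps=400, seed=rep)
            hits += p < 0.05
        assert hits >= 38

    def test_agrees_with_table_based_lilliefors(self):
        """Cross-check the Monte-Carlo p against the published Lilliefors
        table implementation on the same samples."""
        from statsmodels.stats.diagnostic import lilliefors

        for rep in range(5):
            x = np.random.default_rng(100 + rep).normal(0, 1, 80)
            d_mine, p_mine = ks_normality(x, n_reps=4000, seed=rep)
            d_ref, p_ref = lilliefors(x, dist="norm")
            assert d_mine == pytest.approx(d_ref, abs=1e-10)
            assert p_mine == pytest.approx(min(p_ref, 0.999), abs=0.08)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ks_normality(np.full(10, 3.0))

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            ks_normality([1.0, 2.0, 3.0])


class TestRmAnova2x2:
    def test_constant_cells_degenerate_contract(self):
        res = rm_anova_2x2(make_table(np.full((6, 4), 3.25)))
        for eff in res.effects.values():
            assert eff.F == 0.0 and eff.p == 1.0

    def test_matches_paired_t_oracle(self, rng):
        M = rng.normal(10, 2, (4, 4))
        res = rm_anova_2x2(make_table(M))
        # independent oracle: scipy paired t on the explicit contrasts
        d_cond = (M[:, 2] + M[:, 3]) / 2 - (M[:, 0] + M[:, 1]) / 2
        d_task = (M[:, 1] + M[:, 3]) / 2 - (M[:, 0] + M[:, 2]) / 2
        d_int = (M[:, 3] - M[:, 2]) - (M[:, 1] - M[:, 0])
        for name, d in [("condition", d_cond), ("task", d_task),
                        ("condition x task", d_int)]:
            t, p = sps.ttest_1samp(d, 0.0)
            assert res[name].F == pytest.approx(t ** 2, abs=1e-10)
            assert res[name].p == pytest.approx(p, abs=1e-12)
            assert res[name].df_num == 1
            assert res[name].df_den == 3

    def test_matches_general_rm_anova_solver(self, rng):
        """Cross-check against the general repeated-measures ANOVA
        implementation (different algorithm: sums-of-squares decomposition)."""
        import pingouin as pg

        M = rng.normal(0, 1, (12, 4)) + rng.normal(0, 1, (12, 1))
        table = make_table(M)
        res = rm_anova_2x2(table)
        ref = pg.rm_anova(data=table, dv="value",
                          within=["condition", "task"], subject="subject",
                          detailed=True)
        for name, ref_name in [("condition", "condition"), ("task", "task"),
                               ("condition x task", "condition * task")]:
            row = ref[ref["Source"] == ref_name].iloc[0]
            assert res[name].F == pytest.approx(row["F"], rel=1e-8)
            assert res[name].p == pytest.approx(row["p_unc"], rel=1e-6)

    def test_factor_relabel_invariance(self, rng):
        M = rng.normal(0, 1, (8, 4))
        res1 = rm_anova_2x2(make_table(M))
        # swap condition levels: columns (0,1) <-> (2,3)
        res2 = rm_anova_2x2(make_table(M[:, [2, 3, 0, 1]]))
        for name in res1.effects:
            assert res1[name].F == pytest.approx(res2[name].F, abs=1e-10)

    def test_missing_cell_named(self):
        table = make_table(np.zeros((3, 4)))
        broken = table[~((table.subject == "S01")
                         & (table.condition == "negative")
                         & (table.task == "plank"))]
        with pytest.raises(ValueError, match="S01.*negative.*plank"):
            rm_anova_2x2(broken)

    def test_planted_condition_effect_detected_null_task_calibrated(self):
        """Only the factor with a planted shift should reject reliably."""
        cond_hits, task_hits = 0, 0
        n_reps = 200
        for rep in range(n_reps):
            r = np.random.default_rng(rep)
            subj = r.normal(0, 1, (30, 1))
            M = subj + r.normal(0, 1, (30, 4))
            M[:, 2:] += 0.8  # condition shift only
            res = rm_anova_2x2(make_table(M))
            cond_hits += res["condition"].p < 0.05
            task_hits += res["task"].p < 0.05
        assert cond_hits / n_reps > 0.95
        assert 0.01 <= task_hits / n_reps <= 0.10


class TestPartialEtaSquared:
    def test_zero_f(self):
        assert partial_eta_squared(0.0, 1, 74) == 0.0

    def test_consistency_with_anova_output(self, rng):
        res = rm_anova_2x2(make_table(rng.normal(0, 1, (10, 4))))
        for eff in res.effects.values():
            assert eff.eta_p_sq == pytest.approx(
                eff.F / (eff.F + eff.df_den), abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 1, 10)
        with pytest.raises(ValueError):
            partial_eta_squared(1.0, 0, 10)


class TestBonferroni:
    def test_single_comparison_unadjusted(self, rng):
        M = rng.normal(0, 1, (10, 4))
        res = bonferroni_pairwise(make_table(M),
                                  [(("neutral", "elevator"),
                                    ("negative", "elevator"))])
        row = res.comparisons.iloc[0]
        assert row.p_adj == pytest.approx(row.p_raw)

    def test_multiplication_and_cap(self, rng):
        M = rng.normal(0, 1, (10, 4))
        comps = [(("neutral", "elevator"), ("negative", "elevator")),
                 (("neutral", "plank"), ("negative", "plank")),
                 (("neutral", "elevator"), ("neutral", "plank")),
                 (("negative", "elevator"), ("negative", "plank"))]
        res = bonferroni_pairwise(make_table(M), comps)
        assert res.m == 4
        for _, row in res.comparisons.iterrows():
            assert row.p_adj == pytest.approx(min(1.0, 4 * row.p_raw))
            assert row.p_adj >= row.p_raw

    def test_matches_paired_t(self, rng):
        M = rng.normal(0, 1, (12, 4))
        res = bonferroni_pairwise(make_table(M),
                                  [(("neutral", "plank"),
                                    ("negative", "plank"))])
        t_ref, p_ref = sps.ttest_rel(M[:, 1], M[:, 3])
        row = res.comparisons.iloc[0]
        assert row.t == pytest.approx(t_ref, abs=1e-10)
        assert row.p_raw == pytest.approx(p_ref, abs=1e-12)


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.normal(0, 1, 30)
        rho, _ = spearman_correlation(x, np.exp(2 * x))
        assert rho == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = np.arange(10.0)
        rho, _ = spearman_correlation(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_tied_fixture_matches_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 3.0, 6.0])
        rho, _ = spearman_correlation(x, y)
        expected = pearson_oracle(midrank_oracle(x), midrank_oracle(y))
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0, 1, 25)
        rho1, p1 = spearman_correlation(x, y)
        rho2, p2 = spearman_correlation(np.tanh(x), y ** 3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation(np.ones(10), np.arange(10.0))
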