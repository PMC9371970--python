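"""Filtering, imputation, moderated tests, permutation FDR, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import celldissect as cd
from celldissect.proteomics import ProteinMatrix
from helpers import hypergeom_tail


def _pm(values: np.ndarray, groups: list[str]) -> ProteinMatrix:
    cols = [f"s{i}" for i in range(values.shape[1])]
    return ProteinMatrix(
        pd.DataFrame(values, index=[f"P{i}" for i in range(values.shape[0])], columns=cols),
        pd.Series(groups, index=cols),
    )


class TestFilterMatrix:
    def test_thirty_percent_boundary(self):
        vals = np.full((2, 10), 25.0)
        vals[0, :4] = np.nan  # 40% missing -> removed
        vals[1, :3] = np.nan  # 30% missing -> retained ("30% or less")
        pm = _pm(vals, ["A"] * 5 + ["B"] * 5)
        out = cd.filter_matrix(pm, max_missing_frac=0.30)
        assert list(out.values.index) == ["P1"]

    def test_zeros_treated_as_missing(self):
        vals = np.full((1, 10), 25.0)
        vals[0, :4] = 0.0
        out = cd.filter_matrix(_pm(vals, ["A"] * 5 + ["B"] * 5))
        assert out.values.empty

    def test_flagged_proteins_removed(self):
        vals = np.full((3, 4), 25.0)
        pm = _pm(vals, ["A", "A", "B", "B"])
        out = cd.filter_matrix(pm, flagged={"P0", "P2"})
        assert list(out.values.index) == ["P1"]

    def test_fully_observed_unchanged(self):
        vals = np.random.default_rng(0).normal(25, 1, (5, 6))
        pm = _pm(vals, ["A"] * 3 + ["B"] * 3)
        out = cd.filter_matrix(pm)
        pd.testing.assert_frame_equal(out.values, pm.values)


class TestImputeDownshift:
    def test_imputed_moments_match_stated_distribution(self):
        # column engineered to observed mean 25, sd 2 exactly; 10,000 missing
        rng = np.random.default_rng(0)
        obs = rng.normal(0, 1, 500)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 25.0
        col = np.concatenate([obs, np.full(10_000, np.nan)])
        other = np.full_like(col, 25.0)
        pm = _pm(np.column_stack([col, other]), ["A", "B"])
        out = cd.impute_downshift(pm, width=0.3, downshift=1.8, seed=7)
        imputed = out.values.iloc[500:, 0].to_numpy()
        se = 0.3 * 2.0 / np.sqrt(10_000)
        assert abs(imputed.mean() - (25.0 - 1.8 * 2.0)) <= 3 * se
        assert abs(imputed.std(ddof=1) - 0.6) / 0.6 <= 0.02

    def test_same_seed_identical(self):
        vals = np.random.default_rng(1).normal(25, 2, (50, 6))
        vals[::5, 2] = np.nan
        pm = _pm(vals, ["A"] * 3 + ["B"] * 3)
        a = cd.impute_downshift(pm, seed=3)
        b = cd.impute_downshift(pm, seed=3)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_degenerate_parameters_give_column_mean(self):
        # width 0, downshift 0: every imputed cell equals its column's observed mean
        col0 = np.array([24.0, 25.0, 26.0, np.nan])
        col1 = np.full(4, 30.0)
        pm = _pm(np.column_stack([col0, col1]), ["A", "B"])
        out = cd.impute_downshift(pm, width=0.0, downshift=0.0, seed=0)
        assert out.values.iloc[3, 0] == pytest.approx(25.0)

    def test_all_missing_column_rejected(self):
        vals = np.full((3, 4), 25.0)
        vals[:, 0] = np.nan
        with pytest.raises(ValueError):
            cd.impute_downshift(_pm(vals, ["A", "A", "B", "B"]), seed=0)


class TestS0TTest:
    def test_hand_computed_toy(self):
        vals = np.array([[10.0, 11.0, 12.0, 14.0, 15.0, 16.0]])
        res = cd.s0_ttest(_pm(vals, ["A"] * 3 + ["B"] * 3), ("A", "B"), s0=0.1)
        se = np.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert res["statistic"].iloc[0] == pytest.approx(-4.0 / (0.1 + se))

    def test_s0_zero_equals_student_t(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(25, 1, (200, 8))
        pm = _pm(vals, ["A"] * 4 + ["B"] * 4)
        d = cd.s0_ttest(pm, ("A", "B"), s0=0.0)["statistic"].to_numpy()
        t, _ = stats.ttest_ind(vals[:, :4], vals[:, 4:], axis=1)
        assert np.allclose(d, t, atol=1e-10)

    def test_zero_difference_zero_statistic(self):
        vals = np.tile([25.0, 26.0, 24.0, 25.0, 26.0, 24.0], (3, 1))
        res = cd.s0_ttest(_pm(vals, ["A"] * 3 + ["B"] * 3), ("A", "B"))
        assert np.allclose(res["statistic"], 0.0)

    def test_identical_constant_groups(self):
        vals = np.full((2, 6), 25.0)
        res = cd.s0_ttest(_pm(vals, ["A"] * 3 + ["B"] * 3), ("A", "B"))
        assert np.allclose(res["statistic"], 0.0)


class TestAnovaF:
    def test_identical_group_means_small_F(self):
        base = np.array([1.0, 2.0, 3.0])
        vals = np.tile(np.concatenate([base] * 3), (2, 1))
        pm = _pm(vals, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        assert cd.anova_F(pm)["statistic"].max() < 1e-20

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(25, 1, (100, 8))
        pm = _pm(vals, ["A"] * 4 + ["B"] * 4)
        F = cd.anova_F(pm, ("A", "B"))["statistic"].to_numpy()
        t = cd.s0_ttest(pm, ("A", "B"), s0=0.0)["statistic"].to_numpy()
        assert np.allclose(F, t**2, atol=1e-9)

    def test_hand_computed_three_group_table(self):
        # groups (1,2,3), (2,3,4), (6,7,8): SSB = 3*[(2-4)^2+(3-4)^2+(7-4)^2]=42
        # SSW = 6, F = (42/2)/(6/6) = 21
        vals = np.array([[1.0, 2, 3, 2, 3, 4, 6, 7, 8]])
        pm = _pm(vals, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        assert cd.anova_F(pm)["statistic"].iloc[0] == pytest.approx(21.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (50, 9))
        pm = _pm(vals, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        F = cd.anova_F(pm)["statistic"].to_numpy()
        ref = stats.f_oneway(vals[:, :3], vals[:, 3:6], vals[:, 6:], axis=1).statistic
        assert np.allclose(F, ref, atol=1e-9)


class TestPermutationFDR:
    def test_planted_effects_recovered(self):
        spec = cd.ProteomeFixtureSpec(seed=5)
        matrix, groups, truth = cd.make_proteome_fixture(spec)
        pm = cd.impute_downshift(cd.filter_matrix(ProteinMatrix(matrix, groups)), seed=5)
        res = cd.permutation_fdr(pm, "s0_ttest", seed=5)
        planted = set(truth["protein"]) & set(pm.values.index)
        sig = set(res.significant)
        assert len(sig & planted) / len(planted) >= 0.90
        # q-values monotone non-increasing in |statistic|
        tab = res.table.sort_values("statistic", key=np.abs, ascending=False)
        assert (np.diff(tab["q_value"].to_numpy()) >= -1e-12).all()

    def test_identical_columns_nothing_significant(self):
        vals = np.tile(np.random.default_rng(6).normal(25, 2, (100, 1)), (1, 8))
        pm = _pm(vals, ["A"] * 4 + ["B"] * 4)
        res = cd.permutation_fdr(pm, "s0_ttest", seed=0)
        assert len(res.significant) == 0

    def test_exhaustive_enumeration_for_small_designs(self):
        vals = np.random.default_rng(7).normal(25, 1, (50, 8))
        pm = _pm(vals, ["A"] * 4 + ["B"] * 4)
        res = cd.permutation_fdr(pm, "s0_ttest", n_perm=250, seed=0)
        assert res.n_permutations == 70  # C(8,4) distinct labelings

    def test_deterministic_given_seed(self):
        spec = cd.ProteomeFixtureSpec(n_proteins=200, seed=8)
        matrix, groups, _ = cd.make_proteome_fixture(spec)
        pm = cd.impute_downshift(cd.filter_matrix(ProteinMatrix(matrix, groups)), seed=1)
        r1 = cd.permutation_fdr(pm, "s0_ttest", seed=4)
        r2 = cd.permutation_fdr(pm, "s0_ttest", seed=4)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_too_few_samples_rejected(self):
        vals = np.random.default_rng(9).normal(25, 1, (10, 4))
        pm = _pm(vals, ["A", "A", "B", "B"])
        res = cd.permutation_fdr(pm, "s0_ttest", seed=0)  # C(4,2)=6 perms: fine
        assert res.n_permutations == 6

    def test_anova_statistic_supported(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(25, 0.3, (100, 9))
        vals[:10, 6:] += 3.0  # group C shifted for 10 proteins
        pm = _pm(vals, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        res = cd.permutation_fdr(pm, "anova_F", seed=1)
        sig = set(res.significant)
        assert {f"P{i}" for i in range(10)} <= sig


class TestFisherEnrichment:
    def test_matches_hypergeometric_tail_small_universes(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            N = int(rng.integers(8, 51))
            bg = {f"P{i}" for i in range(N)}
            n = int(rng.integers(1, N))
            sig = set(rng.choice(sorted(bg), size=n, replace=False))
            K = int(rng.integers(1, N + 1))
            term = set(rng.choice(sorted(bg), size=K, replace=False))
            res = cd.fisher_enrichment(sig, bg, {"T": term})
            r = res[0]
            assert r.p_value == pytest.approx(
                hypergeom_tail(r.k_sig_in_term, N, K, n), rel=1e-10
            )

    def test_null_terms_uniform_p(self):
        rng = np.random.default_rng(12)
        bg = {f"P{i}" for i in range(400)}
        sig = set(rng.choice(sorted(bg), size=80, replace=False))
        terms = {
            f"T{j}": set(rng.choice(sorted(bg), size=40, replace=False)) for j in range(200)
        }
        res = cd.fisher_enrichment(sig, bg, terms)
        frac_small = np.mean([r.p_value < 0.05 for r in res])
        assert frac_small <= 0.10  # discrete test is conservative; ~<=5% expected
        assert not any(r.enriched for r in res if r.q_value > 0.05)

    def test_empty_significant_set(self):
        bg = {"A", "B", "C", "D"}
        res = cd.fisher_enrichment(set(), bg, {"T": {"A", "B"}})
        assert not any(r.enriched for r in res)
        assert all(r.p_value == 1.0 for r in res)

    def test_bh_monotone_in_p(self):
        rng = np.random.default_rng(13)
        bg = {f"P{i}" for i in range(100)}
        sig = set(rng.choice(sorted(bg), size=30, replace=False))
        terms = {f"T{j}": set(rng.choice(sorted(bg), size=15, replace=False)) for j in range(20)}
        res = sorted(cd.fisher_enrichment(sig, bg, terms), key=lambda r: r.p_value)
        qs = [r.q_value for r in res]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_significant_not_subset_rejected(self):
        with pytest.raises(ValueError):
            cd.fisher_enrichment({"X"}, {"A"}, {"T": {"A"}})


class TestZscoreRows:
    def test_arithmetic(self):
        z = cd.zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert np.allclose(z.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_idempotent_on_standardized(self):
        row = np.array([[-1.0, 0.0, 1.0]])
        z = cd.zscore_rows(pd.DataFrame(row))
        assert np.allclose(z.to_numpy(), row, atol=1e-12)

    def test_random_matrix_property(self, rng):
        m = pd.DataFrame(rng.normal(10, 3, (30, 8)))
        z = cd.zscore_rows(m)
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError):
            cd.zscore_rows(pd.DataFrame([[2.0, 2.0, 2.0]]))
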