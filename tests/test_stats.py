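import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import mfcoupling as mfc
from mfcoupling.exceptions import (
    UndefinedCorrelationError,
    ValidationError,
)
from mfcoupling.stats import label_permutation_pvalue


class TestResidualize:
    def test_orthogonal_covariate_just_demeans(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        z = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to the trend in y
        res = mfc.residualize(y, z[:, None])
        assert np.allclose(res, y - y.mean(), atol=1e-12)

    def test_exact_linear_relation_gives_zero(self, rng):
        age = rng.uniform(20, 60, 50)
        res = mfc.residualize(2.0 * age, age[:, None])
        assert np.max(np.abs(res)) < 1e-10

    def test_residuals_orthogonal_to_covariates(self, rng):
        age = rng.uniform(20, 60, 80)
        y = 2.0 * age + rng.standard_normal(80)
        res = mfc.residualize(y, age[:, None])
        assert abs(np.corrcoef(res, age)[0, 1]) < 1e-10

    def test_collinear_design_named(self, rng):
        age = rng.uniform(20, 60, 30)
        with pytest.raises(ValidationError, match="collinear"):
            mfc.residualize(rng.standard_normal(30),
                            np.column_stack([age, 2.0 * age]))


class TestMannWhitney:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 2.0, 5.0])
        u, z, p = mfc.mann_whitney(x, x.copy())
        assert z == 0.0 and p == 1.0

    def test_smallest_case_exact(self):
        """x=(1,2), y=(3,4): U=0 and the enumeration gives p = 1/3."""
        u, z, p = mfc.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(1.0 / 3.0, abs=1e-12)

    @staticmethod
    def enumeration_p(x, y):
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        n1 = len(x)
        mean_u = n1 * len(y) / 2.0
        offset = n1 * (n1 + 1) / 2.0
        u_obs = ranks[:n1].sum() - offset
        devs = [
            abs(ranks[list(c)].sum() - offset - mean_u)
            for c in itertools.combinations(range(len(pooled)), n1)
        ]
        devs = np.asarray(devs)
        return float(np.mean(devs >= abs(u_obs - mean_u) - 1e-9))

    def test_small_sample_p_matches_enumeration(self, rng):
        """Across all group-size pairs up to 8, the returned p stays within
        0.05 of full enumeration (with and without ties)."""
        worst = 0.0
        for n1 in range(2, 9):
            for n2 in range(n1, 9):
                x = rng.standard_normal(n1)
                y = rng.standard_normal(n2) + 0.5
                _, _, p = mfc.mann_whitney(x, y)
                worst = max(worst, abs(p - self.enumeration_p(x, y)))
                xt = rng.integers(0, 4, n1).astype(float)
                yt = rng.integers(0, 4, n2).astype(float)
                _, _, p = mfc.mann_whitney(xt, yt)
                worst = max(worst, abs(p - self.enumeration_p(xt, yt)))
        assert worst < 0.05

    def test_asymptotic_matches_scipy(self, rng):
        """Cross-check the tie-corrected normal approximation."""
        x = rng.integers(0, 10, 60).astype(float)
        y = rng.integers(2, 12, 70).astype(float)
        _, _, p = mfc.mann_whitney(x, y, method="asymptotic")
        ref = sps.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert p == pytest.approx(ref, abs=1e-9)

    def test_direction_of_z(self):
        _, z_hi, _ = mfc.mann_whitney([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        _, z_lo, _ = mfc.mann_whitney([1.0, 2.0, 3.0], [5.0, 6.0, 7.0])
        assert z_hi > 0 > z_lo

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mfc.mann_whitney([], [1.0])


class TestBhFdr:
    def test_hand_step_up(self):
        q = mfc.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04, atol=1e-12)

    def test_single_and_constant(self):
        assert mfc.bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)
        assert np.allclose(mfc.bh_fdr(np.full(5, 0.3)), 0.3)

    def test_matches_hand_oracle(self, rng):
        """q_i = min over p_(j) >= p_(i) of p_(j) * m / j."""
        p = rng.uniform(0, 1, 20)
        q = mfc.bh_fdr(p)
        order = np.argsort(p)
        m = p.size
        q_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(q, oracle, atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_order_invariance_and_dominance(self, raw):
        p = np.asarray(raw)
        q = mfc.bh_fdr(p)
        assert (q >= p - 1e-12).all()
        perm = np.argsort(p, kind="stable")[::-1]
        q_perm = mfc.bh_fdr(p[perm])
        inv = np.empty_like(perm)
        inv[perm] = np.arange(p.size)
        assert np.allclose(q, q_perm[inv], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            mfc.bh_fdr(np.array([0.5, 1.5]))


class TestPartialCorrelation:
    @staticmethod
    def correlated_triplet(n=24):
        """Three variables with exact sample correlations of 0.5."""
        rng = np.random.default_rng(3)
        raw = rng.standard_normal((n, 3))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)  # exactly uncorrelated columns
        target = np.full((3, 3), 0.5)
        np.fill_diagonal(target, 1.0)
        data = q @ np.linalg.cholesky(target).T
        return data[:, 0], data[:, 1], data[:, 2]

    def test_closed_form_identity(self):
        """r_xy = r_xz = r_yz = 0.5 implies partial r = 1/3."""
        x, y, z = self.correlated_triplet()
        r, _ = mfc.partial_correlation(x, y, z[:, None])
        assert r == pytest.approx(1.0 / 3.0, abs=1e-10)

    def test_no_covariates_is_pearson(self, rng):
        x = rng.standard_normal(40)
        y = x + rng.standard_normal(40)
        r, p = mfc.partial_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_degenerate_residual_raises(self, rng):
        z = rng.standard_normal(30)
        with pytest.raises(UndefinedCorrelationError):
            mfc.partial_correlation(z, rng.standard_normal(30), z[:, None])


class TestSpinNull:
    def test_null_maps_are_permutations(self):
        from mfcoupling.stats import spin_permutations

        cent = mfc.default_centroids(30)
        perms = spin_permutations(cent, n_perm=25, seed=0)
        for p in perms:
            assert sorted(p) == list(range(30))

    def test_self_correlation_is_extreme(self, rng):
        cent = mfc.default_centroids(64)
        smooth = np.sin(cent["z"].to_numpy() * 3.0) + 0.05 * rng.standard_normal(64)
        res = mfc.spin_null_pvalue(smooth, smooth, cent, n_perm=199, seed=1)
        assert res.observed == pytest.approx(1.0)
        assert res.p_spin <= 0.01

    def test_pvalue_definition(self, rng):
        cent = mfc.default_centroids(32)
        a, b = rng.standard_normal(32), rng.standard_normal(32)
        res = mfc.spin_null_pvalue(a, b, cent, n_perm=199, seed=2)
        expected = (1 + np.sum(np.abs(res.nulls) >= abs(res.observed))) / 200.0
        assert res.p_spin == pytest.approx(expected)
        assert 0 < res.p_spin <= 1

    def test_label_permutation_fallback(self, rng):
        a, b = rng.standard_normal(40), rng.standard_normal(40)
        res = label_permutation_pvalue(a, b, n_perm=199, seed=3)
        assert 0 < res.p_spin <= 1

    def test_too_few_permutations_rejected(self, rng):
        cent = mfc.default_centroids(10)
        with pytest.raises(ValidationError):
            mfc.spin_null_pvalue(
                rng.standard_normal(10), rng.standard_normal(10), cent, n_perm=50
            )


class TestDistributionAndSummaryTests:
    def test_ks_hand_values(self, rng):
        d, _ = mfc.ks_two_sample([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])
        assert d == pytest.approx(1.0 / 3.0)
        x = rng.standard_normal(20)
        assert mfc.ks_two_sample(x, x.copy())[0] == 0.0
        assert mfc.ks_two_sample([1.0, 2.0], [5.0, 6.0])[0] == 1.0

    def test_welch_t_hand_value(self):
        assert mfc.t_from_summary(0, 1, 100, 1, 1, 100) == pytest.approx(
            -7.0711, abs=1e-4
        )
        assert mfc.t_from_summary(3, 1, 50, 3, 1, 50) == 0.0

    def test_pooled_t_matches_scipy(self):
        t = mfc.t_from_summary(10, 2, 30, 11, 3, 40, kind="pooled")
        ref = sps.ttest_ind_from_stats(10, 2, 30, 11, 3, 40).statistic
        assert t == pytest.approx(ref, abs=1e-12)

    def test_invalid_summary_rejected(self):
        with pytest.raises(ValidationError):
            mfc.t_from_summary(0, 0, 10, 1, 1, 10)

    def test_chi2_hand_values(self):
        assert mfc.chi2_2x2(10, 20, 30, 60) == pytest.approx(0.0)
        assert mfc.chi2_2x2(10, 0, 0, 10) == pytest.approx(20.0)
        with pytest.raises(ValidationError):
            mfc.chi2_2x2(0, 0, 5, 5)

    def test_hamd_total_range(self):
        assert mfc.hamd_total_range((4,) * 9 + (2,) * 8) == (0, 52)
        assert mfc.hamd_total_range((0,) * 17) == (0, 0)
        assert mfc.hamd_total_range((1,) * 17) == (0, 17)
        with pytest.raises(ValidationError):
            mfc.hamd_total_range((4,) * 10)


class TestCohortTable:
    def make_df(self, **overrides):
        import pandas as pd

        base = dict(
            subject_id=["a", "b", "c", "d"],
            group=["case", "case", "control", "control"],
            site=["s1", "s1", "s1", "s1"],
            age=[30.0, 40.0, 35.0, 28.0],
            sex=["male", "female", "male", "female"],
            education=[12.0, 14.0, 10.0, 16.0],
            mean_fd=[0.1, 0.12, 0.08, 0.15],
            symptom_score=[20.0, 25.0, np.nan, np.nan],
        )
        base.update(overrides)
        return pd.DataFrame(base)

    def test_valid_table_accepted(self):
        table = mfc.CohortTable(self.make_df())
        assert table.is_case.sum() == 2
        assert table.design(("age", "sex")).shape == (4, 2)

    def test_symptom_range_enforced(self):
        with pytest.raises(ValidationError):
            mfc.CohortTable(self.make_df(symptom_score=[60.0, 20, np.nan, np.nan]))

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError):
            mfc.CohortTable(self.make_df(group=["case", "patient", "control",
                                                "control"]))
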