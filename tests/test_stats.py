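"""ROI and clinical statistics: partial correlations, correlation
comparison, Bonferroni, demographics tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from rsfcs.stats import (bonferroni, compare_correlations, correlation_battery,
                         demographics_tests, gender_chi2, partial_correlation,
                         roi_mean)


class TestRoiMean:
    def test_constant_map(self):
        m = np.full((5, 5, 5), 3.25)
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:3, 1:3, 1] = True
        assert roi_mean(m, mask) == 3.25

    def test_single_voxel_cluster(self):
        m = np.arange(27.0).reshape(3, 3, 3)
        assert roi_mean(m, np.array([13])) == 13.0

    def test_checkerboard_averages_to_half(self):
        m = np.indices((4, 4, 4)).sum(axis=0) % 2
        assert roi_mean(m.astype(float), np.ones((4, 4, 4), bool)) == 0.5

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_mean(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool))


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 40))
        res = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_identical_variables_give_unity(self):
        x = np.random.default_rng(1).standard_normal(30)
        assert partial_correlation(x, x).r == pytest.approx(1.0)

    def test_matches_two_stage_residual_oracle(self):
        rng = np.random.default_rng(2)
        n, k = 60, 3
        C = rng.standard_normal((n, k))
        x = C @ [0.5, -0.2, 0.1] + rng.standard_normal(n)
        y = C @ [-0.3, 0.4, 0.2] + 0.5 * x + rng.standard_normal(n)
        res = partial_correlation(x, y, C)
        # independent oracle: explicit per-variable OLS then plain Pearson
        Z = np.column_stack([np.ones(n), C])
        rx = x - Z @ np.linalg.solve(Z.T @ Z, Z.T @ x)
        ry = y - Z @ np.linalg.solve(Z.T @ Z, Z.T @ y)
        r_oracle = float(np.corrcoef(rx, ry)[0, 1])
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.df == n - 2 - k

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((50, 4)),
                          columns=["x", "y", "c1", "c2"])
        res = partial_correlation(df.x, df.y, df[["c1", "c2"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 50.0),
           shift=st.floats(-100.0, 100.0))
    def test_invariant_to_affine_covariate_rescaling(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 30))
        C = rng.standard_normal((30, 2))
        a = partial_correlation(x, y, C)
        b = partial_correlation(x, y, C * scale + shift)
        assert a.r == pytest.approx(b.r, abs=1e-9)

    def test_constant_after_residualization_rejected(self):
        c = np.arange(20.0)
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(2 * c + 1, np.random.default_rng(0).standard_normal(20),
                                c[:, None])


class TestCompareCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = compare_correlations(0.4, 50, 0.4, 60)
        assert z == 0.0
        assert p == 1.0

    def test_antisymmetric_under_group_swap(self):
        z1, p1 = compare_correlations(0.5, 50, 0.1, 40)
        z2, p2 = compare_correlations(0.1, 40, 0.5, 50)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_matches_direct_formula(self):
        z, p = compare_correlations(0.5, 50, 0.0, 50)
        expect = np.arctanh(0.5) / np.sqrt(1 / 47 + 1 / 47)
        assert z == pytest.approx(expect, abs=1e-12)
        assert p == pytest.approx(2 * sps.norm.sf(abs(expect)), abs=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="exceed 3"):
            compare_correlations(0.5, 3, 0.2, 50)


class TestBonferroni:
    def test_multiplies_and_caps(self):
        np.testing.assert_allclose(bonferroni([0.046], 2), [0.092])
        np.testing.assert_allclose(bonferroni([0.9], 5), [1.0])

    def test_family_of_one_is_identity(self):
        np.testing.assert_allclose(bonferroni([0.3, 0.01], 1), [0.3, 0.01])

    def test_preserves_ordering(self):
        p = np.array([0.001, 0.02, 0.3, 0.7])
        adj = bonferroni(p, 4)
        assert np.all(np.diff(adj) >= 0)


class TestDemographics:
    def test_gender_chi2_on_table_counts(self):
        # 25M/28F patients vs 29M/26F controls, no continuity correction
        chi2, p = gender_chi2(np.array([[25, 28], [29, 26]]))
        assert chi2 == pytest.approx(0.333, abs=5e-4)
        assert p == pytest.approx(0.564, abs=5e-4)

    def _table(self, a_vals, b_vals, extra=None):
        n = len(a_vals) + len(b_vals)
        tab = pd.DataFrame({
            "subject": [f"s{i}" for i in range(n)],
            "group": ["control"] * len(a_vals) + ["patient"] * len(b_vals),
            "gender": ["M", "F"] * (n // 2) + ["M"] * (n % 2),
            "value": np.concatenate([a_vals, b_vals])})
        if extra is not None:
            tab["extra"] = extra
        return tab

    def test_identical_groups_give_null_t(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(30)
        rep = demographics_tests(self._table(v, v))
        row = rep[rep.variable == "value"].iloc[0]
        assert row.test == "t"
        assert row.statistic == pytest.approx(0.0, abs=1e-12)

    def test_fully_separated_samples_yield_extreme_u(self):
        a = np.linspace(0, 1, 25)
        b = np.linspace(10, 11, 25)
        rep = demographics_tests(self._table(a, b))
        row = rep[rep.variable == "value"].iloc[0]
        assert row.p < 1e-6

    def test_non_normal_variable_routed_to_mannwhitney(self):
        rng = np.random.default_rng(5)
        a = np.exp(rng.standard_normal(40) * 2)  # heavily skewed
        b = np.exp(rng.standard_normal(40) * 2 + 0.5)
        rep = demographics_tests(self._table(a, b))
        assert rep[rep.variable == "value"].iloc[0].test == "mannwhitney"

    def test_constant_variable_flagged_and_skipped(self):
        rep = demographics_tests(self._table(np.ones(10), np.ones(10)))
        row = rep[rep.variable == "value"].iloc[0]
        assert row.test == "skipped"

    def test_location_shift_sign_agreement(self):
        # t and Mann-Whitney must agree on effect direction for shifted
        # Gaussian samples
        rng = np.random.default_rng(6)
        a = rng.standard_normal(40)
        b = rng.standard_normal(40) + 1.0
        t = sps.ttest_ind(a, b).statistic
        from rsfcs.stats import _mannwhitney_z
        _, z, _ = _mannwhitney_z(a, b)
        assert np.sign(t) == np.sign(z)


class TestCorrelationBattery:
    def _inputs(self, n=20, seed=7):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame({
            "subject": [f"s{i}" for i in range(n)],
            "group": ["control"] * (n // 2) + ["patient"] * (n - n // 2),
            "age": rng.normal(55, 7, n), "gender": ["M", "F"] * (n // 2),
            "education": rng.normal(11, 3, n),
            "hba1c": rng.normal(7, 2, n), "mmse": rng.normal(29, 1, n)})
        roi = pd.DataFrame({"roi1": rng.standard_normal(n)},
                           index=table["subject"])
        return roi, table

    def test_single_pair_bonferroni_is_identity(self):
        roi, table = self._inputs()
        tidy, comp = correlation_battery(roi, table, ["hba1c"])
        assert (tidy.m_family == 1).all()
        np.testing.assert_allclose(tidy.p_bonferroni, tidy.p)
        assert len(comp) == 1

    def test_misaligned_subjects_rejected(self):
        roi, table = self._inputs()
        roi.index = ["x" + s for s in roi.index]
        with pytest.raises(ValueError, match="different subjects"):
            correlation_battery(roi, table, ["hba1c"])

    def test_family_size_counts_all_pairs(self):
        roi, table = self._inputs()
        roi["roi2"] = roi["roi1"] * 2 + 1
        tidy, _ = correlation_battery(roi, table, ["hba1c", "mmse"])
        assert (tidy.m_family == 4).all()
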