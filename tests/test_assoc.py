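import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pubsitar.assoc import (AssociationResult, build_grs, fat_mass_index,
                            pairwise_correlations, regress_adjusted,
                            regress_univariable, standardize_by_group)
from pubsitar.exceptions import CollinearityError, DataError


def _weights(snps, w):
    return pd.DataFrame({"snp": snps, "effect_allele": ["A"] * len(snps),
                         "weight": w})


class TestBuildGrs:
    def test_three_snp_hand_example(self):
        dosages = pd.DataFrame([[2.0, 1.0, 0.0]], columns=["s1", "s2", "s3"])
        out = build_grs(dosages, _weights(["s1", "s2", "s3"], [0.1, 0.2, 0.3]))
        assert out["raw"].iloc[0] == pytest.approx((2 * 0.1 + 1 * 0.2) / 3)

    def test_zero_weights_give_zero_scores(self):
        rng = np.random.default_rng(0)
        dosages = pd.DataFrame(rng.integers(0, 3, (20, 4)).astype(float),
                               columns=list("abcd"))
        out = build_grs(dosages, _weights(list("abcd"), [0.0] * 4))
        assert np.allclose(out["raw"], 0.0)

    def test_standardized_scores_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        dosages = pd.DataFrame(rng.uniform(0, 2, (50, 6)),
                               columns=list("abcdef"))
        out = build_grs(dosages, _weights(list("abcdef"),
                                          [0.1, -0.2, 0.3, 0.05, 0.4, -0.1]))
        assert abs(out["standardized"].mean()) < 1e-12
        assert out["standardized"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_snp_column_order(self):
        rng = np.random.default_rng(2)
        dosages = pd.DataFrame(rng.uniform(0, 2, (30, 3)),
                               columns=["s1", "s2", "s3"])
        w = _weights(["s1", "s2", "s3"], [0.1, 0.2, 0.3])
        a = build_grs(dosages, w)
        b = build_grs(dosages[["s3", "s1", "s2"]], w)
        assert np.allclose(a["raw"], b["raw"])

    def test_weight_scaling_scales_raw_leaves_standardized(self):
        rng = np.random.default_rng(3)
        dosages = pd.DataFrame(rng.uniform(0, 2, (30, 3)),
                               columns=["s1", "s2", "s3"])
        a = build_grs(dosages, _weights(["s1", "s2", "s3"], [0.1, 0.2, 0.3]))
        b = build_grs(dosages, _weights(["s1", "s2", "s3"], [0.5, 1.0, 1.5]))
        assert np.allclose(b["raw"], 5 * a["raw"])
        assert np.allclose(b["standardized"], a["standardized"])

    def test_absent_snp_excluded_with_reduced_divisor(self):
        dosages = pd.DataFrame([[2.0, 1.0]], columns=["s1", "s2"])
        with pytest.warns(UserWarning, match="absent"):
            out = build_grs(dosages,
                            _weights(["s1", "s2", "s9"], [0.1, 0.2, 9.0]))
        assert out["raw"].iloc[0] == pytest.approx((0.2 + 0.2) / 2)

    def test_no_shared_snps_is_an_error(self):
        dosages = pd.DataFrame([[1.0]], columns=["x"])
        with pytest.raises(DataError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            build_grs(dosages, _weights(["y"], [0.1]))

    def test_missing_dosage_mean_imputed_or_dropped(self):
        dosages = pd.DataFrame([[2.0, 1.0], [np.nan, 1.0], [0.0, 1.0]],
                               columns=["s1", "s2"])
        w = _weights(["s1", "s2"], [1.0, 0.0])
        mean_imp = build_grs(dosages, w, missing="mean")
        assert mean_imp["raw"].iloc[1] == pytest.approx(1.0 / 2)  # mean dose 1
        dropped = build_grs(dosages, w, missing="drop")
        assert dropped["raw"].iloc[1] == pytest.approx(0.0)  # only s2 counts

    def test_out_of_range_dosage_rejected(self):
        dosages = pd.DataFrame([[2.5]], columns=["s1"])
        with pytest.raises(DataError):
            build_grs(dosages, _weights(["s1"], [0.1]))


def test_fat_mass_index_arithmetic():
    assert fat_mass_index(20.0, 1.40) == pytest.approx(10.204, abs=1e-3)


class TestPairwiseCorrelations:
    def test_perfect_and_inverse_correlation(self):
        table = pd.DataFrame({"a": [1.0, 2, 3], "b": [3.0, 2, 1],
                              "c": [1.0, 2, 3]})
        corr, n = pairwise_correlations(table)
        assert n == 3
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert corr.loc["a", "c"] == pytest.approx(1.0)

    def test_complete_case_restriction(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4, np.nan],
                              "b": [2.0, 1, 4, 3, 5]})
        _, n = pairwise_correlations(table)
        assert n == 4

    def test_matrix_positive_semidefinite(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.standard_normal((200, 5)),
                             columns=list("abcde"))
        corr, _ = pairwise_correlations(table)
        assert np.linalg.eigvalsh(corr.to_numpy()).min() > -1e-10

    def test_zero_variance_column_flagged(self):
        table = pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, _ = pairwise_correlations(table)
        assert np.isnan(corr.loc["a", "b"])

    def test_too_few_complete_cases_rejected(self):
        table = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(DataError):
            pairwise_correlations(table)


class TestRegressUnivariable:
    def test_exact_linear_relation(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        res = regress_univariable(2 * x, x)
        assert res.beta == pytest.approx(2.0)
        assert res.se == pytest.approx(0.0, abs=1e-10)
        assert res.n == 4

    def test_constant_exposure_rejected(self):
        with pytest.raises(DataError):
            regress_univariable([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])

    def test_null_coverage_of_confidence_intervals(self):
        rng = np.random.default_rng(5)
        covered = 0
        for _ in range(200):
            x = rng.standard_normal(150)
            y = rng.standard_normal(150)
            lcl, ucl = regress_univariable(y, x).ci
            covered += lcl <= 0.0 <= ucl
        assert 0.90 <= covered / 200 <= 0.99

    def test_slope_equals_correlation_times_outcome_sd(self):
        rng = np.random.default_rng(6)
        r, n = 0.4, 4000
        x = rng.standard_normal(n)
        y = 2.0 * (r * x + np.sqrt(1 - r**2) * rng.standard_normal(n))
        res = regress_univariable(y, x)
        assert res.beta == pytest.approx(r * 2.0, abs=0.1)


class TestStandardizeByGroup:
    def test_single_group_example(self):
        z = standardize_by_group([1.0, 2.0, 3.0], ["g", "g", "g"])
        assert np.allclose(z, [-1.0, 0.0, 1.0])

    def test_each_group_centred_and_scaled(self):
        values = [1.0, 2.0, 3.0, 10.0, 20.0, 30.0]
        groups = ["a", "a", "a", "b", "b", "b"]
        z = pd.DataFrame({"z": standardize_by_group(values, groups),
                          "g": groups})
        for _, sub in z.groupby("g"):
            assert sub["z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert sub["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_singleton_group_missing_with_warning(self):
        with pytest.warns(UserWarning, match="singleton"):
            z = standardize_by_group([1.0, 2.0, 3.0], ["a", "a", "b"])
        assert np.isnan(z.iloc[2])


class TestRegressAdjusted:
    def test_empty_covariates_reproduce_univariable(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(100)
        y = 0.5 * x + rng.standard_normal(100)
        uni = regress_univariable(y, x)
        adj = regress_adjusted(y, x)
        assert adj.beta == pytest.approx(uni.beta, abs=1e-12)
        assert adj.se == pytest.approx(uni.se, abs=1e-12)

    def test_independent_covariates_leave_slope_unchanged(self):
        rng = np.random.default_rng(8)
        n = 5000
        x = rng.standard_normal(n)
        c = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        uni = regress_univariable(y, x)
        adj = regress_adjusted(y, x, pd.DataFrame({"c": c}))
        assert adj.beta == pytest.approx(uni.beta, abs=0.05)

    def test_confounded_sem_recovers_direct_effect(self):
        # C -> X (path a), C -> Y (path c), X -> Y (direct d):
        # unadjusted slope ~ d + a*c; adjusted recovers d
        rng = np.random.default_rng(9)
        n, a, c, d = 6000, 0.6, 0.5, -0.3
        C = rng.standard_normal(n)
        X = a * C + np.sqrt(1 - a**2) * rng.standard_normal(n)
        Y = d * X + c * C + rng.standard_normal(n)
        adj = regress_adjusted(Y, X, pd.DataFrame({"C": C}))
        uni = regress_univariable(Y, X)
        assert adj.beta == pytest.approx(d, abs=0.05)
        assert uni.beta == pytest.approx(d + a * c / (1.0), abs=0.06)

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        cov = pd.DataFrame({"dup": x})  # exact copy of the exposure
        with pytest.raises(CollinearityError, match="dup|exposure"):
            regress_adjusted(y, x, cov)


def test_association_result_ci_identity():
    res = AssociationResult("e", "o", beta=0.24, se=0.013, n=100)
    lcl, ucl = res.ci
    assert lcl == pytest.approx(0.24 - 1.96 * 0.013)
    assert ucl == pytest.approx(0.24 + 1.96 * 0.013)
    row = res.as_row()
    assert row["lcl"] == pytest.approx(lcl) and row["n"] == 100


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=10**6))
def test_grs_permutation_invariance_property(n_snps, seed):
    rng = np.random.default_rng(seed)
    dosages = pd.DataFrame(rng.uniform(0, 2, (12, n_snps)),
                           columns=[f"s{j}" for j in range(n_snps)])
    w = _weights(list(dosages.columns),
                 rng.uniform(-0.5, 0.5, n_snps).tolist())
    perm = rng.permutation(dosages.columns)
    a = build_grs(dosages, w)
    b = build_grs(dosages[list(perm)], w)
    assert np.allclose(a["raw"], b["raw"])
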