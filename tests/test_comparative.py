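"""Group-level comparative statistics and pattern scoring."""

import numpy as np
import pandas as pd
import pytest

from petalia.comparative import (
    SingularCovarianceError,
    ap_pattern_category,
    box_m,
    contralateral_association,
    grubbs,
    group_summary,
    hotelling_two_sample,
    mardia_tests,
    pattern_frequencies,
    size_correlation,
)
from petalia.simulate import preset, simulate_cohort_table


class TestSizeCorrelation:
    def test_perfectly_monotone(self):
        ev = np.array([400, 600, 900, 1200, 1500], float)
        res = size_correlation(np.cbrt(ev) * 0.3 + 1, ev)
        assert res["spearman"]["rho"] == pytest.approx(1.0)
        assert res["kendall"]["tau"] == pytest.approx(1.0)
        assert res["linear"]["r"] == pytest.approx(1.0)

    def test_independent_pairs_calibrated(self):
        rng = np.random.default_rng(31)
        rejections = 0
        for _ in range(200):
            res = size_correlation(rng.normal(2, 0.5, 199) ** 2,
                                   rng.normal(1000, 200, 199))
            rejections += res["spearman"]["p"] < 0.05
        assert 1 <= rejections <= 25  # ~alpha of 200

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            size_correlation([1, 2, 3, 4, 5], [800] * 5)


class TestHotelling:
    def test_identical_groups(self):
        rng = np.random.default_rng(32)
        X = rng.normal(size=(20, 4))
        t2, f, p = hotelling_two_sample(X, X.copy())
        assert t2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(33)
        A = rng.normal(0, 1, size=(45, 6))
        B = rng.normal(1, 1, size=(110, 6))
        _, _, p = hotelling_two_sample(A, B)
        assert p < 0.01

    def test_permutation_invariance(self):
        rng = np.random.default_rng(34)
        A = rng.normal(0, 1, size=(15, 3))
        B = rng.normal(0.4, 1, size=(18, 3))
        t2a, _, pa = hotelling_two_sample(A, B)
        t2b, _, pb = hotelling_two_sample(A[rng.permutation(15)], B[rng.permutation(18)])
        assert t2a == pytest.approx(t2b) and pa == pytest.approx(pb)

    def test_affine_invariance(self):
        rng = np.random.default_rng(35)
        A = rng.normal(0, 1, size=(25, 4))
        B = rng.normal(0.3, 1.2, size=(30, 4))
        M = rng.normal(size=(4, 4)) + 4 * np.eye(4)  # nonsingular
        shift = rng.normal(size=4)
        t2a, _, _ = hotelling_two_sample(A, B)
        t2b, _, _ = hotelling_two_sample(A @ M.T + shift, B @ M.T + shift)
        assert t2b == pytest.approx(t2a, rel=1e-8)

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(36)
        A = rng.normal(0, 1, size=(22, 5))
        B = rng.normal(0.5, 1, size=(31, 5))
        t2, f, p = hotelling_two_sample(A, B)
        ref = pingouin.multivariate_ttest(A, B)
        assert t2 == pytest.approx(float(ref["T2"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-9)

    def test_singular_covariance_refused(self):
        X = np.zeros((10, 3))
        X[:, 0] = np.arange(10)
        X[:, 1] = 2 * X[:, 0]  # exactly collinear
        X[:, 2] = np.arange(10) % 2
        with pytest.raises((SingularCovarianceError, ValueError)):
            hotelling_two_sample(X, X + 1)


class TestAssumptionDiagnostics:
    def test_mardia_large_normal_sample(self):
        rng = np.random.default_rng(37)
        X = rng.normal(size=(2000, 4))
        res = mardia_tests(X)
        assert res["skewness"][1] > 0.01
        assert res["kurtosis"][1] > 0.01

    def test_mardia_detects_nonnormal(self):
        rng = np.random.default_rng(38)
        X = rng.exponential(size=(500, 3))
        res = mardia_tests(X)
        assert res["skewness"][1] < 1e-6

    def test_box_m_identical_groups_zero(self):
        rng = np.random.default_rng(39)
        X = rng.normal(size=(30, 3))
        M, p = box_m(X, X.copy())
        assert M == pytest.approx(0.0, abs=1e-9)

    def test_box_m_detects_scaled_covariance(self):
        rng = np.random.default_rng(40)
        A = rng.normal(0, 1, size=(100, 3))
        B = rng.normal(0, 2, size=(100, 3))  # covariance x4
        _, p = box_m(A, B)
        assert p < 0.01


class TestGrubbs:
    def test_hand_worked_statistic(self):
        # {1,1,1,10}: mean 3.25, sd 4.5 -> G = 6.75/4.5 = 1.5, above the
        # n=4 critical value (~1.481 at alpha=0.05)
        flags = grubbs([1, 1, 1, 10])
        assert list(flags) == [False, False, False, True]

    def test_no_outlier_in_uniform_spread(self):
        assert not grubbs([1, 2, 3, 4, 5]).any()

    def test_shift_scale_invariance(self):
        rng = np.random.default_rng(41)
        x = np.append(rng.normal(0, 1, 20), 6.0)
        f1 = grubbs(x)
        f2 = grubbs(3.5 * x - 12.0)
        np.testing.assert_array_equal(f1, f2)
        assert f1[-1]

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            grubbs([2.0, 2.0, 2.0, 2.0])

    def test_iterative_removal(self):
        x = [1.0, 1.1, 0.9, 1.05, 0.95, 1.0, 1.1, 0.9, 25.0, -30.0]
        flags = grubbs(x, iterative=True)
        assert flags[-1] and flags[-2]


class TestPatterns:
    @pytest.mark.parametrize(
        "fa,oa,expected",
        [
            (+2, -5, "RF/LO"),
            (-1, +1, "LF/RO"),
            (+1, +1, "RF/RO"),
            (-2, -2, "LF/LO"),
            (0, -1, "undetermined"),
            (np.nan, 1, "undetermined"),
        ],
    )
    def test_category_mapping(self, fa, oa, expected):
        assert ap_pattern_category(fa, oa) == expected

    def test_one_specimen_per_category(self):
        df = pd.DataFrame(
            {"frontal_ap": [1, -1, 1, -1], "occipital_ap": [-1, 1, 1, -1]}
        )
        res = pattern_frequencies(df)
        assert all(v == pytest.approx(25.0) for v in res["pct"].values())
        assert res["n_undetermined"] == 0

    def test_all_one_category(self):
        df = pd.DataFrame({"frontal_ap": [2, 3], "occipital_ap": [-1, -4]})
        res = pattern_frequencies(df)
        assert res["pct"]["RF/LO"] == 100.0

    def test_amh_preset_left_occipital_patterns_dominate(self):
        """The leftward occipital DA makes LO patterns the bulk of AMH cohorts."""
        lo_share, rf_lo, rf_ro, lf_ro = [], [], [], []
        for seed in range(10):
            res = pattern_frequencies(simulate_cohort_table(preset("AMH"), seed=seed))
            pct = res["pct"]
            lo_share.append(pct["RF/LO"] + pct["LF/LO"])
            rf_lo.append(pct["RF/LO"])
            rf_ro.append(pct["RF/RO"])
            lf_ro.append(pct["LF/RO"])
        assert np.mean(lo_share) > 65
        assert np.mean(rf_lo) > np.mean(rf_ro)
        assert np.mean(rf_lo) > np.mean(lf_ro)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(43)
        df = pd.DataFrame(
            {"frontal_ap": rng.normal(size=60), "occipital_ap": rng.normal(size=60)}
        )
        res = pattern_frequencies(df)
        assert sum(res["pct"].values()) == pytest.approx(100.0, abs=1e-9)


class TestContralateral:
    def test_worked_example(self):
        pct, n, _ = contralateral_association([-1, -2, 1], [1, 3, 1])
        assert pct == pytest.approx(200 / 3)
        assert n == 3

    def test_all_same_signed(self):
        pct, _, _ = contralateral_association([1, 2, -3], [2, 1, -1])
        assert pct == 0.0

    def test_independent_signs_near_half(self):
        rng = np.random.default_rng(44)
        pct, _, _ = contralateral_association(
            rng.normal(size=10_000), rng.normal(size=10_000)
        )
        assert pct == pytest.approx(50.0, abs=2.0)

    def test_positive_scaling_invariance(self):
        ap = [-1.0, 2.0, 0.5, -0.1]
        lat = [0.3, -0.7, 0.2, 0.9]
        assert contralateral_association(ap, lat)[0] == (
            contralateral_association(np.multiply(ap, 7.3), lat)[0]
        )


class TestGroupSummary:
    def test_amh_preset_report_schema(self):
        table = simulate_cohort_table(preset("AMH"), seed=2)
        report = group_summary(table)
        g = report["groups"]["AMH"]
        assert g["n"] == 45
        assert len(g["traits"]) == 6
        assert set(g["patterns"]["pct"]) == {"RF/LO", "LF/RO", "RF/RO", "LF/LO"}
        assert np.isfinite(g["fa11"])
        assert "pct" in g["occipital_contralateral"]

    def test_single_specimen_group(self):
        table = simulate_cohort_table(preset("AMH"), seed=2).head(1)
        g = group_summary(table)["groups"]["AMH"]
        assert all(tc["verdict"] == "insufficient n" for tc in g["traits"].values())

    def test_duplicated_cohort_keeps_means(self):
        table = simulate_cohort_table(preset("GA"), seed=2).head(20)
        doubled = pd.concat([table, table], ignore_index=True)
        doubled["specimen_id"] = [f"s{i}" for i in range(len(doubled))]
        g1 = group_summary(table)["groups"]["GA"]
        g2 = group_summary(doubled)["groups"]["GA"]
        assert g2["fa11"] == pytest.approx(g1["fa11"])
        for t in g1["traits"]:
            assert g2["traits"][t]["indices"]["fa1"] == pytest.approx(
                g1["traits"][t]["indices"]["fa1"]
            )
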