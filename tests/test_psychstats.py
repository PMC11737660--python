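"""Agreement, reliability, correlation, MANOVA, and regression statistics,
cross-checked against independent oracles (brute-force decompositions and
the sklearn/pingouin/statsmodels implementations)."""

import numpy as np
import pytest
from scipy import stats

from sitr.errors import DegenerateDataError
from sitr.psychstats import (
    assumption_checks,
    cohens_kappa,
    hierarchical_regression,
    icc_2k,
    landis_koch_band,
    one_way_manova,
    pearson,
)


def ratings_from_counts(counts):
    a, b = [], []
    for i, row in enumerate(counts):
        for j, n in enumerate(row):
            a += [i] * n
            b += [j] * n
    return a, b


class TestCohensKappa:
    def test_perfect_agreement(self):
        r = cohens_kappa([1, 2, 3, 1], [1, 2, 3, 1])
        assert r.value == pytest.approx(1.0)

    def test_hand_contingency_two_by_two(self):
        a, b = ratings_from_counts([[20, 5], [10, 15]])
        r = cohens_kappa(a, b)
        assert r.value == pytest.approx(0.40, abs=1e-12)
        assert r.band == "fair"

    def test_chance_level_agreement_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 8, size=20000)
        b = rng.integers(1, 8, size=20000)
        assert abs(cohens_kappa(a.tolist(), b.tolist()).value) < 0.03

    @pytest.mark.parametrize("weighting", ["none", "linear", "quadratic"])
    def test_matches_sklearn_on_random_data(self, weighting):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        sk_weights = {"none": None, "linear": "linear", "quadratic": "quadratic"}
        for _ in range(50):
            n = int(rng.integers(10, 60))
            a = rng.integers(1, 6, size=n)
            b = np.clip(a + rng.integers(-2, 3, size=n), 1, 5)
            if len(set(a) | set(b)) < 2 or np.array_equal(a, b):
                continue
            ours = cohens_kappa(a.tolist(), b.tolist(), weighting=weighting).value
            theirs = sklearn_metrics.cohen_kappa_score(
                a, b, weights=sk_weights[weighting]
            )
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_constant_identical_ratings_undefined(self):
        with pytest.raises(DegenerateDataError):
            cohens_kappa([3, 3, 3], [3, 3, 3])

    def test_landis_koch_bands(self):
        assert landis_koch_band(-0.1) == "poor"
        assert landis_koch_band(0.1) == "slight"
        assert landis_koch_band(0.40) == "fair"
        assert landis_koch_band(0.55) == "moderate"
        assert landis_koch_band(0.75) == "substantial"
        assert landis_koch_band(0.95) == "almost perfect"


def icc2k_bruteforce(x):
    """Independent variance-components oracle: explicit two-way ANOVA."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestICC:
    def test_identical_raters_with_target_variance(self):
        x = np.array([[1, 1], [4, 4], [7, 7]], float)
        assert icc_2k(x).value == pytest.approx(1.0)

    def test_small_fixture_against_bruteforce(self):
        x = np.array([[1, 2], [3, 4], [5, 6], [7, 8]], float)
        r = icc_2k(x)
        assert r.value == pytest.approx(icc2k_bruteforce(x), abs=1e-10)

    def test_matches_pingouin_icc2k(self):
        pg = pytest.importorskip("pingouin")
        pd = pytest.importorskip("pandas")
        rng = np.random.default_rng(2)
        x = rng.normal(4, 1, size=(30, 4)) + rng.normal(0, 0.5, size=(30, 1))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(30), 4),
                "raters": np.tile(np.arange(4), 30),
                "scores": x.ravel(),
            }
        )
        theirs = pg.intraclass_corr(
            df, targets="targets", raters="raters", ratings="scores"
        )
        # McGraw & Wong's ICC(A,k) is Shrout & Fleiss's ICC(2,k)
        mask = theirs["Type"].isin(["ICC2k", "ICC(A,k)"])
        icc2k_row = theirs[mask].iloc[0]
        ours = icc_2k(x)
        assert ours.value == pytest.approx(icc2k_row["ICC"], abs=1e-8)

    def test_beta_panel_structure(self):
        # a 30-target x 4-rater panel reports ICC(2,4) with F and p
        rng = np.random.default_rng(9)
        truth = rng.uniform(2, 6, size=30)
        x = truth[:, None] + rng.normal(0, 0.6, size=(30, 4))
        r = icc_2k(x)
        assert r.statistic == "ICC(2,k)"
        assert r.df1 == 29 and r.df2 == 87
        assert 0 < r.value <= 1 and r.p is not None

    def test_degenerate_matrix(self):
        with pytest.raises(DegenerateDataError):
            icc_2k(np.ones((4, 3)))


class TestPearson:
    def test_perfect_and_anti_linearity(self):
        assert pearson([1, 2, 3], [2, 4, 6])[0] == pytest.approx(1.0)
        assert pearson([1, 2, 3], [6, 4, 2])[0] == pytest.approx(-1.0)

    def test_matches_bruteforce_covariance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            r, _ = pearson(x, y)
            brute = float(
                ((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            )
            assert r == pytest.approx(brute, abs=1e-12)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pearson([1, 1, 1], [1, 2, 3])


class TestManova:
    def test_identical_groups(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(10, 2))
        dv = np.vstack([y, y])
        labels = ["g1"] * 10 + ["g2"] * 10
        res = one_way_manova(labels, dv)
        assert res.wilks_lambda == pytest.approx(1.0)
        assert res.F == pytest.approx(0.0, abs=1e-10)
        for diff in res.mean_differences.values():
            assert np.allclose(diff, 0.0)

    def test_single_dv_equals_univariate_anova(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            g1 = rng.normal(0, 1, size=12)
            g2 = rng.normal(0.5, 1, size=15)
            labels = ["a"] * 12 + ["b"] * 15
            res = one_way_manova(labels, np.concatenate([g1, g2])[:, None])
            f_ref, p_ref = stats.f_oneway(g1, g2)
            assert res.F == pytest.approx(f_ref, abs=1e-8)
            assert res.p == pytest.approx(p_ref, abs=1e-8)
            assert res.df1 == 1 and res.df2 == 25

    def test_wilks_matches_statsmodels(self):
        sm_manova = pytest.importorskip("statsmodels.multivariate.manova")
        rng = np.random.default_rng(7)
        n = 40
        labels = np.repeat(["a", "b", "c"], [12, 14, 14])
        y = rng.normal(size=(n, 3)) + (labels == "b")[:, None] * 0.8
        res = one_way_manova(labels, y)
        import pandas as pd

        df = pd.DataFrame(y, columns=["y1", "y2", "y3"])
        df["g"] = labels
        mv = sm_manova.MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df)
        tbl = mv.mv_test().results["g"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(tbl.loc["Wilks' lambda", "Value"]), abs=1e-8
        )
        assert res.F == pytest.approx(
            float(tbl.loc["Wilks' lambda", "F Value"]), abs=1e-6
        )

    def test_layout_reports_pairwise_mean_differences(self):
        labels = ["m"] * 3 + ["r"] * 3
        dv = np.array([[3.0, 4.0]] * 3 + [[2.0, 1.0]] * 3)
        dv = dv + np.arange(6)[:, None] * 0.01  # break singularity
        res = one_way_manova(labels, dv, dv_names=["severity", "outcome"])
        assert ("m", "r") in res.mean_differences
        assert set(res.univariate) == {"severity", "outcome"}

    def test_singular_covariance(self):
        labels = ["a"] * 3 + ["b"] * 3
        col = np.arange(6.0)
        dv = np.column_stack([col, col])  # perfectly collinear DVs
        with pytest.raises(DegenerateDataError):
            one_way_manova(labels, dv)


def hierarchical_bruteforce(y, blocks):
    """Normal-equations oracle for R2 per cumulative block."""
    y = np.asarray(y, float)
    n = y.size
    cols = []
    r2s = []
    for block in blocks:
        cols += [np.asarray(c, float) for c in block.values()]
        X = np.column_stack([np.ones(n)] + cols)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sst = ((y - y.mean()) ** 2).sum()
        r2s.append(1 - (resid @ resid) / sst)
    return r2s


class TestHierarchicalRegression:
    def test_exact_linear_first_block(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        steps = hierarchical_regression(
            y, [{"x": x}, {"z": np.cos(x)}]
        )
        assert steps[0].r_squared == pytest.approx(1.0)
        assert steps[1].delta_r_squared == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_predictor_rank_error(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=10)
        with pytest.raises(DegenerateDataError):
            hierarchical_regression(y, [{"c": np.ones(10)}])

    def test_matches_bruteforce_on_random_small_data(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = 20
            x1, x2, x3 = rng.normal(size=(3, n))
            y = 0.5 * x1 - 0.3 * x2 + rng.normal(size=n)
            blocks = [{"x1": x1, "x2": x2}, {"x3": x3}]
            steps = hierarchical_regression(y, blocks)
            r2s = hierarchical_bruteforce(y, blocks)
            for step, r2 in zip(steps, r2s):
                assert step.r_squared == pytest.approx(r2, abs=1e-8)
            dr2 = r2s[1] - r2s[0]
            fc = (dr2 / 1) / ((1 - r2s[1]) / (n - 3 - 1))
            assert steps[1].F_change == pytest.approx(fc, abs=1e-8)
            assert steps[1].delta_r_squared >= -1e-12
            assert steps[1].r_squared >= steps[0].r_squared - 1e-12

    def test_standardized_beta_is_scale_free(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=25)
        y = 0.8 * x + rng.normal(size=25)
        s1 = hierarchical_regression(y, [{"x": x}])
        s2 = hierarchical_regression(y, [{"x": x * 100}])
        assert s1[0].beta["x"] == pytest.approx(s2[0].beta["x"], abs=1e-10)


class TestAssumptionChecks:
    def test_reports_shapiro_per_group_and_levene(self):
        rng = np.random.default_rng(21)
        y = np.concatenate([rng.normal(0, 1, 100), rng.normal(0, 1, 100)])
        groups = ["a"] * 100 + ["b"] * 100
        rep = assumption_checks(y, groups)
        assert set(rep.shapiro) == {"a", "b"}
        assert rep.levene is not None

    def test_levene_detects_gross_variance_heterogeneity(self):
        rng = np.random.default_rng(22)
        rejections = 0
        for i in range(30):
            y = np.concatenate(
                [rng.normal(0, 1, 100), rng.normal(0, np.sqrt(10), 100)]
            )
            rep = assumption_checks(y, ["a"] * 100 + ["b"] * 100)
            rejections += rep.homogeneity_violated
        assert rejections >= 27  # power > .9

    def test_calibrated_false_positive_rate(self):
        rng = np.random.default_rng(23)
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            y = np.concatenate([rng.normal(0, 1, 200), rng.normal(0, 1, 200)])
            rep = assumption_checks(y, ["a"] * 200 + ["b"] * 200)
            rejections += rep.homogeneity_violated
        assert rejections / n_rep < 0.12  # ~ alpha = .05 within MC error

    def test_constant_outcome_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            assumption_checks([2.0] * 10)
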