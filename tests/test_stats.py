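"""Statistical engine: scaling, PCA, Ward clustering, univariate screen,
volcano selection, ratio regression — each checked against an independent
oracle (hand formulas, brute force, or closed forms)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tifquant import stats
from tifquant.errors import ConfigError, CrossReferenceError, ValidationError
from tifquant.io import SampleSheet
from tifquant.quantify import ConcentrationTable
from tifquant.stats import (
    ScaledMatrix,
    autoscale,
    benjamini_hochberg,
    hierarchical_cluster,
    ratio_regression,
    regress_ratio_vectors,
    run_pca,
    univariate_compare,
    volcano_select,
    welch_t,
)


def conc_table(wide: pd.DataFrame) -> ConcentrationTable:
    """Wide samples x metabolites frame -> quantified ConcentrationTable."""
    long = wide.reset_index(names="sample_id").melt(
        id_vars="sample_id", var_name="metabolite_id", value_name="concentration"
    )
    long["status"] = np.where(
        long["concentration"].notna(), "quantified_isotope_dilution", "missing_peak"
    )
    return ConcentrationTable(frame=long)


def scaled_from(arr, index=None, columns=None) -> ScaledMatrix:
    df = pd.DataFrame(
        arr,
        index=index or [f"s{i}" for i in range(len(arr))],
        columns=columns or [f"m{j}" for j in range(len(arr[0]))],
    )
    return autoscale(df)


class TestAutoscale:
    def test_hand_scaling(self):
        wide = pd.DataFrame({"m1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        scaled = autoscale(wide)
        assert scaled.values["m1"].to_list() == pytest.approx([-1.0, 0.0, 1.0])

    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        wide = pd.DataFrame(rng.lognormal(0, 1, (10, 5)))
        wide.columns = [f"m{i}" for i in range(5)]
        scaled = autoscale(wide)
        assert np.allclose(scaled.values.mean(), 0, atol=1e-12)
        assert np.allclose(scaled.values.std(ddof=1), 1, atol=1e-12)

    def test_constant_column_dropped_and_recorded(self):
        wide = pd.DataFrame({"m1": [1.0, 2.0, 3.0], "m2": [5.0, 5.0, 5.0]})
        scaled = autoscale(wide)
        assert "m2" not in scaled.values.columns
        assert scaled.dropped["m2"] == "zero variance"

    def test_censored_column_dropped_and_recorded(self):
        wide = pd.DataFrame({"m1": [1.0, 2.0, 3.0], "m2": [1.0, np.nan, 2.0]})
        scaled = autoscale(wide)
        assert "m2" not in scaled.values.columns
        assert "censored" in scaled.dropped["m2"]

    def test_unscale_is_inverse(self):
        rng = np.random.default_rng(1)
        wide = pd.DataFrame(rng.normal(3, 2, (6, 4)), columns=list("abcd"))
        scaled = autoscale(wide)
        pd.testing.assert_frame_equal(scaled.unscale(), wide, rtol=1e-12)

    def test_all_constant_is_error(self):
        with pytest.raises(ValidationError):
            autoscale(pd.DataFrame({"m1": [2.0, 2.0, 2.0]}))


class TestPCA:
    def test_rank_one_structure(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        scaled = scaled_from(np.c_[x, 2 * x])
        res = run_pca(scaled)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert res.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-12)

    def test_two_variable_correlation_oracle(self):
        """For 2 auto-scaled variables with sample correlation rho, the
        correlation-matrix eigendecomposition gives ratios (1±rho)/2."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        scaled = scaled_from(np.c_[x, y])
        rho = scaled.values.corr().iloc[0, 1]
        res = run_pca(scaled)
        expected = sorted([(1 + rho) / 2, (1 - rho) / 2], reverse=True)
        assert res.explained_variance_ratio[:2] == pytest.approx(expected)

    def test_ratios_sum_to_one_and_non_increasing(self):
        rng = np.random.default_rng(4)
        scaled = scaled_from(rng.normal(size=(8, 5)))
        evr = run_pca(scaled).explained_variance_ratio
        assert evr.sum() == pytest.approx(1.0)
        assert (np.diff(evr) <= 1e-12).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            run_pca(ScaledMatrix(pd.DataFrame([[0.0, 0.0]]), None, None, {}))


def brute_force_ward(points):
    """Lance–Williams Ward recursion, naive O(n^3), squared-Euclidean based.

    Returns merge list [(i, j, height, size)] with scipy linkage semantics
    (heights = sqrt of the Ward.D2 objective increase x 2, matching scipy).
    """
    points = [np.asarray(p, float) for p in points]
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    centroids = {i: points[i].copy() for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if j <= i:
                    continue
                ni, nj = sizes[i], sizes[j]
                d2 = np.sum((centroids[i] - centroids[j]) ** 2)
                cost = 2.0 * ni * nj / (ni + nj) * d2  # scipy ward height^2
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, i, j)
        cost, i, j = best
        merges.append((i, j, np.sqrt(cost), sizes[i] + sizes[j]))
        centroids[next_id] = (sizes[i] * centroids[i] + sizes[j] * centroids[j]) / (
            sizes[i] + sizes[j]
        )
        sizes[next_id] = sizes[i] + sizes[j]
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        del centroids[i], centroids[j]
        next_id += 1
    return merges


class TestWard:
    def test_two_tight_pairs_recovered(self):
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        scaled = ScaledMatrix(
            pd.DataFrame(pts, index=list("abcd"), columns=["x", "y"]), None, None, {}
        )
        res = hierarchical_cluster(scaled, k=2)
        labels = res.labels
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]

    @pytest.mark.parametrize("n_points,seed", [(3, 0), (4, 1), (5, 2), (5, 3)])
    def test_merge_order_matches_lance_williams(self, n_points, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n_points, 3))
        scaled = ScaledMatrix(pd.DataFrame(pts), None, None, {})
        Z = hierarchical_cluster(scaled).linkage
        expected = brute_force_ward(pts)
        for row, (i, j, h, size) in zip(Z, expected):
            assert sorted(row[:2]) == sorted([i, j])
            assert row[2] == pytest.approx(h)
            assert row[3] == size

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(9)
        scaled = ScaledMatrix(pd.DataFrame(rng.normal(size=(12, 4))), None, None, {})
        heights = hierarchical_cluster(scaled).linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_duplicate_sample_merges_first_at_zero(self):
        pts = np.array([[1.0, 1.0], [5.0, 0.0], [1.0, 1.0]])
        scaled = ScaledMatrix(pd.DataFrame(pts), None, None, {})
        Z = hierarchical_cluster(scaled).linkage
        assert sorted(Z[0, :2]) == [0, 2]
        assert Z[0, 2] == 0.0

    def test_k_out_of_range_rejected(self):
        scaled = ScaledMatrix(pd.DataFrame(np.eye(3)), None, None, {})
        with pytest.raises(ValidationError):
            hierarchical_cluster(scaled, k=7)


class TestUnivariate:
    def sheet(self, groups):
        return SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": list(groups),
                    "matrix_type": "tif",
                    "group": list(groups.values()),
                }
            )
        )

    def test_welch_hand_example(self):
        """(1,2,3) vs (2,3,4): t = -1.2247, df = 4, two-tailed p ~ 0.288."""
        t, df, p = welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(-1.224744871, rel=1e-9)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.2878641347, rel=1e-6)

    def test_pipeline_reproduces_hand_welch(self):
        wide = pd.DataFrame(
            {"m1": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]},
            index=[f"s{i}" for i in range(6)],
        )
        sheet = self.sheet({f"s{i}": ("a" if i < 3 else "b") for i in range(6)})
        res = univariate_compare(conc_table(wide), sheet, "group", "a", "b")
        row = res.iloc[0]
        assert row["method"] == "welch_t"
        assert row["p_value"] == pytest.approx(0.2878641347, rel=1e-6)
        assert row["log2_fold_change"] == pytest.approx(np.log2(2.0 / 3.0))

    def test_skewed_group_switches_to_mann_whitney(self):
        rng = np.random.default_rng(7)
        normal = rng.normal(10, 1, 12)
        skewed = np.exp(rng.normal(0, 1.5, 12)) + 5  # fails Shapiro-Wilk
        wide = pd.DataFrame(
            {
                "sym": np.r_[normal, normal + 1],
                "skew": np.r_[skewed, normal],
            },
            index=[f"s{i}" for i in range(24)],
        )
        sheet = self.sheet({f"s{i}": ("a" if i < 12 else "b") for i in range(24)})
        res = univariate_compare(conc_table(wide), sheet, "group", "a", "b").set_index(
            "metabolite_id"
        )
        assert res.loc["sym", "method"] == "welch_t"
        assert res.loc["skew", "method"] == "mann_whitney"

    def test_small_groups_skipped_and_recorded(self):
        wide = pd.DataFrame(
            {"m1": [1.0, 2.0, np.nan, 2.0, 3.0, 4.0]},
            index=[f"s{i}" for i in range(6)],
        )
        sheet = self.sheet({f"s{i}": ("a" if i < 3 else "b") for i in range(6)})
        res = univariate_compare(conc_table(wide), sheet, "group", "a", "b")
        assert res.iloc[0]["method"] == "skipped"
        assert np.isnan(res.iloc[0]["p_value"])

    def test_unknown_group_is_reference_error(self):
        wide = pd.DataFrame({"m1": [1.0, 2.0]}, index=["s0", "s1"])
        sheet = self.sheet({"s0": "a", "s1": "b"})
        with pytest.raises(CrossReferenceError):
            univariate_compare(conc_table(wide), sheet, "group", "a", "zzz")

    def test_q_values_dominate_p_values(self):
        rng = np.random.default_rng(11)
        wide = pd.DataFrame(
            rng.lognormal(0, 1, (12, 8)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"m{j}" for j in range(8)],
        )
        sheet = self.sheet({f"s{i}": ("a" if i < 6 else "b") for i in range(12)})
        res = univariate_compare(conc_table(wide), sheet, "group", "a", "b")
        tested = res.dropna(subset=["p_value"])
        assert (tested["q_value"] >= tested["p_value"] - 1e-12).all()


def bh_step_up(p):
    """Brute-force Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * n / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


class TestBenjaminiHochberg:
    def test_hand_example(self):
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=20,
        )
    )
    def test_matches_brute_force_step_up(self, p):
        assert benjamini_hochberg(np.array(p)) == pytest.approx(bh_step_up(p))


class TestVolcano:
    def results(self, rows):
        return pd.DataFrame(
            rows, columns=["metabolite_id", "log2_fold_change", "p_value", "q_value"]
        )

    def test_rule_examples(self):
        res = self.results(
            [
                ("hit", np.log2(2.0), 0.001, 0.05),
                ("small_fc", np.log2(1.2), 0.0001, 0.001),
                ("weak_q", np.log2(3.0), 0.001, 0.2),
            ]
        )
        assert "hit" in volcano_select(res, 1.5, "raw_p", 0.01)
        assert "small_fc" not in volcano_select(res, 1.5, "raw_p", 0.01)
        assert "weak_q" not in volcano_select(res, 1.5, "fdr_q", 0.1)
        assert "hit" in volcano_select(res, 1.5, "fdr_q", 0.1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_filter(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 30)
        res = self.results(
            [
                (f"m{i}", rng.normal(0, 1.5), rng.uniform(), rng.uniform())
                for i in range(n)
            ]
        )
        for mode, thr in (("raw_p", 0.01), ("fdr_q", 0.1)):
            got = set(volcano_select(res, 1.5, mode, thr))
            col = "p_value" if mode == "raw_p" else "q_value"
            expected = {
                row["metabolite_id"]
                for _, row in res.iterrows()
                if abs(row["log2_fold_change"]) >= np.log2(1.5) and row[col] < thr
            }
            assert got == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            volcano_select(self.results([("m", 1.0, 0.01, 0.01)]), 1.5, "bonf", 0.1)


class TestRatioRegression:
    def test_identity_vectors(self):
        x = np.array([0.5, 1.0, 2.0, 4.0])
        res = regress_ratio_vectors(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.pearson_r == pytest.approx(1.0)

    def test_doubling_closed_form(self):
        x = np.array([0.2, 1.0, 3.0, 5.0, 8.0])
        res = regress_ratio_vectors(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_r_squared_equals_pearson_squared(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            x = rng.lognormal(0, 1, 15)
            y = x * rng.lognormal(0, 0.3, 15)
            res = regress_ratio_vectors(x, y)
            assert res.r_squared == pytest.approx(res.pearson_r**2, rel=1e-9)

    def test_matched_animal_pipeline(self):
        """TIF/plasma ratios per animal, averaged per diet, regressed y on x."""
        rng = np.random.default_rng(21)
        metabolites = [f"m{i}" for i in range(12)]
        true_ratio = rng.lognormal(0, 0.8, 12)  # shared scaling TIF vs plasma
        rows, sheet_rows = [], []
        for diet, animals in (("chow", 5), ("defined", 3)):
            for a in range(animals):
                animal = f"{diet}{a}"
                plasma_conc = rng.lognormal(2, 0.5, 12)
                tif_conc = plasma_conc * true_ratio
                for matrix, conc in (("tif", tif_conc), ("plasma", plasma_conc)):
                    sid = f"{animal}_{matrix}"
                    sheet_rows.append(
                        {
                            "sample_id": sid,
                            "matrix_type": matrix,
                            "diet": diet,
                            "animal_id": animal,
                        }
                    )
                    for m, c in zip(metabolites, conc):
                        rows.append((sid, m, c, "quantified_isotope_dilution"))
        table = ConcentrationTable(
            frame=pd.DataFrame(
                rows, columns=["sample_id", "metabolite_id", "concentration", "status"]
            )
        )
        sheet = SampleSheet(pd.DataFrame(sheet_rows))
        res = ratio_regression(table, sheet, "diet", "chow", "defined")
        # identical per-animal ratios in both diets -> exact identity line
        assert res.slope == pytest.approx(1.0, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0)
        assert res.n_metabolites == 12
        res_log = ratio_regression(table, sheet, "diet", "chow", "defined", log_space=True)
        assert res_log.slope == pytest.approx(1.0, rel=1e-9)

    def test_no_matched_pairs_is_error(self):
        table = ConcentrationTable(
            frame=pd.DataFrame(
                [("s1", "m1", 1.0, "quantified_external")],
                columns=["sample_id", "metabolite_id", "concentration", "status"],
            )
        )
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["s1"],
                    "matrix_type": ["tif"],
                    "diet": ["chow"],
                    "animal_id": ["a1"],
                }
            )
        )
        with pytest.raises(ValidationError):
            ratio_regression(table, sheet, "diet", "chow", "defined")
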