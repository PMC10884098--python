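"""Detection calls, Venn partitions, the p*q prediction and the origin fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from axiscope.coexpression import (
    default_pair_set,
    depth_inflation_diagnostic,
    detect,
    detection_fractions,
    fit_through_origin,
    independence_fit,
    observed_coexpression,
    predicted_coexpression,
    venn_partition,
)
from axiscope.simulate import DepthDist, panel_params, simulate_sc_counts
from axiscope.types import CountMatrix


def _binary(matrix: np.ndarray, genes=None) -> pd.DataFrame:
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    cells = [f"c{j}" for j in range(matrix.shape[1])]
    return pd.DataFrame(matrix.astype(bool), index=genes, columns=cells)


binary_matrices = hnp.arrays(
    dtype=bool,
    shape=st.tuples(st.integers(2, 5), st.integers(1, 40)),
)


class TestDetection:
    def test_all_zero_matrix_detects_nothing(self):
        cm = CountMatrix(genes=["a"], cells=["c1", "c2"], X=np.zeros((1, 2), int))
        assert not detect(cm).to_numpy().any()

    def test_threshold_edge(self):
        cm = CountMatrix(genes=["a"], cells=["c"], X=np.array([[1]]))
        assert detect(cm, min_count=1).iloc[0, 0]
        assert not detect(cm, min_count=2).iloc[0, 0]

    def test_toy_matrix_detection_fractions(self, toy_counts):
        profile = detection_fractions(detect(toy_counts))
        assert profile["gA"] == pytest.approx(2 / 3)
        assert profile["gB"] == pytest.approx(1 / 3)
        assert profile["gC"] == 1.0
        assert profile.n_cells == 3

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError, match="zero cells"):
            detection_fractions(pd.DataFrame(index=["a"], columns=[], dtype=bool))


class TestVennPartition:
    def test_four_cells_enumerated_regions(self):
        # cells: A only, A&B, none, B only
        B = _binary(np.array([[1, 1, 0, 0], [0, 1, 0, 1]]), genes=["A", "B"])
        part = venn_partition(B, ["A", "B"])
        assert part.fractions[("A",)] == 0.25
        assert part.fractions[("B",)] == 0.25
        assert part.fractions[("A", "B")] == 0.25
        assert part.fractions[()] == 0.25

    def test_single_gene_pattern_within_pair(self):
        B = _binary(np.array([[1, 1, 0, 0], [0, 0, 0, 0]]), genes=["A", "B"])
        part = venn_partition(B, ["A", "B"])
        assert part.fractions[("A",)] == 0.5
        assert part.fractions[()] == 0.5
        assert part.union_fraction(["A", "B"]) == 0.5
        assert part.detected_fraction(["A"]) == 0.5

    def test_unknown_gene_rejected(self):
        B = _binary(np.ones((2, 2)))
        with pytest.raises(KeyError):
            venn_partition(B, ["g0", "nope"])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(binary_matrices)
    def test_partition_law(self, matrix):
        B = _binary(matrix)
        k = min(3, matrix.shape[0])
        part = venn_partition(B, list(B.index[:k]))
        assert len(part.fractions) == 2**k
        assert sum(part.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(f >= 0 for f in part.fractions.values())


class TestPrediction:
    def test_pair_product(self):
        profile = detection_fractions(_binary(np.array([[1, 1, 1, 0, 0, 0, 0, 0, 0, 0]])))
        assert predicted_coexpression(profile, ["g0"]) == pytest.approx(0.3)

    @pytest.mark.parametrize(
        "fracs, genes, expected",
        [
            ((0.3, 0.2), ("a", "b"), 0.06),
            ((0.7, 0.0), ("a", "b"), 0.0),
            ((0.453, 0.1, 0.05), ("a", "b", "c"), 0.0022650),
        ],
    )
    def test_products(self, fracs, genes, expected):
        from axiscope.coexpression import DetectionProfile

        profile = DetectionProfile(
            fractions=pd.Series(fracs, index=list(genes)), n_cells=1000
        )
        assert predicted_coexpression(profile, genes) == pytest.approx(expected, abs=1e-12)

    def test_missing_gene_rejected(self):
        from axiscope.coexpression import DetectionProfile

        profile = DetectionProfile(fractions=pd.Series({"a": 0.5}), n_cells=10)
        with pytest.raises(KeyError):
            predicted_coexpression(profile, ["a", "zz"])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(binary_matrices)
    def test_observed_and_predicted_bounded_by_marginals(self, matrix):
        B = _binary(matrix)
        profile = detection_fractions(B)
        pair = list(B.index[:2])
        marg = min(profile[g] for g in pair)
        assert predicted_coexpression(profile, pair) <= marg + 1e-12
        assert observed_coexpression(B, pair) <= marg + 1e-12


def _origin_slope_oracle(x, y):
    """Brute-force least-squares search for the through-origin slope."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sse = lambda b: ((y - b * x) ** 2).sum()
    bound = 1.0 + np.max(np.abs(y)) / np.min(np.abs(x))  # |slope| can't exceed max|y|/min|x|
    lo, hi = -bound, bound
    for _ in range(12):
        grid = np.linspace(lo, hi, 1001)
        best = grid[np.argmin([sse(b) for b in grid])]
        span = (hi - lo) / 1000
        lo, hi = best - span, best + span
    return (lo + hi) / 2


class TestThroughOriginFit:
    def test_exact_line_recovered(self):
        fit = fit_through_origin([2, 4, 6], [1, 2, 3])
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_worked_two_point_fit(self):
        # x=[1,2], y=[2,3]: slope = (2+6)/(1+4) = 1.6; SS_res = 0.2; sum y^2 = 13
        fit = fit_through_origin([2, 3], [1, 2])
        assert fit.slope == pytest.approx(1.6)
        assert fit.r_squared == pytest.approx(1 - 0.2 / 13)

    def test_identity_lists_give_unit_slope(self):
        fit = fit_through_origin([0.1, 0.4, 0.3], [0.1, 0.4, 0.3])
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_all_zero_predictor_rejected(self):
        with pytest.raises(ValueError, match="slope undefined"):
            fit_through_origin([1.0, 2.0], [0.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_through_origin([1.0], [1.0, 2.0])

    def test_corr_convention_is_squared_pearson(self):
        x, y = [1.0, 2.0, 3.0], [2.1, 3.9, 6.2]
        fit = fit_through_origin(y, x, r2="corr")
        assert fit.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.01, 1.0),
                st.floats(0.0, 1.5),
            ),
            min_size=2,
            max_size=15,
        )
    )
    def test_agrees_with_brute_force_grid_search(self, points):
        x = [p[0] for p in points]
        y = [p[1] for p in points]
        fit = fit_through_origin(y, x)
        # 1e-6 absolute near unit slope, relative for steep flat-SSE cases
        assert fit.slope == pytest.approx(_origin_slope_oracle(x, y), rel=1e-6, abs=1e-6)

    def test_agrees_with_no_constant_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        x = rng.uniform(0.01, 0.3, 25)
        y = 1.2 * x + rng.normal(0, 0.01, 25)
        fit = fit_through_origin(y, x)
        res = sm.OLS(y, x).fit()
        assert fit.slope == pytest.approx(res.params[0], abs=1e-10)
        assert fit.r_squared == pytest.approx(res.rsquared, abs=1e-10)


class TestDepthInflation:
    def test_constant_depth_stratified_slopes_near_one(self):
        cm = simulate_sc_counts(
            panel_params(20_000, depth=DepthDist("constant"), seed=13)
        )
        report = depth_inflation_diagnostic(cm)
        assert all(abs(s - 1) < 0.1 for s in report.stratum_slopes)
        assert abs(report.pooled_slope - 1) < 0.05

    def test_heterogeneous_depth_inflates_pooled_but_not_stratified_slope(self):
        cm = simulate_sc_counts(
            panel_params(20_000, depth=DepthDist("lognormal", sigma=0.8), seed=13)
        )
        report = depth_inflation_diagnostic(cm)
        assert report.pooled_slope > 1.0
        # within depth strata the shared covariate is removed
        assert np.mean(np.abs(np.array(report.stratum_slopes) - 1)) < np.abs(
            report.pooled_slope - 1
        )
        top, bottom = (
            report.observed_by_stratum.iloc[-1],
            report.observed_by_stratum.iloc[0],
        )
        assert (top >= bottom).all()

    def test_recorded_depth_falls_back_to_total_counts(self):
        cm = simulate_sc_counts(
            panel_params(500, depth=DepthDist("lognormal", sigma=0.8), seed=3)
        )
        stripped = CountMatrix(genes=cm.genes, cells=cm.cells, X=cm.X)
        report = depth_inflation_diagnostic(stripped, n_strata=2)
        assert report.stratum_sizes == [250, 250]

    def test_fewer_cells_than_strata_rejected(self):
        cm = simulate_sc_counts(panel_params(3, seed=0))
        with pytest.raises(ValueError, match="strata"):
            depth_inflation_diagnostic(cm, n_strata=4)


class TestPipelineConveniences:
    def test_default_pair_set_deduplicates_shared_pairs(self):
        pairs = default_pair_set()
        # three trios share the En2-Hoxa5 pair: 9 - 1 duplicate = 8 pairs
        assert len(pairs) == 8
        assert len({frozenset(p) for p in pairs}) == 8

    def test_independence_fit_defaults_to_all_pairs(self, toy_counts):
        fit = independence_fit(toy_counts)
        assert len(fit.pairs) == 3
        # gA&gB never co-detected; gA&gC joint = 2/3
        frame = fit.to_frame().set_index("pair")
        assert frame.loc["gA&gB", "observed"] == 0.0
        assert frame.loc["gA&gC", "observed"] == pytest.approx(2 / 3)
        assert frame.loc["gA&gC", "predicted"] == pytest.approx(2 / 3)
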