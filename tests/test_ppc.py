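"""Tests for the over-imputation design, replicate summaries, deviance, and
posterior predictive p-values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import overimpute as oi
from overimpute.datasets import BINARY
from overimpute.engine import draw_linear_params
from overimpute.ppc import (
    NormalMeanModel,
    ReplicateMatrix,
    deviance_residuals,
    ppp_completed,
    ppp_expected_completed,
)


def _toy_incomplete(n=10, n_miss=3, seed=0):
    gen = np.random.default_rng(seed)
    vals = np.column_stack([gen.standard_normal(n), gen.standard_normal(n)])
    mask = np.ones((n, 2), dtype=bool)
    vals[:n_miss, 1] = np.nan
    mask[:n_miss, 1] = False
    return oi.IncompleteDataset(vals, mask, ["x", "y"], ["continuous"] * 2)


class TestDesign:
    def test_rows_and_marks_with_partial_missingness(self):
        """10 cases, 3 missing the target: 7 kept + 7 duplicates, 7 marks."""
        design = oi.build_overimputation_design(_toy_incomplete(), "y")
        assert design.data.n_rows == 14
        assert design.where.sum() == 7
        assert design.n_original == 7

    def test_fully_observed_input_doubles(self):
        data = _toy_incomplete(n=8, n_miss=0)
        design = oi.build_overimputation_design(data, "y")
        assert design.data.n_rows == 16
        assert design.where.sum() == 8

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        n=st.integers(min_value=3, max_value=40),
        n_miss=st.integers(min_value=0, max_value=20),
    )
    def test_mark_count_equals_observed_target_rows(self, n, n_miss):
        n_miss = min(n_miss, n - 2)
        data = _toy_incomplete(n=n, n_miss=n_miss, seed=n)
        design = oi.build_overimputation_design(data, "y")
        j = design.data.column("y")
        assert design.where[:, j].sum() == n - n_miss
        assert design.data.n_rows == 2 * (n - n_miss)

    def test_duplicates_mirror_their_sources(self):
        data = _toy_incomplete()
        design = oi.build_overimputation_design(data, "y")
        jx = design.data.column("x")
        assert np.array_equal(
            design.data.values[design.duplicate_rows, jx],
            design.data.values[design.source_rows, jx],
        )
        jy = design.data.column("y")
        assert np.all(np.isnan(design.data.values[design.duplicate_rows, jy]))

    def test_fully_missing_target_errors(self):
        data = _toy_incomplete(n=5, n_miss=5)
        with pytest.raises(ValueError, match="fully missing"):
            oi.build_overimputation_design(data, "y")

    def test_block_target_marks_both_columns(self):
        df = oi.gen_quadratic_covariate(30, seed=1)
        inc = oi.ampute(
            df, oi.AmputationSpec(["x", "x2"], 0.3, "MCAR"),
            rng=np.random.default_rng(2),
        )
        design = oi.build_overimputation_design(inc, ["x", "x2"])
        jx, jx2 = design.data.column("x"), design.data.column("x2")
        assert np.array_equal(design.where[:, jx], design.where[:, jx2])


class TestSummaries:
    def test_degenerate_draws_equal_observed(self):
        obs = np.array([1.0, -2.0, 0.5])
        rep = ReplicateMatrix(obs, np.tile(obs[:, None], (1, 10)))
        s = oi.summarize_replicates(rep, 0.95)
        assert s.cov == 1.0 and s.distance == 0.0 and s.ciw == 0.0

    @pytest.mark.parametrize(
        "level,width", [(0.95, 2 * 1.959964), (0.75, 2 * 1.150349)]
    )
    def test_interval_width_approaches_analytic_normal_limit(self, level, width):
        gen = np.random.default_rng(21)
        rep = ReplicateMatrix(np.zeros(1), gen.standard_normal((1, 10_000)))
        s = oi.summarize_replicates(rep, level)
        assert abs(s.ciw - width) < 0.02 * width

    def test_distance_approaches_folded_normal_mean(self):
        """Aggregated over many points of a correct unit-variance model,
        Distance tends to sqrt(2/pi)."""
        gen = np.random.default_rng(22)
        n, m = 10_000, 200
        obs = gen.standard_normal(n)
        rep = ReplicateMatrix(obs, gen.standard_normal((n, m)))
        s = oi.summarize_replicates(rep, 0.95)
        assert abs(s.distance - np.sqrt(2 / np.pi)) < 0.02 * np.sqrt(2 / np.pi)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        n=st.integers(min_value=1, max_value=8),
        m=st.integers(min_value=2, max_value=40),
        level=st.floats(min_value=0.5, max_value=0.99),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_quantile_bounds_match_sort_and_interpolate_oracle(
        self, n, m, level, seed
    ):
        """Bounds agree with a hand-rolled type-7 (sort + linear
        interpolation on order statistics) implementation."""
        gen = np.random.default_rng(seed)
        rep = ReplicateMatrix(gen.standard_normal(n), gen.standard_normal((n, m)))
        s = oi.summarize_replicates(rep, level)

        def type7(row, p):
            srt = np.sort(row)
            h = (len(row) - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, len(row) - 1)
            return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

        alpha = 1 - level
        for i in range(n):
            assert np.isclose(s.lower[i], type7(rep.draws[i], alpha / 2))
            assert np.isclose(s.upper[i], type7(rep.draws[i], 1 - alpha / 2))
            assert s.lower[i] <= s.upper[i]

    def test_non_finite_draws_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ReplicateMatrix(np.zeros(1), np.array([[np.nan, 1.0]]))

    def test_invalid_level_rejected(self):
        rep = ReplicateMatrix(np.zeros(1), np.zeros((1, 3)))
        with pytest.raises(ValueError, match="level"):
            oi.summarize_replicates(rep, 1.5)


class TestDeviance:
    def test_half_probability_contribution(self):
        """y = 1 against p~ = 0.5 contributes 2 log 2."""
        rep = ReplicateMatrix(
            np.ones(1), np.array([[1.0, 0.0] * 25]), kind=BINARY
        )
        assert np.isclose(oi.mean_squared_deviance(rep), 2 * np.log(2))

    def test_clipping_keeps_perfect_agreement_finite(self):
        """y = 1 with all 50 draws 1: p~ clips to 1 - 1/100, contributing
        -2 log(1 - 1/100)."""
        rep = ReplicateMatrix(np.ones(1), np.ones((1, 50)), kind=BINARY)
        assert np.isclose(oi.mean_squared_deviance(rep), -2 * np.log(0.99))

    def test_residual_sign_follows_observation(self):
        draws = np.tile(np.array([[1.0] * 30 + [0.0] * 20]), (2, 1))
        rep = ReplicateMatrix(np.array([1.0, 0.0]), draws, kind=BINARY)
        resid = deviance_residuals(rep)
        assert resid[0] > 0 > resid[1]

    def test_continuous_matrix_rejected(self):
        rep = ReplicateMatrix(np.zeros(1), np.zeros((1, 4)))
        with pytest.raises(ValueError, match="binary"):
            oi.mean_squared_deviance(rep)


class TestPValues:
    def test_always_larger_replicate_gives_p_one(self, univariate_normal_incomplete, rng):
        mdl = NormalMeanModel(0)

        def T(M):
            return M[0, 0]  # constant positions; replicate vs completed

        def replicator(data, theta, rng_):
            out = mdl.replicator(data, theta, rng_)
            out[0, 0] = 1e9
            return out

        res = ppp_completed(
            T, mdl.imputer, replicator, univariate_normal_incomplete, N=20, rng=rng
        )
        assert res.p_value == 1.0

    def test_congenial_model_p_values_center_without_degenerating(self, rng):
        """Completed-data p-values under the true model concentrate around
        1/2 (the known conservatism of refit posterior predictive checks)
        and never drift to the extremes."""
        mdl = NormalMeanModel(0)
        ps = []
        for _ in range(120):
            y = rng.standard_normal(50)
            mask = rng.random(50) < 0.3
            vals = y.copy()
            vals[mask] = np.nan
            data = oi.IncompleteDataset(
                vals[:, None], ~mask[:, None], ["y"], ["continuous"]
            )
            res = ppp_completed(
                lambda M: M.mean(), mdl.imputer, mdl.replicator, data, N=60, rng=rng
            )
            ps.append(res.p_value)
        ps = np.array(ps)
        assert 0.05 < ps.min() and ps.max() < 0.95
        assert ps.std() > 0.02
        assert abs(ps.mean() - 0.5) < 0.05

    def test_misspecified_linear_model_flags_quadratic_data(self, rng):
        """Residual skewness of a linear completion of quadratic data is an
        extreme test quantity: p falls outside (0.05, 0.95)."""
        from scipy.stats import skew

        df = oi.gen_quadratic_outcome(300, seed=2)
        inc = oi.ampute(
            df, oi.AmputationSpec(["y"], 0.3, "MCAR"), rng=np.random.default_rng(3)
        )

        class LinearModel:
            def imputer(self, data, rng_, theta=None):
                j, jx = data.column("y"), data.column("x")
                X = np.column_stack([np.ones(data.n_rows), data.values[:, jx]])
                obs = data.observed_mask[:, j]
                if theta is None:
                    p = draw_linear_params(data.values[obs, j], X[obs], rng_)
                    theta = (p.beta_star, p.sigma_star)
                beta, sigma = theta
                y_mis = X[~obs] @ beta + sigma * rng_.standard_normal((~obs).sum())
                return theta, y_mis

            def replicator(self, data, theta, rng_):
                beta, sigma = theta
                jx = data.column("x")
                X = np.column_stack([np.ones(data.n_rows), data.values[:, jx]])
                out = data.values.copy()
                out[:, data.column("y")] = X @ beta + sigma * rng_.standard_normal(
                    data.n_rows
                )
                return out

        def T(M):
            x, y = M[:, 0], M[:, 1]
            X = np.column_stack([np.ones(len(x)), x])
            b = np.linalg.lstsq(X, y, rcond=None)[0]
            return skew(y - X @ b)

        mdl = LinearModel()
        res = ppp_completed(T, mdl.imputer, mdl.replicator, inc, N=100, rng=rng)
        assert res.p_value < 0.05 or res.p_value > 0.95

    def test_inner_averaging_reduces_variance(self, univariate_normal_incomplete, rng):
        """Expected-completed differences, inner-averaged over re-imputations
        at fixed theta, vary less than single completed-data differences."""
        mdl = NormalMeanModel(0)

        def T(M):
            return M.var()

        rc = ppp_completed(
            T, mdl.imputer, mdl.replicator, univariate_normal_incomplete,
            N=200, rng=rng,
        )
        re = ppp_expected_completed(
            T, mdl.imputer, mdl.replicator, univariate_normal_incomplete,
            N1=200, N2=10, rng=rng,
        )
        assert re.mean_differences.var() <= re.differences[:, 0].var()
        assert re.mean_differences.var() < rc.differences.var()

    def test_single_inner_draw_degenerates_to_plain_difference(
        self, univariate_normal_incomplete, rng
    ):
        mdl = NormalMeanModel(0)
        res = ppp_expected_completed(
            lambda M: M.var(), mdl.imputer, mdl.replicator,
            univariate_normal_incomplete, N1=25, N2=1, rng=rng,
        )
        assert res.differences.shape == (25, 1)
        assert np.array_equal(res.mean_differences, res.differences[:, 0])

    def test_all_negative_differences_give_p_zero(self, univariate_normal_incomplete, rng):
        mdl = NormalMeanModel(0)

        def replicator(data, theta, rng_):
            out = mdl.replicator(data, theta, rng_)
            return out - 1e9  # replicate observed part far below the data

        res = ppp_expected_completed(
            lambda M: M.mean(), mdl.imputer, replicator,
            univariate_normal_incomplete, N1=10, N2=3, rng=rng,
        )
        assert res.p_value == 0.0

    def test_non_finite_test_quantity_errors(self, univariate_normal_incomplete, rng):
        mdl = NormalMeanModel(0)
        with pytest.raises(ValueError, match="non-finite"):
            ppp_completed(
                lambda M: np.nan, mdl.imputer, mdl.replicator,
                univariate_normal_incomplete, N=3, rng=rng,
            )
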