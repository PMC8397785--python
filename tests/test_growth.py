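"""Regression models, density-dependence inference and hypothesis tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from microcolony import growth as gr
from microcolony.lineage import CellRecord
from microcolony.simulate import SimBatchConfig, simulate_batch_curve


class TestFitGrowthModel:
    def test_exact_exponential_counts(self):
        fit = gr.fit_growth_model([0, 1, 2, 3], [1, 2, 4, 8], "exponential")
        assert fit.params["r"] == pytest.approx(math.log(2), rel=1e-9)
        assert fit.doubling_time_h == pytest.approx(1.0, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_exact_linear_data(self):
        x = np.arange(5.0)
        fit = gr.fit_growth_model(x, 3 + 2 * x, "linear")
        assert fit.params == pytest.approx({"a": 3.0, "b": 2.0}, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_fits_match_normal_equations_oracle(self, rng):
        # independent oracle: solve X'X beta = X'y explicitly
        x = rng.uniform(1, 10, size=15)
        y = 2.0 - 0.3 * x + rng.normal(0, 0.5, size=15)
        fit = gr.fit_growth_model(x, y, "linear")
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.params["a"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.params["b"] == pytest.approx(beta[1], abs=1e-10)

        fit_sl = gr.fit_growth_model(x, y, "semilog-linear")
        Xs = np.column_stack([np.ones_like(x), np.log10(x)])
        beta_s = np.linalg.solve(Xs.T @ Xs, Xs.T @ y)
        assert fit_sl.params["a"] == pytest.approx(beta_s[0], abs=1e-10)
        assert fit_sl.params["b"] == pytest.approx(beta_s[1], abs=1e-10)

    @pytest.mark.parametrize(
        "model,params,fn",
        [
            ("monod", {"Ymax": 0.35, "K": 4.0}, lambda x, p: p["Ymax"] * x / (p["K"] + x)),
            (
                "saturating-exponential",
                {"Ymax": 0.4, "k": 0.2},
                lambda x, p: p["Ymax"] * (1 - np.exp(-p["k"] * x)),
            ),
            (
                "logistic",
                {"K": 0.5, "r": 0.3, "N0": 0.01},
                lambda x, p: p["K"] / (1 + ((p["K"] - p["N0"]) / p["N0"]) * np.exp(-p["r"] * x)),
            ),
        ],
    )
    def test_nonlinear_fits_recover_noiseless_parameters(self, model, params, fn):
        x = np.linspace(0.5, 40, 30)
        fit = gr.fit_growth_model(x, fn(x, params), model)
        for name, val in params.items():
            assert fit.params[name] == pytest.approx(val, rel=1e-6)

    def test_noisy_logistic_recovery_within_five_percent(self):
        cfg = SimBatchConfig(K=0.4, r=0.35, N0=0.005, noise_sd=0.004, seed=77)
        curve = simulate_batch_curve(cfg)
        fit = gr.fit_growth_model(curve["time_h"], curve["od600"], "logistic")
        assert fit.params["K"] == pytest.approx(0.4, rel=0.05)
        assert fit.params["r"] == pytest.approx(0.35, rel=0.05)

    def test_constant_response_flags_undefined_r2(self):
        fit = gr.fit_growth_model([0, 1, 2, 3], [2.0, 2.0, 2.0, 2.0], "linear")
        assert np.isnan(fit.r2)

    def test_too_few_points_is_an_error(self):
        with pytest.raises(gr.FitError):
            gr.fit_growth_model([0, 1], [1, 2], "logistic")


class TestModelSelection:
    def test_exponential_data_selects_exponential(self):
        t = np.arange(8.0)
        y = 2 * np.exp(0.4 * t)
        fits = [gr.fit_growth_model(t, y, m) for m in ("linear", "exponential")]
        assert gr.select_best_model(fits).model == "exponential"

    def test_linear_data_selects_linear(self):
        t = np.arange(8.0)
        y = 5 + 2 * t
        fits = [gr.fit_growth_model(t, y, m) for m in ("linear", "exponential")]
        assert gr.select_best_model(fits).model == "linear"

    def test_exact_tie_prefers_fewer_parameters(self):
        f2 = gr.GrowthFit("linear", {"a": 0, "b": 1}, 0.9, 5)
        f3 = gr.GrowthFit("logistic", {"K": 1, "r": 1, "N0": 0.1}, 0.9, 4)
        assert gr.select_best_model([f3, f2]).model == "linear"

    def test_all_failed_is_selection_error(self):
        bad = gr.GrowthFit("linear", {}, float("nan"), 3, success=False)
        with pytest.raises(gr.FitError):
            gr.select_best_model([bad])


def _records(births, rates):
    return [
        CellRecord(f"c{i}", None, b, b + 1.0, "censored", r, 0, 0.0, 0.0)
        for i, (b, r) in enumerate(zip(births, rates))
    ]


class TestBinning:
    EDGES = np.linspace(0.0, 18.6, 8)

    def test_median_rate_of_first_bin(self):
        counts = pd.DataFrame({"time_h": [0.0, 1.0, 2.0], "n_sessile": [5, 5, 5]})
        bins = gr.bin_growth_by_birth_time(
            _records([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]), counts, self.EDGES
        )
        assert len(bins) == 1
        assert bins[0].median_rate == pytest.approx(0.2)
        assert bins[0].mean_count == 5.0
        assert bins[0].n_cells == 3

    def test_birth_on_boundary_goes_to_second_bin(self):
        counts = pd.DataFrame({"time_h": np.linspace(0, 18.6, 10), "n_sessile": 5})
        boundary = self.EDGES[1]
        bins = gr.bin_growth_by_birth_time(_records([boundary], [0.5]), counts, self.EDGES)
        assert bins[0].bin_lo_h == pytest.approx(boundary)

    def test_empty_bins_omitted(self):
        counts = pd.DataFrame({"time_h": [0.0, 18.6], "n_sessile": [5, 5]})
        bins = gr.bin_growth_by_birth_time(_records([1.0, 17.0], [0.1, 0.2]), counts, self.EDGES)
        assert len(bins) == 2

    def test_bin_mean_counts_match_ground_truth_series(self, small_chamber):
        from microcolony.lineage import reconstruct_lineage, sessile_count_series

        table, truth = small_chamber
        tree = reconstruct_lineage(table)
        counts = sessile_count_series(tree, truth.frame_times)
        recs = list(tree.records.values())
        edges = np.linspace(0.0, 14.0, 8)
        bins = gr.bin_growth_by_birth_time(recs, counts, edges)
        t = np.asarray(truth.frame_times)
        c = np.asarray(truth.sessile_counts, dtype=float)
        for b in bins:
            sel = (t >= b.bin_lo_h) & ((t < b.bin_hi_h) if b.bin_hi_h < 14.0 else (t <= 14.0))
            assert b.mean_count == pytest.approx(c[sel].mean())


class TestRateDensitySlope:
    def test_hand_value(self):
        bins = [
            gr.BinSummary(0, 1, 0.1, 10, 3),
            gr.BinSummary(1, 2, 0.2, 20, 3),
            gr.BinSummary(2, 3, 0.3, 30, 3),
        ]
        assert gr.rate_density_slope(bins) == pytest.approx(0.01, abs=1e-12)

    def test_flat_rates_give_zero_slope(self):
        bins = [gr.BinSummary(i, i + 1, 0.2, 10 * (i + 1), 3) for i in range(4)]
        assert gr.rate_density_slope(bins) == pytest.approx(0.0, abs=1e-12)

    def test_initial_derivative_variant_inverts_half_saturation(self):
        n = np.array([2.0, 5, 10, 20, 40, 60])
        bins = [
            gr.BinSummary(i, i + 1, 0.35 * x / (4.0 + x), x, 3) for i, x in enumerate(n)
        ]
        d = gr.rate_density_slope(bins, method="initial-derivative")
        assert d == pytest.approx(0.35 / 4.0, rel=1e-4)

    def test_too_few_bins_undefined(self):
        with pytest.raises(gr.FitError):
            gr.rate_density_slope([gr.BinSummary(0, 1, 0.1, 10, 2)] * 2)


class TestAncova:
    def test_zero_partial_effect_of_count(self, rng):
        births = rng.uniform(0, 10, 12)
        rates = 0.1 + 0.02 * births  # exact function of birth time only
        counts = rng.uniform(5, 50, 12)
        res = gr.ancova_rate_density(rates, counts, births)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_f_statistic_matches_normal_equation_oracle(self, rng):
        births = np.array([0.0, 1, 2, 3, 4, 5, 6, 7])
        counts = np.array([4.0, 5, 8, 13, 20, 30, 44, 60])
        rates = np.array([0.10, 0.12, 0.15, 0.16, 0.21, 0.22, 0.26, 0.27])
        res = gr.ancova_rate_density(rates, counts, births)

        def ssr(X):
            beta, *_ = np.linalg.lstsq(X, rates, rcond=None)
            resid = rates - X @ beta
            return float(resid @ resid)

        one = np.ones_like(births)
        ssr_red = ssr(np.column_stack([one, births]))
        ssr_full = ssr(np.column_stack([one, births, counts]))
        f_expected = (ssr_red - ssr_full) / (ssr_full / 5)  # df_resid = 8 - 3
        assert res.statistic == pytest.approx(f_expected, rel=1e-10)
        assert res.effect_size == pytest.approx(
            (ssr_red - ssr_full) / ssr_red, rel=1e-10
        )

    def test_duplicating_rows_raises_f_but_not_eta_squared(self, rng):
        births = rng.uniform(0, 10, 10)
        counts = births * 3 + rng.uniform(0, 5, 10)
        rates = 0.1 + 0.01 * births + 0.002 * counts + rng.normal(0, 0.01, 10)
        res1 = gr.ancova_rate_density(rates, counts, births)
        res2 = gr.ancova_rate_density(
            np.tile(rates, 2), np.tile(counts, 2), np.tile(births, 2)
        )
        assert res2.statistic > res1.statistic
        assert res2.effect_size == pytest.approx(res1.effect_size, rel=1e-9)


class TestInstantaneousRate:
    def test_recovers_density_dependent_rate_pointwise(self, small_chamber):
        table, truth = small_chamber
        inst = gr.instantaneous_rate_vs_count(table)
        params = truth.config.substrates["xylan"]
        for n, r in zip(inst["n_cells"], inst["rate_per_h"]):
            assert r == pytest.approx(params.rate(n), rel=1e-9)


class TestBatchMetrics:
    def test_noiseless_logistic_half_maximum_time(self):
        t = np.linspace(0, 15, 400)
        cfg = SimBatchConfig(K=1.0, r=1.0, N0=0.01, noise_sd=0.0, sample_times_h=tuple(t))
        curve = simulate_batch_curve(cfg)
        m = gr.batch_metrics(curve, smooth_window=1)
        assert m.t_half_h == pytest.approx(math.log(99.0), abs=0.02)
        assert m.max_growth_rate == pytest.approx(1.0, rel=1e-4)

    def test_constant_od_has_negligible_rate(self):
        curve = pd.DataFrame({"time_h": np.arange(10.0), "od600": np.full(10, 0.2)})
        m = gr.batch_metrics(curve)
        assert (not m.fit.success) or abs(m.max_growth_rate) < 1e-3

    def test_seeded_noisy_curve_rate_within_five_percent(self):
        cfg = SimBatchConfig(K=0.4, r=0.35, N0=0.005, noise_sd=0.004, seed=3)
        m = gr.batch_metrics(simulate_batch_curve(cfg))
        assert m.max_growth_rate == pytest.approx(0.35, rel=0.05)


class TestSemilogInoculum:
    DENS = np.array([1e3, 1e4, 1e5, 1e6])

    def test_exact_semilog_relationship(self):
        th = 10 - 2 * np.log10(self.DENS)
        fits, _ = gr.semilog_inoculum_regression(
            {"a": th, "b": th}, {"a": self.DENS, "b": self.DENS}
        )
        assert fits["a"].params["b"] == pytest.approx(-2.0, abs=1e-10)
        assert fits["a"].r2 == pytest.approx(1.0, abs=1e-12)

    def test_identical_groups_do_not_reject(self):
        th = 10 - 2 * np.log10(self.DENS) + np.array([0.1, -0.1, 0.05, -0.05])
        _, res = gr.semilog_inoculum_regression(
            {"a": th, "b": th}, {"a": self.DENS, "b": self.DENS}
        )
        assert res.p_value > 0.9

    def test_distinct_slopes_reject_at_five_percent(self, rng):
        th_a = 100 - 6.78 * np.log10(self.DENS) + rng.normal(0, 0.2, 4)
        th_b = 100 - 3.41 * np.log10(self.DENS) + rng.normal(0, 0.2, 4)
        _, res = gr.semilog_inoculum_regression(
            {"a": th_a, "b": th_b}, {"a": self.DENS, "b": self.DENS}
        )
        assert res.p_value < 0.05

    def test_nonpositive_density_is_domain_error(self):
        with pytest.raises(ValueError):
            gr.semilog_inoculum_regression(
                {"a": np.ones(3), "b": np.ones(3)},
                {"a": np.array([0.0, 1, 2]), "b": np.array([1.0, 2, 3])},
            )


def enumerate_mann_whitney_p(a, b):
    """Oracle: exact two-sided p over all C(6,3)=20 rank assignments."""
    pooled = np.concatenate([a, b])
    n = len(a)

    def u_of(idx):
        xa = pooled[list(idx)]
        xb = np.delete(pooled, list(idx))
        return sum((va > vb) + 0.5 * (va == vb) for va in xa for vb in xb)

    mean_u = len(a) * len(b) / 2
    obs = abs(u_of(range(n)) - mean_u)
    assignments = list(itertools.combinations(range(len(pooled)), n))
    extreme = sum(abs(u_of(c) - mean_u) >= obs - 1e-12 for c in assignments)
    return extreme / len(assignments)


class TestStatTests:
    def test_complete_separation_three_vs_three_exact_p(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = gr.stat_tests({"sep": (a, b)}, test="mann-whitney")[0]
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.p_value == pytest.approx(enumerate_mann_whitney_p(a, b), abs=1e-12)

    def test_eta_squared_from_t_and_df(self):
        # eta^2 = t^2/(t^2+df): t=2, df=4 gives 0.5
        assert 2.0**2 / (2.0**2 + 4) == 0.5
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 6)
        res = gr.stat_tests({"ab": (a, b)}, test="t")[0]
        assert res.effect_size == pytest.approx(
            res.statistic**2 / (res.statistic**2 + 10), abs=1e-12
        )

    def test_bh_step_up_hand_case(self):
        # p = (0.01, 0.02, 0.03, 0.04): q_i = min_{j>=i} p_j * 4 / j = 0.04 all
        qs = gr.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(qs, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_fdr_attaches_q_values_no_smaller_than_p(self, rng):
        groups = {
            f"g{i}": (rng.normal(0, 1, 5), rng.normal(0.5, 1, 5)) for i in range(5)
        }
        results = gr.stat_tests(groups, test="t", fdr=True)
        for r in results:
            assert r.q_value is not None and r.q_value >= r.p_value - 1e-12

    def test_zero_variance_equal_means_convention(self):
        res = gr.stat_tests({"flat": ([1.0, 1.0], [1.0, 1.0])}, test="t")[0]
        assert res.p_value == 1.0 and "convention" in res.note

    def test_exact_and_asymptotic_mann_whitney_agree_for_moderate_n(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        exact = gr.stat_tests({"x": (a, b)}, test="mann-whitney", exact_threshold=8)[0]
        approx = gr.stat_tests({"x": (a, b)}, test="mann-whitney", exact_threshold=1)[0]
        assert exact.p_value == pytest.approx(approx.p_value, abs=0.03)
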