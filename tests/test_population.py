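import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from incval.metrics import ap, auc
from incval.population import (
    AccuracyError,
    QuadratureSettings,
    TrueModelSpec,
    achieved_event_rate,
    correlation_and_concordance,
    default_grid,
    population_coefficients,
    run_sweep,
    scenario_incv,
    score_distribution_pair,
    solve_beta0,
    summarize_sweep,
)


class TestSolveBeta0:
    def test_no_markers_reduces_to_probit_quantile(self):
        assert solve_beta0(0, 0, 0, 0.2) == pytest.approx(norm.ppf(0.2), abs=1e-9)

    def test_no_interaction_closed_form(self):
        # E[Phi(a + b'Z)] = Phi(a / sqrt(1 + |b|^2)) for Gaussian markers
        b1, b2, pi = 1.0, 0.8, 0.05
        expected = norm.ppf(pi) * np.sqrt(1 + b1**2 + b2**2)
        assert solve_beta0(b1, b2, 0.0, pi) == pytest.approx(expected, abs=1e-8)
        assert expected == pytest.approx(-2.6726, abs=5e-4)

    def test_calibration_against_monte_carlo(self, rng):
        spec = TrueModelSpec.calibrated(1.0, 0.8, -0.5, 0.01)
        n = 4_000_000
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        d = rng.random(n) < spec.true_risk(x, y)
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(d.mean() - 0.01) < 3 * se

    def test_quadrature_rate_matches_target(self):
        for params in [(0.3, 1.0, 0.5, 0.5), (1.0, 1.0, -0.5, 0.01)]:
            spec = TrueModelSpec.calibrated(*params)
            assert abs(achieved_event_rate(spec) - params[3]) < 1e-8

    def test_invalid_pi(self):
        with pytest.raises(ValueError):
            solve_beta0(1.0, 0.8, 0.2, 1.5)


class TestPopulationCoefficients:
    def test_true_model_inside_working_class(self):
        # without interaction the two-marker probit IS the true model
        spec = TrueModelSpec.calibrated(0.7, 0.5, 0.0, 0.1)
        work = population_coefficients(spec, ("x", "y"))
        assert np.allclose(work.gamma, (spec.beta0, 0.7, 0.5), atol=1e-7)

    def test_single_marker_truth(self):
        spec = TrueModelSpec.calibrated(0.9, 0.0, 0.0, 0.2)
        work = population_coefficients(spec, ("x",))
        assert np.allclose(work.gamma, (spec.beta0, 0.9), atol=1e-7)

    def test_against_large_sample_probit_fit(self, rng):
        from incval.synthetic import fit_probit, sample_true_model

        spec = TrueModelSpec.calibrated(1.0, 0.8, 0.2, 0.05)
        pop = population_coefficients(spec, ("x", "y"))
        sample = sample_true_model(spec, 2_000_000, seed=77)
        fit = fit_probit(sample, ("x", "y"))
        # asymptotic SEs from the inverse information of the fit
        eta = fit.linear_predictor(sample.x, sample.y)
        p = norm.cdf(eta)
        w = norm.pdf(eta) ** 2 / (p * (1 - p))
        Z = np.column_stack([np.ones(sample.n), sample.x, sample.y])
        se = np.sqrt(np.diag(np.linalg.inv((Z * w[:, None]).T @ Z)))
        assert np.all(np.abs(np.array(fit.gamma) - np.array(pop.gamma)) < 3 * se)


class TestScoreDistributionPair:
    def test_mixture_identity_is_exact_normal(self):
        spec = TrueModelSpec.calibrated(1.0, 0.8, 0.2, 0.01)
        for markers in (("x",), ("x", "y")):
            work = population_coefficients(spec, markers)
            pair, _ = score_distribution_pair(spec, work)  # raises if > 1e-6
            g = work.gamma
            s = abs(g[1]) if len(g) == 2 else float(np.hypot(g[1], g[2]))
            mix = spec.pi * pair.f1_values + (1 - spec.pi) * pair.f0_values
            marginal = norm.cdf((pair.thresholds - g[0]) / s)
            assert np.max(np.abs(mix - marginal)) < 1e-6

    def test_conditional_cdfs_against_monte_carlo(self, rng):
        spec = TrueModelSpec.calibrated(1.0, 0.8, 0.2, 0.01)
        work = population_coefficients(spec, ("x", "y"))
        pair, _ = score_distribution_pair(spec, work)
        n = 2_000_000
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        d = rng.random(n) < spec.true_risk(x, y)
        eta = work.linear_predictor(x, y)
        for q in (0.1, 0.3, 0.5, 0.7, 0.9):
            c = float(np.quantile(eta[d], q))
            for scores, cdf in ((eta[d], pair.cdf1), (eta[~d], pair.cdf0)):
                mc = np.mean(scores <= c)
                se = np.sqrt(mc * (1 - mc) / scores.size)
                assert abs(mc - cdf(c)) < 3 * se + 1e-4

    def test_true_model_has_strictly_better_sbrs(self):
        # with beta3 = 0 the two-marker working model is the true model and
        # the strictly proper Brier score must prefer it
        spec = TrueModelSpec.calibrated(0.8, 0.6, 0.0, 0.1)
        sbrs = {}
        for markers in (("x",), ("x", "y")):
            work = population_coefficients(spec, markers)
            _, comp = score_distribution_pair(spec, work)
            sbrs[markers] = comp.sbrs
        assert sbrs[("x", "y")] > sbrs[("x",)]


class TestScenarioIncv:
    @pytest.mark.parametrize(
        "beta, expected_metric, expected",
        [
            ((1.0, 0.8, 0.2), "d_ap", 0.3339),
            ((1.0, 0.8, -0.5), "d_ap", -0.0720),
            ((0.6, 0.7, -0.4), "d_auc", 0.2018),
            ((0.7, 0.3, -0.3), "d_auc", -0.0011),
        ],
    )
    def test_selected_rare_outcome_scenarios(self, beta, expected_metric, expected):
        res = scenario_incv(*beta, 0.01)
        assert getattr(res, expected_metric) == pytest.approx(expected, abs=5e-4)

    def test_incvs_are_new_minus_old(self):
        res = scenario_incv(0.5, 0.5, 0.3, 0.2)
        assert res.d_auc == pytest.approx(res.auc_2m - res.auc_1m)
        assert res.d_ap == pytest.approx(res.ap_2m - res.ap_1m)
        assert res.d_sbrs == pytest.approx(res.sbrs_2m - res.sbrs_1m)

    def test_quadrature_stability(self, rng):
        # doubling every resolution knob moves each IncV by far less than
        # the 5e-4 stability budget
        doubled = QuadratureSettings(n_u=8001, gh_inner=200, gh_tensor=200,
                                     n_x=8001)
        for _ in range(5):
            b1, b2 = rng.uniform(0.3, 1.0, 2)
            b3 = rng.uniform(0.1, 0.5) * rng.choice([-1, 1])
            pi = rng.choice([0.01, 0.1, 0.5])
            base = scenario_incv(b1, b2, b3, pi)
            fine = scenario_incv(b1, b2, b3, pi, settings=doubled)
            for m in ("d_auc", "d_ap", "d_sbrs"):
                assert abs(getattr(base, m) - getattr(fine, m)) < 5e-4


class TestSweep:
    def test_default_grid_size(self):
        grid = default_grid()
        n = (len(grid["beta1"]) * len(grid["beta2"]) * len(grid["beta3"])
             * len(grid["pi"]))
        assert n == 3200
        assert 0.0 not in grid["beta3"]

    def test_single_cell_matches_scenario(self):
        grid = {"beta1": [0.5], "beta2": [0.8], "beta3": [-0.2], "pi": [0.1]}
        table = run_sweep(grid)
        assert len(table) == 1
        direct = scenario_incv(0.5, 0.8, -0.2, 0.1)
        assert table.loc[0, "d_ap"] == pytest.approx(direct.d_ap, abs=1e-12)

    def test_true_two_marker_variant_all_positive(self):
        # supplementary-style variant: beta3 = 0, the added marker is real
        grid = {"beta1": [0.3, 0.7, 1.0], "beta2": [0.3, 0.7, 1.0],
                "beta3": [0.0], "pi": [0.01, 0.1, 0.5]}
        table = run_sweep(grid)
        assert (table[["d_auc", "d_ap", "d_sbrs"]] > 0).all().all()
        # and sign agreement of every IncV pair is then perfect
        for pair in (("d_sbrs", "d_ap"), ("d_auc", "d_ap")):
            _, conc = correlation_and_concordance(table, pair, 0.1)
            assert conc == 1.0

    def test_cache_resume(self, tmp_path):
        grid = {"beta1": [0.4, 0.6], "beta2": [0.5], "beta3": [0.2], "pi": [0.2]}
        cache = tmp_path / "cache.csv"
        first = run_sweep(grid, cache_path=cache)
        # rerun must reuse the cached rows verbatim
        again = run_sweep(grid, cache_path=cache)
        pd.testing.assert_frame_equal(
            first.reset_index(drop=True), again.reset_index(drop=True))


@pytest.fixture(scope="module")
def small_table():
    grid = {"beta1": [0.4, 1.0], "beta2": [0.4, 1.0],
            "beta3": [-0.3, 0.3], "pi": [0.05, 0.2]}
    return run_sweep(grid)


class TestSummaries:
    def test_five_number_shape_and_counts(self, small_table):
        summary = summarize_sweep(small_table)
        assert len(summary.five_number) == 2 * 3  # pi values x metrics
        assert (summary.five_number["n"] == 8).all()
        assert (summary.five_number["min"] <= summary.five_number["median"]).all()
        assert (summary.five_number["median"] <= summary.five_number["max"]).all()

    def test_concordance_bounds(self, small_table):
        summary = summarize_sweep(small_table)
        assert summary.agreement["concordance"].between(-1, 1).all()
        assert summary.agreement["pearson"].between(-1, 1).all()

    def test_correlation_undefined_on_constant_column(self, small_table):
        t = small_table.copy()
        t["d_auc"] = 0.1
        with pytest.raises(ValueError, match="zero variance"):
            correlation_and_concordance(t, ("d_auc", "d_ap"), 0.05)

    def test_domain_invariants(self, small_table):
        assert small_table["d_auc"].between(-0.5, 0.5).all()
        for _, row in small_table.iterrows():
            assert row.pi - 1 <= row.d_ap <= 1 - row.pi
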