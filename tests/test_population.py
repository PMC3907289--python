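"""Tests of the single-cell variability engine and error-ellipse estimator."""

import numpy as np
import pandas as pd
import pytest

from nerkinetics.control import propagate_cv
from nerkinetics.datasets import generate_paired_measurements
from nerkinetics.model import FACTORS
from nerkinetics.population import (
    PopulationSpec,
    correlate,
    error_ellipse,
    lognormal_mean_cv,
    simulate_population,
    variance_decomposition,
)


class TestPopulationSimulation:
    def test_zero_cv_gives_identical_cells(self, ref_params):
        spec = PopulationSpec(n_cells=5, cv_factors=0.0, cv_lesions=0.0,
                              times=(30.0,), seed=1)
        table = simulate_population(ref_params, spec)
        assert table["edu_30min"].nunique() == 1
        assert table["conc_XPC_uM"].nunique() == 1

    def test_seed_determinism(self, ref_params):
        spec = PopulationSpec(n_cells=8, times=(30.0,), seed=123)
        a = simulate_population(ref_params, spec)
        b = simulate_population(ref_params, spec)
        pd.testing.assert_frame_equal(a, b)

    def test_late_time_cv_approaches_lesion_cv(self, ref_params, population_run):
        # once repair is complete the incorporated EdU equals the lesion
        # dose, so its CV collapses onto the dose CV
        spec, table = population_run
        edu = table["edu_240min"]
        cv = edu.std(ddof=1) / edu.mean()
        assert cv == pytest.approx(spec.cv_lesions, rel=0.15)

    def test_early_cv_matches_propagation_law(self, ref_params, ref_response,
                                              population_run):
        spec, table = population_run
        edu = table["edu_30min"]
        cv = edu.std(ddof=1) / edu.mean()
        predicted = propagate_cv(ref_response, spec.cv_factors, spec.cv_lesions).cv_rate
        assert cv == pytest.approx(predicted, rel=0.10)

    def test_accumulation_linear_in_expression(self, ref_params):
        # damage sites are not saturated: with only one factor varying, its
        # accumulation scales linearly with its nuclear concentration
        for f in ("XPC", "XPA"):
            spec = PopulationSpec(
                n_cells=100, times=(30.0,), seed=21,
                sources_enabled=frozenset([f]),
            )
            table = simulate_population(ref_params, spec)
            x = table[f"conc_{f}_uM"].to_numpy()
            y = table[f"acc_{f}_30min"].to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            assert r**2 > 0.9

    def test_regression_slopes_match_response_coefficients(
        self, ref_params, population_run
    ):
        # slope of normalised EdU(30 min) vs normalised concentration is the
        # single-cell analogue of the response coefficient of the 30-min
        # cumulative repair-synthesis readout
        from nerkinetics.control import response_coefficients

        expected = response_coefficients(ref_params, definition="time_average")
        _, table = population_run
        edu = np.log(table["edu_30min"].to_numpy())
        for f in ("XPC", "XPA"):
            x = np.log(table[f"conc_{f}_uM"].to_numpy())
            # bootstrap CI of the log-log regression slope (the population
            # estimate of the elasticity)
            rng = np.random.default_rng(2)
            idx = rng.integers(0, x.size, size=(500, x.size))
            boots = [np.polyfit(x[i], edu[i], 1)[0] for i in idx]
            lo, hi = np.percentile(boots, [2.5, 97.5])
            assert lo <= expected.R[f] <= hi


class TestCorrelate:
    def test_perfect_correlation(self):
        x = np.linspace(1, 10, 50)
        r, (lo, hi) = correlate(x, x, n_boot=200, seed=1)
        assert r == pytest.approx(1.0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_null_case(self):
        rng = np.random.default_rng(3)
        r, _ = correlate(rng.normal(size=10_000), rng.normal(size=10_000),
                         n_boot=100, seed=2)
        assert abs(r) < 0.05

    def test_bootstrap_coverage(self):
        # CI covers the generative correlation in ~95% of repeats
        rho = 0.6
        rng = np.random.default_rng(7)
        hits = 0
        for rep in range(20):
            z = rng.multivariate_normal(
                [0, 0], [[1, rho], [rho, 1]], size=200
            )
            _, (lo, hi) = correlate(z[:, 0], z[:, 1], n_boot=400, seed=rep)
            hits += lo <= rho <= hi
        assert hits >= 17

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def decomposition(ref_params):
    spec = PopulationSpec(n_cells=120, times=(30.0,), seed=5)
    return variance_decomposition(ref_params, spec, t_obs=(30.0,))


class TestVarianceDecomposition:

    def test_lesions_dominate_single_sources(self, decomposition):
        lesion_cv = decomposition.loc["lesions", 30.0]
        factor_cvs = decomposition.loc[list(FACTORS), 30.0]
        assert (lesion_cv >= factor_cvs).all()

    def test_single_sources_below_total(self, decomposition):
        total = decomposition.loc["all", 30.0]
        singles = decomposition.drop(index="all")[30.0]
        assert (singles <= total * 1.05).all()

    def test_quadrature_approximation(self, decomposition):
        total = decomposition.loc["all", 30.0]
        singles = decomposition.drop(index="all")[30.0].to_numpy()
        quad = np.sqrt(np.sum(singles**2))
        assert total == pytest.approx(quad, rel=0.15)


class TestErrorEllipse:
    def test_zero_noise(self):
        pairs = generate_paired_measurements(200, 0.3, 0.0, seed=1)
        err, r = error_ellipse(pairs.channel_a, pairs.channel_b)
        assert err == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    @pytest.mark.parametrize("true_error,tol", [(0.11, 2.0), (0.05, 1.5)])
    def test_recovers_generative_error(self, true_error, tol):
        pairs = generate_paired_measurements(332, 0.3, true_error, seed=42)
        err, _ = error_ellipse(pairs.channel_a, pairs.channel_b)
        assert err == pytest.approx(100 * true_error, abs=tol)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            error_ellipse([1.0] * 10 + [-1.0], [1.0] * 11)

    def test_attribution_options(self):
        pairs = generate_paired_measurements(500, 0.3, 0.1, seed=2)
        equal, _ = error_ellipse(pairs.channel_a, pairs.channel_b, "equal")
        single, _ = error_ellipse(pairs.channel_a, pairs.channel_b, "single")
        assert single > equal


class TestLognormalDraws:
    def test_mean_preserved_and_cv_matches(self):
        rng = np.random.default_rng(11)
        draws = lognormal_mean_cv(rng, mean=2.0, cv=0.25, size=10_000)
        se_mean = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 2.0) < 3 * se_mean
        cv = draws.std(ddof=1) / draws.mean()
        # SE of the sample CV for lognormal data, ~CV*sqrt((1+2CV^2)/(2n))
        se_cv = 0.25 * np.sqrt((1 + 2 * 0.25**2) / (2 * draws.size))
        assert abs(cv - 0.25) < 3 * se_cv
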