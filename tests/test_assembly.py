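"""Tests of the repair-complex assembly theory.

Independent oracles: hand-derived first-passage closed forms, the
birth-death occupancy recursion for symmetric random assembly, the
independent-site product law for irreversible binding, and Gillespie
sampling.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nerkinetics.assembly import (
    AssemblyScheme,
    build_assembly_chain,
    completion_curve,
    fit_monoexponential,
    match_irreversible_onrate,
    mean_repair_time,
    sample_repair_times,
)


def birth_death_mfpt(n, k, l, rho):
    """Oracle: exact MFPT of the occupancy-count chain (random mechanism).

    States j = 0..n bound components with birth rate (n-j)k, death rate jl,
    absorption from j=n at rho; solved as a linear system independent of the
    subset-enumeration implementation.
    """
    m = n + 1
    Q = np.zeros((m, m))
    for j in range(m):
        if j < n:
            Q[j, j + 1] = (n - j) * k
        if j > 0:
            Q[j, j - 1] = j * l
    out_rate = Q.sum(axis=1).copy()
    out_rate[n] += rho
    A = Q - np.diag(out_rate)
    return float(np.linalg.solve(-A, np.ones(m))[0])


class TestChainConstruction:
    def test_sequential_state_count(self):
        chain = build_assembly_chain(AssemblyScheme(3, "sequential", 1, 1, 600))
        assert chain.n_states == 5
        assert chain.state_labels[:4] == (0, 1, 2, 3)
        assert chain.state_labels[-1] == "repaired"

    def test_random_state_count(self):
        chain = build_assembly_chain(AssemblyScheme(3, "random", 1, 1, 600))
        assert chain.n_states == 2**3 + 1

    def test_single_component_mechanisms_coincide(self):
        seq = build_assembly_chain(AssemblyScheme(1, "sequential", 2.0, 0.5, 10.0))
        rnd = build_assembly_chain(AssemblyScheme(1, "random", 2.0, 0.5, 10.0))
        np.testing.assert_allclose(seq.generator, rnd.generator)

    @pytest.mark.parametrize("mechanism", ["sequential", "random"])
    def test_generator_is_valid(self, mechanism):
        chain = build_assembly_chain(AssemblyScheme(4, mechanism, 1.3, 0.7, 5.0))
        Q = chain.generator
        off_diag = Q - np.diag(np.diag(Q))
        assert np.all(off_diag >= 0)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.all(Q[-1] == 0)

    def test_state_space_cap(self):
        with pytest.raises(ValueError, match="state space"):
            AssemblyScheme(17, "random", 1, 1, 600)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            AssemblyScheme(3, "random", -1.0, 1, 600)


class TestMeanRepairTime:
    @pytest.mark.parametrize(
        "k,l,rho",
        [(1.0, 1.0, 600.0), (0.3, 2.0, 5.0), (10.0, 0.0, 1.0)],
    )
    def test_single_component_closed_form(self, k, l, rho):
        # two-state first passage: T = 1/k + (1 + l/k)/rho
        for mech in ("sequential", "random"):
            t = mean_repair_time(AssemblyScheme(1, mech, k, l, rho))
            assert t == pytest.approx(1 / k + (1 + l / k) / rho, rel=1e-12)

    def test_sequential_irreversible_is_sum_of_stages(self):
        t = mean_repair_time(AssemblyScheme(3, "sequential", 2.0, 0.0, 5.0))
        assert t == pytest.approx(3 / 2.0 + 1 / 5.0, rel=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_random_matches_birth_death_recursion(self, n):
        scheme = AssemblyScheme(n, "random", 1.0, 1.0, 600.0)
        assert mean_repair_time(scheme) == pytest.approx(
            birth_death_mfpt(n, 1.0, 1.0, 600.0), rel=1e-9
        )

    def test_reference_scheme_in_hour_range(self):
        # all elementary rates >= 1/min yet the mean repair time is ~1 h
        t = mean_repair_time(AssemblyScheme(9, "random", 1.0, 1.0, 600.0))
        assert 50.0 <= t <= 90.0

    @pytest.mark.parametrize("n", [2, 4, 6, 8, 10])
    def test_mechanism_similarity(self, n):
        seq = mean_repair_time(AssemblyScheme(n, "sequential", 1.0, 1.0, 600.0))
        rnd = mean_repair_time(AssemblyScheme(n, "random", 1.0, 1.0, 600.0))
        assert max(seq, rnd) / min(seq, rnd) < 3.0


class TestCompletionCurve:
    def test_starts_at_zero_and_monotone(self):
        scheme = AssemblyScheme(4, "random", 1.0, 1.0, 600.0)
        t = np.linspace(0, 400, 120)
        c = completion_curve(scheme, t)
        assert c[0] == 0.0
        assert np.all(np.diff(c) >= -1e-12)
        assert np.all((c >= 0) & (c <= 1))
        assert c[-1] > 0.97

    def test_irreversible_product_law(self):
        # with l=0 and instantaneous catalysis, sites fill independently:
        # F(t) = (1 - exp(-k t))^N
        k, n = 0.5, 3
        scheme = AssemblyScheme(n, "random", k, 0.0, 1e5)
        t = np.linspace(0, 20, 60)
        np.testing.assert_allclose(
            completion_curve(scheme, t), (1 - np.exp(-k * t)) ** n, atol=1e-4
        )

    def test_irreversible_sigmoid_zero_initial_slope(self):
        scheme = AssemblyScheme(9, "random", 0.037, 0.0, 600.0)
        t = np.linspace(0, 2.0, 21)
        c = completion_curve(scheme, t)
        assert c[1] / (t[1] - t[0]) < 1e-4  # flat start

    def test_unsorted_grid_rejected(self):
        scheme = AssemblyScheme(2, "random", 1, 1, 10)
        with pytest.raises(ValueError):
            completion_curve(scheme, [0.0, 2.0, 1.0])


class TestMonoExpFit:
    def test_exact_recovery(self):
        tau, amp = 1.7241, 1.0
        t = np.linspace(0, 8, 50)
        y = amp * (1 - np.exp(-t / tau))
        fit = fit_monoexponential(t, y)
        assert fit.tau == pytest.approx(tau, rel=1e-6)
        assert fit.amplitude == pytest.approx(amp, rel=1e-6)
        assert fit.linear_slope == pytest.approx(-1 / tau, rel=1e-4)

    def test_reversible_reference_is_near_exponential(self):
        scheme = AssemblyScheme(9, "random", 1.0, 1.0, 600.0)
        t = np.linspace(0, 8 * 68.3, 500)
        fit = fit_monoexponential(t, completion_curve(scheme, t))
        assert fit.rmse < 0.01 * fit.amplitude


class TestMatchIrreversible:
    def test_single_component_limit(self):
        # one component: the irreversible curve is exponential with rate k,
        # so the matched k equals the inverse reference mean
        tau_ref = mean_repair_time(AssemblyScheme(1, "random", 1.0, 1.0, 600.0))
        k = match_irreversible_onrate(1, 1.0, 1.0, 600.0)
        assert k == pytest.approx(1 / (tau_ref - 1 / 600.0), rel=1e-3)

    def test_decreases_with_component_number(self):
        ks = [match_irreversible_onrate(n, 1.0, 1.0, 600.0) for n in (2, 4, 6, 8)]
        assert all(a > b for a, b in zip(ks, ks[1:]))


rates = st.floats(min_value=0.05, max_value=50.0, allow_nan=False)


class TestPropertyBased:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(k=rates, l=rates, rho=rates)
    def test_single_component_first_passage(self, k, l, rho):
        # closed form holds across the whole rate space
        t = mean_repair_time(AssemblyScheme(1, "random", k, l, rho))
        assert t == pytest.approx(1 / k + (1 + l / k) / rho, rel=1e-9)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(n=st.integers(min_value=1, max_value=6), k=rates, l=rates)
    def test_completion_curve_is_a_cdf(self, n, k, l):
        scheme = AssemblyScheme(n, "random", k, l, 100.0)
        grid = np.linspace(0.0, 5 * mean_repair_time(scheme), 40)
        c = completion_curve(scheme, grid)
        assert c[0] == 0.0
        assert np.all(np.diff(c) >= -1e-10)
        assert np.all((c >= 0) & (c <= 1))

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(n=st.integers(min_value=1, max_value=5), k=rates, l=rates, rho=rates)
    def test_mean_time_decreases_in_onrate(self, n, k, l, rho):
        t1 = mean_repair_time(AssemblyScheme(n, "random", k, l, rho))
        t2 = mean_repair_time(AssemblyScheme(n, "random", 2 * k, l, rho))
        assert t2 < t1 + 1e-12


class TestSampling:
    def test_seed_reproducibility(self):
        scheme = AssemblyScheme(3, "random", 1.0, 1.0, 600.0)
        a = sample_repair_times(scheme, 200, seed=42)
        b = sample_repair_times(scheme, 200, seed=42)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "scheme",
        [
            AssemblyScheme(3, "random", 1.0, 1.0, 600.0),
            AssemblyScheme(4, "sequential", 2.0, 0.5, 10.0),
        ],
    )
    def test_sample_mean_matches_mfpt(self, scheme):
        samples = sample_repair_times(scheme, 10_000, seed=5)
        mfpt = mean_repair_time(scheme)
        se = samples.std(ddof=1) / np.sqrt(samples.size)
        assert abs(samples.mean() - mfpt) < 3 * se

    def test_sequential_irreversible_variance(self):
        # sum of independent exponentials: var = N/k^2 + 1/rho^2
        k, rho, n = 2.0, 5.0, 3
        samples = sample_repair_times(
            AssemblyScheme(n, "sequential", k, 0.0, rho), 20_000, seed=9
        )
        expected = n / k**2 + 1 / rho**2
        se = np.sqrt(2.0 / (samples.size - 1)) * expected  # approx SE of var
        assert abs(samples.var(ddof=1) - expected) < 4 * se
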