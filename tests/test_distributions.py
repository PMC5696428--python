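"""Distribution layer: parameterizations, closed forms, sampling, matching."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

import flightfit as ff
from flightfit.distributions import DEFAULT_SHIFT_H, ParameterError, default_grid

A = DEFAULT_SHIFT_H


@pytest.mark.parametrize(
    "family,params,shift",
    [
        ("qexponential", {"q": 2.1, "rate": 1.0}, A),
        ("qexponential", {"q": 1.0, "rate": 1.0}, A),
        ("pareto", {"mu": 0.9}, A),
        ("pareto", {"mu": 2.0}, 0.0),  # lower set point must be positive
        ("exponential", {"rate": -1.0}, A),
        ("gamma", {"shape": 0.7}, A),  # missing rate
        ("weibull", {"shape": 1.0}, A),  # unknown family
    ],
)
def test_invalid_parameters_rejected(family, params, shift):
    with pytest.raises(ParameterError):
        ff.make_distribution(family, params, shift)


def test_unit_exponential_at_origin():
    d = ff.make_distribution("exponential", {"rate": 1.0}, shift=0.0)
    assert d.density(0.0) == pytest.approx(1.0)
    assert d.cdf(math.log(2.0)) == pytest.approx(0.5)


def test_pareto_closed_forms():
    d = ff.make_distribution("pareto", {"mu": 2.0}, shift=A)
    assert d.cdf(A) == pytest.approx(0.0)
    assert d.cdf(2 * A) == pytest.approx(0.5)  # median = a * 2^(1/(mu-1))
    d1 = ff.make_distribution("pareto", {"mu": 2.0}, shift=1.0)
    assert d1.quantile(0.75) == pytest.approx(4.0)  # a (1-u)^(-1/(mu-1))


def test_density_zero_below_shift():
    d = ff.make_distribution("exponential", {"rate": 2.0}, shift=0.5)
    assert d.density(0.4) == 0.0
    assert d.cdf(0.4) == 0.0
    assert d.quantile(0.0) == pytest.approx(0.5)


def test_gamma_shape_one_is_exponential():
    lam = 1.7
    g = ff.make_distribution("gamma", {"shape": 1.0, "rate": lam})
    e = ff.make_distribution("exponential", {"rate": lam})
    t = np.linspace(0.0, 10.0, 301)
    np.testing.assert_allclose(g.density(t), e.density(t), rtol=1e-12)


def test_qexponential_limit_is_exponential():
    lam = 1.0
    q = ff.make_distribution("qexponential", {"q": 1.0001, "rate": lam})
    e = ff.make_distribution("exponential", {"rate": lam})
    t = np.linspace(A, A + 20.0, 400)
    assert np.max(np.abs(q.density(t) - e.density(t))) < 1e-3


@pytest.mark.parametrize(
    "family,params",
    [
        ("exponential", {"rate": 2.3}),
        ("gamma", {"shape": 0.42, "rate": 1.7}),
        ("qexponential", {"q": 1.8, "rate": 0.6}),
        ("qexponential", {"q": 1.5, "rate": 2.0}),
        ("pareto", {"mu": 1.3}),
    ],
)
def test_density_normalization(family, params):
    d = ff.make_distribution(family, params)
    total, _ = quad(d.density, d.shift, np.inf, limit=300)
    assert total == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("family", ff.FAMILIES)
def test_quantile_cdf_roundtrip(family, scale_matched_dists):
    d = scale_matched_dists[family]
    u = np.linspace(0.01, 0.99, 25)
    np.testing.assert_allclose(d.cdf(d.quantile(u)), u, atol=1e-9)
    t = d.quantile(u)
    np.testing.assert_allclose(d.quantile(d.cdf(t)), t, rtol=1e-9)


def test_quantile_rejects_out_of_range():
    d = ff.make_distribution("exponential", {"rate": 1.0})
    with pytest.raises(ValueError):
        d.quantile(1.5)


class TestSampling:
    def test_deterministic_given_seed(self):
        d = ff.make_distribution("gamma", {"shape": 0.7, "rate": 0.7})
        np.testing.assert_array_equal(d.sample(100, seed=7), d.sample(100, seed=7))

    def test_exponential_mean_within_3_se(self):
        lam = 1.0
        d = ff.make_distribution("exponential", {"rate": lam})
        x = d.sample(3000, seed=1)
        assert np.all(x >= d.shift)
        se = (1.0 / lam) / math.sqrt(3000)
        assert abs(x.mean() - (d.shift + 1.0 / lam)) < 3 * se

    @pytest.mark.parametrize("family", ff.FAMILIES)
    def test_kolmogorov_distance(self, family, scale_matched_dists):
        # empirical CDF of 1e5 inverse-CDF draws vs the analytic CDF
        d = scale_matched_dists[family]
        x = np.sort(d.sample(100_000, seed=11))
        ecdf_hi = np.arange(1, x.size + 1) / x.size
        c = d.cdf(x)
        ks = max(np.max(np.abs(ecdf_hi - c)), np.max(np.abs(ecdf_hi - 1 / x.size - c)))
        assert ks < 0.01


class TestMoments:
    def test_reference_gamma_mean(self):
        # fitted black-browed albatross 2002 parameters: mean = shape/rate
        d = ff.make_distribution("gamma", {"shape": 1.38, "rate": 1.15})
        assert d.moments()["mean"] == pytest.approx(1.20, abs=0.005)

    def test_reference_gamma_variances(self):
        d04 = ff.make_distribution("gamma", {"shape": 0.314, "rate": 0.392})
        assert d04.moments()["variance"] == pytest.approx(2.04, abs=0.005)
        d98 = ff.make_distribution("gamma", {"shape": 0.0730, "rate": 0.170})
        assert d98.moments()["variance"] == pytest.approx(2.53, abs=0.005)

    def test_heavy_pareto_mean_infinite(self):
        d = ff.make_distribution("pareto", {"mu": 1.5})
        assert math.isinf(d.moments()["mean"])
        assert math.isfinite(d.moments()["median"])

    def test_shift_convention(self):
        # reported moments exclude the shift; sampling-law moments include it
        d = ff.make_distribution("exponential", {"rate": 2.0})
        assert d.moments()["mean"] == pytest.approx(0.5)
        assert d.moments(include_shift=True)["mean"] == pytest.approx(0.5 + A)


class TestScaleMatching:
    def test_exponential_mean(self):
        params, by = ff.solve_params_for_scale("exponential", 1.0)
        assert by == "mean"
        assert params["rate"] == pytest.approx(1.0 / (1.0 - A))

    def test_gamma_rate_at_unit_shape(self):
        params, _ = ff.solve_params_for_scale("gamma", 5.0, fixed={"shape": 1.0})
        assert params["rate"] == pytest.approx(1.0 / (5.0 - A))

    def test_pareto_median(self):
        params, by = ff.solve_params_for_scale("pareto", 1.0)
        assert by == "median"
        assert params["mu"] == pytest.approx(1.0 + math.log(2.0) / math.log(120.0))

    @pytest.mark.parametrize("family", ff.FAMILIES)
    @pytest.mark.parametrize("target", [0.5, 1.0, 5.0, 10.0])
    def test_matched_summary_hits_target(self, family, target):
        fixed = {"q": 1.6} if family == "qexponential" else (
            {"shape": 0.7} if family == "gamma" else {}
        )
        params, by = ff.solve_params_for_scale(family, target, fixed=fixed)
        d = ff.make_distribution(family, params)
        got = d.moments(include_shift=True)[by] if family != "pareto" else d.moments()[by]
        assert got == pytest.approx(target, abs=1e-8)

    def test_target_below_shift_rejected(self):
        with pytest.raises(ValueError):
            ff.solve_params_for_scale("exponential", A / 2)


def test_default_grid_is_4x4():
    grid = default_grid()
    assert len(grid) == 16
    fams = {e.distribution.family for e in grid}
    assert fams == set(ff.FAMILIES)
    for e in grid:
        d = e.distribution
        got = (
            d.moments()[e.matched_by]
            if d.family == "pareto"
            else d.moments(include_shift=True)[e.matched_by]
        )
        assert got == pytest.approx(e.scale_target, abs=1e-6)


def test_config_round_trip():
    d = ff.make_distribution("qexponential", {"q": 1.6, "rate": 3.1})
    d2 = ff.FlightDistribution.from_config(d.to_config())
    assert d2.family == d.family
    assert d2.params == pytest.approx(d.params)
    assert d2.shift == pytest.approx(d.shift)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    mu=st.floats(1.05, 5.0),
    jbig=st.integers(3, 10**7),
)
def test_pareto_cell_mass_positive_and_decreasing(mu, jbig):
    """Stable tail decrements stay positive and monotone above the shift."""
    d = ff.make_distribution("pareto", {"mu": mu})
    tau = 10.0 / 3600.0  # support starts at 30 s = 3 intervals
    lo = np.array([jbig, jbig + 1], dtype=float) * tau
    dec = d.survival_decrement_integral(lo, tau)
    assert dec[0] >= dec[1] >= 0.0
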