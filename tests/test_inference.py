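"""Observation likelihoods and maximum-likelihood fitting."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

import flightfit as ff
from flightfit.inference import (
    DegenerateObservationError,
    cell_probabilities,
    exact_loglik,
    naive_loglik,
    p_obs,
)


class TestPObs:
    @pytest.mark.parametrize(
        "family,params,tau_s",
        [
            ("exponential", {"rate": 1.0}, 3600.0),
            ("gamma", {"shape": 0.7, "rate": 0.7}, 3600.0),
            ("qexponential", {"q": 1.6, "rate": 3.0}, 600.0),
            ("pareto", {"mu": 1.3}, 3600.0),
        ],
    )
    def test_sums_to_one(self, family, params, tau_s):
        d = ff.make_distribution(family, params)
        p = p_obs(d, tau_s / 3600.0, j_max=400)
        assert p.min() >= 0.0
        assert p.sum() == pytest.approx(1.0, abs=1e-8)

    def test_geometric_decay_for_exponential(self):
        # zero-shift exponential: p(j+1)/p(j) = exp(-lam tau) exactly
        lam, tau = 3.0, 0.05
        d = ff.make_distribution("exponential", {"rate": lam}, shift=0.0)
        p = p_obs(d, tau, j_max=60)
        ratios = p[1:-2] / p[:-3]
        np.testing.assert_allclose(ratios, math.exp(-lam * tau), rtol=1e-10)

    def test_unobservable_distribution_raises(self):
        # essentially all mass below one interval: 1 - p(0) underflows to 0
        d = ff.make_distribution("exponential", {"rate": 1e9}, shift=0.0)
        with pytest.raises(DegenerateObservationError):
            p_obs(d, 1.0, j_max=10)

    def test_monte_carlo_histogram(self, gamma_record_10s):
        dist, _ = gamma_record_10s
        fl = ff.sample_flights(dist, 50_000, seed=21)
        scheme = ff.ObservationScheme(1800.0, label="30min")
        rec = ff.emulate_record(fl, scheme, seed=22)
        j, c = rec.arrays()
        p = cell_probabilities(dist, scheme.tau_h, j)
        emp = c / rec.n_flights
        tail = 1.0 - p.sum()
        tv = 0.5 * (np.sum(np.abs(emp - p)) + abs(tail))
        assert tv < 0.01


class TestExactLoglik:
    def test_single_bin(self):
        d = ff.make_distribution("exponential", {"rate": 1.0})
        rec = ff.ObservedRecord({1: 5}, 3600.0)
        p1 = cell_probabilities(d, 1.0, np.array([1]))[0]
        assert exact_loglik(d, rec) == pytest.approx(5 * math.log(p1))

    def test_linear_in_counts(self):
        d = ff.make_distribution("gamma", {"shape": 0.7, "rate": 0.7})
        r1 = ff.ObservedRecord({1: 3, 2: 4, 5: 1}, 3600.0)
        r2 = ff.ObservedRecord({1: 6, 2: 8, 5: 2}, 3600.0)
        assert exact_loglik(d, r2) == pytest.approx(2 * exact_loglik(d, r1))

    def test_matches_multinomial_up_to_constant(self):
        # theta-free gap between Sum d_j log p_j and the multinomial log-pmf
        rec = ff.ObservedRecord({1: 7, 2: 2, 3: 1}, 3600.0)
        j, dcounts = rec.arrays()
        gaps = []
        for rate in (0.5, 1.0, 2.0):
            d = ff.make_distribution("exponential", {"rate": rate})
            p = cell_probabilities(d, 1.0, j)
            p_full = np.append(p, 1.0 - p.sum())  # unobserved remainder cell
            lp = stats.multinomial.logpmf(
                np.append(dcounts, 0), n=dcounts.sum(), p=p_full
            )
            gaps.append(lp - exact_loglik(d, rec))
        assert np.ptp(gaps) < 1e-10

    def test_average_log_probability_nonpositive(self, gamma_record_10s):
        dist, rec = gamma_record_10s
        assert exact_loglik(dist, rec) <= 0.0


class TestNaiveLoglik:
    def test_single_flight_closed_form(self):
        d = ff.make_distribution("exponential", {"rate": 1.0}, shift=0.0)
        rec = ff.ObservedRecord({1: 1}, 3600.0)
        assert naive_loglik(d, rec) == pytest.approx(-1.0)

    def test_bins_below_shift_relocated_with_warning(self):
        # at 10 s, bins j in {1, 2, 3} sit at or below the 30 s limit
        d = ff.make_distribution("gamma", {"shape": 0.7, "rate": 0.7})
        rec = ff.ObservedRecord({1: 2, 2: 3, 3: 4, 100: 5}, 10.0)
        with pytest.warns(UserWarning, match="lower limit"):
            ll = naive_loglik(d, rec)
        assert np.isfinite(ll)

    def test_fine_sampling_recovers_rate(self):
        # durations kept (nearly) exact at 1 s bins: naive MLE is consistent,
        # so the estimate sits within 3 standard errors (lam/sqrt(n)) of truth
        lam, n = 1.0, 3000
        d = ff.make_distribution("exponential", {"rate": lam})
        fl = ff.sample_flights(d, n, seed=31)
        rec = ff.emulate_record(fl, ff.ObservationScheme(1.0, label="1s"), seed=32)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ff.fit_record(rec, "exponential", "naive")
        assert fit.params["rate"] == pytest.approx(lam, abs=3 * lam / math.sqrt(n))


class TestFitRecord:
    def test_bit_reproducible(self, gamma_record_10s):
        _, rec = gamma_record_10s
        f1 = ff.fit_record(rec, "exponential", "exact")
        f2 = ff.fit_record(rec, "exponential", "exact")
        assert f1.params == f2.params
        assert f1.loglik == f2.loglik

    def test_exact_fit_recovers_gamma(self, gamma_record_10s):
        dist, rec = gamma_record_10s
        fit = ff.fit_record(rec, "gamma", "exact")
        assert fit.converged
        for name, truth in dist.params.items():
            assert fit.params[name] == pytest.approx(truth, rel=0.10)

    def test_coarse_aggregation_degrades_exponential_estimate(self):
        # true mean 0.5 h observed at 1 h: most flights are discarded and the
        # few survivors carry little information, so the error distribution is
        # far wider than at 10 s (compare medians over replicates)
        params, _ = ff.solve_params_for_scale("exponential", 0.5)
        d = ff.make_distribution("exponential", params)
        errs = {"10s": [], "1h": []}
        for rep in range(5):
            fl = ff.sample_flights(d, 3000, seed=41 + rep)
            for scheme in (ff.SCHEME_10S, ff.SCHEME_1H):
                rec = ff.emulate_record(fl, scheme, seed=141 + rep)
                fit = ff.fit_record(rec, "exponential", "exact")
                errs[scheme.label].append(
                    abs(fit.params["rate"] / params["rate"] - 1.0)
                )
        assert np.median(errs["1h"]) > np.median(errs["10s"])

    def test_unknown_family_or_method_rejected(self, gamma_record_10s):
        _, rec = gamma_record_10s
        with pytest.raises(ValueError):
            ff.fit_record(rec, "lognormal", "exact")
        with pytest.raises(ValueError):
            ff.fit_record(rec, "gamma", "bayes")

    def test_result_row_serialization(self, gamma_record_10s):
        _, rec = gamma_record_10s
        fit = ff.fit_record(rec, "exponential", "exact")
        row = fit.to_row()
        assert row["family"] == "exponential"
        assert row["k"] == 1
        assert "theta_rate" in row


def test_naive_more_biased_for_heavy_tails_at_30s():
    """Truncation at the 30 s limit biases the naive Pareto fit.

    At a 30 s interval a flight just over the lower limit is often recorded
    as a nonflight; the exact likelihood models that truncation, the naive
    one cannot.
    """
    params, _ = ff.solve_params_for_scale("pareto", 0.5)
    d = ff.make_distribution("pareto", params)
    errs = {"naive": [], "exact": []}
    for rep in range(4):
        fl = ff.sample_flights(d, 3000, seed=50 + rep)
        rec = ff.emulate_record(fl, ff.SCHEME_30S, seed=60 + rep)
        for m in errs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = ff.fit_record(rec, "pareto", m)
            errs[m].append(abs(fit.params["mu"] / params["mu"] - 1.0))
    assert np.mean(errs["naive"]) > np.mean(errs["exact"])
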