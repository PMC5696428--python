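"""Fitting flight-time laws to logger records.

Two likelihoods are available for a record ``r = {d_j}`` of flights observed
as ``j`` whole dry intervals of length tau:

* the *exact* multinomial likelihood
  ``l(theta | r) = sum_j d_j log p(j | theta)``, where ``p(j | theta)``
  integrates the flight-time density against the uniform-phase observation
  kernel and conditions on the flight being observable at all (j >= 1), and
* the *naive* likelihood, which pretends each observed flight is an exact
  continuous duration ``j * tau`` and evaluates the plain density there.

With ``S`` the survival function of the flight law and
``I_m = int_{m tau}^{(m+1) tau} S(s) ds``, uniform-phase aggregation gives
``P(j) = (I_j - I_{j+1}) / tau`` for ``j >= 1`` and observability mass
``1 - p(0) = I_1 / tau``, so the conditional cell probabilities telescope to

    p(j | theta) = (I_j - I_{j+1}) / I_1 ,      sum_{j>=1} p(j) = 1 exactly.

All integrals have closed forms (see
:meth:`flightfit.distributions.FlightDistribution.integrated_survival`), so
likelihood evaluation is vectorised over the distinct observed lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, special

from .distributions import FlightDistribution, make_distribution
from .emulator import ObservedRecord

__all__ = [
    "FitOptions",
    "FitResult",
    "DegenerateObservationError",
    "p_obs",
    "cell_probabilities",
    "exact_loglik",
    "naive_loglik",
    "fit_record",
    "N_FREE_PARAMS",
]

N_FREE_PARAMS = {"exponential": 1, "gamma": 2, "qexponential": 2, "pareto": 1}


class DegenerateObservationError(ValueError):
    """The flight law places (numerically) no mass on observable records."""


def _interval_survival(dist: FlightDistribution, m: np.ndarray, tau: float) -> np.ndarray:
    """I_m = int_{m tau}^{(m+1) tau} S for integer array ``m``."""
    m = np.asarray(m, dtype=float)
    return dist.integrated_survival(m * tau, (m + 1.0) * tau)


def cell_probabilities(dist: FlightDistribution, tau: float, js: np.ndarray) -> np.ndarray:
    """Exact observed-cell probabilities p(j | theta) for the given lengths.

    Sparse counterpart of :func:`p_obs` (no tail lumping): suitable for
    heavy-tailed records whose largest observed length would make a dense
    vector enormous.
    """
    js = np.asarray(js)
    denom = _interval_survival(dist, np.array([1.0]), tau)[0]
    if not denom > 0:
        raise DegenerateObservationError(
            f"all mass of {dist.label()} is discarded at tau={tau} h (1 - p(0) = 0)"
        )
    return dist.survival_decrement_integral(js * tau, tau) / denom


def p_obs(dist: FlightDistribution, tau: float, j_max: int) -> np.ndarray:
    """Observed-length probabilities ``p(1..j_max | theta)`` at interval tau.

    The residual tail mass beyond ``j_max`` is lumped into the last cell, so
    the vector sums to one exactly.  Raises
    :class:`DegenerateObservationError` when the law is (numerically) never
    observable, e.g. a distribution supported entirely below tau.
    """
    if j_max < 1:
        raise ValueError("j_max must be >= 1")
    denom = _interval_survival(dist, np.array([1.0]), tau)[0]  # tau * P(observable)
    if not denom > 0:
        raise DegenerateObservationError(
            f"all mass of {dist.label()} is discarded at tau={tau} h (1 - p(0) = 0)"
        )
    js = np.arange(1, j_max + 1)
    p = dist.survival_decrement_integral(js * tau, tau) / denom
    tail = _interval_survival(dist, np.array([j_max + 1.0]), tau)[0]
    p[-1] += tail / denom  # lump the telescoped tail mass into the last cell
    return p


def exact_loglik(dist: FlightDistribution, record: ObservedRecord) -> float:
    """Multinomial observation log-likelihood sum_j d_j log p(j|theta)."""
    j, d = record.arrays()
    if j.size == 0:
        raise ValueError("record is empty")
    tau = record.tau_h
    denom = _interval_survival(dist, np.array([1.0]), tau)[0]
    if not denom > 0:
        return -np.inf
    logp = dist.log_survival_decrement_integral(j * tau, tau) - np.log(denom)
    if not np.all(np.isfinite(logp)):
        return -np.inf
    return float(np.sum(d * logp))


def naive_loglik(dist: FlightDistribution, record: ObservedRecord) -> float:
    """Log-likelihood ignoring the observation process.

    Each observed flight of length ``j`` is treated as an exact continuous
    duration ``j * tau``.  At fine tau, small bins can fall on or below the
    lower limit ``a`` where the density vanishes (or diverges, for gamma
    shapes < 1 exactly at ``a``); those bins are relocated to
    ``a + j*tau/2`` with a warning so the naive method stays defined for
    every logger generation.
    """
    j, d = record.arrays()
    if j.size == 0:
        raise ValueError("record is empty")
    t = j * record.tau_h
    bad = t <= dist.shift
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} naive bins at or below the {dist.shift * 3600:.0f} s "
            "lower limit relocated to a + j*tau/2",
            stacklevel=2,
        )
        t = np.where(bad, dist.shift + t / 2.0, t)
    f = np.asarray(dist.density(t), dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        return -np.inf
    return float(np.sum(d * np.log(f)))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitOptions:
    n_starts: int = 5
    seed: int = 0
    ftol: float = 1e-8
    max_iter: int = 600
    jitter: float = 0.4


@dataclass
class FitResult:
    """A maximum-likelihood fit of one family to one record."""

    family: str
    method: str
    params: Mapping[str, float]
    shift: float
    loglik: float
    k: int
    n: int
    converged: bool
    n_starts: int
    interval_s: float
    seed: int | None = None
    message: str = ""

    @property
    def distribution(self) -> FlightDistribution:
        return make_distribution(self.family, self.params, self.shift)

    def to_row(self) -> dict:
        row = {
            "family": self.family, "method": self.method, "interval_s": self.interval_s,
            "loglik": self.loglik, "k": self.k, "n": self.n,
            "converged": self.converged, "seed": self.seed,
        }
        row.update({f"theta_{k}": v for k, v in self.params.items()})
        return row


def _pack(family: str, params: Mapping[str, float]) -> np.ndarray:
    """Map parameters to an unconstrained vector (log / logit transforms)."""
    if family == "exponential":
        return np.array([np.log(params["rate"])])
    if family == "gamma":
        return np.log([params["shape"], params["rate"]])
    if family == "qexponential":
        return np.array([special.logit(params["q"] - 1.0), np.log(params["rate"])])
    return np.array([np.log(params["mu"] - 1.0)])


def _unpack(family: str, x: np.ndarray) -> dict[str, float]:
    if family == "exponential":
        return {"rate": float(np.exp(x[0]))}
    if family == "gamma":
        return {"shape": float(np.exp(x[0])), "rate": float(np.exp(x[1]))}
    if family == "qexponential":
        return {"q": float(1.0 + special.expit(x[0])), "rate": float(np.exp(x[1]))}
    return {"mu": float(1.0 + np.exp(x[0]))}


def _moment_init(family: str, record: ObservedRecord, shift: float) -> dict[str, float]:
    """Moment-matched starting values from crudely de-aggregated durations.

    Observed dry time ``j * tau`` under-reports the true duration by about one
    interval (the two wet-contaminated boundary intervals), so initialisation
    uses ``(j + 1) * tau``.
    """
    j, d = record.arrays()
    tau = record.tau_h
    t = (j + 1.0) * tau
    w = d / d.sum()
    m = float(np.sum(w * t))
    v = float(np.sum(w * (t - m) ** 2))
    span = max(m - shift, tau / 4.0, 1e-6)
    v = max(v, (tau / 4.0) ** 2)
    if family == "exponential":
        return {"rate": 1.0 / span}
    if family == "gamma":
        alpha = np.clip(span**2 / v, 0.02, 50.0)
        return {"shape": float(alpha), "rate": float(alpha / span)}
    # heavy-tailed families: the sample mean explodes, start from the median
    order = np.argsort(t)
    cum = np.cumsum(d[order]) / d.sum()
    med = float(t[order][np.searchsorted(cum, 0.5)])
    med = max(med, shift * 1.01, tau / 2.0)
    if family == "qexponential":
        q0 = 1.45
        xi = (q0 - 1.0) / (2.0 - q0)
        sigma = xi * max(med - shift, tau / 4.0) / (2.0**xi - 1.0)
        return {"q": q0, "rate": 1.0 / ((2.0 - q0) * sigma)}
    mu = 1.0 + np.log(2.0) / max(np.log(med / shift), 0.05)
    return {"mu": float(np.clip(mu, 1.01, 25.0))}


def fit_record(
    record: ObservedRecord,
    family: str,
    method: str = "exact",
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Maximize the chosen log-likelihood over log-transformed parameters.

    Derivative-free Nelder-Mead with ``options.n_starts`` multistarts (one at
    moment-matched values, the rest jittered around it); q is mapped onto
    (1, 2) by a logit.  Refitting with identical record, options and seed is
    bit-reproducible.
    """
    if method not in ("naive", "exact"):
        raise ValueError("method must be 'naive' or 'exact'")
    if family not in N_FREE_PARAMS:
        raise ValueError(f"unknown family {family!r}")
    shift = record_shift(record)
    loglik_fn = exact_loglik if method == "exact" else naive_loglik

    def negloglik(x: np.ndarray) -> float:
        try:
            dist = make_distribution(family, _unpack(family, x), shift)
            ll = loglik_fn(dist, record)
        except (ValueError, FloatingPointError, OverflowError):
            return np.inf
        return np.inf if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(options.seed)
    x0 = _pack(family, _moment_init(family, record, shift))
    starts = [x0] + [
        x0 + options.jitter * rng.standard_normal(x0.size)
        for _ in range(options.n_starts - 1)
    ]
    best_x, best_val, best_msg, converged = None, np.inf, "no start converged", False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # naive relocation warned once at top level
        for s in starts:
            if not np.isfinite(negloglik(s)):
                continue
            res = optimize.minimize(
                negloglik, s, method="Nelder-Mead",
                options={
                    "fatol": options.ftol, "xatol": 1e-6,
                    "maxiter": options.max_iter, "maxfev": options.max_iter,
                },
            )
            if res.fun < best_val:
                best_x, best_val, best_msg = res.x, res.fun, res.message
                converged = converged or bool(res.success)
    if best_x is None or not np.isfinite(best_val):
        return FitResult(
            family, method, _moment_init(family, record, shift), shift,
            -np.inf, N_FREE_PARAMS[family], record.n_flights, False,
            options.n_starts, record.interval_s, options.seed, "no start converged",
        )
    return FitResult(
        family, method, _unpack(family, best_x), shift, -best_val,
        N_FREE_PARAMS[family], record.n_flights, converged,
        options.n_starts, record.interval_s, options.seed, str(best_msg),
    )


def record_shift(record: ObservedRecord) -> float:
    """Lower flight limit used when fitting a record (30 s, in hours)."""
    from .distributions import DEFAULT_SHIFT_H

    return DEFAULT_SHIFT_H
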