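"""Candidate flight-duration distributions.

Flight (dry-period) durations of foraging seabirds are modelled with one of
four parametric families that recur in the step-length literature:

* shifted exponential   f(t) = lam * exp(-lam*(t-a))
* shifted gamma         f(t) = beta^alpha (t-a)^(alpha-1) exp(-beta*(t-a)) / Gamma(alpha)
* shifted q-exponential f(t) = (2-q)*lam * [1 + (q-1)*lam*(t-a)]^(1/(1-q)),  1 < q < 2
* Pareto                f(t) = (mu-1) * a^(mu-1) * t^(-mu),  mu > 1

All are supported on [a, inf): a biological lower limit on flight duration
(default 30 s) enters the first three as a left shift and the Pareto as its
lower set point.  The q-exponential interpolates between the exponential
(q -> 1) and a power-law tail (q -> 2); the Pareto is the Levy-flight
step-length law with exponent mu.

Internally each family is a frozen :mod:`scipy.stats` law; the q-exponential
is a reparameterised generalized Pareto with shape xi = (q-1)/(2-q) and scale
sigma = 1/((2-q)*lam).  The internal time unit is hours; the default shift is
a = 30 s = 1/120 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "DEFAULT_SHIFT_H",
    "FlightDistribution",
    "ParameterGrid",
    "make_distribution",
    "solve_params_for_scale",
    "default_grid",
]

FAMILIES = ("exponential", "gamma", "qexponential", "pareto")

#: 30 s expressed in hours — the biological lower limit on flight duration.
DEFAULT_SHIFT_H = 1.0 / 120.0

_PARAM_NAMES = {
    "exponential": ("rate",),
    "gamma": ("shape", "rate"),
    "qexponential": ("q", "rate"),
    "pareto": ("mu",),
}


class ParameterError(ValueError):
    """A family parameter is missing or outside its admissible range."""


def _validate(family: str, params: Mapping[str, float], shift: float) -> dict[str, float]:
    if family not in FAMILIES:
        raise ParameterError(f"unknown family {family!r}; expected one of {FAMILIES}")
    expected = _PARAM_NAMES[family]
    missing = set(expected) - set(params)
    extra = set(params) - set(expected)
    if missing or extra:
        raise ParameterError(
            f"{family}: expected parameters {expected}, missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    out = {k: float(params[k]) for k in expected}
    if shift < 0:
        raise ParameterError(f"shift must be nonnegative, got {shift}")
    for name in ("rate", "shape"):
        if name in out and not out[name] > 0:
            raise ParameterError(f"{family}: parameter '{name}' must be > 0, got {out[name]}")
    if family == "qexponential" and not (1.0 < out["q"] < 2.0):
        raise ParameterError(f"qexponential: parameter 'q' must lie in (1, 2), got {out['q']}")
    if family == "pareto":
        if not out["mu"] > 1.0:
            raise ParameterError(f"pareto: parameter 'mu' must be > 1, got {out['mu']}")
        if not shift > 0:
            raise ParameterError("pareto: lower set point (shift) must be > 0")
    return out


@dataclass(frozen=True)
class FlightDistribution:
    """A parametric flight-duration law with lower limit ``shift`` (hours)."""

    family: str
    params: Mapping[str, float]
    shift: float = DEFAULT_SHIFT_H

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", _validate(self.family, self.params, self.shift))
        object.__setattr__(self, "_frozen_cache", None)

    # -- frozen scipy backend ------------------------------------------------
    @property
    def frozen(self):
        """The backing frozen scipy.stats distribution (built once)."""
        if self._frozen_cache is None:
            object.__setattr__(self, "_frozen_cache", self._build_frozen())
        return self._frozen_cache

    def _build_frozen(self):
        p, a = self.params, self.shift
        if self.family == "exponential":
            return stats.expon(loc=a, scale=1.0 / p["rate"])
        if self.family == "gamma":
            return stats.gamma(p["shape"], loc=a, scale=1.0 / p["rate"])
        if self.family == "qexponential":
            xi, sigma = self._gpd_shape_scale()
            return stats.genpareto(xi, loc=a, scale=sigma)
        return stats.pareto(p["mu"] - 1.0, scale=a)

    def _gpd_shape_scale(self) -> tuple[float, float]:
        q, lam = self.params["q"], self.params["rate"]
        xi = (q - 1.0) / (2.0 - q)
        sigma = 1.0 / ((2.0 - q) * lam)
        return xi, sigma

    # -- evaluation ----------------------------------------------------------
    def density(self, t):
        """Probability density (per hour); zero below the shift."""
        t = np.asarray(t, dtype=float)
        out = np.where(t < self.shift, 0.0, self.frozen.pdf(np.maximum(t, self.shift)))
        return out if out.ndim else float(out)

    pdf = density

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t < self.shift, 0.0, self.frozen.cdf(np.maximum(t, self.shift)))
        return out if out.ndim else float(out)

    def sf(self, t):
        """Survival function P(T > t); one below the shift."""
        t = np.asarray(t, dtype=float)
        out = np.where(t < self.shift, 1.0, self.frozen.sf(np.maximum(t, self.shift)))
        return out if out.ndim else float(out)

    def quantile(self, u):
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError("quantile argument must lie in [0, 1]")
        out = self.frozen.ppf(u)
        return out if out.ndim else float(out)

    ppf = quantile

    def sample(self, n: int, seed: int | np.random.Generator) -> np.ndarray:
        """Draw ``n`` durations by inverse-CDF sampling (reproducible)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return self.quantile(rng.uniform(size=n))

    # -- integrated survival (used by the observation likelihood) ------------
    def integrated_survival(self, lo, hi):
        """Closed-form ``int_lo^hi S(s) ds`` for arrays ``lo <= hi`` (hours).

        S = 1 below the shift, so the integral splits at ``a``; above the
        shift each family has an elementary antiderivative (the gamma via the
        identity int_0^y Q(alpha, beta z) dz = y*Q(alpha, beta y)
        + (alpha/beta)*P(alpha+1, beta y)).
        """
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        a = self.shift
        below = np.clip(np.minimum(hi, a) - lo, 0.0, None)
        l = np.maximum(lo, a)
        h = np.maximum(hi, a)
        return below + self._tail_integral(h) - self._tail_integral(l)

    def _tail_integral(self, s):
        """Antiderivative of S evaluated at s >= shift (elementwise)."""
        from scipy import special

        a = self.shift
        p = self.params
        if self.family == "exponential":
            lam = p["rate"]
            return -np.exp(-lam * (s - a)) / lam
        if self.family == "gamma":
            alpha, beta = p["shape"], p["rate"]
            y = s - a
            by = beta * y
            return y * special.gammaincc(alpha, by) + (alpha / beta) * special.gammainc(
                alpha + 1.0, by
            )
        if self.family == "qexponential":
            xi, sigma = self._gpd_shape_scale()
            z = s - a
            w = 1.0 + xi * z / sigma
            # int (1 + xi z/sigma)^(-1/xi) dz; exponent 1 - 1/xi -> 0 at xi = 1
            # (q = 1.5), where the antiderivative degenerates to a logarithm
            if abs(xi - 1.0) < 1e-4:
                return sigma * np.log(w)
            expo = 1.0 - 1.0 / xi
            return (sigma / (xi * expo)) * np.power(w, expo)
        mu = p["mu"]
        if abs(mu - 2.0) < 1e-12:
            return a * np.log(s)
        return a ** (mu - 1.0) * s ** (2.0 - mu) / (2.0 - mu)

    def survival_decrement_integral(self, lo, tau):
        """``int_lo^{lo+tau} [S(s) - S(s+tau)] ds`` for arrays ``lo`` (hours).

        Equals ``I_j - I_{j+1}`` for ``lo = j*tau`` — the unnormalised mass of
        observed cell ``j``.  The generic difference of
        :meth:`integrated_survival` terms loses all precision for power-law
        tails once ``lo/tau`` is huge (the relative decrement is ~tau/lo), so
        the Pareto uses an explicitly cancellation-free form: an ``expm1``
        second difference for moderate ``lo`` and the asymptotic expansion
        ``tau^2 (mu-1) a^(mu-1) y^(-mu) [1 + mu(mu+1) tau^2 / (12 y^2)]`` with
        ``y = lo + tau`` beyond ``lo/tau > 1e4``.
        """
        lo = np.asarray(lo, dtype=float)
        a = self.shift
        y1 = lo + tau
        far = lo / tau > 1e4
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            # second difference of the antiderivative of S
            A0 = self._tail_integral(np.maximum(lo, a))
            A1 = self._tail_integral(np.maximum(y1, a))
            A2 = self._tail_integral(np.maximum(y1 + tau, a))
            below = np.clip(np.minimum(y1, a) - lo, 0.0, None) - np.clip(
                np.minimum(y1 + tau, a) - y1, 0.0, None
            )
            generic = below + 2.0 * A1 - A0 - A2
            if self.family == "exponential":
                lam = self.params["rate"]
                stable = (
                    (4.0 / lam)
                    * np.exp(-lam * (np.maximum(y1, a) - a))
                    * np.sinh(lam * tau / 2.0) ** 2
                )
            elif self.family == "qexponential":
                xi, sigma = self._gpd_shape_scale()
                w1 = 1.0 + xi * np.maximum(y1 - a, 0.0) / sigma
                delta = xi * tau / (sigma * w1)
                if abs(xi - 1.0) < 1e-4:
                    stable = -sigma * (np.log1p(-delta) + np.log1p(delta))
                else:
                    e = 1.0 - 1.0 / xi
                    stable = -(sigma / (xi * e)) * np.power(w1, e) * (
                        np.expm1(e * np.log1p(-delta)) + np.expm1(e * np.log1p(delta))
                    )
            elif self.family == "pareto":
                mu = self.params["mu"]
                delta = tau / y1
                if abs(mu - 2.0) < 1e-12:  # antiderivative degenerates to a*log(s)
                    stable = -a * (np.log1p(-delta) + np.log1p(delta))
                else:
                    stable = -(a ** (mu - 1.0) / (2.0 - mu)) * np.power(
                        y1, 2.0 - mu
                    ) * (
                        np.expm1((2.0 - mu) * np.log1p(-delta))
                        + np.expm1((2.0 - mu) * np.log1p(delta))
                    )
            else:  # gamma: light tail, the generic difference keeps precision
                stable = generic
            out = np.where(lo >= a, stable, generic)
            if np.any(far):
                # universal large-argument form: dec -> tau^2 f(y1)
                pdf_far = self.frozen.pdf(np.maximum(np.extract(far, y1), a))
                np.place(out, far, tau**2 * np.asarray(pdf_far))
        # the decrement is >= 0 by monotonicity of S; clip roundoff negatives
        return np.maximum(out, 0.0)

    def log_survival_decrement_integral(self, lo, tau):
        """log of :meth:`survival_decrement_integral`, safe against underflow.

        Light-tailed cell masses underflow double precision once the cell sits
        ~700 e-foldings into the tail (fitting a light family to heavy-tailed
        data); there the log-mass is continued analytically as
        ``2 log tau + log f(lo + tau) + 2 log[sinh(r tau/2) / (r tau/2)]``
        with ``r`` the exponential tail rate, which is exact for the
        exponential and asymptotically exact for the gamma.
        """
        lo = np.asarray(lo, dtype=float)
        dec = self.survival_decrement_integral(lo, tau)
        with np.errstate(divide="ignore"):
            out = np.log(dec)
        bad = ~np.isfinite(out)
        if np.any(bad):
            y1 = np.extract(bad, lo) + tau
            logpdf = np.asarray(self.frozen.logpdf(np.maximum(y1, self.shift)))
            rate = self.params.get("rate")
            corr = 0.0
            if self.family in ("exponential", "gamma") and rate is not None:
                x = rate * tau / 2.0
                # log[sinh(x)/x], stable for large x
                corr = 2.0 * (x + np.log1p(-np.exp(-2.0 * x)) - np.log(2.0 * x))
            np.place(out, bad, 2.0 * np.log(tau) + logpdf + corr)
        return out

    # -- summaries -----------------------------------------------------------
    def moments(self, include_shift: bool = False) -> dict[str, float]:
        """Theoretical mean, median and variance (hours, hours, hours^2).

        By convention the reported mean/median of the shifted families exclude
        the shift (e.g. the gamma mean is alpha/beta); pass
        ``include_shift=True`` for the moments of the sampling law itself.
        The Pareto lower set point is intrinsic, so its summaries always refer
        to the sampling law.  Non-existent moments are returned as ``inf``.
        """
        p = self.params
        if self.family == "exponential":
            lam = p["rate"]
            mean, med, var = 1.0 / lam, math.log(2.0) / lam, 1.0 / lam**2
        elif self.family == "gamma":
            alpha, beta = p["shape"], p["rate"]
            mean, var = alpha / beta, alpha / beta**2
            med = float(stats.gamma.ppf(0.5, alpha, scale=1.0 / beta))
        elif self.family == "qexponential":
            q, lam = p["q"], p["rate"]
            xi, sigma = self._gpd_shape_scale()
            mean = sigma / (1.0 - xi) if xi < 1.0 else math.inf
            var = sigma**2 / ((1.0 - xi) ** 2 * (1.0 - 2.0 * xi)) if xi < 0.5 else math.inf
            med = sigma * (2.0**xi - 1.0) / xi
        else:  # pareto
            mu, a = p["mu"], self.shift
            mean = a * (mu - 1.0) / (mu - 2.0) if mu > 2.0 else math.inf
            var = (
                a**2 * (mu - 1.0) / ((mu - 3.0) * (mu - 2.0) ** 2) if mu > 3.0 else math.inf
            )
            med = a * 2.0 ** (1.0 / (mu - 1.0))
            return {"mean": mean, "median": med, "variance": var}
        if include_shift:
            mean = mean + self.shift if math.isfinite(mean) else mean
            med = med + self.shift
        return {"mean": mean, "median": med, "variance": var}

    # -- serialization -------------------------------------------------------
    def to_config(self) -> dict[str, Any]:
        cfg: dict[str, Any] = {"family": self.family, "shift_s": self.shift * 3600.0}
        cfg.update(self.params)
        return cfg

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any]) -> "FlightDistribution":
        cfg = dict(cfg)
        family = cfg.pop("family")
        shift = cfg.pop("shift_s", DEFAULT_SHIFT_H * 3600.0) / 3600.0
        return cls(family, cfg, shift)

    def label(self) -> str:
        ps = ",".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"{self.family}({ps})"


def make_distribution(
    family: str, params: Mapping[str, float], shift: float = DEFAULT_SHIFT_H
) -> FlightDistribution:
    """Validated constructor; see :class:`FlightDistribution`."""
    return FlightDistribution(family, params, shift)


def theoretical_moments(dist: FlightDistribution, include_shift: bool = False) -> dict[str, float]:
    """Functional alias for :meth:`FlightDistribution.moments`."""
    return dist.moments(include_shift=include_shift)


# ---------------------------------------------------------------------------
# Scale matching across families
# ---------------------------------------------------------------------------

def solve_params_for_scale(
    family: str,
    target: float,
    shift: float = DEFAULT_SHIFT_H,
    fixed: Mapping[str, float] | None = None,
) -> tuple[dict[str, float], str]:
    """Parameters whose sampling-law location summary equals ``target`` hours.

    Light-tailed families are matched on the mean of the sampling law
    (shift + unshifted mean); families whose mean does not exist at the fixed
    shape (Pareto always when mu <= 2, q-exponential when q >= 1.5) fall back
    to matching the median.  Returns ``(params, matched_by)`` where
    ``matched_by`` is ``"mean"`` or ``"median"``.
    """
    fixed = dict(fixed or {})
    if target <= shift:
        raise ValueError(f"target scale {target} h must exceed the shift {shift} h")
    span = target - shift
    if family == "exponential":
        return {"rate": 1.0 / span}, "mean"
    if family == "gamma":
        alpha = float(fixed.get("shape", 1.0))
        return {"shape": alpha, "rate": alpha / span}, "mean"
    if family == "qexponential":
        q = float(fixed.get("q", 1.5))
        xi = (q - 1.0) / (2.0 - q)
        if q < 1.5:  # finite mean: span = sigma/(1-xi) = 1/((3-2q) lam)
            lam = 1.0 / ((3.0 - 2.0 * q) * span)
            return {"q": q, "rate": lam}, "mean"
        sigma = xi * span / (2.0**xi - 1.0)  # median matching
        lam = 1.0 / ((2.0 - q) * sigma)
        return {"q": q, "rate": lam}, "median"
    if family == "pareto":
        # median = a * 2^(1/(mu-1)); always matched on the median
        mu = 1.0 + math.log(2.0) / math.log(target / shift)
        return {"mu": mu}, "median"
    raise ParameterError(f"unknown family {family!r}")


@dataclass(frozen=True)
class GridEntry:
    label: str
    distribution: FlightDistribution
    scale_target: float
    matched_by: str


@dataclass(frozen=True)
class ParameterGrid:
    """The generator bank of a simulation study: families x scale levels."""

    entries: tuple[GridEntry, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def default_grid(
    scale_targets: Sequence[float] = (0.5, 1.0, 5.0, 10.0),
    families: Iterable[str] = FAMILIES,
    shift: float = DEFAULT_SHIFT_H,
    gamma_shape: float = 0.7,
    q: float = 1.6,
) -> ParameterGrid:
    """Families crossed with scale levels, location-matched per level.

    Defaults give the 4 x 4 = 16 generating distributions of the simulation
    studies: scale targets 0.5, 1, 5 and 10 h bracket flight times from well
    below to well above the coarsest (1 h) aggregation interval.  The gamma
    shape (0.7) and the q-exponential q (1.6) are held fixed across levels so
    that each family has a single free scale parameter to match.
    """
    entries = []
    for s in scale_targets:
        for fam in families:
            fixed = {}
            if fam == "gamma":
                fixed["shape"] = gamma_shape
            elif fam == "qexponential":
                fixed["q"] = q
            params, matched_by = solve_params_for_scale(fam, s, shift, fixed)
            dist = FlightDistribution(fam, params, shift)
            entries.append(GridEntry(f"{fam}@{s:g}h", dist, float(s), matched_by))
    return ParameterGrid(tuple(entries))
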