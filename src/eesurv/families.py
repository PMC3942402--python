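"""Right-skewed lifetime distribution families.

Four families used for modelling uncensored survival durations (months):

* ``EE``  — exponentiated exponential (generalized exponential),
  CDF ``(1 - exp(-lam*x))**alpha``.
* ``EW``  — exponentiated Weibull, CDF ``(1 - exp(-lam*x**beta))**alpha``.
* ``BGE`` — beta generalized exponential: the EE distribution function
  pushed through a Beta(a, b) distribution function.
* ``BIW`` — beta inverse Weibull: the Frechet-type CDF ``exp(-x**-beta)``
  pushed through Beta(a, b).

All densities are evaluated in log space first; ``pdf = exp(log_pdf)``.
Products over cohorts of several hundred observations underflow in linear
space, so every downstream likelihood is built on :func:`log_pdf`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special as sc

__all__ = [
    "FAMILIES",
    "ModelFamily",
    "ParamVector",
    "get_family",
    "pdf",
    "log_pdf",
    "cdf",
    "quantile",
    "sample",
]

_LOG_TINY = -37.0  # below this, log(1 - exp(-t)) == log(t) to double precision


def _log1mexp(t: np.ndarray) -> np.ndarray:
    """log(1 - exp(-t)) for t > 0, stable for both tiny and large t."""
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    small = t <= math.log(2.0)
    with np.errstate(divide="ignore"):
        out[small] = np.log(-np.expm1(-t[small]))
        out[~small] = np.log1p(-np.exp(-t[~small]))
    return out


def _log1mexp_from_log(log_t: np.ndarray) -> np.ndarray:
    """log(1 - exp(-t)) given log(t); survives t underflowing to 0."""
    log_t = np.asarray(log_t, dtype=float)
    out = np.where(log_t < _LOG_TINY, log_t, _log1mexp(np.exp(np.minimum(log_t, 700.0))))
    return out


class ModelFamily:
    """One of the four lifetime families; a closed enumeration.

    Subclasses implement the log-density, distribution function, quantile
    function and sampler on validated parameter arrays. Parameters are
    ordered positive reals; shapes are dimensionless, rates are per month.
    """

    tag: str = ""
    param_names: tuple[str, ...] = ()

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- parameter validation -------------------------------------------------
    def validate(self, params: Sequence[float]) -> np.ndarray:
        p = np.asarray(params, dtype=float).ravel()
        if p.size != self.n_params:
            raise ValueError(
                f"{self.tag} expects {self.n_params} parameters "
                f"{self.param_names}, got {p.size}"
            )
        if not np.all(np.isfinite(p)) or np.any(p <= 0.0):
            raise ValueError(f"{self.tag} parameters must be finite and > 0, got {p}")
        return p

    def params_ok(self, params: Sequence[float]) -> bool:
        p = np.asarray(params, dtype=float).ravel()
        return (
            p.size == self.n_params
            and bool(np.all(np.isfinite(p)))
            and bool(np.all(p > 0.0))
        )

    # -- interface ------------------------------------------------------------
    def log_pdf(self, params, x):
        raise NotImplementedError

    def cdf(self, params, x):
        raise NotImplementedError

    def ppf(self, params, p):
        raise NotImplementedError

    def rvs(self, params, n: int, rng: np.random.Generator) -> np.ndarray:
        """Default sampler: inverse-CDF of a uniform draw."""
        if n < 1:
            raise ValueError("n must be >= 1")
        u = rng.uniform(size=n)
        return self._ppf_impl(self.validate(params), u)

    # -- shared plumbing ------------------------------------------------------
    def _check_x_positive(self, x) -> np.ndarray:
        xa = np.asarray(x, dtype=float)
        if np.any(~np.isfinite(xa)) or np.any(xa <= 0.0):
            raise ValueError(f"support of {self.tag} is x > 0")
        return xa

    def _check_x_nonneg(self, x) -> np.ndarray:
        xa = np.asarray(x, dtype=float)
        if np.any(~np.isfinite(xa)) or np.any(xa < 0.0):
            raise ValueError("cdf requires x >= 0")
        return xa

    def _check_p(self, p) -> np.ndarray:
        pa = np.asarray(p, dtype=float)
        if np.any(~np.isfinite(pa)) or np.any(pa <= 0.0) or np.any(pa >= 1.0):
            raise ValueError("probability must lie strictly inside (0, 1)")
        return pa

    def _bisect_ppf(self, params, p: float, guess: float) -> float:
        # Guarded bisection fallback around a multiplicative bracket; used when
        # the analytic beta-quantile composition loses precision in a flat tail.
        lo, hi = guess / 10.0, guess * 10.0
        f = lambda x: float(self.cdf(params, x)) - p
        while f(lo) > 0.0 and lo > 1e-300:
            lo /= 10.0
        while f(hi) < 0.0 and hi < 1e300:
            hi *= 10.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0.0:
                lo = mid
            else:
                hi = mid
            if hi - lo <= 1e-12 * max(1.0, mid):
                break
        return 0.5 * (lo + hi)


class ExponentiatedExponential(ModelFamily):
    """EE(alpha, lam): pdf = alpha*lam*exp(-lam x)*(1-exp(-lam x))**(alpha-1)."""

    tag = "ee"
    param_names = ("alpha", "lam")

    def log_pdf(self, params, x):
        a, lam = self.validate(params)
        xa = self._check_x_positive(x)
        t = lam * xa
        shape_term = 0.0 if a == 1.0 else (a - 1.0) * _log1mexp(t)
        return math.log(a) + math.log(lam) - t + shape_term

    def cdf(self, params, x):
        a, lam = self.validate(params)
        xa = self._check_x_nonneg(x)
        with np.errstate(divide="ignore"):
            out = np.exp(a * _log1mexp_from_log(np.log(lam) + np.log(xa)))
        return np.where(xa == 0.0, 0.0, out)

    def ppf(self, params, p):
        pars = self.validate(params)
        pa = self._check_p(p)
        return self._ppf_impl(pars, pa)

    @staticmethod
    def _ppf_impl(pars, pa):
        a, lam = pars
        return -np.log1p(-np.power(pa, 1.0 / a)) / lam


class ExponentiatedWeibull(ModelFamily):
    """EW(alpha, beta, lam): CDF (1 - exp(-lam*x**beta))**alpha."""

    tag = "ew"
    param_names = ("alpha", "beta", "lam")

    def log_pdf(self, params, x):
        a, b, lam = self.validate(params)
        xa = self._check_x_positive(x)
        t = lam * np.power(xa, b)
        shape_term = 0.0 if a == 1.0 else (a - 1.0) * _log1mexp(t)
        return (
            math.log(a)
            + math.log(b)
            + math.log(lam)
            + (b - 1.0) * np.log(xa)
            - t
            + shape_term
        )

    def cdf(self, params, x):
        a, b, lam = self.validate(params)
        xa = self._check_x_nonneg(x)
        with np.errstate(divide="ignore"):
            log_t = np.log(lam) + b * np.log(xa)
            out = np.exp(a * _log1mexp_from_log(log_t))
        return np.where(xa == 0.0, 0.0, out)

    def ppf(self, params, p):
        pars = self.validate(params)
        pa = self._check_p(p)
        return self._ppf_impl(pars, pa)

    @staticmethod
    def _ppf_impl(pars, pa):
        a, b, lam = pars
        return np.power(-np.log1p(-np.power(pa, 1.0 / a)) / lam, 1.0 / b)


class BetaGeneralizedExponential(ModelFamily):
    """BGE(a, b, alpha, lam): EE distribution function through Beta(a, b).

    pdf = alpha*lam/B(a,b) * exp(-lam x) * u**(a*alpha-1) * (1-u**alpha)**(b-1)
    with u = 1 - exp(-lam x); CDF = I_{u**alpha}(a, b).
    """

    tag = "bge"
    param_names = ("a", "b", "alpha", "lam")

    def log_pdf(self, params, x):
        a, b, al, lam = self.validate(params)
        xa = self._check_x_positive(x)
        t = np.asarray(lam * xa, dtype=float)
        log_u = _log1mexp(t)
        # exponents of 0 are skipped: 0 * (-inf) at the support edges is NaN
        first = 0.0 if a * al == 1.0 else (a * al - 1.0) * log_u
        if b == 1.0:
            second = 0.0
        else:
            # log(1 - u**alpha) = log(-expm1(alpha * log u)); in the deep
            # right tail log_u underflows to -0 and 1 - u**alpha ~ alpha*e^-t
            arg = -al * log_u
            second_log = np.where(arg > 0.0, _log1mexp(np.maximum(arg, 1e-300)), 0.0)
            tail = arg == 0.0
            if np.any(tail):
                second_log = np.asarray(second_log)
                second_log[tail] = math.log(al) - t[tail]
            second = (b - 1.0) * second_log
        return (
            math.log(al)
            + math.log(lam)
            - sc.betaln(a, b)
            - t
            + first
            + second
        )

    def cdf(self, params, x):
        a, b, al, lam = self.validate(params)
        xa = self._check_x_nonneg(x)
        with np.errstate(divide="ignore"):
            u_al = np.exp(al * _log1mexp_from_log(np.log(lam) + np.log(xa)))
        return np.where(xa == 0.0, 0.0, sc.betainc(a, b, u_al))

    def ppf(self, params, p):
        pars = self.validate(params)
        pa = self._check_p(p)
        out = self._ppf_impl(pars, pa)
        if np.any(~np.isfinite(out)) or np.any(out <= 0.0):
            out = np.asarray(out, dtype=float)
            flat = np.atleast_1d(out)
            pflat = np.atleast_1d(pa)
            med_guess = float(self._ppf_impl(pars, np.asarray(0.5)))
            for i in np.nonzero(~np.isfinite(flat) | (flat <= 0.0))[0]:
                flat[i] = self._bisect_ppf(pars, float(pflat[i]), med_guess)
            out = flat.reshape(np.shape(out)) if np.ndim(out) else float(flat[0])
        return out

    @staticmethod
    def _ppf_impl(pars, pa):
        a, b, al, lam = pars
        w = sc.betaincinv(a, b, pa)
        return -np.log1p(-np.power(w, 1.0 / al)) / lam

    def rvs(self, params, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        a, b, al, lam = self.validate(params)
        v = rng.beta(a, b, size=n)
        return -np.log1p(-np.power(v, 1.0 / al)) / lam


class BetaInverseWeibull(ModelFamily):
    """BIW(beta, a, b): Frechet CDF exp(-x**-beta) through Beta(a, b).

    pdf = beta/B(a,b) * x**-(beta+1) * exp(-a*x**-beta)
          * (1 - exp(-x**-beta))**(b-1);  CDF = I_{exp(-x**-beta)}(a, b).
    There is no separate scale parameter; the tail behaves like
    x**-(beta*b + 1).
    """

    tag = "biw"
    param_names = ("beta", "a", "b")

    def log_pdf(self, params, x):
        b_shape, a, b = self.validate(params)
        xa = self._check_x_positive(x)
        log_t = -b_shape * np.log(xa)  # log of x**-beta
        t = np.exp(np.minimum(log_t, 700.0))
        return (
            math.log(b_shape)
            - sc.betaln(a, b)
            - (b_shape + 1.0) * np.log(xa)
            - a * t
            + (b - 1.0) * _log1mexp_from_log(log_t)
        )

    def cdf(self, params, x):
        b_shape, a, b = self.validate(params)
        xa = self._check_x_nonneg(x)
        with np.errstate(divide="ignore", over="ignore"):
            log_t = -b_shape * np.log(xa)
            v = np.exp(-np.exp(np.minimum(log_t, 700.0)))
        return np.where(xa == 0.0, 0.0, sc.betainc(a, b, v))

    def ppf(self, params, p):
        pars = self.validate(params)
        pa = self._check_p(p)
        out = np.asarray(self._ppf_impl(pars, pa), dtype=float)
        bad = ~np.isfinite(out) | (out <= 0.0)
        if np.any(bad):
            flat = np.atleast_1d(out)
            pflat = np.atleast_1d(pa)
            med_guess = float(self._ppf_impl(pars, np.asarray(0.4)))
            if not np.isfinite(med_guess) or med_guess <= 0:
                med_guess = 1.0
            for i in np.nonzero(np.atleast_1d(bad))[0]:
                flat[i] = self._bisect_ppf(pars, float(pflat[i]), med_guess)
            out = flat.reshape(out.shape)
        return out if out.ndim else float(out)

    @staticmethod
    def _ppf_impl(pars, pa):
        b_shape, a, b = pars
        v = sc.betaincinv(a, b, pa)
        with np.errstate(divide="ignore"):
            return np.power(-np.log(v), -1.0 / b_shape)

    def rvs(self, params, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        b_shape, a, b = self.validate(params)
        v = rng.beta(a, b, size=n)
        return np.power(-np.log(v), -1.0 / b_shape)


FAMILIES: dict[str, ModelFamily] = {
    f.tag: f
    for f in (
        ExponentiatedExponential(),
        ExponentiatedWeibull(),
        BetaGeneralizedExponential(),
        BetaInverseWeibull(),
    )
}


def get_family(family: "str | ModelFamily") -> ModelFamily:
    """Resolve a family tag ('ee', 'ew', 'bge', 'biw') to its singleton."""
    if isinstance(family, ModelFamily):
        return family
    tag = str(family).lower()
    if tag not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; valid tags: {sorted(FAMILIES)}")
    return FAMILIES[tag]


@dataclass(frozen=True)
class ParamVector:
    """Named positive parameters of one family, validated on construction."""

    family: str
    values: tuple[float, ...]

    def __post_init__(self):
        fam = get_family(self.family)
        vals = tuple(float(v) for v in fam.validate(self.values))
        object.__setattr__(self, "family", fam.tag)
        object.__setattr__(self, "values", vals)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(get_family(self.family).param_names, self.values))


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def log_pdf(family, params, x):
    """Log-density of ``family`` at ``x`` (> 0), computed without underflow."""
    return get_family(family).log_pdf(params, x)


def pdf(family, params, x):
    """Density of ``family`` at ``x`` (> 0)."""
    return np.exp(get_family(family).log_pdf(params, x))


def cdf(family, params, x):
    """Distribution function at ``x`` (>= 0); 0 at the support boundary."""
    return get_family(family).cdf(params, x)


def quantile(family, params, p):
    """Quantile function for p strictly inside (0, 1)."""
    return get_family(family).ppf(params, p)


def sample(family, params, n, seed=None):
    """Draw ``n`` independent survival times; reproducible for a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return get_family(family).rvs(params, int(n), rng)
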