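"""Maximum-likelihood fits and AIC / BIC / DIC model comparison.

AIC and BIC are computed from a numerically maximized likelihood
(multi-start quasi-Newton in the unconstrained log-parameter space). DIC
follows the WinBUGS convention: Dbar is the posterior mean of the deviance
-2 log L over retained MCMC draws, Dhat the deviance at the posterior mean
of the natural-scale parameters, pD = Dbar - Dhat and DIC = Dbar + pD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .families import get_family
from .inference import (
    McmcConfig,
    McmcDraws,
    PriorBox,
    check_survival_times,
    log_likelihood,
    run_mcmc,
)

__all__ = [
    "FitCriteria",
    "MaximumLikelihoodFit",
    "ModelComparison",
    "aic",
    "bic",
    "dic",
    "fit_mle",
    "compare_models",
]


def aic(loglik_max: float, k: int) -> float:
    """Akaike information criterion, -2*loglik + 2k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return -2.0 * loglik_max + 2.0 * k


def bic(loglik_max: float, k: int, n: int) -> float:
    """Bayesian information criterion, -2*loglik + k*ln(n)."""
    if k < 1 or n < 2:
        raise ValueError("require k >= 1 and n >= 2")
    return -2.0 * loglik_max + k * float(np.log(n))


@dataclass(frozen=True)
class FitCriteria:
    """One comparison-table row; the AIC/BIC/DIC identities hold exactly."""

    family: str
    k: int
    n: int
    loglik_max: float
    aic: float
    bic: float
    dbar: float = float("nan")
    dhat: float = float("nan")
    pd: float = float("nan")
    dic: float = float("nan")

    @classmethod
    def from_fit(cls, family, k, n, loglik_max, dbar=np.nan, dhat=np.nan) -> "FitCriteria":
        pd_ = dbar - dhat
        return cls(
            family=get_family(family).tag,
            k=int(k),
            n=int(n),
            loglik_max=float(loglik_max),
            aic=aic(loglik_max, k),
            bic=bic(loglik_max, k, n),
            dbar=float(dbar),
            dhat=float(dhat),
            pd=float(pd_),
            dic=float(dbar + pd_),
        )


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

def _start_params(tag: str, x: np.ndarray) -> np.ndarray:
    """Moment-flavoured starting values on the natural scale."""
    mean = float(np.mean(x))
    median = float(np.median(x))
    if tag == "ee":
        return np.array([1.0, 1.0 / mean])
    if tag == "ew":
        return np.array([1.0, 1.0, 1.0 / mean])
    if tag == "bge":
        return np.array([1.0, 1.0, 1.0, 1.0 / mean])
    if tag == "biw":
        # with beta=1 the median of the a-scaled inverse exponential is a/ln 2
        return np.array([1.0, max(median * np.log(2.0), 1e-3), 1.0])
    raise ValueError(tag)


class MaximumLikelihoodFit(BaseEstimator):
    """Multi-start maximum-likelihood fit of one family.

    Optimization runs in rho = log(theta) (unconstrained); each start is a
    jittered copy of a moment-flavoured initial point, refined by L-BFGS-B
    and, when that stalls, by Nelder-Mead.

    Attributes
    ----------
    params_ : ndarray            natural-scale MLE
    loglik_ : float              maximized log-likelihood
    aic_, bic_ : float
    criteria_ : FitCriteria
    """

    def __init__(self, family: str = "ee", n_starts: int = 3, random_state=None):
        self.family = family
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y=None):
        fam = get_family(self.family)
        x = check_survival_times(np.asarray(X, dtype=float).reshape(-1), min_n=2)
        rng = np.random.default_rng(self.random_state)
        base_rho = np.log(_start_params(fam.tag, x))

        def neg_ll(rho):
            if np.any(np.abs(rho) > 50):
                return 1e300
            ll = log_likelihood(fam, np.exp(rho), x)
            return -ll if np.isfinite(ll) else 1e300

        best = None
        failures = []
        for s in range(max(int(self.n_starts), 1)):
            start = base_rho if s == 0 else base_rho + rng.normal(0, 0.3, base_rho.size)
            try:
                res = optimize.minimize(neg_ll, start, method="L-BFGS-B")
                res_nm = optimize.minimize(
                    neg_ll, res.x if np.isfinite(res.fun) else start,
                    method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
                )
                if res_nm.fun < getattr(res, "fun", np.inf):
                    res = res_nm
            except Exception as exc:  # pragma: no cover - optimizer edge cases
                failures.append(f"start {s}: {exc}")
                continue
            if np.isfinite(res.fun) and res.fun < 1e299:
                if best is None or res.fun < best.fun:
                    best = res
            else:
                failures.append(f"start {s}: non-finite objective")
        if best is None:
            raise RuntimeError(
                f"all {self.n_starts} starts failed for {fam.tag}: {failures}"
            )

        self.params_ = np.exp(best.x)
        self.loglik_ = -float(best.fun)
        self.k_ = fam.n_params
        self.n_ = x.size
        self.aic_ = aic(self.loglik_, self.k_)
        self.bic_ = bic(self.loglik_, self.k_, self.n_)
        self.criteria_ = FitCriteria.from_fit(fam, self.k_, self.n_, self.loglik_)
        return self


def fit_mle(family, data, starts: int = 3, random_state=None):
    """Return ``(natural-scale MLE array, maximized log-likelihood)``."""
    est = MaximumLikelihoodFit(
        family=get_family(family).tag, n_starts=starts, random_state=random_state
    ).fit(np.asarray(data, dtype=float))
    return est.params_, est.loglik_


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

def dic(draws: McmcDraws, family=None, data=None):
    """Deviance information criterion from retained draws.

    Returns ``(dbar, dhat, pd, dic)``. Draws whose deviance is non-finite
    (outside the parameter domain) are excluded with a warning count.
    """
    fam = get_family(family if family is not None else draws.family)
    x = check_survival_times(data)
    dev = np.empty(draws.n_retained)
    for i in range(draws.n_retained):
        dev[i] = -2.0 * log_likelihood(fam, draws.natural[i], x)
    good = np.isfinite(dev)
    n_bad = int(np.sum(~good))
    if n_bad:
        warnings.warn(f"excluded {n_bad} draws with non-finite deviance from DIC")
    if not np.any(good):
        raise ValueError("no draws with finite deviance")
    dbar = float(np.mean(dev[good]))
    theta_bar = draws.natural[good].mean(axis=0)
    dhat = -2.0 * log_likelihood(fam, theta_bar, x)
    pd_ = dbar - dhat
    return dbar, float(dhat), float(pd_), float(dbar + pd_)


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

class ModelComparison(BaseEstimator):
    """Fit several families and rank them by an information criterion.

    Parameters
    ----------
    families : sequence of tags, default all four
    criterion : 'aic' | 'bic' | 'dic'
        Ranking column; DIC requires ``compute_dic=True``.
    compute_dic : bool
        Run an MCMC chain per family to obtain Dbar/Dhat/pD/DIC.
    prior_boxes : None | 'wide' | dict
        Boxes for the DIC chains. ``'wide'`` (default) uses (-10, 10) per
        component, which accommodates arbitrary month-scale data; a dict
        maps family tags to PriorBox-like values; ``None`` falls back to
        the family defaults.
    iterations, burn_in, random_state : MCMC settings for the DIC chains.

    Attributes
    ----------
    results_ : DataFrame ranked ascending by the criterion
    criteria_ : list[FitCriteria]
    best_family_ : str
    """

    def __init__(
        self,
        families: Sequence[str] = ("ee", "ew", "bge", "biw"),
        criterion: str = "aic",
        compute_dic: bool = False,
        prior_boxes="wide",
        iterations: int = 5_000,
        burn_in: int = 1_000,
        n_starts: int = 3,
        random_state=None,
    ):
        self.families = families
        self.criterion = criterion
        self.compute_dic = compute_dic
        self.prior_boxes = prior_boxes
        self.iterations = iterations
        self.burn_in = burn_in
        self.n_starts = n_starts
        self.random_state = random_state

    def _box_for(self, tag: str):
        fam = get_family(tag)
        if self.prior_boxes == "wide":
            return PriorBox.wide(fam.n_params)
        if isinstance(self.prior_boxes, dict):
            box = self.prior_boxes.get(tag)
            return box if box is None or isinstance(box, PriorBox) else PriorBox(tuple(map(tuple, box)))
        return self.prior_boxes  # None -> family default inside run_mcmc

    def fit(self, X, y=None):
        if self.criterion not in ("aic", "bic", "dic"):
            raise ValueError("criterion must be one of 'aic', 'bic', 'dic'")
        if self.criterion == "dic" and not self.compute_dic:
            raise ValueError("criterion='dic' requires compute_dic=True")
        x = check_survival_times(np.asarray(X, dtype=float).reshape(-1), min_n=2)
        seed_seq = np.random.SeedSequence(
            self.random_state if self.random_state is not None else 0
        )
        rows, crits, errors = [], [], {}
        for tag, child in zip(self.families, seed_seq.spawn(len(list(self.families)))):
            tag = get_family(tag).tag
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            try:
                mle = MaximumLikelihoodFit(
                    family=tag, n_starts=self.n_starts, random_state=sub_seed
                ).fit(x)
                dbar = dhat = np.nan
                if self.compute_dic:
                    box = self._box_for(tag)
                    if box is None:
                        from .inference import default_prior_box

                        box = default_prior_box(tag)
                    # start the DIC chain at the MLE (clipped into the box)
                    # so short chains spend their budget exploring the mode
                    init = np.clip(
                        np.log(mle.params_), box.low + 1e-6, box.high - 1e-6
                    )
                    draws = run_mcmc(
                        tag,
                        x,
                        box=box,
                        config=McmcConfig(
                            iterations=self.iterations,
                            burn_in=self.burn_in,
                            seed=sub_seed,
                            init=init,
                        ),
                    )
                    dbar, dhat, _, _ = dic(draws, tag, x)
                crit = FitCriteria.from_fit(tag, mle.k_, mle.n_, mle.loglik_, dbar, dhat)
                crits.append(crit)
                row = crit.__dict__.copy()
                row["params"] = tuple(float(v) for v in mle.params_)
                rows.append(row)
            except Exception as exc:
                errors[tag] = str(exc)
                warnings.warn(f"fit of family {tag} failed: {exc}")
        if not rows:
            raise RuntimeError(f"every family failed to fit: {errors}")
        df = pd.DataFrame(rows).sort_values(self.criterion, kind="mergesort")
        df = df.reset_index(drop=True)
        self.results_ = df
        self.criteria_ = crits
        self.failed_ = errors
        self.best_family_ = str(df.iloc[0]["family"])
        return self


def compare_models(
    data,
    families: Sequence[str] = ("ee", "ew", "bge", "biw"),
    criterion: str = "aic",
    compute_dic: bool = False,
    prior_boxes="wide",
    iterations: int = 5_000,
    burn_in: int = 1_000,
    random_state=None,
) -> pd.DataFrame:
    """Ranked comparison table; thin wrapper over :class:`ModelComparison`."""
    est = ModelComparison(
        families=families,
        criterion=criterion,
        compute_dic=compute_dic,
        prior_boxes=prior_boxes,
        iterations=iterations,
        burn_in=burn_in,
        random_state=random_state,
    ).fit(np.asarray(data, dtype=float))
    return est.results_
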