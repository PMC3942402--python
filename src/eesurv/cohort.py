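"""Seeded generator of SEER-like breast-cancer cohort tables.

The generator emulates the statistical structure of a registry extract of
Black Hispanic female breast-cancer patients: survival months from an
exponentiated-exponential law (shape ~1.234, rate ~0.01595 per month), age
at diagnosis from a normal truncated at 24 years (mean 54.11, SD 14.41),
and state / marital-status categories drawn from the registry frequencies.
An optional comparison group is generated under proportional hazards with a
configurable log hazard ratio. Censoring is off by default (the parametric
likelihood stages assume fully observed times) but can be requested as an
independent uniform censoring scheme solved to hit a target fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .families import get_family

__all__ = [
    "STATE_COUNTS",
    "MARITAL_COUNTS",
    "CohortConfig",
    "sample_cohort",
    "write_cohort",
    "read_cohort",
]

#: Registry state frequencies of the emulated cohort (sum to 298).
STATE_COUNTS: dict[str, int] = {
    "Georgia": 94,
    "Hawaii": 1,
    "Iowa": 3,
    "Michigan": 44,
    "New Mexico": 5,
    "Utah": 4,
    "Washington": 9,
    "California": 67,
    "Connecticut": 71,
}

#: Marital-status frequencies of the emulated cohort (sum to 298).
MARITAL_COUNTS: dict[str, int] = {
    "Single": 57,
    "Married": 124,
    "Separated": 7,
    "Divorced": 51,
    "Widowed": 50,
    "Unknown": 9,
}

REQUIRED_COLUMNS = (
    "patient_id",
    "state",
    "age_at_diagnosis_years",
    "marital_status",
    "survival_months",
    "event",
)


def _normalize(counts: dict) -> dict:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n: int = 298
    family: str = "ee"
    params: tuple = (1.234, 0.01595)
    age_mean: float = 54.11
    age_sd: float = 14.41
    age_min: float = 24.0
    state_probs: dict = field(default_factory=lambda: _normalize(STATE_COUNTS))
    marital_probs: dict = field(default_factory=lambda: _normalize(MARITAL_COUNTS))
    comparison_n: int = 0
    comparison_log_hr: float = 0.0
    censoring_fraction: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for probs, name in ((self.state_probs, "state"), (self.marital_probs, "marital")):
            s = float(sum(probs.values()))
            if abs(s - 1.0) > 1e-12:
                raise ValueError(f"{name} probabilities sum to {s}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} probabilities must be nonnegative")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring fraction must lie in [0, 1)")
        get_family(self.family).validate(self.params)


def _truncated_normal_ages(n, mean, sd, lower, rng) -> np.ndarray:
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _categorical(probs: dict, n: int, rng) -> np.ndarray:
    labels = list(probs.keys())
    p = np.array([probs[k] for k in labels], dtype=float)
    return rng.choice(labels, size=n, p=p / p.sum())


def _apply_censoring(x: np.ndarray, fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Independent U(0, c_max) censoring, c_max solved for the target fraction.

    The censoring probability of a subject with latent time x is
    P(C < x) = min(x, c_max)/c_max; c_max solves the empirical mean of that
    expression equal to ``fraction``.
    """
    if fraction <= 0:
        return x, np.ones(x.size, dtype=int)

    def expected_fraction(c_max):
        return float(np.mean(np.minimum(x, c_max) / c_max)) - fraction

    hi = float(np.max(x))
    while expected_fraction(hi) > 0:
        hi *= 2.0
    c_max = optimize.brentq(expected_fraction, 1e-9, hi)
    c = rng.uniform(0.0, c_max, size=x.size)
    event = (x <= c).astype(int)
    observed = np.minimum(x, c)
    return observed, event


def sample_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one cohort table; reproducible for a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    fam = get_family(config.family)

    n_total = config.n + config.comparison_n
    x_main = fam.rvs(config.params, config.n, rng)

    frames = [
        pd.DataFrame(
            {
                "patient_id": np.arange(1, config.n + 1),
                "state": _categorical(config.state_probs, config.n, rng),
                "age_at_diagnosis_years": _truncated_normal_ages(
                    config.n, config.age_mean, config.age_sd, config.age_min, rng
                ),
                "marital_status": _categorical(config.marital_probs, config.n, rng),
                "survival_months": x_main,
                "event": np.ones(config.n, dtype=int),
                "ethnic_group": "black_hispanic",
            }
        )
    ]
    if config.comparison_n > 0:
        # proportional hazards: S1(x) = S0(x)**HR  =>  x = F0^{-1}(1-(1-u)^{1/HR})
        hr = float(np.exp(config.comparison_log_hr))
        u = rng.uniform(size=config.comparison_n)
        p0 = 1.0 - np.power(1.0 - u, 1.0 / hr)
        p0 = np.clip(p0, 1e-15, 1.0 - 1e-15)
        x_cmp = fam.ppf(config.params, p0)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.arange(config.n + 1, n_total + 1),
                    "state": _categorical(config.state_probs, config.comparison_n, rng),
                    "age_at_diagnosis_years": _truncated_normal_ages(
                        config.comparison_n,
                        config.age_mean,
                        config.age_sd,
                        config.age_min,
                        rng,
                    ),
                    "marital_status": _categorical(
                        config.marital_probs, config.comparison_n, rng
                    ),
                    "survival_months": np.asarray(x_cmp, dtype=float),
                    "event": np.ones(config.comparison_n, dtype=int),
                    "ethnic_group": "comparison",
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)

    obs, event = _apply_censoring(
        table["survival_months"].to_numpy(), config.censoring_fraction, rng
    )
    table["survival_months"] = obs
    table["event"] = event

    if config.comparison_n == 0:
        table = table.drop(columns=["ethnic_group"])
    return table


def validate_cohort(table: pd.DataFrame, source: str = "cohort") -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{source}: missing required columns {missing}")
    surv = pd.to_numeric(table["survival_months"], errors="coerce")
    bad = ~np.isfinite(surv.to_numpy()) | (surv.to_numpy() <= 0)
    if bad.any():
        line = int(np.nonzero(bad)[0][0]) + 2  # header is line 1
        raise ValueError(
            f"{source}: nonpositive or malformed survival_months at line {line}"
        )
    ages = pd.to_numeric(table["age_at_diagnosis_years"], errors="coerce")
    if (~np.isfinite(ages.to_numpy())).any():
        line = int(np.nonzero(~np.isfinite(ages.to_numpy()))[0][0]) + 2
        raise ValueError(f"{source}: malformed age at line {line}")
    return table


def write_cohort(table: pd.DataFrame, path) -> None:
    """Lossless CSV writer with the fixed column order first."""
    validate_cohort(table, source=str(path))
    extras = [c for c in table.columns if c not in REQUIRED_COLUMNS]
    table[list(REQUIRED_COLUMNS) + extras].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; unknown extra columns are preserved."""
    table = pd.read_csv(path)
    return validate_cohort(table, source=str(path))
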