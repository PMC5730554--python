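"""Synthetic cohort generation and cohort-table I/O.

A cohort is a plain :class:`pandas.DataFrame` with one row per subject and
the fixed column set ``subject_id, age, bmi, sbp, heart_rate, cholesterol,
ex_smoker, smoker, time, event, population``: five continuous risk
factors, two smoking dummies (never-smoker = both zero), follow-up time in
years and a binary CHD-death indicator.

Event times are drawn from a proportional-hazards model with constant
baseline hazard ``lambda = -ln(S0)/horizon`` and relative hazard
``exp(beta'(x - xbar))`` centred at the spec means, so that a subject at
the means has exactly the target baseline cumulative survival at the
horizon.  An independent exponential censoring time models competing
non-CHD death, and everyone still in follow-up is administratively
censored at the horizon.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .specs import (
    CONTINUOUS_TERMS,
    MODEL_TERMS,
    PHYSIOLOGIC_FLOORS,
    PopulationSpec,
    SpecValidationError,
)

#: Fixed column order of a cohort table on disk.
COHORT_COLUMNS = (
    "subject_id", "age", "bmi", "sbp", "heart_rate", "cholesterol",
    "ex_smoker", "smoker", "time", "event", "population",
)


class CohortValidationError(ValueError):
    """A cohort table violates one of its invariants."""


def sample_covariates(
    spec: PopulationSpec, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` covariate records from the spec's marginal distributions.

    Continuous covariates are truncated normals (mean +/- 4 SD, floored at
    physiologic minima); when the spec carries a correlation matrix the
    margins are coupled through a Gaussian copula, otherwise they are
    independent.  The smoking category is multinomial and expanded to the
    two dummies.
    """
    spec.validate()
    if n < 1:
        raise SpecValidationError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)

    k = len(CONTINUOUS_TERMS)
    if spec.correlation is None:
        z = rng.standard_normal((n, k))
    else:
        chol = np.linalg.cholesky(spec.correlation)
        z = rng.standard_normal((n, k)) @ chol.T
    u = stats.norm.cdf(z)

    out = {}
    for j, term in enumerate(CONTINUOUS_TERMS):
        mu, sd = spec.continuous_means[term], spec.continuous_sds[term]
        lo = max(mu - 4.0 * sd, PHYSIOLOGIC_FLOORS[term])
        hi = mu + 4.0 * sd
        a, b = (lo - mu) / sd, (hi - mu) / sd
        out[term] = stats.truncnorm.ppf(u[:, j], a, b, loc=mu, scale=sd)

    cat = rng.choice(3, size=n, p=np.asarray(spec.smoking_proportions))
    out["ex_smoker"] = (cat == 1).astype(int)
    out["smoker"] = (cat == 2).astype(int)
    return pd.DataFrame(out, columns=list(MODEL_TERMS))


def sample_survival(
    spec: PopulationSpec, covariates: pd.DataFrame, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw ``(time, event)`` for each covariate record.

    The CHD event time is exponential with rate
    ``lambda * exp(beta'(x - xbar_spec))``; the censoring time is
    exponential at ``spec.censoring_rate`` (infinite when the rate is 0);
    follow-up is truncated at the horizon.  ``event`` is 1 iff the CHD
    time comes first.
    """
    spec.validate()
    if covariates[list(MODEL_TERMS)].isna().any().any():
        raise CohortValidationError("covariate table contains missing values")
    rng = np.random.default_rng(seed)
    n = len(covariates)

    means = spec.covariate_means
    beta = np.array([spec.true_coefficients[t] for t in MODEL_TERMS])
    x = covariates[list(MODEL_TERMS)].to_numpy(dtype=float)
    xbar = np.array([means[t] for t in MODEL_TERMS])
    eta = (x - xbar) @ beta

    rate = spec.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    if spec.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)

    time = np.minimum(np.minimum(t_event, t_cens), spec.horizon)
    event = (t_event <= np.minimum(t_cens, spec.horizon)).astype(int)
    return pd.DataFrame({"time": time, "event": event})


def generate_cohort(
    spec: PopulationSpec, n: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Generate a full synthetic cohort of ``n`` subjects (default
    ``spec.n_default``).

    The master seed is split deterministically between covariate and
    survival sampling, so one integer reproduces the whole table.
    """
    if n is None:
        n = spec.n_default
    ss_cov, ss_surv = np.random.SeedSequence(seed).spawn(2)
    cov = sample_covariates(spec, n, np.random.default_rng(ss_cov))
    surv = sample_survival(spec, cov, np.random.default_rng(ss_surv))
    df = pd.concat([cov, surv], axis=1)
    df.insert(0, "subject_id", [f"{spec.name}-{i + 1:05d}" for i in range(n)])
    df["population"] = spec.name
    return df[list(COHORT_COLUMNS)]


def validate_cohort(df: pd.DataFrame, horizon: float | None = None) -> pd.DataFrame:
    """Check cohort invariants; return the table untouched if valid."""
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(f"cohort table missing columns: {sorted(missing)}")
    if df[list(COHORT_COLUMNS)].isna().any().any():
        raise CohortValidationError("cohort table contains missing values")
    if not df["event"].isin([0, 1]).all():
        raise CohortValidationError("event indicator must be 0/1")
    for d in ("ex_smoker", "smoker"):
        if not df[d].isin([0, 1]).all():
            raise CohortValidationError(f"{d} dummy must be 0/1")
    if ((df["ex_smoker"] == 1) & (df["smoker"] == 1)).any():
        raise CohortValidationError("ex_smoker and smoker dummies are exclusive")
    if (df["time"] <= 0).any():
        raise CohortValidationError("follow-up times must be strictly positive")
    if horizon is not None and (df["time"] > horizon + 1e-12).any():
        raise CohortValidationError(f"follow-up times exceed the horizon {horizon}")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort as CSV with the fixed header."""
    validate_cohort(df).to_csv(path, index=False, columns=list(COHORT_COLUMNS))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    return validate_cohort(pd.read_csv(path))
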