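"""Greenwood-Nam-D'Agostino calibration test for survival risk models
(Demler's modification).

The test splits subjects into D groups (deciles by default) of predicted
risk, estimates each group's *observed* risk at the horizon with the
Kaplan-Meier estimator, and compares it with the group's mean *predicted*
risk, weighting squared discrepancies by the Greenwood variance of the
KM estimate:

    chi2 = sum_d ((1 - S_d) - pbar_d)^2 / V_d,     df = (#groups - 1)

Unlike the Hosmer-Lemeshow statistic for binary outcomes, the test uses
survival probabilities rather than event counts, so censored follow-up is
handled correctly.  Groups with too few events (Greenwood variance is
unstable there) are merged with their higher-risk neighbour before
computing the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import validate_cohort


class DataError(ValueError):
    """Input data are empty or malformed."""


class DegenerateDataError(ValueError):
    """A risk group has zero Greenwood variance after merging; the
    chi-squared statistic is undefined."""


class ConfigurationError(ValueError):
    """Invalid grouping configuration (e.g. more groups than subjects)."""


def km_at(time, event, t: float) -> tuple[float, float]:
    """Kaplan-Meier survival probability at ``t`` and its Greenwood variance.

    The product-limit estimate runs over distinct event times up to and
    including ``t``; at tied times, events precede censorings.  The
    Greenwood variance is ``S(t)^2 * sum_i d_i / (n_i (n_i - d_i))``; it
    is reported as 0 when the survival estimate reaches 0.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise DataError("cannot estimate survival from an empty sample")
    if t <= 0:
        raise DataError(f"evaluation time must be positive, got {t}")

    event_times = np.unique(time[(event == 1) & (time <= t)])
    surv = 1.0
    gw_sum = 0.0
    for ti in event_times:
        n_at_risk = int((time >= ti).sum())
        d = int(((time == ti) & (event == 1)).sum())
        surv *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            gw_sum += d / (n_at_risk * (n_at_risk - d))
        else:
            return 0.0, 0.0
    return surv, surv * surv * gw_sum


def assign_deciles(predicted_risks, D: int = 10) -> np.ndarray:
    """Rank-based assignment of subjects to ``D`` near-equal groups of
    increasing predicted risk (labels 0..D-1).

    Ties are broken by original row order (stable sort), so equal risks
    never produce empty groups.
    """
    risks = np.asarray(predicted_risks, dtype=float)
    n = risks.size
    if D < 2:
        raise ConfigurationError(f"need at least 2 groups, got D={D}")
    if n < D:
        raise ConfigurationError(f"cannot form {D} groups from {n} subjects")
    order = np.argsort(risks, kind="stable")
    labels = np.empty(n, dtype=int)
    labels[order] = (np.arange(n) * D) // n
    return labels


def gnd_chi_squared(observed_risk, expected_risk, variance) -> tuple[float, int, float]:
    """The GND statistic from per-group summaries.

    Returns ``(chi2, df, p)`` with ``df = len(groups) - 1`` and the
    p-value from the upper chi-squared tail.
    """
    obs = np.asarray(observed_risk, dtype=float)
    exp_ = np.asarray(expected_risk, dtype=float)
    var = np.asarray(variance, dtype=float)
    if (var <= 0).any():
        raise DegenerateDataError(
            "zero Greenwood variance in a risk group; merge further or "
            "supply more events"
        )
    chi2 = float((((obs - exp_) ** 2) / var).sum())
    df = obs.size - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclass
class GNDDResult:
    """Outcome of the GND calibration test.

    ``rows`` holds one post-merge risk group per row: size, events, mean
    predicted risk, KM survival, observed risk (1 - KM), Greenwood
    variance.  ``decile_ratio`` is the mean predicted risk of the top
    group over the bottom group — a crude relative-risk gradient.
    """

    rows: pd.DataFrame
    chi_squared: float
    degrees_of_freedom: int
    p_value: float
    mean_observed: float
    mean_expected: float
    decile_ratio: float


def gndd_test(
    cohort: pd.DataFrame,
    predicted_risks,
    horizon: float = 25.0,
    D: int = 10,
    min_events: int = 5,
) -> GNDDResult:
    """Run the GND calibration test on a cohort with externally supplied
    predicted risks.

    Groups with fewer than ``min_events`` observed events are merged into
    their higher-risk neighbour (the top group merges downward),
    iterating from the lowest-risk group upward, before the statistic is
    computed.  The KM estimate of each group is evaluated at its largest
    observed follow-up time at or before the horizon.
    """
    validate_cohort(cohort)
    risks = np.asarray(predicted_risks, dtype=float)
    if len(risks) != len(cohort):
        raise DataError(
            f"predicted risks ({len(risks)}) not aligned with cohort rows "
            f"({len(cohort)})"
        )

    time = cohort["time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=int)
    labels = assign_deciles(risks, D)

    groups = [np.flatnonzero(labels == g) for g in range(D)]

    def events_in(idx: np.ndarray) -> int:
        return int(event[idx][time[idx] <= horizon].sum())

    # merge sparse groups into the higher-risk neighbour, bottom-up
    i = 0
    while len(groups) > 1 and i < len(groups):
        if events_in(groups[i]) < min_events:
            j = i + 1 if i + 1 < len(groups) else i - 1
            merged = np.concatenate([groups[min(i, j)], groups[max(i, j)]])
            groups[min(i, j)] = merged
            del groups[max(i, j)]
            i = min(i, j)  # re-check the merged group before moving on
        else:
            i += 1

    rows = []
    for g, idx in enumerate(groups):
        tg = float(time[idx][time[idx] <= horizon].max())
        surv, var = km_at(time[idx], event[idx], tg)
        rows.append({
            "group": g + 1,
            "n": int(idx.size),
            "events": events_in(idx),
            "mean_predicted": float(risks[idx].mean()),
            "km_survival": surv,
            "observed_risk": 1.0 - surv,
            "greenwood_variance": var,
        })
    table = pd.DataFrame(rows)

    chi2, df, p = gnd_chi_squared(
        table["observed_risk"], table["mean_predicted"], table["greenwood_variance"]
    )
    weights = table["n"] / table["n"].sum()
    return GNDDResult(
        rows=table,
        chi_squared=chi2,
        degrees_of_freedom=df,
        p_value=p,
        mean_observed=float((weights * table["observed_risk"]).sum()),
        mean_expected=float(risks.mean()),
        decile_ratio=float(
            table["mean_predicted"].iloc[-1] / table["mean_predicted"].iloc[0]
        ),
    )


def calibration_summary(result: GNDDResult, model: str = "", population: str = "") -> dict:
    """One summary row per model: the six headline calibration quantities."""
    return {
        "model": model,
        "population": population,
        "mean_observed": result.mean_observed,
        "mean_expected": result.mean_expected,
        "decile_1": float(result.rows["mean_predicted"].iloc[0]),
        "decile_10": float(result.rows["mean_predicted"].iloc[-1]),
        "decile_ratio": result.decile_ratio,
        "p_value": result.p_value,
    }


def format_p(p: float) -> str:
    """Render a p-value to 4 decimals; values below 1e-4 as ``<0.0001``."""
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"
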