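"""Cox risk-function engine: fitting, the transportable triple, and
absolute-risk prediction.

The object of interest is the transportable triple (beta, xbar, S0):
per-unit log-hazard coefficients, the covariate means of the fitting
cohort, and the baseline cumulative survival at the horizon evaluated at
those means.  The absolute risk of a subject with covariates x over the
horizon is then

    p(x) = 1 - S0 ** exp(beta'(x - xbar))

which is the quantity the re-calibration schemes transport between
populations, one component at a time.

Partial-likelihood maximisation is delegated to
:class:`lifelines.CoxPHFitter` (Efron tie handling); covariates are
mean-centred before fitting so that the Breslow baseline cumulative
hazard — and hence S0 — refers to the average subject of the fitting
cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .cohort import validate_cohort
from .specs import MODEL_TERMS


class CoxFittingError(RuntimeError):
    """Model fitting failed (too few events or non-convergence)."""


class SchemaError(ValueError):
    """Covariate table does not match the model's term names."""


@dataclass
class CoxComponents:
    """The transportable risk-function triple plus provenance.

    ``coefficients`` maps each of the seven model terms to its per-unit
    log-hazard value; ``means`` holds the centring vector (the fitting
    cohort's covariate means); ``s0`` is the baseline cumulative survival
    at ``horizon`` for a subject at the means.
    """

    coefficients: dict[str, float]
    means: dict[str, float]
    s0: float
    horizon: float
    source_label: str = ""
    deltas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.s0 < 1.0:
            raise ValueError(f"s0 must lie strictly in (0,1), got {self.s0}")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        for name, mapping in (("coefficients", self.coefficients), ("means", self.means)):
            if not all(np.isfinite(list(mapping.values()))):
                raise ValueError(f"{name} must be finite")
        if set(self.coefficients) != set(self.means):
            raise ValueError("coefficients and means must share term names")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for t in MODEL_TERMS if t in self.coefficients) or tuple(self.coefficients)

    # ------------------------------------------------------------------
    # serialization (lossless: floats survive a JSON/YAML round trip)
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "means": {k: float(v) for k, v in self.means.items()},
            "s0": float(self.s0),
            "horizon": float(self.horizon),
            "source_label": self.source_label,
            "deltas": {k: float(v) for k, v in self.deltas.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoxComponents":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CoxComponents":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_cox(cohort: pd.DataFrame, horizon: float = 25.0) -> CoxComponents:
    """Fit a proportional-hazards model and extract the transportable triple.

    Follow-up beyond the horizon is administratively censored.  The model
    is fit on mean-centred covariates; ``s0`` is the exponentiated
    negative Breslow cumulative hazard at the largest event time at or
    before the horizon, i.e. the estimated survival of the average
    subject.

    Raises
    ------
    CoxFittingError
        If the cohort has fewer than two events or the optimiser fails.
    """
    validate_cohort(cohort)
    df = cohort.copy()
    over = df["time"] > horizon
    df.loc[over, "time"] = horizon
    df.loc[over, "event"] = 0

    n_events = int(df["event"].sum())
    if n_events < 2:
        raise CoxFittingError(
            f"cannot fit a Cox model with {n_events} event(s); need at least 2"
        )

    means = {t: float(df[t].mean()) for t in MODEL_TERMS}
    centred = df[list(MODEL_TERMS)] - pd.Series(means)
    centred["time"] = df["time"].to_numpy()
    centred["event"] = df["event"].to_numpy()

    cph = CoxPHFitter()
    try:
        cph.fit(centred, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError et al.
        raise CoxFittingError(f"Cox partial-likelihood fit failed: {exc}") from exc

    coeffs = {t: float(cph.params_[t]) for t in MODEL_TERMS}

    cumhaz = cph.baseline_cumulative_hazard_
    times = cumhaz.index.to_numpy(dtype=float)
    idx = np.searchsorted(times, horizon, side="right") - 1
    if idx < 0:
        raise CoxFittingError("no event time at or before the horizon")
    s0 = float(np.exp(-cumhaz.iloc[idx, 0]))

    labels = cohort["population"].unique()
    label = f"{labels[0]}-fit" if len(labels) == 1 else "fit"
    return CoxComponents(coefficients=coeffs, means=means, s0=s0,
                         horizon=float(horizon), source_label=label)


def predict_risk(components: CoxComponents, covariates: pd.DataFrame) -> np.ndarray:
    """Absolute risk over the horizon for each covariate record:
    ``1 - s0 ** exp(beta'(x - xbar))``.

    Raises
    ------
    SchemaError
        If the covariate table lacks any of the model's terms.
    """
    terms = components.terms
    missing = [t for t in terms if t not in covariates.columns]
    if missing:
        raise SchemaError(f"covariate table missing model terms: {missing}")
    x = covariates[list(terms)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise SchemaError("covariate table contains missing values")
    beta = np.array([components.coefficients[t] for t in terms])
    xbar = np.array([components.means[t] for t in terms])
    eta = (x - xbar) @ beta
    return 1.0 - components.s0 ** np.exp(eta)


def hazard_ratio_table(
    components: CoxComponents, deltas: dict[str, float] | None = None
) -> pd.DataFrame:
    """Hazard ratios ``exp(beta * delta)`` at the given scaling steps.

    ``deltas`` defaults to the steps stored on the components (or 1 per
    term); each delta must be positive.
    """
    if deltas is None:
        deltas = components.deltas or {t: 1.0 for t in components.terms}
    if any(d <= 0 for d in deltas.values()):
        raise ValueError("deltas must be positive")
    rows = [
        {
            "term": t,
            "delta": deltas[t],
            "hazard_ratio": math.exp(components.coefficients[t] * deltas[t]),
        }
        for t in components.terms
        if t in deltas
    ]
    return pd.DataFrame(rows).set_index("term")
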