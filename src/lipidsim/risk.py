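"""Baseline cardiovascular risk and simulated risk reduction.

For patients with established atherosclerotic disease, baseline risk of a
next cardiovascular event comes from a 20-month recurrent-event risk model
(REACH-style Cox linear predictor over demographics and history), converted
to a 10-year horizon under a constant event rate (exponential survival).
The effect of LDL-C lowering is simulated by drawing a rate ratio per
1.0 mmol/L from a log-normal matched to a meta-analytic estimate and its
95% CI (default 0.78, CI 0.76-0.80), giving
RRR = 1 - rr^deltaLDL, residual = baseline x (1 - RRR), ARR = baseline - residual.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, DomainError, MissingCovariateError

#: Covariates of the 20-month recurrent-event model, in linear-predictor order.
REACH_COVARIATES = (
    "age",              # years
    "female",           # 0/1
    "current_smoker",   # 0/1
    "former_smoker",    # 0/1
    "diabetes",         # 0/1
    "bmi",              # kg/m2
    "n_vascular_beds",  # 1-3
    "event_past_year",  # 0/1
    "chf",              # 0/1
    "af",               # 0/1
    "statin",           # 0/1 (protective)
    "aspirin",          # 0/1 (protective)
    "region_high_risk", # 0/1
)


@dataclass(frozen=True)
class ReachParameters:
    """Parameters of the 20-month next-CV-event model.

    20-month risk = 1 - baseline_survival ^ exp(lp - lp_offset), a Cox-type
    relative-risk form where ``lp`` is the dot product of ``coefficients``
    with the covariate vector and ``lp_offset`` centres the predictor at a
    reference profile. The published coefficient table is not reproduced
    here; the defaults are calibrated values following the published model's
    covariate structure and hazard-ratio magnitudes, and are plain config
    data a user can override.
    """

    coefficients: dict[str, float]
    baseline_survival: float = 0.925
    lp_offset: float = 2.47
    source_months: float = 20.0
    horizon_months: float = 120.0

    def __post_init__(self) -> None:
        errs = []
        missing = set(REACH_COVARIATES) - set(self.coefficients)
        if missing:
            errs.append(f"REACH coefficients missing: {sorted(missing)}")
        for extra in set(self.coefficients) - set(REACH_COVARIATES):
            errs.append(f"unknown REACH coefficient {extra!r}")
        if not 0.0 < self.baseline_survival <= 1.0:
            errs.append("baseline_survival must be in (0, 1]")
        if self.source_months <= 0 or self.horizon_months <= 0:
            errs.append("source_months and horizon_months must be positive")
        if errs:
            raise ConfigurationError(errs)


def default_reach_parameters() -> ReachParameters:
    return ReachParameters(
        coefficients={
            "age": 0.030,
            "female": -0.18,
            "current_smoker": 0.28,
            "former_smoker": 0.09,
            "diabetes": 0.40,
            "bmi": -0.006,
            "n_vascular_beds": 0.33,
            "event_past_year": 0.55,
            "chf": 0.60,
            "af": 0.33,
            "statin": -0.25,
            "aspirin": -0.10,
            "region_high_risk": 0.20,
        }
    )


def reach_20month_risk(covariates: dict, params: ReachParameters | None = None) -> float:
    """20-month risk of a next CV event for one patient.

    ``covariates`` maps every name in :data:`REACH_COVARIATES` to its value;
    a missing or NaN covariate raises :class:`MissingCovariateError` naming it.
    """
    params = params or default_reach_parameters()
    lp = 0.0
    for name in REACH_COVARIATES:
        value = covariates.get(name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise MissingCovariateError(f"REACH requires covariate {name!r}")
        lp += params.coefficients[name] * float(value)
    risk = 1.0 - params.baseline_survival ** math.exp(lp - params.lp_offset)
    return min(max(risk, 0.0), 1.0)


def convert_horizon(
    risk_source: float, source_months: float = 20.0, horizon_months: float = 120.0
) -> float:
    """Re-express a cumulative event risk on a different time horizon
    assuming a constant event rate: 1 - (1 - r)^(horizon/source)."""
    if not 0.0 <= risk_source <= 1.0:
        raise DomainError(f"risk must be in [0,1], got {risk_source}")
    if source_months <= 0 or horizon_months <= 0:
        raise DomainError("horizons must be positive")
    if risk_source == 1.0:
        return 1.0
    return 1.0 - (1.0 - risk_source) ** (horizon_months / source_months)


@dataclass(frozen=True)
class RateRatioModel:
    """Rate ratio of CV events per 1.0 mmol/L LDL-C reduction.

    Sampled on the log scale: log-normal with median ``rr_per_mmol`` and
    2.5/97.5 percentiles at the CI bounds (inverse-CDF sampling).
    """

    rr_per_mmol: float = 0.78
    ci_lower: float = 0.76
    ci_upper: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_lower <= self.rr_per_mmol <= self.ci_upper < 1.0:
            raise ConfigurationError(
                "rate ratio model requires 0 < ci_lower <= rr <= ci_upper < 1, "
                f"got ({self.ci_lower}, {self.rr_per_mmol}, {self.ci_upper})"
            )

    @property
    def log_sigma(self) -> float:
        z975 = norm.ppf(0.975)
        return (math.log(self.ci_upper) - math.log(self.ci_lower)) / (2.0 * z975)


def sample_rate_ratio(model: RateRatioModel, rng, size=None):
    """Inverse-CDF draw(s) of the per-mmol/L rate ratio; always > 0."""
    u = rng.uniform(size=size)
    z = norm.ppf(u)
    rr = np.exp(math.log(model.rr_per_mmol) + model.log_sigma * z)
    return float(rr) if size is None else rr


def relative_risk_reduction(rr, delta_ldl):
    """RRR implied by an achieved LDL-C drop: 1 - rr^delta (vectorised)."""
    rr = np.asarray(rr, dtype=float)
    delta = np.asarray(delta_ldl, dtype=float)
    if np.any(delta < 0):
        raise DomainError("delta_ldl must be non-negative")
    if np.any((rr <= 0) | (rr > 1)):
        raise DomainError("rate ratio must lie in (0, 1]")
    out = 1.0 - rr**delta
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RiskEstimate:
    """Risk bookkeeping for one patient-replicate."""

    baseline_risk_10yr: float
    rrr: float
    arr: float
    residual_risk: float
    delta_ldl: float


def risk_outcomes(baseline_risk: float, rr: float, delta_ldl: float) -> RiskEstimate:
    """Residual risk and absolute reduction after an achieved LDL-C drop.

    ``delta_ldl`` below zero (a tail draw pushing simulated LDL-C above
    baseline) is floored at 0.
    """
    if not 0.0 <= baseline_risk <= 1.0:
        raise DomainError(f"baseline risk must be in [0,1], got {baseline_risk}")
    delta = max(float(delta_ldl), 0.0)
    rrr = float(relative_risk_reduction(rr, delta))
    residual = baseline_risk * (1.0 - rrr)
    return RiskEstimate(
        baseline_risk_10yr=baseline_risk,
        rrr=rrr,
        arr=baseline_risk - residual,
        residual_risk=residual,
        delta_ldl=delta,
    )
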