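"""ESC/EAS risk categories, LDL-C goals, and the SCORE first-event risk model.

Risk categories map onto LDL-C treatment goals (mmol/L). Goal attainment is
strict ("less than"). For patients without established atherosclerotic
disease, baseline 10-year fatal-CVD risk comes from the published SCORE
Weibull equation (two causes, coronary and non-coronary), and total
first-event risk is approximated by multiplying the fatal estimate by 3 in
men and 4 in women, as the 2019 guidelines recommend.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError, MissingCovariateError

RISK_CATEGORIES = (
    "low",
    "moderate",
    "high",
    "very_high",
    "ascvd_nonrecurrent",
    "ascvd_recurrent",
)
#: Categories eligible for a PCSK9 inhibitor at step 3 of the algorithm.
VERY_HIGH_RISK_CATEGORIES = ("very_high", "ascvd_nonrecurrent", "ascvd_recurrent")
ASCVD_CATEGORIES = ("ascvd_nonrecurrent", "ascvd_recurrent")
REGION_CLASSES = ("low_risk", "high_risk")


@dataclass(frozen=True)
class GoalTable:
    """LDL-C goal thresholds (mmol/L) per risk category.

    Thresholds must be positive and non-increasing from low risk down to
    recurrent atherosclerotic disease (ties are allowed: the very-high and
    non-recurrent ASCVD goals coincide in the 2019 guidelines).
    """

    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        errs = []
        for cat in RISK_CATEGORIES:
            if cat not in self.thresholds:
                errs.append(f"goal table missing category {cat!r}")
            elif self.thresholds[cat] <= 0:
                errs.append(f"goal for {cat!r} must be positive")
        for extra in set(self.thresholds) - set(RISK_CATEGORIES):
            errs.append(f"unknown risk category {extra!r} in goal table")
        if not errs:
            vals = [self.thresholds[c] for c in RISK_CATEGORIES]
            if any(a < b for a, b in zip(vals, vals[1:])):
                errs.append("goal thresholds must be non-increasing from low risk downward")
        if errs:
            raise ConfigurationError(errs)


def default_goal_table() -> GoalTable:
    """2019 ESC/EAS goals: <3.0 / <2.6 / <1.8 / <1.4 mmol/L by risk, and
    <1.0 mmol/L for recurrent events within 2 years."""
    return GoalTable(
        thresholds={
            "low": 3.0,
            "moderate": 2.6,
            "high": 1.8,
            "very_high": 1.4,
            "ascvd_nonrecurrent": 1.4,
            "ascvd_recurrent": 1.0,
        }
    )


def ldl_goal(category: str, goals: GoalTable | None = None) -> float:
    """LDL-C goal threshold (mmol/L) for a risk category."""
    goals = goals or default_goal_table()
    try:
        return goals.thresholds[category]
    except KeyError:
        raise ConfigurationError(f"no goal configured for category {category!r}") from None


def attains_goal(ldl: float, category: str, goals: GoalTable | None = None) -> bool:
    """True iff ``ldl`` is strictly below the category's goal threshold."""
    return ldl < ldl_goal(category, goals)


# ---------------------------------------------------------------------------
# SCORE fatal-CVD risk (Weibull, two causes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CauseCoefficients:
    """One cause's Weibull baseline (alpha, p) per sex, plus covariate betas."""

    alpha: dict[str, float]  # sex -> alpha
    p: dict[str, float]      # sex -> shape
    beta_chol: float
    beta_sbp: float
    beta_smoker: float


@dataclass(frozen=True)
class ScoreParameters:
    """Parameters of the SCORE fatal-CVD equation plus fatal->total multipliers.

    ``regions`` maps region class -> {'chd': CauseCoefficients,
    'non_chd': CauseCoefficients}. ``cholesterol_term`` selects whether the
    cholesterol covariate is total cholesterol (centred at 6 mmol/L) or the
    TC/HDL-C ratio (centred at 5).
    """

    regions: dict[str, dict[str, CauseCoefficients]]
    multipliers: dict[str, float] = field(
        default_factory=lambda: {"male": 3.0, "female": 4.0}
    )
    cholesterol_term: str = "tc"

    def __post_init__(self) -> None:
        errs = []
        for sex, m in self.multipliers.items():
            if m <= 0:
                errs.append(f"multiplier for {sex!r} must be positive")
        if self.cholesterol_term not in ("tc", "tc_hdl_ratio"):
            errs.append(f"cholesterol_term must be 'tc' or 'tc_hdl_ratio'")
        for region in self.regions:
            if region not in REGION_CLASSES:
                errs.append(f"unknown region class {region!r}")
        if errs:
            raise ConfigurationError(errs)


def default_score_parameters() -> ScoreParameters:
    """Coefficients of the published SCORE equation, by region class."""
    def cause(alpha_m, p_m, alpha_f, p_f, bc, bs, bk):
        return CauseCoefficients(
            alpha={"male": alpha_m, "female": alpha_f},
            p={"male": p_m, "female": p_f},
            beta_chol=bc, beta_sbp=bs, beta_smoker=bk,
        )

    return ScoreParameters(
        regions={
            "low_risk": {
                "chd": cause(-22.1, 4.71, -29.8, 6.36, 0.24, 0.018, 0.71),
                "non_chd": cause(-26.7, 5.64, -31.0, 6.62, 0.02, 0.022, 0.63),
            },
            "high_risk": {
                "chd": cause(-21.0, 4.62, -28.7, 6.23, 0.24, 0.018, 0.71),
                "non_chd": cause(-25.7, 5.47, -30.0, 6.42, 0.02, 0.022, 0.63),
            },
        }
    )


def _require(value, name: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingCovariateError(f"SCORE requires covariate {name!r}")
    return value


def score_fatal_10yr(
    *,
    age: float,
    sex: str,
    current_smoker: bool,
    sbp: float,
    total_chol: float,
    hdl: float | None = None,
    region: str,
    params: ScoreParameters | None = None,
) -> float:
    """10-year fatal-CVD risk from the SCORE Weibull equation.

    Sums coronary and non-coronary cause-specific risks, each computed as
    1 - S0(age+10)^exp(w) / S0(age)^exp(w) with
    S0(a) = exp(-exp(alpha) * (a - 20)^p). Ages below 20 are clamped to 20
    (the equation's support). Output clamped to [0, 1].
    """
    params = params or default_score_parameters()
    age = max(float(_require(age, "age")), 20.0)
    sex = _require(sex, "sex")
    sbp = float(_require(sbp, "sbp"))
    tc = float(_require(total_chol, "total_chol"))
    region = _require(region, "region")
    if params.cholesterol_term == "tc_hdl_ratio":
        hdl = float(_require(hdl, "hdl"))
        chol_term = tc / hdl - 5.0
    else:
        chol_term = tc - 6.0
    smoker = 1.0 if _require(current_smoker, "current_smoker") else 0.0
    try:
        causes = params.regions[region]
    except KeyError:
        raise ConfigurationError(f"no SCORE coefficients for region {region!r}") from None

    total = 0.0
    for coefs in causes.values():
        alpha = coefs.alpha[sex]
        p = coefs.p[sex]
        s_now = math.exp(-math.exp(alpha) * (age - 20.0) ** p)
        s_10 = math.exp(-math.exp(alpha) * (age - 10.0) ** p)
        w = coefs.beta_chol * chol_term + coefs.beta_sbp * (sbp - 120.0) + coefs.beta_smoker * smoker
        ew = math.exp(w)
        total += 1.0 - (s_10**ew) / (s_now**ew) if s_now > 0 else 1.0
    return min(max(total, 0.0), 1.0)


def total_first_event_risk_10yr(
    fatal_risk: float, sex: str, params: ScoreParameters | None = None
) -> float:
    """Approximate total (fatal + non-fatal) first-event risk: min(1, fatal x
    3) for men, min(1, fatal x 4) for women."""
    params = params or default_score_parameters()
    if not 0.0 <= fatal_risk <= 1.0:
        raise ConfigurationError(f"fatal_risk must be in [0,1], got {fatal_risk}")
    try:
        mult = params.multipliers[sex]
    except KeyError:
        raise ConfigurationError(f"no fatal->total multiplier for sex {sex!r}") from None
    return min(1.0, fatal_risk * mult)
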