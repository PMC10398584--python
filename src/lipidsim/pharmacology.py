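"""Treatment-effect model for lipid-lowering therapies.

Holds the statin dose ladders and their expected percent LDL-C reductions,
the incremental effects of ezetimibe and the PCSK9 inhibitors, and the
truncated-normal sampling of per-replicate treatment effects.

Expected reductions are deterministic table lookups used to back-calculate
untreated LDL-C from an observed on-treatment value; forward application of
a therapy in the simulation instead *samples* a reduction from a normal
distribution truncated to [2%, 98%] so that replicate-to-replicate variation
mirrors between-patient variation in trials.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, DomainError

STATIN_INTENSITIES = ("low", "moderate", "high")
PCSK9_DRUGS = ("alirocumab", "evolocumab")


@dataclass(frozen=True)
class TreatmentEffect:
    """Percent LDL-C reduction distribution for one therapy step.

    mean, sd      : percent reduction (e.g. 43 means an expected 43% drop)
    lower, upper  : truncation bounds of the sampling distribution, percent.
    """

    mean: float
    sd: float
    lower: float = 2.0
    upper: float = 98.0

    def __post_init__(self) -> None:
        errs = []
        if not (0.0 <= self.lower < self.upper <= 100.0):
            errs.append(
                f"truncation bounds must satisfy 0 <= lower < upper <= 100, "
                f"got [{self.lower}, {self.upper}]"
            )
        if self.sd < 0:
            errs.append(f"sd must be non-negative, got {self.sd}")
        if errs:
            raise ConfigurationError(errs)


@dataclass(frozen=True)
class Regimen:
    """A lipid-lowering regimen: statin agent/dose, ezetimibe, PCSK9 inhibitor.

    ``dose_position`` indexes the agent's dose ladder (0 = lowest dose).
    ``statin_agent`` is ``None`` for statin-free regimens (ezetimibe
    monotherapy or untreated).
    """

    statin_agent: str | None = None
    dose_position: int | None = None
    ezetimibe: bool = False
    pcsk9: str | None = None

    @property
    def on_statin(self) -> bool:
        return self.statin_agent is not None

    def __post_init__(self) -> None:
        if (self.statin_agent is None) != (self.dose_position is None):
            raise ConfigurationError(
                "statin_agent and dose_position must both be set or both be None"
            )
        if self.pcsk9 is not None and self.pcsk9 not in PCSK9_DRUGS:
            raise ConfigurationError(f"unknown PCSK9 inhibitor {self.pcsk9!r}")


@dataclass
class EfficacyTable:
    """Expected LDL-C reductions for every (agent, dose) plus add-on therapies.

    statins   : agent -> list of TreatmentEffect, one per dose position
    doses_mg  : agent -> list of dose strengths (mg), same order
    intensity : agent -> list of 'low'|'moderate'|'high', same order
    """

    statins: dict[str, list[TreatmentEffect]]
    doses_mg: dict[str, list[float]]
    intensity: dict[str, list[str]]
    ezetimibe: TreatmentEffect
    pcsk9: dict[str, TreatmentEffect]

    def __post_init__(self) -> None:
        errs = []
        for agent, effects in self.statins.items():
            if not effects:
                errs.append(f"agent {agent!r} has an empty dose ladder")
                continue
            for name, other in (("doses_mg", self.doses_mg), ("intensity", self.intensity)):
                if len(other.get(agent, [])) != len(effects):
                    errs.append(f"{name}[{agent!r}] length does not match the dose ladder")
            for label in self.intensity.get(agent, []):
                if label not in STATIN_INTENSITIES:
                    errs.append(f"unknown intensity label {label!r} for {agent!r}")
        for drug in self.pcsk9:
            if drug not in PCSK9_DRUGS:
                errs.append(f"unknown PCSK9 inhibitor {drug!r}")
        if errs:
            raise ConfigurationError(errs)

    # -- lookups ----------------------------------------------------------
    def top_position(self, agent: str) -> int:
        """Index of the highest available dose of ``agent``."""
        return len(self._ladder(agent)) - 1

    def statin_effect(self, agent: str, dose_position: int) -> TreatmentEffect:
        ladder = self._ladder(agent)
        if not 0 <= dose_position < len(ladder):
            raise ConfigurationError(
                f"dose position {dose_position} not in the {agent} ladder "
                f"(0..{len(ladder) - 1})"
            )
        return ladder[dose_position]

    def intensity_of(self, agent: str, dose_position: int) -> str:
        self.statin_effect(agent, dose_position)  # bounds check
        return self.intensity[agent][dose_position]

    def _ladder(self, agent: str) -> list[TreatmentEffect]:
        try:
            return self.statins[agent]
        except KeyError:
            raise ConfigurationError(f"unknown statin agent {agent!r}") from None


def default_efficacy_table() -> EfficacyTable:
    """Default efficacy table.

    Statin reductions follow published dose-response meta-analyses of
    LDL-C lowering (roughly +6-7 percentage points per dose doubling of
    atorvastatin/rosuvastatin); intensity labels follow the conventional
    low/moderate/high classification (<30% / 30-49% / >=50% expected
    reduction). Ezetimibe adds ~22% on the residual; the two PCSK9
    inhibitors add ~55-60%. All values are config data and overridable.
    """

    def ladder(*pairs: tuple[float, float]) -> list[TreatmentEffect]:
        return [TreatmentEffect(mean=m, sd=s) for m, s in pairs]

    return EfficacyTable(
        statins={
            "atorvastatin": ladder((37, 7), (43, 7), (49, 7), (55, 7)),
            "rosuvastatin": ladder((38, 7), (43, 7), (48, 7), (53, 7)),
            "simvastatin": ladder((27, 7), (32, 7), (37, 7)),
            "pravastatin": ladder((20, 7), (24, 7), (29, 7)),
        },
        doses_mg={
            "atorvastatin": [10, 20, 40, 80],
            "rosuvastatin": [5, 10, 20, 40],
            "simvastatin": [10, 20, 40],
            "pravastatin": [10, 20, 40],
        },
        intensity={
            "atorvastatin": ["moderate", "moderate", "high", "high"],
            "rosuvastatin": ["moderate", "moderate", "high", "high"],
            "simvastatin": ["low", "moderate", "moderate"],
            "pravastatin": ["low", "low", "moderate"],
        },
        ezetimibe=TreatmentEffect(mean=22, sd=8),
        pcsk9={
            "alirocumab": TreatmentEffect(mean=56, sd=13),
            "evolocumab": TreatmentEffect(mean=60, sd=13),
        },
    )


def expected_reduction(regimen: Regimen, table: EfficacyTable) -> float:
    """Mean fractional LDL-C reduction of a regimen (deterministic).

    Components combine multiplicatively on the residual:
    1 - (1 - r_statin)(1 - r_ezetimibe)(1 - r_pcsk9).
    """
    residual = 1.0
    if regimen.on_statin:
        eff = table.statin_effect(regimen.statin_agent, regimen.dose_position)
        residual *= 1.0 - eff.mean / 100.0
    if regimen.ezetimibe:
        residual *= 1.0 - table.ezetimibe.mean / 100.0
    if regimen.pcsk9 is not None:
        try:
            eff = table.pcsk9[regimen.pcsk9]
        except KeyError:
            raise ConfigurationError(
                f"no efficacy entry for PCSK9 inhibitor {regimen.pcsk9!r}"
            ) from None
        residual *= 1.0 - eff.mean / 100.0
    return 1.0 - residual


def untreated_ldl(observed: float, regimen: Regimen, table: EfficacyTable) -> float:
    """Back-calculate the untreated LDL-C behind an on-treatment observation.

    Divides by the residual fraction implied by the regimen's *expected*
    (mean) reduction; always >= observed.
    """
    if observed <= 0:
        raise DomainError(f"observed LDL-C must be positive, got {observed}")
    red = expected_reduction(regimen, table)
    if red >= 1.0:
        raise DomainError("expected reduction >= 100%; untreated LDL-C undefined")
    return observed / (1.0 - red)


def truncated_normal(mean, sd, lower, upper, rng, size=None):
    """Draws from Normal(mean, sd) truncated to [lower, upper].

    Vectorised over ``mean``/``sd``; uses inverse-CDF sampling so one
    uniform per draw is consumed regardless of the truncation mass.
    sd == 0 degenerates to clamp(mean).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    scalar_out = size is None and mean.ndim == 0 and sd.ndim == 0
    if size is None:
        size = np.broadcast_shapes(mean.shape, sd.shape)
    u = rng.uniform(size=size)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = norm.cdf(np.where(sd > 0, (lower - mean) / np.where(sd > 0, sd, 1.0), 0.0))
        b = norm.cdf(np.where(sd > 0, (upper - mean) / np.where(sd > 0, sd, 1.0), 1.0))
        x = mean + sd * norm.ppf(a + u * (b - a))
    x = np.where(sd > 0, x, mean)
    x = np.clip(x, lower, upper)
    return float(x) if scalar_out else x


def sample_reduction(effect: TreatmentEffect, rng, size=None):
    """Sample fractional LDL-C reduction(s) from a TreatmentEffect.

    Returns fractions (percent / 100); every draw lies inside the effect's
    truncation bounds.
    """
    x = truncated_normal(effect.mean, effect.sd, effect.lower, effect.upper, rng, size=size)
    return x / 100.0
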