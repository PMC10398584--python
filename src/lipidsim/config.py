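"""Configuration: one YAML file describing cohort, goals, efficacy and risk.

A config file contains overrides that are deep-merged onto the packaged
defaults, so a minimal file like::

    seed: 7
    simulation:
      n_replicates: 200
    goals:
      high: 2.0

changes only what it names. ``load_config`` validates the merged result and
raises a single :class:`ConfigurationError` listing every violated key.
"""
from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field

import yaml

from .cohort import (
    CohortSpec,
    CovariateModel,
    RegimenWeight,
    StratumSpec,
    default_cohort_spec,
)
from .errors import ConfigurationError
from .goals import (
    CauseCoefficients,
    GoalTable,
    ScoreParameters,
    default_goal_table,
    default_score_parameters,
)
from .pharmacology import EfficacyTable, TreatmentEffect, default_efficacy_table
from .risk import RateRatioModel, ReachParameters, default_reach_parameters
from .simulate import SimulationConfig


@dataclass
class Config:
    """Fully resolved run configuration."""

    cohort: CohortSpec
    simulation: SimulationConfig

    @property
    def seed(self) -> int:
        return self.simulation.seed


def default_config(seed: int = 0) -> Config:
    sim = SimulationConfig(seed=seed)
    return Config(cohort=default_cohort_spec(seed=seed), simulation=sim)


# ---------------------------------------------------------------------------
# dict form
# ---------------------------------------------------------------------------

def config_to_dict(config: Config) -> dict:
    sim = config.simulation
    eff = sim.efficacy

    def _effect(e: TreatmentEffect) -> dict:
        return {"mean": float(e.mean), "sd": float(e.sd)}

    strata = {}
    for s in config.cohort.strata:
        strata[s.name] = {
            "n": s.n,
            "age_mean": s.age_mean, "age_sd": s.age_sd,
            "prop_female": s.prop_female,
            "smoking_probs": list(s.smoking_probs),
            "comorbidity_probs": dict(s.comorbidity_probs),
            "ckd_stage_probs": {int(k): v for k, v in s.ckd_stage_probs.items()},
            "ldl_mean": s.ldl_mean, "ldl_sd": s.ldl_sd,
            "llt_mix": [
                {"weight": w.weight, "statin_agent": w.statin_agent,
                 "dose_position": w.dose_position, "ezetimibe": w.ezetimibe}
                for w in s.llt_mix
            ],
            "covariates": {
                "sbp_normotensive": list(s.covariates.sbp_normotensive),
                "sbp_hypertensive": list(s.covariates.sbp_hypertensive),
                "sbp_range": list(s.covariates.sbp_range),
                "hdl_female": list(s.covariates.hdl_female),
                "hdl_male": list(s.covariates.hdl_male),
                "hdl_range": list(s.covariates.hdl_range),
                "remnant_gap": list(s.covariates.remnant_gap),
                "bmi": list(s.covariates.bmi),
                "bmi_range": list(s.covariates.bmi_range),
                "aspirin_p": s.covariates.aspirin_p,
                "event_past_year_p": s.covariates.event_past_year_p,
                "region_high_risk_p": s.covariates.region_high_risk_p,
            },
            "vascular_bed_probs": dict(s.vascular_bed_probs) if s.vascular_bed_probs else None,
        }

    score = sim.score
    regions = {
        region: {
            cause: {
                "alpha": dict(c.alpha), "p": dict(c.p),
                "beta_chol": c.beta_chol, "beta_sbp": c.beta_sbp,
                "beta_smoker": c.beta_smoker,
            }
            for cause, c in causes.items()
        }
        for region, causes in score.regions.items()
    }

    return {
        "seed": sim.seed,
        "simulation": {
            "n_replicates": sim.n_replicates,
            "scenario": sim.scenario,
            "pcsk9_drugs": list(sim.pcsk9_drugs),
            "include_risk": sim.include_risk,
        },
        "goals": dict(sim.goals.thresholds),
        "efficacy": {
            "truncation": {"lower": eff.ezetimibe.lower, "upper": eff.ezetimibe.upper},
            "statins": {
                agent: {
                    "doses_mg": [float(d) for d in eff.doses_mg[agent]],
                    "mean": [float(e.mean) for e in ladder],
                    "sd": [float(e.sd) for e in ladder],
                    "intensity": list(eff.intensity[agent]),
                }
                for agent, ladder in eff.statins.items()
            },
            "ezetimibe": _effect(eff.ezetimibe),
            "pcsk9": {drug: _effect(e) for drug, e in eff.pcsk9.items()},
        },
        "score": {
            "multipliers": dict(score.multipliers),
            "cholesterol_term": score.cholesterol_term,
            "regions": regions,
        },
        "reach": {
            "coefficients": dict(sim.reach.coefficients),
            "baseline_survival": sim.reach.baseline_survival,
            "lp_offset": sim.reach.lp_offset,
            "source_months": sim.reach.source_months,
            "horizon_months": sim.reach.horizon_months,
        },
        "rate_ratio": {
            "rr_per_mmol": sim.rate_ratio.rr_per_mmol,
            "ci_lower": sim.rate_ratio.ci_lower,
            "ci_upper": sim.rate_ratio.ci_upper,
        },
        "cohort": {"strata": strata},
    }


def _deep_merge(base: dict, override: dict, path: str, errors: list[str]) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            errors.append(f"unknown config key {here!r}")
            continue
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(base[key], value, here, errors)
        else:
            out[key] = copy.deepcopy(value)
    return out


def config_from_dict(data: dict, *, merge_defaults: bool = True) -> Config:
    errors: list[str] = []
    base = config_to_dict(default_config())
    merged = _deep_merge(base, data or {}, "", errors) if merge_defaults else data
    if errors:
        raise ConfigurationError(errors)

    seed = int(merged["seed"])
    try:
        goals = GoalTable(thresholds={k: float(v) for k, v in merged["goals"].items()})
        eff_d = merged["efficacy"]
        lo, hi = eff_d["truncation"]["lower"], eff_d["truncation"]["upper"]

        def _eff(d):
            return TreatmentEffect(mean=float(d["mean"]), sd=float(d["sd"]), lower=lo, upper=hi)

        efficacy = EfficacyTable(
            statins={
                agent: [
                    TreatmentEffect(mean=float(m), sd=float(s), lower=lo, upper=hi)
                    for m, s in zip(d["mean"], d["sd"])
                ]
                for agent, d in eff_d["statins"].items()
            },
            doses_mg={a: [float(x) for x in d["doses_mg"]] for a, d in eff_d["statins"].items()},
            intensity={a: list(d["intensity"]) for a, d in eff_d["statins"].items()},
            ezetimibe=_eff(eff_d["ezetimibe"]),
            pcsk9={drug: _eff(d) for drug, d in eff_d["pcsk9"].items()},
        )

        sc = merged["score"]
        score = ScoreParameters(
            regions={
                region: {
                    cause: CauseCoefficients(
                        alpha=dict(c["alpha"]), p=dict(c["p"]),
                        beta_chol=float(c["beta_chol"]),
                        beta_sbp=float(c["beta_sbp"]),
                        beta_smoker=float(c["beta_smoker"]),
                    )
                    for cause, c in causes.items()
                }
                for region, causes in sc["regions"].items()
            },
            multipliers={k: float(v) for k, v in sc["multipliers"].items()},
            cholesterol_term=sc["cholesterol_term"],
        )

        rd = merged["reach"]
        reach = ReachParameters(
            coefficients={k: float(v) for k, v in rd["coefficients"].items()},
            baseline_survival=float(rd["baseline_survival"]),
            lp_offset=float(rd["lp_offset"]),
            source_months=float(rd["source_months"]),
            horizon_months=float(rd["horizon_months"]),
        )

        rr = merged["rate_ratio"]
        rate_ratio = RateRatioModel(
            rr_per_mmol=float(rr["rr_per_mmol"]),
            ci_lower=float(rr["ci_lower"]),
            ci_upper=float(rr["ci_upper"]),
        )

        strata = []
        for name, s in merged["cohort"]["strata"].items():
            cv = s["covariates"]
            strata.append(StratumSpec(
                name=name,
                n=int(s["n"]),
                age_mean=float(s["age_mean"]), age_sd=float(s["age_sd"]),
                prop_female=float(s["prop_female"]),
                smoking_probs=tuple(float(x) for x in s["smoking_probs"]),
                comorbidity_probs={k: float(v) for k, v in s["comorbidity_probs"].items()},
                ckd_stage_probs={int(k): float(v) for k, v in s["ckd_stage_probs"].items()},
                ldl_mean=float(s["ldl_mean"]), ldl_sd=float(s["ldl_sd"]),
                llt_mix=tuple(
                    RegimenWeight(
                        weight=float(w["weight"]),
                        statin_agent=w["statin_agent"],
                        dose_position=None if w["dose_position"] is None else int(w["dose_position"]),
                        ezetimibe=bool(w["ezetimibe"]),
                    )
                    for w in s["llt_mix"]
                ),
                covariates=CovariateModel(
                    sbp_normotensive=tuple(cv["sbp_normotensive"]),
                    sbp_hypertensive=tuple(cv["sbp_hypertensive"]),
                    sbp_range=tuple(cv["sbp_range"]),
                    hdl_female=tuple(cv["hdl_female"]),
                    hdl_male=tuple(cv["hdl_male"]),
                    hdl_range=tuple(cv["hdl_range"]),
                    remnant_gap=tuple(cv["remnant_gap"]),
                    bmi=tuple(cv["bmi"]),
                    bmi_range=tuple(cv["bmi_range"]),
                    aspirin_p=float(cv["aspirin_p"]),
                    event_past_year_p=float(cv["event_past_year_p"]),
                    region_high_risk_p=float(cv["region_high_risk_p"]),
                ),
                vascular_bed_probs=(
                    {k: float(v) for k, v in s["vascular_bed_probs"].items()}
                    if s["vascular_bed_probs"] else None
                ),
            ))
        cohort_spec = CohortSpec(strata=tuple(strata), seed=seed)
        cohort_spec.validate()

        sim_d = merged["simulation"]
        sim = SimulationConfig(
            n_replicates=int(sim_d["n_replicates"]),
            seed=seed,
            scenario=sim_d["scenario"],
            goals=goals,
            efficacy=efficacy,
            score=score,
            reach=reach,
            rate_ratio=rate_ratio,
            pcsk9_drugs=tuple(sim_d["pcsk9_drugs"]),
            include_risk=bool(sim_d["include_risk"]),
        )
        sim.validate()
    except ConfigurationError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError([f"malformed config: {exc}"]) from exc

    return Config(cohort=cohort_spec, simulation=sim)


def load_config(path) -> Config:
    """Read a YAML config file and merge it onto the defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(["config file must contain a mapping"])
    return config_from_dict(data)


def save_config(config: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_hash(config: Config) -> str:
    """SHA-256 of the canonical YAML dump; identifies a run's inputs."""
    canonical = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
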