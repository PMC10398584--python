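"""Stepwise treatment-optimisation simulation.

Implements the three-step algorithm over a cohort of patients above their
LDL-C goal, replicated with Monte Carlo sampling of treatment effects:

  step 1  up-titrate the current statin to its highest available dose
          (only for patients on a statin below its top dose and not on
          ezetimibe); the new LDL-C is the back-calculated untreated value
          times (1 - sampled top-dose reduction)
  step 2  add ezetimibe for patients not on it and not yet at goal
  step 3  add a PCSK9 inhibitor (alirocumab or evolocumab, equally likely)
          for very-high-risk patients (established ASCVD, or very-high
          primary prevention) not yet at goal

Patients at goal after a step are frozen: their regimen and LDL-C carry
unchanged through later steps. An alternative scenario applies statin
up-titration and ezetimibe as a single combined step.

The engine is vectorised: one replicate is a handful of array operations
over the whole cohort, so the full study size (2,482 patients x 1,000
replicates) runs in seconds on one CPU.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import SyntheticPatient
from .errors import ConfigurationError
from .goals import (
    GoalTable,
    ScoreParameters,
    VERY_HIGH_RISK_CATEGORIES,
    default_goal_table,
    default_score_parameters,
    ldl_goal,
    score_fatal_10yr,
    total_first_event_risk_10yr,
)
from .pharmacology import (
    EfficacyTable,
    Regimen,
    default_efficacy_table,
    expected_reduction,
)
from .risk import (
    RateRatioModel,
    ReachParameters,
    convert_horizon,
    default_reach_parameters,
    reach_20month_risk,
    sample_rate_ratio,
)

SCENARIOS = ("stepwise", "combined_step")
REGIMEN_CLASSES = (
    "none",
    "ezetimibe_only",
    "low_statin",
    "moderate_statin",
    "high_statin",
    "low_statin_ezetimibe",
    "moderate_statin_ezetimibe",
    "high_statin_ezetimibe",
    "pcsk9_combination",
)
_INTENSITY_CODE = {"none": 0, "low": 1, "moderate": 2, "high": 3}


@dataclass
class SimulationConfig:
    """Everything a simulation run needs besides the cohort itself."""

    n_replicates: int = 1000
    seed: int = 0
    scenario: str = "stepwise"
    goals: GoalTable = field(default_factory=default_goal_table)
    efficacy: EfficacyTable = field(default_factory=default_efficacy_table)
    score: ScoreParameters = field(default_factory=default_score_parameters)
    reach: ReachParameters = field(default_factory=default_reach_parameters)
    rate_ratio: RateRatioModel = field(default_factory=RateRatioModel)
    pcsk9_drugs: tuple[str, str] = ("alirocumab", "evolocumab")
    include_risk: bool = True

    def validate(self) -> None:
        errs = []
        if self.n_replicates < 1:
            errs.append("n_replicates must be >= 1")
        if self.scenario not in SCENARIOS:
            errs.append(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        for drug in self.pcsk9_drugs:
            if drug not in self.efficacy.pcsk9:
                errs.append(f"no efficacy entry for PCSK9 inhibitor {drug!r}")
        if errs:
            raise ConfigurationError(errs)


@dataclass(frozen=True)
class StepRecord:
    regimen: Regimen
    ldl: float
    attained: bool


@dataclass(frozen=True)
class PatientPath:
    """One patient x one replicate: state after each applicable step."""

    patient_id: str
    replicate: int
    steps: dict[int, StepRecord]
    first_attainment_step: int | None


@dataclass
class CohortSummary:
    """Aggregated simulation output.

    attainment : per group, mean/SD over replicates of the cumulative
                 proportion at goal by each step (step 3 reported only for
                 groups wholly eligible for a PCSK9 inhibitor)
    ldl        : per group, mean/SD of LDL-C pooled over patient x replicate
    regimen_mix: per (group, regimen class), mean proportion at each step
    risk       : per group, pooled mean/SD of baseline risk, residual risk,
                 RRR and ARR (None if risk was not requested)
    extra_ezetimibe : combined-step scenario only - mean/SD of the count and
                 percentage of very-high-risk patients receiving ezetimibe
                 beyond the stepwise scenario
    """

    scenario: str
    n_patients: int
    n_replicates: int
    attainment: pd.DataFrame
    ldl: pd.DataFrame
    regimen_mix: pd.DataFrame
    risk: pd.DataFrame | None = None
    extra_ezetimibe: dict | None = None

    @property
    def pooled_n(self) -> int:
        """Number of patient x replicate values behind the pooled summaries."""
        return self.n_patients * self.n_replicates


# ---------------------------------------------------------------------------
# Cohort -> arrays
# ---------------------------------------------------------------------------

class _Arrays:
    """Vector view of a cohort, precomputed once per simulation."""

    def __init__(self, cohort: list[SyntheticPatient], config: SimulationConfig):
        eff = config.efficacy
        n = len(cohort)
        self.cohort = cohort
        self.n = n
        self.ids = [p.id for p in cohort]
        self.ldl0 = np.array([p.ldl_mmol_l for p in cohort])
        self.goal = np.array([ldl_goal(p.risk_category, config.goals) for p in cohort])
        self.category = np.array([p.risk_category for p in cohort])
        self.ascvd = np.array([p.ascvd for p in cohort])
        self.vh_eligible = np.array(
            [p.risk_category in VERY_HIGH_RISK_CATEGORIES for p in cohort]
        )
        self.eze0 = np.array([p.regimen.ezetimibe for p in cohort])
        self.on_statin = np.array([p.regimen.on_statin for p in cohort])

        below_top = np.array([
            p.regimen.on_statin and p.regimen.dose_position < eff.top_position(p.regimen.statin_agent)
            for p in cohort
        ])
        self.can_up = self.on_statin & below_top & ~self.eze0
        # residual fraction of the *current* regimen (for back-calculation)
        self.cur_residual = np.array(
            [1.0 - expected_reduction(p.regimen, eff) for p in cohort]
        )
        # top-dose effect of each patient's current agent (nan if no statin)
        self.top_mean = np.full(n, np.nan)
        self.top_sd = np.full(n, np.nan)
        self.intensity0 = np.array(
            [_INTENSITY_CODE[p.statin_intensity] for p in cohort]
        )
        self.intensity_top = self.intensity0.copy()
        for i, p in enumerate(cohort):
            if p.regimen.on_statin:
                top = eff.top_position(p.regimen.statin_agent)
                e = eff.statin_effect(p.regimen.statin_agent, top)
                self.top_mean[i], self.top_sd[i] = e.mean, e.sd
                self.intensity_top[i] = _INTENSITY_CODE[
                    eff.intensity_of(p.regimen.statin_agent, top)
                ]
        self.trunc = (eff.ezetimibe.lower, eff.ezetimibe.upper)
        self.eze_mean, self.eze_sd = eff.ezetimibe.mean, eff.ezetimibe.sd
        d0, d1 = config.pcsk9_drugs
        self.pcsk9_mean = np.array([eff.pcsk9[d0].mean, eff.pcsk9[d1].mean])
        self.pcsk9_sd = np.array([eff.pcsk9[d0].sd, eff.pcsk9[d1].sd])

        self.bed_masks = {
            "cad": np.array(["CAD" in p.beds for p in cohort]),
            "cevd": np.array(["CeVD" in p.beds for p in cohort]),
            "pad": np.array(["PAD" in p.beds for p in cohort]),
        }

    def groups(self) -> dict[str, np.ndarray]:
        g: dict[str, np.ndarray] = {}
        for cat in dict.fromkeys(self.category):
            g[cat] = self.category == cat
        g["no_ascvd"] = ~self.ascvd
        g["ascvd"] = self.ascvd
        g["overall"] = np.ones(self.n, dtype=bool)
        for name, mask in self.bed_masks.items():
            if mask.any():
                g[name] = mask
        return {k: v for k, v in g.items() if v.any()}


def _trunc_from_u(u, mean, sd, lower, upper):
    """Truncated-normal inverse CDF, percent scale -> fraction."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    safe_sd = np.where(sd > 0, sd, 1.0)
    a = norm.cdf((lower - mean) / safe_sd)
    b = norm.cdf((upper - mean) / safe_sd)
    x = mean + sd * norm.ppf(a + u * (b - a))
    x = np.where(sd > 0, x, mean)
    return np.clip(x, lower, upper) / 100.0


def _replicate_rng(config: SimulationConfig, replicate: int) -> np.random.Generator:
    # child key (1, replicate): independent of the cohort stream (key (0,))
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, replicate)))


def _draws(arrays: _Arrays, rng) -> dict[str, np.ndarray]:
    """All random numbers for one replicate, in a fixed order."""
    n = arrays.n
    lo, hi = arrays.trunc
    r_statin = _trunc_from_u(
        rng.uniform(size=n), np.nan_to_num(arrays.top_mean), np.nan_to_num(arrays.top_sd), lo, hi
    )
    r_eze = _trunc_from_u(rng.uniform(size=n), arrays.eze_mean, arrays.eze_sd, lo, hi)
    drug = (rng.uniform(size=n) < 0.5).astype(int)  # 0/1 index into pcsk9_drugs
    r_pcsk9 = _trunc_from_u(
        rng.uniform(size=n), arrays.pcsk9_mean[drug], arrays.pcsk9_sd[drug], lo, hi
    )
    u_rr = rng.uniform(size=n)
    return {"r_statin": r_statin, "r_eze": r_eze, "drug": drug,
            "r_pcsk9": r_pcsk9, "u_rr": u_rr}


def _apply_stepwise(arrays: _Arrays, d: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    ldl0, goal = arrays.ldl0, arrays.goal
    untreated = ldl0 / arrays.cur_residual

    up = arrays.can_up
    ldl1 = np.where(up, untreated * (1.0 - d["r_statin"]), ldl0)
    at1 = ldl1 < goal

    give2 = ~at1 & ~arrays.eze0
    ldl2 = np.where(give2, ldl1 * (1.0 - d["r_eze"]), ldl1)
    at2 = at1 | (ldl2 < goal)

    give3 = ~at2 & arrays.vh_eligible
    ldl3 = np.where(give3, ldl2 * (1.0 - d["r_pcsk9"]), ldl2)
    at3 = at2 | (ldl3 < goal)

    return {"ldl1": ldl1, "ldl2": ldl2, "ldl3": ldl3,
            "at1": at1, "at2": at2, "at3": at3,
            "up": up, "give2": give2, "give3": give3, "drug": d["drug"]}


def _apply_combined(arrays: _Arrays, d: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Statin up-titration and ezetimibe as one step, then the PCSK9 step."""
    ldl0, goal = arrays.ldl0, arrays.goal
    untreated = ldl0 / arrays.cur_residual

    # any patient not on ezetimibe receives it in the combined step; those on
    # a statin below its top dose are simultaneously up-titrated
    give_eze = ~arrays.eze0
    base = np.where(arrays.can_up, untreated * (1.0 - d["r_statin"]), ldl0)
    ldl1 = np.where(give_eze, base * (1.0 - d["r_eze"]), ldl0)
    at1 = ldl1 < goal

    give3 = ~at1 & arrays.vh_eligible
    ldl3 = np.where(give3, ldl1 * (1.0 - d["r_pcsk9"]), ldl1)
    at3 = at1 | (ldl3 < goal)

    return {"ldl1": ldl1, "ldl2": ldl1, "ldl3": ldl3,
            "at1": at1, "at2": at1, "at3": at3,
            "up": arrays.can_up, "give2": give_eze, "give3": give3,
            "drug": d["drug"]}


def _regimen_class_codes(arrays: _Arrays, intensity, eze, pcsk9) -> np.ndarray:
    """Map regimen state vectors to REGIMEN_CLASSES codes."""
    codes = np.zeros(arrays.n, dtype=int)  # none
    statin = intensity > 0
    codes = np.where(~statin & eze, 1, codes)                # ezetimibe_only
    codes = np.where(statin & ~eze, 1 + intensity, codes)    # low/mod/high statin
    codes = np.where(statin & eze, 4 + intensity, codes)     # ...+ ezetimibe
    codes = np.where(pcsk9, 8, codes)                        # pcsk9_combination
    return codes


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def step1_statin_intensify(patient: SyntheticPatient, state: dict, rng,
                           config: SimulationConfig | None = None) -> dict:
    """Apply step 1 to a single patient state ({'regimen', 'ldl'})."""
    config = config or SimulationConfig()
    return _single_step(patient, state, rng, config, step=1)


def step2_add_ezetimibe(patient: SyntheticPatient, state: dict, rng,
                        config: SimulationConfig | None = None) -> dict:
    config = config or SimulationConfig()
    return _single_step(patient, state, rng, config, step=2)


def step3_add_pcsk9(patient: SyntheticPatient, state: dict, rng,
                    config: SimulationConfig | None = None) -> dict:
    config = config or SimulationConfig()
    return _single_step(patient, state, rng, config, step=3)


def _single_step(patient, state, rng, config, step):
    """Scalar reference path for the per-step operations.

    The vectorised engine is the production path; this keeps the per-step
    rules available one patient at a time (and testable in isolation).
    """
    from .pharmacology import sample_reduction, untreated_ldl

    eff = config.efficacy
    regimen: Regimen = state["regimen"]
    ldl: float = state["ldl"]
    goal = ldl_goal(patient.risk_category, config.goals)
    at_goal = state.get("attained", ldl < goal)
    out = dict(state)

    if step == 1:
        can_up = (
            regimen.on_statin
            and regimen.dose_position < eff.top_position(regimen.statin_agent)
            and not regimen.ezetimibe
        )
        if can_up and not at_goal:
            top = eff.top_position(regimen.statin_agent)
            r = sample_reduction(eff.statin_effect(regimen.statin_agent, top), rng)
            out["ldl"] = untreated_ldl(ldl, regimen, eff) * (1.0 - r)
            out["regimen"] = replace(regimen, dose_position=top)
    elif step == 2:
        if not at_goal and not regimen.ezetimibe:
            r = sample_reduction(eff.ezetimibe, rng)
            out["ldl"] = ldl * (1.0 - r)
            out["regimen"] = replace(regimen, ezetimibe=True)
    elif step == 3:
        eligible = patient.risk_category in VERY_HIGH_RISK_CATEGORIES
        if not at_goal and eligible:
            drug = config.pcsk9_drugs[int(rng.uniform() < 0.5)]
            r = sample_reduction(eff.pcsk9[drug], rng)
            out["ldl"] = ldl * (1.0 - r)
            out["regimen"] = replace(regimen, pcsk9=drug)
    out["attained"] = at_goal or out["ldl"] < goal
    return out


def run_replicate(cohort: list[SyntheticPatient], config: SimulationConfig,
                  replicate_index: int) -> list[PatientPath]:
    """Run one Monte Carlo replicate and return per-patient paths.

    Deterministic given (config.seed, replicate_index).
    """
    config.validate()
    arrays = _Arrays(cohort, config)
    rng = _replicate_rng(config, replicate_index)
    d = _draws(arrays, rng)
    apply = _apply_combined if config.scenario == "combined_step" else _apply_stepwise
    res = apply(arrays, d)

    paths = []
    for i, p in enumerate(cohort):
        reg0 = p.regimen
        eff = config.efficacy
        if res["up"][i]:
            reg1 = replace(reg0, dose_position=eff.top_position(reg0.statin_agent))
        else:
            reg1 = reg0
        reg2 = replace(reg1, ezetimibe=True) if res["give2"][i] else reg1
        steps = {
            1: StepRecord(reg1, float(res["ldl1"][i]), bool(res["at1"][i])),
            2: StepRecord(reg2, float(res["ldl2"][i]), bool(res["at2"][i])),
        }
        if arrays.vh_eligible[i]:
            reg3 = (
                replace(reg2, pcsk9=config.pcsk9_drugs[int(res["drug"][i])])
                if res["give3"][i] else reg2
            )
            steps[3] = StepRecord(reg3, float(res["ldl3"][i]), bool(res["at3"][i]))
        first = next((s for s in sorted(steps) if steps[s].attained), None)
        paths.append(PatientPath(p.id, replicate_index, steps, first))
    return paths


class _Pooled:
    """Running pooled mean/SD accumulator (sum, sum of squares, count)."""

    def __init__(self):
        self.s = 0.0
        self.s2 = 0.0
        self.n = 0

    def add(self, values: np.ndarray) -> None:
        self.s += float(values.sum())
        self.s2 += float((values**2).sum())
        self.n += values.size

    def mean(self) -> float:
        return self.s / self.n if self.n else float("nan")

    def sd(self) -> float:
        if self.n < 2:
            return 0.0 if self.n else float("nan")
        var = (self.s2 - self.s**2 / self.n) / (self.n - 1)
        return float(np.sqrt(max(var, 0.0)))


def _baseline_risk(cohort: list[SyntheticPatient], config: SimulationConfig) -> np.ndarray:
    """Deterministic 10-year baseline risk per patient (SCORE or REACH)."""
    risks = np.empty(len(cohort))
    for i, p in enumerate(cohort):
        if p.ascvd:
            r20 = reach_20month_risk(
                {
                    "age": p.age,
                    "female": p.sex == "female",
                    "current_smoker": p.smoker == "current",
                    "former_smoker": p.smoker == "former",
                    "diabetes": p.diabetes,
                    "bmi": p.bmi,
                    "n_vascular_beds": p.n_vascular_beds,
                    "event_past_year": p.event_past_year,
                    "chf": p.chf,
                    "af": p.af,
                    "statin": p.regimen.on_statin,
                    "aspirin": p.aspirin,
                    "region_high_risk": p.region == "high_risk",
                },
                config.reach,
            )
            risks[i] = convert_horizon(
                r20, config.reach.source_months, config.reach.horizon_months
            )
        else:
            fatal = score_fatal_10yr(
                age=p.age, sex=p.sex, current_smoker=p.smoker == "current",
                sbp=p.sbp, total_chol=p.tc_mmol_l, hdl=p.hdl_mmol_l,
                region=p.region, params=config.score,
            )
            risks[i] = total_first_event_risk_10yr(fatal, p.sex, config.score)
    return risks


def run_simulation(cohort: list[SyntheticPatient], config: SimulationConfig) -> CohortSummary:
    """Run ``config.n_replicates`` replicates and aggregate.

    Attainment proportions are summarised as mean/SD over replicates; LDL-C
    and risk quantities are pooled over all patient x replicate values.
    """
    config.validate()
    arrays = _Arrays(cohort, config)
    groups = arrays.groups()
    reps = config.n_replicates
    apply = _apply_combined if config.scenario == "combined_step" else _apply_stepwise

    # step-3 results are reported only for groups wholly PCSK9-eligible
    step3_groups = {g for g, m in groups.items() if arrays.vh_eligible[m].all()}

    attain = {g: np.empty((reps, 3)) for g in groups}
    ldl_pool = {g: [ _Pooled() for _ in range(4) ] for g in groups}  # baseline..step3
    mix_counts = {g: np.zeros((4, len(REGIMEN_CLASSES))) for g in groups}
    risk_pool = (
        {g: {k: _Pooled() for k in ("baseline", "residual", "rrr", "arr")} for g in groups}
        if config.include_risk else None
    )
    extra_eze = np.empty(reps)
    n_vh = int(arrays.vh_eligible.sum())

    baseline = _baseline_risk(cohort, config) if config.include_risk else None

    for rep in range(reps):
        rng = _replicate_rng(config, rep)
        d = _draws(arrays, rng)
        res = apply(arrays, d)
        if config.scenario == "combined_step":
            sw = _apply_stepwise(arrays, d)
            extra_eze[rep] = float((sw["at1"] & ~arrays.eze0 & arrays.vh_eligible).sum())

        # regimen state per step
        intensity1 = np.where(res["up"], arrays.intensity_top, arrays.intensity0)
        eze2 = arrays.eze0 | res["give2"]
        states = [
            (arrays.intensity0, arrays.eze0, np.zeros(arrays.n, bool)),
            (intensity1, arrays.eze0 | (res["give2"] & (config.scenario == "combined_step")), np.zeros(arrays.n, bool)),
            (intensity1, eze2, np.zeros(arrays.n, bool)),
            (intensity1, eze2, res["give3"]),
        ]
        class_codes = [
            _regimen_class_codes(arrays, inten, eze, pk) for inten, eze, pk in states
        ]
        ldls = [arrays.ldl0, res["ldl1"], res["ldl2"], res["ldl3"]]
        ats = [res["at1"], res["at2"], res["at3"]]

        if config.include_risk:
            rr = np.exp(
                np.log(config.rate_ratio.rr_per_mmol)
                + config.rate_ratio.log_sigma * norm.ppf(d["u_rr"])
            )
            delta = np.maximum(arrays.ldl0 - res["ldl3"], 0.0)
            rrr = 1.0 - rr**delta
            residual = baseline * (1.0 - rrr)
            arr = baseline - residual

        for g, mask in groups.items():
            nm = int(mask.sum())
            for s in range(3):
                attain[g][rep, s] = float(ats[s][mask].sum()) / nm
            for s in range(4):
                if s == 3 and g not in step3_groups:
                    continue
                ldl_pool[g][s].add(ldls[s][mask])
                mix_counts[g][s] += np.bincount(
                    class_codes[s][mask], minlength=len(REGIMEN_CLASSES)
                )
            if config.include_risk:
                risk_pool[g]["baseline"].add(baseline[mask])
                risk_pool[g]["residual"].add(residual[mask])
                risk_pool[g]["rrr"].add(rrr[mask])
                risk_pool[g]["arr"].add(arr[mask])

    # ---- assemble frames --------------------------------------------------
    att_rows = {}
    for g, mat in attain.items():
        row = {"n": int(groups[g].sum())}
        for s in range(3):
            col = mat[:, s]
            mean = col.mean()
            sd = col.std(ddof=1) if reps > 1 else 0.0
            if s == 2 and g not in step3_groups:
                mean, sd = float("nan"), float("nan")
            row[f"step{s + 1}_mean"] = mean
            row[f"step{s + 1}_sd"] = sd
        att_rows[g] = row
    attainment = pd.DataFrame.from_dict(att_rows, orient="index")

    ldl_rows = {}
    stages = ("baseline", "step1", "step2", "step3")
    for g, pools in ldl_pool.items():
        row = {}
        for s, stage in enumerate(stages):
            if s == 3 and g not in step3_groups:
                row[f"{stage}_mean"] = float("nan")
                row[f"{stage}_sd"] = float("nan")
            else:
                row[f"{stage}_mean"] = pools[s].mean()
                row[f"{stage}_sd"] = pools[s].sd()
        ldl_rows[g] = row
    ldl = pd.DataFrame.from_dict(ldl_rows, orient="index")

    mix_rows = []
    for g, counts in mix_counts.items():
        nm = int(groups[g].sum())
        for ci, cls in enumerate(REGIMEN_CLASSES):
            row = {"group": g, "regimen_class": cls}
            for s, stage in enumerate(stages):
                denom = nm * reps
                row[stage] = counts[s, ci] / denom if denom else float("nan")
                if s == 3 and g not in step3_groups:
                    row[stage] = float("nan")
            mix_rows.append(row)
    regimen_mix = pd.DataFrame(mix_rows).set_index(["group", "regimen_class"])

    risk_frame = None
    if config.include_risk:
        risk_rows = {}
        for g, pools in risk_pool.items():
            row = {}
            for k, pool in pools.items():
                row[f"{k}_mean"] = pool.mean()
                row[f"{k}_sd"] = pool.sd()
            risk_rows[g] = row
        risk_frame = pd.DataFrame.from_dict(risk_rows, orient="index")

    extra = None
    if config.scenario == "combined_step":
        extra = {
            "count_mean": float(extra_eze.mean()),
            "count_sd": float(extra_eze.std(ddof=1)) if reps > 1 else 0.0,
            "pct_of_very_high": 100.0 * extra_eze.mean() / n_vh if n_vh else float("nan"),
            "n_very_high": n_vh,
        }

    return CohortSummary(
        scenario=config.scenario,
        n_patients=arrays.n,
        n_replicates=reps,
        attainment=attainment,
        ldl=ldl,
        regimen_mix=regimen_mix,
        risk=risk_frame,
        extra_ezetimibe=extra,
    )


def run_combined_scenario(cohort: list[SyntheticPatient], config: SimulationConfig) -> CohortSummary:
    """Run the alternative single-step (statin + ezetimibe) scenario.

    The returned summary's ``extra_ezetimibe`` reports how many very-high-risk
    patients receive ezetimibe beyond the stepwise scenario: exactly those who
    attain goal at step 1 of the stepwise algorithm while not already on it.
    """
    cfg = replace_config(config, scenario="combined_step")
    return run_simulation(cohort, cfg)


def replace_config(config: SimulationConfig, **kw) -> SimulationConfig:
    from dataclasses import replace as _r

    return _r(config, **kw)
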