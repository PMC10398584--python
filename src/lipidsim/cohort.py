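"""Synthetic cohort generator.

Emulates the statistical structure of the 2,482 European patients on stable
lipid-lowering therapy who had not attained their 2019 ESC/EAS risk-based
LDL-C goal: six risk strata (four primary-prevention categories plus
non-recurrent and recurrent established-ASCVD), with the published
demographic and comorbidity marginals, the published baseline statin
intensity/ezetimibe mix, and baseline LDL-C drawn from a normal truncated
on the left at each patient's goal (every generated patient is above goal
by construction, matching the simulation's inclusion criterion).

Comorbidities are sampled independently given the stratum: the source
reports stratum-conditional marginals only, so no joint correlation
structure is imposed. Covariates the source never reports at patient level
(SBP, BMI, HDL-C, aspirin, event-in-past-year, region class) come from
configurable plausible distributions and feed only the risk equations.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ConfigurationError, ParseError, SchemaError
from .goals import ASCVD_CATEGORIES, GoalTable, RISK_CATEGORIES, default_goal_table, ldl_goal
from .pharmacology import EfficacyTable, Regimen, default_efficacy_table

SMOKING_LEVELS = ("never", "former", "current")
VASCULAR_BEDS = ("CAD", "CeVD", "PAD")
_BED_KEYS = {"coronary": "CAD", "cerebrovascular": "CeVD", "peripheral": "PAD"}

#: Fixed cohort CSV column order.
COHORT_COLUMNS = [
    "id", "ascvd", "recurrent", "risk_category", "sex", "age", "smoker",
    "diabetes", "hypertension", "chf", "af", "ckd_stage", "fh",
    "n_vascular_beds", "beds", "ldl_mmol_l",
    "statin_agent", "statin_dose_position", "statin_intensity", "ezetimibe",
    "sbp", "tc_mmol_l", "hdl_mmol_l", "bmi", "aspirin", "event_past_year",
    "region",
]


@dataclass(frozen=True)
class RegimenWeight:
    """One entry of a stratum's baseline regimen mixture."""

    weight: float
    statin_agent: str | None = None
    dose_position: int | None = None
    ezetimibe: bool = False


@dataclass(frozen=True)
class CovariateModel:
    """Plausible distributions for covariates not reported at patient level.

    Normal (mean, sd) pairs are clipped to the stated ranges; probabilities
    are Bernoulli parameters. Units: SBP mmHg, cholesterol mmol/L, BMI kg/m2.
    """

    sbp_normotensive: tuple[float, float] = (130.0, 14.0)
    sbp_hypertensive: tuple[float, float] = (145.0, 15.0)
    sbp_range: tuple[float, float] = (90.0, 210.0)
    hdl_female: tuple[float, float] = (1.4, 0.35)
    hdl_male: tuple[float, float] = (1.2, 0.30)
    hdl_range: tuple[float, float] = (0.5, 3.0)
    # total cholesterol = LDL-C + HDL-C + remnant gap (VLDL-C etc.)
    remnant_gap: tuple[float, float] = (0.8, 0.3)
    bmi: tuple[float, float] = (28.5, 4.8)
    bmi_range: tuple[float, float] = (16.0, 55.0)
    aspirin_p: float = 0.2
    event_past_year_p: float = 0.0
    region_high_risk_p: float = 0.3


@dataclass(frozen=True)
class StratumSpec:
    """Target marginals for one risk stratum."""

    name: str
    n: int
    age_mean: float
    age_sd: float
    prop_female: float
    smoking_probs: tuple[float, float, float]  # never, former, current
    comorbidity_probs: dict[str, float]        # diabetes, hypertension, chf, af, fh
    ckd_stage_probs: dict[int, float]          # stage (0=none, 3, 4, 5) -> prob
    ldl_mean: float
    ldl_sd: float
    llt_mix: tuple[RegimenWeight, ...]
    covariates: CovariateModel = field(default_factory=CovariateModel)
    vascular_bed_probs: dict[str, float] | None = None  # coronary/cerebrovascular/peripheral

    def validate(self) -> list[str]:
        errs = []
        if self.name not in RISK_CATEGORIES:
            errs.append(f"unknown stratum name {self.name!r}")
        if self.n < 0 or int(self.n) != self.n:
            errs.append(f"{self.name}: n must be a non-negative integer")
        if self.age_sd <= 0 or self.ldl_sd <= 0:
            errs.append(f"{self.name}: SDs must be positive")
        if not 0.0 <= self.prop_female <= 1.0:
            errs.append(f"{self.name}: prop_female must be in [0,1]")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-9:
            errs.append(f"{self.name}: smoking_probs must sum to 1")
        for k, p in {**self.comorbidity_probs, **{str(s): p for s, p in self.ckd_stage_probs.items()}}.items():
            if not 0.0 <= p <= 1.0:
                errs.append(f"{self.name}: probability for {k!r} outside [0,1]")
        if abs(sum(self.ckd_stage_probs.values()) - 1.0) > 1e-9:
            errs.append(f"{self.name}: ckd_stage_probs must sum to 1")
        if self.n > 0 and not self.llt_mix:
            errs.append(f"{self.name}: non-empty stratum needs a baseline regimen mix")
        if self.llt_mix and abs(sum(w.weight for w in self.llt_mix) - 1.0) > 1e-9:
            errs.append(f"{self.name}: llt_mix weights must sum to 1")
        is_ascvd = self.name in ASCVD_CATEGORIES
        if is_ascvd and not self.vascular_bed_probs:
            errs.append(f"{self.name}: ASCVD strata need vascular_bed_probs")
        if not is_ascvd and self.name == "ascvd_recurrent":
            errs.append("recurrent stratum only valid with ASCVD")
        return errs

    @property
    def is_ascvd(self) -> bool:
        return self.name in ASCVD_CATEGORIES


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort recipe: strata plus the master seed. LDL-C is in mmol/L."""

    strata: tuple[StratumSpec, ...]
    seed: int = 0
    ldl_units: str = "mmol/L"

    def validate(self) -> None:
        errs = []
        names = [s.name for s in self.strata]
        if len(set(names)) != len(names):
            errs.append("duplicate stratum names")
        for s in self.strata:
            errs.extend(s.validate())
        if self.ldl_units != "mmol/L":
            errs.append("ldl_units is fixed to mmol/L")
        if errs:
            raise ConfigurationError(errs)

    @property
    def total_n(self) -> int:
        return sum(s.n for s in self.strata)


@dataclass(frozen=True)
class SyntheticPatient:
    """One simulated individual (see COHORT_COLUMNS for the CSV schema)."""

    id: str
    ascvd: bool
    recurrent: bool
    risk_category: str
    sex: str
    age: float
    smoker: str
    diabetes: bool
    hypertension: bool
    chf: bool
    af: bool
    ckd_stage: int
    fh: bool
    n_vascular_beds: int
    beds: tuple[str, ...]
    ldl_mmol_l: float
    regimen: Regimen
    statin_intensity: str
    sbp: float
    tc_mmol_l: float
    hdl_mmol_l: float
    bmi: float
    aspirin: bool
    event_past_year: bool
    region: str


# ---------------------------------------------------------------------------
# Default spec (published stratum marginals)
# ---------------------------------------------------------------------------

# (weight within intensity class, agent, dose position)
_AGENT_MIX = {
    "low": [(0.40, "simvastatin", 0), (0.40, "pravastatin", 1), (0.20, "pravastatin", 0)],
    "moderate": [
        (0.30, "atorvastatin", 0), (0.25, "atorvastatin", 1),
        (0.15, "simvastatin", 1), (0.10, "simvastatin", 2),
        (0.10, "rosuvastatin", 0), (0.10, "rosuvastatin", 1),
    ],
    "high": [
        (0.35, "atorvastatin", 2), (0.20, "atorvastatin", 3),
        (0.30, "rosuvastatin", 2), (0.15, "rosuvastatin", 3),
    ],
}


def _llt_mix(intensity_shares: dict[str, float], eze_mono: float,
             eze_given_statin: float) -> tuple[RegimenWeight, ...]:
    """Expand intensity-class shares into an explicit (agent, dose, eze) mixture."""
    out = []
    for intensity, share in intensity_shares.items():
        for w, agent, pos in _AGENT_MIX[intensity]:
            for eze, p_eze in ((False, 1 - eze_given_statin), (True, eze_given_statin)):
                weight = share * w * p_eze
                if weight > 0:
                    out.append(RegimenWeight(weight, agent, pos, eze))
    if eze_mono > 0:
        out.append(RegimenWeight(eze_mono, None, None, True))
    total = sum(w.weight for w in out)
    return tuple(replace(w, weight=w.weight / total) for w in out)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Default cohort: 2,482 patients across six strata.

    Counts, demographics and comorbidity marginals follow the published
    stratum table; the regimen mix follows the published overall statin
    share (98.5%), intensity split (4.8/57.9/35.5% low/moderate/high),
    per-group high-intensity shares (23.1% without vs 43.4% with ASCVD)
    and ~10% any-ezetimibe in both groups.
    """
    # statin-user fraction 98.5% => 1.5% ezetimibe monotherapy
    no_ascvd = dict(eze_mono=0.015, eze_given_statin=0.095)
    with_ascvd = dict(eze_mono=0.015, eze_given_statin=0.081)
    mix_no = _llt_mix({"low": 0.070, "moderate": 0.684, "high": 0.231}, **no_ascvd)
    mix_asc = _llt_mix({"low": 0.034, "moderate": 0.517, "high": 0.434}, **with_ascvd)

    cov_primary = CovariateModel(aspirin_p=0.2, event_past_year_p=0.0)
    cov_ascvd = CovariateModel(aspirin_p=0.8, event_past_year_p=0.25)
    cov_recurrent = CovariateModel(aspirin_p=0.85, event_past_year_p=0.9)

    strata = (
        StratumSpec(
            name="low", n=55, age_mean=39.0, age_sd=9.6, prop_female=0.636,
            smoking_probs=(0.709, 0.182, 0.109),
            comorbidity_probs={"diabetes": 0.127, "hypertension": 0.164,
                               "chf": 0.0, "af": 0.0, "fh": 0.545},
            ckd_stage_probs={0: 1.0, 3: 0.0, 4: 0.0, 5: 0.0},
            ldl_mean=3.1, ldl_sd=0.8, llt_mix=mix_no, covariates=cov_primary,
        ),
        StratumSpec(
            name="moderate", n=424, age_mean=62.3, age_sd=9.8, prop_female=0.592,
            smoking_probs=(0.625, 0.269, 0.106),
            comorbidity_probs={"diabetes": 0.328, "hypertension": 0.630,
                               "chf": 0.035, "af": 0.054, "fh": 0.097},
            ckd_stage_probs={0: 0.993, 3: 0.007, 4: 0.0, 5: 0.0},
            ldl_mean=3.1, ldl_sd=0.8, llt_mix=mix_no, covariates=cov_primary,
        ),
        StratumSpec(
            name="high", n=409, age_mean=69.5, age_sd=8.2, prop_female=0.391,
            smoking_probs=(0.555, 0.296, 0.149),
            comorbidity_probs={"diabetes": 0.440, "hypertension": 0.844,
                               "chf": 0.056, "af": 0.139, "fh": 0.032},
            ckd_stage_probs={0: 0.842, 3: 0.156, 4: 0.002, 5: 0.0},
            ldl_mean=3.1, ldl_sd=0.8, llt_mix=mix_no, covariates=cov_primary,
        ),
        StratumSpec(
            name="very_high", n=74, age_mean=71.1, age_sd=9.3, prop_female=0.284,
            smoking_probs=(0.378, 0.189, 0.433),
            comorbidity_probs={"diabetes": 0.514, "hypertension": 0.838,
                               "chf": 0.108, "af": 0.108, "fh": 0.0},
            ckd_stage_probs={0: 0.661, 3: 0.095, 4: 0.149, 5: 0.095},
            ldl_mean=3.1, ldl_sd=0.8, llt_mix=mix_no, covariates=cov_primary,
        ),
        StratumSpec(
            name="ascvd_nonrecurrent", n=1470, age_mean=68.4, age_sd=10.0,
            prop_female=0.329,
            smoking_probs=(0.403, 0.412, 0.185),
            comorbidity_probs={"diabetes": 0.421, "hypertension": 0.797,
                               "chf": 0.107, "af": 0.156, "fh": 0.0},
            ckd_stage_probs={0: 0.908, 3: 0.076, 4: 0.011, 5: 0.005},
            ldl_mean=2.3, ldl_sd=0.8, llt_mix=mix_asc, covariates=cov_ascvd,
            vascular_bed_probs={"coronary": 0.369, "cerebrovascular": 0.427,
                                "peripheral": 0.395},
        ),
        StratumSpec(
            name="ascvd_recurrent", n=50, age_mean=67.5, age_sd=11.7,
            prop_female=0.340,
            smoking_probs=(0.20, 0.54, 0.26),
            comorbidity_probs={"diabetes": 0.44, "hypertension": 0.78,
                               "chf": 0.20, "af": 0.16, "fh": 0.0},
            ckd_stage_probs={0: 0.76, 3: 0.14, 4: 0.06, 5: 0.04},
            ldl_mean=2.3, ldl_sd=0.8, llt_mix=mix_asc, covariates=cov_recurrent,
            vascular_bed_probs={"coronary": 0.62, "cerebrovascular": 0.44,
                                "peripheral": 0.66},
        ),
    )
    return CohortSpec(strata=strata, seed=seed)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _norm_clip(rng, n, mean, sd, lo, hi):
    return np.clip(rng.normal(mean, sd, size=n), lo, hi)


def _generate_stratum(stratum: StratumSpec, rng, goals: GoalTable,
                      efficacy: EfficacyTable, id_offset: int) -> list[SyntheticPatient]:
    n = stratum.n
    cov = stratum.covariates
    goal = ldl_goal(stratum.name, goals)

    female = rng.random(n) < stratum.prop_female
    age = _norm_clip(rng, n, stratum.age_mean, stratum.age_sd, 18.0, 110.0)
    smoker = rng.choice(len(SMOKING_LEVELS), size=n, p=np.asarray(stratum.smoking_probs))
    flags = {
        k: rng.random(n) < p for k, p in stratum.comorbidity_probs.items()
    }
    stages = sorted(stratum.ckd_stage_probs)
    ckd = rng.choice(stages, size=n, p=[stratum.ckd_stage_probs[s] for s in stages])

    # vascular beds: independent Bernoulli marginals; ASCVD patients with no
    # bed drawn get one assigned by normalised marginal weight (>=1 bed).
    beds = np.zeros((n, 3), dtype=bool)
    if stratum.is_ascvd:
        probs = np.array([stratum.vascular_bed_probs[k] for k in
                          ("coronary", "cerebrovascular", "peripheral")])
        beds = rng.random((n, 3)) < probs
        none = ~beds.any(axis=1)
        if none.any():
            forced = rng.choice(3, size=int(none.sum()), p=probs / probs.sum())
            beds[np.flatnonzero(none), forced] = True

    # baseline regimen
    weights = np.array([w.weight for w in stratum.llt_mix])
    reg_idx = rng.choice(len(weights), size=n, p=weights)

    # baseline LDL-C: left-truncated at the goal so every patient is above it
    if n:
        a = (goal - stratum.ldl_mean) / stratum.ldl_sd
        ldl = truncnorm.rvs(a, np.inf, loc=stratum.ldl_mean, scale=stratum.ldl_sd,
                            size=n, random_state=rng)
    else:
        ldl = np.empty(0)

    hypertensive = flags["hypertension"]
    sbp = np.where(
        hypertensive,
        rng.normal(*cov.sbp_hypertensive, size=n),
        rng.normal(*cov.sbp_normotensive, size=n),
    )
    sbp = np.clip(sbp, *cov.sbp_range)
    hdl = np.where(
        female, rng.normal(*cov.hdl_female, size=n), rng.normal(*cov.hdl_male, size=n)
    )
    hdl = np.clip(hdl, *cov.hdl_range)
    gap = np.clip(rng.normal(*cov.remnant_gap, size=n), 0.1, None)
    tc = ldl + hdl + gap
    bmi = _norm_clip(rng, n, *cov.bmi, *cov.bmi_range)
    aspirin = rng.random(n) < cov.aspirin_p
    event_py = rng.random(n) < cov.event_past_year_p
    region = np.where(rng.random(n) < cov.region_high_risk_p, "high_risk", "low_risk")

    patients = []
    bed_names = np.array(VASCULAR_BEDS)
    for i in range(n):
        rw = stratum.llt_mix[reg_idx[i]]
        regimen = Regimen(statin_agent=rw.statin_agent, dose_position=rw.dose_position,
                          ezetimibe=rw.ezetimibe)
        intensity = (
            efficacy.intensity_of(rw.statin_agent, rw.dose_position)
            if rw.statin_agent is not None else "none"
        )
        pbeds = tuple(bed_names[beds[i]])
        patients.append(SyntheticPatient(
            id=f"P{id_offset + i:05d}",
            ascvd=stratum.is_ascvd,
            recurrent=stratum.name == "ascvd_recurrent",
            risk_category=stratum.name,
            sex="female" if female[i] else "male",
            age=float(age[i]),
            smoker=SMOKING_LEVELS[smoker[i]],
            diabetes=bool(flags["diabetes"][i]),
            hypertension=bool(hypertensive[i]),
            chf=bool(flags["chf"][i]),
            af=bool(flags["af"][i]),
            ckd_stage=int(ckd[i]),
            fh=bool(flags["fh"][i]),
            n_vascular_beds=int(beds[i].sum()),
            beds=pbeds,
            ldl_mmol_l=float(ldl[i]),
            regimen=regimen,
            statin_intensity=intensity,
            sbp=float(sbp[i]),
            tc_mmol_l=float(tc[i]),
            hdl_mmol_l=float(hdl[i]),
            bmi=float(bmi[i]),
            aspirin=bool(aspirin[i]),
            event_past_year=bool(event_py[i]),
            region=str(region[i]),
        ))
    return patients


def generate_cohort(
    spec: CohortSpec,
    goals: GoalTable | None = None,
    efficacy: EfficacyTable | None = None,
) -> list[SyntheticPatient]:
    """Generate the synthetic cohort described by ``spec``.

    Deterministic given ``spec.seed`` (one independent child stream per
    stratum, all spawned from the master seed so cohorts are reusable
    across simulation runs, which consume separate child streams).
    """
    spec.validate()
    goals = goals or default_goal_table()
    efficacy = efficacy or default_efficacy_table()
    # child 0 is reserved for cohort synthesis; simulation uses child 1+
    root = np.random.SeedSequence(spec.seed, spawn_key=(0,))
    streams = root.spawn(len(spec.strata))
    patients: list[SyntheticPatient] = []
    for stratum, ss in zip(spec.strata, streams):
        rng = np.random.default_rng(ss)
        patients.extend(_generate_stratum(stratum, rng, goals, efficacy, len(patients)))
    return patients


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def cohort_to_frame(cohort: list[SyntheticPatient]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        rows.append({
            "id": p.id,
            "ascvd": int(p.ascvd),
            "recurrent": int(p.recurrent),
            "risk_category": p.risk_category,
            "sex": p.sex,
            "age": p.age,
            "smoker": p.smoker,
            "diabetes": int(p.diabetes),
            "hypertension": int(p.hypertension),
            "chf": int(p.chf),
            "af": int(p.af),
            "ckd_stage": p.ckd_stage,
            "fh": int(p.fh),
            "n_vascular_beds": p.n_vascular_beds,
            "beds": ";".join(p.beds),
            "ldl_mmol_l": p.ldl_mmol_l,
            "statin_agent": p.regimen.statin_agent or "",
            "statin_dose_position": -1 if p.regimen.dose_position is None else p.regimen.dose_position,
            "statin_intensity": p.statin_intensity,
            "ezetimibe": int(p.regimen.ezetimibe),
            "sbp": p.sbp,
            "tc_mmol_l": p.tc_mmol_l,
            "hdl_mmol_l": p.hdl_mmol_l,
            "bmi": p.bmi,
            "aspirin": int(p.aspirin),
            "event_past_year": int(p.event_past_year),
            "region": p.region,
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(cohort: list[SyntheticPatient], path) -> None:
    """Write the cohort as CSV with the fixed column schema."""
    cohort_to_frame(cohort).to_csv(path, index=False, lineterminator="\n")


def read_cohort(path) -> list[SyntheticPatient]:
    """Read a cohort CSV; inverse of :func:`write_cohort` field-for-field."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing mandatory column(s): {', '.join(missing)}")

    def _float(value, column, row):
        try:
            return float(value)
        except ValueError:
            raise ParseError(
                f"non-numeric {column} value {value!r} in row {row + 2}"
            ) from None

    patients = []
    for i, row in enumerate(df.itertuples(index=False)):
        agent = row.statin_agent or None
        pos = int(row.statin_dose_position)
        regimen = Regimen(
            statin_agent=agent,
            dose_position=None if agent is None else pos,
            ezetimibe=bool(int(row.ezetimibe)),
        )
        patients.append(SyntheticPatient(
            id=row.id,
            ascvd=bool(int(row.ascvd)),
            recurrent=bool(int(row.recurrent)),
            risk_category=row.risk_category,
            sex=row.sex,
            age=_float(row.age, "age", i),
            smoker=row.smoker,
            diabetes=bool(int(row.diabetes)),
            hypertension=bool(int(row.hypertension)),
            chf=bool(int(row.chf)),
            af=bool(int(row.af)),
            ckd_stage=int(row.ckd_stage),
            fh=bool(int(row.fh)),
            n_vascular_beds=int(row.n_vascular_beds),
            beds=tuple(row.beds.split(";")) if row.beds else (),
            ldl_mmol_l=_float(row.ldl_mmol_l, "ldl_mmol_l", i),
            regimen=regimen,
            statin_intensity=row.statin_intensity,
            sbp=_float(row.sbp, "sbp", i),
            tc_mmol_l=_float(row.tc_mmol_l, "tc_mmol_l", i),
            hdl_mmol_l=_float(row.hdl_mmol_l, "hdl_mmol_l", i),
            bmi=_float(row.bmi, "bmi", i),
            aspirin=bool(int(row.aspirin)),
            event_past_year=bool(int(row.event_past_year)),
            region=row.region,
        ))
    return patients
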