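"""Shared fixtures: tiny hand-built cohorts and deterministic configs."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")

from lipidsim import (
    EfficacyTable,
    Regimen,
    SimulationConfig,
    SyntheticPatient,
    TreatmentEffect,
    default_cohort_spec,
    default_efficacy_table,
    generate_cohort,
)


def make_patient(
    pid: str,
    category: str = "ascvd_nonrecurrent",
    ldl: float = 2.5,
    agent: str | None = "atorvastatin",
    pos: int | None = 1,
    ezetimibe: bool = False,
    intensity: str = "moderate",
    **overrides,
) -> SyntheticPatient:
    ascvd = category.startswith("ascvd")
    fields = dict(
        id=pid,
        ascvd=ascvd,
        recurrent=category == "ascvd_recurrent",
        risk_category=category,
        sex="male",
        age=65.0,
        smoker="never",
        diabetes=False,
        hypertension=True,
        chf=False,
        af=False,
        ckd_stage=0,
        fh=False,
        n_vascular_beds=1 if ascvd else 0,
        beds=("CAD",) if ascvd else (),
        ldl_mmol_l=ldl,
        regimen=Regimen(statin_agent=agent, dose_position=pos, ezetimibe=ezetimibe),
        statin_intensity=intensity if agent else "none",
        sbp=140.0,
        tc_mmol_l=ldl + 1.2 + 0.8,
        hdl_mmol_l=1.2,
        bmi=28.0,
        aspirin=ascvd,
        event_past_year=False,
        region="low_risk",
    )
    fields.update(overrides)
    return SyntheticPatient(**fields)


def zero_variance_efficacy() -> EfficacyTable:
    """Default efficacy table with all SDs zeroed and identical PCSK9 drugs,
    so a replicate is fully determined by the path rules."""
    base = default_efficacy_table()
    return EfficacyTable(
        statins={
            agent: [TreatmentEffect(e.mean, 0.0) for e in ladder]
            for agent, ladder in base.statins.items()
        },
        doses_mg=base.doses_mg,
        intensity=base.intensity,
        ezetimibe=TreatmentEffect(base.ezetimibe.mean, 0.0),
        pcsk9={drug: TreatmentEffect(58.0, 0.0) for drug in base.pcsk9},
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Full default synthetic cohort, seed 0 (shared; treat as read-only)."""
    return generate_cohort(default_cohort_spec(seed=0))


@pytest.fixture()
def ten_patient_cohort():
    """Ten patients covering every path rule of the stepwise algorithm."""
    return [
        # on moderate statin below top dose -> up-titrates
        make_patient("P0", "ascvd_nonrecurrent", 2.5, "atorvastatin", 1),
        # already on top-dose high-intensity statin -> carried over
        make_patient("P1", "ascvd_nonrecurrent", 2.2, "atorvastatin", 3, intensity="high"),
        # on statin + ezetimibe -> no up-titration, no step 2, PCSK9 at step 3
        make_patient("P2", "ascvd_nonrecurrent", 2.8, "simvastatin", 1, ezetimibe=True),
        # ezetimibe monotherapy -> carried to step 3 unchanged
        make_patient("P3", "ascvd_recurrent", 2.0, None, None, ezetimibe=True),
        # moderate risk, no ASCVD -> never eligible for PCSK9
        make_patient("P4", "moderate", 3.5, "simvastatin", 0, intensity="low"),
        # low dose, low LDL: attains at step 1 -> frozen afterwards
        make_patient("P5", "moderate", 2.7, "atorvastatin", 0),
        # high primary-prevention risk on pravastatin (moderate top dose)
        make_patient("P6", "high", 2.9, "pravastatin", 1, intensity="low"),
        # very-high primary prevention -> PCSK9-eligible without ASCVD
        make_patient("P7", "very_high", 3.4, "rosuvastatin", 1),
        # recurrent ASCVD on high-intensity below top dose
        make_patient("P8", "ascvd_recurrent", 2.4, "rosuvastatin", 2, intensity="high"),
        # low risk, large margin above goal
        make_patient("P9", "low", 4.2, "simvastatin", 1),
    ]


@pytest.fixture()
def deterministic_config():
    return SimulationConfig(
        n_replicates=3, seed=42, efficacy=zero_variance_efficacy()
    )
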