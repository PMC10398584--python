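"""Stepwise algorithm: path rules, freeze-at-goal, oracle equivalence."""
from dataclasses import replace

import numpy as np
import pytest

from lipidsim import (
    Regimen,
    SimulationConfig,
    default_goal_table,
    ldl_goal,
    run_combined_scenario,
    run_replicate,
    run_simulation,
    untreated_ldl,
)
from lipidsim.errors import ConfigurationError
from lipidsim.goals import VERY_HIGH_RISK_CATEGORIES
from lipidsim.simulate import (
    step1_statin_intensify,
    step2_add_ezetimibe,
    step3_add_pcsk9,
)

from conftest import make_patient, zero_variance_efficacy


# ---------------------------------------------------------------------------
# Independent brute-force oracle: a per-patient enumeration of the rules,
# written without reference to the vectorised engine.
# ---------------------------------------------------------------------------

def oracle_path(patient, config):
    """Enumerate the three-step rules for one patient, zero-variance effects.

    Returns (ldl_by_step, attained_by_step) with step 3 present only for
    very-high-risk patients.
    """
    eff = config.efficacy
    goal = ldl_goal(patient.risk_category, config.goals)
    reg = patient.regimen
    ldl = patient.ldl_mmol_l
    ldls, ats = {}, {}

    # step 1: up-titrate unless top dose, no statin, or on ezetimibe
    if (reg.on_statin and not reg.ezetimibe
            and reg.dose_position < eff.top_position(reg.statin_agent)):
        top = eff.top_position(reg.statin_agent)
        r_top = eff.statin_effect(reg.statin_agent, top).mean / 100.0
        ldl = untreated_ldl(patient.ldl_mmol_l, reg, eff) * (1.0 - r_top)
    ldls[1], ats[1] = ldl, ldl < goal

    # step 2: add ezetimibe unless frozen at goal or already on it
    if not ats[1] and not reg.ezetimibe:
        ldl = ldl * (1.0 - eff.ezetimibe.mean / 100.0)
    ldls[2], ats[2] = ldl, ats[1] or ldl < goal

    # step 3: PCSK9 inhibitor for very-high-risk patients only
    if patient.risk_category in VERY_HIGH_RISK_CATEGORIES:
        if not ats[2]:
            # drugs made identical in the zero-variance table
            r = eff.pcsk9["alirocumab"].mean / 100.0
            ldl = ldl * (1.0 - r)
        ldls[3], ats[3] = ldl, ats[2] or ldl < goal
    return ldls, ats


class TestOracleEquivalence:
    def test_replicate_matches_brute_force(self, ten_patient_cohort,
                                           deterministic_config):
        """Engine vs independent enumeration on 10 patients, sd = 0."""
        paths = run_replicate(ten_patient_cohort, deterministic_config, 0)
        for patient, path in zip(ten_patient_cohort, paths):
            ldls, ats = oracle_path(patient, deterministic_config)
            assert set(path.steps) == set(ldls), patient.id
            for step in ldls:
                rec = path.steps[step]
                assert rec.ldl == pytest.approx(ldls[step], rel=1e-12), (
                    patient.id, step)
                assert rec.attained is ats[step], (patient.id, step)

    def test_first_attainment_step_consistent(self, ten_patient_cohort,
                                              deterministic_config):
        for path in run_replicate(ten_patient_cohort, deterministic_config, 0):
            attained_steps = [s for s, r in sorted(path.steps.items())
                              if r.attained]
            expected = attained_steps[0] if attained_steps else None
            assert path.first_attainment_step == expected


class TestStepRules:
    def test_top_dose_statin_unchanged_at_step1(self, deterministic_config):
        p = make_patient("X", "ascvd_nonrecurrent", 2.2, "atorvastatin", 3,
                         intensity="high")
        rng = np.random.default_rng(0)
        state = {"regimen": p.regimen, "ldl": p.ldl_mmol_l}
        out = step1_statin_intensify(p, state, rng, deterministic_config)
        assert out["ldl"] == 2.2 and out["regimen"] == p.regimen

    def test_ezetimibe_blocks_uptitration(self, deterministic_config):
        p = make_patient("X", "ascvd_nonrecurrent", 2.8, "simvastatin", 0,
                         ezetimibe=True)
        rng = np.random.default_rng(0)
        out = step1_statin_intensify(
            p, {"regimen": p.regimen, "ldl": 2.8}, rng, deterministic_config)
        assert out["ldl"] == 2.8 and out["regimen"] == p.regimen

    def test_uptitration_hand_computation(self, deterministic_config):
        # atorvastatin 20 mg (43%) -> 80 mg (55%), sd = 0
        p = make_patient("X", "ascvd_nonrecurrent", 2.5, "atorvastatin", 1)
        rng = np.random.default_rng(0)
        out = step1_statin_intensify(
            p, {"regimen": p.regimen, "ldl": 2.5}, rng, deterministic_config)
        assert out["ldl"] == pytest.approx(2.5 / 0.57 * 0.45, rel=1e-12)
        assert out["regimen"].dose_position == 3

    def test_step2_frozen_at_goal(self, deterministic_config):
        p = make_patient("X", "ascvd_nonrecurrent", 1.2, "atorvastatin", 3)
        rng = np.random.default_rng(0)
        out = step2_add_ezetimibe(
            p, {"regimen": p.regimen, "ldl": 1.2, "attained": True}, rng,
            deterministic_config)
        assert out["ldl"] == 1.2 and not out["regimen"].ezetimibe

    def test_step2_carryover_when_already_on_ezetimibe(self, deterministic_config):
        p = make_patient("X", "ascvd_nonrecurrent", 2.8, "simvastatin", 1,
                         ezetimibe=True)
        rng = np.random.default_rng(0)
        out = step2_add_ezetimibe(
            p, {"regimen": p.regimen, "ldl": 2.8}, rng, deterministic_config)
        assert out["ldl"] == 2.8

    def test_step2_arithmetic(self, deterministic_config):
        p = make_patient("X", "ascvd_nonrecurrent", 2.0, "atorvastatin", 3,
                         intensity="high")
        rng = np.random.default_rng(0)
        out = step2_add_ezetimibe(
            p, {"regimen": p.regimen, "ldl": 2.0}, rng, deterministic_config)
        assert out["ldl"] == pytest.approx(2.0 * 0.78, rel=1e-12)

    def test_step3_ineligible_moderate_risk_unchanged(self, deterministic_config):
        p = make_patient("X", "moderate", 2.9, "atorvastatin", 3)
        rng = np.random.default_rng(0)
        out = step3_add_pcsk9(
            p, {"regimen": p.regimen, "ldl": 2.9}, rng, deterministic_config)
        assert out["ldl"] == 2.9 and out["regimen"].pcsk9 is None

    def test_step3_arithmetic(self, deterministic_config):
        p = make_patient("X", "ascvd_nonrecurrent", 2.0, "atorvastatin", 3)
        rng = np.random.default_rng(0)
        out = step3_add_pcsk9(
            p, {"regimen": p.regimen, "ldl": 2.0}, rng, deterministic_config)
        assert out["ldl"] == pytest.approx(2.0 * 0.42, rel=1e-12)
        assert out["regimen"].pcsk9 in ("alirocumab", "evolocumab")

    def test_drug_choice_balanced(self, default_cohort):
        """Over many replicates PCSK9 drug choice is ~50/50 (within 3 SE)."""
        config = SimulationConfig(n_replicates=1, seed=9)
        counts = {"alirocumab": 0, "evolocumab": 0}
        for rep in range(40):
            for path in run_replicate(default_cohort[-200:], config, rep):
                rec = path.steps.get(3)
                if rec is not None and rec.regimen.pcsk9:
                    counts[rec.regimen.pcsk9] += 1
        total = sum(counts.values())
        se = np.sqrt(0.25 / total)
        assert abs(counts["alirocumab"] / total - 0.5) < 3 * se


class TestReplicateInvariants:
    def test_same_seed_identical_paths(self, ten_patient_cohort):
        config = SimulationConfig(n_replicates=1, seed=5)
        a = run_replicate(ten_patient_cohort, config, 3)
        b = run_replicate(ten_patient_cohort, config, 3)
        assert a == b

    def test_ldl_non_increasing_along_path(self, default_cohort):
        config = SimulationConfig(n_replicates=1, seed=11)
        for path in run_replicate(default_cohort[::25], config, 0):
            ldls = [r.ldl for _, r in sorted(path.steps.items())]
            assert all(x >= y - 1e-12 for x, y in zip(ldls, ldls[1:]))

    def test_regimen_frozen_after_attainment(self, default_cohort):
        config = SimulationConfig(n_replicates=1, seed=11)
        for path in run_replicate(default_cohort[::25], config, 0):
            first = path.first_attainment_step
            if first is None:
                continue
            frozen = path.steps[first].regimen
            for step, rec in path.steps.items():
                if step > first:
                    assert rec.regimen == frozen

    def test_step3_only_for_very_high_risk(self, default_cohort):
        config = SimulationConfig(n_replicates=1, seed=11)
        by_id = {p.id: p for p in default_cohort}
        for path in run_replicate(default_cohort[::10], config, 0):
            eligible = by_id[path.patient_id].risk_category in VERY_HIGH_RISK_CATEGORIES
            assert (3 in path.steps) == eligible


class TestRunSimulation:
    def test_replicate_count_validation(self, ten_patient_cohort):
        with pytest.raises(ConfigurationError):
            run_simulation(ten_patient_cohort, SimulationConfig(n_replicates=0))

    def test_zero_variance_effects_give_zero_sd(self, ten_patient_cohort):
        config = SimulationConfig(n_replicates=10, seed=1,
                                  efficacy=zero_variance_efficacy(),
                                  include_risk=False)
        summary = run_simulation(ten_patient_cohort, config)
        sds = summary.attainment[["step1_sd", "step2_sd", "step3_sd"]].to_numpy()
        assert np.nanmax(sds) == 0.0

    def test_attainment_monotone_across_steps(self, default_cohort):
        config = SimulationConfig(n_replicates=5, seed=3, include_risk=False)
        att = run_simulation(default_cohort, config).attainment
        assert (att["step2_mean"] >= att["step1_mean"] - 1e-12).all()
        step3 = att["step3_mean"].dropna()
        assert (step3 >= att.loc[step3.index, "step2_mean"] - 1e-12).all()

    def test_pooled_n_accounting(self, default_cohort):
        config = SimulationConfig(n_replicates=2, seed=3, include_risk=False)
        summary = run_simulation(default_cohort, config)
        assert summary.pooled_n == 2482 * 2
        assert summary.attainment.loc["overall", "n"] == 2482

    def test_conservation_attained_plus_not(self, ten_patient_cohort):
        config = SimulationConfig(n_replicates=1, seed=2)
        paths = run_replicate(ten_patient_cohort, config, 0)
        attained = sum(p.steps[2].attained for p in paths)
        not_attained = sum(not p.steps[2].attained for p in paths)
        assert attained + not_attained == len(ten_patient_cohort)


class TestCombinedScenario:
    def test_all_on_ezetimibe_identical_to_stepwise(self):
        cohort = [
            make_patient(f"E{i}", "ascvd_nonrecurrent", 2.0 + 0.2 * i,
                         "atorvastatin", 3, ezetimibe=True, intensity="high")
            for i in range(6)
        ]
        config = SimulationConfig(n_replicates=4, seed=8)
        stepwise = run_simulation(cohort, config)
        combined = run_combined_scenario(cohort, config)
        assert np.allclose(
            stepwise.attainment[["step1_mean", "step2_mean", "step3_mean"]],
            combined.attainment[["step1_mean", "step2_mean", "step3_mean"]],
            equal_nan=True,
        )
        assert combined.extra_ezetimibe["count_mean"] == 0.0

    def test_combined_equals_stepwise_steps_1_plus_2(self, ten_patient_cohort):
        """With deterministic effects, the combined step reproduces the
        stepwise step-2 LDL for patients not at goal after step 1."""
        config = SimulationConfig(n_replicates=1, seed=4,
                                  efficacy=zero_variance_efficacy())
        stepwise = run_replicate(ten_patient_cohort, config, 0)
        combined = run_replicate(
            ten_patient_cohort, replace(config, scenario="combined_step"), 0)
        for sw, cb in zip(stepwise, combined):
            if not sw.steps[1].attained:
                assert cb.steps[1].ldl == pytest.approx(sw.steps[2].ldl, rel=1e-12)

    def test_extra_ezetimibe_count_identity(self, ten_patient_cohort):
        """Extra recipients = very-high-risk patients attaining at stepwise
        step 1 while not already on ezetimibe (brute-force set identity)."""
        config = SimulationConfig(n_replicates=1, seed=4,
                                  efficacy=zero_variance_efficacy())
        stepwise = run_replicate(ten_patient_cohort, config, 0)
        by_id = {p.id: p for p in ten_patient_cohort}
        expected = sum(
            1 for path in stepwise
            if path.steps[1].attained
            and not by_id[path.patient_id].regimen.ezetimibe
            and by_id[path.patient_id].risk_category in VERY_HIGH_RISK_CATEGORIES
        )
        combined = run_combined_scenario(ten_patient_cohort, config)
        assert combined.extra_ezetimibe["count_mean"] == expected
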