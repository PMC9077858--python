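import numpy as np
import pandas as pd
import pytest

from pedsep import rules
from pedsep.rules import (ClinicalRuleSet, DEFAULT_RULES, classify_ipmof,
                          classify_mas, classify_npmof, classify_smof,
                          classify_tamof, cohort_daily_ofi, label_cohort,
                          ofi_score, sirs_count)

from conftest import make_day, make_series


# ---------------------------------------------------------------------------
# OFI

def test_single_organ_and_saturated_ofi():
    one, flags, _ = ofi_score(pd.Series(make_day(on_vasoactive=1.0)))
    assert one == 1 and flags["cardiovascular"]
    all_day = make_day(on_vasoactive=1.0, mech_vent=1.0, pf_ratio=200.0,
                       bilirubin=2.0, alt=200.0, creatinine=2.0,
                       urine_output=0.2, platelets=50.0, inr=2.0, gcs=8.0,
                       sedated=0.0)
    six, flags, _ = ofi_score(pd.Series(all_day))
    assert six == 6 and all(flags.values())


def test_ofi_conjunctions_require_both_members():
    # platelets below threshold but INR not above: no hematologic failure
    s, flags, _ = ofi_score(pd.Series(make_day(platelets=90.0, inr=1.4)))
    assert s == 0 and not flags["hematologic"]
    s, _, _ = ofi_score(pd.Series(make_day(creatinine=2.0, urine_output=1.0)))
    assert s == 0


def test_ofi_missing_field_scores_zero_and_flags_unevaluable():
    day = make_day(creatinine=np.nan, urine_output=0.1)
    s, flags, unevaluable = ofi_score(pd.Series(day))
    assert s == 0 and "renal" in unevaluable


def test_ofi_missing_sedation_warns_and_uses_gcs_alone():
    day = make_day(gcs=8.0)
    day.pop("sedated")
    with pytest.warns(UserWarning, match="sedation"):
        s, flags, _ = ofi_score(pd.Series(day))
    assert flags["cns"] and s == 1


def test_ofi_matches_randomized_order_oracle(rng):
    """The score equals an independent re-implementation that evaluates the
    six predicates in randomized order."""
    def oracle(day, order):
        preds = {
            "cardiovascular": lambda d: bool(d["on_vasoactive"]),
            "pulmonary": lambda d: bool(d["mech_vent"]) and d["pf_ratio"] < 300,
            "hepatic": lambda d: d["bilirubin"] > 1 and d["alt"] > 100,
            "renal": lambda d: d["creatinine"] > 1 and d["urine_output"] < 0.5,
            "hematologic": lambda d: d["platelets"] < 100 and d["inr"] > 1.5,
            "cns": lambda d: d["gcs"] < 12 and not d["sedated"],
        }
        return sum(preds[o](day) for o in order)

    for _ in range(50):
        day = make_day(
            on_vasoactive=float(rng.integers(2)), mech_vent=float(rng.integers(2)),
            pf_ratio=float(rng.uniform(100, 500)), bilirubin=float(rng.uniform(0, 3)),
            alt=float(rng.uniform(10, 300)), creatinine=float(rng.uniform(0.1, 3)),
            urine_output=float(rng.uniform(0, 2)), platelets=float(rng.uniform(10, 400)),
            inr=float(rng.uniform(0.8, 3)), gcs=float(rng.integers(3, 16)),
            sedated=float(rng.integers(2)))
        order = list(rules.ORGANS)
        rng.shuffle(order)
        assert ofi_score(pd.Series(day))[0] == oracle(day, order)


# ---------------------------------------------------------------------------
# SIRS

def test_sirs_count_extremes_and_single_criterion():
    normal = pd.Series(make_day(heart_rate=100.0, resp_rate=20.0, wbc=10.0,
                                temperature_low=37.0, temperature_high=37.5))
    assert sirs_count(normal, age_years=3.0) == 0
    febrile = pd.Series(make_day(heart_rate=100.0, resp_rate=20.0, wbc=10.0,
                                 temperature_low=36.5, temperature_high=38.6))
    assert sirs_count(febrile, age_years=3.0) == 1
    stormy = pd.Series(make_day(heart_rate=190.0, resp_rate=40.0, wbc=25.0,
                                temperature_low=35.0, temperature_high=39.5))
    assert sirs_count(stormy, age_years=3.0) == 4


def test_sirs_unknown_age_band_raises():
    with pytest.raises(ValueError, match="band"):
        sirs_count(pd.Series(make_day()), age_years=45.0)


# ---------------------------------------------------------------------------
# MOF phenotype rules

MAS_DAY = dict(ferritin=610.0, platelets=88.0, inr=1.6, alt=150.0,
               bilirubin=1.2)
TAMOF_DAY = dict(adamts13=40.0, platelets=80.0, urine_output=0.3,
                 creatinine=1.4)


def test_mas_fires_when_all_five_conditions_met_same_day():
    assert classify_mas(make_series(make_day(**MAS_DAY)))


@pytest.mark.parametrize("knockout", [
    {"ferritin": 499.0}, {"ferritin": 500.0}, {"platelets": 100.0},
    {"inr": 1.5}, {"alt": 100.0}, {"bilirubin": 1.0},
])
def test_mas_every_conjunct_necessary_and_boundaries_strict(knockout):
    day = {**MAS_DAY, **knockout}
    assert not classify_mas(make_series(make_day(**day)))


def test_mas_conditions_on_different_days_do_not_fire():
    """Brute-force day scan: each day misses one conjunct."""
    s = make_series(
        make_day(day=1, ferritin=610.0, platelets=88.0, inr=1.6, alt=150.0),
        make_day(day=2, platelets=88.0, inr=1.6, alt=150.0, bilirubin=1.2),
    )
    assert not classify_mas(s)
    # sanity: a single day holding everything does fire
    assert classify_mas(make_series(make_day(day=3, **MAS_DAY)))


def test_tamof_rule_and_strict_boundary():
    assert classify_tamof(make_series(make_day(**TAMOF_DAY)))
    assert not classify_tamof(make_series(
        make_day(**{**TAMOF_DAY, "adamts13": 57.0})))


@pytest.mark.parametrize("knockout", [
    {"adamts13": 80.0}, {"platelets": 150.0}, {"urine_output": 1.0},
    {"creatinine": 0.8},
])
def test_tamof_every_conjunct_necessary(knockout):
    assert not classify_tamof(make_series(make_day(**{**TAMOF_DAY, **knockout})))


def test_tamof_all_days_missing_adamts13_is_negative():
    s = make_series(make_day(**{**TAMOF_DAY, "adamts13": np.nan}))
    assert not classify_tamof(s)


def test_ipmof_requires_day_beyond_three_and_two_organ_failures():
    failing = dict(tnf_response=150.0, on_vasoactive=1.0, mech_vent=1.0,
                   pf_ratio=200.0)
    assert classify_ipmof(make_series(make_day(day=5, **failing)))
    assert not classify_ipmof(make_series(make_day(day=2, **failing)))
    one_organ = dict(tnf_response=150.0, on_vasoactive=1.0)
    assert not classify_ipmof(make_series(make_day(day=5, **one_organ)))
    ok_tnf = dict(tnf_response=250.0, on_vasoactive=1.0, mech_vent=1.0,
                  pf_ratio=200.0)
    assert not classify_ipmof(make_series(make_day(day=5, **ok_tnf)))


SMOF_TRIGGER = dict(sfasl=300.0, pf_ratio=250.0, mech_vent=1.0)
SMOF_LIVER = dict(alt=150.0, bilirubin=1.5)


def test_smof_lag_of_seven_days():
    fires = make_series(make_day(day=1, **SMOF_TRIGGER),
                        make_day(day=8, **SMOF_LIVER))
    assert classify_smof(fires)
    early_liver = make_series(make_day(day=1, **SMOF_TRIGGER),
                              make_day(day=5, **SMOF_LIVER))
    assert not classify_smof(early_liver)


def test_smof_exhaustive_pair_scan_uses_any_valid_pair():
    # two trigger days; only the earlier pairs with the liver day
    s = make_series(make_day(day=1, **SMOF_TRIGGER),
                    make_day(day=6, **SMOF_TRIGGER),
                    make_day(day=8, **SMOF_LIVER))
    assert classify_smof(s)


@pytest.mark.parametrize("knockout", [
    {"sfasl": 150.0}, {"pf_ratio": 350.0}, {"mech_vent": 0.0},
])
def test_smof_trigger_conjuncts_necessary(knockout):
    s = make_series(make_day(day=1, **{**SMOF_TRIGGER, **knockout}),
                    make_day(day=8, **SMOF_LIVER))
    assert not classify_smof(s)


def test_npmof_new_organ_after_day_one():
    s = make_series(make_day(day=1, on_vasoactive=1.0),
                    make_day(day=3, on_vasoactive=1.0, creatinine=2.0,
                             urine_output=0.2))
    assert classify_npmof(s)
    persists = make_series(make_day(day=1, on_vasoactive=1.0),
                           make_day(day=3, on_vasoactive=1.0))
    assert not classify_npmof(persists)


def test_npmof_saturated_day_one_cannot_progress():
    full = dict(on_vasoactive=1.0, mech_vent=1.0, pf_ratio=200.0,
                bilirubin=2.0, alt=200.0, creatinine=2.0, urine_output=0.2,
                platelets=50.0, inr=2.0, gcs=8.0, sedated=0.0)
    s = make_series(make_day(day=1, **full), make_day(day=5, **full))
    assert not classify_npmof(s)


def test_relaxing_thresholds_is_monotone():
    """Loosening any threshold in the permissive direction never turns a
    positive classification negative."""
    base = make_series(make_day(**MAS_DAY))
    assert classify_mas(base, DEFAULT_RULES)
    looser = ClinicalRuleSet(ferritin_mas=400.0, platelet_low=120.0,
                             inr_high=1.2, alt_high=80.0, bilirubin_high=0.8)
    assert classify_mas(base, looser)
    tam = make_series(make_day(**TAMOF_DAY))
    assert classify_tamof(tam, ClinicalRuleSet(adamts13_low=70.0,
                                               platelet_low=120.0,
                                               oliguria=0.8,
                                               creatinine_high=0.9))


def test_vectorized_daily_ofi_agrees_with_rowwise_engine(default_cohort):
    sample = default_cohort.patients["patient_id"].iloc[:40]
    days = default_cohort.days[default_cohort.days.patient_id.isin(sample)]
    fast = cohort_daily_ofi(days).set_index(["patient_id", "day"])["ofi"]
    for pid, series in days.groupby("patient_id"):
        traj = rules.ofi_trajectory(series).set_index("day")["ofi"]
        for day, val in traj.items():
            assert fast.loc[(pid, day)] == val


def test_label_cohort_agrees_with_generator_truth(default_cohort):
    """The row-wise rule engine reproduces the generator's vectorized truth
    log (dual-route check of the same definitions)."""
    sample = default_cohort.patients["patient_id"].iloc[:60]
    days = default_cohort.days[default_cohort.days.patient_id.isin(sample)]
    labels = label_cohort(days).set_index("patient_id")
    truth = default_cohort.truth.set_index("patient_id").loc[sample]
    for col in ("mas", "tamof", "ipmof", "smof", "npmof"):
        assert (labels[col] == truth[col]).all(), col


def test_rule_thresholds_load_from_yaml():
    rs = ClinicalRuleSet.from_yaml()
    assert rs == DEFAULT_RULES
    with pytest.raises(ValueError, match="positive"):
        ClinicalRuleSet(ferritin_mas=-1.0)
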