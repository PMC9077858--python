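"""Rule-based computable clinical phenotypes.

Implements the per-organ failure index (OFI, 0-6), the age-banded SIRS
count (0-4) and the empirical multiple-organ-failure phenotypes:

* MAS    -- hyperinflammation: ferritin > 500 ng/mL with platelets < 100
            K/mm^3, INR > 1.5, ALT > 100 U/L and bilirubin > 1 mg/dL, all
            on the same day.
* TAMOF  -- thrombotic microangiopathy: ADAMTS13 activity < 57% of control
            with platelets < 100 K/mm^3 and same-day acute kidney injury
            (oliguria < 0.5 mL/kg/h and creatinine > 1 mg/dL).
* IPMOF  -- immunoparalysis: ex vivo TNF response to endotoxin < 200 pg/mL
            beyond day 3 with >= 2 organ failures on that day.
* SMOF   -- sequential liver failure: sFasL > 200 pg/mL with hypoxemic
            respiratory failure (P/F < 300 on mechanical ventilation),
            followed >= 7 days later by ALT > 100 U/L and bilirubin > 1.
* NPMOF  -- any organ failure appearing after day 1 that was absent day 1.

All inequalities are strict: boundary values never fire a rule.  A missing
required value scores the organ 0 / leaves the conjunct unsatisfied, and is
flagged unevaluable rather than raising.
"""

from __future__ import annotations

import dataclasses
import warnings
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .config import load_sirs_bands

ORGANS = ("cardiovascular", "pulmonary", "hepatic", "renal", "hematologic", "cns")

#: Columns that are aggregated to the day's most abnormal value when a day
#: has several rows (e.g. the separate first-6h record on day 1).
_DAY_MIN = ("temperature_low", "systolic_bp", "gcs", "hemoglobin", "platelets",
            "alc", "pf_ratio", "urine_output", "adamts13", "tnf_response")
_DAY_MAX = ("temperature_high", "heart_rate", "creatinine", "inr", "alt",
            "bilirubin", "crp", "ferritin", "sfasl", "wbc", "resp_rate")
_DAY_ANY = ("on_vasoactive", "intubated", "mech_vent", "sedated")


@dataclasses.dataclass(frozen=True)
class ClinicalRuleSet:
    """Thresholds of the computable phenotype rules; overridable via YAML."""

    ferritin_mas: float = 500.0
    platelet_low: float = 100.0
    inr_high: float = 1.5
    alt_high: float = 100.0
    bilirubin_high: float = 1.0
    creatinine_high: float = 1.0
    oliguria: float = 0.5
    pf_low: float = 300.0
    gcs_low: float = 12.0
    adamts13_low: float = 57.0
    tnf_low: float = 200.0
    tnf_day: int = 3
    sfasl_high: float = 200.0
    smof_lag: int = 7
    min_of_for_mof: int = 2

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"rule threshold {f.name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | None = None) -> "ClinicalRuleSet":
        if path is None:
            with resources.files("pedsep.data").joinpath(
                    "rule_thresholds.yaml").open() as fh:
                raw = yaml.safe_load(fh)
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        defaults = cls()
        overrides = {k: v for k, v in raw.items()
                     if getattr(defaults, k, None) != v}
        if path is not None and overrides:
            warnings.warn(f"rule thresholds overridden: {sorted(overrides)}")
        return cls(**{k: type(getattr(defaults, k))(v) for k, v in raw.items()})


DEFAULT_RULES = ClinicalRuleSet()


def _gt(value, thr) -> bool:
    return value is not None and not pd.isna(value) and value > thr


def _lt(value, thr) -> bool:
    return value is not None and not pd.isna(value) and value < thr


def day_worst(day_rows: pd.DataFrame) -> pd.Series:
    """Collapse one day's rows to a single most-abnormal record."""
    if len(day_rows) == 1:
        return day_rows.iloc[0]
    out = day_rows.iloc[-1].copy()
    for col in _DAY_MIN:
        if col in day_rows:
            out[col] = day_rows[col].min()
    for col in _DAY_MAX:
        if col in day_rows:
            out[col] = day_rows[col].max()
    for col in _DAY_ANY:
        if col in day_rows:
            vals = day_rows[col].dropna()
            out[col] = bool(vals.any()) if len(vals) else np.nan
    return out


def ofi_score(day: pd.Series, rules: ClinicalRuleSet = DEFAULT_RULES,
              ) -> tuple[int, dict[str, bool], list[str]]:
    """Organ failure index for one day: (score, per-organ flags, unevaluable).

    An organ with a missing required field scores 0 and is listed in the
    third element.  A missing sedation flag leaves the CNS criterion on GCS
    alone (with a warning) rather than suppressing the organ.
    """
    flags: dict[str, bool] = {}
    unevaluable: list[str] = []

    def need(*cols) -> bool:
        missing = [c for c in cols if c not in day.index or pd.isna(day[c])]
        return not missing

    flags["cardiovascular"] = bool(day.get("on_vasoactive")) \
        if need("on_vasoactive") else False
    if not need("on_vasoactive"):
        unevaluable.append("cardiovascular")

    if need("mech_vent", "pf_ratio"):
        flags["pulmonary"] = bool(day["mech_vent"]) and _lt(day["pf_ratio"], rules.pf_low)
    else:
        flags["pulmonary"] = False
        unevaluable.append("pulmonary")

    if need("bilirubin", "alt"):
        flags["hepatic"] = _gt(day["bilirubin"], rules.bilirubin_high) and \
            _gt(day["alt"], rules.alt_high)
    else:
        flags["hepatic"] = False
        unevaluable.append("hepatic")

    if need("creatinine", "urine_output"):
        flags["renal"] = _gt(day["creatinine"], rules.creatinine_high) and \
            _lt(day["urine_output"], rules.oliguria)
    else:
        flags["renal"] = False
        unevaluable.append("renal")

    if need("platelets", "inr"):
        flags["hematologic"] = _lt(day["platelets"], rules.platelet_low) and \
            _gt(day["inr"], rules.inr_high)
    else:
        flags["hematologic"] = False
        unevaluable.append("hematologic")

    if need("gcs"):
        low_gcs = _lt(day["gcs"], rules.gcs_low)
        if need("sedated"):
            flags["cns"] = low_gcs and not bool(day["sedated"])
        else:
            warnings.warn("sedation flag missing; CNS criterion evaluated on "
                          "GCS alone")
            flags["cns"] = low_gcs
    else:
        flags["cns"] = False
        unevaluable.append("cns")

    return sum(flags.values()), flags, unevaluable


def sirs_count(day: pd.Series, age_years: float,
               bands: list[dict] | None = None) -> int:
    """SIRS criterion count 0-4 against the age-banded reference ranges."""
    if bands is None:
        bands = load_sirs_bands()
    band = next((b for b in bands if b["age_lo"] <= age_years < b["age_hi"]), None)
    if band is None:
        raise ValueError(f"no SIRS reference band for age {age_years}")
    count = 0
    hr = day.get("heart_rate")
    if not pd.isna(hr) and not (band["heart_rate"]["lo"] <= hr <= band["heart_rate"]["hi"]):
        count += 1
    rr = day.get("resp_rate")
    if not pd.isna(rr) and rr > band["resp_rate"]["hi"]:
        count += 1
    tlo = day.get("temperature_low")
    thi = day.get("temperature_high", tlo)
    t_abn = (not pd.isna(tlo) and tlo < band["temperature"]["lo"]) or \
            (not pd.isna(thi) and thi > band["temperature"]["hi"])
    if t_abn:
        count += 1
    wbc = day.get("wbc")
    if not pd.isna(wbc) and not (band["wbc"]["lo"] <= wbc <= band["wbc"]["hi"]):
        count += 1
    return count


def _daily(series: pd.DataFrame) -> pd.DataFrame:
    """One most-abnormal record per day, indexed by day, days ascending."""
    if series.empty:
        raise ValueError("patient series is empty")
    rows = [day_worst(g) for _, g in series.groupby("day", sort=True)]
    out = pd.DataFrame(rows)
    out.index = sorted(series["day"].unique())
    return out


def classify_mas(series: pd.DataFrame,
                 rules: ClinicalRuleSet = DEFAULT_RULES) -> bool:
    """True iff some single day satisfies all five MAS conditions."""
    for _, d in _daily(series).iterrows():
        if (_gt(d.get("ferritin"), rules.ferritin_mas)
                and _lt(d.get("platelets"), rules.platelet_low)
                and _gt(d.get("inr"), rules.inr_high)
                and _gt(d.get("alt"), rules.alt_high)
                and _gt(d.get("bilirubin"), rules.bilirubin_high)):
            return True
    return False


def classify_tamof(series: pd.DataFrame,
                   rules: ClinicalRuleSet = DEFAULT_RULES) -> bool:
    """True iff some single day satisfies all four TAMOF conditions."""
    for _, d in _daily(series).iterrows():
        if (_lt(d.get("adamts13"), rules.adamts13_low)
                and _lt(d.get("platelets"), rules.platelet_low)
                and _lt(d.get("urine_output"), rules.oliguria)
                and _gt(d.get("creatinine"), rules.creatinine_high)):
            return True
    return False


def classify_ipmof(series: pd.DataFrame,
                   rules: ClinicalRuleSet = DEFAULT_RULES) -> bool:
    """True iff some day with index > 3 has TNF response < 200 and OFI >= 2."""
    for day_idx, d in _daily(series).iterrows():
        if day_idx <= rules.tnf_day:
            continue
        if _lt(d.get("tnf_response"), rules.tnf_low):
            score, _, _ = ofi_score(d, rules)
            if score >= rules.min_of_for_mof:
                return True
    return False


def classify_smof(series: pd.DataFrame,
                  rules: ClinicalRuleSet = DEFAULT_RULES) -> bool:
    """True iff a hypoxemic sFasL day is followed >= 7 days later by liver
    failure (exhaustive day-pair scan)."""
    daily = _daily(series)
    trigger_days = [
        day for day, d in daily.iterrows()
        if (_gt(d.get("sfasl"), rules.sfasl_high)
            and _lt(d.get("pf_ratio"), rules.pf_low)
            and bool(d.get("mech_vent")) and not pd.isna(d.get("mech_vent")))
    ]
    if not trigger_days:
        return False
    liver_days = [
        day for day, d in daily.iterrows()
        if _gt(d.get("alt"), rules.alt_high)
        and _gt(d.get("bilirubin"), rules.bilirubin_high)
    ]
    return any(d2 >= d1 + rules.smof_lag for d1 in trigger_days for d2 in liver_days)


def classify_npmof(series: pd.DataFrame,
                   rules: ClinicalRuleSet = DEFAULT_RULES) -> bool:
    """True iff any organ flag fires on a day > 1 that was absent on day 1."""
    daily = _daily(series)
    if 1 not in daily.index:
        raise ValueError("patient series has no day-1 record")
    _, day1_flags, _ = ofi_score(daily.loc[1], rules)
    for day_idx, d in daily.iterrows():
        if day_idx <= 1:
            continue
        _, flags, _ = ofi_score(d, rules)
        if any(flags[o] and not day1_flags[o] for o in ORGANS):
            return True
    return False


def ofi_trajectory(series: pd.DataFrame,
                   rules: ClinicalRuleSet = DEFAULT_RULES) -> pd.DataFrame:
    """Per-day OFI score and organ flags (one row per day in PICU)."""
    records = []
    for day_idx, d in _daily(series).iterrows():
        score, flags, _ = ofi_score(d, rules)
        records.append({"day": day_idx, "ofi": score,
                        **{f"of_{o}": flags[o] for o in ORGANS}})
    return pd.DataFrame(records)


def cohort_daily_ofi(days: pd.DataFrame,
                     rules: ClinicalRuleSet = DEFAULT_RULES) -> pd.DataFrame:
    """Vectorized per-(patient, day) organ flags and OFI for a long table.

    Multiple rows per day (the first-6h record) are collapsed to the day's
    most abnormal values first.  Missing fields leave the organ unflagged.
    """
    agg: dict[str, str] = {}
    for c in _DAY_MIN:
        if c in days.columns:
            agg[c] = "min"
    for c in _DAY_MAX:
        if c in days.columns:
            agg[c] = "max"
    for c in _DAY_ANY:
        if c in days.columns:
            agg[c] = "max"
    d = days.groupby(["patient_id", "day"], sort=True).agg(agg).reset_index()

    def col(name):
        return d[name] if name in d else pd.Series(np.nan, index=d.index)

    flags = pd.DataFrame({
        "of_cardiovascular": col("on_vasoactive") > 0,
        "of_pulmonary": (col("mech_vent") > 0) & (col("pf_ratio") < rules.pf_low),
        "of_hepatic": (col("bilirubin") > rules.bilirubin_high)
                      & (col("alt") > rules.alt_high),
        "of_renal": (col("creatinine") > rules.creatinine_high)
                    & (col("urine_output") < rules.oliguria),
        "of_hematologic": (col("platelets") < rules.platelet_low)
                          & (col("inr") > rules.inr_high),
        "of_cns": (col("gcs") < rules.gcs_low) & ~(col("sedated") > 0),
    })
    out = pd.concat([d[["patient_id", "day"]], flags.fillna(False)], axis=1)
    out["ofi"] = flags.fillna(False).sum(axis=1).astype(int)
    return out


def label_cohort(days: pd.DataFrame,
                 rules: ClinicalRuleSet = DEFAULT_RULES) -> pd.DataFrame:
    """MOF phenotype labels for every patient in a long patient-day table.

    Returns one row per patient: ipmof, tamof, smof, mas, npmof booleans plus
    max_ofi over the stay.
    """
    out = []
    for pid, series in days.groupby("patient_id", sort=True):
        traj = ofi_trajectory(series, rules)
        out.append({
            "patient_id": pid,
            "mas": classify_mas(series, rules),
            "tamof": classify_tamof(series, rules),
            "ipmof": classify_ipmof(series, rules),
            "smof": classify_smof(series, rules),
            "npmof": classify_npmof(series, rules),
            "max_ofi": int(traj["ofi"].max()),
        })
    return pd.DataFrame(out)
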