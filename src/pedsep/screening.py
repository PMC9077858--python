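"""Day-1 feature extraction, variable screening, imputation and scaling.

The 25 clustering variables are extracted per patient from the first PICU
day: PRISM-type vitals and labs take the most abnormal value in the first
6 hours, inflammation markers and organ-failure flags the most abnormal
value within 24 hours.  Candidate variables are then screened (< 20%
missingness; < 60% pairwise correlation, greedy elimination), imputed
(median / mode) and transformed (log1p on skewed variables, then z-scored)
into the matrix the consensus clustering consumes.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .config import load_sirs_bands
from .rules import DEFAULT_RULES, ClinicalRuleSet, day_worst, ofi_score, sirs_count


@dataclasses.dataclass(frozen=True)
class VariableSpec:
    name: str
    kind: str                  # continuous | binary | ordinal
    abnormal_direction: str    # high | low | both | none
    window: str                # 6h | 24h | demographic
    log_transform: bool = False
    cluster_input: bool = True
    source: str | None = None  # patient-day column; defaults to name


def default_schema() -> list[VariableSpec]:
    """The 25 day-1 clustering variables."""
    V = VariableSpec
    return [
        V("age", "continuous", "none", "demographic", log_transform=True),
        V("male", "binary", "none", "demographic"),
        V("hispanic", "binary", "none", "demographic"),
        V("prev_healthy", "binary", "none", "demographic"),
        V("post_op", "binary", "none", "demographic"),
        V("systolic_bp", "continuous", "low", "6h", log_transform=True),
        V("heart_rate", "continuous", "high", "6h", log_transform=True),
        V("gcs", "ordinal", "low", "6h", log_transform=True),
        V("hemoglobin", "continuous", "low", "6h", log_transform=True),
        V("creatinine", "continuous", "high", "6h", log_transform=True),
        V("platelets", "continuous", "low", "6h", log_transform=True),
        V("intubated", "binary", "high", "6h"),
        V("temperature_low", "continuous", "low", "24h"),
        V("temperature_high", "continuous", "high", "24h"),
        V("sirs_count", "ordinal", "high", "24h"),
        V("alc", "continuous", "low", "24h", log_transform=True),
        V("crp", "continuous", "high", "24h", log_transform=True),
        V("ferritin", "continuous", "high", "24h", log_transform=True),
        V("ofi_cardiovascular", "binary", "high", "24h"),
        V("ofi_pulmonary", "binary", "high", "24h"),
        V("ofi_renal", "binary", "high", "24h"),
        V("ofi_hepatic", "binary", "high", "24h"),
        V("ofi_hematologic", "binary", "high", "24h"),
        V("ofi_cns", "binary", "high", "24h"),
        V("ofi_total", "ordinal", "high", "24h", log_transform=True),
    ]


def _window_value(day1: pd.DataFrame, col: str, direction: str,
                  prefer_6h: bool) -> float:
    """Most abnormal value of `col` in the requested day-1 window."""
    rows = day1
    if prefer_6h:
        six = day1[day1["first_6h"].astype(bool)]
        if six[col].notna().any():
            rows = six
    vals = rows[col].dropna()
    if vals.empty:
        return np.nan
    if direction == "low":
        return float(vals.min())
    if direction == "high":
        return float(vals.max())
    return float(vals.iloc[0])


def extract_day1_features(series: pd.DataFrame, patient: pd.Series,
                          schema: list[VariableSpec] | None = None,
                          rules: ClinicalRuleSet = DEFAULT_RULES,
                          sirs_bands: list[dict] | None = None) -> dict:
    """Day-1 feature vector for one patient.

    ``series`` is the patient's day table (may include the first-6h record);
    ``patient`` supplies demographics.  An empty window yields a missing
    value, never an error.
    """
    schema = schema or default_schema()
    day1 = series[series["day"] == 1]
    if day1.empty:
        raise ValueError("series has no day-1 data")
    worst = day_worst(day1)
    score, flags, _ = ofi_score(worst, rules)
    sirs = sirs_count(worst, float(patient["age"]), sirs_bands)
    out: dict[str, float] = {}
    for spec in schema:
        if spec.window == "demographic":
            out[spec.name] = float(patient[spec.name]) if not pd.isna(
                patient.get(spec.name)) else np.nan
        elif spec.name == "sirs_count":
            out[spec.name] = float(sirs)
        elif spec.name == "ofi_total":
            out[spec.name] = float(score)
        elif spec.name.startswith("ofi_"):
            out[spec.name] = float(flags[spec.name[4:]])
        elif spec.name in ("temperature_low", "temperature_high"):
            out[spec.name] = _window_value(day1, spec.name,
                                           spec.abnormal_direction, False)
        else:
            col = spec.source or spec.name
            out[spec.name] = _window_value(day1, col, spec.abnormal_direction,
                                           prefer_6h=(spec.window == "6h"))
    return out


def build_feature_table(cohort, schema: list[VariableSpec] | None = None,
                        rules: ClinicalRuleSet = DEFAULT_RULES) -> pd.DataFrame:
    """Day-1 feature table for a whole cohort (rows indexed by patient_id)."""
    schema = schema or default_schema()
    bands = load_sirs_bands()
    patients = cohort.patients.set_index("patient_id")
    rows = {}
    for pid, series in cohort.iter_series():
        rows[pid] = extract_day1_features(series, patients.loc[pid], schema,
                                          rules, bands)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table[[s.name for s in schema]]
    table.index.name = "patient_id"
    return table


# ---------------------------------------------------------------------------
# screening

@dataclasses.dataclass
class ScreeningReport:
    """Per-candidate screening outcome."""

    table: pd.DataFrame  # variable, missing_fraction, max_abs_correlation,
                         # partner, retained, drop_reason

    @property
    def retained(self) -> list[str]:
        return self.table.loc[self.table["retained"], "variable"].tolist()


def screen_variables(table: pd.DataFrame, miss_thresh: float = 0.20,
                     corr_thresh: float = 0.60,
                     schema_order: list[str] | None = None) -> ScreeningReport:
    """Missingness/correlation screening with greedy pair elimination.

    A column is retained iff its missing fraction is < ``miss_thresh`` and
    its maximum absolute Spearman correlation with any retained column is
    < ``corr_thresh``.  Correlated pairs are eliminated greedily in
    descending |r|, dropping the member with more missingness (ties: the one
    later in schema order), which makes the result independent of column
    order.
    """
    cols = [c for c in table.columns if c != "patient_id"]
    if len(cols) < 2:
        raise ValueError("screening needs at least two candidate columns")
    if not (0 < miss_thresh < 1 and 0 < corr_thresh < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    order = schema_order or cols
    rank = {c: order.index(c) if c in order else len(order) + i
            for i, c in enumerate(cols)}
    miss = table[cols].isna().mean()

    dropped: dict[str, str] = {}
    for c in cols:
        if miss[c] >= miss_thresh:
            dropped[c] = "missingness"

    survivors = [c for c in cols if c not in dropped]
    corr = table[survivors].corr(method="spearman").abs()
    np.fill_diagonal(corr.values, 0.0)
    corr = corr.fillna(0.0)

    active = set(survivors)
    while True:
        sub = corr.loc[sorted(active, key=rank.get), sorted(active, key=rank.get)]
        if sub.empty:
            break
        flat = sub.stack()
        if flat.empty or flat.max() < corr_thresh:
            break
        a, b = flat.idxmax()
        if miss[a] > miss[b]:
            victim = a
        elif miss[b] > miss[a]:
            victim = b
        else:
            victim = a if rank[a] > rank[b] else b
        dropped[victim] = "correlation"
        active.discard(victim)

    if not active:
        raise ValueError("screening eliminated every candidate column")

    retained_cols = [c for c in cols if c in active]
    full_corr = table[cols].corr(method="spearman").abs().fillna(0.0)
    np.fill_diagonal(full_corr.values, 0.0)
    records = []
    for c in cols:
        partners = [r for r in retained_cols if r != c]
        if partners:
            sub = full_corr.loc[c, partners]
            partner, max_r = sub.idxmax(), float(sub.max())
        else:
            partner, max_r = "", 0.0
        records.append({
            "variable": c,
            "missing_fraction": float(miss[c]),
            "max_abs_correlation": max_r,
            "partner": partner,
            "retained": c in active,
            "drop_reason": dropped.get(c, "none"),
        })
    return ScreeningReport(pd.DataFrame(records))


def impute(table: pd.DataFrame, method: str = "median",
           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median (continuous) / mode (binary) imputation; returns the completed
    table and the imputation mask."""
    if method != "median":
        raise ValueError(f"unknown imputation method {method!r}")
    out = table.copy()
    mask = table.isna()
    for c in table.columns:
        col = table[c]
        if col.isna().all():
            raise ValueError(f"column {c!r} is entirely missing")
        vals = col.dropna()
        if set(vals.unique()) <= {0, 1, 0.0, 1.0, True, False}:
            fill = float(vals.mode().iloc[0])
        else:
            fill = float(vals.median())
        out[c] = col.fillna(fill)
    return out, mask


@dataclasses.dataclass
class CohortMatrix:
    """Standardized clustering matrix plus the transform needed to map a new
    raw patient into the same space."""

    X: np.ndarray
    columns: list[str]
    patient_ids: list
    log_flags: dict[str, bool]
    means: dict[str, float]
    sds: dict[str, float]

    def transform(self, raw: pd.DataFrame) -> np.ndarray:
        """Apply the stored log/z transform to raw feature rows (NaN-safe)."""
        out = np.empty((len(raw), len(self.columns)))
        for j, c in enumerate(self.columns):
            x = raw[c].to_numpy(dtype=float)
            if self.log_flags[c]:
                x = np.log1p(x)
            out[:, j] = (x - self.means[c]) / self.sds[c]
        return out

    def inverse_transform(self, Z: np.ndarray) -> pd.DataFrame:
        rows = {}
        for j, c in enumerate(self.columns):
            x = Z[:, j] * self.sds[c] + self.means[c]
            if self.log_flags[c]:
                x = np.expm1(x)
            rows[c] = x
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "log_flags": self.log_flags,
            "means": self.means,
            "sds": self.sds,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.patient_ids, columns=self.columns)


def transform_standardize(table: pd.DataFrame,
                          schema: list[VariableSpec] | None = None,
                          ) -> CohortMatrix:
    """log1p skewed columns, then z-score every column to mean 0, SD 1."""
    schema = schema or default_schema()
    log_map = {s.name: s.log_transform for s in schema}
    cols = list(table.columns)
    X = np.empty((len(table), len(cols)))
    means, sds, logs = {}, {}, {}
    for j, c in enumerate(cols):
        x = table[c].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"column {c!r} has missing values; impute first")
        lg = bool(log_map.get(c, False))
        if lg:
            x = np.log1p(x)
        mu, sd = float(x.mean()), float(x.std(ddof=0))
        if sd == 0:
            raise ValueError(f"column {c!r} has zero variance")
        X[:, j] = (x - mu) / sd
        means[c], sds[c], logs[c] = mu, sd, lg
    return CohortMatrix(X=X, columns=cols, patient_ids=list(table.index),
                        log_flags=logs, means=means, sds=sds)


def save_matrix(matrix: CohortMatrix, csv_path: str, json_path: str) -> None:
    matrix.to_frame().to_csv(csv_path)
    with open(json_path, "w") as fh:
        json.dump(matrix.to_dict(), fh, indent=1)
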