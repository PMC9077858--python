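"""Phenotype association statistics and outcome summaries.

Group comparisons across phenotypes (Kruskal-Wallis for continuous
variables, chi-square or Fisher's exact for categorical ones, with
Benjamini-Hochberg adjustment across each table family), unadjusted and
covariate-adjusted odds ratios, percentage rate tables, daily organ-failure
and cumulative-mortality curves without carry-forward after PICU exit,
chord-diagram links, biomarker log-median-ratio heatmap inputs, and
standardized survivor/non-survivor profiles.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm


# ---------------------------------------------------------------------------
# group comparisons

@dataclasses.dataclass
class GroupComparisonRow:
    variable: str
    test: str           # kruskal-wallis | chi-square | fisher | permutation
    statistic: float
    raw_p: float
    adjusted_p: float
    significant: bool
    note: str = ""


def _is_categorical(values: pd.Series) -> bool:
    vals = values.dropna().unique()
    return set(np.unique(vals)) <= {0, 1, 0.0, 1.0, True, False}


def _categorical_test(var: pd.Series, labels: pd.Series, seed: int,
                      ) -> tuple[str, float, float]:
    tab = pd.crosstab(var, labels)
    chi2, p, dof, expected = sps.chi2_contingency(tab)
    if (expected < 5).any():
        if tab.shape == (2, 2):
            res = sps.fisher_exact(tab.to_numpy())
            return "fisher", float(res[0]), float(res[1])
        # r x c exact test is impractical; permutation chi-square instead
        obs = float(chi2)
        rng = np.random.default_rng(seed)
        v = var.to_numpy()
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = pd.crosstab(rng.permutation(v), labels)
            c, _, _, _ = sps.chi2_contingency(perm, correction=False)
            if c >= obs:
                count += 1
        return "permutation", obs, (count + 1) / (n_perm + 1)
    return "chi-square", float(chi2), float(p)


def compare_groups(features: pd.DataFrame, labels: pd.Series | np.ndarray,
                   variables: list[str] | None = None,
                   alpha: float = 0.05, method: str = "fdr_bh",
                   seed: int = 0) -> list[GroupComparisonRow]:
    """Across-group tests for every variable, multiplicity-adjusted as one
    family.  Continuous -> Kruskal-Wallis; categorical -> chi-square, or
    Fisher's exact (2x2) / permutation chi-square when expected cells < 5.
    """
    labels = pd.Series(np.asarray(labels), index=features.index)
    groups = labels.dropna().unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    variables = variables or list(features.columns)
    rows: list[GroupComparisonRow] = []
    for var in variables:
        col = features[var]
        ok = col.notna() & labels.notna()
        if col[ok].nunique() <= 1:
            rows.append(GroupComparisonRow(var, "skipped", np.nan, np.nan,
                                           np.nan, False, "constant variable"))
            continue
        if _is_categorical(col):
            test, stat, p = _categorical_test(col[ok], labels[ok], seed)
        else:
            samples = [col[ok][labels[ok] == g].to_numpy() for g in groups]
            samples = [s for s in samples if len(s)]
            stat, p = sps.kruskal(*samples)
            test = "kruskal-wallis"
        rows.append(GroupComparisonRow(var, test, float(stat), float(p),
                                       np.nan, False))
    tested = [r for r in rows if not math.isnan(r.raw_p)]
    if tested:
        _, adj, _, _ = multipletests([r.raw_p for r in tested], method=method)
        for r, a in zip(tested, adj):
            r.adjusted_p = float(max(a, r.raw_p))
            r.significant = r.adjusted_p < alpha
    return rows


def comparison_table(rows: list[GroupComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


# ---------------------------------------------------------------------------
# rates and odds ratios

def rate_table(counts: dict[str, int] | pd.Series,
               denominators: dict[str, int] | pd.Series,
               decimals: int = 1) -> pd.DataFrame:
    """Percentages 100*count/denominator, one row per key."""
    counts = pd.Series(counts)
    denominators = pd.Series(denominators)
    rows = []
    for key in counts.index:
        n, d = int(counts[key]), int(denominators[key])
        if d == 0:
            raise ZeroDivisionError(f"zero denominator for {key!r}")
        if n > d:
            raise ValueError(f"count exceeds denominator for {key!r}")
        rows.append({"group": key, "count": n, "denominator": d,
                     "percent": round(100.0 * n / d, decimals)})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class TwoByTwo:
    """Cell counts: exposed-event, exposed-nonevent, unexposed-event,
    unexposed-nonevent."""
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")


@dataclasses.dataclass
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool
    covariates: list[str]
    continuity_corrected: bool = False


def unadjusted_or(t: TwoByTwo) -> ORResult:
    """Cross-product odds ratio with a Woolf log-normal 95% CI.

    Zero cells get the Haldane-Anscombe +0.5 correction (flagged).
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - 1.96 * se), math.exp(math.log(or_) + 1.96 * se)
    z = math.log(or_) / se
    p = 2 * sps.norm.sf(abs(z))
    return ORResult(or_, lo, hi, float(p), adjusted=False, covariates=[],
                    continuity_corrected=corrected)


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows (quasi-)separation."""


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparation or convergence failure
            raise SeparationError(
                "logistic fit failed (possible separation); consider a "
                f"penalized or exact fit: {exc}") from exc
    if not res.mle_retvals.get("converged", True) or \
            np.abs(res.params.iloc[1:]).max() > 15:
        raise SeparationError(
            "logistic fit did not converge to finite coefficients "
            "(quasi-separation); consider a penalized or exact fit")
    return res


def adjusted_or(outcome: np.ndarray | pd.Series,
                exposure: np.ndarray | pd.Series,
                covariates: pd.DataFrame | None = None) -> ORResult:
    """Covariate-adjusted odds ratio from a maximum-likelihood logistic fit
    (Wald 95% CI on the exposure coefficient)."""
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    X = pd.DataFrame({"exposure": np.asarray(exposure, dtype=float)})
    names: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
        names = list(covariates.columns)
    res = _fit_logit(y, X)
    coef = res.params["exposure"]
    lo, hi = res.conf_int().loc["exposure"]
    return ORResult(math.exp(coef), math.exp(lo), math.exp(hi),
                    float(res.pvalues["exposure"]), adjusted=bool(names),
                    covariates=names)


# ---------------------------------------------------------------------------
# curves

def organ_failure_curves(daily_ofi: pd.DataFrame, patients: pd.DataFrame,
                         labels: pd.Series) -> pd.DataFrame:
    """Per-day mean OFI with 95% CI per phenotype, non-nested: a patient
    contributes to day d only while still in the PICU on day d (no
    carry-forward after death or discharge)."""
    lab = labels.rename("phenotype")
    d = daily_ofi.merge(lab, left_on="patient_id", right_index=True)
    d = d.merge(patients[["patient_id", "last_day"]], on="patient_id")
    d = d[d["day"] <= d["last_day"]]
    rows = []
    for (ph, day), g in d.groupby(["phenotype", "day"], sort=True):
        if g.empty:
            continue
        m = float(g["ofi"].mean())
        se = float(g["ofi"].std(ddof=1) / math.sqrt(len(g))) if len(g) > 1 else 0.0
        rows.append({"phenotype": ph, "day": int(day), "mean_ofi": m,
                     "lo": m - 1.96 * se, "hi": m + 1.96 * se,
                     "n_at_risk": len(g)})
    return pd.DataFrame(rows)


def mortality_curves(patients: pd.DataFrame, labels: pd.Series,
                     n_days: int = 28) -> pd.DataFrame:
    """Cumulative mortality fraction by day per phenotype (monotone)."""
    lab = labels.rename("phenotype")
    d = patients.merge(lab, left_on="patient_id", right_index=True)
    rows = []
    for ph, g in d.groupby("phenotype", sort=True):
        n = len(g)
        deaths = g.loc[g["died"].astype(bool), "death_day"]
        for day in range(0, n_days + 1):
            rows.append({"phenotype": ph, "day": day,
                         "cum_mortality": float((deaths <= day).sum()) / n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# figure-style summaries

#: Variable-category map for the chord diagram, and the variables whose link
#: direction is "lower than the cohort mean".
CHORD_CATEGORIES: dict[str, list[str]] = {
    "inflammation": ["temperature_low", "temperature_high", "crp", "ferritin"],
    "organ_failure": ["ofi_total"],
    "pulmonary": ["ofi_pulmonary", "intubated"],
    "cardiovascular": ["heart_rate", "systolic_bp", "ofi_cardiovascular"],
    "renal": ["creatinine", "ofi_renal"],
    "hepatic": ["ofi_hepatic"],
    "hematologic": ["hemoglobin", "platelets", "ofi_hematologic"],
    "neurologic": ["gcs", "ofi_cns"],
}
CHORD_LOWER = {"temperature_low", "systolic_bp", "hemoglobin", "platelets", "gcs"}


def chord_links(features: pd.DataFrame, labels: pd.Series,
                categories: dict[str, list[str]] | None = None,
                require_significance: bool = True,
                alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """(phenotype, category) links: a chord is drawn when any member
    variable's group mean differs from the cohort mean in the specified
    direction (lower for the low-abnormal set, higher otherwise), optionally
    requiring a significant group-vs-rest contrast (BH-adjusted per
    phenotype)."""
    categories = categories or CHORD_CATEGORIES
    labels = pd.Series(np.asarray(labels), index=features.index)
    rows = []
    for ph in sorted(labels.dropna().unique()):
        in_g = labels == ph
        varlist = [v for vars_ in categories.values() for v in vars_
                   if v in features.columns]
        pvals = {}
        for v in varlist:
            col = features[v]
            ok = col.notna()
            if col[ok].nunique() <= 1:
                pvals[v] = 1.0
            elif _is_categorical(col):
                test, _, p = _categorical_test(col[ok], in_g[ok].map(
                    {True: "in", False: "out"}), seed)
                pvals[v] = p
            else:
                _, p = sps.mannwhitneyu(col[ok & in_g], col[ok & ~in_g])
                pvals[v] = float(p)
        if require_significance and pvals:
            _, adj, _, _ = multipletests(list(pvals.values()), method="fdr_bh")
            adj_p = dict(zip(pvals, adj))
        else:
            adj_p = {v: 0.0 for v in pvals}
        for cat, vars_ in categories.items():
            linked = False
            for v in vars_:
                if v not in features.columns:
                    continue
                gmean = features.loc[in_g, v].mean()
                cmean = features[v].mean()
                direction_ok = gmean < cmean if v in CHORD_LOWER else gmean > cmean
                if direction_ok and adj_p[v] < alpha:
                    linked = True
                    break
            rows.append({"phenotype": ph, "category": cat, "linked": linked})
    return pd.DataFrame(rows)


def biomarker_log_ratios(biomarkers: pd.DataFrame, labels: pd.Series,
                         ) -> pd.DataFrame:
    """log(phenotype median / cohort median) per marker, rows and columns
    ordered by average-linkage hierarchical clustering of the profiles."""
    labels = pd.Series(np.asarray(labels), index=biomarkers.index)
    phens = sorted(labels.dropna().unique())
    out = {}
    for marker in biomarkers.columns:
        cohort_med = float(biomarkers[marker].median())
        if cohort_med == 0 or math.isnan(cohort_med):
            warnings.warn(f"marker {marker!r} skipped (zero/undefined cohort "
                          "median)")
            continue
        out[marker] = {
            ph: math.log(float(biomarkers.loc[labels == ph, marker].median())
                         / cohort_med)
            for ph in phens
        }
    mat = pd.DataFrame(out).T  # markers x phenotypes
    if len(mat) > 2:
        order = leaves_list(linkage(mat.to_numpy(), method="average"))
        mat = mat.iloc[order]
    if mat.shape[1] > 2:
        order = leaves_list(linkage(mat.to_numpy().T, method="average"))
        mat = mat.iloc[:, order]
    return mat


def standardized_profiles(features: pd.DataFrame, labels: pd.Series,
                          survival: pd.Series,
                          low_n: int = 5) -> pd.DataFrame:
    """Per-phenotype, per-survival-status means of z-scored variables
    (z-scores over the plotted population).  Strata smaller than ``low_n``
    are flagged."""
    labels = pd.Series(np.asarray(labels), index=features.index)
    survival = pd.Series(np.asarray(survival, dtype=bool), index=features.index)
    z = (features - features.mean()) / features.std(ddof=0)
    rows = []
    for ph in sorted(labels.dropna().unique()):
        for status, name in ((False, "survivor"), (True, "nonsurvivor")):
            m = (labels == ph) & (survival == status)
            rec = {"phenotype": ph, "status": name, "n": int(m.sum()),
                   "low_n_flag": bool(m.sum() < low_n)}
            for v in features.columns:
                rec[v] = float(z.loc[m, v].mean()) if m.any() else np.nan
            rows.append(rec)
    return pd.DataFrame(rows)
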