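import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedsep import stats
from pedsep.stats import (TwoByTwo, adjusted_or, biomarker_log_ratios,
                          chord_links, compare_groups, mortality_curves,
                          organ_failure_curves, rate_table,
                          standardized_profiles, unadjusted_or)


# ---------------------------------------------------------------------------
# group comparisons

def _groups_frame(rng, shift=0.0, n=50):
    g = np.repeat(list("ABCD"), n)
    x = rng.normal(0, 1, 4 * n)
    x[:n] += shift
    flag = rng.random(4 * n) < 0.3
    return pd.DataFrame({"x": x, "flag": flag.astype(float)}), pd.Series(g)


def test_identical_groups_rarely_significant(rng):
    """Type-I control: four identical groups yield no significant variable
    in >= 95% of replicates."""
    hits = 0
    reps = 40
    for _ in range(reps):
        df, g = _groups_frame(rng)
        rows = compare_groups(df, g)
        hits += any(r.significant for r in rows)
    assert hits / reps <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)


def test_shifted_group_detected(rng):
    df, g = _groups_frame(rng, shift=3.0)
    rows = {r.variable: r for r in compare_groups(df, g)}
    assert rows["x"].significant
    assert rows["x"].test == "kruskal-wallis"


def test_fisher_chosen_when_expected_cell_small():
    df = pd.DataFrame({"rare": [1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]})
    g = pd.Series(["X"] * 6 + ["Y"] * 6)
    rows = compare_groups(df, g)
    assert rows[0].test == "fisher"


def test_chi_square_for_common_binary(rng):
    df = pd.DataFrame({"b": (rng.random(400) < 0.5).astype(float)})
    g = pd.Series(np.repeat(list("ABCD"), 100))
    rows = compare_groups(df, g)
    assert rows[0].test == "chi-square"


def test_constant_variable_skipped():
    df = pd.DataFrame({"c": [1.0] * 20, "x": np.arange(20.0)})
    g = pd.Series(["A"] * 10 + ["B"] * 10)
    rows = {r.variable: r for r in compare_groups(df, g)}
    assert rows["c"].test == "skipped"
    assert math.isnan(rows["c"].raw_p)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2,
                max_size=12))
def test_bh_adjustment_monotone_and_at_least_raw(raw_ps):
    from statsmodels.stats.multitest import multipletests
    _, adj, _, _ = multipletests(raw_ps, method="fdr_bh")
    order = np.argsort(raw_ps)
    assert all(adj[order[i]] <= adj[order[i + 1]] + 1e-12
               for i in range(len(raw_ps) - 1))
    # inflating every raw p never increases the number of discoveries
    inflated = np.minimum(np.array(raw_ps) * 2, 1.0)
    _, adj2, _, _ = multipletests(inflated, method="fdr_bh")
    assert (adj2 < 0.05).sum() <= (adj < 0.05).sum()


# ---------------------------------------------------------------------------
# rates and odds ratios

def test_rate_table_printed_count_arithmetic():
    t = rate_table({"total": 45, "D": 19, "A": 0}, {"total": 404, "D": 56,
                                                    "A": 136})
    t = t.set_index("group")
    assert t.loc["total", "percent"] == 11.1
    assert t.loc["D", "percent"] == 33.9
    assert t.loc["A", "percent"] == 0.0


def test_rate_table_guards():
    with pytest.raises(ZeroDivisionError):
        rate_table({"x": 1}, {"x": 0})
    with pytest.raises(ValueError, match="exceeds"):
        rate_table({"x": 5}, {"x": 4})


def test_unadjusted_or_unit_table():
    r = unadjusted_or(TwoByTwo(1, 1, 1, 1))
    assert r.odds_ratio == pytest.approx(1.0)
    assert r.ci_low <= 1.0 <= r.ci_high


def test_unadjusted_or_phenotype_d_mortality_contrast():
    # D vs rest mortality cross-product from the published counts
    r = unadjusted_or(TwoByTwo(19, 37, 26, 322))
    assert r.odds_ratio == pytest.approx(6.36, abs=0.01)
    assert r.p_value < 1e-6


def test_unadjusted_or_zero_cell_continuity_corrected():
    r = unadjusted_or(TwoByTwo(10, 0, 5, 5))
    assert r.continuity_corrected
    assert np.isfinite(r.odds_ratio) and r.odds_ratio > 1


def test_unadjusted_or_matches_saturated_logistic_mle():
    """Cross-product OR equals the exposure coefficient of a saturated 2x2
    logistic fit within 1e-6."""
    import statsmodels.api as sm
    t = TwoByTwo(19, 37, 26, 322)
    y = np.concatenate([np.ones(t.a), np.zeros(t.b), np.ones(t.c),
                        np.zeros(t.d)])
    x = np.concatenate([np.ones(t.a + t.b), np.zeros(t.c + t.d)])
    fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    assert unadjusted_or(t).odds_ratio == pytest.approx(
        math.exp(fit.params[1]), abs=1e-6)


def test_adjusted_or_consistent_with_unadjusted_under_null_covariates(rng):
    n = 4000
    exp = (rng.random(n) < 0.4).astype(float)
    cov = pd.DataFrame({"age": rng.uniform(0, 18, n)})  # independent of y
    p = 1 / (1 + np.exp(-(-2.0 + 1.0 * exp)))
    y = (rng.random(n) < p).astype(float)
    adj = adjusted_or(y, exp, cov)
    una = adjusted_or(y, exp)
    se = (math.log(adj.ci_high) - math.log(adj.odds_ratio)) / 1.96
    assert abs(math.log(adj.odds_ratio) - math.log(una.odds_ratio)) <= 3 * se
    assert adj.adjusted and adj.covariates == ["age"]


def test_adjusted_or_null_exposure_coverage(rng):
    covered = 0
    reps = 40
    for _ in range(reps):
        n = 400
        exp = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        r = adjusted_or(y, exp)
        covered += r.ci_low <= 1.0 <= r.ci_high
    assert covered / reps >= 0.85


def test_adjusted_or_separation_raises():
    y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
    x = y.copy()  # perfect separation
    with pytest.raises(stats.SeparationError):
        adjusted_or(y, x)


# ---------------------------------------------------------------------------
# curves

def _three_patient_setup():
    daily = pd.DataFrame([
        {"patient_id": "P1", "day": 1, "ofi": 2},
        {"patient_id": "P1", "day": 2, "ofi": 3},
        {"patient_id": "P2", "day": 1, "ofi": 1},
        {"patient_id": "P2", "day": 2, "ofi": 1},
        {"patient_id": "P3", "day": 1, "ofi": 0},
    ])
    patients = pd.DataFrame({
        "patient_id": ["P1", "P2", "P3"],
        "last_day": [2, 2, 1],
        "died": [True, False, False],
        "death_day": [2, 0, 0],
    })
    labels = pd.Series(["X", "X", "X"], index=["P1", "P2", "P3"])
    return daily, patients, labels


def test_ofi_curve_hand_computed_means_and_at_risk():
    daily, patients, labels = _three_patient_setup()
    c = organ_failure_curves(daily, patients, labels).set_index("day")
    assert c.loc[1, "mean_ofi"] == pytest.approx(1.0)   # (2+1+0)/3
    assert c.loc[1, "n_at_risk"] == 3
    assert c.loc[2, "mean_ofi"] == pytest.approx(2.0)   # (3+1)/2, P3 left
    assert c.loc[2, "n_at_risk"] == 2


def test_ofi_curve_no_carry_forward_after_exit():
    daily, patients, labels = _three_patient_setup()
    c = organ_failure_curves(daily, patients, labels)
    assert c["day"].max() == 2


def test_ofi_curve_constant_ofi_zero_width_ci():
    daily = pd.DataFrame([{"patient_id": p, "day": d, "ofi": 2}
                          for p in ("A1", "A2") for d in (1, 2)])
    patients = pd.DataFrame({"patient_id": ["A1", "A2"], "last_day": [2, 2]})
    labels = pd.Series(["X", "X"], index=["A1", "A2"])
    c = organ_failure_curves(daily, patients, labels)
    assert (c["mean_ofi"] == 2).all()
    assert np.allclose(c["hi"] - c["lo"], 0.0)


def test_mortality_curves_monotone_and_final_rate():
    _, patients, labels = _three_patient_setup()
    c = mortality_curves(patients, labels, n_days=5)
    vals = c["cum_mortality"].to_numpy()
    assert np.all(np.diff(vals) >= 0)
    assert vals[-1] == pytest.approx(1 / 3)
    no_deaths = patients.assign(died=False, death_day=0)
    c0 = mortality_curves(no_deaths, labels, n_days=5)
    assert (c0["cum_mortality"] == 0).all()


# ---------------------------------------------------------------------------
# figure-style summaries

def test_chord_links_absent_for_identical_groups(rng):
    n = 200
    df = pd.DataFrame({"creatinine": rng.normal(1, 0.2, n),
                       "platelets": rng.normal(200, 30, n),
                       "ofi_renal": (rng.random(n) < 0.2).astype(float)})
    labels = pd.Series(rng.choice(["A", "B"], n), index=df.index)
    links = chord_links(df, labels, categories={
        "renal": ["creatinine", "ofi_renal"], "hematologic": ["platelets"]})
    assert not links["linked"].any()


def test_chord_links_direction_rules(rng):
    n = 300
    lab = pd.Series(np.where(np.arange(n) < 100, "HI", "LO"))
    creat = rng.normal(1.0, 0.2, n)
    creat[:100] += 2.0                      # higher-is-link variable
    plate = rng.normal(200, 20, n)
    plate[:100] -= 100                      # lower-is-link variable
    df = pd.DataFrame({"creatinine": creat, "platelets": plate})
    links = chord_links(df, lab, categories={
        "renal": ["creatinine"], "hematologic": ["platelets"]})
    li = links.set_index(["phenotype", "category"])["linked"]
    assert li.loc[("HI", "renal")] and li.loc[("HI", "hematologic")]
    assert not li.loc[("LO", "renal")]


def test_biomarker_log_ratios_values_and_ordering(rng):
    n = 90
    labels = pd.Series(np.repeat(["A", "B", "C"], n // 3))
    base = rng.lognormal(3, 0.1, n)
    m1 = base.copy()
    m2 = base.copy()
    m2[labels == "B"] *= math.e            # median ratio e in group B
    df = pd.DataFrame({"m1": m1, "m2": m2, "m3": rng.lognormal(1, 0.1, n)})
    mat = biomarker_log_ratios(df, labels)
    assert mat.loc["m1"].abs().max() < 0.2          # near cohort median
    assert mat.loc["m2", "B"] > 0.5                 # elevated in B
    # ordering matches brute-force average linkage on 3 leaves
    from scipy.cluster.hierarchy import leaves_list, linkage
    raw = biomarker_log_ratios(df, labels)
    assert list(mat.index) == list(raw.index)


def test_biomarker_zero_median_skipped(rng):
    df = pd.DataFrame({"ok": rng.lognormal(0, 1, 40),
                       "zero": np.zeros(40)})
    labels = pd.Series(np.repeat(["A", "B"], 20))
    with pytest.warns(UserWarning, match="zero"):
        mat = biomarker_log_ratios(df, labels)
    assert "zero" not in mat.index


def test_standardized_profiles_zero_mean_and_shift(rng):
    n = 200
    x = rng.normal(5, 2, n)
    died = np.zeros(n, dtype=bool)
    died[:20] = True
    x[:20] += 2.0
    df = pd.DataFrame({"x": x})
    labels = pd.Series(["P"] * n)
    prof = standardized_profiles(df, labels, pd.Series(died))
    z = (df["x"] - df["x"].mean()) / df["x"].std(ddof=0)
    ns = prof[prof["status"] == "nonsurvivor"].iloc[0]
    assert ns["x"] == pytest.approx(z[died].mean())
    assert ns["x"] > 0.5
    # whole-population z mean is 0 by construction
    weighted = (prof["x"] * prof["n"]).sum() / prof["n"].sum()
    assert weighted == pytest.approx(0.0, abs=1e-9)


def test_standardized_profiles_low_n_flag(rng):
    df = pd.DataFrame({"x": rng.normal(size=50)})
    labels = pd.Series(["P"] * 50)
    survival = pd.Series([False] * 47 + [True] * 3)
    prof = standardized_profiles(df, labels, survival)
    ns = prof[prof["status"] == "nonsurvivor"].iloc[0]
    assert ns["low_n_flag"] and ns["n"] == 3
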