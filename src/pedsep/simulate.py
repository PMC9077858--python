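"""Synthetic severe-sepsis cohort generator.

Generates patient-level longitudinal records with the statistical structure
the phenotyping pipeline assumes: a four-component mixture over the 25 day-1
clustering variables (phenotype-conditional distributions calibrated to the
published cohort tables), day-1 organ-failure flags, an AR(1) within-patient
day-to-day walk, phenotype-conditional mortality and length of stay, therapy
exposures, and biomarker trajectories constructed so that each MOF rule fires
in a configured fraction of each phenotype.

Rule prevalences are enforced by *classify-then-top-up*: baseline
trajectories keep the rule-specific biomarkers (ADAMTS13, TNF response,
sFasL) in rule-safe ranges, natural positives are counted with the same
logic the rule engine applies, and additional patients are injected with
qualifying biomarker windows until the count reaches a Binomial(n, rate)
draw.  Day-1 values are never modified by injections, so the calibrated
day-1 marginals are untouched.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .config import PHENOTYPES, SimConfig
from .rules import ORGANS, ClinicalRuleSet, DEFAULT_RULES

# PRISM-window variables: the calibrated draw lives in the first-6h day-1
# record; the full-day record may deteriorate past rule thresholds.
PRISM_VARS = ("systolic_bp", "heart_rate", "gcs", "hemoglobin", "creatinine",
              "platelets")

VALUE_COLUMNS = [
    "temperature_low", "temperature_high", "heart_rate", "systolic_bp", "gcs",
    "hemoglobin", "platelets", "inr", "alc", "crp", "ferritin", "creatinine",
    "alt", "bilirubin", "pf_ratio", "urine_output", "on_vasoactive",
    "intubated", "mech_vent", "sedated", "tnf_response", "adamts13", "sfasl",
    "wbc", "resp_rate",
]

# AR-evolving continuous variables and whether they walk on a log scale.
_AR_VARS = {
    "heart_rate": False, "systolic_bp": False, "temperature_low": False,
    "temperature_high": False, "hemoglobin": False, "platelets": False,
    "gcs": False, "crp": True, "alc": True, "ferritin": True,
    "creatinine": True,
}

# Rule-safe per-phenotype biomarker baseline ranges (uniform draws).  The
# lower bounds sit strictly on the non-firing side of each rule threshold;
# injections alone cross them.
_ADAMTS13_RANGE = {"A": (80, 140), "B": (70, 130), "C": (65, 125), "D": (58, 110)}
_TNF_RANGE = {"A": (400, 1200), "B": (300, 900), "C": (260, 800), "D": (210, 600)}
_SFASL_RANGE = {"A": (20, 150), "B": (25, 160), "C": (35, 175), "D": (60, 195)}


@dataclasses.dataclass
class Cohort:
    """A simulated cohort: long patient-day table, per-patient table with
    demographics / therapies / outcomes, and the generator's truth log."""

    days: pd.DataFrame
    patients: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def series(self, patient_id) -> pd.DataFrame:
        return self.days[self.days["patient_id"] == patient_id]

    def iter_series(self) -> Iterator[tuple[object, pd.DataFrame]]:
        yield from self.days.groupby("patient_id", sort=True)

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.days.to_csv(out / "patient_days.csv", index=False)
        self.patients.to_csv(out / "patients.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        self.config.to_yaml(str(out / "sim_config.yaml"))


def _scaled_cont_params(config: SimConfig) -> dict[str, dict[str, tuple[float, float]]]:
    """Phenotype-conditional (location, scale) with mean offsets scaled by
    ``separation_scale`` around the mixture-weighted grand location."""
    s = config.separation_scale
    w = config.mixture_weights
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for name, spec in config.continuous.items():
        grand = sum(wi * spec.params[p][0] for wi, p in zip(w, PHENOTYPES))
        out[name] = {p: (grand + s * (spec.params[p][0] - grand), spec.params[p][1])
                     for p in PHENOTYPES}
    return out


def _scaled_rate(config: SimConfig, rates: dict[str, float]) -> dict[str, float]:
    s = config.separation_scale
    w = config.mixture_weights
    grand = sum(wi * rates[p] for wi, p in zip(w, PHENOTYPES))
    return {p: float(np.clip(grand + s * (rates[p] - grand), 0.0, 1.0))
            for p in PHENOTYPES}


def _sample_cont(config: SimConfig, params, name: str, phen: str,
                 rng: np.random.Generator, size: int) -> np.ndarray:
    from scipy import stats
    spec = config.continuous[name]
    mu, scale = params[name][phen]
    if spec.dist == "truncnorm":
        a, b = (spec.lo - mu) / scale, (spec.hi - mu) / scale
        x = stats.truncnorm.rvs(a, b, loc=mu, scale=scale, size=size,
                                random_state=rng)
    else:
        x = rng.lognormal(mu, scale, size=size)
        if spec.lo is not None or spec.hi is not None:
            x = np.clip(x, spec.lo, spec.hi)
    if spec.integer:
        x = np.round(x)
    return x


def _cont_cdf(config: SimConfig, params, name: str, phen: str, x: float) -> float:
    from scipy import stats
    spec = config.continuous[name]
    mu, scale = params[name][phen]
    if spec.dist == "truncnorm":
        a, b = (spec.lo - mu) / scale, (spec.hi - mu) / scale
        q = math.ceil(x) - 0.5 if spec.integer else x
        return float(stats.truncnorm.cdf(q, a, b, loc=mu, scale=scale))
    return float(stats.lognorm.cdf(x, s=scale, scale=math.exp(mu)))


def _lognorm_iqr_draw(rng, median, q1, q3, size):
    from .config import lognorm_params_from_iqr
    mu, sigma = lognorm_params_from_iqr(median, q1, q3)
    return rng.lognormal(mu, sigma, size=size)


def _binorm_cdf(a: float, b: float, rho: float) -> float:
    return float(stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([a, b]))


def _ofi_sd_under(ps: np.ndarray, rho: float) -> float:
    """SD of a sum of Bernoulli flags under a common-rho Gaussian copula."""
    z = stats.norm.ppf(ps)
    var = float(np.sum(ps * (1 - ps)))
    for i in range(len(ps)):
        for j in range(i + 1, len(ps)):
            var += 2 * (_binorm_cdf(z[i], z[j], rho) - ps[i] * ps[j])
    return math.sqrt(max(var, 0.0))


def _solve_copula_rho(ps: np.ndarray, target_sd: float) -> float:
    """Common latent correlation matching a target SD of the flag total."""
    from scipy import optimize
    if len(ps) < 2:
        return 0.0
    lo = -1.0 / (len(ps) - 1) + 1e-3
    f = lambda r: _ofi_sd_under(ps, r) - target_sd
    if f(lo) > 0 and f(0.95) > 0:
        return lo
    if f(lo) < 0 and f(0.95) < 0:
        return 0.95
    return float(optimize.brentq(f, lo, 0.95, xtol=1e-4))


def _solve_pair_rho(p1: float, p2: float, joint: float) -> float:
    """Latent correlation of one flag pair matching a target joint rate."""
    from scipy import optimize
    z1, z2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    joint = float(np.clip(joint, max(p1 + p2 - 1 + 1e-4, 1e-4),
                          min(p1, p2) - 1e-4))
    f = lambda r: _binorm_cdf(z1, z2, r) - joint
    lo, hi = -0.995, 0.995
    if f(lo) * f(hi) > 0:          # target outside the copula's reach
        return lo if abs(f(lo)) < abs(f(hi)) else hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-4))


class _Sim:
    """Working state of one cohort generation (value matrices n x n_days)."""

    def __init__(self, config: SimConfig, rng: np.random.Generator,
                 rules: ClinicalRuleSet):
        self.cfg = config
        self.rng = rng
        self.rules = rules
        self.n = config.n_patients
        self.T = config.n_days
        self.params = _scaled_cont_params(config)

    # -- helpers -----------------------------------------------------------

    def by_phen(self, sampler) -> np.ndarray:
        """Fill an (n,) array phenotype group by phenotype group."""
        out = np.empty(self.n)
        for p in PHENOTYPES:
            m = self.z == p
            if m.any():
                out[m] = sampler(p, int(m.sum()))
        return out

    def rate_arr(self, rates: dict[str, float]) -> np.ndarray:
        scaled = _scaled_rate(self.cfg, rates)
        return np.array([scaled[p] for p in self.z])

    # -- generation stages -------------------------------------------------

    def draw_patients(self):
        cfg, rng, n = self.cfg, self.rng, self.n
        idx = rng.choice(len(PHENOTYPES), size=n, p=cfg.mixture_weights)
        self.z = np.array([PHENOTYPES[i] for i in idx])
        self.day1 = {
            name: self.by_phen(lambda p, k, nm=name: _sample_cont(
                cfg, self.params, nm, p, rng, k))
            for name in cfg.continuous
        }
        lo = np.minimum(self.day1["temperature_low"], self.day1["temperature_high"])
        hi = np.maximum(self.day1["temperature_low"], self.day1["temperature_high"])
        self.day1["temperature_low"], self.day1["temperature_high"] = lo, hi
        self.binary = {name: (rng.random(n) < self.rate_arr(rates)).astype(float)
                       for name, rates in cfg.binary.items()}

    def draw_day1_flags(self):
        """Day-1 organ-failure flags at the printed prevalences, coupled
        within phenotype by a Gaussian copula.

        The common latent correlation per phenotype is solved so the SD of
        the total OFI matches its printed within-phenotype SD; the
        renal x hematologic pair can carry its own configured joint
        prevalence.  Flags are defined on the 24-h window: when a flag fires
        but the calibrated 6-h value has not crossed its threshold, the
        full-day record deteriorates past it (see ``_flag_values``), leaving
        the 6-h feature marginals untouched.
        """
        cfg, rng, n = self.cfg, self.rng, self.n
        organs = list(cfg.organ_failure_day1)
        rates = {o: _scaled_rate(cfg, cfg.organ_failure_day1[o]) for o in organs}
        coupling = cfg.organ_flag_coupling
        ofi_sd = coupling.get("ofi_sd", {})
        rh_joint_D = coupling.get("renal_hematologic_joint_D")

        flags = {o: np.zeros(n, dtype=bool) for o in organs}
        for p in PHENOTYPES:
            m = self.z == p
            if not m.any():
                continue
            ps = np.array([rates[o][p] for o in organs])
            live = ps > 0
            thr = np.full(len(organs), -np.inf)
            thr[live] = stats.norm.ppf(ps[live])
            rho = _solve_copula_rho(ps[live], float(ofi_sd[p])) \
                if p in ofi_sd else 0.0
            R = np.full((len(organs), len(organs)), rho)
            np.fill_diagonal(R, 1.0)
            if (p == "D" and rh_joint_D is not None
                    and "renal" in organs and "hematologic" in organs):
                i, j = organs.index("renal"), organs.index("hematologic")
                if 0.01 < ps[i] < 0.99 and 0.01 < ps[j] < 0.99:
                    rho_rh = _solve_pair_rho(ps[i], ps[j], float(rh_joint_D))
                    R[i, j] = R[j, i] = rho_rh
            # nudge to PSD if the targeted entry broke it
            w, U = np.linalg.eigh(R)
            if w.min() < 1e-8:
                R = (U * np.clip(w, 1e-8, None)) @ U.T
                d = np.sqrt(np.diag(R))
                R = R / np.outer(d, d)
            g = rng.multivariate_normal(np.zeros(len(organs)), R,
                                        size=int(m.sum()), method="eigh")
            # couple lab-linked flags to their defining lab's within-
            # phenotype normal score (marginals preserved): failing organs
            # concentrate in the abnormal tail of the lab
            lam = float(coupling.get("lab_coupling", 0.7))
            for organ, (var, low_abnormal) in (("renal", ("creatinine", False)),
                                               ("hematologic", ("platelets", True)),
                                               ("cns", ("gcs", True))):
                if organ not in organs or lam == 0:
                    continue
                k = organs.index(organ)
                score = self._lab_normal_score(var, p, m, low_abnormal)
                g[:, k] = -lam * score + math.sqrt(1 - lam ** 2) * g[:, k]
            hit = g < thr[None, :]
            for k, o in enumerate(organs):
                flags[o][m] = hit[:, k]
        self.flags1 = flags
        self.ofi1 = sum(v.astype(int) for v in flags.values())

    def _lab_normal_score(self, var: str, phen: str, mask: np.ndarray,
                          low_abnormal: bool) -> np.ndarray:
        """Phenotype-conditional normal score of a day-1 lab draw, oriented
        so larger = more abnormal."""
        spec = self.cfg.continuous[var]
        mu, scale = self.params[var][phen]
        x = self.day1[var][mask]
        if spec.dist == "truncnorm":
            a, b = (spec.lo - mu) / scale, (spec.hi - mu) / scale
            u = stats.truncnorm.cdf(x, a, b, loc=mu, scale=scale)
        else:
            u = stats.lognorm.cdf(x, s=scale, scale=math.exp(mu))
        u = np.clip(u, 1e-9, 1 - 1e-9)
        z = stats.norm.ppf(u)
        return -z if low_abnormal else z

    def draw_outcomes_therapies(self):
        cfg, rng, n = self.cfg, self.rng, self.n
        los_p = {p: cfg.length_of_stay[p] for p in PHENOTYPES}
        self.los = np.clip(np.round(self.by_phen(
            lambda p, k: _lognorm_iqr_draw(rng, los_p[p]["median"], los_p[p]["q1"],
                                           los_p[p]["q3"], k))), 1, self.T).astype(int)
        # therapies (methylprednisolone & IVIG jointly, others independent)
        joint = self.rate_arr(cfg.methylpred_ivig_joint)
        combo = rng.random(n) < joint
        exposures: dict[str, np.ndarray] = {}
        for name, rates in cfg.therapies.items():
            pr = self.rate_arr(rates)
            if name in ("methylprednisolone", "ivig"):
                resid = np.clip((pr - joint) / np.clip(1 - joint, 1e-9, None), 0, 1)
                exposures[name] = combo | (rng.random(n) < resid)
            else:
                exposures[name] = rng.random(n) < pr
        self.exposures = exposures

        p = self.rate_arr(cfg.mortality)
        ie = cfg.interaction_effect
        mult = ie["odds_multiplier"]
        if mult != 1.0 and ie["therapy_a"] in exposures and ie["therapy_b"] in exposures:
            hit = exposures[ie["therapy_a"]] & exposures[ie["therapy_b"]] & \
                (self.z == ie["phenotype"])
            odds = p / np.clip(1 - p, 1e-9, None) * np.where(hit, mult, 1.0)
            p = odds / (1 + odds)
        self.died = rng.random(n) < p
        raw_dd = np.clip(np.ceil(self.los * rng.uniform(0.4, 1.1, n)), 1, self.T).astype(int)
        raw_dd[self.z == "A"] = np.minimum(raw_dd[self.z == "A"], 6)
        self.death_day = np.where(self.died, raw_dd, 0)
        self.last_day = np.where(self.died, raw_dd, self.los).astype(int)

    def _flag_values(self, day_col: int, flags: dict[str, np.ndarray],
                     active: np.ndarray):
        """Overwrite day `day_col` value columns so value-derived organ flags
        equal the given flag state for active patients."""
        rng, n = self.rng, self.n
        V = self.V
        a = active
        V["on_vasoactive"][a, day_col] = flags["cardiovascular"][a].astype(float)
        mv = self.mv_state
        pulm = flags["pulmonary"]
        V["mech_vent"][a, day_col] = (pulm | mv)[a].astype(float)
        pf = np.where(pulm, rng.uniform(80, 290, n),
                      np.where(mv, rng.uniform(305, 480, n), rng.uniform(150, 480, n)))
        V["pf_ratio"][a, day_col] = pf[a]
        V["urine_output"][a, day_col] = np.where(
            flags["renal"], rng.uniform(0.10, 0.45, n), rng.uniform(0.6, 3.5, n))[a]
        V["inr"][a, day_col] = np.where(
            flags["hematologic"], rng.uniform(1.6, 2.8, n), rng.uniform(0.9, 1.45, n))[a]
        V["alt"][a, day_col] = np.where(
            flags["hepatic"], rng.uniform(120, 500, n), rng.uniform(10, 95, n))[a]
        V["bilirubin"][a, day_col] = np.where(
            flags["hepatic"], rng.uniform(1.2, 4.5, n), rng.uniform(0.10, 0.95, n))[a]
        # flag-implied continuous deterioration (day 1: the 24-h record
        # worsens past the threshold the 6-h value did not cross)
        cre = V["creatinine"][:, day_col]
        V["creatinine"][a, day_col] = np.where(
            flags["renal"], np.maximum(cre, rng.uniform(1.1, 2.6, n)), cre)[a]
        plt_ = V["platelets"][:, day_col]
        V["platelets"][a, day_col] = np.where(
            flags["hematologic"], np.minimum(plt_, rng.uniform(20, 95, n)), plt_)[a]
        g = V["gcs"][:, day_col]
        V["gcs"][a, day_col] = np.where(
            flags["cns"], np.minimum(g, rng.integers(3, 12, n).astype(float)), g)[a]
        worst_gcs = V["gcs"][:, day_col]
        if day_col == 0:
            worst_gcs = np.minimum(worst_gcs, self.true1["gcs"])
        low_gcs = worst_gcs < self.rules.gcs_low
        sed = np.where(flags["cns"], 0.0, np.where(low_gcs, 1.0,
                       (rng.random(n) < 0.4).astype(float)))
        V["sedated"][a, day_col] = sed[a]

    def build_trajectories(self):
        cfg, rng, n, T = self.cfg, self.rng, self.n, self.T
        rho = cfg.persistence
        innov = math.sqrt(max(1.0 - rho ** 2, 0.0))
        self.V = {c: np.full((n, T), np.nan) for c in VALUE_COLUMNS}
        V = self.V
        # the "true" (6-h window) day-1 PRISM values; the day-1 full-day
        # record carries a copy attenuated toward the phenotype mean
        self.true1 = {v: self.day1[v].copy() for v in PRISM_VARS}
        means = {name: np.array([self.params[name][p][0] for p in self.z])
                 for name in _AR_VARS}
        for name in _AR_VARS:
            V[name][:, 0] = self.day1[name]
        for name in ("alc", "crp", "ferritin"):
            V[name][:, 0] = self.day1[name]
        V["intubated"][:, 0] = self.binary["intubated"]
        # non-AR day-1 values
        self.mv_state = np.zeros(n, dtype=bool)
        extra_mv = {}
        for p in PHENOTYPES:
            pulm_rate = _scaled_rate(cfg, cfg.organ_failure_day1["pulmonary"])[p]
            tgt = _scaled_rate(cfg, cfg.mech_vent)[p]
            extra_mv[p] = float(np.clip((tgt - pulm_rate) / max(1 - pulm_rate, 1e-9), 0, 1))
        self.mv_state = (self.binary["intubated"] > 0) | \
            (rng.random(n) < np.array([extra_mv[p] for p in self.z]))
        all_active = np.ones(n, dtype=bool)
        self._flag_values(0, self.flags1, all_active)
        self._draw_daily_misc(0, all_active)

        # AR walk with flag persistence; no new organ failures arise here
        state = {name: (np.log(self.day1[name]) if _AR_VARS[name]
                        else self.day1[name].copy()) for name in _AR_VARS}
        flags = {o: self.flags1[o].copy() for o in ORGANS}
        self.flag_mat = {o: np.zeros((n, T), dtype=bool) for o in ORGANS}
        for o in ORGANS:
            self.flag_mat[o][:, 0] = flags[o]
        for t in range(1, int(self.last_day.max())):
            active = self.last_day > t
            if not active.any():
                break
            for name in _AR_VARS:
                spec = cfg.continuous[name]
                mu = means[name]
                sd = np.array([self.params[name][p][1] for p in self.z])
                state[name] = mu + rho * (state[name] - mu) + \
                    innov * sd * rng.standard_normal(n)
                x = np.exp(state[name]) if _AR_VARS[name] else state[name]
                if spec.lo is not None:
                    x = np.clip(x, spec.lo, spec.hi)
                V[name][active, t] = np.round(x[active]) if spec.integer else x[active]
            tl = np.minimum(V["temperature_low"][:, t], V["temperature_high"][:, t])
            th = np.maximum(V["temperature_low"][:, t], V["temperature_high"][:, t])
            V["temperature_low"][active, t] = tl[active]
            V["temperature_high"][active, t] = th[active]
            for o in ORGANS:
                flags[o] = flags[o] & (rng.random(n) < 0.75)
                self.flag_mat[o][active, t] = flags[o][active]
            self.mv_state = self.mv_state & (rng.random(n) < 0.85)
            V["intubated"][active, t] = ((V["intubated"][:, t - 1] > 0)
                                         & (rng.random(n) < 0.85))[active].astype(float)
            self._flag_values(t, flags, active)
            self._draw_daily_misc(t, active)

    def _draw_daily_misc(self, t: int, active: np.ndarray):
        rng, n = self.rng, self.n
        V = self.V
        lo = np.array([_ADAMTS13_RANGE[p][0] for p in self.z], dtype=float)
        hi = np.array([_ADAMTS13_RANGE[p][1] for p in self.z], dtype=float)
        V["adamts13"][active, t] = rng.uniform(lo, hi)[active]
        lo = np.array([_TNF_RANGE[p][0] for p in self.z], dtype=float)
        hi = np.array([_TNF_RANGE[p][1] for p in self.z], dtype=float)
        V["tnf_response"][active, t] = rng.uniform(lo, hi)[active]
        lo = np.array([_SFASL_RANGE[p][0] for p in self.z], dtype=float)
        hi = np.array([_SFASL_RANGE[p][1] for p in self.z], dtype=float)
        V["sfasl"][active, t] = rng.uniform(lo, hi)[active]
        V["wbc"][active, t] = rng.lognormal(math.log(13.0), 0.5, n)[active]
        band_hi = np.select(
            [self.day1["age"] < 1, self.day1["age"] < 6, self.day1["age"] < 13],
            [34.0, 22.0, 18.0], default=14.0)
        V["resp_rate"][active, t] = (band_hi * rng.uniform(0.8, 1.8, n))[active]

    # -- rule-prevalence enforcement ----------------------------------------

    def _check_mat(self, name: str) -> np.ndarray:
        """Day-level most-abnormal matrix: the day-1 column combines the 6-h
        record and the full-day record, taking the more abnormal of the two."""
        M = self.V[name].copy()
        if name in PRISM_VARS:
            worse = np.minimum if name in ("platelets", "gcs", "systolic_bp",
                                           "hemoglobin") else np.maximum
            M[:, 0] = worse(M[:, 0], self.true1[name])
        return M

    def _active_mask(self) -> np.ndarray:
        days = np.arange(1, self.T + 1)[None, :]
        return days <= self.last_day[:, None]

    def _natural_mas(self) -> np.ndarray:
        r = self.rules
        act = self._active_mask()
        hit = (self._check_mat("ferritin") > r.ferritin_mas) & \
              (self._check_mat("platelets") < r.platelet_low) & \
              (self.V["inr"] > r.inr_high) & \
              (self.V["alt"] > r.alt_high) & \
              (self.V["bilirubin"] > r.bilirubin_high) & act
        return hit.any(axis=1)

    def _extend_stay(self, i: int, day: int):
        if self.last_day[i] < day:
            self.last_day[i] = day
            if self.died[i]:
                self.death_day[i] = day
            else:
                self.los[i] = day
            # fill the newly active days from the last observed day
            act = self._active_mask()[i]
            for c in VALUE_COLUMNS:
                col = self.V[c][i]
                last_obs = np.where(~np.isnan(col))[0]
                if len(last_obs):
                    fill = col[last_obs[-1]]
                    need = act & np.isnan(col)
                    col[need] = fill

    def _pick(self, candidates: np.ndarray, score: np.ndarray, k: int) -> np.ndarray:
        """k candidate indices, best score first, random within ties."""
        idx = np.where(candidates)[0]
        if len(idx) == 0 or k <= 0:
            return np.array([], dtype=int)
        jitter = self.rng.random(len(idx))
        order = np.lexsort((jitter, -score[idx]))
        return idx[order][:k]

    def _target(self, label: str) -> np.ndarray:
        rates = _scaled_rate(self.cfg, self.cfg.mof_rates[label])
        tgt = np.zeros(self.n, dtype=bool)
        for p in PHENOTYPES:
            m = self.z == p
            tgt[m] = self.rng.random(int(m.sum())) < rates[p]
        return tgt

    def inject_mof(self):
        rng, n, r = self.rng, self.n, self.rules
        V = self.V
        self.injected = {}

        # TAMOF: one day with ADAMTS13 < 57, platelets < 100, oliguria, creat > 1
        want = self._target("tamof")
        score = self.flags1["renal"].astype(float) * 2 + \
            self.flags1["hematologic"].astype(float) + (self.last_day >= 3)
        chosen = self._pick(want, score, int(want.sum()))
        for i in chosen:
            d = int(min(max(self.last_day[i], 2), 3))
            self._extend_stay(i, d)
            c = d - 1
            V["adamts13"][i, c] = rng.uniform(15, 50)
            V["platelets"][i, c] = min(V["platelets"][i, c], rng.uniform(25, 95))
            V["creatinine"][i, c] = max(V["creatinine"][i, c], rng.uniform(1.2, 2.8))
            V["urine_output"][i, c] = rng.uniform(0.10, 0.40)
        self.injected["tamof"] = set(chosen.tolist())

        # SMOF: hypoxemic sFasL day followed >= 7 days later by liver failure
        want = self._target("smof")
        score = self.flags1["hepatic"].astype(float) + \
            self.flags1["pulmonary"].astype(float) + (self.last_day >= 9) * 2
        chosen = self._pick(want, score, int(want.sum()))
        for i in chosen:
            d1, d2 = 2, 2 + r.smof_lag
            self._extend_stay(i, d2)
            V["sfasl"][i, d1 - 1] = rng.uniform(220, 600)
            V["pf_ratio"][i, d1 - 1] = rng.uniform(80, 290)
            V["mech_vent"][i, d1 - 1] = 1.0
            V["alt"][i, d2 - 1] = rng.uniform(120, 500)
            V["bilirubin"][i, d2 - 1] = rng.uniform(1.2, 4.5)
        self.injected["smof"] = set(chosen.tolist())

        # IPMOF: TNF response < 200 beyond day 3 with >= 2 organ failures
        want = self._target("ipmof")
        score = (self.ofi1 >= 2).astype(float) + (self.last_day >= 4)
        chosen = self._pick(want, score, int(want.sum()))
        for i in chosen:
            d = 4
            self._extend_stay(i, d)
            c = d - 1
            V["tnf_response"][i, c] = rng.uniform(30, 180)
            # guarantee two same-day organ failures
            n_of = self._day_ofi_row(i, c)
            if n_of < r.min_of_for_mof:
                V["on_vasoactive"][i, c] = 1.0
            if self._day_ofi_row(i, c) < r.min_of_for_mof:
                V["mech_vent"][i, c] = 1.0
                V["pf_ratio"][i, c] = rng.uniform(80, 290)
        self.injected["ipmof"] = set(chosen.tolist())

        # MAS: one day with ferritin > 500 plus the DIC-liver tetrad.
        # Natural positives (day-1 co-occurrence) count toward the target;
        # the top-up is per phenotype so rates stay calibrated.
        natural = self._natural_mas()
        want = self._target("mas")
        score = self.flags1["hematologic"].astype(float) + \
            self.flags1["hepatic"].astype(float) + (self.last_day >= 3)
        chosen_all = []
        for p in PHENOTYPES:
            m = self.z == p
            need = max(0, int((want & m).sum()) - int((natural & m).sum()))
            chosen_all.extend(self._pick(~natural & m, score, need))
        chosen = np.array(chosen_all, dtype=int)
        for i in chosen:
            d = int(min(max(self.last_day[i], 2), 3))
            self._extend_stay(i, d)
            c = d - 1
            V["ferritin"][i, c] = max(V["ferritin"][i, c], rng.uniform(600, 3000))
            V["platelets"][i, c] = min(V["platelets"][i, c], rng.uniform(20, 95))
            V["inr"][i, c] = max(V["inr"][i, c], rng.uniform(1.6, 2.6))
            V["alt"][i, c] = rng.uniform(120, 500)
            V["bilirubin"][i, c] = rng.uniform(1.2, 4.5)
        self.injected["mas"] = set(chosen.tolist()) | set(np.where(natural)[0].tolist())

        # NPMOF: a new organ failure after day 1 (top-up over what the other
        # injections already produced)
        G = self.value_flags()
        natural = self._npmof_from(G)
        want = self._target("npmof")
        injectable = np.array([
            any(not G[o][i, 0] for o in ("cardiovascular", "renal", "hepatic"))
            for i in range(n)])
        candidates = ~natural & (self.last_day >= 2) & injectable
        score = np.zeros(n)
        chosen_all = []
        for p in PHENOTYPES:
            m = self.z == p
            need = max(0, int((want & m).sum()) - int((natural & m).sum()))
            chosen_all.extend(self._pick(candidates & m, score, need))
        for i in chosen_all:
            d = int(min(3, self.last_day[i]))
            c = d - 1
            organ = next(o for o in ("cardiovascular", "renal", "hepatic")
                         if not G[o][i, 0])
            if organ == "cardiovascular":
                V["on_vasoactive"][i, c] = 1.0
            elif organ == "renal":
                V["creatinine"][i, c] = max(V["creatinine"][i, c], rng.uniform(1.2, 2.6))
                V["urine_output"][i, c] = rng.uniform(0.10, 0.40)
            else:
                V["alt"][i, c] = rng.uniform(120, 500)
                V["bilirubin"][i, c] = rng.uniform(1.2, 4.5)

    def _day_ofi_row(self, i: int, c: int) -> int:
        r = self.rules
        V = self.V
        gcs = min(self.true1["gcs"][i], V["gcs"][i, c]) if c == 0 else V["gcs"][i, c]
        plt_ = min(self.true1["platelets"][i], V["platelets"][i, c]) \
            if c == 0 else V["platelets"][i, c]
        cre = max(self.true1["creatinine"][i], V["creatinine"][i, c]) \
            if c == 0 else V["creatinine"][i, c]
        return int(
            (V["on_vasoactive"][i, c] > 0)
            + ((V["mech_vent"][i, c] > 0) and V["pf_ratio"][i, c] < r.pf_low)
            + (V["bilirubin"][i, c] > r.bilirubin_high and V["alt"][i, c] > r.alt_high)
            + (cre > r.creatinine_high and V["urine_output"][i, c] < r.oliguria)
            + (plt_ < r.platelet_low and V["inr"][i, c] > r.inr_high)
            + (gcs < r.gcs_low and not V["sedated"][i, c] > 0))

    def value_flags(self) -> dict[str, np.ndarray]:
        """Per-(patient, day) organ-failure flags derived from the values."""
        r = self.rules
        V = self.V
        act = self._active_mask()
        return {
            "cardiovascular": (V["on_vasoactive"] > 0) & act,
            "pulmonary": (V["mech_vent"] > 0) & (V["pf_ratio"] < r.pf_low) & act,
            "hepatic": (V["bilirubin"] > r.bilirubin_high) & (V["alt"] > r.alt_high) & act,
            "renal": (self._check_mat("creatinine") > r.creatinine_high)
                     & (V["urine_output"] < r.oliguria) & act,
            "hematologic": (self._check_mat("platelets") < r.platelet_low)
                           & (V["inr"] > r.inr_high) & act,
            "cns": (self._check_mat("gcs") < r.gcs_low) & ~(V["sedated"] > 0) & act,
        }

    def _npmof_from(self, G: dict[str, np.ndarray]) -> np.ndarray:
        out = np.zeros(self.n, dtype=bool)
        for o in ORGANS:
            out |= (G[o][:, 1:] & ~G[o][:, [0]]).any(axis=1)
        return out

    def final_truth(self) -> pd.DataFrame:
        """Vectorized rule classification of the finished value matrices."""
        r = self.rules
        V = self.V
        act = self._active_mask()
        G = self.value_flags()
        ofi = sum(g.astype(int) for g in G.values())
        mas = self._natural_mas()
        tamof = ((V["adamts13"] < r.adamts13_low)
                 & (self._check_mat("platelets") < r.platelet_low)
                 & (V["urine_output"] < r.oliguria)
                 & (self._check_mat("creatinine") > r.creatinine_high) & act).any(axis=1)
        days = np.arange(1, self.T + 1)[None, :]
        ipmof = ((days > r.tnf_day) & (V["tnf_response"] < r.tnf_low)
                 & (ofi >= r.min_of_for_mof) & act).any(axis=1)
        trigger = (V["sfasl"] > r.sfasl_high) & (V["pf_ratio"] < r.pf_low) \
            & (V["mech_vent"] > 0) & act
        liver = (V["alt"] > r.alt_high) & (V["bilirubin"] > r.bilirubin_high) & act
        tmin = np.where(trigger.any(axis=1),
                        np.argmax(trigger, axis=1) + 1, 10 ** 6)
        lmax = np.where(liver.any(axis=1),
                        self.T - np.argmax(liver[:, ::-1], axis=1), -1)
        smof = lmax >= tmin + r.smof_lag
        npmof = self._npmof_from(G)
        return pd.DataFrame({
            "patient_id": self.patient_ids,
            "latent_phenotype": self.z,
            "mas": mas, "tamof": tamof, "ipmof": ipmof, "smof": smof,
            "npmof": npmof, "max_ofi": ofi.max(axis=1),
        })

    # -- assembly ------------------------------------------------------------

    def assemble(self) -> Cohort:
        n = self.n
        self.patient_ids = np.array([f"P{i + 1:04d}" for i in range(n)])
        frames = []
        # day-1 first-6h record: PRISM extremes (+ sedation state)
        six = pd.DataFrame({c: np.nan for c in VALUE_COLUMNS}, index=range(n))
        for v in PRISM_VARS:
            six[v] = self.true1[v]
        six["intubated"] = self.binary["intubated"]
        six["sedated"] = self.V["sedated"][:, 0]
        six.insert(0, "patient_id", self.patient_ids)
        six.insert(1, "day", 1)
        six.insert(2, "first_6h", True)
        frames.append(six)
        act = self._active_mask()
        for t in range(self.T):
            alive = act[:, t]
            if not alive.any():
                break
            df = pd.DataFrame({c: self.V[c][alive, t] for c in VALUE_COLUMNS})
            df.insert(0, "patient_id", self.patient_ids[alive])
            df.insert(1, "day", t + 1)
            df.insert(2, "first_6h", False)
            frames.append(df)
        days = pd.concat(frames, ignore_index=True)
        days = days.sort_values(["patient_id", "day", "first_6h"],
                                ascending=[True, True, False], ignore_index=True)

        mv_any = days.groupby("patient_id")["mech_vent"].max().reindex(self.patient_ids)
        patients = pd.DataFrame({
            "patient_id": self.patient_ids,
            "age": self.day1["age"],
            "male": self.binary["male"],
            "hispanic": self.binary["hispanic"],
            "prev_healthy": self.binary["prev_healthy"],
            "post_op": self.binary["post_op"],
            "prism": np.clip(np.round(5 + 3.2 * self.ofi1
                                      + self.rng.normal(0, 4, n)), 0, 60),
            "died": self.died,
            "death_day": self.death_day,
            "discharge_day": np.where(self.died, 0, self.los),
            "last_day": self.last_day,
            "mech_vent": mv_any.to_numpy().astype(bool),
        })
        for name, arr in self.exposures.items():
            patients[name] = arr
        truth = self.final_truth()
        return Cohort(days=days, patients=patients, truth=truth, config=self.cfg)


def generate_cohort(config: SimConfig,
                    rules: ClinicalRuleSet = DEFAULT_RULES) -> Cohort:
    """Generate a cohort under the given configuration (deterministic in
    ``config.seed``)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    sim = _Sim(config, rng, rules)
    sim.draw_patients()
    sim.draw_day1_flags()
    sim.draw_outcomes_therapies()
    sim.build_trajectories()
    sim.inject_mof()
    return sim.assemble()


def inject_missingness(cohort: Cohort, rates: dict[str, float] | None = None,
                       seed: int | None = None) -> Cohort:
    """Mask values missing-completely-at-random at the patient x variable
    level (a masked lab is absent on every day, as when it was never sent).

    The returned cohort is a copy; the input cohort serves as the truth log.
    """
    cfg = cohort.config
    if rates is None:
        rates = cfg.missingness
    for var, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {var} outside [0, 1]: {rate}")
    rng = np.random.default_rng(np.random.SeedSequence(
        [seed if seed is not None else cfg.seed, 909]))
    days = cohort.days.copy()
    pids = cohort.patients["patient_id"].to_numpy()
    mask_records = {}
    for var, rate in rates.items():
        if var not in days.columns or rate == 0:
            continue
        masked = pids[rng.random(len(pids)) < rate]
        days.loc[days["patient_id"].isin(masked), var] = np.nan
        mask_records[var] = set(masked.tolist())
    out = Cohort(days=days, patients=cohort.patients.copy(),
                 truth=cohort.truth.copy(), config=cfg)
    out.missing_mask = mask_records
    return out


def make_candidate_table(cohort: Cohort, config: SimConfig | None = None,
                         rules: ClinicalRuleSet = DEFAULT_RULES,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The 52-column candidate feature table plus per-column violation flags.

    The first 25 columns are the day-1 clustering features; the remainder are
    designed screening failures: columns with excess missingness and
    near-duplicate columns highly correlated with a retained variable.
    """
    from .screening import build_feature_table, default_schema
    cfg = config or cohort.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 717]))
    schema = default_schema()
    table = build_feature_table(cohort, schema=schema, rules=rules)
    n = len(table)
    flags = [{"column": c, "violating": False, "reason": "none"}
             for c in table.columns]

    extras = cfg.candidate_extras or {}
    hm = extras.get("high_missingness", {})
    for name in hm.get("names", []):
        vals = rng.lognormal(1.0, 0.8, n)
        vals[rng.random(n) < float(hm.get("rate", 0.45))] = np.nan
        table[name] = vals
        flags.append({"column": name, "violating": True, "reason": "missingness"})
    hc = extras.get("high_correlation", {})
    noise_sd = float(hc.get("noise_sd", 0.05))
    extra_miss = float(hc.get("missingness", 0.08))
    for partner in hc.get("partners", []):
        base = table[partner].to_numpy(dtype=float)
        # rank-preserving jitter so the pair correlation stays decisively
        # above the screen: multiplicative on ratio-scaled (skewed) columns,
        # additive in SD units on interval-scaled ones
        q1, q3 = np.nanpercentile(base, [25, 75])
        if np.nanmin(base) > 0 and q1 > 0 and q3 / q1 > 3:
            vals = base * np.exp(rng.normal(0, noise_sd, n))
        else:
            sd = np.nanstd(base)
            vals = base + rng.normal(0, max(noise_sd * sd, 1e-9), n)
        vals[rng.random(n) < extra_miss] = np.nan
        name = f"{partner}_repeat"
        table[name] = vals
        flags.append({"column": name, "violating": True, "reason": "correlation"})
    return table, pd.DataFrame(flags)
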