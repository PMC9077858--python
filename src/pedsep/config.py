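"""Configuration objects for the simulation and pipeline.

``SimConfig`` wraps the YAML calibration file that defines the synthetic
cohort: a four-component mixture over the 25 day-1 clustering variables,
organ-failure flag prevalences, outcome and therapy rates, missingness and
the candidate-table layout.  Distribution parameters are resolved once at
load time (log-normal location/scale from median/IQR or mean/SD moment
matching; truncated-normal location solved so the truncated mean hits the
printed mean).
"""

from __future__ import annotations

import copy
import dataclasses
import math
from importlib import resources
from typing import Any

import numpy as np
import yaml
from scipy import optimize, stats

PHENOTYPES = ("A", "B", "C", "D")

#: z-score of the 75th percentile, used to solve log-normal scale from an IQR.
_Z75 = stats.norm.ppf(0.75)


class ConfigError(ValueError):
    """A configuration value is invalid; the message names the field."""


def _load_packaged_yaml(name: str) -> dict:
    with resources.files("pedsep.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def lognorm_params_from_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and quartiles."""
    if not (0 < q1 < median < q3):
        raise ConfigError(f"invalid median/IQR triple ({median}, {q1}, {q3})")
    return math.log(median), math.log(q3 / q1) / (2 * _Z75)


def lognorm_params_from_meansd(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ConfigError(f"log-normal mean/sd must be positive ({mean}, {sd})")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def solve_truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location mu such that a normal(mu, sd) truncated to [lo, hi] has the
    target mean.  Monotone in mu, solved by bracketing."""

    def trunc_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))

    lo_b, hi_b = target_mean - 8 * sd, target_mean + 8 * sd
    return float(optimize.brentq(lambda m: trunc_mean(m) - target_mean, lo_b, hi_b))


@dataclasses.dataclass
class ContinuousSpec:
    """Resolved sampling parameters for one continuous variable."""

    name: str
    dist: str                       # truncnorm | lognorm_iqr | lognorm_meansd
    lo: float | None
    hi: float | None
    integer: bool
    # per-phenotype resolved params: truncnorm -> (mu, sd); lognorm -> (mu, sigma)
    params: dict[str, tuple[float, float]]
    target_mean: dict[str, float]   # printed mean (truncnorm) or implied mean

    def sample(self, phen: str, rng: np.random.Generator, size: int) -> np.ndarray:
        mu, scale = self.params[phen]
        if self.dist == "truncnorm":
            a, b = (self.lo - mu) / scale, (self.hi - mu) / scale
            x = stats.truncnorm.rvs(a, b, loc=mu, scale=scale, size=size,
                                    random_state=rng)
        else:
            x = rng.lognormal(mu, scale, size=size)
            if self.lo is not None or self.hi is not None:
                x = np.clip(x, self.lo, self.hi)
        if self.integer:
            x = np.round(x)
        return x

    def cdf(self, phen: str, x: float) -> float:
        """P(value < x) under the phenotype-conditional distribution."""
        mu, scale = self.params[phen]
        if self.dist == "truncnorm":
            a, b = (self.lo - mu) / scale, (self.hi - mu) / scale
            # integer-rounded variables: round(v) < x  <=>  v < ceil(x) - 0.5
            q = math.ceil(x) - 0.5 if self.integer else x
            return float(stats.truncnorm.cdf(q, a, b, loc=mu, scale=scale))
        return float(stats.lognorm.cdf(x, s=scale, scale=math.exp(mu)))


def _check_prob(value: float, field: str) -> float:
    if not (isinstance(value, (int, float)) and 0.0 <= value <= 1.0):
        raise ConfigError(f"{field} must be a probability in [0, 1], got {value!r}")
    return float(value)


def _check_rates(d: dict, field: str) -> dict[str, float]:
    out = {}
    for p in PHENOTYPES:
        if p not in d:
            raise ConfigError(f"{field} missing phenotype {p}")
        out[p] = _check_prob(d[p], f"{field}[{p}]")
    return out


class SimConfig:
    """Validated synthetic-cohort configuration.

    Construct with :meth:`default`, :meth:`from_yaml` or from a raw dict.
    The raw dict round-trips losslessly to YAML via :meth:`to_yaml`.
    """

    def __init__(self, raw: dict[str, Any]):
        self.raw = copy.deepcopy(raw)
        r = self.raw
        self.n_patients = int(r.get("n_patients", 404))
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        self.n_days = int(r.get("n_days", 28))
        if self.n_days < 1:
            raise ConfigError(f"n_days must be >= 1, got {self.n_days}")
        self.seed = int(r.get("seed", 0))

        w = r.get("mixture_weights")
        if w is None or set(w) != set(PHENOTYPES):
            raise ConfigError("mixture_weights must give a weight for each of A-D")
        weights = np.array([float(w[p]) for p in PHENOTYPES])
        if (weights < 0).any():
            raise ConfigError("mixture_weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-6:
            raise ConfigError(f"mixture_weights must sum to 1, got {weights.sum():.6f}")
        self.mixture_weights = weights / weights.sum()

        self.separation_scale = float(r.get("separation_scale", 1.0))
        if self.separation_scale < 0:
            raise ConfigError("separation_scale must be >= 0")
        self.persistence = float(r.get("persistence", 0.7))
        if not 0.0 <= self.persistence < 1.0:
            raise ConfigError("persistence must be in [0, 1)")

        self.continuous = {
            name: self._resolve_continuous(name, spec)
            for name, spec in r.get("continuous", {}).items()
        }
        self.binary = {
            name: _check_rates(d, f"binary[{name}]")
            for name, d in r.get("binary", {}).items()
        }
        self.organ_failure_day1 = {
            organ: _check_rates(d, f"organ_failure_day1[{organ}]")
            for organ, d in r.get("organ_failure_day1", {}).items()
        }
        self.organ_flag_coupling = r.get("organ_flag_coupling", {}) or {}
        self.mech_vent = _check_rates(r.get("mech_vent", {}), "mech_vent")
        out = r.get("outcomes", {})
        self.mortality = _check_rates(out.get("mortality", {}), "outcomes.mortality")
        self.mof_rates = {
            k: _check_rates(d, f"outcomes.mof[{k}]")
            for k, d in out.get("mof", {}).items()
        }
        self.length_of_stay = r.get("length_of_stay", {})
        self.therapies = {
            name: _check_rates(d, f"therapies[{name}]")
            for name, d in r.get("therapies", {}).items()
        }
        self.methylpred_ivig_joint = _check_rates(
            r.get("methylpred_ivig_joint", {p: 0.0 for p in PHENOTYPES}),
            "methylpred_ivig_joint")
        ie = r.get("interaction_effect", {}) or {}
        self.interaction_effect = {
            "therapy_a": ie.get("therapy_a"),
            "therapy_b": ie.get("therapy_b"),
            "phenotype": ie.get("phenotype"),
            "odds_multiplier": float(ie.get("odds_multiplier", 1.0)),
        }
        if self.interaction_effect["odds_multiplier"] <= 0:
            raise ConfigError("interaction_effect.odds_multiplier must be > 0")
        self.missingness = {
            k: _check_prob(v, f"missingness[{k}]")
            for k, v in (r.get("missingness", {}) or {}).items()
        }
        self.candidate_extras = r.get("candidate_extras", {})

    # -- resolution helpers -------------------------------------------------

    def _resolve_continuous(self, name: str, spec: dict) -> ContinuousSpec:
        dist = spec.get("dist")
        lo, hi = spec.get("lo"), spec.get("hi")
        params: dict[str, tuple[float, float]] = {}
        target_mean: dict[str, float] = {}
        for p in PHENOTYPES:
            if p not in spec:
                raise ConfigError(f"continuous[{name}] missing phenotype {p}")
            d = spec[p]
            if dist == "truncnorm":
                mean, sd = float(d["mean"]), float(d["sd"])
                if sd <= 0:
                    raise ConfigError(f"continuous[{name}][{p}].sd must be > 0")
                mu = solve_truncnorm_loc(mean, sd, lo, hi)
                params[p] = (mu, sd)
                target_mean[p] = mean
            elif dist == "lognorm_iqr":
                mu, sigma = lognorm_params_from_iqr(
                    float(d["median"]), float(d["q1"]), float(d["q3"]))
                params[p] = (mu, sigma)
                target_mean[p] = math.exp(mu + sigma ** 2 / 2)
            elif dist == "lognorm_meansd":
                mu, sigma = lognorm_params_from_meansd(float(d["mean"]), float(d["sd"]))
                params[p] = (mu, sigma)
                target_mean[p] = float(d["mean"])
            else:
                raise ConfigError(f"continuous[{name}].dist unknown: {dist!r}")
        return ContinuousSpec(name, dist, lo, hi, bool(spec.get("integer", False)),
                              params, target_mean)

    # -- constructors / serialization --------------------------------------

    @classmethod
    def default(cls, **overrides: Any) -> "SimConfig":
        """The shipped default calibration, with optional top-level overrides."""
        raw = _load_packaged_yaml("cohort_defaults.yaml")
        raw.update(overrides)
        return cls(raw)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=False)

    def replace(self, **overrides: Any) -> "SimConfig":
        raw = copy.deepcopy(self.raw)
        raw.update(overrides)
        return SimConfig(raw)

    @property
    def therapy_names(self) -> list[str]:
        return ["mech_vent"] + list(self.therapies)


def load_sirs_bands(path: str | None = None) -> list[dict]:
    """The age-banded SIRS reference table (shipped default or user file)."""
    if path is None:
        raw = _load_packaged_yaml("sirs_age_bands.yaml")
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return raw["bands"]


def load_phenotype_risk() -> dict:
    """Published per-phenotype outcome counts for risk annotation."""
    return _load_packaged_yaml("phenotype_risk.yaml")
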