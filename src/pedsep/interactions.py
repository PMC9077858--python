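"""Heterogeneous treatment-interaction screening.

Therapies univariably associated with survival (overall or within any
phenotype, p < 0.05) enter an elastic-net logistic model of mortality whose
design holds every therapy main effect plus all pairwise products (14
therapies -> 105 terms).  Exponentiated coefficients populate a symmetric
heatmap grid (diagonal = single therapies, off-diagonal = combinations);
the penalized fit yields no confidence intervals by construction, so cells
with odds ratio < 0.1 are re-examined with covariate-adjusted
maximum-likelihood logistic regression of the product term.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .stats import ORResult, SeparationError, _fit_logit


@dataclasses.dataclass
class PenalizedFitSpec:
    """Elastic-net hyperparameters (the published analysis names the method
    but no settings; these are exposed defaults)."""

    alpha: float = 0.5          # l1 ratio
    n_lambda: int = 10
    folds: int = 10
    seed: int = 0
    max_iter: int = 5000
    fixed_C: float | None = None   # bypass CV at a fixed penalty strength

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha (l1 ratio) must be in (0, 1]")
        if self.folds < 3:
            raise ValueError("need at least 3 cross-validation folds")


@dataclasses.dataclass
class InteractionGrid:
    therapies: list[str]
    grid: pd.DataFrame        # odds ratios, therapy x therapy, NaN = blank
    cell_n: pd.DataFrame      # patients exposed to the (pair of) therapies
    blank: pd.DataFrame       # True where no patient carries the combination

    def cells(self) -> pd.DataFrame:
        """Long form: therapy_i, therapy_j (i <= j), OR, n, blank flag."""
        rows = []
        for i, ti in enumerate(self.therapies):
            for j, tj in enumerate(self.therapies):
                if j < i:
                    continue
                rows.append({"therapy_i": ti, "therapy_j": tj,
                             "odds_ratio": self.grid.loc[ti, tj],
                             "n": int(self.cell_n.loc[ti, tj]),
                             "blank": bool(self.blank.loc[ti, tj])})
        return pd.DataFrame(rows)


def select_therapies(exposures: pd.DataFrame, outcome: pd.Series,
                     labels: pd.Series | None = None,
                     alpha: float = 0.05) -> list[str]:
    """Therapies univariably associated with survival at p < alpha overall
    or within any phenotype stratum (chi-square, Fisher's exact when an
    expected cell < 5).  Zero-exposure therapies are excluded."""
    y = pd.Series(np.asarray(outcome, dtype=int), index=exposures.index)
    strata: list[pd.Series] = [pd.Series(True, index=exposures.index)]
    if labels is not None:
        lab = pd.Series(np.asarray(labels), index=exposures.index)
        strata += [lab == ph for ph in sorted(lab.dropna().unique())]
    selected = []
    for t in exposures.columns:
        x = exposures[t].astype(int)
        if x.sum() == 0:
            continue
        for mask in strata:
            xs, ys = x[mask], y[mask]
            if xs.nunique() < 2 or ys.nunique() < 2:
                continue
            tab = pd.crosstab(xs, ys)
            if tab.shape != (2, 2):
                continue
            _, _, _, expected = sps.chi2_contingency(tab)
            if (expected < 5).any():
                _, p = sps.fisher_exact(tab.to_numpy())
            else:
                _, p, _, _ = sps.chi2_contingency(tab)
            if p < alpha:
                selected.append(t)
                break
    return selected


def build_design(exposures: pd.DataFrame,
                 therapies: list[str] | None = None) -> pd.DataFrame:
    """Main-effect columns plus all pairwise products, T + C(T, 2) columns.

    Therapies are ordered alphabetically; product columns are named
    ``a*b`` with a < b, so the layout is deterministic.
    """
    therapies = sorted(therapies if therapies is not None
                       else list(exposures.columns))
    if not therapies:
        raise ValueError("need at least one therapy")
    X = pd.DataFrame(index=exposures.index)
    for t in therapies:
        X[t] = exposures[t].astype(float)
    for a, b in itertools.combinations(therapies, 2):
        X[f"{a}*{b}"] = X[a] * X[b]
    return X


def elastic_net_grid(design: pd.DataFrame, outcome: pd.Series,
                     spec: PenalizedFitSpec | None = None,
                     min_deaths: int = 5,
                     stratum: str = "") -> InteractionGrid:
    """Penalized logistic mortality model over the interaction design.

    Cell (i, i) holds exp(beta) of therapy i; cell (i, j) the combination
    term.  Combinations no patient received are blank.  Strata with fewer
    than ``min_deaths`` deaths are refused (mirroring the exclusion of the
    lowest-mortality phenotype from the published analysis).
    """
    spec = spec or PenalizedFitSpec()
    y = np.asarray(outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    if y.sum() < min_deaths:
        raise ValueError(
            f"stratum {stratum or '(all)'} not analyzed: only {int(y.sum())} "
            f"deaths (< {min_deaths}), too few for a mortality model")
    therapies = sorted({c.split("*")[0] for c in design.columns}
                       | {c.split("*")[-1] for c in design.columns})
    if spec.fixed_C is not None:
        from sklearn.linear_model import LogisticRegression
        model = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=spec.alpha,
            C=spec.fixed_C, max_iter=spec.max_iter)
    else:
        cv = StratifiedKFold(n_splits=spec.folds, shuffle=True,
                             random_state=spec.seed)
        model = LogisticRegressionCV(
            penalty="elasticnet", solver="saga", l1_ratios=[spec.alpha],
            Cs=spec.n_lambda, cv=cv, scoring="neg_log_loss",
            max_iter=spec.max_iter, random_state=spec.seed)
    model.fit(design.to_numpy(), y)
    coefs = pd.Series(model.coef_[0], index=design.columns)

    grid = pd.DataFrame(np.nan, index=therapies, columns=therapies)
    cell_n = pd.DataFrame(0, index=therapies, columns=therapies)
    blank = pd.DataFrame(True, index=therapies, columns=therapies)
    for col, beta in coefs.items():
        parts = col.split("*")
        ti, tj = (parts[0], parts[0]) if len(parts) == 1 else (parts[0], parts[1])
        n_cell = int(design[col].sum())
        value = math.exp(beta) if n_cell > 0 else np.nan
        grid.loc[ti, tj] = grid.loc[tj, ti] = value
        cell_n.loc[ti, tj] = cell_n.loc[tj, ti] = n_cell
        blank.loc[ti, tj] = blank.loc[tj, ti] = n_cell == 0
    return InteractionGrid(therapies=therapies, grid=grid, cell_n=cell_n,
                           blank=blank)


def flag_candidates(grid: InteractionGrid, threshold: float = 0.1,
                    ) -> list[tuple[str, str, float]]:
    """Defined cells with odds ratio < threshold, sorted ascending."""
    out = []
    for i, ti in enumerate(grid.therapies):
        for j, tj in enumerate(grid.therapies):
            if j < i:
                continue
            v = grid.grid.loc[ti, tj]
            if not pd.isna(v) and v < threshold:
                out.append((ti, tj, float(v)))
    return sorted(out, key=lambda r: r[2])


def confirm_interaction(outcome: pd.Series, therapy1: pd.Series,
                        therapy2: pd.Series,
                        covariates: pd.DataFrame | None = None,
                        membership: pd.Series | None = None) -> ORResult:
    """Maximum-likelihood logistic confirmation of a flagged interaction.

    Fits outcome ~ t1 + t2 + t1:t2 (+ covariates), or, when ``membership``
    is given, outcome ~ membership + combo + membership:combo with
    combo = t1 & t2.  Returns the product-term odds ratio with a Wald 95%
    CI; (quasi-)separation raises rather than silently degrading.
    """
    t1 = np.asarray(therapy1, dtype=float)
    t2 = np.asarray(therapy2, dtype=float)
    if np.array_equal(t1, t2):
        raise ValueError("a therapy cannot interact with itself")
    y = np.asarray(outcome, dtype=float)
    if membership is None:
        X = pd.DataFrame({"t1": t1, "t2": t2, "t1:t2": t1 * t2})
        term = "t1:t2"
    else:
        mem = np.asarray(membership, dtype=float)
        combo = t1 * t2
        X = pd.DataFrame({"membership": mem, "combo": combo,
                          "membership:combo": mem * combo})
        term = "membership:combo"
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
    both_cells = pd.crosstab(X[term.split(":")[0]] * 0 + (X[term] > 0), y)
    if both_cells.shape[0] > 1 and (both_cells.to_numpy() == 0).any():
        raise SeparationError(
            "interaction term is one-sided in the outcome; use exact or "
            "penalized inference")
    res = _fit_logit(y, X)
    coef = res.params[term]
    lo, hi = res.conf_int().loc[term]
    return ORResult(math.exp(coef), math.exp(lo), math.exp(hi),
                    float(res.pvalues[term]), adjusted=covariates is not None,
                    covariates=list(covariates.columns) if covariates is not None
                    else [])
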