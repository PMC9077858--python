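"""Individual-patient phenotype membership (the bedside-tool logic).

A new patient's raw day-1 features are mapped through the training
transform (log1p where flagged, then the stored z-scaling) and assigned to
the nearest phenotype centroid by Euclidean distance in the standardized
space.  Missing inputs are imputed at the training median (0 in z-space)
and counted; assignment is refused when more than 40% of inputs are absent.
Softmax membership weights are descriptive only, never thresholds.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .config import load_phenotype_risk
from .consensus import ConsensusModel

_LETTER_ORDER = {"PedSep-A": 0, "PedSep-B": 1, "PedSep-C": 2, "PedSep-D": 3}


@dataclasses.dataclass
class PhenotypeAssignment:
    label: str
    distances: dict[str, float]
    membership_weights: dict[str, float]
    n_missing_inputs: int
    missing_inputs: list[str]
    tie_flag: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class AssignmentError(ValueError):
    """Raised when a patient cannot be assigned (too many missing inputs)."""


def _model_parts(model: ConsensusModel | dict):
    """(columns, log_flags, means, sds, centroids df, names) from either a
    live ConsensusModel or a loaded model-file dict."""
    if isinstance(model, ConsensusModel):
        tr = model.transform
        if tr is None:
            raise ValueError("model carries no stored transform")
        cents = model.centroids
        names = model.cluster_names
    else:
        tr = model["transform"]
        cents = pd.DataFrame({int(k): v for k, v in model["centroids"].items()}).T
        names = {int(k): v for k, v in model["cluster_names"].items()}
    return tr["columns"], tr["log_flags"], tr["means"], tr["sds"], cents, names


def assign(raw_features: dict | pd.Series,
           model: ConsensusModel | dict,
           min_complete: float = 0.60,
           softmax_temperature: float = 1.0) -> PhenotypeAssignment:
    """Assign one patient to the nearest phenotype centroid.

    ``raw_features`` holds raw-scale day-1 values keyed by variable name;
    absent or NaN entries count as missing.
    """
    columns, log_flags, means, sds, cents, names = _model_parts(model)
    feats = dict(raw_features) if not isinstance(raw_features, dict) else raw_features
    z = np.zeros(len(columns))
    missing: list[str] = []
    for j, c in enumerate(columns):
        v = feats.get(c)
        if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
            missing.append(c)
            z[j] = 0.0  # training median in standardized space
            continue
        x = float(v)
        if log_flags[c]:
            x = math.log1p(x)
        z[j] = (x - means[c]) / sds[c]
    frac_present = 1.0 - len(missing) / len(columns)
    if frac_present < min_complete:
        raise AssignmentError(
            f"only {frac_present:.0%} of the {len(columns)} inputs present "
            f"(need >= {min_complete:.0%}); missing: {missing}")

    dists: dict[str, float] = {}
    for cid, row in cents.iterrows():
        name = names[int(cid)]
        dists[name] = float(np.linalg.norm(z - row.reindex(columns).to_numpy()))
    ordered = sorted(dists, key=lambda nm: (dists[nm],
                                            _LETTER_ORDER.get(nm, 99), nm))
    best = ordered[0]
    tie = len(ordered) > 1 and abs(dists[ordered[1]] - dists[best]) < 1e-12

    neg = np.array([-dists[nm] / softmax_temperature for nm in ordered])
    w = np.exp(neg - neg.max())
    w /= w.sum()
    weights = {nm: float(wi) for nm, wi in zip(ordered, w)}
    return PhenotypeAssignment(label=best, distances=dists,
                               membership_weights=weights,
                               n_missing_inputs=len(missing),
                               missing_inputs=missing, tie_flag=tie)


def assign_table(features: pd.DataFrame, model: ConsensusModel | dict,
                 min_complete: float = 0.60) -> pd.DataFrame:
    """Batch assignment; one row per patient with label, distances, flags."""
    rows = []
    for pid, row in features.iterrows():
        a = assign(row.to_dict(), model, min_complete=min_complete)
        rec = {"patient_id": pid, "label": a.label,
               "n_missing_inputs": a.n_missing_inputs, "tie_flag": a.tie_flag}
        rec.update({f"dist_{nm[-1]}": d for nm, d in a.distances.items()})
        rows.append(rec)
    return pd.DataFrame(rows)


def risk_annotation(label: str) -> dict[str, float]:
    """Published outcome rates (percent) for a named phenotype; empty for
    unnamed clusters."""
    letter = label.replace("PedSep-", "")
    risk = load_phenotype_risk()
    if letter not in risk["phenotype_n"]:
        return {}
    denom = risk["phenotype_n"][letter]
    return {outcome: round(100.0 * d["counts"][letter] / denom, 1)
            for outcome, d in risk["outcomes"].items()}
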