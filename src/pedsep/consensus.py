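"""Consensus k-means phenotype derivation.

For each candidate k, many k-means fits on random 80% patient subsamples are
aggregated into a consensus matrix M(k): the fraction of runs in which two
patients fell in the same cluster, among runs where both were sampled.  The
empirical CDF of the consensus values summarises cluster stability; the area
under that CDF, A(k), and its relative change Δ(k) between consecutive k
give the elbow rule used to choose the number of phenotypes.  Final labels
come from an average-linkage hierarchical cut of 1 - M at the chosen k, and
clusters are mapped onto the canonical PedSep letters by matching centroid
signatures.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .screening import CohortMatrix

# Standardized-centroid sign signatures of the four published phenotypes:
# A younger / previously healthy / low inflammation, high lymphocytes and
# platelets; B intubated with the lowest GCS; C febrile, awake, lymphopenic,
# least pulmonary failure; D highest creatinine and organ-failure burden.
SIGNATURES: dict[str, dict[str, float]] = {
    "A": {"age": -1, "prev_healthy": 1, "crp": -1, "ferritin": -1, "alc": 1,
          "platelets": 1, "heart_rate": 1, "creatinine": -1},
    "B": {"intubated": 1, "gcs": -1, "ofi_pulmonary": 1},
    "C": {"temperature_high": 1, "gcs": 1, "alc": -1, "intubated": -1,
          "ofi_pulmonary": -1},
    "D": {"creatinine": 1, "ofi_total": 1, "ofi_renal": 1, "ofi_hepatic": 1,
          "ofi_hematologic": 1, "platelets": -1},
}


@dataclasses.dataclass
class ConsensusModel:
    """Everything the derivation produced, plus what assignment needs."""

    k_range: list[int]
    n_iterations: int
    subsample_fraction: float
    seed: int
    consensus: dict[int, np.ndarray]          # per-k consensus matrix
    areas: dict[int, float]
    deltas: dict[int, float]
    chosen_k: int
    ambiguous: bool
    labels: np.ndarray                        # final labels, 1..k
    centroids: pd.DataFrame                   # k x p, standardized space
    cluster_names: dict[int, str]             # cluster id -> PedSep-X / Cluster-i
    name_scores: pd.DataFrame | None
    transform: dict | None                    # CohortMatrix.to_dict()
    patient_ids: list

    def labels_named(self) -> list[str]:
        return [self.cluster_names[int(l)] for l in self.labels]

    def to_json(self, path: str) -> None:
        """Persist the phenotype model file consumed by bedside assignment."""
        payload = {
            "schema_version": 1,
            "chosen_k": self.chosen_k,
            "ambiguous": self.ambiguous,
            "areas": {str(k): v for k, v in self.areas.items()},
            "deltas": {str(k): v for k, v in self.deltas.items()},
            "cluster_names": {str(k): v for k, v in self.cluster_names.items()},
            "centroids": {str(int(i)): row.to_dict()
                          for i, row in self.centroids.iterrows()},
            "transform": self.transform,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def consensus_from_runs(runs: list[tuple[np.ndarray, np.ndarray]],
                        n: int) -> np.ndarray:
    """Consensus matrix from explicit (subsample indices, labels) runs.

    M[i, j] = #(runs where i, j co-sampled and co-clustered) /
              #(runs where i, j co-sampled); pairs never co-sampled get 0
    with a warning.  The diagonal is 1.
    """
    conn = np.zeros((n, n))
    both = np.zeros((n, n))
    for idx, labels in runs:
        idx = np.asarray(idx)
        labels = np.asarray(labels)
        ix = np.ix_(idx, idx)
        both[ix] += 1
        same = (labels[:, None] == labels[None, :]).astype(float)
        conn[ix] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(both > 0, conn / np.where(both > 0, both, 1), 0.0)
    never = (both == 0)
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(f"{int(never.sum()) // 2} patient pairs were never "
                      "co-sampled; their consensus entries are set to 0 and "
                      "excluded from the CDF")
    np.fill_diagonal(M, 1.0)
    return M


def cdf_area(M: np.ndarray,
             exclude: np.ndarray | None = None) -> tuple[callable, float]:
    """Empirical CDF of the upper-triangle consensus values and the area
    under it over [0, 1] (step integration over the observed values).

    ``exclude`` optionally masks pairs (e.g. never co-sampled) out of the CDF.
    """
    iu = np.triu_indices(M.shape[0], k=1)
    vals = M[iu]
    if exclude is not None:
        vals = vals[~exclude[iu]]
    vals = np.sort(vals)
    m = len(vals)

    def cdf(t: float) -> float:
        return float(np.searchsorted(vals, t, side="right")) / m

    xs = np.unique(np.concatenate([[0.0], vals, [1.0]]))
    area = float(np.sum(np.diff(xs) * np.array([cdf(x) for x in xs[:-1]])))
    return cdf, area


def delta_area(areas: dict[int, float]) -> dict[int, float]:
    """Relative change of the CDF area between consecutive k.

    Δ(k_min) = A(k_min); Δ(k) = (A(k) - A(k-1)) / A(k-1) for larger k.
    """
    ks = sorted(areas)
    deltas: dict[int, float] = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        if areas[prev] == 0:
            warnings.warn(f"A({prev}) = 0; delta({k}) undefined, set to nan")
            deltas[k] = float("nan")
        else:
            deltas[k] = (areas[k] - areas[prev]) / areas[prev]
    return deltas


def select_k(deltas: dict[int, float], threshold: float = 0.08,
             ) -> tuple[int, bool]:
    """Elbow rule: the largest k whose relative area gain is >= threshold.

    The default threshold sits inside the window between the spurious gain
    of splitting a true cluster (<~ w^2-share of pairs) and the ideal-limit
    gain of separating the two smallest true clusters (their pair share of
    the CDF area); see the methods note for the derivation at the default
    cohort weights.

    The ambiguity flag is raised when the delta profile shows no dominant
    k: either it is flat beyond the smallest k (max gain < threshold/2) or
    it declines smoothly with no elbow (no consecutive drop ratio >= 2,
    the signature of resampling-stable but hierarchy-free structure).
    ``consensus_run`` additionally raises the flag on poor consensus
    quality (high PAC) at the chosen k.
    """
    ks = sorted(deltas)
    k_min = ks[0]
    chosen = k_min
    for k in ks:
        d = deltas[k]
        if not np.isnan(d) and d >= threshold:
            chosen = k
    beyond = [deltas[k] for k in ks if k > k_min and not np.isnan(deltas[k])]
    flat = (not beyond) or max(beyond) < threshold / 2
    ratios = [deltas[a] / deltas[b]
              for a, b in zip(ks, ks[1:])
              if not (np.isnan(deltas[a]) or np.isnan(deltas[b]))
              and deltas[b] > 0]
    no_elbow = bool(ratios) and max(ratios) < 2.0
    return chosen, (flat or no_elbow)


def proportion_ambiguous(M: np.ndarray, lo: float = 0.1,
                         hi: float = 0.9) -> float:
    """PAC: fraction of consensus entries strictly between lo and hi.

    Low values mean pairs are either almost always or almost never
    co-clustered (clean structure); high values mean unstable membership.
    """
    iu = np.triu_indices(M.shape[0], k=1)
    v = M[iu]
    return float(((v > lo) & (v < hi)).mean())


def final_labels(M: np.ndarray, X: np.ndarray, k: int,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Cut an average-linkage tree of the consensus distance 1 - M at k;
    centroids are per-cluster means in the standardized space.

    Labels are renumbered 1..k by decreasing cluster size.
    """
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    if len(sizes) < k:
        raise ValueError(f"consensus cut produced only {len(sizes)} clusters; "
                         "try a lower k")
    remap = {old: new + 1 for new, old in enumerate(sizes.index)}
    labels = np.array([remap[r] for r in raw])
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in range(1, k + 1)])
    return labels, centroids


def canonical_phenotype_names(centroids: pd.DataFrame,
                              ) -> tuple[dict[int, str], pd.DataFrame | None]:
    """Match clusters to the PedSep letters by centroid signature agreement.

    Only defined for k = 4; otherwise clusters are named Cluster-1..k.
    The assignment maximizes the total signed agreement between standardized
    centroids and the reference signatures (a bijection; ties are resolved
    by the globally optimal assignment and reported in the score table).
    """
    k = len(centroids)
    if k != 4:
        return {i: f"Cluster-{i}" for i in centroids.index}, None
    letters = list(SIGNATURES)
    scores = np.zeros((k, 4))
    for row, (cid, cent) in enumerate(centroids.iterrows()):
        for col, letter in enumerate(letters):
            sig = SIGNATURES[letter]
            present = [v for v in sig if v in cent.index]
            if not present:
                continue
            scores[row, col] = float(np.mean([sig[v] * cent[v] for v in present]))
    ri, ci = linear_sum_assignment(-scores)
    names = {int(centroids.index[r]): f"PedSep-{letters[c]}"
             for r, c in zip(ri, ci)}
    score_df = pd.DataFrame(scores, index=centroids.index, columns=letters)
    return names, score_df


def consensus_run(X: CohortMatrix | np.ndarray,
                  k_range: tuple[int, int] = (2, 6),
                  n_iterations: int = 1000,
                  subsample_fraction: float = 0.8,
                  seed: int = 0,
                  n_init: int = 10,
                  select_threshold: float = 0.08) -> ConsensusModel:
    """Full consensus derivation over a range of k.

    Deterministic given ``seed``; every per-iteration k-means fit gets its
    own seed derived from it.
    """
    if isinstance(X, CohortMatrix):
        mat, transform, pids, columns = (X.X, X.to_dict(), X.patient_ids,
                                         X.columns)
    else:
        mat = np.asarray(X, dtype=float)
        transform, pids, columns = None, list(range(len(mat))), [
            f"x{j}" for j in range(mat.shape[1])]
    n = len(mat)
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if k_lo < 2 or k_hi > n // 2:
        raise ValueError(f"k_range ({k_lo}, {k_hi}) outside [2, n/2] for n={n}")
    if np.isnan(mat).any():
        raise ValueError("clustering matrix contains missing entries")
    m = max(2, int(round(subsample_fraction * n)))

    ss = np.random.SeedSequence(seed)
    consensus: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    for k, child in zip(range(k_lo, k_hi + 1), ss.spawn(k_hi - k_lo + 1)):
        rng = np.random.default_rng(child)
        conn = np.zeros((n, n))
        both = np.zeros((n, n))
        for _ in range(n_iterations):
            idx = rng.choice(n, size=m, replace=False)
            km_seed = int(rng.integers(0, 2 ** 31 - 1))
            km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                        max_iter=300, random_state=km_seed)
            labels = km.fit_predict(mat[idx])
            ix = np.ix_(idx, idx)
            both[ix] += 1
            conn[ix] += (labels[:, None] == labels[None, :]).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(both > 0, conn / np.where(both > 0, both, 1), 0.0)
        never = (both == 0)
        np.fill_diagonal(never, False)
        if never.any():
            warnings.warn(f"k={k}: {int(never.sum()) // 2} pairs never "
                          "co-sampled; entries set to 0, excluded from CDF")
        np.fill_diagonal(M, 1.0)
        consensus[k] = M
        areas[k] = cdf_area(M, exclude=never if never.any() else None)[1]

    deltas = delta_area(areas)
    chosen_k, ambiguous = select_k(deltas, select_threshold)
    if proportion_ambiguous(consensus[chosen_k]) > 0.3:
        ambiguous = True
    labels, cents = final_labels(consensus[chosen_k], mat, chosen_k)
    centroids = pd.DataFrame(cents, index=range(1, chosen_k + 1),
                             columns=columns)
    names, score_df = canonical_phenotype_names(centroids)
    return ConsensusModel(
        k_range=list(range(k_lo, k_hi + 1)), n_iterations=n_iterations,
        subsample_fraction=subsample_fraction, seed=seed, consensus=consensus,
        areas=areas, deltas=deltas, chosen_k=chosen_k, ambiguous=ambiguous,
        labels=labels, centroids=centroids, cluster_names=names,
        name_scores=score_df, transform=transform, patient_ids=pids)


def embed_2d(X: CohortMatrix | np.ndarray, seed: int = 0) -> np.ndarray:
    """Delegated 2-D t-SNE embedding for visualization only."""
    from sklearn.manifold import TSNE
    mat = X.X if isinstance(X, CohortMatrix) else np.asarray(X, dtype=float)
    if len(mat) < 5:
        raise ValueError("embedding needs at least 5 points")
    perplexity = min(30.0, (len(mat) - 1) / 3.0)
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
              init="pca")
    return ts.fit_transform(mat)


def load_model(path: str) -> dict:
    """Load a phenotype model file written by :meth:`ConsensusModel.to_json`."""
    with open(path) as fh:
        model = json.load(fh)
    if "centroids" not in model or "transform" not in model:
        raise ValueError("not a phenotype model file")
    return model
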