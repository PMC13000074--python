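"""Sub-phenotype discovery on the learned encodings.

Stage two of the pipeline: K-means over per-(patient, window) encodings
(the clustering unit is the window, so patients move between phenotypes
over their stay), silhouette analysis to choose K, Table-style cluster
summaries on the original clinical scale, admission->...->discharge/death
transition counts (the substrate of Sankey diagrams), and optimal-assignment
alignment of cluster centroids across independently clustered cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .features import MISSING_FLAG_FEATURES
from .preprocessing import TimeStepTensor


@dataclass
class ClusterModel:
    K: int
    centroids: np.ndarray  # (K, encoding_dim)
    inertia: float
    seed: int
    n_init: int


@dataclass
class SilhouetteResult:
    k_candidates: list[int]
    scores: dict[int, float]
    k_star: int
    subsample_fraction: float
    seed: int
    models: dict[int, ClusterModel] = field(default_factory=dict)


def fit_kmeans(X, K: int, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """Lloyd iterations from k-means++ seeding, best of ``n_init`` runs."""
    arr = np.asarray(X, float)
    if K > arr.shape[0]:
        raise ValueError(f"K={K} exceeds the number of rows ({arr.shape[0]})")
    km = KMeans(n_clusters=K, n_init=n_init, max_iter=300, random_state=seed)
    km.fit(arr)
    return ClusterModel(
        K=K,
        centroids=km.cluster_centers_.copy(),
        inertia=float(km.inertia_),
        seed=seed,
        n_init=n_init,
    )


def assign(model: ClusterModel, X) -> np.ndarray:
    """Nearest-centroid (Euclidean) labels; ties go to the lowest index."""
    arr = np.atleast_2d(np.asarray(X, float))
    if arr.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"dimension mismatch: points have {arr.shape[1]}, centroids "
            f"{model.centroids.shape[1]}"
        )
    d = cdist(arr, model.centroids)
    return d.argmin(axis=1)


def select_k_silhouette(
    X,
    k_range=range(2, 11),
    subsample_fraction: float = 1.0,
    seed: int = 0,
    n_init: int = 10,
) -> SilhouetteResult:
    """Mean silhouette per candidate K; K* = argmax (ties -> smaller K).

    Silhouette uses s(i) = (b - a)/max(a, b) with s = 0 for singleton
    clusters. An optional row subsample bounds the O(n^2) distance work.
    """
    arr = np.asarray(X, float)
    rng = np.random.default_rng(seed)
    if subsample_fraction < 1.0:
        n = max(2, int(round(subsample_fraction * arr.shape[0])))
        arr = arr[rng.choice(arr.shape[0], size=n, replace=False)]
    ks = sorted(k for k in k_range)
    valid = [k for k in ks if 2 <= k <= arr.shape[0] - 1]
    if valid != ks:
        import warnings

        warnings.warn(f"k_range clipped to {valid} for n={arr.shape[0]}", stacklevel=2)
    scores, models = {}, {}
    for k in valid:
        m = fit_kmeans(arr, k, seed=seed, n_init=n_init)
        labels = assign(m, arr)
        if len(np.unique(labels)) < 2:
            scores[k] = -1.0
        else:
            scores[k] = float(silhouette_score(arr, labels))
        models[k] = m
    k_star = max(valid, key=lambda k: (scores[k], -k))
    return SilhouetteResult(
        k_candidates=valid,
        scores=scores,
        k_star=k_star,
        subsample_fraction=subsample_fraction,
        seed=seed,
        models=models,
    )


def assignment_frame(model: ClusterModel, encodings: pd.DataFrame) -> pd.DataFrame:
    """ClusterAssignment table: (patient_id, window) -> cluster id."""
    labels = assign(model, encodings.to_numpy())
    out = encodings.index.to_frame(index=False)
    out["cluster"] = labels
    return out


def summarize_clusters(
    assignment: pd.DataFrame,
    tensors: list[TimeStepTensor],
    skewed: set[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster sample statistics on the original clinical scale.

    Columns: window count and share, mean (SD) for symmetric features and
    median [Q1, Q3] (linear-interpolation quantiles) for skewed ones, plus
    outcome rates (90-day mortality %, median remaining LOS, next-step RRT
    and MV %), all computed over member windows. A ``cohort`` row summarises
    all windows together.
    """
    skewed = skewed or set()
    names = tensors[0].feature_names
    rows = []
    for t in tensors:
        raw = t.features_raw if t.features_raw is not None else t.features
        for w in range(t.n_windows):
            rows.append(
                (t.patient_id, w, *raw[w], t.died_90d, t.remaining_los_days[w],
                 t.rrt_next[w], t.mv_next[w])
            )
    frame = pd.DataFrame(
        rows,
        columns=["patient_id", "window", *names, "died_90d", "remaining_los_days",
                 "rrt_next", "mv_next"],
    )
    merged = frame.merge(assignment, on=["patient_id", "window"], how="inner")
    total = len(merged)

    def describe(sub: pd.DataFrame) -> dict:
        d: dict[str, float | str] = {
            "n_windows": len(sub),
            "pct_windows": 100.0 * len(sub) / total,
        }
        if len(sub) == 0:
            for n in names:
                d[n] = "NA"
            d.update(mortality_pct="NA", median_remaining_los_days="NA",
                     rrt_pct="NA", mv_pct="NA")
            return d
        for n in names:
            v = sub[n].to_numpy(float)
            if n in skewed:
                q1, q2, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
                d[n] = f"{q2:.2f} [{q1:.2f},{q3:.2f}]"
            else:
                d[n] = f"{v.mean():.2f} (±{v.std(ddof=1) if len(v) > 1 else 0.0:.2f})"
        d["mortality_pct"] = 100.0 * sub["died_90d"].mean()
        d["median_remaining_los_days"] = float(sub["remaining_los_days"].median())
        d["rrt_pct"] = 100.0 * sub["rrt_next"].mean()
        d["mv_pct"] = 100.0 * sub["mv_next"].mean()
        return d

    K = int(assignment["cluster"].max()) + 1
    table = {"cohort": describe(merged)}
    for k in range(K):
        table[f"C{k}"] = describe(merged[merged["cluster"] == k])
    return pd.DataFrame(table).T


def transition_counts(assignment: pd.DataFrame, died_90d: pd.Series) -> pd.DataFrame:
    """Sankey-style counts over (K clusters + admission) x (K clusters +
    discharge + death). Each patient contributes n_windows + 1 transitions:
    admission -> first cluster, consecutive window pairs, and last cluster
    -> discharge or death."""
    K = int(assignment["cluster"].max()) + 1
    rows = [f"C{k}" for k in range(K)] + ["admission"]
    cols = [f"C{k}" for k in range(K)] + ["discharge", "death"]
    M = pd.DataFrame(0, index=rows, columns=cols)
    for pid, g in assignment.sort_values("window").groupby("patient_id"):
        seq = g["cluster"].to_numpy()
        M.loc["admission", f"C{seq[0]}"] += 1
        for a, b in zip(seq[:-1], seq[1:]):
            M.loc[f"C{a}", f"C{b}"] += 1
        sink = "death" if died_90d.loc[pid] else "discharge"
        M.loc[f"C{seq[-1]}", sink] += 1
    return M


def align_clusters(
    model_a: ClusterModel, model_b: ClusterModel
) -> tuple[dict[int, int], float, list[int]]:
    """Optimal centroid matching between two cluster models.

    Returns (mapping a_id -> b_id minimizing summed Euclidean centroid
    distance, total cost, unmatched ids of the larger model). Equal K gives
    a bijection; unequal K gives a partial matching.
    """
    A, B = model_a.centroids, model_b.centroids
    if A.shape[1] != B.shape[1]:
        raise ValueError("centroid dimension mismatch")
    cost = cdist(A, B)
    ra, rb = linear_sum_assignment(cost)
    mapping = {int(a): int(b) for a, b in zip(ra, rb)}
    total = float(cost[ra, rb].sum())
    if A.shape[0] <= B.shape[0]:
        unmatched = sorted(set(range(B.shape[0])) - set(mapping.values()))
    else:
        unmatched = sorted(set(range(A.shape[0])) - set(mapping.keys()))
    return mapping, total, unmatched
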