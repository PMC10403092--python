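"""Risk grouping by spectral clustering of post-alert risk trajectories.

Positive-predicted encounters are stratified by the shape of their risk-score
trajectory in the 6 hours after the early prediction point (73 points at
5-minute resolution).  The clustering is the standard normalized spectral
recipe: a symmetric K-nearest-neighbor graph (Euclidean distance on raw
trajectories), the symmetric normalized Laplacian, the number of clusters
chosen by the maximum eigengap, and seeded k-means on the row-normalized
spectral embedding.  Cluster stability is assessed by repeated 80%
subsampling without replacement and the maximum Jaccard index of each
reference cluster against the subsample clusterings.  Groups are ordered by
mean risk score at the alert time (low < medium < high) and test encounters
receive labels by K-nearest-neighbor transfer from the training clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAJECTORY_POINTS = 73  # 0..6 h inclusive at 5-min steps
GRID_STEP = 5

GROUP_NAMES = {1: ["high"], 2: ["low", "high"], 3: ["low", "medium", "high"]}


def group_names(k: int) -> list:
    if k in GROUP_NAMES:
        return GROUP_NAMES[k]
    return [f"group_{i}" for i in range(k)]


@dataclass
class RiskGroupModel:
    trajectories: np.ndarray  # (n_train, 73) reference rows
    labels: np.ndarray        # ordered labels: 0 = lowest risk
    k: int
    K: int = 200
    k_nn: int = 15
    names: list = field(default_factory=list)

    def __post_init__(self):
        if not self.names:
            self.names = group_names(self.k)


# ---------------------------------------------------------------------------
# trajectory extraction
# ---------------------------------------------------------------------------

def extract_trajectories(
    score_series: pd.DataFrame,
    predictions: pd.DataFrame,
    n_points: int = TRAJECTORY_POINTS,
):
    """Post-EPP trajectory matrix for positive-predicted encounters.

    Each row is ``scores[EPP .. EPP + 6 h]`` on the 5-minute grid (73
    points).  Encounters whose series ends (prep time or discharge) before
    the full window are excluded from the matrix but returned separately
    with their last value carried forward, so they can still receive a
    transferred group label; exclusions are logged.

    Returns ``(matrix, ids, padded_matrix, padded_ids)``.
    """
    pos = predictions[predictions["predicted"]]
    if len(pos) == 0:
        raise ValueError("no positive predictions to extract trajectories from")
    series_by = {k: v for k, v in score_series.groupby("encounter_id")}
    full_rows, full_ids, pad_rows, pad_ids = [], [], [], []
    for r in pos.itertuples(index=False):
        g = series_by[r.encounter_id]
        t = g["time"].to_numpy(float)
        s = g["score"].to_numpy(float)
        start = int(np.searchsorted(t, r.epp))
        window = s[start : start + n_points]
        if window.size == n_points:
            full_rows.append(window)
            full_ids.append(r.encounter_id)
        else:
            padded = np.concatenate(
                [window, np.full(n_points - window.size, window[-1])]
            )
            pad_rows.append(padded)
            pad_ids.append(r.encounter_id)
    if pad_ids:
        logger.info(
            "%d trajectories shorter than 6 h excluded from clustering "
            "(padded copies kept for label transfer)", len(pad_ids)
        )
    full = np.asarray(full_rows) if full_rows else np.empty((0, n_points))
    pad = np.asarray(pad_rows) if pad_rows else np.empty((0, n_points))
    return full, full_ids, pad, pad_ids


# ---------------------------------------------------------------------------
# spectral clustering
# ---------------------------------------------------------------------------

def _knn_adjacency(X: np.ndarray, K: int) -> np.ndarray:
    """Symmetric binary KNN graph: edge if either point is in the other's
    K-neighborhood (Euclidean)."""
    from scipy.spatial.distance import squareform, pdist

    n = X.shape[0]
    D = squareform(pdist(X))
    A = np.zeros((n, n), bool)
    order = np.argsort(D, axis=1, kind="stable")
    for i in range(n):
        neigh = order[i][order[i] != i][:K]
        A[i, neigh] = True
    A = A | A.T
    return A.astype(float)


def spectral_cluster(
    X: np.ndarray,
    K: int = 200,
    k: int | None = None,
    k_max: int = 8,
    seed: int = 0,
):
    """Normalized spectral clustering with eigengap model selection.

    Returns ``(labels, k)``.  ``K`` is silently capped at n - 1 (logged).
    Degenerate inputs (all rows identical) return a single cluster with a
    warning.  If the KNN graph splits into more connected components than
    ``k_max`` an error advises a larger K.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 trajectories to cluster")
    if np.allclose(X, X[0]):
        warnings.warn("all trajectories identical: returning a single cluster")
        return np.zeros(n, int), 1
    if K > n - 1:
        logger.info("K=%d capped at n-1=%d", K, n - 1)
        K = n - 1
    A = _knn_adjacency(X, K)
    deg = A.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(n) - (d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :])
    vals, vecs = np.linalg.eigh(L)

    k_hi = min(k_max, n - 1)
    n_components = int((vals < 1e-10).sum())
    if n_components > k_hi:
        raise ValueError(
            f"KNN graph has {n_components} connected components > k_max={k_hi}; "
            "increase K"
        )
    if k is None:
        gaps = vals[1 : k_hi + 1] - vals[:k_hi]  # gap after each candidate k
        k = int(np.argmax(gaps[1:]) + 2)  # k in [2, k_hi]
    emb = vecs[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = emb / norms
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
    return km.labels_.astype(int), k


def order_groups(labels: np.ndarray, trajectories: np.ndarray) -> np.ndarray:
    """Relabel clusters by ascending mean score at the alert time (t = 0):
    0 = low ... k-1 = high."""
    ks = np.unique(labels)
    at_epp = np.array([trajectories[labels == c, 0].mean() for c in ks])
    rank = {c: r for r, c in enumerate(ks[np.argsort(at_epp, kind="stable")])}
    return np.array([rank[c] for c in labels], int)


def fit_risk_groups(
    trajectories: np.ndarray,
    K: int = 200,
    k: int | None = None,
    k_max: int = 8,
    k_nn: int = 15,
    seed: int = 0,
) -> RiskGroupModel:
    raw_labels, k_found = spectral_cluster(trajectories, K=K, k=k, k_max=k_max, seed=seed)
    labels = order_groups(raw_labels, trajectories)
    return RiskGroupModel(
        trajectories=trajectories, labels=labels, k=k_found, K=K, k_nn=k_nn
    )


# ---------------------------------------------------------------------------
# bootstrap stability
# ---------------------------------------------------------------------------

def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return float("nan")
    return len(a & b) / len(a | b)


def stability_jaccard(
    trajectories: np.ndarray,
    reference_labels: np.ndarray,
    K: int = 200,
    n_boot: int = 50,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Per-reference-cluster mean of the maximum Jaccard index over bootstrap
    reclusterings.

    Each draw subsamples ``subsample_fraction`` of rows without replacement,
    reclusters with the same K and the reference number of clusters, and for
    every reference cluster takes the best Jaccard overlap (restricted to
    the subsampled points) against the subsample clusters.  A cluster absent
    from a draw contributes nothing to its mean; draws smaller than k are
    skipped with a log line.
    """
    rng = np.random.default_rng(seed)
    n = trajectories.shape[0]
    ref_ids = np.unique(reference_labels)
    k_ref = ref_ids.size
    sums = np.zeros(k_ref)
    counts = np.zeros(k_ref)
    m = int(round(subsample_fraction * n))
    for _ in range(n_boot):
        take = rng.choice(n, size=m, replace=False)
        if m < k_ref:
            logger.info("subsample smaller than k; draw skipped")
            continue
        sub_labels, _ = spectral_cluster(
            trajectories[take], K=K, k=k_ref, seed=int(rng.integers(0, 2**31 - 1))
        )
        sub_sets = [set(take[sub_labels == c]) for c in np.unique(sub_labels)]
        take_set = set(take)
        for r_i, r in enumerate(ref_ids):
            ref_set = set(np.flatnonzero(reference_labels == r)) & take_set
            if not ref_set:
                continue
            best = max(jaccard(ref_set, s) for s in sub_sets)
            sums[r_i] += best
            counts[r_i] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


# ---------------------------------------------------------------------------
# label transfer and group metrics
# ---------------------------------------------------------------------------

def transfer_labels(
    model: RiskGroupModel, test_trajectories: np.ndarray, k_nn: int | None = None
) -> np.ndarray:
    """Majority vote among the k_nn nearest training trajectories
    (Euclidean); ties break toward the higher-risk group."""
    k_nn = k_nn or model.k_nn
    test_trajectories = np.atleast_2d(np.asarray(test_trajectories, float))
    if test_trajectories.shape[0] == 0:
        return np.empty(0, int)
    k_nn = min(k_nn, model.trajectories.shape[0])
    out = np.empty(test_trajectories.shape[0], int)
    for i, row in enumerate(test_trajectories):
        d = np.linalg.norm(model.trajectories - row, axis=1)
        nn = np.argsort(d, kind="stable")[:k_nn]
        votes = np.bincount(model.labels[nn], minlength=model.k)
        best = votes.max()
        out[i] = np.flatnonzero(votes == best).max()  # tie -> higher risk
    return out


def group_metrics(
    group_labels: np.ndarray,
    encounter_ids,
    encounters: pd.DataFrame,
    epps: dict,
    k: int,
) -> pd.DataFrame:
    """Per-group positive-prediction count, PPV, and EWT median [IQR].

    ``group_labels`` cover positive-predicted encounters only; groups
    partition them, so the counts sum to the number of positives.  Empty
    groups report n = 0 with null metrics.
    """
    from .early_warning import _ewt_summary, compute_ewt

    enc = encounters.set_index("encounter_id")
    names = group_names(k)
    rows = []
    for g in range(k):
        ids = [e for e, lbl in zip(encounter_ids, group_labels) if lbl == g]
        n_pos = len(ids)
        if n_pos == 0:
            rows.append((names[g], 0, float("nan"), float("nan"),
                         (float("nan"), float("nan"))))
            continue
        mv = np.array([bool(enc.at[e, "mv_flag"]) for e in ids])
        ppv = float(mv.mean())
        ewts = np.array(
            [
                compute_ewt(epps[e], float(enc.at[e, "mv_onset_time"]))
                for e, is_mv in zip(ids, mv)
                if is_mv
            ]
        )
        med, iqr = _ewt_summary(ewts)
        rows.append((names[g], n_pos, ppv, med, iqr))
    return pd.DataFrame(
        rows,
        columns=["group", "n_positive_predictions", "ppv",
                 "ewt_median_hours", "ewt_iqr_hours"],
    )
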