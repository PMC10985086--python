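"""SHAP-space subgrouping: PCA embedding, shared-nearest-neighbour Louvain
clustering, resolution scoring by subsampled silhouettes combined with
per-cluster prediction metrics, and cluster characterisation.

The resolution score for a candidate clustering is

    cluster_score = weighted_mean(silhouette scores)
                    / (1 - weighted_median(prediction values))

with cluster sizes as weights, per-cluster median subsampled silhouette
widths as the silhouette scores, and per-cluster F1 of case classification
(out-of-fold predictions at threshold 0.5) as the prediction values.  The
weighted median is the lower weighted median, except that when the
cumulative weight hits exactly half the total the two adjacent values are
averaged.  A score is capped to +inf when the weighted median F1 reaches 1.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from ._util import child_seed, rng_for
from .risk_model import confusion_counts, metrics_from_counts


@dataclass
class Embedding:
    scores: np.ndarray              # subjects x d, columns by decreasing variance
    explained_variance_ratio: np.ndarray


def embed_pca(values, d: int = 10) -> Embedding:
    """Centered PCA scores with deterministic signs (each component's
    largest-magnitude loading is made positive). Rank-deficient input yields
    fewer columns."""
    X = np.asarray(values, dtype=float)
    if X.shape[0] <= d:
        raise ValueError("need more subjects than embedding dimensions")
    d_eff = min(d, X.shape[1], X.shape[0] - 1)
    pca = PCA(n_components=d_eff, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(d_eff):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return Embedding(scores, pca.explained_variance_ratio_)


def snn_graph(scores: np.ndarray, k_neighbors: int = 20, prune: float = 1 / 15) -> ig.Graph:
    """Shared-nearest-neighbour graph: Euclidean k-NN (self included in the
    neighbour sets), Jaccard edge weights between neighbour sets, edges with
    weight < prune removed."""
    n = scores.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(scores)
    _, idx = nn.kneighbors(scores)  # first column is self
    rows = np.repeat(np.arange(n), k_neighbors + 1)
    A = sparse.csr_matrix(
        (np.ones(idx.size), (rows, idx.ravel())), shape=(n, n), dtype=np.float64
    )
    inter = (A @ A.T).tocoo()
    i, j, shared = inter.row, inter.col, inter.data
    keep = i < j
    i, j, shared = i[keep], j[keep], shared[keep]
    union = 2.0 * (k_neighbors + 1) - shared
    jac = shared / union
    # only connect pairs that are k-NN of one another in at least one direction
    neighbor_pair = np.asarray(A[i, j]).ravel() + np.asarray(A[j, i]).ravel() > 0
    keep = neighbor_pair & (jac >= prune)
    g = ig.Graph(n=n, edges=list(zip(i[keep].tolist(), j[keep].tolist())))
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster_graph(embedding: Embedding, resolution: float, k_neighbors: int = 20,
                  seed: int = 0, min_cluster_size: int = 5) -> np.ndarray:
    """Louvain community detection on the SNN graph at the given resolution.

    Labels are renumbered by decreasing cluster size (ties by first
    subject).  Communities smaller than min_cluster_size — far below the
    neighbourhood scale of the graph, and too small for the subsampled
    silhouette to score reliably — are absorbed into the nearest retained
    cluster by centroid distance (singletons from pruning included).
    """
    scores = embedding.scores
    if scores.shape[0] <= k_neighbors:
        raise ValueError("need more subjects than k_neighbors")
    g = snn_graph(scores, k_neighbors)
    state = random.Random(child_seed(seed, "louvain"))
    ig.set_random_number_generator(state)
    try:
        part = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        ig.set_random_number_generator(random)
    labels = np.asarray(part.membership)
    labels = _absorb_small(labels, scores, min_cluster_size)
    return _relabel_by_size(labels)


def _absorb_small(labels: np.ndarray, scores: np.ndarray, min_size: int) -> np.ndarray:
    ids, counts = np.unique(labels, return_counts=True)
    small = ids[counts < min_size]
    big = ids[counts >= min_size]
    if small.size == 0 or big.size == 0:
        return labels
    centroids = np.stack([scores[labels == c].mean(axis=0) for c in big])
    out = labels.copy()
    for c in small:
        for i in np.flatnonzero(labels == c):
            out[i] = big[int(np.argmin(np.linalg.norm(centroids - scores[i], axis=1)))]
    return out


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, first, counts = np.unique(labels, return_index=True, return_counts=True)
    order = sorted(range(ids.size), key=lambda t: (-counts[t], first[t]))
    mapping = {ids[t]: rank for rank, t in enumerate(order)}
    return np.array([mapping[c] for c in labels])


def weighted_mean(values, weights) -> float:
    v, w = np.asarray(values, float), np.asarray(weights, float)
    return float(np.sum(v * w) / np.sum(w))


def weighted_median(values, weights) -> float:
    """Lower weighted median; when the cumulative weight reaches exactly half
    the total, the two adjacent values are averaged."""
    v, w = np.asarray(values, float), np.asarray(weights, float)
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    k = int(np.searchsorted(cum, half))
    if abs(cum[k] - half) <= 1e-12 * cum[-1] and k + 1 < v.size:
        return float(0.5 * (v[k] + v[k + 1]))
    return float(v[k])


def cluster_score(silhouettes, prediction_values, sizes) -> float:
    """The resolution score (see module docstring); +inf when the weighted
    median prediction value reaches 1."""
    wmed = weighted_median(prediction_values, sizes)
    if wmed >= 1.0 - 1e-9:
        return float("inf")
    return weighted_mean(silhouettes, sizes) / (1.0 - wmed)


@dataclass
class ClusterSolution:
    resolution: float
    labels: np.ndarray
    per_cluster: pd.DataFrame  # index cluster id: size, size_frac, case_frac, mean_prob, silhouette, f1, ppv, sensitivity
    score: float
    valid: bool

    @property
    def n_clusters(self) -> int:
        return int(self.per_cluster.shape[0])


def score_resolution(embedding: Embedding, labels: np.ndarray, oof_probs, case_labels,
                     resolution: float = np.nan, n_subsamples: int = 30, frac: float = 0.8,
                     seed: int = 0, threshold: float = 0.5) -> ClusterSolution:
    """Score one clustering: subsampled silhouettes (median per cluster over
    n_subsamples random fractions of subjects), per-cluster case-prediction
    metrics from out-of-fold probabilities, and the combined cluster score."""
    scores = embedding.scores
    y = np.asarray(case_labels, int)
    p = np.asarray(oof_probs, float)
    ids, sizes = np.unique(labels, return_counts=True)
    n = labels.size
    if ids.size < 2:
        per = pd.DataFrame(index=pd.Index(ids, name="cluster"))
        per["size"] = sizes
        return ClusterSolution(resolution, labels, per, float("nan"), False)
    rng = rng_for(seed, "silhouette", resolution)
    sil_samples: dict[int, list[float]] = {c: [] for c in ids}
    m = int(round(frac * n))
    for _ in range(n_subsamples):
        sub = rng.choice(n, size=m, replace=False)
        sub_labels = labels[sub]
        present = np.unique(sub_labels)
        if present.size < 2:
            continue
        widths = silhouette_samples(scores[sub], sub_labels)
        for c in present:
            sil_samples[c].append(float(np.mean(widths[sub_labels == c])))
    rows = []
    for c, size in zip(ids, sizes):
        member = labels == c
        counts = confusion_counts(y[member], p[member], threshold)
        mets = metrics_from_counts(counts)
        rows.append(
            {
                "cluster": int(c),
                "size": int(size),
                "size_frac": size / n,
                "case_frac": float(np.mean(y[member])),
                "mean_prob": float(np.mean(p[member])),
                "silhouette": float(np.median(sil_samples[c])) if sil_samples[c] else np.nan,
                "f1": 0.0 if np.isnan(mets["f1"]) else mets["f1"],
                "ppv": mets["ppv"],
                "sensitivity": mets["sensitivity"],
            }
        )
    per = pd.DataFrame(rows).set_index("cluster")
    score = cluster_score(per["silhouette"].fillna(0.0), per["f1"], per["size"])
    return ClusterSolution(resolution, labels, per, score, bool(np.isfinite(score) or np.isinf(score)))


DEFAULT_RESOLUTIONS = (0.3, 0.4, 0.5, 0.6, 0.8, 1.0)


def scan_resolutions(embedding: Embedding, oof_probs, case_labels,
                     resolutions=DEFAULT_RESOLUTIONS, k_neighbors: int = 20,
                     n_subsamples: int = 30, frac: float = 0.8,
                     seed: int = 0) -> list[ClusterSolution]:
    out = []
    for r in resolutions:
        labels = cluster_graph(embedding, r, k_neighbors, seed)
        out.append(
            score_resolution(
                embedding, labels, oof_probs, case_labels,
                resolution=r, n_subsamples=n_subsamples, frac=frac, seed=seed,
            )
        )
    return out


def select_resolution(solutions: list[ClusterSolution]) -> ClusterSolution:
    """Highest cluster score; ties broken by more clusters, then lower
    resolution. The full score table is available on each solution for
    inspection."""
    valid = [s for s in solutions if s.valid]
    if not valid:
        raise ValueError("no valid clustering solution")
    return max(valid, key=lambda s: (s.score, s.n_clusters, -s.resolution))


def characterize(solution: ClusterSolution, input_table: pd.DataFrame,
                 ranking: pd.DataFrame, feature_kinds: dict[str, str] | None = None,
                 top_k: int = 6, oof_probs=None) -> pd.DataFrame:
    """Per-cluster mean of the top_k globally ranked features, recoded for
    comparability: binary features stay as {0,1} means, ordinal scales are
    rescaled to [0,1], continuous features are Z-scored over all subjects.
    Adds the mean predicted probability when oof_probs is given."""
    feats = [f for f in ranking["feature"].tolist() if f in input_table.columns][:top_k]
    kinds = feature_kinds or {}
    recoded = pd.DataFrame(index=input_table.index)
    for f in feats:
        col = input_table[f].astype(float)
        kind = kinds.get(f) or _infer_kind(col)
        if kind == "binary":
            recoded[f] = col
        elif kind == "ordinal":
            span = col.max() - col.min()
            recoded[f] = (col - col.min()) / span if span > 0 else 0.0
        else:
            sd = col.std(ddof=0)
            recoded[f] = (col - col.mean()) / sd if sd > 0 else 0.0
    recoded["cluster"] = solution.labels
    profile = recoded.groupby("cluster").mean()
    if oof_probs is not None:
        profile["mean_prob"] = (
            pd.DataFrame({"p": np.asarray(oof_probs), "cluster": solution.labels})
            .groupby("cluster")["p"].mean()
        )
    return profile


def _infer_kind(col: pd.Series) -> str:
    vals = col.dropna().unique()
    if len(vals) <= 2 and set(vals) <= {0.0, 1.0}:
        return "binary"
    if len(vals) <= 10 and np.allclose(vals, np.round(vals)):
        return "ordinal"
    return "continuous"
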