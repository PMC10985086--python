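"""PCA embedding, SNN-Louvain clustering, the silhouette/F1 resolution
score and cluster characterisation."""

import numpy as np
import pandas as pd
import pytest

from riskcarver.subgroup import (
    ClusterSolution,
    cluster_graph,
    cluster_score,
    characterize,
    embed_pca,
    score_resolution,
    select_resolution,
    weighted_mean,
    weighted_median,
)


def _oracle_weighted_median(values, weights):
    """10-line independent oracle: scan the sorted cumulative weights."""
    pairs = sorted(zip(values, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    for i, (v, w) in enumerate(pairs):
        cum += w
        if cum > total / 2:
            return v
        if cum == total / 2:
            return (v + pairs[i + 1][0]) / 2
    return pairs[-1][0]


def test_weighted_median_matches_oracle_on_random_inputs():
    rng = np.random.default_rng(0)
    for _ in range(200):
        k = rng.integers(1, 12)
        values = rng.random(k)
        weights = rng.integers(1, 10, k).astype(float)
        assert weighted_median(values, weights) == pytest.approx(
            _oracle_weighted_median(values, weights), abs=1e-12
        )


def test_cluster_score_matches_arithmetic_oracle_on_random_inputs():
    rng = np.random.default_rng(1)
    for _ in range(200):
        k = rng.integers(2, 10)
        sil = rng.uniform(-1, 1, k)
        f1 = rng.uniform(0, 0.99, k)
        sizes = rng.integers(1, 50, k).astype(float)
        expected = (np.sum(sil * sizes) / sizes.sum()) / (1 - _oracle_weighted_median(f1, sizes))
        assert cluster_score(sil, f1, sizes) == pytest.approx(expected, abs=1e-12)


def test_cluster_score_worked_instance():
    # sizes {2,2}, silhouettes {0.5,0.3}, F1 {0.8,0.4}:
    # weighted mean 0.4, weighted median 0.6 -> score 1.0
    assert cluster_score([0.5, 0.3], [0.8, 0.4], [2, 2]) == pytest.approx(1.0)


def test_cluster_score_capped_at_perfect_prediction():
    assert np.isinf(cluster_score([0.5, 0.5], [1.0, 1.0], [3, 3]))


def test_pca_variance_ordering_and_sign_convention():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(200, 6)) * np.array([5.0, 3.0, 1.0, 0.5, 0.2, 0.1])
    emb = embed_pca(X, d=4)
    assert emb.scores.shape == (200, 4)
    variances = emb.scores.var(axis=0, ddof=1)
    assert np.all(np.diff(variances) <= 1e-9)
    # eigen-decomposition oracle for the leading variance
    eigvals = np.linalg.eigvalsh(np.cov(X.T))
    assert variances[0] == pytest.approx(eigvals[-1], rel=1e-6)
    # deterministic including signs
    emb2 = embed_pca(X, d=4)
    np.testing.assert_array_equal(emb.scores, emb2.scores)


def test_pca_duplicated_subjects_share_embedding_rows():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(50, 4))
    X[10] = X[3]
    emb = embed_pca(X, d=3)
    np.testing.assert_allclose(emb.scores[10], emb.scores[3], atol=1e-10)


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(4)
    X = np.vstack([rng.normal(0, 1, (250, 5)), rng.normal(10, 1, (250, 5))])
    return embed_pca(X, d=5), np.r_[np.zeros(250, int), np.ones(250, int)]


def test_separated_blobs_yield_two_matching_clusters(blobs):
    emb, truth = blobs
    labels = cluster_graph(emb, resolution=0.5, seed=1)
    assert len(np.unique(labels)) == 2
    # label agreement up to permutation
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)


def test_clustering_deterministic_under_seed(blobs):
    emb, _ = blobs
    a = cluster_graph(emb, resolution=0.5, seed=7)
    b = cluster_graph(emb, resolution=0.5, seed=7)
    np.testing.assert_array_equal(a, b)


def test_clustering_invariant_to_subject_order(blobs):
    from sklearn.metrics import adjusted_rand_score

    emb, _ = blobs
    base = cluster_graph(emb, resolution=0.5, seed=7)
    perm = np.random.default_rng(5).permutation(len(emb.scores))
    from riskcarver.subgroup import Embedding

    emb_perm = Embedding(emb.scores[perm], emb.explained_variance_ratio)
    permuted = cluster_graph(emb_perm, resolution=0.5, seed=7)
    assert adjusted_rand_score(base[perm], permuted) == pytest.approx(1.0)


def test_score_resolution_on_separated_blobs(blobs):
    emb, truth = blobs
    labels = cluster_graph(emb, resolution=0.5, seed=1)
    probs = np.where(truth == 1, 0.9, 0.1)
    sol = score_resolution(emb, labels, probs, truth, resolution=0.5, seed=2)
    assert sol.valid
    assert sol.per_cluster["silhouette"].min() > 0.8
    assert sol.per_cluster["size_frac"].sum() == pytest.approx(1.0)
    case_cluster = sol.per_cluster["case_frac"].idxmax()
    assert sol.per_cluster.loc[case_cluster, "f1"] == pytest.approx(1.0)


def test_single_cluster_solution_is_invalid(blobs):
    emb, truth = blobs
    labels = np.zeros(len(emb.scores), int)
    sol = score_resolution(emb, labels, np.full(len(labels), 0.5), truth, seed=3)
    assert not sol.valid


def _solution(resolution, score, n_clusters):
    per = pd.DataFrame({"size": [10] * n_clusters}, index=range(n_clusters))
    return ClusterSolution(resolution, np.zeros(10, int), per, score, True)


def test_select_resolution_argmax_and_tie_breaks():
    assert select_resolution([_solution(0.3, 1.2, 4), _solution(0.5, 0.9, 8)]).resolution == 0.3
    # equal scores: more clusters wins
    assert select_resolution([_solution(0.3, 1.0, 4), _solution(0.5, 1.0, 6)]).resolution == 0.5
    # still tied: lower resolution wins
    assert select_resolution([_solution(0.6, 1.0, 5), _solution(0.4, 1.0, 5)]).resolution == 0.4
    with pytest.raises(ValueError):
        select_resolution([ClusterSolution(0.3, np.zeros(5, int), pd.DataFrame(), np.nan, False)])


def test_characterize_recodes_by_feature_kind():
    table = pd.DataFrame(
        {
            "drug": [1.0, 1.0, 0.0, 0.0],
            "pace": [0.0, 1.0, 2.0, 2.0],      # ordinal 0..2 -> rescaled to [0,1]
            "bmi": [20.0, 30.0, 20.0, 30.0],
        }
    )
    ranking = pd.DataFrame({"feature": ["drug", "pace", "bmi"]})
    labels = np.array([0, 0, 1, 1])
    sol = ClusterSolution(0.5, labels, pd.DataFrame({"size": [2, 2]}, index=[0, 1]), 1.0, True)
    prof = characterize(sol, table, ranking,
                        feature_kinds={"drug": "binary", "pace": "ordinal", "bmi": "continuous"})
    assert prof.loc[0, "drug"] == 1.0 and prof.loc[1, "drug"] == 0.0
    assert prof.loc[0, "pace"] == pytest.approx(0.25)
    assert prof.loc[1, "pace"] == pytest.approx(1.0)
    # Z-scores across clusters, weighted by cluster size, average to 0
    sizes = np.array([2, 2])
    assert np.average(prof["bmi"], weights=sizes) == pytest.approx(0.0, abs=1e-12)


def test_characterize_identical_cluster_members_reproduce_their_row():
    table = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [0.0, 0.0, 1.0]})
    ranking = pd.DataFrame({"feature": ["a", "b"]})
    labels = np.array([0, 0, 1])
    sol = ClusterSolution(0.5, labels, pd.DataFrame({"size": [2, 1]}, index=[0, 1]), 1.0, True)
    prof = characterize(sol, table, ranking, feature_kinds={"a": "binary", "b": "binary"})
    assert prof.loc[0, "a"] == 1.0 and prof.loc[0, "b"] == 0.0
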