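import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from litmap.corpus import TermList, extract_terms
from litmap.grid import ConfigError
from litmap.semantic_graph import (
    CooccurrenceMatrix,
    EmbeddingTable,
    TermGraph,
    build_cooccurrence,
    community_profiles,
    cosine_knn,
    embed_graph,
    kmeans_cluster,
    kneedle,
    select_k_elbow,
    silhouette_validate,
)
from litmap.synthetic import CorpusConfig, generate_corpus


# ---------------------------------------------------------------------------
# co-occurrence


def test_cooccurrence_hand_count(five_records):
    tl = TermList([("alpha beta", 4), ("gamma delta", 3)])
    co = build_cooccurrence(five_records, tl)
    assert co.counts[0, 1] == 3  # both terms in records 1-3
    assert co.counts[0, 0] == 4  # diagonal = document frequency
    assert co.counts[1, 1] == 3


def test_cooccurrence_symmetric_and_bounded(five_records):
    tl = TermList([("alpha beta", 4), ("gamma delta", 3), ("nothing relevant", 1)])
    co = build_cooccurrence(five_records, tl)
    assert np.array_equal(co.counts, co.counts.T)
    off = co.counts - np.diag(np.diag(co.counts))
    assert (off <= np.minimum.outer(np.diag(co.counts), np.diag(co.counts))).all()
    assert co.counts[0, 2] == 0  # never co-occur


# ---------------------------------------------------------------------------
# cosine kNN graph


def _matrix(rows, terms=None):
    rows = np.asarray(rows)
    terms = terms or [f"t{i} x" for i in range(len(rows))]
    return CooccurrenceMatrix(terms, rows)


def test_cosine_identical_rows_similarity_one():
    g = cosine_knn(_matrix([[2, 1, 0], [2, 1, 0], [0, 0, 5]]), k=2)
    assert g.edges[(0, 1)] == pytest.approx(1.0)


def test_cosine_orthogonal_rows_similarity_zero():
    g = cosine_knn(_matrix([[1, 0, 0], [0, 1, 0], [1, 1, 0]]), k=2)
    assert g.edges[(0, 1)] == pytest.approx(0.0)


def test_knn_capped_at_n_minus_one():
    g = cosine_knn(_matrix(np.eye(3, dtype=int) + 1), k=15)
    for i in range(3):
        assert sum(1 for e in g.edges if i in e) <= 2


def test_row_scaling_invariance():
    rows = np.array([[4, 2, 1], [1, 3, 2], [2, 2, 5]])
    g1 = cosine_knn(_matrix(rows), k=2)
    scaled = rows.astype(float).copy()
    scaled[1] *= 7.3
    g2 = cosine_knn(_matrix(scaled), k=2)
    assert g1.edges.keys() == g2.edges.keys()
    for e in g1.edges:
        assert g1.edges[e] == pytest.approx(g2.edges[e])


def test_zero_row_isolated_with_warning():
    with pytest.warns(UserWarning, match="isolated"):
        g = cosine_knn(_matrix([[1, 1, 0], [1, 2, 0], [0, 0, 0]]), k=2)
    assert not any(2 in e for e in g.edges)


# ---------------------------------------------------------------------------
# embedding


def _two_cliques():
    terms = [f"n{i} x" for i in range(10)]
    edges = {}
    for base in (0, 5):
        for i in range(base, base + 5):
            for j in range(i + 1, base + 5):
                edges[(i, j)] = 1.0
    return TermGraph(terms, edges, 4)


def test_embedding_separates_disconnected_cliques():
    emb = embed_graph(_two_cliques(), d=16, walks_per_node=10, walk_length=20,
                      window=4, epochs=3, seed=0)
    v = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
    sim = v @ v.T
    within = np.mean([sim[i, j] for i in range(5) for j in range(5) if i != j])
    between = np.mean([sim[i, j] for i in range(5) for j in range(5, 10)])
    assert within > between


def test_embedding_deterministic_under_seed():
    e1 = embed_graph(_two_cliques(), d=8, walks_per_node=4, walk_length=10,
                     window=3, epochs=2, seed=42)
    e2 = embed_graph(_two_cliques(), d=8, walks_per_node=4, walk_length=10,
                     window=3, epochs=2, seed=42)
    assert np.array_equal(e1.vectors, e2.vectors)


def test_single_edge_graph_embeds_finite():
    g = TermGraph(["a b", "c d"], {(0, 1): 0.5}, 1)
    emb = embed_graph(g, d=4, walks_per_node=2, walk_length=5, window=2, epochs=1, seed=0)
    assert np.all(np.isfinite(emb.vectors))


def test_too_small_graph_rejected():
    with pytest.raises(ConfigError):
        embed_graph(TermGraph(["a b"], {}, 1), d=4)


# ---------------------------------------------------------------------------
# K-means + model selection


def _blobs(k=2, n=30, d=5, sep=20.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, size=(k, d))
    vecs, labels = [], []
    for i in range(k):
        vecs.append(centers[i] + rng.normal(0, 1.0, size=(n, d)))
        labels += [i] * n
    terms = [f"t{i} x" for i in range(k * n)]
    return EmbeddingTable(terms, np.vstack(vecs)), np.array(labels)


def test_kmeans_recovers_separated_clouds():
    emb, truth = _blobs(k=2)
    sol = kmeans_cluster(emb, 2, seed=0)
    pred = [sol.labels[t] for t in emb.terms]
    assert adjusted_rand_score(truth, pred) == 1.0


def test_kmeans_k1_inertia_is_total_scatter():
    emb, _ = _blobs(k=1, n=20)
    sol = kmeans_cluster(emb, 1, seed=0)
    centered = emb.vectors - emb.vectors.mean(axis=0)
    assert sol.inertia == pytest.approx((centered**2).sum())


def test_kmeans_k_equals_n_zero_inertia():
    emb, _ = _blobs(k=1, n=6)
    sol = kmeans_cluster(emb, 6, seed=0)
    assert sol.inertia == pytest.approx(0.0, abs=1e-9)


def test_kmeans_k_exceeding_n_rejected():
    emb, _ = _blobs(k=1, n=5)
    with pytest.raises(ConfigError, match="k"):
        kmeans_cluster(emb, 6)


def test_kneedle_hand_evaluated_example():
    """Inertia curve [100, 20, 18, 17, 16] over k=1..5: the normalized
    difference curve peaks at k=2 and clears the S=1 threshold."""
    assert kneedle(np.arange(1, 6), np.array([100.0, 20, 18, 17, 16])) == 2


def test_kneedle_linear_curve_has_no_knee():
    assert kneedle(np.arange(1, 6), np.array([50.0, 40, 30, 20, 10])) is None


def test_select_k_recovers_planted_count():
    emb, _ = _blobs(k=4, n=25, sep=25.0, seed=3)
    res = select_k_elbow(emb, list(range(2, 9)), seed=0)
    assert res.k == 4
    assert len(res.trace) == 7


def test_select_k_requires_four_values():
    emb, _ = _blobs(k=2, n=10)
    with pytest.raises(ConfigError, match="k_range"):
        select_k_elbow(emb, [2, 3, 4])


def test_silhouette_far_clusters_near_one_random_near_zero():
    emb, truth = _blobs(k=2, n=25, sep=40.0, seed=1)
    labels = {t: int(l) for t, l in zip(emb.terms, truth)}
    out = silhouette_validate(emb, {2: labels})
    assert out[2] > 0.9
    rng = np.random.default_rng(0)
    one_cloud, _ = _blobs(k=1, n=50, seed=2)
    rand_labels = {t: int(l) for t, l in zip(one_cloud.terms, rng.integers(0, 2, 50))}
    assert abs(silhouette_validate(one_cloud, {2: rand_labels})[2]) < 0.1


def test_silhouette_k1_rejected():
    emb, _ = _blobs(k=1, n=5)
    with pytest.raises(ConfigError):
        silhouette_validate(emb, {1: {t: 0 for t in emb.terms}})


# ---------------------------------------------------------------------------
# community profiles


def test_profiles_hand_built_degrees():
    """4-node community: t0 connects to t1,t2,t3 (3 intra edges); t3 also
    links to the other community, which must not count."""
    terms = ["t0 x", "t1 x", "t2 x", "t3 x", "u0 x", "u1 x"]
    edges = {(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0, (3, 4): 1.0, (4, 5): 1.0}
    graph = TermGraph(terms, edges, 3)
    from litmap.semantic_graph import ClusterSolution

    sol = ClusterSolution(2, {t: (0 if t[0] == "t" else 1) for t in terms}, 0.0)
    tl = TermList([(t, 10 - i) for i, t in enumerate(terms)])
    prof = community_profiles(sol, tl, graph, top_n=4)
    assert prof[0]["by_degree"][0] == "t0 x"  # 3 intra edges
    assert prof[0]["by_frequency"] == ["t0 x", "t1 x", "t2 x", "t3 x"]
    assert prof[1]["by_frequency"][0] == "u0 x"


def test_profiles_singleton_community():
    terms = ["a x", "b x"]
    graph = TermGraph(terms, {(0, 1): 1.0}, 1)
    from litmap.semantic_graph import ClusterSolution

    sol = ClusterSolution(2, {"a x": 0, "b x": 1}, 0.0)
    prof = community_profiles(sol, TermList([("a x", 5), ("b x", 3)]), graph)
    assert prof[0] == {"by_frequency": ["a x"], "by_degree": ["a x"]}


# ---------------------------------------------------------------------------
# cross-granularity stability


def test_stability_across_granularity_levels():
    """Re-clustering with the top 50% of terms assigns >= 90% of the shared
    terms to matching communities (Hungarian-aligned labels)."""
    records, truth = generate_corpus(
        CorpusConfig(n_communities=4, terms_per_community=25,
                     n_articles_per_community=80, cross_community_mixing=0.02, seed=17)
    )
    tl_full = extract_terms(records, 100)
    labels = {}
    for frac, tl in (("full", tl_full), ("half", tl_full.head(50))):
        co = build_cooccurrence(records, tl)
        g = cosine_knn(co, k=10)
        emb = embed_graph(g, d=32, walks_per_node=8, walk_length=20, window=4,
                          epochs=3, seed=7)
        labels[frac] = kmeans_cluster(emb, 4, seed=7).labels
    shared = sorted(set(labels["full"]) & set(labels["half"]))
    cm = np.zeros((4, 4))
    for t in shared:
        cm[labels["full"][t], labels["half"][t]] += 1
    r, c = linear_sum_assignment(-cm)
    assert cm[r, c].sum() / len(shared) >= 0.9
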