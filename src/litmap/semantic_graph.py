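"""Term co-occurrence graph, embedding, clustering and model selection.

The semantic structure of a corpus is summarized as a graph whose nodes
are the top-frequency multiword terms and whose edges carry the cosine
similarity between term co-occurrence profiles, sparsified to each term's
k nearest neighbors. The graph is embedded with node2vec and partitioned
with K-means; the number of communities is chosen by the Kneedle elbow
criterion on the inertia curve and validated post hoc with the mean
silhouette.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from . import _node2vec
from .corpus import BibRecord, TermList, detect_terms
from .grid import ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "CooccurrenceMatrix",
    "TermGraph",
    "EmbeddingTable",
    "ClusterSolution",
    "ElbowResult",
    "build_cooccurrence",
    "cosine_knn",
    "embed_graph",
    "kmeans_cluster",
    "kneedle",
    "select_k_elbow",
    "silhouette_validate",
    "community_profiles",
]


@dataclass
class CooccurrenceMatrix:
    """Symmetric abstract-level co-occurrence counts.

    Entry (i, j), i != j, is the number of records whose detected-term set
    contains both terms; the diagonal is each term's document frequency.
    """

    terms: list[str]
    counts: np.ndarray

    def __post_init__(self):
        n = len(self.terms)
        if self.counts.shape != (n, n):
            raise ConfigError("counts: shape mismatch with terms")


@dataclass
class TermGraph:
    """Union-symmetrized cosine kNN graph over terms (weights in [0, 1])."""

    terms: list[str]
    edges: dict[tuple[int, int], float]  # i < j
    k_neighbors: int

    def degree(self, i: int) -> int:
        return sum(1 for a, b in self.edges if a == i or b == i)

    def to_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sorted-adjacency CSR arrays for the walk generator."""
        n = len(self.terms)
        adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for (i, j), w in self.edges.items():
            adj[i].append((j, w))
            adj[j].append((i, w))
        indptr = np.zeros(n + 1, dtype=np.int64)
        idx: list[int] = []
        wts: list[float] = []
        for i in range(n):
            nbrs = sorted(adj[i])
            indptr[i + 1] = indptr[i] + len(nbrs)
            idx.extend(j for j, _ in nbrs)
            wts.extend(w for _, w in nbrs)
        return indptr, np.array(idx, dtype=np.int64), np.array(wts)


@dataclass
class EmbeddingTable:
    """One vector per term plus the training metadata."""

    terms: list[str]
    vectors: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.vectors.shape[0] != len(self.terms):
            raise ConfigError("vectors: row count mismatch with terms")
        if not np.all(np.isfinite(self.vectors)):
            raise ConfigError("vectors: non-finite entries")


@dataclass
class ClusterSolution:
    k: int
    labels: dict[str, int]
    inertia: float
    silhouette_mean: float | None = None
    selection_trace: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class ElbowResult:
    k: int | None  # None = no knee found
    trace: list[tuple[int, float]]


# ---------------------------------------------------------------------------


def build_cooccurrence(records: list[BibRecord], term_list: TermList) -> CooccurrenceMatrix:
    """Count, for every term pair, the records containing both terms.

    Each record contributes at most 1 to any entry (binary, abstract-level
    co-occurrence); the diagonal is the per-term document frequency.
    """
    if not len(term_list):
        raise ConfigError("term_list: empty")
    terms = term_list.term_strings
    pos = {t: i for i, t in enumerate(terms)}
    inc = np.zeros((len(records), len(terms)), dtype=np.int64)
    for r_i, rec in enumerate(records):
        for t in detect_terms(rec, term_list):
            inc[r_i, pos[t]] = 1
    counts = inc.T @ inc
    return CooccurrenceMatrix(list(terms), counts)


def cosine_knn(matrix: CooccurrenceMatrix, k: int = 15, include_diagonal: bool = True) -> TermGraph:
    """Cosine-similarity k-nearest-neighbor graph of co-occurrence rows.

    For each node the ``k`` most similar partners (excluding self) are
    selected, ties broken lexicographically by term; the edge set is the
    union of the per-node selections. Rows of all zeros yield isolated
    nodes (warned). Scaling any row by a positive constant leaves the
    weights unchanged.
    """
    if k < 1:
        raise ConfigError("k: must be >= 1")
    rows = matrix.counts.astype(float)
    if not include_diagonal:
        rows = rows.copy()
        np.fill_diagonal(rows, 0.0)
    norms = np.linalg.norm(rows, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} term(s) with all-zero co-occurrence rows are isolated",
            stacklevel=2,
        )
    unit = rows / np.where(norms == 0, 1.0, norms)[:, None]
    sim = np.clip(unit @ unit.T, 0.0, 1.0)

    n = len(matrix.terms)
    kk = min(k, n - 1)
    terms = matrix.terms
    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        if zero[i]:
            continue
        cand = [(-sim[i, j], terms[j], j) for j in range(n) if j != i and not zero[j]]
        cand.sort()
        for _negs, _t, j in cand[:kk]:
            a, b = (i, j) if i < j else (j, i)
            edges[(a, b)] = float(sim[i, j])
    return TermGraph(list(terms), edges, k)


def embed_graph(
    graph: TermGraph,
    d: int = 700,
    p: float = 1.0,
    q: float = 1.0,
    walks_per_node: int = 20,
    walk_length: int = 30,
    window: int = 10,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    seed: int = 0,
) -> EmbeddingTable:
    """node2vec embedding of the term graph.

    Biased second-order random walks (return parameter ``p``, in-out
    parameter ``q``, transitions proportional to edge weight within the
    bias scheme) generate a corpus of node sequences; a skip-gram
    negative-sampling objective trains one ``d``-vector per node. The run
    is seeded end-to-end and single-threaded, so results are reproducible.
    """
    n = len(graph.terms)
    if n < 2:
        raise ConfigError("graph: need >= 2 nodes")
    if not graph.edges:
        raise ConfigError("graph: no edges")
    indptr, indices, weights = graph.to_csr()
    iso = np.flatnonzero(np.diff(indptr) == 0)
    if iso.size:
        warnings.warn(f"{iso.size} isolated node(s) embedded from self-only walks", stacklevel=2)
    walks = _node2vec.generate_walks(
        indptr, indices, weights, walk_length, walks_per_node, p, q, seed % (2**31 - 1)
    )
    counts = np.bincount(walks.ravel(), minlength=n).astype(float)
    noise = counts**0.75
    neg_cum = np.cumsum(noise / noise.sum())
    vectors = _node2vec.train_sgns(
        walks, n, d, window, epochs, negative, alpha, neg_cum, seed % (2**31 - 1)
    )
    meta = dict(
        d=d, p=p, q=q, walks_per_node=walks_per_node, walk_length=walk_length,
        window=window, epochs=epochs, negative=negative, alpha=alpha, seed=seed,
    )
    return EmbeddingTable(list(graph.terms), vectors, meta)


# ---------------------------------------------------------------------------
# clustering and model selection


def kmeans_cluster(
    embedding: EmbeddingTable, k: int, n_restarts: int = 10, seed: int = 0
) -> ClusterSolution:
    """Best-inertia K-means over ``n_restarts`` k-means++ initializations."""
    n = len(embedding.terms)
    if k > n:
        raise ConfigError(f"k: {k} exceeds number of terms {n}")
    if k < 1:
        raise ConfigError("k: must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2**32 - 1))
    labels = km.fit_predict(embedding.vectors)
    sil = None
    if 2 <= k <= n - 1:
        sil = float(silhouette_score(embedding.vectors, labels))
    return ClusterSolution(
        k=k,
        labels={t: int(l) for t, l in zip(embedding.terms, labels)},
        inertia=float(km.inertia_),
        silhouette_mean=sil,
    )


def kneedle(
    x: np.ndarray, y: np.ndarray, S: float = 1.0
) -> float | None:
    """Knee of a decreasing convex curve (Kneedle algorithm).

    Both axes are normalized to [0, 1]; the curve is flipped to increasing
    concave form and the difference to the diagonal is scanned for a local
    maximum that stays above its sensitivity threshold
    ``d_max - S * mean(dx)`` until the curve drops below it. Returns the
    x value at the knee, or None when the curve has no knee (for example
    when it is a straight line).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ConfigError("x: kneedle needs >= 4 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    xn = (x - x.min()) / np.ptp(x)
    yn = (y - y.min()) / np.ptp(y)
    d = (1.0 - yn) - xn  # flip decreasing-convex to concave, diff to diagonal
    lmx = [
        i
        for i in range(1, len(d) - 1)
        if d[i] > d[i - 1] and d[i] >= d[i + 1]
    ]
    if not lmx:
        return None
    mean_dx = float(np.mean(np.diff(xn)))
    for li, i in enumerate(lmx):
        thresh = d[i] - S * mean_dx
        j_end = lmx[li + 1] if li + 1 < len(lmx) else len(d)
        for j in range(i + 1, j_end):
            if d[j] < thresh:
                return float(x[i])
    return None


def select_k_elbow(
    embedding: EmbeddingTable,
    k_range: list[int],
    S: float = 1.0,
    n_restarts: int = 10,
    seed: int = 0,
) -> ElbowResult:
    """Scan k over ``k_range``, fit K-means, and return the Kneedle knee
    of the (k, inertia) curve; ``k=None`` signals "no knee", never a guess."""
    ks = sorted(k_range)
    if len(ks) < 4:
        raise ConfigError("k_range: need >= 4 values")
    trace = []
    for k in ks:
        sol = kmeans_cluster(embedding, k, n_restarts=n_restarts, seed=seed)
        trace.append((k, sol.inertia))
    knee = kneedle(np.array([t[0] for t in trace]), np.array([t[1] for t in trace]), S=S)
    return ElbowResult(int(knee) if knee is not None else None, trace)


def silhouette_validate(
    embedding: EmbeddingTable, labels_by_k: dict[int, dict[str, int]]
) -> dict[int, float]:
    """Mean silhouette s(i) = (b - a)/max(a, b) for each candidate k."""
    out = {}
    for k, labels in labels_by_k.items():
        if k < 2:
            raise ConfigError("k: silhouette undefined for k < 2")
        lab = np.array([labels[t] for t in embedding.terms])
        out[k] = float(silhouette_score(embedding.vectors, lab))
    return out


def community_profiles(
    solution: ClusterSolution,
    term_list: TermList,
    graph: TermGraph,
    top_n: int = 4,
) -> dict[int, dict[str, list[str]]]:
    """Most frequent and most intra-connected terms of each community.

    ``by_frequency`` ranks by corpus frequency; ``by_degree`` by the number
    of graph edges to same-community terms. Ties break lexicographically.
    """
    freq = dict(term_list.terms)
    idx = {t: i for i, t in enumerate(graph.terms)}
    wdeg: dict[str, int] = {t: 0 for t in solution.labels}
    for (i, j), _w in graph.edges.items():
        ti, tj = graph.terms[i], graph.terms[j]
        if solution.labels.get(ti) == solution.labels.get(tj):
            wdeg[ti] += 1
            wdeg[tj] += 1
    out: dict[int, dict[str, list[str]]] = {}
    for c in sorted(set(solution.labels.values())):
        members = [t for t, l in solution.labels.items() if l == c]
        by_freq = sorted(members, key=lambda t: (-freq.get(t, 0), t))[:top_n]
        by_deg = sorted(members, key=lambda t: (-wdeg[t], t))[:top_n]
        out[c] = {"by_frequency": by_freq, "by_degree": by_deg}
    return out
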