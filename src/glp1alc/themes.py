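"""Theme discovery: embed cleaned posts, pick k by the distortion knee,
cluster with k-means, merge clusters into named themes, and project to 2-D.

The default encoder is a deterministic feature-hashing encoder producing
512-dimensional L2-normalised vectors, so the whole pipeline runs offline;
any pretrained sentence encoder exposing the same ``encode_tokens``
contract (deterministic token sequence -> fixed-length vector) can be
plugged in instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Protocol, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.feature_extraction.text import HashingVectorizer

from .corpus import Corpus

__all__ = [
    "Encoder",
    "HashedEncoder",
    "EmbeddingMatrix",
    "DistortionCurve",
    "ClusterSolution",
    "encode",
    "sweep_kmeans",
    "find_knee",
    "merge_clusters",
    "suggest_merges",
    "project_2d",
]


class Encoder(Protocol):
    dim: int
    encoder_id: str

    def encode_tokens(self, docs: Sequence[Sequence[str]]) -> np.ndarray: ...


class HashedEncoder:
    """Deterministic hashed bag-of-tokens encoder (L2-normalised)."""

    def __init__(self, dim: int = 512):
        self.dim = dim
        self.encoder_id = f"hashed-unigram-{dim}"
        self._vec = HashingVectorizer(
            n_features=dim,
            norm="l2",
            alternate_sign=True,
            analyzer=_identity,
            lowercase=False,
        )

    def encode_tokens(self, docs: Sequence[Sequence[str]]) -> np.ndarray:
        if len(docs) == 0:
            return np.zeros((0, self.dim))
        X = self._vec.transform(docs).toarray()
        return X


def _identity(x):
    return x


@dataclass
class EmbeddingMatrix:
    vectors: np.ndarray  # n_posts x d
    encoder_id: str

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains NaN/Inf")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


@dataclass
class DistortionCurve:
    """Within-cluster sum of squared distances as a function of k."""

    ks: list[int]
    distortions: list[float]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.ks, self.ks[1:])):
            raise ValueError("ks must be strictly increasing")
        drops = [b - a for a, b in zip(self.distortions, self.distortions[1:])]
        if any(d > 1e-8 * max(1.0, abs(self.distortions[0])) for d in drops):
            warnings.warn("distortion curve is not nonincreasing (solver noise?)")


@dataclass
class ClusterSolution:
    labels: np.ndarray  # per-post theme id, dense 0..k-1
    k: int
    seed: int
    centroids: np.ndarray | None = None
    theme_names: list[str] | None = None
    merge_map: dict[int, str] | None = None
    raw: "ClusterSolution | None" = None  # provenance before merging

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError("theme ids must be dense 0..k-1 with every id present")


def encode(corpus: Corpus, encoder: Encoder | None = None) -> EmbeddingMatrix:
    """One vector per post, in corpus order; empty posts map to the zero
    vector (with a warning)."""
    encoder = encoder or HashedEncoder()
    X = encoder.encode_tokens(corpus.cleaned)
    if X.shape[0] != len(corpus):
        raise ValueError("encoder returned a row count different from the corpus size")
    if X.ndim != 2:
        raise ValueError("encoder must return a 2-D matrix")
    empty = [i for i, t in enumerate(corpus.cleaned) if len(t) == 0]
    if empty:
        warnings.warn(f"{len(empty)} empty post(s) encoded as zero vectors")
    return EmbeddingMatrix(vectors=X, encoder_id=encoder.encoder_id)


def sweep_kmeans(
    emb: EmbeddingMatrix,
    ks: Sequence[int],
    seed: int,
    n_init: int = 10,
) -> tuple[DistortionCurve, dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Best-of-``n_init`` k-means for each candidate k.

    Returns the distortion curve (inertia: summed squared Euclidean
    distances to assigned centroids), per-k label arrays and per-k
    centroid matrices.
    """
    ks = list(ks)
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise ValueError("ks must be strictly increasing")
    if max(ks) > emb.n:
        raise ValueError(f"k={max(ks)} exceeds the number of posts ({emb.n})")
    distortions: list[float] = []
    labelings: dict[int, np.ndarray] = {}
    centroids: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labelings[k] = km.fit_predict(emb.vectors)
        centroids[k] = km.cluster_centers_
        distortions.append(float(km.inertia_))
    return DistortionCurve(ks=ks, distortions=distortions), labelings, centroids


def find_knee(curve: DistortionCurve, tol: float = 1e-9) -> int | None:
    """Knee of a decreasing distortion curve.

    Both axes are min-max normalised; the knee is the point at maximum
    perpendicular distance from the chord joining the endpoints
    (kneedle-style).  Ties break toward the smallest k; a curve that is
    linear to within ``tol`` has no knee and returns ``None``.
    """
    ks = np.asarray(curve.ks, dtype=float)
    ds = np.asarray(curve.distortions, dtype=float)
    if len(ks) < 3:
        raise ValueError("need at least 3 points to locate a knee")
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    span = ds[0] - ds[-1]
    if abs(span) < tol:
        return None
    y = (ds - ds[-1]) / span
    # chord from (0, y0) to (1, y_last) in normalised coords is x + y = 1
    dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    best = float(dist.max())
    if best <= tol:
        return None
    return int(ks[int(np.argmax(dist))])  # argmax returns the first (smallest k) tie


def merge_clusters(sol: ClusterSolution, merge_map: Mapping[int, str]) -> ClusterSolution:
    """Relabel raw clusters into named themes.

    ``merge_map`` must cover every raw cluster id exactly once; theme ids
    in the result are dense, ordered by first appearance of each theme
    name over raw ids.  The raw solution is retained as provenance.
    """
    raw_ids = set(range(sol.k))
    mapped = set(merge_map)
    if mapped != raw_ids:
        missing = sorted(raw_ids - mapped)
        extra = sorted(mapped - raw_ids)
        raise ValueError(
            f"merge map must cover raw ids exactly once; missing={missing}, unknown={extra}"
        )
    names: list[str] = []
    for rid in range(sol.k):
        name = merge_map[rid]
        if name not in names:
            names.append(name)
    name_to_id = {name: i for i, name in enumerate(names)}
    lut = np.array([name_to_id[merge_map[rid]] for rid in range(sol.k)])
    return ClusterSolution(
        labels=lut[sol.labels],
        k=len(names),
        seed=sol.seed,
        centroids=None,
        theme_names=names,
        merge_map=dict(merge_map),
        raw=sol,
    )


def suggest_merges(
    sol: ClusterSolution,
    corpus: Corpus,
    top_n: int = 100,
    threshold: float = 0.5,
) -> dict[int, str]:
    """Propose a merge map from top-keyword overlap.

    Cluster pairs whose top-``top_n`` unigram sets have Jaccard similarity
    at or above ``threshold`` are grouped (with transitive closure); the
    proposal names each group after its smallest member id.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    from collections import Counter

    tops: list[set[str]] = []
    for cid in range(sol.k):
        counts: Counter[str] = Counter()
        for toks, lab in zip(corpus.cleaned, sol.labels):
            if lab == cid:
                counts.update(toks)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        tops.append({t for t, _ in ranked})

    parent = list(range(sol.k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(sol.k):
        for j in range(i + 1, sol.k):
            union = tops[i] | tops[j]
            if not union:
                continue
            jac = len(tops[i] & tops[j]) / len(union)
            if jac >= threshold:
                parent[find(j)] = find(i)

    return {cid: f"theme_{find(cid)}" for cid in range(sol.k)}


def project_2d(
    emb: EmbeddingMatrix,
    seed: int,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """Neighbourhood-preserving 2-D projection (UMAP) for visualisation only."""
    if emb.n < 10:
        raise ValueError("2-D projection needs at least 10 points")
    import umap  # deferred: heavy import

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that a fixed seed disables parallelism
        coords = reducer.fit_transform(emb.vectors)
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("projection produced non-finite coordinates")
    return coords
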