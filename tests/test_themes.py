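import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from glp1alc.themes import (
    ClusterSolution,
    DistortionCurve,
    EmbeddingMatrix,
    HashedEncoder,
    encode,
    find_knee,
    merge_clusters,
    project_2d,
    suggest_merges,
    sweep_kmeans,
)

from conftest import corpus_from_tokens


class TestEncoder:
    def test_default_dimension_is_512(self):
        vec = HashedEncoder().encode_tokens([["ozempic", "nausea"]])
        assert vec.shape == (1, 512)

    def test_identical_texts_identical_vectors(self, two_topic_corpus):
        corpus, _, _ = two_topic_corpus
        emb1 = encode(corpus)
        emb2 = encode(corpus)
        assert np.array_equal(emb1.vectors, emb2.vectors)
        assert emb1.encoder_id == "hashed-unigram-512"

    def test_empty_post_is_zero_vector_with_warning(self):
        corpus = corpus_from_tokens([["word"] * 5, []])
        with pytest.warns(UserWarning, match="empty"):
            emb = encode(corpus)
        assert np.all(emb.vectors[1] == 0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            EmbeddingMatrix(vectors=np.array([[np.nan, 1.0]]), encoder_id="x")


class TestSweep:
    def test_distortion_zero_at_k_equals_n(self):
        X = np.eye(4)
        emb = EmbeddingMatrix(vectors=X, encoder_id="t")
        curve, _, _ = sweep_kmeans(emb, [2, 3, 4], seed=0)
        assert curve.distortions[-1] == pytest.approx(0.0, abs=1e-12)

    def test_separated_topics_halve_distortion(self):
        # long posts over small disjoint lexicons embed as two tight clouds
        from datetime import date
        from glp1alc.corpus import preprocess_corpus
        from glp1alc.synthetic import CorpusSpec, disjoint_topics, generate_corpus

        spec = CorpusSpec(
            n_posts=300,
            n_users=50,
            date_range=(date(2021, 1, 1), date(2022, 1, 1)),
            topics=disjoint_topics(2, lexicon_size=20, mean_length=150),
            alcohol_rate_by_topic={},
            reduction_rate=0.0,
            seed=11,
            filler_rate=0.1,
        )
        posts, _ = generate_corpus(spec)
        emb = encode(preprocess_corpus(posts))
        curve, _, _ = sweep_kmeans(emb, [1, 2], seed=0)
        assert curve.distortions[1] < 0.5 * curve.distortions[0]

    def test_deterministic_given_seed(self, two_topic_corpus):
        corpus, _, _ = two_topic_corpus
        emb = encode(corpus)
        c1, l1, _ = sweep_kmeans(emb, [2, 3], seed=7)
        c2, l2, _ = sweep_kmeans(emb, [2, 3], seed=7)
        assert c1.distortions == c2.distortions
        assert all(np.array_equal(l1[k], l2[k]) for k in (2, 3))

    def test_k_above_n_rejected(self):
        emb = EmbeddingMatrix(vectors=np.eye(3), encoder_id="t")
        with pytest.raises(ValueError, match="exceeds"):
            sweep_kmeans(emb, [2, 4], seed=0)

    def test_recovery_at_true_k(self, two_topic_corpus):
        corpus, truth, true_labels = two_topic_corpus
        emb = encode(corpus)
        _, labelings, _ = sweep_kmeans(emb, [2], seed=0)
        assert adjusted_rand_score(true_labels, labelings[2]) > 0.9


def brute_force_knee(ks, ds):
    """Independent oracle: max distance to the chord over all points,
    computed from the raw two-point line formula."""
    ks = np.asarray(ks, float)
    ds = np.asarray(ds, float)
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    y = (ds - ds.min()) / (ds.max() - ds.min())
    x1, y1, x2, y2 = x[0], y[0], x[-1], y[-1]
    denom = np.hypot(y2 - y1, x2 - x1)
    dist = np.abs((y2 - y1) * x - (x2 - x1) * y + x2 * y1 - y2 * x1) / denom
    if dist.max() <= 1e-9:
        return None
    return int(ks[int(np.argmax(dist))])


class TestKnee:
    def test_linear_curve_has_no_knee(self):
        assert find_knee(DistortionCurve([1, 2, 3], [100.0, 99.0, 98.0])) is None

    def test_hand_curve(self):
        curve = DistortionCurve([1, 2, 3, 4, 5], [100.0, 30.0, 25.0, 22.0, 20.0])
        assert find_knee(curve) == 2 == brute_force_knee(curve.ks, curve.distortions)

    def test_matches_brute_force_on_random_convex_curves(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            drops = np.sort(rng.gamma(1.0, 5.0, size=n))[::-1]
            ds = 1000 - np.cumsum(drops)
            ks = list(range(1, n + 1))
            curve = DistortionCurve(ks, list(ds))
            assert find_knee(curve) == brute_force_knee(ks, ds)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            find_knee(DistortionCurve([1, 2], [5.0, 1.0]))


class TestMerge:
    def _sol(self, labels, k):
        return ClusterSolution(labels=np.asarray(labels), k=k, seed=0)

    def test_identity_map_keeps_labels(self):
        sol = self._sol([0, 1, 2, 0], 3)
        merged = merge_clusters(sol, {0: "a", 1: "b", 2: "c"})
        assert np.array_equal(merged.labels, sol.labels)
        assert merged.raw is sol

    def test_thirteen_raw_to_eight_themes(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 13, size=400)
        labels[:13] = np.arange(13)  # every raw id present
        sol = self._sol(labels, 13)
        merge_map = {i: f"theme_{i % 8}" for i in range(13)}
        merged = merge_clusters(sol, merge_map)
        assert merged.k == 8
        assert set(np.unique(merged.labels)) == set(range(8))

    def test_all_to_one(self):
        sol = self._sol([0, 1, 2], 3)
        merged = merge_clusters(sol, {0: "one", 1: "one", 2: "one"})
        assert merged.k == 1 and np.all(merged.labels == 0)

    def test_cocluster_preserved(self):
        rng = np.random.default_rng(1)
        labels = np.concatenate([np.arange(5), rng.integers(0, 5, 100)])
        sol = self._sol(labels, 5)
        merged = merge_clusters(sol, {0: "x", 1: "x", 2: "y", 3: "y", 4: "z"})
        for raw in range(5):
            assert len(np.unique(merged.labels[labels == raw])) == 1

    def test_uncovered_id_rejected(self):
        sol = self._sol([0, 1], 2)
        with pytest.raises(ValueError, match="missing"):
            merge_clusters(sol, {0: "a"})


class TestSuggestMerges:
    def test_identical_clusters_proposed_for_merge(self):
        toks = [["drug", "dose", "pen"]] * 6
        corpus = corpus_from_tokens(toks)
        sol = ClusterSolution(labels=np.array([0, 0, 0, 1, 1, 1]), k=2, seed=0)
        proposal = suggest_merges(sol, corpus, top_n=10, threshold=0.5)
        assert proposal[0] == proposal[1]

    def test_disjoint_clusters_left_alone(self):
        toks = [["insulin", "sugar"]] * 3 + [["pharmacy", "refill"]] * 3
        corpus = corpus_from_tokens(toks)
        sol = ClusterSolution(labels=np.array([0, 0, 0, 1, 1, 1]), k=2, seed=0)
        proposal = suggest_merges(sol, corpus, top_n=10, threshold=0.5)
        assert proposal[0] != proposal[1]

    def test_overclustered_topic_split_is_detected(self, two_topic_corpus):
        corpus, _, _ = two_topic_corpus
        from glp1alc.themes import encode, sweep_kmeans

        emb = encode(corpus)
        _, labelings, _ = sweep_kmeans(emb, [3], seed=0)  # true k is 2
        sol = ClusterSolution(labels=labelings[3], k=3, seed=0)
        proposal = suggest_merges(sol, corpus, top_n=100, threshold=0.5)
        assert len(set(proposal.values())) == 2


class TestProjection:
    def test_shape_determinism_and_separation(self, two_topic_corpus):
        corpus, truth, labels = two_topic_corpus
        sub = corpus_from_tokens(corpus.cleaned[:300])
        emb = encode(sub)
        xy1 = project_2d(emb, seed=3)
        xy2 = project_2d(emb, seed=3)
        assert xy1.shape == (300, 2) and np.all(np.isfinite(xy1))
        assert np.allclose(xy1, xy2)
        lab = np.asarray(labels[:300])
        c0, c1 = xy1[lab == 0].mean(axis=0), xy1[lab == 1].mean(axis=0)
        spread = np.mean(
            [np.linalg.norm(xy1[lab == g] - c, axis=1).mean() for g, c in ((0, c0), (1, c1))]
        )
        assert np.linalg.norm(c0 - c1) > spread

    def test_too_few_points(self):
        emb = EmbeddingMatrix(vectors=np.eye(5), encoder_id="t")
        with pytest.raises(ValueError, match="at least 10"):
            project_2d(emb, seed=0)
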