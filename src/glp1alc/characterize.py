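"""What drives each theme: one-vs-rest random-forest feature importances,
per-theme n-gram tables and overall theme shares."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import CountVectorizer

from .corpus import Corpus

__all__ = [
    "FeatureImportanceTable",
    "cluster_importance",
    "ngram_table",
    "theme_share",
]


@dataclass
class FeatureImportanceTable:
    theme: int
    features: list[tuple[str, float]]  # (token or bigram, weight), sorted descending
    classifier_seed: int

    def __post_init__(self) -> None:
        weights = [w for _, w in self.features]
        if any(w < 0 for w in weights):
            raise ValueError("importance weights must be nonnegative")
        if any(b > a + 1e-12 for a, b in zip(weights, weights[1:])):
            raise ValueError("features must be sorted by descending weight")
        if sum(weights) > 1 + 1e-9:
            raise ValueError("reported weights cannot exceed total importance 1")


def _split(text: str) -> list[str]:
    return text.split()


def _key(t):
    """Theme labels may be ints or names; normalise numpy scalars."""
    try:
        return int(t)
    except (TypeError, ValueError):
        return str(t)


def cluster_importance(
    corpus: Corpus,
    labels: np.ndarray,
    top_k: int = 20,
    seed: int = 0,
    min_df: int = 5,
    n_estimators: int = 200,
) -> list[FeatureImportanceTable]:
    """Per-theme one-vs-rest random forests on unigram+bigram counts.

    For each theme the posts of that theme are labelled 1 and the rest 0;
    a random forest is trained on token-count features of the cleaned
    text and the ``top_k`` features by impurity importance are reported.
    """
    labels = np.asarray(labels)
    themes = np.unique(labels)
    if themes.size < 2:
        raise ValueError("need at least 2 themes for one-vs-rest importance")
    for t in themes:
        if (labels == t).sum() < 2:
            raise ValueError(f"theme {t} has fewer than 2 posts")

    vec = CountVectorizer(
        tokenizer=_split, ngram_range=(1, 2), min_df=min_df, lowercase=False,
        token_pattern=None,
    )
    X = vec.fit_transform(corpus.texts)
    vocab = np.asarray(vec.get_feature_names_out())

    tables = []
    for t in themes:
        y = (labels == t).astype(int)
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
        clf.fit(X, y)
        imp = clf.feature_importances_
        order = np.lexsort((vocab, -imp))[:top_k]
        tables.append(
            FeatureImportanceTable(
                theme=int(t),
                features=[(str(vocab[i]), float(imp[i])) for i in order],
                classifier_seed=seed,
            )
        )
    return tables


def ngram_table(
    corpus: Corpus,
    labels: np.ndarray,
    n: int = 1,
    top_k: int = 30,
) -> dict[int, list[tuple[str, int]]]:
    """Top-``top_k`` unigrams (n=1) or adjacent bigrams (n=2) per theme,
    counted on cleaned tokens; ties break lexicographically."""
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    labels = np.asarray(labels)
    out: dict[int, list[tuple[str, int]]] = {}
    for t in np.unique(labels):
        counts: Counter[str] = Counter()
        for toks, lab in zip(corpus.cleaned, labels):
            if lab != t:
                continue
            if n == 1:
                counts.update(toks)
            else:
                counts.update(f"{a} {b}" for a, b in zip(toks, toks[1:]))
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out[_key(t)] = ranked[:top_k]
    return out


def theme_share(labels: np.ndarray) -> dict[int, float]:
    """Proportion of posts per theme; proportions sum to 1 exactly
    (up to float addition) before any rounding for display."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    uniq, counts = np.unique(labels, return_counts=True)
    total = labels.size
    return {_key(t): float(c) / total for t, c in zip(uniq, counts)}
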