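"""Keyword mining: locate keyword posts, build prefix/suffix word trees,
flag reduction-related posts, and test per-theme enrichment with an exact
upper-tail hypergeometric probability."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .corpus import Corpus

__all__ = [
    "KeywordHit",
    "KeywordHits",
    "WordTreeNode",
    "WordTree",
    "ReductionSummary",
    "EnrichmentResult",
    "DEFAULT_REDUCTION_LEXICON",
    "match_keyword",
    "build_word_tree",
    "classify_reduction",
    "enrichment",
    "hypergeom_upper_tail",
]

# phrases whose presence marks a post as reporting reduced/averse drinking
DEFAULT_REDUCTION_LEXICON: tuple[str, ...] = (
    "stopped",
    "reduced",
    "sick",
    "full",
    "nausea",
    "don't want",
    "cutback",
    "low tolerance",
    "craving",
)


@dataclass(frozen=True)
class KeywordHit:
    post_index: int
    post_id: str
    theme: int
    positions: tuple[int, ...]


@dataclass
class KeywordHits:
    keyword: str
    variants: frozenset[str]
    hits: list[KeywordHit]

    @property
    def n_posts(self) -> int:
        return len(self.hits)

    @property
    def n_occurrences(self) -> int:
        return sum(len(h.positions) for h in self.hits)


@dataclass
class WordTreeNode:
    token: str
    count: int = 0
    highlight: bool = False
    children: dict[str, "WordTreeNode"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "token": self.token,
            "count": self.count,
            "highlight": self.highlight,
            "children": [c.to_dict() for c in self.children.values()],
        }


@dataclass
class WordTree:
    direction: str  # {prefix, suffix}
    root: WordTreeNode  # root token is the keyword; count = total occurrences

    def to_dict(self) -> dict:
        return {"direction": self.direction, **self.root.to_dict()}


@dataclass
class ReductionSummary:
    count: int
    total: int
    proportion: float | None
    flags: dict[str, bool]  # post id -> reduction-related


@dataclass
class EnrichmentResult:
    theme: int
    N: int  # total posts
    K: int  # posts in theme
    n: int  # keyword posts total
    k: int  # keyword posts in theme
    p: float  # upper-tail hypergeometric probability P(X >= k)
    p_bonferroni: float


def match_keyword(
    corpus: Corpus,
    labels: Sequence[int],
    keyword: str,
    variants: Iterable[str] | None = None,
) -> KeywordHits:
    """Whole-token, case-insensitive match on cleaned text.

    A post with several occurrences contributes all its token positions
    but counts once as a keyword post.
    """
    if not keyword:
        raise ValueError("keyword must be nonempty")
    vset = frozenset(v.lower() for v in (variants or ())) | {keyword.lower()}
    labels = np.asarray(labels)
    hits: list[KeywordHit] = []
    for i, toks in enumerate(corpus.cleaned):
        positions = tuple(j for j, t in enumerate(toks) if t in vset)
        if positions:
            hits.append(
                KeywordHit(
                    post_index=i,
                    post_id=corpus.posts[i].id,
                    theme=int(labels[i]),
                    positions=positions,
                )
            )
    return KeywordHits(keyword=keyword.lower(), variants=vset, hits=hits)


def _phrase_tuples(lexicon: Iterable[str]) -> list[tuple[str, ...]]:
    return [tuple(p.lower().split()) for p in lexicon]


def _contains_phrase(tokens: Sequence[str], phrase: tuple[str, ...]) -> bool:
    L = len(phrase)
    if L == 0 or L > len(tokens):
        return False
    return any(tuple(tokens[i : i + L]) == phrase for i in range(len(tokens) - L + 1))


def build_word_tree(
    corpus: Corpus,
    hits: KeywordHits,
    direction: str,
    max_depth: int = 5,
    min_count: int = 1,
    highlight_lexicon: Iterable[str] | None = None,
) -> WordTree:
    """Aggregate the tokens around each keyword occurrence into a tree.

    For a prefix tree the up-to-``max_depth`` tokens *before* an
    occurrence are stored nearest-first; for a suffix tree the tokens
    after it.  Shared paths accumulate counts; nodes with fewer than
    ``min_count`` occurrences are pruned.  When a highlight lexicon is
    given, a node is highlighted if the path's phrase, read in natural
    order including the keyword, contains a lexicon phrase.
    """
    if direction not in ("prefix", "suffix"):
        raise ValueError("direction must be 'prefix' or 'suffix'")
    root = WordTreeNode(token=hits.keyword)
    phrases = _phrase_tuples(highlight_lexicon) if highlight_lexicon else []

    for hit in hits.hits:
        toks = corpus.cleaned[hit.post_index]
        for pos in hit.positions:
            root.count += 1
            if direction == "prefix":
                context = list(reversed(toks[max(0, pos - max_depth) : pos]))
            else:
                context = list(toks[pos + 1 : pos + 1 + max_depth])
            node = root
            path: list[str] = []
            for tok in context:
                path.append(tok)
                node = node.children.setdefault(tok, WordTreeNode(token=tok))
                node.count += 1
                if phrases:
                    if direction == "prefix":
                        phrase_tokens = list(reversed(path)) + [hits.keyword]
                    else:
                        phrase_tokens = [hits.keyword] + path
                    if any(_contains_phrase(phrase_tokens, p) for p in phrases):
                        node.highlight = True

    _prune(root, min_count)
    return WordTree(direction=direction, root=root)


def _prune(node: WordTreeNode, min_count: int) -> None:
    node.children = {
        t: c for t, c in node.children.items() if c.count >= min_count
    }
    for child in node.children.values():
        _prune(child, min_count)


def classify_reduction(
    hits: KeywordHits,
    corpus: Corpus,
    lexicon: Iterable[str] = DEFAULT_REDUCTION_LEXICON,
) -> ReductionSummary:
    """Flag keyword posts whose cleaned text contains any lexicon phrase
    (multi-token phrases matched as adjacent tokens)."""
    phrases = _phrase_tuples(lexicon)
    flags: dict[str, bool] = {}
    for hit in hits.hits:
        toks = corpus.cleaned[hit.post_index]
        flags[hit.post_id] = any(_contains_phrase(toks, p) for p in phrases)
    total = len(flags)
    count = sum(flags.values())
    if total == 0:
        warnings.warn("no keyword posts: reduction proportion undefined")
        proportion = None
    else:
        proportion = count / total
    return ReductionSummary(count=count, total=total, proportion=proportion, flags=flags)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    Summed in log space over the exact support for numerical stability at
    corpus-sized N.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}: inconsistent data")
    lo = max(k, 0)
    hi = min(K, n)
    if lo <= max(0, n - (N - K)):
        return 1.0
    x = np.arange(lo, hi + 1)
    log_terms = (
        gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
        + gammaln(N - K + 1) - gammaln(n - x + 1) - gammaln(N - K - (n - x) + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrichment(labels: Sequence[int], hits: KeywordHits) -> list[EnrichmentResult]:
    """Per-theme upper-tail hypergeometric enrichment of keyword posts,
    sorted by ascending p; Bonferroni-adjusted p reported alongside."""
    labels = np.asarray(labels)
    N = int(labels.size)
    n = hits.n_posts
    themes, Ks = np.unique(labels, return_counts=True)
    hit_themes = np.array([h.theme for h in hits.hits])
    g = themes.size
    results = []
    for t, K in zip(themes, Ks):
        k = int((hit_themes == t).sum()) if n else 0
        p = hypergeom_upper_tail(N, int(K), n, k)
        results.append(
            EnrichmentResult(
                theme=int(t), N=N, K=int(K), n=n, k=k,
                p=p, p_bonferroni=min(1.0, p * g),
            )
        )
    results.sort(key=lambda r: (r.p, r.theme))
    return results
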