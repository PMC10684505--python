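from datetime import date, datetime, timezone

import numpy as np
import pytest

from glp1alc.corpus import Corpus, Post
from glp1alc.synthetic import CorpusSpec, disjoint_topics, generate_corpus
from glp1alc.corpus import preprocess_corpus


def make_post(i, title, body, ts=None, user=None):
    return Post(
        id=f"p{i:04d}",
        user=user or f"u{i:03d}",
        subreddit="r_test",
        timestamp=ts or datetime(2022, 1, 1, tzinfo=timezone.utc),
        title=title,
        body=body,
    )


def corpus_from_tokens(token_lists, themes=None):
    """Corpus built directly from cleaned token sequences (bypasses cleaning)."""
    posts = [
        make_post(i, "", " ".join(toks)) for i, toks in enumerate(token_lists)
    ]
    return Corpus(posts=posts, cleaned=[list(t) for t in token_lists])


@pytest.fixture(scope="session")
def two_topic_corpus():
    """1000-post corpus with two disjoint planted topics; alcohol posts in
    topic0 only, reduction rate 0.7."""
    spec = CorpusSpec(
        n_posts=1000,
        n_users=200,
        date_range=(date(2020, 1, 1), date(2023, 1, 1)),
        topics=disjoint_topics(2),
        alcohol_rate_by_topic={"topic0": 0.5, "topic1": 0.0},
        reduction_rate=0.7,
        seed=11,
    )
    posts, truth = generate_corpus(spec)
    corpus = preprocess_corpus(posts)
    truth = truth.set_index("id").loc[[p.id for p in corpus.posts]].reset_index()
    labels = (truth["topic"] == "topic1").to_numpy().astype(int)
    return corpus, truth, labels
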