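"""Shared paths and loaders for the numbered analysis drivers."""

import json
from pathlib import Path

from glp1alc.corpus import Corpus, read_posts

RESULTS = Path(__file__).resolve().parent.parent / "results"
CORPUS_DIR = RESULTS / "corpus"
THEMES_DIR = RESULTS / "themes"
SURVEY_DIR = RESULTS / "survey"


def load_clean_corpus() -> Corpus:
    posts, _ = read_posts(CORPUS_DIR / "clean_posts.jsonl")
    with open(CORPUS_DIR / "clean_tokens.json") as fh:
        tokens = json.load(fh)
    return Corpus(posts=posts, cleaned=[tokens[p.id] for p in posts])
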