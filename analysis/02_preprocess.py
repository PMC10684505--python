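"""Clean and filter the raw corpus.

Merges titles into bodies, strips URLs/punctuation/case/stopwords, removes
exact duplicates and posts under 100 cleaned characters, then writes the
cleaned corpus and a retention report under results/corpus/.
"""

import json
from pathlib import Path

from glp1alc.corpus import preprocess_corpus, read_posts, write_posts_jsonl

OUT = Path(__file__).resolve().parent.parent / "results" / "corpus"


def main() -> None:
    posts, ingest = read_posts(OUT / "raw_posts.jsonl")
    if ingest.n_malformed:
        print(f"warning: {ingest.n_malformed} malformed rows skipped")
    corpus = preprocess_corpus(posts, min_chars=100)
    write_posts_jsonl(corpus.posts, OUT / "clean_posts.jsonl")
    with open(OUT / "clean_tokens.json", "w") as fh:
        json.dump({p.id: toks for p, toks in zip(corpus.posts, corpus.cleaned)}, fh)
    report = corpus.report
    (OUT / "retention_report.json").write_text(
        json.dumps(
            {
                "input": report.n_input,
                "retained": report.n_retained,
                "duplicates_dropped": report.n_duplicates,
                "too_short_dropped": report.n_too_short,
            },
            indent=2,
        )
    )
    print(
        f"retained {report.n_retained}/{report.n_input} posts "
        f"({report.n_duplicates} duplicates, {report.n_too_short} too short)"
    )


if __name__ == "__main__":
    main()
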