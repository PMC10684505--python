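"""Mine the alcohol discussions: locate keyword posts, test per-theme
hypergeometric enrichment, classify reduction-related posts against the
phrase lexicon, and export prefix/suffix word trees.

Writes enrichment and reduction summaries plus word-tree JSON under
results/themes/.
"""

import json

import pandas as pd

from _common import THEMES_DIR, load_clean_corpus
from glp1alc.keywords import (
    DEFAULT_REDUCTION_LEXICON,
    build_word_tree,
    classify_reduction,
    enrichment,
    match_keyword,
)


def main() -> None:
    corpus = load_clean_corpus()
    labels = pd.read_csv(THEMES_DIR / "labels.csv")["theme"].to_numpy()

    hits = match_keyword(corpus, labels, "alcohol")
    print(f"{hits.n_posts} keyword posts ({hits.n_occurrences} occurrences)")

    results = enrichment(labels, hits)
    pd.DataFrame(
        [
            {
                "theme": r.theme, "posts_in_theme": r.K, "keyword_posts_in_theme": r.k,
                "p": r.p, "p_bonferroni": r.p_bonferroni,
            }
            for r in results
        ]
    ).to_csv(THEMES_DIR / "alcohol_enrichment.csv", index=False)
    top = results[0]
    print(
        f"most enriched theme: {top.theme} "
        f"(k={top.k} of n={top.n} keyword posts, p={top.p:.3g})"
    )

    summary = classify_reduction(hits, corpus, DEFAULT_REDUCTION_LEXICON)
    (THEMES_DIR / "reduction_summary.json").write_text(
        json.dumps(
            {
                "reduction_posts": summary.count,
                "keyword_posts": summary.total,
                "proportion": summary.proportion,
            },
            indent=2,
        )
    )
    print(
        f"reduction-related: {summary.count}/{summary.total} "
        f"({100 * summary.proportion:.1f}%) of alcohol posts"
    )

    for direction in ("prefix", "suffix"):
        tree = build_word_tree(
            corpus, hits, direction, max_depth=4, min_count=2,
            highlight_lexicon=DEFAULT_REDUCTION_LEXICON,
        )
        (THEMES_DIR / f"word_tree_{direction}.json").write_text(
            json.dumps(tree.to_dict(), indent=2)
        )
    print(f"wrote enrichment, reduction summary and word trees -> {THEMES_DIR}")


if __name__ == "__main__":
    main()
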