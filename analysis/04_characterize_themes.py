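"""Characterize the discovered themes: one-vs-rest random-forest feature
importances, top unigram/bigram tables and overall theme shares.

Writes per-theme CSVs under results/themes/.
"""

import pandas as pd

from _common import THEMES_DIR, load_clean_corpus
from glp1alc.characterize import cluster_importance, ngram_table, theme_share

SEED = 17


def main() -> None:
    corpus = load_clean_corpus()
    labels = pd.read_csv(THEMES_DIR / "labels.csv")["theme"].to_numpy()

    shares = theme_share(labels)
    pd.DataFrame(
        [{"theme": t, "share": s, "percent": round(100 * s, 1)} for t, s in shares.items()]
    ).to_csv(THEMES_DIR / "theme_shares.csv", index=False)
    dominant = max(shares, key=shares.get)
    print("theme shares:", {t: f"{100 * s:.1f}%" for t, s in sorted(shares.items())})
    print(f"dominant theme: {dominant} ({100 * shares[dominant]:.1f}% of posts)")

    tables = cluster_importance(corpus, labels, top_k=20, seed=SEED)
    pd.DataFrame(
        [
            {"theme": t.theme, "rank": r, "feature": f, "weight": w}
            for t in tables
            for r, (f, w) in enumerate(t.features, start=1)
        ]
    ).to_csv(THEMES_DIR / "feature_importance.csv", index=False)

    for n, name in ((1, "unigrams"), (2, "bigrams")):
        rows = [
            {"theme": t, "rank": r, "ngram": g, "count": c}
            for t, ranked in ngram_table(corpus, labels, n=n, top_k=30).items()
            for r, (g, c) in enumerate(ranked, start=1)
        ]
        pd.DataFrame(rows).to_csv(THEMES_DIR / f"top_{name}.csv", index=False)
    print(f"wrote importances and n-gram tables -> {THEMES_DIR}")


if __name__ == "__main__":
    main()
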