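"""Simulate the social-media corpus used by the theme-attribution analysis.

Plants six discussion topics with disjoint keyword lexicons over a shared
filler vocabulary, with alcohol mentions concentrated in two topics and a
70% reduction rate among alcohol posts, then writes the raw corpus (JSONL)
and the ground-truth table (CSV) under results/corpus/.
"""

from datetime import date
from pathlib import Path

from glp1alc.corpus import write_posts_jsonl
from glp1alc.synthetic import CorpusSpec, disjoint_topics, generate_corpus

OUT = Path(__file__).resolve().parent.parent / "results" / "corpus"
SEED = 20230901

TOPIC_WEIGHTS = [0.30, 0.21, 0.19, 0.14, 0.06, 0.10]
ALCOHOL_RATES = {  # alcohol talk concentrated in the two dominant topics
    "topic0": 0.12, "topic1": 0.02, "topic2": 0.08,
    "topic3": 0.01, "topic4": 0.01, "topic5": 0.01,
}


def main() -> None:
    spec = CorpusSpec(
        n_posts=8000,
        n_users=1500,
        date_range=(date(2009, 1, 1), date(2023, 7, 1)),
        topics=disjoint_topics(6, lexicon_size=50, mean_length=60,
                               weights=TOPIC_WEIGHTS),
        alcohol_rate_by_topic=ALCOHOL_RATES,
        reduction_rate=0.7,
        seed=SEED,
        growth_weighted=True,  # posting volume surges late in the range
    )
    posts, truth = generate_corpus(spec)
    OUT.mkdir(parents=True, exist_ok=True)
    write_posts_jsonl(posts, OUT / "raw_posts.jsonl")
    truth.to_csv(OUT / "ground_truth.csv", index=False)
    n_alc = int(truth["is_alcohol"].sum())
    print(f"wrote {len(posts)} posts from {spec.n_users} users -> {OUT}")
    print(f"alcohol posts planted: {n_alc} "
          f"({truth['is_reduction'].sum() / max(n_alc, 1):.1%} reduction-related)")


if __name__ == "__main__":
    main()
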