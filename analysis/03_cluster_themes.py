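"""Discover themes: embed the cleaned corpus, choose k at the distortion
knee, cluster, propose and apply keyword-overlap merges, and export a 2-D
projection for plotting.

Writes the distortion curve, per-post labels (raw cluster and merged
theme) and UMAP coordinates under results/themes/.
"""

import json

import pandas as pd

from _common import THEMES_DIR, load_clean_corpus
from glp1alc.themes import (
    encode,
    find_knee,
    merge_clusters,
    project_2d,
    suggest_merges,
    sweep_kmeans,
    ClusterSolution,
)

SEED = 17
K_RANGE = list(range(2, 13))


def main() -> None:
    corpus = load_clean_corpus()
    emb = encode(corpus)
    curve, labelings, centroids = sweep_kmeans(emb, K_RANGE, seed=SEED)
    k = find_knee(curve)
    if k is None:
        raise SystemExit("distortion curve is linear: no knee found")
    print(f"knee detection selected k = {k} over k in {K_RANGE[0]}..{K_RANGE[-1]}")

    raw = ClusterSolution(labels=labelings[k], k=k, seed=SEED, centroids=centroids[k])
    proposal = suggest_merges(raw, corpus, top_n=100, threshold=0.5)
    merged = merge_clusters(raw, proposal)
    print(f"keyword-overlap merge proposal: {k} raw clusters -> {merged.k} themes")

    THEMES_DIR.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"k": curve.ks, "distortion": curve.distortions}).to_csv(
        THEMES_DIR / "distortion_curve.csv", index=False
    )
    coords = project_2d(emb, seed=SEED)
    pd.DataFrame(
        {
            "post_id": [p.id for p in corpus.posts],
            "raw_cluster": raw.labels,
            "theme": merged.labels,
            "umap_x": coords[:, 0],
            "umap_y": coords[:, 1],
        }
    ).to_csv(THEMES_DIR / "labels.csv", index=False)
    (THEMES_DIR / "merge_map.json").write_text(json.dumps(proposal, indent=2))
    print(f"wrote labels, distortion curve and coordinates -> {THEMES_DIR}")


if __name__ == "__main__":
    main()
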