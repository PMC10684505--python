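"""Theme dynamics: monthly theme-share time series and the full-order
partial-correlation network between themes.

Writes the series, the correlation/p matrices and an edge list under
results/themes/.
"""

import pandas as pd

from _common import THEMES_DIR, load_clean_corpus
from glp1alc.dynamics import bin_series, partial_correlation


def main() -> None:
    corpus = load_clean_corpus()
    labels = pd.read_csv(THEMES_DIR / "labels.csv")["theme"].to_numpy()

    series = bin_series(corpus, labels, bin="month")
    print(
        f"{len(series.periods)} monthly periods with posts "
        f"({len(series.empty_periods)} empty months excluded)"
    )
    pd.DataFrame(
        series.proportions, index=series.periods, columns=series.theme_ids
    ).to_csv(THEMES_DIR / "theme_series_monthly.csv")

    res = partial_correlation(series, values="proportions")
    g = len(series.theme_ids)
    pd.DataFrame(res.rho, index=series.theme_ids, columns=series.theme_ids).to_csv(
        THEMES_DIR / "partial_corr_rho.csv"
    )
    pd.DataFrame(res.p, index=series.theme_ids, columns=series.theme_ids).to_csv(
        THEMES_DIR / "partial_corr_p.csv"
    )
    edges = [
        {
            "theme_i": series.theme_ids[i], "theme_j": series.theme_ids[j],
            "rho": res.rho[i, j], "p": res.p[i, j],
        }
        for i in range(g)
        for j in range(i + 1, g)
    ]
    pd.DataFrame(edges).to_csv(THEMES_DIR / "partial_corr_edges.csv", index=False)
    sig = sum(e["p"] < 0.05 for e in edges)
    print(
        f"{len(edges)} theme pairs, {sig} with p < 0.05 "
        f"(controls per pair: {res.n_controls}, T = {res.T_effective})"
    )


if __name__ == "__main__":
    main()
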