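#!/usr/bin/env python
"""Cluster the roar-groan combination patterns.

Summarizes each pattern by mean duration, element count and rhythm, builds
the Ward dendrogram on Euclidean distances, and cuts it automatically at
the largest relative height gap. Writes the dendrogram (Newick with
heights) and the cluster assignment.
"""

from pathlib import Path

import pandas as pd

from pacavoc import combinations as comb
from pacavoc import io as pio

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = pio.read_combination_csv(OUT / "combinations.csv")
    means = comb.summarize_combinations(records)
    print("per-pattern means:")
    print(means.round(2).to_string(index=False))

    dendro = comb.ward_cluster(means)
    print("\nmerge sequence (height = within-cluster variance increase):")
    for a, b, h in dendro.merges:
        print(f"  {'+'.join(a)} | {'+'.join(b)}  at {h:.2f}")

    groups = comb.auto_truncate(dendro)
    k = len(set(groups.values()))
    print(f"\nautomatic truncation: {k} combination call groups")
    for g in sorted(set(groups.values())):
        members = [p for p, gi in groups.items() if gi == g]
        print(f"  group {g}: {members}")

    (OUT / "combination_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    pd.Series(groups, name="cluster").rename_axis("pattern").to_csv(
        OUT / "combination_clusters.csv"
    )


if __name__ == "__main__":
    main()
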