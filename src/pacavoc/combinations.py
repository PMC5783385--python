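"""Roar-groan combination sequences: summary and Ward clustering.

Sequences of two element types (A = roar, B = groan) are summarized per
pattern by mean duration, element count and rhythm, then clustered
agglomeratively with Ward's criterion on Euclidean distances. Merge
heights are reported as the within-cluster variance increase of each merge
(Ward's objective). The dendrogram is cut automatically; the published
workflow used a proprietary "entropy" truncation with no public formula,
so the default surrogate cuts at the largest relative gap in merge
heights, with an entropy-weighted alternative behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "summarize_combinations",
    "Dendrogram",
    "ward_cluster",
    "auto_truncate",
]

SUMMARY_VARS = ("duration", "n_elements", "rhythm")


def summarize_combinations(records: pd.DataFrame) -> pd.DataFrame:
    """Per-pattern arithmetic means of duration, element count and rhythm."""
    if records.empty:
        raise ValueError("empty combination table")
    missing = set(("pattern",) + SUMMARY_VARS) - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = (
        records.groupby("pattern", sort=True)[list(SUMMARY_VARS)]
        .mean()
        .reset_index()
    )
    return out


@dataclass
class Dendrogram:
    """Agglomerative merge sequence.

    ``merges`` is a list of (members_a, members_b, height) with members as
    sorted tuples of labels and height the increase in total within-cluster
    variance caused by the merge. Heights are non-decreasing for Ward
    linkage.
    """

    labels: tuple[str, ...]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def cut(self, k: int) -> dict[str, int]:
        """Cluster assignment with k clusters (undo the last k-1 merges)."""
        clusters = [frozenset([l]) for l in self.labels]
        for a, b, _ in self.merges[: len(self.labels) - k]:
            fa, fb = frozenset(a), frozenset(b)
            clusters = [c for c in clusters if c != fa and c != fb] + [fa | fb]
        clusters = sorted(clusters, key=lambda c: min(c))
        return {label: i for i, c in enumerate(clusters) for label in sorted(c)}

    def to_newick(self) -> str:
        """Serialize with heights as node depths (cophenetic-style)."""
        trees = {frozenset([l]): (l, 0.0) for l in self.labels}
        for a, b, h in self.merges:
            fa, fb = frozenset(a), frozenset(b)
            (sa, ha), (sb, hb) = trees.pop(fa), trees.pop(fb)
            node = f"({sa}:{max(h - ha, 0.0):.6f},{sb}:{max(h - hb, 0.0):.6f})"
            trees[fa | fb] = (node, h)
        (s, _), = trees.values()
        return s + ";"


def ward_cluster(vectors: pd.DataFrame, standardize: bool = False) -> Dendrogram:
    """Ward agglomeration of per-pattern mean vectors.

    Implements the Lance-Williams update on squared Euclidean distances;
    at each step the merge minimizing the increase in total within-cluster
    variance is chosen. Heights are that variance increase, so two
    identical vectors merge at height 0. Ties are broken by the
    lexicographically smallest pair of member tuples, which makes the
    result invariant to input row order. ``standardize`` optionally
    z-scores the variables first (the default follows the reference
    workflow: unscaled).
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 items to cluster")
    labels = tuple(vectors["pattern"].astype(str)) if "pattern" in vectors else tuple(
        str(i) for i in vectors.index
    )
    cols = [c for c in vectors.columns if c != "pattern"]
    x = vectors[cols].to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd

    members: list[tuple[str, ...]] = [(l,) for l in labels]
    sizes = [1] * len(labels)
    # D holds 2 * (variance increase of merging i and j); for singletons the
    # increase is ||xi - xj||^2 / 2.
    d = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d[(i, j)] = float(((x[i] - x[j]) ** 2).sum())

    def dget(i, j):
        return d[(i, j) if i < j else (j, i)]

    merges = []
    active = list(range(len(labels)))
    next_id = len(labels)
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = tuple(sorted((tuple(sorted(members[i])), tuple(sorted(members[j])))))
                cand = (dget(i, j), key, i, j)
                if best is None or cand < best:
                    best = cand
        dij, _, i, j = best
        merges.append((tuple(sorted(members[i])), tuple(sorted(members[j])), dij / 2.0))
        ni, nj = sizes[i], sizes[j]
        members.append(tuple(sorted(members[i] + members[j])))
        sizes.append(ni + nj)
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dnew = (
                (ni + nk) * dget(i, k) + (nj + nk) * dget(j, k) - nk * dij
            ) / (ni + nj + nk)
            d[(min(k, next_id), max(k, next_id))] = dnew
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return Dendrogram(labels=labels, merges=merges)


def auto_truncate(
    dendrogram: Dendrogram,
    method: str = "gap",
    height_floor: float = 1e-12,
) -> dict[str, int]:
    """Automatic dendrogram cut.

    ``method="gap"`` (default) cuts before the merge with the largest
    relative jump in merge heights, a reconstructed surrogate for the
    proprietary entropy-based truncation of the original workflow;
    ``method="entropy"`` weights each candidate gap by the Shannon entropy
    of the resulting cluster-size partition (normalized by log k),
    preferring balanced groupings. Items that are all identical (every
    merge at height ~0) form a single cluster.
    """
    h = dendrogram.heights
    n = len(dendrogram.labels)
    if np.all(h <= height_floor):
        return dendrogram.cut(1)
    if method not in ("gap", "entropy"):
        raise ValueError(f"unknown truncation method {method!r}")

    best_k, best_score = 2, -np.inf
    for i in range(1, len(h)):
        gap = h[i] / max(h[i - 1], height_floor)
        k = n - i  # cutting between merges i-1 and i leaves n - i clusters
        if k < 2:
            continue
        score = gap
        if method == "entropy":
            sizes = np.array(
                list(pd.Series(dendrogram.cut(k)).value_counts()), dtype=float
            )
            p = sizes / sizes.sum()
            ent = -(p * np.log(p)).sum() / np.log(len(p)) if len(p) > 1 else 0.0
            score = gap * ent
        if score > best_score:
            best_k, best_score = k, score
    return dendrogram.cut(best_k)
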