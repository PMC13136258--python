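"""Phenotype-based hierarchical clustering of accessions.

Accessions are clustered on Z-score standardized traits with Euclidean
distance and complete linkage (the farthest-neighbour criterion); Ward
linkage is available for comparison.  Cutting the dendrogram at k groups
yields per-group trait summaries with pairwise Welch tests and a compact
letter display at alpha = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 merge sequence
    labels: list[str]
    linkage: str
    distance: str = "euclidean"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]


@dataclass
class GroupSummary:
    group: int
    size: int
    means: pd.Series  # per-trait mean
    letters: pd.Series  # per-trait compact letter display at alpha


def distance_matrix(ztable: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between accessions (rows)."""
    x = ztable.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values: impute or drop before distances")
    d = squareform(pdist(x, metric="euclidean"))
    return pd.DataFrame(d, index=ztable.index, columns=ztable.index)


def hcluster(dist: pd.DataFrame, *, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix.

    Complete linkage matches the farthest-neighbour criterion; "ward"
    additionally requires Euclidean input.  scipy's implementation
    resolves ties deterministically by cluster index order, so results
    are platform-stable.
    """
    if dist.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    condensed = squareform(dist.to_numpy(), checks=True)
    z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(linkage_matrix=z, labels=[str(i) for i in dist.index],
                      linkage=linkage)


def cut_k(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut into k clusters; labels are 1..k in order of first appearance
    along the row order."""
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    raw = hierarchy.fcluster(dendrogram.linkage_matrix, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[i] = relabel[c]
    return pd.Series(out, index=dendrogram.labels, name="group")


def _letter_display(groups: list[int], distinct: set[tuple[int, int]]) -> dict[int, str]:
    """Compact letter display: groups not flagged distinct share a letter.

    Greedy insertion: each group joins every existing letter-set it is
    compatible with, or opens a new one.
    """
    sets: list[set[int]] = []
    for g in groups:
        placed = False
        for s in sets:
            if all((min(g, h), max(g, h)) not in distinct for h in s):
                s.add(g)
                placed = True
        if not placed:
            sets.append({g})
    letters = {g: "" for g in groups}
    for s, letter in zip(sets, "abcdefghijklmnopqrstuvwxyz"):
        for g in sorted(s):
            letters[g] += letter
    return letters


def group_summaries(table, labels: pd.Series, *, alpha: float = 0.01) -> list[GroupSummary]:
    """Per-group trait means with pairwise Welch t-tests per trait.

    Two groups get different letters for a trait when Welch's test
    rejects at ``alpha``.  Size-1 groups are excluded from testing but
    their means are still reported (they share letters with everyone).
    """
    df = table.values if hasattr(table, "trait_names") else table
    df = df.astype(float)
    if len(labels) != len(df):
        raise ValueError("labels do not align with table rows")
    groups = sorted(pd.Series(labels).unique())
    means = {g: df[np.asarray(labels) == g].mean() for g in groups}
    sizes = {g: int((np.asarray(labels) == g).sum()) for g in groups}
    letters_per_trait: dict[str, dict[int, str]] = {}
    for trait in df.columns:
        distinct: set[tuple[int, int]] = set()
        for i, g in enumerate(groups):
            for h in groups[i + 1:]:
                x = df.loc[np.asarray(labels) == g, trait].dropna()
                y = df.loc[np.asarray(labels) == h, trait].dropna()
                if len(x) < 2 or len(y) < 2:
                    continue
                if x.std() == 0 and y.std() == 0:
                    if x.iloc[0] != y.iloc[0]:
                        distinct.add((g, h))
                    continue
                p = stats.ttest_ind(x, y, equal_var=False).pvalue
                if p < alpha:
                    distinct.add((g, h))
        letters_per_trait[trait] = _letter_display(groups, distinct)
    out = []
    for g in groups:
        out.append(
            GroupSummary(
                group=int(g),
                size=sizes[g],
                means=means[g],
                letters=pd.Series({t: letters_per_trait[t][g] for t in df.columns}),
            )
        )
    return out


def cluster_accessions(table, k: int, *, linkage: str = "complete"):
    """Convenience pipeline: standardize -> distances -> dendrogram -> k groups."""
    from germdiv.evaluation import zscore

    z = zscore(table)
    if z.isna().any().any():
        z = z.fillna(0.0)
    dist = distance_matrix(z)
    dend = hcluster(dist, linkage=linkage)
    return dend, cut_k(dend, k)
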