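"""Redundancy among centrality indices.

Two centralities are redundant when they order the proteins alike.  Pairwise
agreement is measured with the Goodman-Kruskal gamma statistic — concordant
minus discordant pairs over their sum, with pairs tied in either ranking
excluded — and the resulting 6x6 association matrix is summarized by an
average-linkage dendrogram over the index profiles.  Four-index subsets can
be re-run through the two-round hub detection to check how well they recover
a reference hub set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .centrality import INDEX_LABELS
from .hubdetect import HubDetector, MixtureFit

__all__ = [
    "gk_gamma",
    "gk_lambda",
    "association_matrix",
    "IndexDendrogram",
    "index_dendrogram",
    "SubsetEvaluation",
    "evaluate_subset",
]


def gk_gamma(rank_a, rank_b) -> float:
    """Goodman-Kruskal gamma between two rankings of the same proteins.

    gamma = (C - D) / (C + D) over all unordered protein pairs, where C and
    D count concordant and discordant pairs; pairs tied in either input are
    excluded.  Returns NaN if every pair is tied.  If the inputs are pandas
    Series they must cover identical protein sets (they are aligned by id).
    """
    if isinstance(rank_a, pd.Series) and isinstance(rank_b, pd.Series):
        if set(rank_a.index) != set(rank_b.index):
            raise ValueError("rankings cover different protein sets")
        rank_b = rank_b.reindex(rank_a.index)
    a = np.asarray(rank_a, dtype=float)
    b = np.asarray(rank_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rankings must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least two proteins to compare rankings")
    iu = np.triu_indices(a.size, k=1)
    da = np.sign(a[:, None] - a[None, :])[iu]
    db = np.sign(b[:, None] - b[None, :])[iu]
    prod = da * db
    concordant = int(np.sum(prod > 0))
    discordant = int(np.sum(prod < 0))
    if concordant + discordant == 0:
        return float("nan")
    return (concordant - discordant) / (concordant + discordant)


#: Historical alias: the statistic is reported as "lambda" in parts of the
#: network literature although it is the signed concordance measure gamma.
gk_lambda = gk_gamma


def association_matrix(
    table: pd.DataFrame, labels: Sequence[str] = INDEX_LABELS
) -> pd.DataFrame:
    """Symmetric matrix of pairwise gamma scores between centrality columns."""
    if len(table) == 0:
        raise ValueError("empty centrality table")
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            g = gk_gamma(table[la].to_numpy(), table[lb].to_numpy())
            mat.loc[la, lb] = mat.loc[lb, la] = g
    return mat


@dataclass
class IndexDendrogram:
    """Average-linkage merge tree over the centrality indices."""

    linkage: np.ndarray  # scipy linkage matrix, (k-1) x 4
    labels: tuple[str, ...]

    def merge_order(self) -> list[frozenset]:
        """Leaf-label sets of each merge, in merge order."""
        clusters = {i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        merges = []
        for step, (i, j, _h, _c) in enumerate(self.linkage):
            new = clusters[int(i)] | clusters[int(j)]
            clusters[len(self.labels) + step] = new
            merges.append(new)
        return merges

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def _profile_distance(mat: pd.DataFrame, a: str, b: str) -> float:
    """Euclidean distance between score profiles, self-entries excluded."""
    others = [c for c in mat.columns if c not in (a, b)]
    va = mat.loc[a, others].to_numpy(dtype=float)
    vb = mat.loc[b, others].to_numpy(dtype=float)
    return float(np.linalg.norm(va - vb))


def index_dendrogram(
    matrix: pd.DataFrame, linkage: str = "average"
) -> IndexDendrogram:
    """Agglomerate the indices on their association profiles.

    The dissimilarity between two indices is the Euclidean distance between
    their rows of the association matrix with the two self/pair entries
    excluded, so indices cluster when they relate to all *other* indices
    alike.
    """
    valid = {"single", "complete", "average", "weighted", "ward"}
    if linkage not in valid:
        raise ValueError(f"unknown linkage {linkage!r}; pick one of {sorted(valid)}")
    labels = tuple(matrix.columns)
    condensed = [
        _profile_distance(matrix, labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    z = hierarchy.linkage(np.asarray(condensed), method=linkage)
    return IndexDendrogram(linkage=z, labels=labels)


@dataclass
class SubsetEvaluation:
    """Recovery of a reference hub set by a restricted centrality subset."""

    subset: tuple[str, ...]
    round1: MixtureFit
    round1_central_size: int
    round2: MixtureFit | None
    overlap_1cluster: tuple[int, int]  # (reference hubs recovered, cluster size)
    overlap_2clusters: tuple[int, int]
    reference_size: int


def evaluate_subset(
    table: pd.DataFrame,
    subset: Sequence[str],
    reference_hubs: set[str],
    k_range: tuple[int, int] = (1, 20),
    n_init: int = 10,
    seed: int | None = 0,
    min_central_cluster: int = 10,
) -> SubsetEvaluation:
    """Re-run two-round hub detection on a subset of the indices.

    The final round's components are ranked by their mean normalized
    centrality; the report counts how many reference hubs fall in the top
    component alone and in the top two together, with the matching cluster
    sizes.
    """
    unknown = set(subset) - set(INDEX_LABELS)
    if unknown:
        raise ValueError(f"unknown centrality labels: {sorted(unknown)}")
    if not reference_hubs:
        raise ValueError("reference hub set is empty")
    cols = [f"{c}_norm" for c in subset]
    det = HubDetector(
        k_min=k_range[0],
        k_max=k_range[1],
        n_init=n_init,
        seed=seed,
        min_central_cluster=min_central_cluster,
        columns=cols,
    ).fit(table)
    res = det.result_
    final = res.round2 if res.round2 is not None else res.round1
    order = (
        final.component_means.mean(axis=1).sort_values(ascending=False).index
    )

    def members(components) -> set[str]:
        mask = final.assignments.isin(list(components))
        return set(final.assignments.index[mask])

    top1 = members(order[:1])
    top2 = members(order[:2])
    return SubsetEvaluation(
        subset=tuple(subset),
        round1=res.round1,
        round1_central_size=len(res.round1_central_cluster),
        round2=res.round2,
        overlap_1cluster=(len(top1 & reference_hubs), len(top1)),
        overlap_2clusters=(len(top2 & reference_hubs), len(top2)),
        reference_size=len(reference_hubs),
    )
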