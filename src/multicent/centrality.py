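"""Six centrality indices for protein interaction networks.

The profile combines local (degree ``D``, eigenvector score ``EC``),
meso-scale (topological importance ``TI1``/``TI4``) and global (betweenness
``B``, closeness ``C``) views of a protein's position.  Topological
importance follows the multiplicative-additive indirect-effect construction
used in ecological network analysis: the one-step effect of protein *j* on an
adjacent protein *i* is 1/D_i, indirect effects along longer walks multiply
step effects and sum over parallel routes, and TI^m averages the total effect
a protein exerts over walks of length 1..m.

Conventions (chosen so that the toy worked example is reproduced exactly):

* betweenness is raw (unnormalized), over unordered pairs, endpoints excluded;
* closeness is (n-1) / sum of shortest-path distances;
* the eigenvector score is the dominant adjacency eigenvector rescaled so its
  maximum entry is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _to_igraph(net: nx.Graph) -> tuple[ig.Graph, list[str]]:
    """igraph copy of the network plus its node order (used for the
    all-pairs shortest-path computations, where igraph is much faster)."""
    nodes = sorted(net.nodes())
    index = {node: i for i, node in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes), edges=[(index[a], index[b]) for a, b in net.edges()]
    )
    return g, nodes

#: Canonical column order of the centrality table.
INDEX_LABELS = ("D", "EC", "TI1", "TI4", "B", "C")

#: Normalized (max = 1) counterparts, in the same order.
NORM_LABELS = tuple(f"{c}_norm" for c in INDEX_LABELS)


def _require_connected(net: nx.Graph, what: str) -> None:
    if net.number_of_nodes() == 0:
        raise ValueError(f"{what}: empty network")
    if not nx.is_connected(net):
        raise ValueError(
            f"{what} is only defined on a connected network; extract the "
            "giant component first (graphio.giant_component)"
        )


def degree(net: nx.Graph) -> dict[str, int]:
    """Number of interaction partners of each protein."""
    return {node: d for node, d in net.degree()}


def eigenvector(
    net: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000
) -> dict[str, float]:
    """Dominant-adjacency-eigenvector scores, rescaled to maximum 1.

    Computed by power iteration on A + I (the unit shift leaves eigenvectors
    unchanged but makes the dominant eigenvalue strictly largest in modulus,
    so the iteration converges on bipartite graphs such as trees).
    Convergence is certified on the eigen-relation residual
    ``max|A v - lambda v|``.
    """
    _require_connected(net, "eigenvector centrality")
    nodes = sorted(net.nodes())
    a = nx.to_numpy_array(net, nodelist=nodes, dtype=float)
    v = np.ones(len(nodes)) / np.sqrt(len(nodes))
    shifted = a + np.eye(len(nodes))
    residual = np.inf
    for _ in range(max_iter):
        w = shifted @ v
        w /= np.linalg.norm(w)
        lam = v @ (a @ v)
        residual = np.max(np.abs(a @ v - lam * v))
        if residual < tol:
            break
        v = w
    else:
        raise RuntimeError(
            f"eigenvector iteration did not converge within {max_iter} "
            f"iterations (residual {residual:.3e})"
        )
    v = np.abs(v)
    v /= v.max()
    return dict(zip(nodes, v))


def closeness(net: nx.Graph) -> dict[str, float]:
    """(n-1) divided by the sum of shortest-path distances to all others."""
    _require_connected(net, "closeness centrality")
    g, nodes = _to_igraph(net)
    if len(nodes) == 1:
        return {nodes[0]: 0.0}
    return dict(zip(nodes, g.closeness()))


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Raw shortest-path betweenness over unordered pairs, endpoints excluded.

    When a pair is joined by several geodesics each contributes fractionally.
    """
    g, nodes = _to_igraph(net)
    return dict(zip(nodes, (float(b) for b in g.betweenness(directed=False))))


@dataclass(frozen=True)
class EffectMatrix:
    """Row-stochastic one-step interaction-effect matrix.

    ``matrix[i, j]`` is the one-step effect of protein ``nodes[j]`` on
    protein ``nodes[i]``: 1/degree(i) if they interact, else 0.  Rows sum to
    one for every non-isolated protein; the diagonal is zero on simple graphs.
    """

    matrix: np.ndarray
    nodes: tuple[str, ...] = field(repr=False)


def effect_matrix(net: nx.Graph) -> EffectMatrix:
    """Build the one-step effect matrix (entries a_ij / D_i)."""
    nodes = sorted(net.nodes())
    degrees = np.array([net.degree(n) for n in nodes], dtype=float)
    isolated = [n for n, d in zip(nodes, degrees) if d == 0]
    if isolated:
        raise ValueError(
            f"effect matrix undefined for isolated node(s): {isolated}"
        )
    a = nx.to_numpy_array(net, nodelist=nodes, dtype=float)
    return EffectMatrix(matrix=a / degrees[:, None], nodes=tuple(nodes))


def topological_importance(net: nx.Graph, m: int) -> dict[str, float]:
    """Topological importance TI^m of every protein.

    With E the effect matrix, the q-step effect of i on j is ``(E^q)[j, i]``
    (effects propagate along walks; revisits are allowed).  phi_q,i sums the
    q-step effect of i on every other protein (column-i sum of E^q excluding
    the diagonal), and TI^m_i = (sum_{q=1..m} phi_q,i) / m.
    """
    if m < 1:
        raise ValueError(f"step limit m must be >= 1, got {m}")
    em = effect_matrix(net)
    e = em.matrix
    power = np.eye(len(em.nodes))
    total = np.zeros(len(em.nodes))
    for _ in range(m):
        power = power @ e
        total += power.sum(axis=0) - np.diagonal(power)
    return dict(zip(em.nodes, total / m))


def centrality_table(net: nx.Graph, eigen_tol: float = 1e-10) -> pd.DataFrame:
    """Per-protein table of the six indices, raw and max-normalized.

    Columns ``D, EC, TI1, TI4, B, C`` hold the raw values and
    ``*_norm`` their per-column max-1 rescaling; the index is the sorted
    protein identifiers.
    """
    _require_connected(net, "centrality table")
    nodes = sorted(net.nodes())
    raw = pd.DataFrame(
        {
            "D": pd.Series(degree(net), dtype=float),
            "EC": pd.Series(eigenvector(net, tol=eigen_tol)),
            "TI1": pd.Series(topological_importance(net, 1)),
            "TI4": pd.Series(topological_importance(net, 4)),
            "B": pd.Series(betweenness(net)),
            "C": pd.Series(closeness(net)),
        },
        index=nodes,
    )
    raw.index.name = "protein_id"
    return normalize_max1(raw)


def normalize_max1(table: pd.DataFrame) -> pd.DataFrame:
    """Append (or refresh) ``*_norm`` columns dividing each index by its max.

    A column whose maximum is zero is left as zeros with a warning; the raw
    columns are preserved unchanged.  Idempotent.
    """
    if len(table) == 0:
        raise ValueError("cannot normalize an empty centrality table")
    present = [c for c in INDEX_LABELS if c in table.columns]
    out = table[present].copy()
    for col in present:
        colmax = out[col].max()
        if colmax > 0:
            out[f"{col}_norm"] = out[col] / colmax
        else:
            logger.warning("column %s has zero maximum; left unnormalized", col)
            out[f"{col}_norm"] = out[col]
    return out


def write_table(table: pd.DataFrame, path) -> None:
    """Serialize a centrality table as TSV (one row per protein)."""
    table.to_csv(path, sep="\t", float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    """Read a TSV centrality table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", index_col="protein_id")
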