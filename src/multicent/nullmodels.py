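"""Null-model networks and the redundancy analysis on them.

Three reference families are matched to an empirical network: uniform
G(n, m) graphs, degree-preserving rewirings of the network itself (double
edge swaps), and Watts-Strogatz small-world graphs with the same edge count
packed onto fewer nodes (hence higher density).  Rerunning the
centrality-redundancy analysis on these nulls shows which parts of the
empirical association structure follow from the degree sequence alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .centrality import INDEX_LABELS, centrality_table
from .graphio import giant_component
from .redundancy import IndexDendrogram, association_matrix, index_dendrogram


def _as_protein_graph(g: nx.Graph) -> nx.Graph:
    """Relabel integer nodes to zero-padded string identifiers."""
    width = len(str(max(g.nodes, default=0)))
    return nx.relabel_nodes(g, {n: f"N{n:0{width}d}" for n in g.nodes})


def gnm_random(n: int, m: int, seed: int | None = None) -> nx.Graph:
    """Uniform simple graph with exactly n nodes and m edges."""
    max_m = n * (n - 1) // 2
    if m > max_m:
        raise ValueError(f"cannot place {m} edges on {n} nodes (max {max_m})")
    return _as_protein_graph(nx.gnm_random_graph(n, m, seed=seed))


def rewire_preserving_degree(
    net: nx.Graph, swap_factor: float = 10.0, seed: int | None = None
) -> nx.Graph:
    """Randomize edges by double edge swaps, preserving every degree.

    Attempts ``swap_factor * m`` swaps; an attempt that would create a
    self-loop or duplicate edge is skipped, so graphs with no valid swap
    (e.g. stars) come back unchanged.
    """
    if net.number_of_edges() < 2:
        raise ValueError("need at least two edges to attempt a swap")
    rng = np.random.default_rng(seed)
    g = net.copy()
    edges = [tuple(e) for e in g.edges()]
    n_attempts = int(round(swap_factor * len(edges)))
    for _ in range(n_attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        # swap to (a, d), (c, b)
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i], edges[j] = (a, d), (c, b)
    return g


def small_world(
    n: int, mean_degree: int, p: float, seed: int | None = None
) -> nx.Graph:
    """Watts-Strogatz graph: ring lattice with probabilistic rewiring.

    ``mean_degree`` must be even and below n; every node starts linked to
    its ``mean_degree`` nearest ring neighbours and each edge is rewired
    with probability p (avoiding loops and duplicates), preserving the edge
    count n * mean_degree / 2.
    """
    if mean_degree % 2 != 0 or mean_degree >= n or mean_degree <= 0:
        raise ValueError("mean_degree must be a positive even number below n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("rewiring probability must lie in [0, 1]")
    return _as_protein_graph(nx.watts_strogatz_graph(n, mean_degree, p, seed=seed))


@dataclass(frozen=True)
class NullModelSpec:
    """One null-model family with generation parameters.

    ``model`` is one of ``gnm``, ``rewired``, ``smallworld``.  ``n``/``m``
    size gnm; ``mean_degree``/``p`` size the small-world model; ``rewired``
    uses the reference network itself.
    """

    model: str
    n: int | None = None
    m: int | None = None
    mean_degree: int | None = None
    p: float = 0.05
    swap_factor: float = 10.0
    replicates: int = 1
    seed: int | None = 0

    def __post_init__(self):
        if self.model not in ("gnm", "rewired", "smallworld"):
            raise ValueError(f"unknown null model {self.model!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _generate(spec: NullModelSpec, reference: nx.Graph, seed: int) -> nx.Graph:
    if spec.model == "gnm":
        n = spec.n or reference.number_of_nodes()
        m = spec.m or reference.number_of_edges()
        return gnm_random(n, m, seed=seed)
    if spec.model == "rewired":
        return rewire_preserving_degree(
            reference, swap_factor=spec.swap_factor, seed=seed
        )
    n = spec.n or reference.number_of_nodes()
    k = spec.mean_degree or max(
        2, 2 * round(reference.number_of_edges() / n)
    )
    return small_world(n, k, spec.p, seed=seed)


@dataclass
class NullModelSummary:
    """Replicate-averaged association matrix and its dendrogram."""

    spec: NullModelSpec
    mean_matrix: pd.DataFrame
    dendrogram: IndexDendrogram
    replicate_seeds: tuple[int, ...]

    def manifest(self) -> str:
        return json.dumps(
            {"spec": asdict(self.spec), "replicate_seeds": self.replicate_seeds},
            indent=2,
        )


def null_redundancy_suite(
    net: nx.Graph, specs: Sequence[NullModelSpec]
) -> dict[str, NullModelSummary]:
    """Redundancy analysis on every requested null model.

    For each replicate: generate the null graph, keep its giant component,
    compute the six-centrality table and its rank-association matrix; the
    per-model result is the entrywise mean matrix across replicates and the
    dendrogram built from it.  Fully reproducible under the NullModelSpec seeds.
    """
    out: dict[str, NullModelSummary] = {}
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        rep_seeds = tuple(int(s) for s in rng.integers(0, 2**31 - 1, spec.replicates))
        mats = []
        for s in rep_seeds:
            g = giant_component(_generate(spec, net, seed=s))
            table = centrality_table(g)
            mats.append(association_matrix(table))
        mean = sum(mats) / len(mats)
        mean = pd.DataFrame(mean, index=list(INDEX_LABELS), columns=list(INDEX_LABELS))
        out[spec.model] = NullModelSummary(
            spec=spec,
            mean_matrix=mean,
            dendrogram=index_dendrogram(mean),
            replicate_seeds=rep_seeds,
        )
    return out
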