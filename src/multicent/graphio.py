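"""Reading, writing and global description of interaction networks.

An interaction network is a simple undirected :class:`networkx.Graph` whose
nodes are opaque protein-identifier strings (UniProt accessions in practice)
and whose edges are unweighted binary interactions.  Self-loops and duplicate
interactions — common in merged interaction databases — are dropped at read
time, and all downstream analyses operate on the giant (largest connected)
component.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from typing import IO, Iterable

import networkx as nx

logger = logging.getLogger(__name__)

#: Header tokens that mark the first line of an edgelist as a column header.
HEADER_LABELS = frozenset({"protein1", "protein2"})


class EdgelistParseError(ValueError):
    """Raised for malformed edgelist input."""


@dataclass(frozen=True)
class NetworkStats:
    """Whole-network descriptive statistics.

    ``diameter`` and ``avg_path_length`` are shortest-path based and only
    defined on connected networks; on disconnected input they are ``None``.
    ``clustering_coefficient`` is the global transitivity
    (3 x triangles / connected triples); the mean-local variant is available
    separately via :func:`mean_local_clustering`.
    """

    n_nodes: int
    n_edges: int
    density: float
    clustering_coefficient: float
    diameter: int | None
    avg_path_length: float | None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def read_edgelist(source: IO[str] | Iterable[str]) -> nx.Graph:
    """Parse a two-column tab/whitespace-separated edgelist.

    Self-loops and duplicate edges are silently dropped (counts logged).
    A first line whose tokens match the known header labels ("protein1",
    "protein2") is skipped.

    Raises
    ------
    EdgelistParseError
        If a non-empty line has fewer than two tokens (the line number is
        reported), or if the input contains no edges at all.
    """
    net = nx.Graph()
    n_loops = 0
    n_dups = 0
    n_lines = 0
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line:
            continue
        tokens = line.split()
        if lineno == 1 and HEADER_LABELS.intersection(t.lower() for t in tokens):
            continue
        if len(tokens) < 2:
            raise EdgelistParseError(
                f"line {lineno}: expected two identifiers, got {line!r}"
            )
        a, b = tokens[0], tokens[1]
        n_lines += 1
        if a == b:
            n_loops += 1
            net.add_node(a)
            continue
        if net.has_edge(a, b):
            n_dups += 1
            continue
        net.add_edge(a, b)
    if n_lines == 0:
        raise EdgelistParseError("empty edgelist input")
    if n_loops or n_dups:
        logger.info(
            "dropped %d self-loop(s) and %d duplicate edge(s)", n_loops, n_dups
        )
    return net


def write_edgelist(net: nx.Graph, sink: IO[str], header: bool = True) -> None:
    """Write the network in the same tab-separated dialect read_edgelist reads."""
    if header:
        sink.write("protein1\tprotein2\n")
    for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
        sink.write(f"{a}\t{b}\n")


def giant_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties between equally sized components are broken in favour of the
    component containing the lexicographically smallest node.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network has no giant component")
    components = sorted(
        nx.connected_components(net), key=lambda c: (-len(c), min(c))
    )
    return net.subgraph(components[0]).copy()


def global_stats(net: nx.Graph) -> NetworkStats:
    """Density, global clustering, diameter and average shortest-path length.

    density = 2m / (n(n-1)); clustering = global transitivity.  On a
    disconnected network the path-based fields are ``None`` and a warning is
    logged.
    """
    n = net.number_of_nodes()
    m = net.number_of_edges()
    if n < 2:
        density = 0.0
    else:
        density = 2.0 * m / (n * (n - 1))
    transitivity = nx.transitivity(net)
    if n >= 2 and nx.is_connected(net):
        from .centrality import _to_igraph

        g, _ = _to_igraph(net)
        diameter = int(g.diameter())
        apl = float(g.average_path_length())
    else:
        logger.warning(
            "network is disconnected (or trivial): diameter and average "
            "path length undefined"
        )
        diameter = None
        apl = None
    return NetworkStats(
        n_nodes=n,
        n_edges=m,
        density=density,
        clustering_coefficient=transitivity,
        diameter=diameter,
        avg_path_length=apl,
    )


def mean_local_clustering(net: nx.Graph) -> float:
    """Mean of per-node local clustering coefficients (the non-default variant)."""
    return nx.average_clustering(net)
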