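"""Independent brute-force oracles for the path-based indices.

These enumerate geodesics and walk effects directly (no matrix algebra, no
graph-library centrality calls) and exist solely to cross-check the fast
implementations on small graphs.
"""

from itertools import combinations

import networkx as nx


def all_geodesics(net: nx.Graph, s, t):
    return list(nx.all_shortest_paths(net, s, t))


def brute_betweenness(net: nx.Graph) -> dict:
    """Fractional geodesic counting over unordered pairs, endpoints excluded."""
    score = {v: 0.0 for v in net.nodes}
    for s, t in combinations(net.nodes, 2):
        if not nx.has_path(net, s, t):
            continue
        paths = all_geodesics(net, s, t)
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


def brute_closeness(net: nx.Graph) -> dict:
    """(n-1) over the sum of BFS distances."""
    n = net.number_of_nodes()
    out = {}
    for v in net.nodes:
        dist = nx.single_source_shortest_path_length(net, v)
        out[v] = (n - 1) / sum(dist.values()) if n > 1 else 0.0
    return out


def brute_topological_importance(net: nx.Graph, m: int) -> dict:
    """Recursive walk-effect summation.

    The q-step effect of i on j sums, over all q-step walks from i to j,
    the product of 1/degree(receiver) at every step; TI^m averages the total
    outgoing effect over q = 1..m.
    """
    deg = dict(net.degree())

    # recursion: effect_q(i->j) = sum_{k ~ i} (1/deg k) * effect_{q-1}(k->j)
    def effect_q(i, q):
        if q == 0:
            return {i: 1.0}
        acc = {}
        for k in net.neighbors(i):
            for j, e in effect_q(k, q - 1).items():
                acc[j] = acc.get(j, 0.0) + (1.0 / deg[k]) * e
        return acc

    out = {}
    for i in net.nodes:
        total = 0.0
        for q in range(1, m + 1):
            eff = effect_q(i, q)
            total += sum(v for j, v in eff.items() if j != i)
        out[i] = total / m
    return out
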