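"""Small built-in example networks."""

from __future__ import annotations

import networkx as nx

#: Node names of the 9-node worked example: hub ``b`` with three branch
#: neighbours ``g1`` (no leaves), ``g2`` (three leaves) and ``g3`` (two).
TOY_HUB = "b"
TOY_BRANCHES = ("g1", "g2", "g3")


def toy_hub_tree() -> nx.Graph:
    """The 9-node tree used as the worked centrality example.

    A hub ``b`` is adjacent to three branch nodes; ``g2`` carries leaves
    ``w1..w3`` and ``g3`` carries ``w4, w5``.  On this tree the hub scores
    D = 3, TI^1 = 1 + 1/4 + 1/3 ~ 1.58, B = 19, C = 8/13 ~ 0.615 and an
    eigenvector score of 0.925 (g2 scores 1, g3 scores 0.676).
    """
    g = nx.Graph()
    g.add_edges_from(
        [
            ("b", "g1"),
            ("b", "g2"),
            ("b", "g3"),
            ("g2", "w1"),
            ("g2", "w2"),
            ("g2", "w3"),
            ("g3", "w4"),
            ("g3", "w5"),
        ]
    )
    return g
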