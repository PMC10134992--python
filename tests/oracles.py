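"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: modularity is
maximized by exhaustive set-partition enumeration, and the partition
quality function is written directly from the weighted-modularity
definition rather than through igraph.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import networkx as nx
import numpy as np


def set_partitions(items: Sequence) -> Iterator[list[list]]:
    """All partitions of ``items`` via restricted-growth strings."""
    n = len(items)
    if n == 0:
        yield []
        return
    codes = [0] * n
    maxes = [0] * n
    while True:
        blocks: dict[int, list] = {}
        for item, code in zip(items, codes):
            blocks.setdefault(code, []).append(item)
        yield [blocks[k] for k in sorted(blocks)]
        i = n - 1
        while i > 0:
            if codes[i] <= maxes[i - 1]:
                codes[i] += 1
                maxes[i] = max(maxes[i], codes[i])
                for j in range(i + 1, n):
                    codes[j] = 0
                    maxes[j] = maxes[i]
                break
            i -= 1
        else:
            return


def weighted_modularity(graph: nx.Graph, membership: dict) -> float:
    """Newman weighted modularity, computed from its definition."""
    total = sum(d["weight"] for _, _, d in graph.edges(data=True))
    if total == 0:
        return 0.0
    strength = {n: 0.0 for n in graph}
    for u, v, d in graph.edges(data=True):
        strength[u] += d["weight"]
        strength[v] += d["weight"]
    q = 0.0
    communities: dict[int, list] = {}
    for node, cid in membership.items():
        communities.setdefault(cid, []).append(node)
    for members in communities.values():
        internal = sum(d["weight"] for u, v, d in
                       graph.subgraph(members).edges(data=True))
        degree_sum = sum(strength[n] for n in members)
        q += internal / total - (degree_sum / (2 * total)) ** 2
    return q


def max_modularity_exhaustive(graph: nx.Graph) -> float:
    """Best weighted modularity over every partition of the node set."""
    nodes = sorted(graph.nodes)
    best = -np.inf
    for blocks in set_partitions(nodes):
        membership = {n: i for i, block in enumerate(blocks) for n in block}
        q = weighted_modularity(graph, membership)
        if q > best:
            best = q
    return float(best)


def correlation_p_closed_form(r: float, n: int) -> float:
    """Two-sided correlation p via the regularized incomplete beta function."""
    from scipy import special

    df = n - 2
    t2 = r * r * df / (1.0 - r * r)
    return float(special.betainc(df / 2.0, 0.5, df / (df + t2)))
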