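"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: orbit counts come
from exhaustive subset enumeration plus networkx isomorphism matching
against reference graphlets, and betweenness from explicit all-pairs
shortest-path enumeration.
"""

from itertools import combinations

import networkx as nx
import pandas as pd


def _reference_graphlets():
    """(graph, node -> orbit id) for every connected graphlet on 2-4 nodes."""
    out = []
    out.append((nx.Graph([(0, 1)]), {0: 0, 1: 0}))
    out.append((nx.path_graph(3), {0: 1, 1: 2, 2: 1}))
    out.append((nx.complete_graph(3), {i: 3 for i in range(3)}))
    out.append((nx.path_graph(4), {0: 4, 1: 5, 2: 5, 3: 4}))
    out.append((nx.star_graph(3), {0: 7, 1: 6, 2: 6, 3: 6}))
    out.append((nx.cycle_graph(4), {i: 8 for i in range(4)}))
    # tailed triangle: tail end 9, triangle rim 10, centre 11
    out.append((nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3)]), {0: 10, 1: 10, 2: 11, 3: 9}))
    # diamond: rim (degree 2) 12, chord (degree 3) 13
    out.append((nx.Graph([(0, 1), (1, 2), (2, 0), (0, 3), (1, 3)]),
                {2: 12, 3: 12, 0: 13, 1: 13}))
    out.append((nx.complete_graph(4), {i: 14 for i in range(4)}))
    return out


_REFS = _reference_graphlets()


def brute_force_orbits(g: nx.Graph) -> pd.DataFrame:
    """Exact node x 15 orbit counts by enumerating all 2-4 node subsets."""
    nodes = list(g.nodes)
    counts = pd.DataFrame(0, index=nodes, columns=range(15), dtype=int)
    for k in (2, 3, 4):
        for sub in combinations(nodes, k):
            sg = g.subgraph(sub)
            if not nx.is_connected(sg):
                continue
            for ref, orbit_of in _REFS:
                if len(ref) != k:
                    continue
                gm = nx.algorithms.isomorphism.GraphMatcher(sg, ref)
                if gm.is_isomorphic():
                    for node, ref_node in gm.mapping.items():
                        counts.at[node, orbit_of[ref_node]] += 1
                    break
    return counts


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Unnormalised betweenness by enumerating all shortest paths per pair."""
    nodes = list(g.nodes)
    btw = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                btw[v] += through / len(paths)
    return btw
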