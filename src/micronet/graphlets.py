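"""Graphlet-based network comparison.

Networks are summarised by how often each node participates in each orbit of
the connected graphlets on 2-4 nodes (orbits 0-14 in the standard numbering:
edge 0; path ends/middle 1/2; triangle 3; 4-path ends/middle 4/5; claw
leaves/centre 6/7; 4-cycle 8; tailed-triangle tail/rim/centre 9/10/11;
diamond rim/chord 12/13; K4 14). The Spearman correlation matrix of the 11
non-redundant orbits across nodes is a size-independent topology signature;
the Frobenius norm between two such matrices is the graphlet correlation
distance (GCD), and classical (Torgerson) MDS embeds a set of networks by
their pairwise GCDs.

Orbit counting enumerates each connected induced subgraph exactly once
(2-node from the edge list, 3-node by closed-form neighbourhood counts,
4-node by the ESU enumeration) and classifies it by its internal degree
sequence, which identifies every connected graphlet on <= 4 nodes uniquely.
"""

from __future__ import annotations

from dataclasses import dataclass


import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "N_ORBITS",
    "GCD11_ORBITS",
    "count_orbits",
    "graphlet_correlation_matrix",
    "GraphletCorrelationMatrix",
    "gcd",
    "embed_networks",
    "NetworkEmbedding",
]

N_ORBITS = 15
#: the canonical non-redundant orbit set used for graphlet correlation matrices
GCD11_ORBITS = (0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11)

# orbit of a node inside a connected 4-node graphlet, keyed by
# (edge count, node degree) -- unique for all connected graphs on 4 nodes
_ORBIT4 = {
    (3, 1, "path"): 4, (3, 2, "path"): 5,      # P4
    (3, 1, "star"): 6, (3, 3, "star"): 7,      # claw K1,3
    (4, 2, "cycle"): 8,                        # C4
    (4, 1, "paw"): 9, (4, 2, "paw"): 10, (4, 3, "paw"): 11,  # tailed triangle
    (5, 2, None): 12, (5, 3, None): 13,        # diamond
    (6, 3, None): 14,                          # K4
}


def _as_graph(net) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    return net.graph  # AssociationNetwork


def _esu_4sets(adj: dict, nodes: list):
    """Wernicke's ESU: yield each connected induced 4-subgraph exactly once."""
    index = {v: i for i, v in enumerate(nodes)}
    for v in nodes:
        ext = {u for u in adj[v] if index[u] > index[v]}
        yield from _esu_extend([v], ext, v, adj, index, 4)


def _esu_extend(sub, ext, root, adj, index, k):
    if len(sub) == k:
        yield tuple(sub)
        return
    sub_neighbors = set().union(*(adj[u] for u in sub)) | set(sub)
    ext = set(ext)
    while ext:
        w = ext.pop()
        new_ext = ext | {u for u in adj[w]
                         if index[u] > index[root] and u not in sub_neighbors}
        yield from _esu_extend(sub + [w], new_ext, root, adj, index, k)


def _classify4(sub, adj):
    """Orbit id per node of a connected 4-set."""
    deg = {v: sum(1 for u in sub if u != v and u in adj[v]) for v in sub}
    m = sum(deg.values()) // 2
    degs = sorted(deg.values())
    if m == 3:
        kind = "star" if degs == [1, 1, 1, 3] else "path"
    elif m == 4:
        kind = "cycle" if degs == [2, 2, 2, 2] else "paw"
    else:
        kind = None
    return {v: _ORBIT4[(m, deg[v], kind)] for v in sub}


def count_orbits(net) -> pd.DataFrame:
    """Node x 15 orbit participation counts (exact, induced subgraphs)."""
    g = _as_graph(net)
    nodes = list(g.nodes)
    counts = pd.DataFrame(0, index=nodes, columns=range(N_ORBITS), dtype=np.int64)
    if not nodes:
        return counts
    adj = {v: set(g.neighbors(v)) for v in nodes}
    deg = pd.Series({v: len(adj[v]) for v in nodes})

    # orbit 0: the edge graphlet = degree
    counts[0] = deg

    # 3-node graphlets in closed form
    A = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    tri = pd.Series(((A @ A) * A).sum(axis=1) / 2, index=nodes).round().astype(np.int64)
    counts[3] = tri
    counts[2] = (deg * (deg - 1) // 2) - tri
    nbr_deg_sum = pd.Series({v: sum(deg[u] - 1 for u in adj[v]) for v in nodes})
    counts[1] = nbr_deg_sum - 2 * tri

    # 4-node graphlets by ESU enumeration
    for sub in _esu_4sets(adj, nodes):
        for v, orbit in _classify4(sub, adj).items():
            counts.at[v, orbit] += 1
    return counts


@dataclass
class GraphletCorrelationMatrix:
    """Spearman correlations among the 11 non-redundant orbit counts."""

    values: np.ndarray
    orbit_ids: tuple = GCD11_ORBITS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.orbit_ids),) * 2:
            raise ValueError("GCM shape must match the orbit set")
        if np.abs(v - v.T).max(initial=0) > 1e-10 or np.abs(np.diag(v) - 1).max() > 1e-10:
            raise ValueError("GCM must be symmetric with unit diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.orbit_ids),
                            columns=list(self.orbit_ids))


def graphlet_correlation_matrix(orbits: pd.DataFrame,
                                orbit_ids=GCD11_ORBITS) -> GraphletCorrelationMatrix:
    """GCM from an orbit count matrix.

    A dummy node with all orbit counts 1 is appended before the Spearman
    correlation so that all-constant orbit columns (common in small or
    regular graphs) still have defined correlations; any remaining
    undefined entry (both columns constant after the dummy) is set to 0.
    """
    if orbits.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    sub = orbits[list(orbit_ids)].to_numpy(dtype=float)
    sub = np.vstack([sub, np.ones(len(orbit_ids))])
    with np.errstate(invalid="ignore"):
        corr = spearmanr(sub, axis=0).statistic
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2
    return GraphletCorrelationMatrix(values=corr, orbit_ids=tuple(orbit_ids))


def gcd(a: GraphletCorrelationMatrix, b: GraphletCorrelationMatrix,
        mode: str = "frobenius") -> float:
    """Graphlet correlation distance between two networks' GCMs.

    ``frobenius`` (default) is the norm over the full matrix; ``upper`` uses
    the strict upper triangle only (smaller by a factor sqrt(2)).
    """
    if a.orbit_ids != b.orbit_ids:
        raise ValueError("GCMs computed over different orbit sets")
    diff = a.values - b.values
    if mode == "frobenius":
        return float(np.linalg.norm(diff))
    if mode == "upper":
        iu = np.triu_indices(diff.shape[0], k=1)
        return float(np.sqrt((diff[iu] ** 2).sum()))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class NetworkEmbedding:
    """Classical-MDS coordinates for a set of networks."""

    coordinates: np.ndarray          # n_networks x 2
    eigenvalues: np.ndarray
    labels: list
    distances: np.ndarray
    stress: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coordinates, columns=["x", "y"])
        df.insert(0, "network", [str(l) for l in self.labels])
        return df


def pairwise_gcd(nets, mode: str = "frobenius") -> np.ndarray:
    gcms = []
    for net in nets:
        if isinstance(net, GraphletCorrelationMatrix):
            gcms.append(net)
        else:
            gcms.append(graphlet_correlation_matrix(count_orbits(net)))
    k = len(gcms)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = gcd(gcms[i], gcms[j], mode=mode)
    return D


def embed_networks(nets, labels=None, mode: str = "frobenius") -> NetworkEmbedding:
    """Classical (Torgerson) MDS of pairwise graphlet correlation distances.

    Accepts networks or precomputed :class:`GraphletCorrelationMatrix`
    objects; requires at least 3 of them. The first two principal coordinates
    are returned together with the full eigenvalue spectrum and the raw
    stress (root sum of squared distance discrepancies in 2-D).
    """
    if len(nets) < 3:
        raise ValueError("need at least 3 networks to embed")
    D = pairwise_gcd(nets, mode=mode)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = eigvec[:, :2] * np.sqrt(np.clip(eigval[:2], 0, None))
    emb_d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, k=1)
    stress = float(np.sqrt(((emb_d[iu] - D[iu]) ** 2).sum()))
    if labels is None:
        labels = list(range(n))
    return NetworkEmbedding(coordinates=coords, eigenvalues=eigval,
                            labels=list(labels), distances=D, stress=stress)
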