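"""Network robustness under simulated attack, and keystone-taxon ranking.

Natural connectivity, ln((1/N) sum_i exp(lambda_i)) over the adjacency
spectrum, is a spectral robustness measure that decreases monotonically as
edges are removed. Attack curves record it as nodes are deleted one at a
time: at random (averaged over orderings), or targeted by degree or
betweenness centrality of the intact graph. Keystone taxa are nodes that are
simultaneously hubs (high degree) and bottlenecks (high betweenness); they
are ranked by the sum of the two ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

__all__ = ["natural_connectivity", "betweenness_centrality", "attack_curves",
           "AttackCurve", "keystone_taxa", "KeystoneRanking"]


def _as_graph(net) -> nx.Graph:
    return net if isinstance(net, nx.Graph) else net.graph


def natural_connectivity(net) -> float:
    """ln of the average eigenvalue exponential of the unweighted adjacency."""
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity undefined on an empty node set")
    A = nx.to_numpy_array(g, weight=None)
    lam = np.linalg.eigvalsh(A)
    return float(logsumexp(lam) - np.log(n))


def betweenness_centrality(net) -> pd.Series:
    """Exact unnormalised shortest-path betweenness (Brandes)."""
    g = _as_graph(net)
    return pd.Series(nx.betweenness_centrality(g, normalized=False), dtype=float)


@dataclass
class AttackCurve:
    """Natural connectivity as nodes are removed under one strategy.

    ``values`` has shape (n_orderings, n_steps); step 0 is the intact graph
    and removal stops when a single node remains. For deterministic
    strategies n_orderings == 1.
    """

    strategy: str
    fraction_removed: np.ndarray
    values: np.ndarray
    n_orderings: int = 1

    @property
    def mean_curve(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def auc(self) -> float:
        """Area under the mean curve over the removed fraction (trapezoid)."""
        return float(np.trapezoid(self.mean_curve, self.fraction_removed))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in range(self.values.shape[0]):
            for s, (f, v) in enumerate(zip(self.fraction_removed, self.values[o])):
                rows.append({"strategy": self.strategy, "ordering_id": o,
                             "step": s, "fraction_removed": f, "value": v})
        return pd.DataFrame(rows)


def _trace(g: nx.Graph, order) -> np.ndarray:
    work = g.copy()
    vals = [natural_connectivity(work)]
    for v in order[:-1]:  # stop when one node remains
        work.remove_node(v)
        vals.append(natural_connectivity(work))
    return np.array(vals)


def _dynamic_trace(g: nx.Graph, stat: str) -> np.ndarray:
    work = g.copy()
    vals = [natural_connectivity(work)]
    while work.number_of_nodes() > 1:
        if stat == "degree":
            scores = dict(work.degree())
        else:
            scores = nx.betweenness_centrality(work, normalized=False)
        target = max(sorted(scores), key=lambda v: scores[v])
        work.remove_node(target)
        vals.append(natural_connectivity(work))
    return np.array(vals)


def attack_curves(
    net,
    strategies=("random", "degree", "betweenness"),
    n_random_orderings: int = 30,
    rng_seed: int = 0,
    dynamic: bool = False,
) -> list[AttackCurve]:
    """Attack the network node by node and record natural connectivity.

    Targeted strategies remove nodes in decreasing order of the intact
    graph's degree or betweenness (static ordering; set ``dynamic=True`` to
    recompute the target after every removal). The random strategy averages
    ``n_random_orderings`` random orderings (default 30). Ties in targeted
    orderings break lexically by node id for determinism.
    """
    if n_random_orderings < 1:
        raise ValueError("n_random_orderings must be >= 1")
    g = _as_graph(net)
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("attack needs at least 2 nodes")
    frac = np.arange(n) / n
    rng = np.random.default_rng(rng_seed)
    curves = []
    for strat in strategies:
        if strat == "random":
            traces = np.vstack([
                _trace(g, [nodes[i] for i in rng.permutation(n)])
                for _ in range(n_random_orderings)
            ])
            curves.append(AttackCurve(strat, frac, traces, n_random_orderings))
        elif strat in ("degree", "betweenness"):
            if dynamic:
                traces = _dynamic_trace(g, strat)[None, :]
            else:
                scores = (dict(g.degree()) if strat == "degree"
                          else nx.betweenness_centrality(g, normalized=False))
                order = sorted(nodes, key=lambda v: (-scores[v], v))
                traces = _trace(g, order)[None, :]
            curves.append(AttackCurve(strat, frac, traces, 1))
        else:
            raise ValueError(f"unknown attack strategy {strat!r}")
    return curves


@dataclass
class KeystoneRanking:
    """Per-node hub/bottleneck statistics and the combined keystone score."""

    table: pd.DataFrame   # taxon-indexed: degree, betweenness, score, rank
    k: int

    @property
    def top(self) -> list[str]:
        return list(self.table.index[: self.k])

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index(names="taxon")


def keystone_taxa(net, k: int = 3) -> KeystoneRanking:
    """Rank taxa that are both hubs and bottlenecks.

    Score = rank of degree + rank of betweenness (rank 1 = highest, average
    ranks on ties); lower score is better. Residual ties break by higher
    geometric-mean abundance (node attribute, when present), then by taxon id.
    """
    g = _as_graph(net)
    nodes = list(g.nodes)
    if k > len(nodes):
        raise ValueError("k exceeds the number of nodes")
    deg = pd.Series(dict(g.degree()), dtype=float)[nodes]
    btw = betweenness_centrality(g)[nodes]
    deg_rank = pd.Series(rankdata(-deg.to_numpy(), method="average"), index=nodes)
    btw_rank = pd.Series(rankdata(-btw.to_numpy(), method="average"), index=nodes)
    score = deg_rank + btw_rank
    abund = pd.Series({v: g.nodes[v].get("mean_abundance", 0.0) for v in nodes}).fillna(0.0)
    df = pd.DataFrame({
        "degree": deg, "betweenness": btw,
        "degree_rank": deg_rank, "betweenness_rank": btw_rank,
        "score": score, "mean_abundance": abund,
    })
    df = df.assign(_taxon=df.index.astype(str)).sort_values(
        ["score", "mean_abundance", "_taxon"], ascending=[True, False, True]
    ).drop(columns="_taxon")
    df["rank"] = np.arange(1, len(df) + 1)
    if "taxonomy_family" in next(iter(g.nodes(data=True)), (None, {}))[1]:
        df["taxonomy_family"] = [g.nodes[v].get("taxonomy_family", "") for v in df.index]
    return KeystoneRanking(table=df, k=k)
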