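"""Sparse microbial association network inference.

The model estimates a conditional-dependence graph over taxa from
clr-transformed counts by per-node L1-penalised regression (neighbourhood
selection): each taxon's clr profile is regressed on all other taxa's
profiles with a lasso penalty, and an edge is drawn between two taxa when
either neighbourhood selects the other (OR rule; AND available). Because
compositional counts only identify abundances up to the per-sample total,
the clr representation is the standard device that makes this regression
meaningful for relative-abundance data.

Regularisation is chosen by StARS (Stability Approach to Regularisation
Selection): the graph is re-estimated on many subsamples along a decreasing
lambda path, per-edge selection frequencies f give per-edge instabilities
2 f (1 - f), and the selected lambda is the smallest one whose monotonised
mean instability stays below the threshold beta (default 0.05). The
per-edge selection frequencies at the selected lambda double as edge
confidence scores.

Usage::

    model = NeighborhoodNetwork(clr)
    res = model.fit(seed=0)           # StARS selection -> StarsResults
    net = res.network(table)          # prevalence-filtered AssociationNetwork
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .otu import ClrMatrix, OtuTable

__all__ = ["LambdaPath", "NeighborhoodNetwork", "StarsResults", "AssociationNetwork",
           "neighborhood_fit", "stars_select", "build_network"]


# ---------------------------------------------------------------------------
# lambda path
# ---------------------------------------------------------------------------

@dataclass
class LambdaPath:
    """Strictly decreasing positive regularisation strengths."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v <= 0).any() or (np.diff(v) >= 0).any():
            raise ValueError("lambda path must be strictly decreasing and positive")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)

    @property
    def min_ratio(self) -> float:
        return float(self.values[-1] / self.values[0])

    @classmethod
    def from_data(cls, X: np.ndarray, length: int = 30, min_ratio: float = 0.01) -> "LambdaPath":
        """Log-spaced path from lambda_max = max |off-diagonal correlation|."""
        lam_max = _lambda_max(X)
        return cls(np.geomspace(lam_max, lam_max * min_ratio, length))


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 1e-12
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return Z, ok


def _lambda_max(X: np.ndarray) -> float:
    Z, ok = _standardize(X)
    n = X.shape[0]
    C = (Z.T @ Z) / n
    np.fill_diagonal(C, 0.0)
    m = np.abs(C).max(initial=0.0)
    return m if m > 0 else 1.0


# ---------------------------------------------------------------------------
# neighbourhood lasso
# ---------------------------------------------------------------------------

def _neighborhood_coefs(X: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Directed lasso coefficients along the path.

    Returns ``coefs[l, j, i]`` = coefficient of predictor i in the
    regression of node j at ``lambdas[l]`` (standardised data, sklearn
    1/(2n) objective scaling so lambda equals a correlation scale).
    Constant columns are left isolated.
    """
    n, p = X.shape
    Z, ok = _standardize(X)
    coefs = np.zeros((len(lambdas), p, p))
    for j in range(p):
        if not ok[j]:
            warnings.warn(f"constant clr column {j}: node left isolated")
            continue
        mask = np.arange(p) != j
        _, path_coefs, _ = lasso_path(Z[:, mask], Z[:, j], alphas=lambdas)
        # lasso_path sorts alphas descending, matching our decreasing path
        coefs[:, j, mask] = path_coefs.T
    return coefs


def _symmetrize(coefs_l: np.ndarray, rule: str = "or"):
    """Adjacency and sign matrices from one lambda's directed coefficients."""
    present = coefs_l != 0
    if rule == "or":
        adj = present | present.T
    elif rule == "and":
        adj = present & present.T
    else:
        raise ValueError(f"unknown symmetrization rule {rule!r}")
    np.fill_diagonal(adj, False)
    sign = np.sign(coefs_l + coefs_l.T) * adj
    return adj, sign


def neighborhood_fit(clr: ClrMatrix | pd.DataFrame, lam: float, rule: str = "or"):
    """One-shot neighbourhood selection at a single penalty.

    Returns ``(adjacency, sign)`` as taxa x taxa DataFrames.
    """
    values = clr.values if isinstance(clr, ClrMatrix) else clr
    X = np.asarray(values, dtype=float)
    taxa = list(values.columns)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 2 taxa and >= 3 samples")
    coefs = _neighborhood_coefs(X, np.array([lam], dtype=float))
    adj, sign = _symmetrize(coefs[0], rule=rule)
    return (pd.DataFrame(adj, index=taxa, columns=taxa),
            pd.DataFrame(sign, index=taxa, columns=taxa))


# ---------------------------------------------------------------------------
# association networks
# ---------------------------------------------------------------------------

def _family(lineage: str) -> str:
    for token in str(lineage).split(";"):
        token = token.strip()
        if token.startswith("f__"):
            return token[3:] or "unclassified"
    return "unclassified"


@dataclass
class AssociationNetwork:
    """Undirected network over taxa with signed, confidence-weighted edges."""

    graph: nx.Graph

    @property
    def taxa(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edge_density(self) -> float:
        n = self.graph.number_of_nodes()
        pairs = n * (n - 1) / 2
        return self.n_edges / pairs if pairs else 0.0

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((u, v))) for u, v in self.graph.edges}

    def adjacency(self) -> pd.DataFrame:
        nodes = self.taxa
        return pd.DataFrame(
            nx.to_numpy_array(self.graph, nodelist=nodes, weight=None).astype(bool),
            index=nodes, columns=nodes,
        )

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def to_edge_tsv(self, path) -> None:
        rows = [
            {"taxon_a": min(u, v), "taxon_b": max(u, v),
             "sign": d.get("sign", 0), "confidence": d.get("confidence", np.nan)}
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "sign", "confidence"]) \
            .sort_values(["taxon_a", "taxon_b"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_adjacency(cls, adj: pd.DataFrame, sign: pd.DataFrame | None = None,
                       confidence: pd.DataFrame | None = None) -> "AssociationNetwork":
        g = nx.Graph()
        taxa = list(adj.index)
        g.add_nodes_from(taxa)
        A = adj.to_numpy(dtype=bool)
        for a in range(len(taxa)):
            for b in range(a + 1, len(taxa)):
                if A[a, b]:
                    attrs = {}
                    if sign is not None:
                        attrs["sign"] = int(np.sign(sign.iloc[a, b]))
                    if confidence is not None:
                        attrs["confidence"] = float(confidence.iloc[a, b])
                    g.add_edge(taxa[a], taxa[b], **attrs)
        return cls(graph=g)


# ---------------------------------------------------------------------------
# StARS
# ---------------------------------------------------------------------------

@dataclass
class StarsResults:
    """Stability-selection output over the lambda path.

    ``edge_frequency[l]`` is the fraction of subsamples in which each node
    pair was selected at path lambda l; per-edge instability is
    ``2 f (1 - f)`` and ``instability`` its mean over all node pairs.
    ``full_adjacency``/``full_sign`` are the full-data refits along the path.
    """

    taxa: list[str]
    path: LambdaPath
    edge_frequency: np.ndarray          # (L, p, p) symmetric
    instability: np.ndarray             # (L,)
    monotone_instability: np.ndarray    # (L,)
    selected_index: int
    n_subsamples: int
    subsample_size: int
    beta: float
    full_adjacency: np.ndarray          # (L, p, p) bool
    full_sign: np.ndarray               # (L, p, p)
    seed: int | None = None
    no_lambda_flag: bool = False

    @property
    def selected_lambda(self) -> float:
        return float(self.path.values[self.selected_index])

    def frequency_frame(self, index: int | None = None) -> pd.DataFrame:
        idx = self.selected_index if index is None else index
        return pd.DataFrame(self.edge_frequency[idx], index=self.taxa, columns=self.taxa)

    def selected_adjacency(self) -> pd.DataFrame:
        return pd.DataFrame(self.full_adjacency[self.selected_index],
                            index=self.taxa, columns=self.taxa)

    def selected_sign(self) -> pd.DataFrame:
        return pd.DataFrame(self.full_sign[self.selected_index],
                            index=self.taxa, columns=self.taxa)

    def network(self, table: OtuTable | None = None, min_prevalence: float = 0.0) -> AssociationNetwork:
        return build_network(self, table, min_prevalence=min_prevalence)

    def summary(self) -> str:
        lines = [
            "Neighborhood selection with StARS",
            f"  taxa: {len(self.taxa)}   lambda path: {len(self.path)} values "
            f"({self.path.values[0]:.4f} .. {self.path.values[-1]:.4f})",
            f"  subsamples: {self.n_subsamples} of size {self.subsample_size}   beta: {self.beta}",
            f"  selected lambda: {self.selected_lambda:.4f} (index {self.selected_index})"
            + ("  [no lambda met beta; densest returned]" if self.no_lambda_flag else ""),
            f"  instability at selection: {self.monotone_instability[self.selected_index]:.4f}",
            f"  edges at selection: {int(self.full_adjacency[self.selected_index].sum() // 2)}",
        ]
        return "\n".join(lines)


class NeighborhoodNetwork:
    """Model object: sparse neighbourhood-selection network over taxa.

    Parameters
    ----------
    clr : ClrMatrix or samples x taxa DataFrame
    rule : 'or' | 'and'
        Edge symmetrisation rule across the two directed neighbourhoods.
    """

    def __init__(self, clr: ClrMatrix | pd.DataFrame, rule: str = "or"):
        values = clr.values if isinstance(clr, ClrMatrix) else clr
        self.values = values
        self.X = np.asarray(values, dtype=float)
        self.taxa = list(values.columns)
        self.sample_ids = list(values.index)
        self.rule = rule
        if self.X.shape[1] < 2 or self.X.shape[0] < 3:
            raise ValueError("need >= 2 taxa and >= 3 samples")

    @classmethod
    def from_table(cls, table: OtuTable, pseudocount: float = 1.0, **kw) -> "NeighborhoodNetwork":
        from .prep import clr_transform
        return cls(clr_transform(table, pseudocount=pseudocount), **kw)

    def fit_path(self, path: LambdaPath | None = None):
        """Full-data adjacency/sign along the lambda path (no subsampling)."""
        path = path or LambdaPath.from_data(self.X)
        coefs = _neighborhood_coefs(self.X, path.values)
        adj = np.zeros(coefs.shape, dtype=bool)
        sign = np.zeros(coefs.shape)
        for l in range(len(path)):
            adj[l], sign[l] = _symmetrize(coefs[l], rule=self.rule)
        return path, adj, sign

    def fit(
        self,
        path: LambdaPath | None = None,
        n_subsamples: int = 50,
        subsample_size: int | None = None,
        beta: float = 0.05,
        seed: int = 0,
    ) -> StarsResults:
        """Run StARS stability selection and return :class:`StarsResults`."""
        n, p = self.X.shape
        if n_subsamples < 2:
            raise ValueError("n_subsamples must be >= 2")
        if subsample_size is None:
            subsample_size = min(int(np.floor(10 * np.sqrt(n))), int(np.floor(0.8 * n)))
        if not 1 < subsample_size < n:
            raise ValueError("subsample_size must lie strictly between 1 and n_samples")
        path, full_adj, full_sign = self.fit_path(path)
        L = len(path)
        rng = np.random.default_rng(seed)
        freq = np.zeros((L, p, p))
        for _ in range(n_subsamples):
            idx = rng.choice(n, size=subsample_size, replace=False)
            coefs = _neighborhood_coefs(self.X[idx], path.values)
            for l in range(L):
                adj, _ = _symmetrize(coefs[l], rule=self.rule)
                freq[l] += adj
        freq /= n_subsamples
        iu = np.triu_indices(p, k=1)
        xi = 2.0 * freq * (1.0 - freq)
        instability = np.array([xi[l][iu].mean() for l in range(L)])
        monotone = np.maximum.accumulate(instability)  # non-decreasing as lambda decreases
        ok = np.nonzero(monotone <= beta)[0]
        if len(ok):
            selected = int(ok[-1])  # smallest stable lambda -> densest stable graph
            flag = False
        else:
            selected = L - 1
            flag = True
            warnings.warn("no lambda met the StARS instability threshold; "
                          "returning the densest path graph")
        return StarsResults(
            taxa=self.taxa, path=path, edge_frequency=freq,
            instability=instability, monotone_instability=monotone,
            selected_index=selected, n_subsamples=n_subsamples,
            subsample_size=subsample_size, beta=beta,
            full_adjacency=full_adj, full_sign=full_sign,
            seed=seed, no_lambda_flag=flag,
        )


def stars_select(
    clr: ClrMatrix | pd.DataFrame,
    path: LambdaPath | None = None,
    n_subsamples: int = 50,
    subsample_size: int | None = None,
    beta: float = 0.05,
    rng_seed: int = 0,
    rule: str = "or",
) -> StarsResults:
    """Functional wrapper over :meth:`NeighborhoodNetwork.fit`."""
    return NeighborhoodNetwork(clr, rule=rule).fit(
        path=path, n_subsamples=n_subsamples, subsample_size=subsample_size,
        beta=beta, seed=rng_seed,
    )


def build_network(
    stab: StarsResults,
    table: OtuTable | None = None,
    min_prevalence: float = 0.0,
) -> AssociationNetwork:
    """Association network at the selected lambda.

    Nodes are restricted to taxa present in strictly more than
    ``min_prevalence`` of samples (requires ``table``); edge confidence is
    the StARS selection frequency at the selected lambda; nodes carry
    family-level taxonomy and geometric-mean relative abundance.
    """
    taxa = list(stab.taxa)
    abundance = {}
    families = {}
    if table is not None:
        missing = set(taxa) - set(table.taxon_ids)
        if missing:
            raise ValueError("stability result computed on taxa absent from table")
        if min_prevalence > 0:
            prev = (table.counts.loc[taxa] > 0).mean(axis=1)
            taxa = [t for t in taxa if prev[t] > min_prevalence]
        relab = table.relative_abundance().loc[stab.taxa]
        pseudo = 0.5 / max(table.depths().max(), 1)
        gm = np.exp(np.log(relab + pseudo).mean(axis=1))
        abundance = gm.to_dict()
        families = {t: _family(table.taxonomy.loc[t]) for t in stab.taxa}

    pos = {t: i for i, t in enumerate(stab.taxa)}
    adj = stab.full_adjacency[stab.selected_index]
    sign = stab.full_sign[stab.selected_index]
    conf = stab.edge_frequency[stab.selected_index]
    g = nx.Graph()
    for t in taxa:
        g.add_node(t,
                   taxonomy_family=families.get(t, "unclassified"),
                   mean_abundance=float(abundance.get(t, np.nan)))
    for a in range(len(taxa)):
        for b in range(a + 1, len(taxa)):
            i, j = pos[taxa[a]], pos[taxa[b]]
            if adj[i, j]:
                g.add_edge(taxa[a], taxa[b],
                           sign=int(np.sign(sign[i, j])),
                           confidence=float(conf[i, j]))
    return AssociationNetwork(graph=g)
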