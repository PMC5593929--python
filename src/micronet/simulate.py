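"""Synthetic data with known ground truth.

Every downstream stage of the pipeline has a recovery test against data
generated here: sparse conditional-dependence graphs, logistic-normal
multinomial count tables whose latent precision matrix has exactly the
graph's support, two-condition (control vs antibiotic-perturbed) designs in
which the perturbed condition loses a designated keystone hub, longitudinal
per-subject sIgA trajectories driven by a known sparse set of clr-taxa, and
paired IgA+/IgA- fraction tables with known coating affinities.

Counts are drawn from a logistic-normal multinomial: a latent Gaussian
z ~ N(0, precision^-1) is pushed through a softmax to a composition, and
reads are multinomial at a per-sample depth. The clr transform of such counts
approximately recovers the latent z up to its per-sample mean, which makes
clr-based neighbourhood selection the matched estimator.

Defaults describe a desk-scale murine 16S study: p=50 taxa, n=100 samples,
depths uniform in 2,000-20,000 reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu import OtuTable

__all__ = [
    "SyntheticTruth",
    "synth_graph",
    "make_precision",
    "synth_counts",
    "synth_two_condition",
    "synth_longitudinal_iga",
    "synth_igaseq",
]

DEFAULT_DEPTH_RANGE = (2_000, 20_000)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _taxon_ids(p: int) -> list[str]:
    return [f"OTU{i:03d}" for i in range(p)]


@dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic community.

    ``graph`` is a p x p boolean adjacency; ``precision`` is symmetric
    positive definite with off-diagonal support exactly equal to the graph's
    edges. ``spls_support``/``spls_beta`` define which clr-taxa drive the
    sIgA response, and ``coating_affinity`` the per-taxon IgA coating odds.
    """

    graph: np.ndarray
    precision: np.ndarray
    condition: str = "control"
    taxon_ids: list[str] = field(default_factory=list)
    spls_support: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    spls_beta: np.ndarray = field(default_factory=lambda: np.array([]))
    coating_affinity: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = self.graph.shape[0]
        if not self.taxon_ids:
            self.taxon_ids = _taxon_ids(p)
        self.graph = np.asarray(self.graph, dtype=bool)
        np.fill_diagonal(self.graph, False)
        if not np.array_equal(self.graph, self.graph.T):
            raise ValueError("graph adjacency must be symmetric")
        eig = np.linalg.eigvalsh(self.precision)
        if eig.min() <= 0:
            raise ValueError("precision matrix is not positive definite")
        off_support = (np.abs(self.precision) > 1e-12) & ~np.eye(p, dtype=bool)
        if not np.array_equal(off_support, self.graph):
            raise ValueError("precision off-diagonal support must equal graph edges")
        if self.coating_affinity is None:
            self.coating_affinity = np.ones(p)

    @property
    def p(self) -> int:
        return self.graph.shape[0]

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def edge_set(self) -> set[tuple[str, str]]:
        iu, ju = np.triu_indices(self.p, k=1)
        return {
            tuple(sorted((self.taxon_ids[i], self.taxon_ids[j])))
            for i, j in zip(iu, ju)
            if self.graph[i, j]
        }

    def edges_to_tsv(self, path) -> None:
        rows = sorted(self.edge_set())
        pd.DataFrame(rows, columns=["taxon_a", "taxon_b"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# graphs and precision matrices
# ---------------------------------------------------------------------------

def synth_graph(p: int, topology: str = "band", n_edges: int | None = None, rng_seed=0) -> np.ndarray:
    """Simple undirected graph with exactly ``n_edges`` edges.

    ``band``: fills diagonals (i, i+1), (i, i+2), ... in order, giving a
    path/band structure. ``cluster``: dense blocks filled in random order.
    ``scale_free``: preferential attachment, producing a heavy-tailed degree
    distribution with hubs. Isolated nodes are allowed when ``n_edges`` is
    small.
    """
    rng = _rng(rng_seed)
    max_edges = p * (p - 1) // 2
    if n_edges is None:
        n_edges = p
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"n_edges={n_edges} infeasible for p={p}")
    adj = np.zeros((p, p), dtype=bool)

    def add(i, j):
        adj[i, j] = adj[j, i] = True

    if topology == "band":
        added = 0
        for width in range(1, p):
            for i in range(p - width):
                if added == n_edges:
                    break
                add(i, i + width)
                added += 1
            if added == n_edges:
                break
    elif topology == "cluster":
        n_blocks = 3
        while n_blocks > 1:
            sizes = [len(b) for b in np.array_split(np.arange(p), n_blocks)]
            if sum(s * (s - 1) // 2 for s in sizes) >= n_edges:
                break
            n_blocks -= 1
        pairs = []
        for block in np.array_split(np.arange(p), n_blocks):
            pairs.extend((int(block[a]), int(block[b]))
                         for a in range(len(block)) for b in range(a + 1, len(block)))
        order = rng.permutation(len(pairs))
        for k in order[:n_edges]:
            add(*pairs[k])
    elif topology == "scale_free":
        # preferential attachment on the first m+1 nodes (m = n_edges), then
        # densify by degree-proportional pairing if a tree is not enough
        if n_edges == 0:
            return adj
        m = min(p, n_edges + 1)
        add(0, 1)
        deg = adj.sum(axis=0).astype(float)
        for v in range(2, m):
            probs = deg[:v] / deg[:v].sum()
            add(v, int(rng.choice(v, p=probs)))
            deg = adj.sum(axis=0).astype(float)
        while adj.sum() // 2 < n_edges:
            deg = adj.sum(axis=0).astype(float) + 1e-9
            probs = deg / deg.sum()
            i, j = rng.choice(p, size=2, replace=False, p=probs)
            if not adj[i, j]:
                add(i, j)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    assert adj.sum() // 2 == n_edges
    return adj


def make_precision(adj: np.ndarray, edge_weight: float = 0.5, rng_seed=0,
                   sign_mix: float = 0.0) -> np.ndarray:
    """Positive-definite precision matrix with support equal to ``adj``.

    Off-diagonal entries get magnitude ``edge_weight`` (a fraction
    ``sign_mix`` of edges flipped to negative); the diagonal is raised to
    ``|lambda_min| + 0.1`` above singularity, which also bounds the condition
    number.
    """
    rng = _rng(rng_seed)
    p = adj.shape[0]
    omega = np.zeros((p, p))
    iu, ju = np.triu_indices(p, k=1)
    for i, j in zip(iu, ju):
        if adj[i, j]:
            s = -1.0 if rng.random() < sign_mix else 1.0
            omega[i, j] = omega[j, i] = s * edge_weight
    eig_min = np.linalg.eigvalsh(omega).min()
    np.fill_diagonal(omega, abs(eig_min) + 0.1)
    return omega


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _sample_counts(truth: SyntheticTruth, n_samples: int, depth_range, rng,
                   base_log_abundance: np.ndarray | None = None):
    cov = truth.covariance
    lo, hi = depth_range
    if lo <= 0 or hi < lo:
        raise ValueError("depth_range must be positive with lo <= hi")
    z = rng.multivariate_normal(np.zeros(truth.p), cov, size=n_samples, method="cholesky")
    if base_log_abundance is not None:
        z = z + base_log_abundance
    z = z - z.max(axis=1, keepdims=True)
    comp = np.exp(z)
    comp /= comp.sum(axis=1, keepdims=True)
    depths = rng.integers(lo, hi + 1, size=n_samples)
    counts = np.vstack([rng.multinomial(d, c) for d, c in zip(depths, comp)])
    return counts.T  # taxa x samples


def synth_counts(
    truth: SyntheticTruth,
    n_samples: int = 100,
    depth_range=DEFAULT_DEPTH_RANGE,
    rng_seed=0,
    group: str | None = None,
    experiment: str = "synthetic",
    sample_prefix: str = "S",
) -> OtuTable:
    """Logistic-normal multinomial counts from a known precision matrix."""
    rng = _rng(rng_seed)
    counts = _sample_counts(truth, n_samples, depth_range, rng)
    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "subject_id": sample_ids,
            "group": group or truth.condition,
            "experiment": experiment,
            "time_point": 0,
        },
        index=sample_ids,
    )
    return OtuTable(
        counts=pd.DataFrame(counts, index=truth.taxon_ids, columns=sample_ids),
        sample_meta=meta,
    )


# ---------------------------------------------------------------------------
# two-condition designs
# ---------------------------------------------------------------------------

def synth_two_condition(
    p: int = 40,
    shared_edges: int = 30,
    unique_edges_per_condition: int = 12,
    hub_degree: int | None = None,
    edge_weight: float = 0.5,
    rng_seed=0,
) -> tuple[SyntheticTruth, SyntheticTruth]:
    """Control and perturbed truths sharing exactly ``shared_edges`` edges.

    Each condition has ``unique_edges_per_condition`` private edges. In the
    control condition the private edges include a designated keystone hub
    (node 0) with ``hub_degree`` neighbours; the perturbed condition has no
    edges at the hub, emulating antibiotic loss of a keystone taxon.
    """
    rng = _rng(rng_seed)
    unique = unique_edges_per_condition
    if hub_degree is None:
        hub_degree = min(unique, max(3, p // 5))
    hub_degree = min(hub_degree, unique, p - 1)
    total_pairs_no_hub = (p - 1) * (p - 2) // 2
    if shared_edges + (unique - hub_degree) + unique > total_pairs_no_hub:
        raise ValueError("edge budget infeasible for p")

    hub = 0
    others = np.arange(1, p)
    # shared edges among non-hub nodes
    pool = [(int(others[a]), int(others[b]))
            for a in range(p - 1) for b in range(a + 1, p - 1)]
    order = rng.permutation(len(pool))
    shared = [pool[k] for k in order[:shared_edges]]
    remaining = [pool[k] for k in order[shared_edges:]]
    # control-unique: hub edges + filler
    hub_targets = rng.choice(others, size=hub_degree, replace=False)
    control_unique = [(hub, int(t)) for t in hub_targets]
    need = unique - hub_degree
    control_unique += remaining[:need]
    # perturbed-unique: non-hub pairs disjoint from everything above
    perturbed_unique = remaining[need:need + unique]
    if len(perturbed_unique) < unique:
        raise ValueError("not enough non-hub pairs for the requested unique edges")

    def build(edges, condition):
        adj = np.zeros((p, p), dtype=bool)
        for i, j in edges:
            adj[i, j] = adj[j, i] = True
        prec = make_precision(adj, edge_weight=edge_weight, rng_seed=rng)
        return SyntheticTruth(graph=adj, precision=prec, condition=condition)

    control = build(shared + control_unique, "control")
    perturbed = build(shared + perturbed_unique, "perturbed")
    return control, perturbed


# ---------------------------------------------------------------------------
# longitudinal sIgA
# ---------------------------------------------------------------------------

def synth_longitudinal_iga(
    truth: SyntheticTruth,
    n_subjects: int = 20,
    timepoints=(0, 7, 14, 21, 28),
    effect_sizes: np.ndarray | None = None,
    noise_sd: float = 0.5,
    depth_range=DEFAULT_DEPTH_RANGE,
    pseudocount: float = 1.0,
    intercept_sd: float = 1.0,
    rng_seed=0,
    experiment: str = "synthetic",
    group: str | None = None,
) -> OtuTable:
    """Longitudinal counts whose within-subject sIgA changes are a known
    sparse linear function of clr-taxa.

    Per subject, the sIgA trajectory starts at a random intercept and moves
    at each later time point t by ``sum_j beta_j clr_j(t) + noise``, where
    clr is computed from the emitted counts with ``pseudocount`` (so at
    ``noise_sd=0`` the response is exactly collinear with the observed clr
    support columns). The sIgA value is stored in the ``siga`` metadata
    column; units are arbitrary (the analysis centres and scales responses).
    """
    rng = _rng(rng_seed)
    if effect_sizes is not None:
        effect_sizes = np.asarray(effect_sizes, dtype=float)
        if len(effect_sizes) != len(truth.spls_support):
            raise ValueError("effect_sizes must match truth.spls_support length")
        beta = effect_sizes
    else:
        beta = truth.spls_beta
    support = np.asarray(truth.spls_support, dtype=int)
    timepoints = list(timepoints)
    n_samples = n_subjects * len(timepoints)
    counts = _sample_counts(truth, n_samples, depth_range, rng)  # taxa x samples

    # observed clr for the response construction
    x = counts.T.astype(float) + pseudocount
    logp = np.log(x / x.sum(axis=1, keepdims=True))
    clr = logp - logp.mean(axis=1, keepdims=True)

    sample_ids, subject_ids, tps, siga = [], [], [], []
    k = 0
    for s in range(n_subjects):
        subj = f"M{s:03d}"
        level = 100.0 * np.exp(rng.normal(0.0, intercept_sd))
        for ti, t in enumerate(timepoints):
            if ti > 0:
                delta = float(clr[k, support] @ beta) if len(support) else 0.0
                level = level + delta + rng.normal(0.0, noise_sd)
            sample_ids.append(f"{subj}T{ti}")
            subject_ids.append(subj)
            tps.append(t)
            siga.append(level)
            k += 1
    meta = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": group or truth.condition,
            "experiment": experiment,
            "time_point": tps,
            "siga": siga,
        },
        index=sample_ids,
    )
    return OtuTable(
        counts=pd.DataFrame(counts, index=truth.taxon_ids, columns=sample_ids),
        sample_meta=meta,
    )


# ---------------------------------------------------------------------------
# IgA-Seq fractions
# ---------------------------------------------------------------------------

def synth_igaseq(
    truth: SyntheticTruth,
    community: np.ndarray | None = None,
    depth: int = 100_000,
    n_samples: int = 10,
    rng_seed=0,
) -> tuple[OtuTable, OtuTable, OtuTable]:
    """Paired (pre, IgA+, IgA-) fraction tables with known coating affinities.

    Each taxon cell sorts into the IgA+ fraction with probability
    ``a/(1+a)`` where ``a`` is its coating affinity (equal affinities give
    identical expected fractions, hence ICI = 1). Fraction compositions are
    multinomially sampled at ``depth`` reads.
    """
    rng = _rng(rng_seed)
    a = np.asarray(truth.coating_affinity, dtype=float)
    if (a < 0).any():
        raise ValueError("coating affinities must be non-negative")
    coat = a / (1.0 + a)
    tables = {"pre": [], "pos": [], "neg": []}
    for _ in range(n_samples):
        if community is None:
            z = rng.multivariate_normal(np.zeros(truth.p), truth.covariance, method="cholesky")
            pi = np.exp(z - z.max())
            pi /= pi.sum()
        else:
            pi = np.asarray(community, dtype=float)
            pi = pi / pi.sum()
        pos_comp = pi * coat
        neg_comp = pi * (1.0 - coat)
        for name, comp in (("pre", pi), ("pos", pos_comp), ("neg", neg_comp)):
            total = comp.sum()
            if total == 0:
                tables[name].append(np.zeros(truth.p, dtype=int))
            else:
                tables[name].append(rng.multinomial(depth, comp / total))
    out = []
    for name in ("pre", "pos", "neg"):
        sample_ids = [f"IGA{i:03d}" for i in range(n_samples)]
        meta = pd.DataFrame(
            {
                "subject_id": sample_ids,
                "group": truth.condition,
                "experiment": "igaseq",
                "time_point": 0,
                "fraction": name,
            },
            index=sample_ids,
        )
        out.append(
            OtuTable(
                counts=pd.DataFrame(
                    np.vstack(tables[name]).T, index=truth.taxon_ids, columns=sample_ids
                ),
                sample_meta=meta,
            )
        )
    return tuple(out)
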