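"""Ranked-edge recovery: precision/recall sweeps and max F1."""

import numpy as np
import pandas as pd
import pytest

from micronet.inference import AssociationNetwork
from micronet.prep import clr_transform
from micronet.recovery import rank_edges, recovery_curve
from micronet.simulate import (
    SyntheticTruth,
    make_precision,
    synth_counts,
    synth_graph,
    synth_two_condition,
)


def ranked_frame(pairs_with_conf):
    rows = [{"taxon_a": min(a, b), "taxon_b": max(a, b), "confidence": c}
            for (a, b), c in pairs_with_conf]
    return pd.DataFrame(rows)


def truth_network(edges, taxa):
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(taxa)
    g.add_edges_from(edges)
    return AssociationNetwork(graph=g)


class TestRankEdges:
    def _stars(self):
        from micronet.inference import stars_select
        adj = synth_graph(6, "band", n_edges=5, rng_seed=0)
        truth = SyntheticTruth(graph=adj, precision=make_precision(adj, rng_seed=0))
        tab = synth_counts(truth, n_samples=120, rng_seed=0)
        return stars_select(clr_transform(tab), n_subsamples=10, rng_seed=0)

    def test_descending_confidence_with_lexical_ties(self):
        res = self._stars()
        ranked = rank_edges(res)
        conf = ranked["confidence"].to_numpy()
        assert (np.diff(conf) <= 0).all()
        ties = ranked[ranked["confidence"] == conf[0]]
        pair_ids = list(zip(ties["taxon_a"], ties["taxon_b"]))
        assert pair_ids == sorted(pair_ids)

    def test_subset_excludes_pairs_outside(self):
        res = self._stars()
        subset = res.taxa[:4]
        ranked = rank_edges(res, taxa_subset=subset)
        assert len(ranked) == 6  # C(4,2)
        assert set(ranked["taxon_a"]) | set(ranked["taxon_b"]) <= set(subset)

    def test_unknown_taxa_rejected(self):
        res = self._stars()
        with pytest.raises(ValueError):
            rank_edges(res, taxa_subset=["nope"])


class TestRecoveryCurve:
    def test_perfect_ranking_reaches_f1_one(self):
        taxa = list("abcd")
        truth = truth_network([("a", "b"), ("c", "d")], taxa)
        ranked = ranked_frame([(("a", "b"), 0.9), (("c", "d"), 0.8),
                               (("a", "c"), 0.1), (("b", "d"), 0.0)])
        rec = recovery_curve(ranked, truth, taxa)
        assert rec.max_f1 == pytest.approx(1.0)
        assert rec.k_at_max == 2

    def test_hand_example_max_f1_point_eight(self):
        # truth {e1,e2}, ranking (e1, e3, e2): F1 = 2/3, 1/2, 4/5
        taxa = list("abcd")
        truth = truth_network([("a", "b"), ("c", "d")], taxa)
        ranked = ranked_frame([(("a", "b"), 0.9), (("a", "c"), 0.5),
                               (("c", "d"), 0.2)])
        rec = recovery_curve(ranked, truth, taxa)
        f1 = rec.curve["f1"].tolist()
        assert f1 == pytest.approx([2 / 3, 1 / 2, 4 / 5])
        assert rec.max_f1 == pytest.approx(0.8)

    def test_relabeling_invariance(self):
        taxa = list("abcd")
        truth_edges = [("a", "b"), ("b", "c")]
        ranked = ranked_frame([(("a", "b"), 0.9), (("a", "d"), 0.6),
                               (("b", "c"), 0.5), (("c", "d"), 0.1)])
        rec1 = recovery_curve(ranked, truth_network(truth_edges, taxa), taxa)
        mapping = {"a": "w", "b": "x", "c": "y", "d": "z"}
        taxa2 = [mapping[t] for t in taxa]
        ranked2 = ranked.assign(taxon_a=ranked["taxon_a"].map(mapping),
                                taxon_b=ranked["taxon_b"].map(mapping))
        ranked2[["taxon_a", "taxon_b"]] = np.sort(
            ranked2[["taxon_a", "taxon_b"]].to_numpy(), axis=1)
        rec2 = recovery_curve(
            ranked2, truth_network([(mapping[a], mapping[b]) for a, b in truth_edges],
                                   taxa2), taxa2)
        assert rec1.max_f1 == pytest.approx(rec2.max_f1)

    def test_random_ranking_precision_near_density(self):
        # with a random ranking the expected precision at any cutoff is the
        # truth density (the at-random baseline)
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(10)]
        pairs = [(taxa[i], taxa[j]) for i in range(10) for j in range(i + 1, 10)]
        truth_edges = [pairs[i] for i in rng.choice(len(pairs), 9, replace=False)]
        truth = truth_network(truth_edges, taxa)
        density = 9 / len(pairs)
        prec_at_10 = []
        for _ in range(200):
            order = rng.permutation(len(pairs))
            ranked = ranked_frame([(pairs[i], 1.0 - k / len(pairs))
                                   for k, i in enumerate(order)])
            rec = recovery_curve(ranked, truth, taxa)
            prec_at_10.append(rec.curve.loc[rec.curve["k"] == 10, "precision"].iloc[0])
        assert np.mean(prec_at_10) == pytest.approx(density, abs=0.03)

    def test_empty_truth_raises(self):
        taxa = list("abc")
        with pytest.raises(ValueError):
            recovery_curve(ranked_frame([(("a", "b"), 1.0)]),
                           truth_network([], taxa), taxa)


class TestSharedStructureRecovery:
    def test_same_truth_recovers_better_than_cross_truth(self):
        # two independent data sets from the SAME graph should agree on edges
        # more than data sets from two different graphs sharing 70% of edges
        from micronet.inference import stars_select
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            control, perturbed = synth_two_condition(
                p=20, shared_edges=14, unique_edges_per_condition=6, rng_seed=seed)
            tabs = {
                "c1": synth_counts(control, n_samples=150, rng_seed=seed * 10 + 1),
                "c2": synth_counts(control, n_samples=150, rng_seed=seed * 10 + 2),
                "p1": synth_counts(perturbed, n_samples=150, rng_seed=seed * 10 + 3),
            }
            stars = {k: stars_select(clr_transform(t), n_subsamples=20,
                                     rng_seed=seed)
                     for k, t in tabs.items()}
            nets = {k: s.network() for k, s in stars.items()}
            taxa = control.taxon_ids
            same = recovery_curve(rank_edges(stars["c2"]), nets["c1"], taxa).max_f1
            cross = recovery_curve(rank_edges(stars["p1"]), nets["c1"], taxa).max_f1
            wins += same > cross
        assert wins >= n_seeds - 1
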