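"""Generators: graph topologies, counts, two-condition designs, sIgA, IgA-Seq."""

import numpy as np
import pandas as pd
import pytest

from micronet.prep import clr_transform
from micronet.simulate import (
    SyntheticTruth,
    make_precision,
    synth_counts,
    synth_graph,
    synth_igaseq,
    synth_longitudinal_iga,
    synth_two_condition,
)


def edge_count(adj):
    return int(adj.sum() // 2)


class TestSynthGraph:
    def test_band_width_one_is_path(self):
        adj = synth_graph(5, "band", n_edges=4)
        expected = np.zeros((5, 5), dtype=bool)
        for i in range(4):
            expected[i, i + 1] = expected[i + 1, i] = True
        assert np.array_equal(adj, expected)

    @pytest.mark.parametrize("topology", ["band", "cluster", "scale_free"])
    @pytest.mark.parametrize("n_edges", [5, 17, 40])
    def test_exact_edge_count_no_selfloops(self, topology, n_edges):
        adj = synth_graph(10, topology, n_edges=n_edges, rng_seed=3)
        assert edge_count(adj) == n_edges
        assert not np.diag(adj).any()
        assert np.array_equal(adj, adj.T)

    def test_infeasible_edge_count_raises(self):
        with pytest.raises(ValueError):
            synth_graph(5, "band", n_edges=11)

    def test_scale_free_has_heavier_degree_tail_than_band(self):
        # same edge budget; hub-dominated graphs should show larger max degree
        wins = 0
        for seed in range(30):
            sf = synth_graph(50, "scale_free", n_edges=60, rng_seed=seed)
            band = synth_graph(50, "band", n_edges=60, rng_seed=seed)
            wins += sf.sum(axis=0).max() > band.sum(axis=0).max()
        assert wins >= 25


class TestPrecision:
    def test_positive_definite_with_exact_support(self):
        adj = synth_graph(12, "cluster", n_edges=14, rng_seed=1)
        omega = make_precision(adj, rng_seed=1)
        assert np.linalg.eigvalsh(omega).min() > 0
        off = (np.abs(omega) > 1e-12) & ~np.eye(12, dtype=bool)
        assert np.array_equal(off, adj)

    def test_truth_rejects_support_mismatch(self):
        adj = synth_graph(6, "band", n_edges=5)
        omega = make_precision(adj)
        wrong = omega.copy()
        wrong[0, 3] = wrong[3, 0] = 0.4  # edge not in the graph
        with pytest.raises(ValueError):
            SyntheticTruth(graph=adj, precision=wrong)


class TestSynthCounts:
    def test_fixed_depth_and_determinism(self, band_truth):
        tab = synth_counts(band_truth, n_samples=8, depth_range=(500, 500), rng_seed=9)
        assert (tab.depths() == 500).all()
        tab2 = synth_counts(band_truth, n_samples=8, depth_range=(500, 500), rng_seed=9)
        pd.testing.assert_frame_equal(tab.counts, tab2.counts)

    def test_independent_latents_give_small_clr_correlations(self):
        # with identity precision the latents are independent; clr closure
        # still induces a -1/(p-1) baseline correlation, so pairwise |r|
        # stays small but not zero (n large enough to tame sampling noise)
        p = 10
        truth = SyntheticTruth(graph=np.zeros((p, p), dtype=bool),
                               precision=np.eye(p))
        tab = synth_counts(truth, n_samples=2000, rng_seed=0)
        clr = clr_transform(tab).values.to_numpy()
        corr = np.corrcoef(clr.T)
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() < 0.2
        iu = np.triu_indices(p, 1)
        assert corr[iu].mean() == pytest.approx(-1 / (p - 1), abs=0.04)
        assert (corr[iu] < 0.05).all()  # no spurious positive association


class TestTwoCondition:
    def test_zero_unique_gives_identical_graphs(self):
        a, b = synth_two_condition(p=15, shared_edges=10,
                                   unique_edges_per_condition=0, rng_seed=2)
        assert np.array_equal(a.graph, b.graph)

    def test_shared_and_unique_edge_budget(self):
        a, b = synth_two_condition(p=20, shared_edges=10,
                                   unique_edges_per_condition=5, rng_seed=4)
        ea, eb = a.edge_set(), b.edge_set()
        assert len(ea) == len(eb) == 15
        assert len(ea & eb) == 10

    def test_perturbed_condition_loses_the_keystone_hub(self):
        a, b = synth_two_condition(p=30, shared_edges=20,
                                   unique_edges_per_condition=10, rng_seed=7)
        hub = a.taxon_ids[0]
        hub_deg_control = sum(hub in e for e in a.edge_set())
        hub_deg_perturbed = sum(hub in e for e in b.edge_set())
        assert hub_deg_control >= 3
        assert hub_deg_perturbed == 0


class TestLongitudinalIga:
    def _truth(self, seed=0, p=12):
        adj = synth_graph(p, "band", n_edges=p - 1, rng_seed=seed)
        return SyntheticTruth(
            graph=adj, precision=make_precision(adj, rng_seed=seed),
            spls_support=np.array([2, 5]), spls_beta=np.array([1.0, -1.0]),
        )

    def test_noise_free_response_is_exactly_linear_in_clr_support(self):
        truth = self._truth()
        tab = synth_longitudinal_iga(truth, n_subjects=4, timepoints=(0, 7, 14),
                                     noise_sd=0.0, rng_seed=1)
        clr = clr_transform(tab).values
        meta = tab.sample_meta
        for subj, sub in meta.groupby("subject_id"):
            sub = sub.sort_values("time_point")
            diffs = np.diff(sub["siga"].to_numpy())
            pred = clr.loc[sub.index[1:], [truth.taxon_ids[i] for i in truth.spls_support]]
            expected = pred.to_numpy() @ truth.spls_beta
            assert np.allclose(diffs, expected, atol=1e-9)

    def test_metadata_carries_subject_and_time(self):
        tab = synth_longitudinal_iga(self._truth(), n_subjects=3, timepoints=(0, 7))
        assert set(tab.sample_meta["subject_id"]) == {"M000", "M001", "M002"}
        assert set(tab.sample_meta["time_point"]) == {0, 7}
        assert "siga" in tab.sample_meta.columns


class TestIgaSeq:
    def _truth(self, affinity):
        p = len(affinity)
        return SyntheticTruth(graph=np.zeros((p, p), dtype=bool),
                              precision=np.eye(p),
                              coating_affinity=np.asarray(affinity, dtype=float))

    def test_zero_affinity_never_coated(self):
        truth = self._truth([0.0, 1.0, 1.0, 1.0])
        _, pos, _ = synth_igaseq(truth, depth=10_000, n_samples=5, rng_seed=0)
        assert (pos.counts.iloc[0] == 0).all()

    def test_equal_affinity_ici_near_one(self):
        from micronet.igaseq import ici
        truth = self._truth([1.0] * 6)
        _, pos, neg = synth_igaseq(truth, depth=100_000, n_samples=10, rng_seed=1)
        table = ici(pos, neg)
        med = table.ici.median(axis=1)
        assert ((med > 0.8) & (med < 1.25)).all()

    def test_depth_scaling_tightens_ici_spread(self):
        # multinomial noise: sd of log ICI should shrink ~ 1/sqrt(depth)
        from micronet.igaseq import ici
        truth = self._truth([1.0] * 8)
        spreads = {}
        for depth in (2_000, 8_000):
            logs = []
            for seed in range(50):
                _, pos, neg = synth_igaseq(truth, depth=depth, n_samples=1,
                                           rng_seed=seed)
                logs.append(ici(pos, neg, epsilon=1e-6).log2_ici.to_numpy().ravel())
            spreads[depth] = np.std(np.concatenate(logs))
        ratio = spreads[2_000] / spreads[8_000]
        assert 1.5 < ratio < 2.7  # ideal 2 for a 4x depth increase
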