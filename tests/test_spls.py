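"""Multilevel decomposition, ΔIgA construction, sparse PLS and selection."""

import numpy as np
import pandas as pd
import pytest

from micronet.simulate import (
    SyntheticTruth,
    make_precision,
    synth_graph,
    synth_longitudinal_iga,
)
from micronet.spls import (
    LongitudinalDesign,
    MultilevelSPLS,
    delta_iga,
    iterative_filter,
    multilevel_within,
    stability_select,
)


def design_from(truth, n_subjects, timepoints, noise_sd, seed):
    tab = synth_longitudinal_iga(truth, n_subjects=n_subjects,
                                 timepoints=timepoints, noise_sd=noise_sd,
                                 rng_seed=seed)
    return LongitudinalDesign.from_table(tab)


def small_truth(seed=0, p=12, support=(2, 5), beta=(1.0, -1.0)):
    adj = synth_graph(p, "band", n_edges=p - 1, rng_seed=seed)
    return SyntheticTruth(graph=adj, precision=make_precision(adj, rng_seed=seed),
                          spls_support=np.array(support),
                          spls_beta=np.array(beta))


class TestMultilevelWithin:
    def _X(self, seed=0, n_subj=4, reps=3, p=5):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n_subj * reps)]
        subjects = np.repeat([f"m{j}" for j in range(n_subj)], reps)
        X = pd.DataFrame(rng.normal(size=(n_subj * reps, p)), index=idx)
        return X, pd.Series(subjects, index=idx)

    def test_subject_means_collapse_to_grand_mean(self):
        X, subj = self._X()
        Xw = multilevel_within(X, subj)
        grand = X.mean(axis=0)
        for _, block in Xw.groupby(subj):
            assert np.allclose(block.mean(axis=0), grand, atol=1e-12)

    def test_constant_subject_rows_become_grand_mean(self):
        X, subj = self._X()
        X.iloc[0:3] = 7.0  # subject m0 identical rows
        Xw = multilevel_within(X, subj)
        assert np.allclose(Xw.iloc[0:3].to_numpy(),
                           np.tile(X.mean(axis=0), (3, 1)), atol=1e-12)

    def test_idempotent_and_offset_invariant(self):
        X, subj = self._X(seed=1)
        Xw = multilevel_within(X, subj)
        assert np.allclose(multilevel_within(Xw, subj), Xw, atol=1e-12)
        # adding a per-subject constant only shifts through the grand mean
        offsets = subj.map({f"m{j}": j * 10.0 for j in range(4)})
        X2 = X.add(offsets, axis=0)
        Xw2 = multilevel_within(X2, subj)
        shift = X2.mean(axis=0) - X.mean(axis=0)
        assert np.allclose(Xw2, Xw.add(shift, axis=1), atol=1e-10)

    def test_singleton_subject_rejected(self):
        X, subj = self._X()
        subj.iloc[0] = "loner"
        with pytest.raises(ValueError, match="loner"):
            multilevel_within(X, subj)


class TestDeltaIga:
    def test_consecutive_differences(self):
        siga = pd.Series([2.0, 5.0, 9.0], index=["a", "b", "c"])
        subj = pd.Series(["m", "m", "m"], index=siga.index)
        t = pd.Series([0, 7, 14], index=siga.index)
        res = delta_iga(siga, subj, t)
        assert res.raw.tolist() == [3.0, 4.0]
        assert list(res.raw.index) == ["b", "c"]

    def test_scaled_output_mean_zero_unit_variance(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(12)]
        siga = pd.Series(rng.uniform(10, 500, 12), index=idx)
        subj = pd.Series(np.repeat(["m0", "m1", "m2"], 4), index=idx)
        t = pd.Series(list(range(4)) * 3, index=idx)
        res = delta_iga(siga, subj, t)
        assert res.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert res.values.std(ddof=0) == pytest.approx(1.0)

    def test_constant_series_degenerate_flag(self):
        idx = list("abcd")
        siga = pd.Series([5.0] * 4, index=idx)
        subj = pd.Series(["m", "m", "n", "n"], index=idx)
        t = pd.Series([0, 1, 0, 1], index=idx)
        res = delta_iga(siga, subj, t)
        assert res.degenerate
        assert (res.values == 0).all()


class TestSplsFit:
    def test_exact_single_taxon_response(self):
        truth = small_truth()
        design = design_from(truth, 6, (0, 7, 14, 21), noise_sd=0.0, seed=3)
        # response exactly one clr column (within transform preserved)
        target = design.X.columns[4]
        Xw = multilevel_within(design.X, design.subject_ids)
        y = Xw[target]
        y = (y - y.mean()) / y.std(ddof=0)
        design = LongitudinalDesign(X=design.X, y=y, subject_ids=design.subject_ids)
        res = MultilevelSPLS(design, n_components=1, keep_per_component=1).fit()
        assert res.selected_taxa == [target]
        assert res.within_sample_r2 >= 0.99

    def test_dense_pls_matches_ols(self):
        rng = np.random.default_rng(4)
        n, p = 40, 6
        idx = [f"s{i}" for i in range(n)]
        subj = pd.Series(np.repeat([f"m{j}" for j in range(n // 4)], 4), index=idx)
        X = pd.DataFrame(rng.normal(size=(n, p)), index=idx,
                         columns=[f"t{j}" for j in range(p)])
        y = pd.Series(rng.normal(size=n), index=idx)
        design = LongitudinalDesign(X=X, y=y, subject_ids=subj)
        res = MultilevelSPLS(design, n_components=min(n, p),
                             keep_per_component=p).fit()
        Xw = multilevel_within(X, subj).to_numpy()
        Xc = Xw - Xw.mean(axis=0)
        yc = y.to_numpy() - y.mean()
        ols = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        assert np.allclose(res.coefficients.to_numpy(), ols, atol=1e-6)

    def test_null_response_low_cv_r2(self):
        # independent noise response: out-of-sample r2 should hover near zero
        truth = small_truth(p=20, support=(), beta=())
        r2s = []
        for seed in range(6):
            train = design_from(truth, 10, (0, 7, 14, 21, 28), 0.5, seed * 2)
            test = design_from(truth, 10, (0, 7, 14, 21, 28), 0.5, seed * 2 + 1)
            res = MultilevelSPLS(train, n_components=2, keep_per_component=8).fit()
            res.oos_r2 = res.score(test)
            r2s.append(res.oos_r2)
        assert np.mean(r2s) < 0.1

    def test_zero_variance_response_rejected(self):
        truth = small_truth()
        design = design_from(truth, 4, (0, 7), 0.5, 0)
        design = LongitudinalDesign(X=design.X, y=design.y * 0,
                                    subject_ids=design.subject_ids)
        with pytest.raises(ValueError, match="zero-variance"):
            MultilevelSPLS(design)


class TestStabilityAndFilter:
    def test_true_support_scores_dominate_null(self):
        hits = 0
        for seed in range(8):
            truth = small_truth(seed=seed, p=15)
            design = design_from(truth, 14, (0, 7, 14, 21, 28), 0.5, seed + 50)
            scores = stability_select(design, keep_per_component=4,
                                      n_resamples=40, rng_seed=seed)
            true_names = [truth.taxon_ids[i] for i in truth.spls_support]
            top4 = set(scores.sort_values(ascending=False).index[:4])
            hits += set(true_names) <= top4
        assert hits >= 7  # both true taxa in the top-4 stability scores

    def test_scores_invariant_to_column_order(self):
        truth = small_truth(seed=2)
        design = design_from(truth, 8, (0, 7, 14), 0.5, 9)
        scores = stability_select(design, n_resamples=20, rng_seed=1)
        perm = list(reversed(design.X.columns))
        design2 = LongitudinalDesign(X=design.X[perm], y=design.y,
                                     subject_ids=design.subject_ids)
        scores2 = stability_select(design2, n_resamples=20, rng_seed=1)
        assert np.allclose(scores[perm].to_numpy(), scores2.to_numpy())

    def test_degenerate_split_oos_equals_within_r2(self):
        truth = small_truth(seed=3)
        design = design_from(truth, 8, (0, 7, 14), 0.5, 11)
        scores = stability_select(design, n_resamples=20, rng_seed=2)
        best = iterative_filter(design, design, scores)
        refit = MultilevelSPLS(design.restrict_taxa(best.taxa),
                               n_components=best.n_components,
                               keep_per_component=best.keep_per_component).fit()
        assert best.oos_r2 == pytest.approx(refit.within_sample_r2, abs=1e-10)

    def test_constant_test_response_not_clamped(self):
        truth = small_truth(seed=4)
        train = design_from(truth, 8, (0, 7, 14), 0.5, 13)
        test = design_from(truth, 6, (0, 7, 14), 0.5, 14)
        test = LongitudinalDesign(X=test.X, y=test.y * 0,
                                  subject_ids=test.subject_ids)
        res = MultilevelSPLS(train, keep_per_component=4).fit()
        assert res.score(test) == -np.inf

    def test_sparse_model_beats_full_model_with_many_nulls(self):
        # 40 null taxa added: restricting to the stable set should help oos r2
        wins = 0
        for seed in range(6):
            truth = small_truth(seed=seed + 30, p=44, support=(1, 3),
                                beta=(1.0, -1.0))
            train = design_from(truth, 12, (0, 7, 14, 21, 28), 0.5, seed + 70)
            test = design_from(truth, 12, (0, 7, 14, 21, 28), 0.5, seed + 170)
            scores = stability_select(train, keep_per_component=4,
                                      n_resamples=40, rng_seed=seed)
            best = iterative_filter(train, test, scores, keep_per_component=4)
            full = MultilevelSPLS(train, keep_per_component=44,
                                  n_components=2).fit()
            full_oos = full.score(test)
            wins += best.oos_r2 >= full_oos
        assert wins >= 4
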