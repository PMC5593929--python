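"""Multilevel sparse PLS association of taxa with within-subject sIgA change.

The response is the within-subject change in faecal secretory IgA (ΔIgA):
consecutive time-point differences per subject, centred and scaled to unit
variance. Predictors are clr-transformed taxa, passed through a multilevel
(split-plot) decomposition X_w = X - subject means + grand mean so that only
within-subject variation drives the fit — the appropriate design for
repeated measures on the same animals.

The fit itself is univariate-response sparse PLS in regression mode:
latent components t = X w with soft-thresholded loading vectors w keeping a
fixed number of taxa per component; with no thresholding and enough
components the coefficients coincide with ordinary least squares. Stability
selection (subject-level resampling) gives per-taxon confidence scores, and
an iterative filter retains the top-m taxa (m descending) refitting each
candidate set and keeping the one that maximises out-of-sample r² on an
independent experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu import OtuTable
from .prep import clr_transform

__all__ = [
    "multilevel_within",
    "delta_iga",
    "LongitudinalDesign",
    "MultilevelSPLS",
    "SPLSResults",
    "stability_select",
    "iterative_filter",
    "significant_taxa",
]

DEFAULT_SPARSITY_GRID = (4, 8, 16, 32)


# ---------------------------------------------------------------------------
# multilevel decomposition and response construction
# ---------------------------------------------------------------------------

def multilevel_within(X: pd.DataFrame, subject_ids) -> pd.DataFrame:
    """Within-subject part of a repeated-measures matrix.

    ``X_w = X - subject_mean(X) + grand_mean(X)``; every subject's mean row
    of the result equals the grand mean, so between-subject variation is
    removed exactly. Subjects with a single sample are rejected.
    """
    subject_ids = pd.Series(np.asarray(subject_ids), index=X.index)
    sizes = subject_ids.value_counts()
    singletons = sorted(sizes.index[sizes < 2])
    if singletons:
        raise ValueError(f"subjects with a single sample cannot be decomposed: {singletons}")
    grand = X.mean(axis=0)
    subj_means = X.groupby(subject_ids).transform("mean")
    return X - subj_means + grand


@dataclass
class DeltaResult:
    values: pd.Series        # scaled ΔIgA indexed by sample id (later time points)
    raw: pd.Series
    degenerate: bool         # True when all raw differences were identical


def delta_iga(siga: pd.Series, subject_ids: pd.Series, time_points: pd.Series) -> DeltaResult:
    """Scaled within-subject consecutive sIgA differences.

    Per subject, samples are ordered by time point and consecutive
    differences computed (the first time point drops out); the pooled
    differences are then centred and scaled to unit variance. A zero-variance
    guard returns all zeros with ``degenerate=True`` instead of dividing by
    zero.
    """
    df = pd.DataFrame({"siga": siga, "subject": subject_ids, "t": time_points})
    raw = {}
    for _, sub in df.groupby("subject"):
        sub = sub.sort_values("t", kind="stable")
        vals = sub["siga"].to_numpy(dtype=float)
        for sample_id, d in zip(sub.index[1:], np.diff(vals)):
            raw[sample_id] = d
    raw = pd.Series(raw, dtype=float)
    sd = raw.std(ddof=0)
    if sd < 1e-12:
        return DeltaResult(values=raw * 0.0, raw=raw, degenerate=True)
    return DeltaResult(values=(raw - raw.mean()) / sd, raw=raw, degenerate=False)


@dataclass
class LongitudinalDesign:
    """Aligned (X, y) for the multilevel sPLS: clr taxa and scaled ΔIgA."""

    X: pd.DataFrame                 # samples x taxa (clr, NOT yet within-transformed)
    y: pd.Series                    # scaled ΔIgA
    subject_ids: pd.Series
    time_point: pd.Series | None = None
    experiment: str = ""
    degenerate_y: bool = False

    @classmethod
    def from_table(cls, table: OtuTable, pseudocount: float = 1.0,
                   experiment: str = "") -> "LongitudinalDesign":
        """Build the design from an OTU table whose metadata carries
        ``subject_id``, ``time_point`` and ``siga``."""
        meta = table.sample_meta
        for col in ("subject_id", "time_point", "siga"):
            if col not in meta.columns:
                raise ValueError(f"metadata missing column {col!r}")
        clr = clr_transform(table, pseudocount=pseudocount).values
        delta = delta_iga(meta["siga"], meta["subject_id"], meta["time_point"])
        keep = delta.values.index
        return cls(
            X=clr.loc[keep],
            y=delta.values,
            subject_ids=meta.loc[keep, "subject_id"],
            time_point=meta.loc[keep, "time_point"],
            experiment=experiment,
            degenerate_y=delta.degenerate,
        )

    def restrict_taxa(self, taxa) -> "LongitudinalDesign":
        return LongitudinalDesign(
            X=self.X[list(taxa)], y=self.y, subject_ids=self.subject_ids,
            time_point=self.time_point, experiment=self.experiment,
            degenerate_y=self.degenerate_y,
        )


# ---------------------------------------------------------------------------
# sparse PLS core
# ---------------------------------------------------------------------------

def _soft_threshold_top(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so that only the ``keep`` largest |w| survive."""
    if keep >= len(w):
        return w.copy()
    absw = np.abs(w)
    lam = np.partition(absw, len(w) - keep - 1)[len(w) - keep - 1]
    return np.sign(w) * np.maximum(absw - lam, 0.0)


def _spls_core(X: np.ndarray, y: np.ndarray, n_components: int, keep: int):
    """PLS1 with soft-thresholded X-loadings; returns coefficients on the
    centred scale plus the component matrices."""
    n, p = X.shape
    xbar, ybar = X.mean(axis=0), y.mean()
    Xc, yc = X - xbar, y - ybar
    H = min(n_components, n - 1, p)
    W = np.zeros((p, H))
    P = np.zeros((p, H))
    C = np.zeros(H)
    T = np.zeros((n, H))
    Xd, yd = Xc.copy(), yc.copy()
    h_used = 0
    for h in range(H):
        w = Xd.T @ yd
        w = _soft_threshold_top(w, keep)
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            break
        W[:, h] = w
        P[:, h] = Xd.T @ t / tt
        C[h] = yd @ t / tt
        T[:, h] = t
        Xd = Xd - np.outer(t, P[:, h])
        yd = yd - C[h] * t
        h_used += 1
    W, P, C, T = W[:, :h_used], P[:, :h_used], C[:h_used], T[:, :h_used]
    if h_used == 0:
        coef = np.zeros(p)
    else:
        # B = W (P'W)^-1 C maps centred X to centred y
        coef = W @ np.linalg.solve(P.T @ W, C)
    intercept = ybar - xbar @ coef
    return coef, intercept, W, P, C, T, xbar, ybar


@dataclass
class SPLSResults:
    """Fitted multilevel sPLS model.

    ``coefficients`` act on within-transformed clr values; ``selected_taxa``
    is the union of taxa with non-zero loadings over components.
    """

    taxa: list[str]
    coefficients: pd.Series
    intercept: float
    loadings: pd.DataFrame          # taxa x components (W)
    scores: np.ndarray              # samples x components (T)
    n_components: int
    keep_per_component: int
    within_sample_r2: float
    selected_taxa: list[str] = field(default_factory=list)
    stability_scores: pd.Series | None = None
    oos_r2: float | None = None
    model: "MultilevelSPLS | None" = None

    def predict(self, design: LongitudinalDesign) -> pd.Series:
        """Predict scaled ΔIgA for a new design (its own within transform)."""
        Xw = multilevel_within(design.X[self.taxa], design.subject_ids)
        return pd.Series(Xw.to_numpy() @ self.coefficients.to_numpy() + self.intercept,
                         index=design.X.index)

    def score(self, design: LongitudinalDesign) -> float:
        """Out-of-sample r² = 1 - SSE/SST on the design's ΔIgA (not clamped)."""
        yhat = self.predict(design)
        y = design.y
        sst = ((y - y.mean()) ** 2).sum()
        if sst < 1e-12:
            return -np.inf
        return float(1.0 - ((y - yhat) ** 2).sum() / sst)

    def summary(self) -> str:
        sel = ", ".join(self.selected_taxa[:8])
        more = "" if len(self.selected_taxa) <= 8 else f" (+{len(self.selected_taxa) - 8} more)"
        lines = [
            "Multilevel sparse PLS (regression mode)",
            f"  taxa: {len(self.taxa)}   components: {self.n_components}"
            f"   keep/component: {self.keep_per_component}",
            f"  within-sample r2: {self.within_sample_r2:.3f}",
        ]
        if self.oos_r2 is not None:
            lines.append(f"  out-of-sample r2: {self.oos_r2:.3f}")
        lines.append(f"  selected taxa ({len(self.selected_taxa)}): {sel}{more}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"coefficient": self.coefficients})
        if self.stability_scores is not None:
            df["stability_score"] = self.stability_scores
        df["selected"] = [t in set(self.selected_taxa) for t in df.index]
        return df.reset_index(names="taxon")


class MultilevelSPLS:
    """Model object: sparse PLS on within-subject clr variation.

    Parameters
    ----------
    design : LongitudinalDesign
        Aligned clr matrix, scaled ΔIgA and subject ids.
    n_components : int
        Latent components (default 2).
    keep_per_component : int
        Taxa retained per component by soft-thresholding.
    """

    def __init__(self, design: LongitudinalDesign, n_components: int = 2,
                 keep_per_component: int = 8):
        if keep_per_component > design.X.shape[1]:
            raise ValueError("keep_per_component exceeds the number of taxa")
        if design.y.std(ddof=0) < 1e-12:
            raise ValueError("zero-variance response")
        self.design = design
        self.n_components = n_components
        self.keep = keep_per_component
        self.taxa = list(design.X.columns)

    @classmethod
    def from_table(cls, table: OtuTable, **kw) -> "MultilevelSPLS":
        return cls(LongitudinalDesign.from_table(table), **kw)

    def fit(self) -> SPLSResults:
        Xw = multilevel_within(self.design.X, self.design.subject_ids)
        X = Xw.to_numpy(dtype=float)
        y = self.design.y.to_numpy(dtype=float)
        coef, intercept, W, P, C, T, xbar, ybar = _spls_core(
            X, y, self.n_components, self.keep)
        yhat = X @ coef + intercept
        sst = ((y - y.mean()) ** 2).sum()
        r2 = float(1.0 - ((y - yhat) ** 2).sum() / sst)
        selected = [t for t, row in zip(self.taxa, W) if np.abs(row).max(initial=0) > 0]
        return SPLSResults(
            taxa=self.taxa,
            coefficients=pd.Series(coef, index=self.taxa),
            intercept=float(intercept),
            loadings=pd.DataFrame(W, index=self.taxa,
                                  columns=[f"comp{h+1}" for h in range(W.shape[1])]),
            scores=T,
            n_components=self.n_components,
            keep_per_component=self.keep,
            within_sample_r2=r2,
            selected_taxa=selected,
            model=self,
        )


# ---------------------------------------------------------------------------
# stability selection and iterative filtering
# ---------------------------------------------------------------------------

def stability_select(
    design: LongitudinalDesign,
    keep_per_component: int = 8,
    n_components: int = 2,
    n_resamples: int = 100,
    resample_fraction: float = 0.5,
    rng_seed: int = 0,
) -> pd.Series:
    """Per-taxon selection frequency over subject-level resamples.

    Each resample draws ``resample_fraction`` of the subjects without
    replacement (keeping the multilevel structure intact), refits the sPLS at
    the fixed sparsity level, and records which taxa carry non-zero loadings.
    """
    rng = np.random.default_rng(rng_seed)
    subjects = np.array(sorted(design.subject_ids.unique()))
    n_draw = max(2, int(round(resample_fraction * len(subjects))))
    counts = pd.Series(0.0, index=design.X.columns)
    for _ in range(n_resamples):
        chosen = set(rng.choice(subjects, size=n_draw, replace=False))
        mask = design.subject_ids.isin(chosen)
        sub = LongitudinalDesign(
            X=design.X[mask], y=design.y[mask],
            subject_ids=design.subject_ids[mask],
        )
        if sub.y.std(ddof=0) < 1e-12:
            continue
        res = MultilevelSPLS(sub, n_components=n_components,
                             keep_per_component=keep_per_component).fit()
        counts[res.selected_taxa] += 1.0
    return counts / n_resamples


def iterative_filter(
    train: LongitudinalDesign,
    test: LongitudinalDesign,
    stability_scores: pd.Series,
    sparsity_grid=DEFAULT_SPARSITY_GRID,
    n_components: int = 2,
    keep_per_component: int = 8,
) -> SPLSResults:
    """Retain the top-m taxa by stability that maximise out-of-sample r².

    For each m in the grid (descending, plus 'all'), the model is refitted on
    the training design restricted to the m most stable taxa and scored on
    the test design; the refit with the highest out-of-sample r² is returned
    with its candidate path recorded in ``.candidate_path``.
    """
    if set(train.X.columns) != set(test.X.columns):
        raise ValueError("train and test must share the taxon universe")
    p = train.X.shape[1]
    grid = sorted({m for m in (*sparsity_grid, p) if 0 < m <= p}, reverse=True)
    order = stability_scores.sort_values(ascending=False).index
    best = None
    path_rows = []
    for m in grid:
        taxa_m = list(order[:m])
        res = MultilevelSPLS(
            train.restrict_taxa(taxa_m),
            n_components=n_components,
            keep_per_component=min(keep_per_component, m),
        ).fit()
        res.oos_r2 = res.score(test.restrict_taxa(taxa_m))
        res.stability_scores = stability_scores.reindex(taxa_m)
        path_rows.append({"m": m, "oos_r2": res.oos_r2,
                          "within_sample_r2": res.within_sample_r2})
        if best is None or res.oos_r2 > best.oos_r2:
            best = res
    best.candidate_path = pd.DataFrame(path_rows)  # type: ignore[attr-defined]
    return best


def significant_taxa(
    design: LongitudinalDesign,
    stability_scores: pd.Series,
    n_permutations: int = 20,
    alpha: float = 0.05,
    rng_seed: int = 0,
    **stability_kw,
) -> pd.Index:
    """Taxa whose stability score exceeds a permutation-null quantile.

    The response is permuted across samples ``n_permutations`` times, the
    stability selection is re-run, and the (1 - alpha) quantile of all
    permuted scores becomes the significance threshold — an operational
    stand-in for coefficient significance at level alpha.
    """
    rng = np.random.default_rng(rng_seed)
    null_scores = []
    for i in range(n_permutations):
        perm = rng.permutation(len(design.y))
        permuted = LongitudinalDesign(
            X=design.X, y=pd.Series(design.y.to_numpy()[perm], index=design.y.index),
            subject_ids=design.subject_ids,
        )
        null_scores.append(stability_select(permuted, rng_seed=int(rng.integers(2**31)),
                                            **stability_kw).to_numpy())
    threshold = float(np.quantile(np.concatenate(null_scores), 1 - alpha))
    return stability_scores.index[stability_scores > threshold]
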