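"""Sample/taxon filtering, clr transform, and resampled intergroup distances.

Filtering mirrors common 16S practice: drop shallow samples (sequencing depth
below a threshold), then drop rare taxa by prevalence ("present in strictly
more than a fraction of samples") and mean relative abundance. The clr
transform maps each sample's composition to an unconstrained real vector whose
coordinates sum to zero, which is the input representation for both network
inference and the sparse PLS association model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .otu import ClrMatrix, DistanceMatrix, OtuTable

__all__ = [
    "filter_samples_by_depth",
    "filter_taxa",
    "clr_transform",
    "intergroup_distance",
    "IntergroupSummary",
]


class EmptyResultError(ValueError):
    """A filter removed every sample or taxon."""


def filter_samples_by_depth(table: OtuTable, min_depth: int) -> OtuTable:
    """Keep samples whose total count (sequencing depth) is >= ``min_depth``."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    keep = table.depths() >= min_depth
    if not keep.any():
        raise EmptyResultError(
            f"all {table.n_samples} samples fall below depth threshold {min_depth}"
        )
    return table.select_samples(keep.index[keep])


def filter_taxa(
    table: OtuTable,
    min_prevalence: float = 0.0,
    min_mean_relabund: float = 0.0,
) -> OtuTable:
    """Keep taxa present in strictly more than ``min_prevalence`` of samples
    AND whose mean relative abundance is >= ``min_mean_relabund``.

    Prevalence uses a strict inequality (a taxon in exactly 20% of samples is
    removed at ``min_prevalence=0.2``); the abundance criterion is applied to
    the mean relative abundance across samples. Taxon order is preserved.
    """
    for name, frac in (("min_prevalence", min_prevalence), ("min_mean_relabund", min_mean_relabund)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {frac}")
    relab = table.relative_abundance()
    prevalence = (table.counts > 0).mean(axis=1)
    mean_relab = relab.mean(axis=1)
    keep = (prevalence > min_prevalence) & (mean_relab >= min_mean_relabund)
    if min_prevalence == 0.0:
        # prevalence > 0 would drop all-zero taxa; the zero threshold is a no-op
        keep = mean_relab >= min_mean_relabund
    if not keep.any():
        raise EmptyResultError("taxon filter removed every taxon")
    return table.select_taxa(keep.index[keep])


def clr_transform(table: OtuTable, pseudocount: float = 1.0) -> ClrMatrix:
    """Centred log-ratio transform of counts (samples x taxa).

    For each sample: add ``pseudocount`` to every count, close to relative
    abundances p, and return ``ln p_j - mean_j ln p_j``. ``pseudocount=0`` is
    permitted only when every count is strictly positive.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    x = table.counts.to_numpy(dtype=float).T + pseudocount  # samples x taxa
    if (x <= 0).any():
        raise ValueError("zero counts require a positive pseudocount")
    logp = np.log(x / x.sum(axis=1, keepdims=True))
    clr = logp - logp.mean(axis=1, keepdims=True)
    values = pd.DataFrame(clr, index=table.sample_ids, columns=table.taxon_ids)
    return ClrMatrix(values=values, pseudocount=pseudocount)


@dataclass
class IntergroupSummary:
    pair: tuple[str, str]
    mean: float
    sd: float
    replicate_means: np.ndarray
    n_rep: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_a": [self.pair[0]],
                "group_b": [self.pair[1]],
                "mean": [self.mean],
                "sd": [self.sd],
                "n_rep": [self.n_rep],
                "seed": [self.seed],
            }
        )


def intergroup_distance(
    dm: DistanceMatrix,
    groups: dict[str, str] | pd.Series,
    pair: tuple[str, str],
    n_rep: int = 999,
    rng_seed: int = 0,
) -> IntergroupSummary:
    """Mean between-group distance averaged over resampled disjoint pairs.

    Each replicate shuffles the larger group, pairs its first ``min(|A|,|B|)``
    members with the smaller group (disjoint cross-group pairs, drawn without
    replacement), and averages the pair distances; the summary is the mean and
    sd over ``n_rep`` replicates (the study's convention used 999).
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    label_a, label_b = pair
    idx = {s: i for i, s in enumerate(dm.sample_ids)}
    members: dict[str, np.ndarray] = {}
    for label in (label_a, label_b):
        samp = [s for s, g in groups.items() if g == label and s in idx]
        if not samp:
            raise ValueError(f"unknown or empty group label {label!r}")
        members[label] = np.array([idx[s] for s in samp])
    a, b = members[label_a], members[label_b]
    if len(a) > len(b):  # always shuffle the larger side
        a, b = b, a
    rng = np.random.default_rng(rng_seed)
    reps = np.empty(n_rep)
    for r in range(n_rep):
        partners = rng.permutation(b)[: len(a)]
        reps[r] = dm.values[a, partners].mean()
    return IntergroupSummary(
        pair=(label_a, label_b),
        mean=float(reps.mean()),
        sd=float(reps.std(ddof=0)),
        replicate_means=reps,
        n_rep=n_rep,
        seed=rng_seed,
    )
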