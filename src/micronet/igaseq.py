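"""IgA-Seq coating indices.

After flow-sorting a faecal community into IgA-coated (IgA+) and uncoated
(IgA-) fractions and sequencing both, the IgA coating index of a taxon in a
sample is the ratio of its relative abundance in the IgA+ fraction to that
in the IgA- fraction, regularised by a pseudo relative abundance epsilon so
taxa absent from a fraction stay finite:

    ICI = (relabund_pos + eps) / (relabund_neg + eps)

log2(ICI) > 0 marks taxa preferentially coated by secretory IgA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .otu import OtuTable

__all__ = ["ici", "IciTable", "rank_coated"]


@dataclass
class IciTable:
    """Per-taxon, per-sample IgA coating indices and the inputs behind them."""

    ici: pd.DataFrame          # taxa x samples
    log2_ici: pd.DataFrame
    relabund_pos: pd.DataFrame
    relabund_neg: pd.DataFrame
    epsilon: float
    pos_depths: pd.Series
    neg_depths: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.log2_ici.stack().rename("log2_ici").reset_index()
        out.columns = ["taxon", "sample_id", "log2_ici"]
        out["ici"] = self.ici.stack().to_numpy()
        return out


def ici(pos: OtuTable, neg: OtuTable, epsilon: float | None = None) -> IciTable:
    """IgA coating index from paired IgA+ / IgA- fraction tables.

    Tables must share taxa and sample ids (pairing is by sample id). The
    default epsilon is one read at the deepest fraction expressed as a
    relative abundance, ``1 / max(depth)``.
    """
    if list(pos.taxon_ids) != list(neg.taxon_ids):
        raise ValueError("fraction tables must share the same taxa in the same order")
    pos_ids, neg_ids = set(pos.sample_ids), set(neg.sample_ids)
    unpaired = sorted(pos_ids ^ neg_ids)
    if unpaired:
        raise ValueError(f"unpaired samples between fractions: {unpaired}")
    samples = list(pos.sample_ids)
    rp = pos.relative_abundance()[samples]
    rn = neg.relative_abundance()[samples]
    if epsilon is None:
        max_depth = max(pos.depths().max(), neg.depths().max())
        epsilon = 1.0 / max(float(max_depth), 1.0)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    ratio = (rp + epsilon) / (rn + epsilon)
    return IciTable(
        ici=ratio,
        log2_ici=np.log2(ratio),
        relabund_pos=rp,
        relabund_neg=rn,
        epsilon=float(epsilon),
        pos_depths=pos.depths(),
        neg_depths=neg.depths()[samples],
    )


def rank_coated(table: IciTable, min_consistent: float = 0.75) -> pd.DataFrame:
    """Rank taxa by median log2 ICI and call consistent coating.

    A taxon is called over-coated when its median log2 ICI is > 0 and it is
    positive in at least ``min_consistent`` of samples; under-coated calls
    mirror this below zero. Everything else is uncalled.
    """
    if not 0 < min_consistent <= 1:
        raise ValueError("min_consistent must lie in (0, 1]")
    med = table.log2_ici.median(axis=1)
    frac_pos = (table.log2_ici > 0).mean(axis=1)
    frac_neg = (table.log2_ici < 0).mean(axis=1)
    call = pd.Series("none", index=med.index, dtype=object)
    call[(med > 0) & (frac_pos >= min_consistent)] = "over_coated"
    call[(med < 0) & (frac_neg >= min_consistent)] = "under_coated"
    out = pd.DataFrame({
        "median_log2_ici": med,
        "fraction_positive": frac_pos,
        "call": call,
    }).sort_values("median_log2_ici", ascending=False)
    out.index.name = "taxon"
    return out.reset_index()
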