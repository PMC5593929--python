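"""Cross-experiment edge recovery.

Edges inferred in one experiment are ranked by their StARS stability
(confidence) scores and compared against the network inferred in another
experiment, treated as truth, over the set of taxa common to both. Sweeping
a cutoff down the ranking yields precision-recall and ROC curves; the
headline statistic is the maximum F1 (harmonic mean of precision and
recall) over all cutoffs, judged against the at-random baseline given by the
truth network's edge density.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .inference import AssociationNetwork, StarsResults

__all__ = ["rank_edges", "recovery_curve", "RecoveryResult"]


def rank_edges(stab: StarsResults, taxa_subset=None) -> pd.DataFrame:
    """All node pairs within ``taxa_subset`` by descending confidence.

    Confidence is the StARS selection frequency at the selected lambda; ties
    break by lexical pair id, so the ordering is fully deterministic.
    """
    taxa = list(stab.taxa) if taxa_subset is None else list(taxa_subset)
    unknown = set(taxa) - set(stab.taxa)
    if unknown:
        raise ValueError(f"taxa not in stability result: {sorted(unknown)}")
    freq = stab.frequency_frame()
    rows = []
    for a in range(len(taxa)):
        for b in range(a + 1, len(taxa)):
            u, v = sorted((taxa[a], taxa[b]))
            rows.append({"taxon_a": u, "taxon_b": v,
                         "confidence": float(freq.loc[u, v])})
    df = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "confidence"])
    return df.sort_values(["confidence", "taxon_a", "taxon_b"],
                          ascending=[False, True, True]).reset_index(drop=True)


@dataclass
class RecoveryResult:
    """Precision/recall/ROC sweep of a ranked edge list against a truth set."""

    curve: pd.DataFrame          # k, precision, recall, f1, tpr, fpr
    max_f1: float
    k_at_max: int
    baseline_density: float
    common_taxa: list[str]
    truth_edges: set

    def to_frame(self) -> pd.DataFrame:
        return self.curve

    def summary_dict(self) -> dict:
        return {"max_f1": self.max_f1, "k_at_max": self.k_at_max,
                "baseline_density": self.baseline_density,
                "n_common_taxa": len(self.common_taxa),
                "n_truth_edges": len(self.truth_edges)}


def recovery_curve(ranked: pd.DataFrame,
                   truth: AssociationNetwork | set,
                   common_taxa) -> RecoveryResult:
    """Sweep the ranking cutoff and score recovery of the truth edge set.

    The evaluation universe is every unordered pair of ``common_taxa``;
    negatives are the non-edges of the truth network within that universe.
    """
    common = sorted(set(common_taxa))
    universe = {tuple(sorted(p)) for i, a in enumerate(common)
                for p in [(a, b) for b in common[i + 1:]]}
    if isinstance(truth, AssociationNetwork):
        truth_edges = {e for e in truth.edge_set() if e in universe}
    else:
        truth_edges = {tuple(sorted(e)) for e in truth if tuple(sorted(e)) in universe}
    if not truth_edges:
        raise ValueError("empty truth edge set within the common taxa; F1 undefined")

    pairs = [tuple(sorted((r.taxon_a, r.taxon_b))) for r in ranked.itertuples()]
    pairs = [p for p in pairs if p in universe]
    n_pos = len(truth_edges)
    n_neg = len(universe) - n_pos
    tp = fp = 0
    rows = []
    for k, pair in enumerate(pairs, start=1):
        if pair in truth_edges:
            tp += 1
        else:
            fp += 1
        precision = tp / k
        recall = tp / n_pos
        f1 = 2 * precision * recall / (precision + recall) if tp else 0.0
        rows.append({"k": k, "precision": precision, "recall": recall, "f1": f1,
                     "tpr": recall, "fpr": fp / n_neg if n_neg else 0.0})
    curve = pd.DataFrame(rows)
    best = curve["f1"].idxmax()
    return RecoveryResult(
        curve=curve,
        max_f1=float(curve.loc[best, "f1"]),
        k_at_max=int(curve.loc[best, "k"]),
        baseline_density=n_pos / len(universe),
        common_taxa=common,
        truth_edges=truth_edges,
    )
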