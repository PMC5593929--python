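"""Core data containers for compositional microbiome analysis.

The universal input is an :class:`OtuTable`: a taxa x samples count matrix with
taxonomy strings and per-sample metadata. Downstream modules consume the
centred log-ratio (clr) transform (:class:`ClrMatrix`) or a caller-supplied
:class:`DistanceMatrix` (e.g. UniFrac distances computed elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd

__all__ = ["OtuTable", "ClrMatrix", "DistanceMatrix"]

#: metadata columns required by the pipeline; ``siga`` and ``sex`` are optional
REQUIRED_META = ["sample_id", "subject_id", "group", "experiment", "time_point"]


@dataclass
class OtuTable:
    """Taxa x samples count table with taxonomy and sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, index = taxon ids, columns = sample ids.
    taxonomy : pandas.Series
        Lineage string per taxon (may be empty strings); index = taxon ids.
    sample_meta : pandas.DataFrame
        One record per sample, indexed by sample id. Must carry
        ``subject_id``, ``group``, ``experiment``, ``time_point``; ``siga``
        (faecal sIgA, µg/ml) and ``sex`` are optional.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.taxonomy is None:
            self.taxonomy = pd.Series("", index=self.counts.index, dtype=object)
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.counts.columns)
        self.taxonomy = self.taxonomy.reindex(self.counts.index).fillna("")
        self._validate()

    def _validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate taxon ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("counts must be finite and non-negative")
        missing = self.counts.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.sample_meta = self.sample_meta.loc[self.counts.columns]

    # -- basic views ------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (column sums)."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample closure: columns sum to 1 (zero-depth columns -> 0)."""
        d = self.depths().replace(0, np.nan)
        return self.counts.div(d, axis=1).fillna(0.0)

    def select_samples(self, sample_ids) -> "OtuTable":
        ids = list(sample_ids)
        return OtuTable(
            counts=self.counts[ids].copy(),
            taxonomy=self.taxonomy.copy(),
            sample_meta=self.sample_meta.loc[ids].copy(),
        )

    def select_taxa(self, taxon_ids) -> "OtuTable":
        ids = list(taxon_ids)
        return OtuTable(
            counts=self.counts.loc[ids].copy(),
            taxonomy=self.taxonomy.loc[ids].copy(),
            sample_meta=self.sample_meta.copy(),
        )

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_tsv(cls, counts_path, meta_path=None) -> "OtuTable":
        """Read a taxa-in-rows TSV (header = sample ids, optional trailing
        ``taxonomy`` column) plus an optional metadata TSV keyed by
        ``sample_id``."""
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        taxonomy = None
        if "taxonomy" in df.columns:
            taxonomy = df.pop("taxonomy").astype(str)
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t")
            for col in REQUIRED_META:
                if col not in meta.columns:
                    raise ValueError(f"metadata missing required column {col!r}")
            meta["sample_id"] = meta["sample_id"].astype(str)
            meta = meta.set_index("sample_id")
        df.columns = df.columns.astype(str)
        return cls(counts=df, taxonomy=taxonomy, sample_meta=meta)

    def to_tsv(self, counts_path, meta_path=None) -> None:
        out = self.counts.copy()
        out["taxonomy"] = self.taxonomy
        out.to_csv(counts_path, sep="\t", index_label="taxon_id")
        if meta_path is not None:
            self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


@dataclass
class ClrMatrix:
    """Centred log-ratio transformed abundances, samples x taxa.

    Each row sums to zero (within 1e-8) by construction.
    """

    values: pd.DataFrame  # samples x taxa
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("clr matrix contains non-finite entries")
        rowsums = vals.sum(axis=1)
        if len(rowsums) and np.abs(rowsums).max() > 1e-8 * max(1, vals.shape[1]):
            raise ValueError("clr rows must sum to zero")

    @property
    def source_taxa(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix over samples (zero diagonal)."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(v.shape[0])]
        if len(self.sample_ids) != v.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if np.abs(v - v.T).max(initial=0.0) > 1e-10:
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 0:
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(dtype=float), sample_ids=[str(s) for s in df.index])

    def loc(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])
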