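"""Count-matrix container shared by every pipeline stage.

A :class:`CountMatrix` holds integer read counts for genes x samples together
with per-sample metadata (extraction, condition, replicate) and per-gene
transcript lengths.  It is the boundary object of the pipeline: simulation
produces one, quantification and differential-expression testing consume one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "ValidationError"]

METADATA_COLUMNS = ("extraction", "condition", "replicate")


class ValidationError(ValueError):
    """Raised when a container or parameter violates its documented contract."""


@dataclass
class CountMatrix:
    """Genes x samples integer read counts with sample metadata and gene lengths.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, index = gene ids, columns = sample ids.
    metadata : pandas.DataFrame
        One row per sample (index = sample id) with columns
        ``extraction``, ``condition``, ``replicate``.
    gene_lengths : pandas.Series
        Transcript length in bp per gene (>= 1), indexed by gene id.
    truth : pandas.DataFrame, optional
        Ground-truth labels attached by the simulator; columns
        ``gene_id``, ``tissue``, ``label``, ``log2fc``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    gene_lengths: pd.Series
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        if self.counts.index.has_duplicates:
            raise ValidationError("gene ids must be unique")
        if self.counts.columns.has_duplicates:
            raise ValidationError("sample ids must be unique")
        values = self.counts.to_numpy()
        if values.size == 0:
            raise ValidationError("count matrix is empty")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")

        missing_cols = set(METADATA_COLUMNS) - set(self.metadata.columns)
        if missing_cols:
            raise ValidationError(f"metadata missing columns: {sorted(missing_cols)}")
        missing_meta = set(self.counts.columns) - set(self.metadata.index)
        if missing_meta:
            raise ValidationError(f"samples without metadata: {sorted(missing_meta)}")
        self.metadata = self.metadata.loc[list(self.counts.columns)]

        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            bad = self.gene_lengths.index[self.gene_lengths.isna()][0]
            raise ValidationError(f"gene without length: {bad!r}")
        if (self.gene_lengths < 1).any():
            raise ValidationError("gene lengths must be >= 1 bp")
        self.gene_lengths = self.gene_lengths.astype(float)

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def select_samples(self, extraction: str | None = None, condition: str | None = None) -> "CountMatrix":
        """Return the sub-matrix of samples matching extraction and/or condition."""
        mask = pd.Series(True, index=self.metadata.index)
        if extraction is not None:
            mask &= self.metadata["extraction"] == extraction
        if condition is not None:
            mask &= self.metadata["condition"] == condition
        keep = self.metadata.index[mask]
        if len(keep) == 0:
            raise ValidationError(
                f"no samples match extraction={extraction!r}, condition={condition!r}"
            )
        return CountMatrix(self.counts[keep], self.metadata.loc[keep], self.gene_lengths, self.truth)

    # ------------------------------------------------------------------
    # TSV round trip: counts (first column gene id), sidecar metadata,
    # gene lengths, optional truth labels.
    def to_tsv(self, counts_path, metadata_path, lengths_path, truth_path=None) -> None:
        out = self.counts.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        meta = self.metadata.copy()
        meta.insert(0, "sample_id", meta.index)
        meta.to_csv(metadata_path, sep="\t", index=False)
        pd.DataFrame(
            {"gene_id": self.gene_lengths.index, "length_bp": self.gene_lengths.astype(int)}
        ).to_csv(lengths_path, sep="\t", index=False)
        if truth_path is not None and self.truth is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, metadata_path, lengths_path, truth_path=None) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t").set_index("gene_id")
        counts.index.name = None
        meta = pd.read_csv(metadata_path, sep="\t").set_index("sample_id")
        meta.index.name = None
        lengths = pd.read_csv(lengths_path, sep="\t").set_index("gene_id")["length_bp"].rename(None)
        truth = None
        if truth_path is not None and Path(truth_path).exists():
            truth = pd.read_csv(truth_path, sep="\t")
        return cls(counts, meta, lengths, truth)
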