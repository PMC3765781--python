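"""RPKM quantification, transcriptome membership and depth equalization.

RPKM (reads per kilobase of transcript per million mapped reads) for gene g in
sample s is ``10^9 * c_gs / (N_s * L_g)`` with ``N_s`` the sample's column sum
and ``L_g`` the annotated transcript length in bp.  A gene belongs to the
transcriptome of an (extraction, condition) when its replicate-mean RPKM is
strictly above a threshold (default 10).  Depth is equalized across samples by
thinning each column without replacement (multivariate hypergeometric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countdata import CountMatrix, ValidationError
from ._seeds import derived_rng

__all__ = [
    "RpkmMatrix",
    "TranscriptomeSet",
    "compute_rpkm",
    "transcriptome_membership",
    "downsample_counts",
]


@dataclass
class RpkmMatrix:
    """Genes x samples RPKM values with the sample metadata carried along."""

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValidationError("RPKM values must be finite and non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def group_means(self, extraction: str, condition: str) -> pd.Series:
        """Replicate-mean RPKM per gene for one (extraction, condition)."""
        mask = (self.metadata["extraction"] == extraction) & (
            self.metadata["condition"] == condition
        )
        cols = self.metadata.index[mask]
        if len(cols) == 0:
            raise ValidationError(
                f"no samples for extraction={extraction!r}, condition={condition!r}"
            )
        return self.values[cols].mean(axis=1)

    def to_tsv(self, path) -> None:
        out = self.values.copy().round(4)
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.4f")


@dataclass
class TranscriptomeSet:
    """Genes whose replicate-mean RPKM exceeds a threshold in one extraction/condition."""

    extraction: str
    condition: str
    threshold: float
    members: frozenset

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("membership threshold must be > 0")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id) -> bool:
        return gene_id in self.members

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# extraction={self.extraction} condition={self.condition} "
                f"threshold={self.threshold}\n"
            )
            fh.write("gene_id\n")
            for gid in sorted(self.members):
                fh.write(f"{gid}\n")


def compute_rpkm(counts: CountMatrix) -> RpkmMatrix:
    """Convert a count matrix to RPKM.

    Raises
    ------
    ValidationError
        If any sample has a zero column sum (the per-million factor is undefined).
    """
    totals = counts.library_sizes()
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"sample {zero[0]!r} has zero total counts")
    c = counts.counts.to_numpy(dtype=float)
    lengths = counts.gene_lengths.to_numpy()[:, None]
    rpkm = 1e9 * c / (totals.to_numpy()[None, :] * lengths)
    return RpkmMatrix(
        pd.DataFrame(rpkm, index=counts.gene_ids, columns=counts.sample_ids),
        counts.metadata,
    )


def transcriptome_membership(
    rpkm: RpkmMatrix, extraction: str, condition: str, threshold: float = 10.0
) -> TranscriptomeSet:
    """Genes with replicate-mean RPKM strictly greater than ``threshold``."""
    if threshold <= 0:
        raise ValidationError("membership threshold must be > 0")
    means = rpkm.group_means(extraction, condition)
    members = frozenset(means.index[means > threshold])
    return TranscriptomeSet(extraction, condition, threshold, members)


def downsample_counts(counts: CountMatrix, target_depth: int, seed: int) -> CountMatrix:
    """Thin every sample to exactly ``target_depth`` total reads.

    Each column is subsampled without replacement (multivariate hypergeometric),
    so a gene holding fraction f of a column keeps fraction f of the target in
    expectation.  Per-sample random streams are derived from ``seed`` and the
    sample id, so the result for one sample does not depend on which other
    samples are present.
    """
    target_depth = int(target_depth)
    if target_depth < 1:
        raise ValidationError("target depth must be >= 1")
    totals = counts.library_sizes()
    short = totals.index[totals < target_depth]
    if len(short):
        raise ValidationError(
            f"sample {short[0]!r} has only {totals[short[0]]} reads "
            f"(< target {target_depth})"
        )
    new = {}
    for sample in counts.sample_ids:
        col = counts.counts[sample].to_numpy(dtype=np.int64)
        if col.sum() == target_depth:
            new[sample] = col
            continue
        rng = derived_rng(seed, "downsample", sample)
        new[sample] = rng.multivariate_hypergeometric(col, target_depth, method="marginals")
    frame = pd.DataFrame(new, index=counts.gene_ids)[list(counts.sample_ids)]
    return CountMatrix(frame, counts.metadata, counts.gene_lengths, counts.truth)
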