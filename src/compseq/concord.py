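"""Cross-extraction concordance analyses.

These operations compare the differential-expression picture seen in a
focal-tissue extraction with the one seen in the composite extraction that
contains it: which focal transcriptome members the composite misses, how
focal-DE genes are re-called in the composite (not significant, same
direction, opposite direction), how strongly each gene's signal is diluted
(focal/composite RPKM ratio), and Fisher's exact comparisons between focal
tissues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .countdata import ValidationError
from .detest import DEResults
from .quantify import RpkmMatrix, transcriptome_membership

__all__ = [
    "ConcordanceTable",
    "PresenceAbsenceTable",
    "DilutionRatioSet",
    "FisherResult",
    "classify_cross_extraction",
    "presence_absence_table",
    "dilution_ratios",
    "fisher_exact_2x2",
    "compare_focal_tissues",
    "subset_analysis",
]

DEFAULT_BIN_EDGES = (10.0, 30.0, 100.0, 300.0)
_TIE_RTOL = 1e-7


@dataclass
class ConcordanceTable:
    """Fate of focal-tissue DE genes in the composite extraction.

    ``categories`` maps each focal-DE gene id to one of
    {"not_sig", "same_direction", "opposite_direction"}.
    """

    focal: str
    composite: str
    categories: dict = field(repr=False)
    unresolved: tuple = ()

    def __post_init__(self) -> None:
        bad = set(self.categories.values()) - {"not_sig", "same_direction", "opposite_direction"}
        if bad:
            raise ValidationError(f"unknown concordance categories: {sorted(bad)}")

    @property
    def n_focal_de(self) -> int:
        return len(self.categories)

    @property
    def n_not_sig(self) -> int:
        return sum(1 for v in self.categories.values() if v == "not_sig")

    @property
    def n_same_direction(self) -> int:
        return sum(1 for v in self.categories.values() if v == "same_direction")

    @property
    def n_opposite_direction(self) -> int:
        return sum(1 for v in self.categories.values() if v == "opposite_direction")

    def proportions(self) -> dict:
        """Category shares of the focal-DE genes (empty table -> zeros)."""
        n = max(self.n_focal_de, 1)
        return {
            "not_sig": self.n_not_sig / n,
            "same_direction": self.n_same_direction / n,
            "opposite_direction": self.n_opposite_direction / n,
        }

    @classmethod
    def from_counts(
        cls, focal: str, composite: str, n_not_sig: int, n_same: int, n_opposite: int
    ) -> "ConcordanceTable":
        """Build a table from published category counts (synthetic gene ids)."""
        cats = {}
        i = 0
        for label, n in (
            ("not_sig", n_not_sig),
            ("same_direction", n_same),
            ("opposite_direction", n_opposite),
        ):
            for _ in range(int(n)):
                cats[f"{focal}_de_{i:05d}"] = label
                i += 1
        return cls(focal, composite, cats)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.categories), "category": list(self.categories.values())}
        )


@dataclass
class PresenceAbsenceTable:
    """Transcriptome-membership mismatches between focal and composite.

    ``focal_only`` / ``composite_only`` map gene id -> RPKM in the extraction
    where the gene IS present; ``bins`` gives the per-set histogram over
    expression bins (pandas.Interval -> count).
    """

    threshold: float
    focal_only: dict
    composite_only: dict
    bin_edges: tuple = DEFAULT_BIN_EDGES
    bins_focal_only: pd.Series = field(default=None, repr=False)
    bins_composite_only: pd.Series = field(default=None, repr=False)

    def __post_init__(self) -> None:
        overlap = set(self.focal_only) & set(self.composite_only)
        if overlap:
            raise ValidationError("presence/absence sets must be disjoint")


@dataclass
class DilutionRatioSet:
    """Per-gene focal/composite RPKM ratios for a gene set.

    A ratio is defined only when both RPKM means are positive; genes with a
    zero composite (or focal) mean are tracked in ``n_undefined`` and
    excluded from the above/below-1 counts.
    """

    focal: str
    composite: str
    ratios: pd.Series = field(repr=False)
    undefined: tuple = ()

    @property
    def n_above_1(self) -> int:
        return int((self.ratios > 1.0).sum())

    @property
    def n_at_or_below_1(self) -> int:
        return int((self.ratios <= 1.0).sum())

    @property
    def n_undefined(self) -> int:
        return len(self.undefined)

    def proportions(self) -> dict:
        n = max(len(self.ratios), 1)
        return {"above_1": self.n_above_1 / n, "at_or_below_1": self.n_at_or_below_1 / n}

    @classmethod
    def from_counts(cls, focal, composite, n_above_1, n_at_or_below_1) -> "DilutionRatioSet":
        """Build a set from published above/below counts (ratios 2 and 0.5)."""
        vals = [2.0] * int(n_above_1) + [0.5] * int(n_at_or_below_1)
        idx = [f"{focal}_ratio_{i:05d}" for i in range(len(vals))]
        return cls(focal, composite, pd.Series(vals, index=idx))


@dataclass(frozen=True)
class FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table."""

    table: tuple
    odds_ratio: float
    p_value: float

    def __str__(self) -> str:
        (a, b), (c, d) = self.table
        return (
            f"Fisher 2x2 [[{a}, {b}], [{c}, {d}]]: OR={self.odds_ratio:.4g}, "
            f"p={self.p_value:.4g}"
        )


def classify_cross_extraction(
    focal_results: DEResults, composite_results: DEResults
) -> ConcordanceTable:
    """Classify each focal-DE gene by its composite-extraction call.

    Categories: ``not_sig`` when the composite call is not_DE or the gene is
    absent from the composite results; ``same_direction`` /
    ``opposite_direction`` by comparing direction fields.  Both result sets
    must come from the same method (like is compared with like).
    """
    if focal_results.method != composite_results.method:
        raise ValidationError(
            f"method mismatch: focal={focal_results.method!r} vs "
            f"composite={composite_results.method!r}"
        )
    comp = composite_results.table
    categories = {}
    for gid in focal_results.de_genes:
        if gid not in comp.index or comp.at[gid, "call"] != "DE":
            categories[gid] = "not_sig"
        elif comp.at[gid, "direction"] == focal_results.direction_of(gid):
            categories[gid] = "same_direction"
        else:
            categories[gid] = "opposite_direction"
    return ConcordanceTable(
        focal_results.model.extraction, composite_results.model.extraction, categories
    )


def presence_absence_table(
    rpkm: RpkmMatrix,
    focal: str,
    composite: str,
    condition: str,
    threshold: float = 10.0,
    bin_edges: tuple = DEFAULT_BIN_EDGES,
) -> PresenceAbsenceTable:
    """Genes present in one transcriptome but absent from the other.

    Membership per :func:`~compseq.quantify.transcriptome_membership`;
    (+focal, -composite) genes are binned by their focal RPKM,
    (-focal, +composite) genes by their composite RPKM, on
    (e1, e2], ..., (e_last, inf) intervals.
    """
    if threshold <= 0:
        raise ValidationError("membership threshold must be > 0")
    foc = transcriptome_membership(rpkm, focal, condition, threshold)
    com = transcriptome_membership(rpkm, composite, condition, threshold)
    foc_means = rpkm.group_means(focal, condition)
    com_means = rpkm.group_means(composite, condition)
    focal_only = {g: float(foc_means[g]) for g in foc.members - com.members}
    composite_only = {g: float(com_means[g]) for g in com.members - foc.members}

    edges = list(bin_edges) + [np.inf]

    def _bin(values: dict) -> pd.Series:
        if not values:
            return pd.cut(pd.Series(dtype=float), edges).value_counts().sort_index()
        return pd.cut(pd.Series(values), edges).value_counts().sort_index()

    return PresenceAbsenceTable(
        threshold, focal_only, composite_only, tuple(bin_edges), _bin(focal_only),
        _bin(composite_only),
    )


def dilution_ratios(
    rpkm: RpkmMatrix,
    focal: str,
    composite: str,
    condition: str,
    gene_set,
) -> DilutionRatioSet:
    """Focal/composite replicate-mean RPKM ratio for each gene in ``gene_set``."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValidationError("gene_set must be non-empty")
    foc = rpkm.group_means(focal, condition).reindex(gene_set)
    com = rpkm.group_means(composite, condition).reindex(gene_set)
    missing = foc.index[foc.isna() | com.isna()]
    if len(missing):
        raise ValidationError(f"gene {missing[0]!r} absent from the RPKM matrix")
    defined = (foc > 0) & (com > 0)
    ratios = (foc[defined] / com[defined]).rename("ratio")
    return DilutionRatioSet(focal, composite, ratios, tuple(foc.index[~defined]))


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher's exact test by hypergeometric enumeration.

    Sums the point probabilities of every table with the observed margins
    whose probability is no greater than the observed table's (within 1e-7
    relative tolerance, so floating-point ties are kept).  The odds ratio is
    ad/bc with an infinity convention when bc = 0.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValidationError("cells must be non-negative integers")
    a, b, c, d = (int(x) for x in arr.ravel())
    n = a + b + c + d
    if n == 0:
        raise ValidationError("at least one margin must be nonzero")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    return FisherResult(((a, b), (c, d)), odds, min(p, 1.0))


def _property_counts(obj) -> tuple:
    """(property-present, property-absent) counts for the Fisher comparison."""
    if isinstance(obj, ConcordanceTable):
        return obj.n_not_sig, obj.n_same_direction + obj.n_opposite_direction
    if isinstance(obj, DilutionRatioSet):
        return obj.n_above_1, obj.n_at_or_below_1
    raise ValidationError(f"unsupported table type: {type(obj).__name__}")


def compare_focal_tissues(table_a, table_b) -> FisherResult:
    """Fisher comparison of a property share between two focal tissues.

    For :class:`ConcordanceTable` inputs the property is "not significant in
    the composite"; for :class:`DilutionRatioSet` it is "dilution ratio > 1"
    (undefined-ratio genes are excluded before the 2x2 is built).
    """
    if type(table_a) is not type(table_b):
        raise ValidationError("both inputs must be the same table type")
    row_a = _property_counts(table_a)
    row_b = _property_counts(table_b)
    return fisher_exact_2x2((row_a, row_b))


def subset_analysis(
    focal_results: DEResults, composite_results: DEResults, gene_list
) -> ConcordanceTable:
    """Cross-extraction classification restricted to a user gene list.

    Typical use: a curated transcription-factor list.  Gene ids not found in
    either result set are reported on the returned table, not fatal.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValidationError("gene_list must be non-empty")
    full = classify_cross_extraction(focal_results, composite_results)
    wanted = set(gene_list)
    universe = set(focal_results.table.index) | set(composite_results.table.index)
    unresolved = tuple(g for g in gene_list if g not in universe)
    categories = {g: cat for g, cat in full.categories.items() if g in wanted}
    return ConcordanceTable(full.focal, full.composite, categories, unresolved)
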