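"""Differential-expression testing between two conditions within one extraction.

Two method families are provided, mirroring the standard count-based and
nonparametric approaches for two-group bulk RNA-seq designs:

``nb_exact``
    An exact negative-binomial test.  Replicate counts are scaled to a common
    effective library size and summed within condition; conditional on the
    two-condition total s, the two-sided p-value sums the null point
    probabilities of every split (a, s - a) no more likely than the observed
    one (minimum-likelihood rule, ties included).  Dispersion phi (variance
    mu + phi mu^2) is estimated by a method-of-moments common dispersion, and
    p-values are Benjamini-Hochberg adjusted.

``noiseq_like``
    A nonparametric signal-vs-noise probability on the RPKM scale.  The
    per-gene signal is the pair (M, D) with M the pseudo-counted log2 ratio
    of condition means and D their absolute difference; the noise
    distribution pools (|M*|, D*) over all genes and all within-condition
    replicate pairs.  The DE probability q_g is the fraction of noise points
    strictly dominated by the gene's signal; genes with q_g above a cutoff
    (default 0.8) are called differentially expressed.

The entry point is the :class:`DifferentialExpression` model: construct it
from a :class:`~compseq.countdata.CountMatrix` and an extraction name, call
``fit()``, and read calls and statistics off the returned :class:`DEResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from .countdata import CountMatrix, ValidationError
from .quantify import RpkmMatrix, compute_rpkm

__all__ = [
    "DEConfig",
    "DispersionEstimate",
    "DEResults",
    "DifferentialExpression",
    "estimate_common_dispersion",
    "nb_exact_test",
    "noiseq_like_probability",
    "bh_adjust",
    "call_de",
]

_TIE_RTOL = 1e-7  # relative tolerance for "no more likely" ties in enumeration


@dataclass(frozen=True)
class DEConfig:
    """Thresholds and conventions for one DE analysis.

    alpha is the FDR threshold for the exact test (call when q <= alpha,
    inclusive); q_cut is the nonparametric probability cutoff (call when
    q_g > q_cut, exclusive); pseudo_count k (RPKM units) regularizes log
    ratios; dispersion_floor is the minimum mean normalized count for a gene
    to enter the common-dispersion median.
    """

    method: str = "noiseq_like"
    alpha: float = 0.05
    q_cut: float = 0.8
    pseudo_count: float = 0.5
    dispersion_floor: float = 5.0
    dispersion: float | None = None  # supply to skip estimation

    def __post_init__(self) -> None:
        if self.method not in ("nb_exact", "noiseq_like"):
            raise ValidationError("method must be 'nb_exact' or 'noiseq_like'")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0.0 < self.q_cut < 1.0:
            raise ValidationError("q_cut must lie in (0, 1)")
        if self.pseudo_count <= 0:
            raise ValidationError("pseudo_count must be > 0")


@dataclass(frozen=True)
class DispersionEstimate:
    """Common negative-binomial dispersion and the group sizes it was based on."""

    phi: float
    group_sizes: tuple
    n_genes_used: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi) or self.phi < 0:
            raise ValidationError("dispersion must be finite and >= 0")


def estimate_common_dispersion(
    counts: CountMatrix,
    groups: pd.Series | np.ndarray,
    floor: float = 5.0,
) -> DispersionEstimate:
    """Method-of-moments common dispersion across two (or more) groups.

    Counts are normalized to the mean library size; per gene and group with
    >= 2 replicates, phi_g = max(0, (s^2 - mean) / mean^2); group estimates
    are averaged per gene weighted by their degrees of freedom, and the
    common phi is the median over genes whose mean normalized count is at
    least ``floor``.
    """
    groups = pd.Series(np.asarray(groups), index=counts.sample_ids)
    sizes = counts.library_sizes().to_numpy(dtype=float)
    norm = counts.counts.to_numpy(dtype=float) * (sizes.mean() / sizes)[None, :]

    num = np.zeros(norm.shape[0])
    dof = np.zeros(norm.shape[0])
    any_replication = False
    for g in groups.unique():
        cols = np.flatnonzero((groups == g).to_numpy())
        n = len(cols)
        if n < 2:
            continue
        any_replication = True
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
        num += np.maximum(phi_g, 0.0) * (n - 1)
        dof += n - 1
    if not any_replication:
        raise ValidationError(
            "no group has replication; supply a dispersion explicitly via DEConfig"
        )
    phi_per_gene = num / np.maximum(dof, 1)
    keep = norm.mean(axis=1) >= floor
    if not keep.any():
        keep = norm.mean(axis=1) > 0
    phi = float(np.median(phi_per_gene[keep]))
    group_sizes = tuple(int((groups == g).sum()) for g in groups.unique())
    return DispersionEstimate(max(phi, 0.0), group_sizes, int(keep.sum()))


def _nb_logpmf(a: np.ndarray, mean: float, size: float) -> np.ndarray:
    return nbinom.logpmf(a, size, size / (size + mean))


def nb_exact_test(
    counts1: np.ndarray,
    counts2: np.ndarray,
    lib_sizes1: np.ndarray,
    lib_sizes2: np.ndarray,
    phi: float,
) -> float:
    """Exact two-sided NB test for one gene.

    Replicate counts are scaled to the geometric-mean library size and summed
    within condition (rounded to the nearest integer, the NB support).  Under
    the null the condition sums A ~ NB(n1 mu, phi/n1) and B ~ NB(n2 mu,
    phi/n2) are compared conditionally on s = A + B: the p-value sums the
    point probabilities of all splits no more likely than the observed one.
    phi below 1e-8 falls back to the Poisson (conditional binomial) limit.
    Returns 1.0 when s = 0 (nothing to test).
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValidationError("counts must be non-negative")
    if phi < 0:
        raise ValidationError("dispersion must be >= 0")
    sizes = np.concatenate([np.asarray(lib_sizes1, float), np.asarray(lib_sizes2, float)])
    if (sizes <= 0).any():
        raise ValidationError("library sizes must be positive")
    common = float(np.exp(np.mean(np.log(sizes))))
    a_obs = int(round((c1 * common / np.asarray(lib_sizes1, float)).sum()))
    b_obs = int(round((c2 * common / np.asarray(lib_sizes2, float)).sum()))
    s = a_obs + b_obs
    if s == 0:
        return 1.0
    n1, n2 = len(c1), len(c2)
    a = np.arange(s + 1)
    if phi < 1e-8:
        # Poisson limit: conditional distribution of A given s is binomial
        from scipy.stats import binom

        logp = binom.logpmf(a, s, n1 / (n1 + n2))
    else:
        mu = s / (n1 + n2)
        logp = _nb_logpmf(a, n1 * mu, n1 / phi) + _nb_logpmf(s - a, n2 * mu, n2 / phi)
    log_obs = logp[a_obs]
    keep = logp <= log_obs + np.log1p(_TIE_RTOL)
    p = float(np.exp(logsumexp(logp[keep]) - logsumexp(logp)))
    return min(p, 1.0)


def noiseq_like_probability(
    rpkm: RpkmMatrix,
    groups: pd.Series | np.ndarray,
    pseudo_count: float = 0.5,
) -> pd.Series:
    """Nonparametric signal-vs-noise DE probability per gene.

    Signal: M_g = log2((m1 + k)/(m2 + k)), D_g = |m1 - m2| on replicate-mean
    RPKM.  Noise: the same statistics between every within-condition
    replicate pair, pooled over all genes.  q_g is the fraction of noise
    points with |M*| < |M_g| and D* < D_g (strict on both).
    """
    groups = pd.Series(np.asarray(groups), index=rpkm.sample_ids)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValidationError("exactly two conditions are required")
    k = float(pseudo_count)
    x = rpkm.values.to_numpy(dtype=float)
    cols1 = np.flatnonzero((groups == levels[0]).to_numpy())
    cols2 = np.flatnonzero((groups == levels[1]).to_numpy())
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValidationError(
            "noiseq_like needs >= 2 replicates per condition to build the noise pool"
        )
    m1 = x[:, cols1].mean(axis=1)
    m2 = x[:, cols2].mean(axis=1)
    M = np.log2((m1 + k) / (m2 + k))
    D = np.abs(m1 - m2)

    noise_M, noise_D = [], []
    for cols in (cols1, cols2):
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                xa, xb = x[:, cols[i]], x[:, cols[j]]
                noise_M.append(np.log2((xa + k) / (xb + k)))
                noise_D.append(np.abs(xa - xb))
    abs_Mstar = np.abs(np.concatenate(noise_M))
    Dstar = np.concatenate(noise_D)

    q = np.empty(len(M))
    abs_M = np.abs(M)
    chunk = 512
    for start in range(0, len(M), chunk):
        stop = min(start + chunk, len(M))
        dominated = (abs_Mstar[None, :] < abs_M[start:stop, None]) & (
            Dstar[None, :] < D[start:stop, None]
        )
        q[start:stop] = dominated.mean(axis=1)
    return pd.Series(q, index=rpkm.gene_ids, name="q_g")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving, q >= p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
# Model / Results


class DifferentialExpression:
    """Two-condition DE model for one extraction of a count matrix.

    Parameters
    ----------
    counts : CountMatrix
        Counts with metadata; only samples of ``extraction`` are used.
    extraction : str
        Extraction (tissue or "composite") to test within.
    conditions : tuple of str, optional
        The two condition labels to contrast, in (condition1, condition2)
        order; defaults to the sorted labels present.
    config : DEConfig, optional
        Method and thresholds.
    """

    def __init__(
        self,
        counts: CountMatrix,
        extraction: str,
        conditions: tuple | None = None,
        config: DEConfig | None = None,
    ) -> None:
        self.config = config or DEConfig()
        self.extraction = extraction
        sub = counts.select_samples(extraction=extraction)
        labels = sub.metadata["condition"]
        if conditions is None:
            conditions = tuple(sorted(labels.unique()))
        if len(conditions) != 2:
            raise ValidationError(f"need exactly two conditions, got {conditions}")
        keep = labels.isin(conditions)
        if labels[keep].nunique() != 2:
            missing = set(conditions) - set(labels.unique())
            raise ValidationError(f"condition(s) {sorted(missing)} absent from {extraction!r}")
        self.data = CountMatrix(
            sub.counts.loc[:, keep[keep].index], sub.metadata.loc[keep[keep].index],
            sub.gene_lengths, sub.truth,
        )
        self.conditions = conditions
        self.groups = self.data.metadata["condition"]

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, metadata: pd.DataFrame, gene_lengths: pd.Series,
        extraction: str, **kwargs,
    ) -> "DifferentialExpression":
        return cls(CountMatrix(counts, metadata, gene_lengths), extraction, **kwargs)

    def fit(self) -> "DEResults":
        """Run the configured test and return per-gene results."""
        cfg = self.config
        rpkm = compute_rpkm(self.data)
        m1 = rpkm.group_means(self.extraction, self.conditions[0])
        m2 = rpkm.group_means(self.extraction, self.conditions[1])
        k = cfg.pseudo_count
        M = np.log2((m1.to_numpy() + k) / (m2.to_numpy() + k))
        D = np.abs(m1.to_numpy() - m2.to_numpy())

        table = pd.DataFrame(
            {"mean1": m1, "mean2": m2, "M": M, "D": D}, index=self.data.gene_ids
        )
        dispersion = None
        if cfg.method == "nb_exact":
            if cfg.dispersion is not None:
                dispersion = DispersionEstimate(
                    cfg.dispersion,
                    tuple(int((self.groups == c).sum()) for c in self.conditions),
                )
            else:
                dispersion = estimate_common_dispersion(
                    self.data, self.groups, floor=cfg.dispersion_floor
                )
            cols1 = self.groups.index[self.groups == self.conditions[0]]
            cols2 = self.groups.index[self.groups == self.conditions[1]]
            sizes = self.data.library_sizes()
            c1 = self.data.counts[cols1].to_numpy()
            c2 = self.data.counts[cols2].to_numpy()
            s1 = sizes[cols1].to_numpy(dtype=float)
            s2 = sizes[cols2].to_numpy(dtype=float)
            pvals = np.array(
                [
                    nb_exact_test(c1[i], c2[i], s1, s2, dispersion.phi)
                    for i in range(len(table))
                ]
            )
            table["p_or_q"] = pvals
            table["q_adj"] = bh_adjust(pvals)
        else:
            q = noiseq_like_probability(rpkm, self.groups, pseudo_count=k)
            table["p_or_q"] = q.to_numpy()
            table["q_adj"] = np.nan
        results = DEResults(self, table, dispersion)
        return call_de(results, cfg)


@dataclass
class DEResults:
    """Per-gene DE statistics, calls and directions for one contrast.

    ``table`` columns: mean1, mean2 (replicate-mean RPKM per condition),
    M (log2 fold change, condition1 over condition2, pseudo-counted),
    D (absolute RPKM difference), p_or_q (exact-test p-value or
    nonparametric probability), q_adj (BH-adjusted q, nb_exact only),
    call in {not_DE, DE}, direction in {up_in_condition1, up_in_condition2,
    none}.
    """

    model: DifferentialExpression
    table: pd.DataFrame
    dispersion: DispersionEstimate | None = None
    _called: bool = field(default=False, repr=False)

    @property
    def method(self) -> str:
        return self.model.config.method

    @property
    def de_genes(self) -> pd.Index:
        return self.table.index[self.table["call"] == "DE"]

    def direction_of(self, gene_id) -> str:
        return self.table.at[gene_id, "direction"]

    def summary(self) -> str:
        cfg = self.model.config
        n_de = int((self.table["call"] == "DE").sum())
        up1 = int((self.table["direction"] == "up_in_condition1").sum())
        up2 = int((self.table["direction"] == "up_in_condition2").sum())
        lines = [
            "Differential expression summary",
            "=" * 48,
            f"extraction:      {self.model.extraction}",
            f"contrast:        {self.model.conditions[0]} vs {self.model.conditions[1]}",
            f"method:          {cfg.method}",
            f"genes tested:    {len(self.table)}",
            f"DE calls:        {n_de}  (up in {self.model.conditions[0]}: {up1}, "
            f"up in {self.model.conditions[1]}: {up2})",
        ]
        if cfg.method == "nb_exact":
            lines.append(f"FDR threshold:   q <= {cfg.alpha}")
            if self.dispersion is not None:
                lines.append(f"common phi:      {self.dispersion.phi:.4g}")
        else:
            lines.append(f"probability cut: q_g > {cfg.q_cut}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cfg = self.model.config
        with open(path, "w") as fh:
            phi = self.dispersion.phi if self.dispersion is not None else "NA"
            fh.write(
                f"# method={cfg.method} alpha={cfg.alpha} q_cut={cfg.q_cut} phi={phi} "
                f"extraction={self.model.extraction}\n"
            )
            out = self.table.copy()
            out.insert(0, "gene_id", out.index)
            out.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def call_de(results: DEResults, config: DEConfig) -> DEResults:
    """Attach DE calls and directions to a result table.

    nb_exact calls DE when the BH-adjusted q <= alpha (inclusive);
    noiseq_like when q_g > q_cut (strict).  Direction follows the sign of M;
    a DE call with M = 0 cannot occur (the exact test's mode has p = 1 and a
    zero-signal gene has q_g = 0).
    """
    table = results.table
    if config.method == "nb_exact":
        de = table["q_adj"] <= config.alpha
    else:
        de = table["p_or_q"] > config.q_cut
    de &= table["M"] != 0.0
    direction = np.where(
        ~de, "none", np.where(table["M"] > 0, "up_in_condition1", "up_in_condition2")
    )
    table["call"] = np.where(de, "DE", "not_DE")
    table["direction"] = direction
    results._called = True
    return results
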