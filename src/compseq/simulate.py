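"""Generative tissue-mixture model for composite-extraction RNA-seq.

The model formalizes why sequencing a composite anatomical structure (an
insect abdomen, say) dilutes and can invert the differential-expression
signal of an organ nested inside it.  Each tissue t contributes a fraction
w_t of the composite's RNA mass; the expected relative transcript abundance
of gene g in tissue t under condition c is lambda[g, t, c].  A
tissue-specific extraction sequences lambda[., t, c] directly; a composite
extraction sequences the mass-weighted mixture sum_t w'_t * lambda[., t, c],
where the realized fractions w' deviate from w when homogenization is
incomplete (the ground powder has finitely many grains, so small organs are
stochastically over- or under-represented in the aliquot actually extracted).

Read counts are drawn per gene from a negative binomial around
depth * share.  Within one tissue a gene's share of the sequenced mass is
proportional to abundance times transcript length (longer transcripts
attract more reads at equal molarity, matching the RPKM convention
downstream); the composite mixes the per-tissue mass-normalized profiles
with the weights w', so each tissue contributes exactly its RNA mass
fraction to the library whatever its absolute abundance scale.

A gene exclusive to a tissue of mass fraction w has expected composite RPKM
equal to w times its focal RPKM, i.e. an expected focal/composite dilution
ratio of 1/w — the quantity the downstream concordance analysis measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countdata import CountMatrix, ValidationError
from ._seeds import derived_rng

__all__ = [
    "EffectConfig",
    "HomogenizationSpec",
    "TissueMixtureModel",
    "build_mixture_model",
    "sample_homogenization_fractions",
    "simulate_extraction_counts",
    "simulate_experiment",
]

CONDITIONS = ("condition1", "condition2")

#: Three-tissue demo defaults: a small specialized gland, a large organ, and
#: the remainder of the composite structure.  Mass fractions are illustrative
#: (relative RNA yields of real dissected organs are rarely published).
DEFAULT_TISSUES = (("gland", 0.02, 0.05), ("gut", 0.30, 0.05), ("remainder", 0.68, 0.05))


@dataclass(frozen=True)
class EffectConfig:
    """Gene-effect layout of a simulated experiment.

    Parameters
    ----------
    n_genes : int
        Number of genes in the annotation.
    de_fraction : float
        Fraction of genes differentially expressed per tissue.
    log2fc_loc, log2fc_scale : float
        Normal location/scale of the DE genes' |log2 fold change|.
    exclusive_fraction : float
        Fraction of a tissue's DE genes expressed in that tissue only
        (abundance ~0 elsewhere) — the specialized-gene class.
    opposite_fraction : float
        Fraction of a tissue's DE genes that carry the opposite-direction
        effect in a second tissue — the contrasting-signal class.
    baseline_meanlog, baseline_sdlog : float
        Log-normal parameters of baseline abundance (natural-log scale).
    min_length, max_length : int
        Transcript lengths are drawn uniformly on this range (bp).
    """

    n_genes: int = 10_000
    de_fraction: float = 0.05
    log2fc_loc: float = 2.0
    log2fc_scale: float = 0.5
    exclusive_fraction: float = 0.3
    opposite_fraction: float = 0.05
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 1.2
    min_length: int = 500
    max_length: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        for name in ("de_fraction", "exclusive_fraction", "opposite_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.exclusive_fraction + self.opposite_fraction > 1.0:
            raise ValidationError("DE subtype fractions must sum to <= 1")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValidationError("invalid transcript length range")


@dataclass(frozen=True)
class HomogenizationSpec:
    """Grain model of incomplete homogenization.

    The ground composite sample is treated as ``grain_count`` equally sized
    grains, each belonging to tissue t with probability w_t; the realized
    fraction of tissue t in an extraction aliquot is its grain share.
    ``grain_count="infinite"`` recovers perfect homogenization (w' = w).
    """

    grain_count: int | str = "infinite"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.grain_count != "infinite":
            if int(self.grain_count) < 1:
                raise ValidationError("grain_count must be >= 1 or 'infinite'")
            object.__setattr__(self, "grain_count", int(self.grain_count))


@dataclass
class TissueMixtureModel:
    """Ground truth of a simulated tissue-mixture experiment.

    Attributes
    ----------
    gene_ids : list of str
    gene_lengths : ndarray, shape (G,)
        Transcript lengths in bp.
    tissues : list of str
    mass_fractions : ndarray, shape (T,)
        RNA mass fraction of each tissue in the composite; sums to 1.
    abundance : ndarray, shape (G, T, 2)
        Expected relative transcript abundance per gene, tissue, condition.
    dispersion : ndarray, shape (T,)
        Negative-binomial dispersion phi per tissue (variance = mu + phi mu^2).
    truth_labels : pandas.DataFrame
        Columns gene_id, tissue, label, log2fc; one row per (gene, tissue)
        with label in {not_DE, up_in_condition1, up_in_condition2}.
    """

    gene_ids: list
    gene_lengths: np.ndarray
    tissues: list
    mass_fractions: np.ndarray
    abundance: np.ndarray
    dispersion: np.ndarray
    truth_labels: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        self.mass_fractions = np.asarray(self.mass_fractions, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        if (self.mass_fractions < 0).any() or abs(self.mass_fractions.sum() - 1.0) > 1e-9:
            raise ValidationError("mass fractions must be >= 0 and sum to 1")
        if (self.abundance < 0).any():
            raise ValidationError("abundances must be >= 0")
        if (self.abundance.max(axis=(1, 2)) <= 0).any():
            raise ValidationError("every gene needs positive abundance somewhere")
        if (self.gene_lengths < 1).any():
            raise ValidationError("gene lengths must be >= 1")
        if (self.dispersion < 0).any():
            raise ValidationError("dispersions must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def tissue_index(self, tissue: str) -> int:
        try:
            return self.tissues.index(tissue)
        except ValueError:
            raise ValidationError(
                f"unknown extraction {tissue!r}; expected one of "
                f"{self.tissues + ['composite']}"
            ) from None

    def read_shares(self, extraction: str, condition: str, weights=None) -> np.ndarray:
        """Expected per-gene read share of one extraction's library.

        A tissue's library share of gene g is lambda[g, t, c] * L_g
        normalized over genes (mass share of the tissue's RNA).  The
        composite mixes the *normalized* per-tissue mass shares with the RNA
        mass fractions, so each tissue contributes exactly its fraction of
        the sequenced mass regardless of its absolute abundance scale.
        """
        c = CONDITIONS.index(condition)
        mass = self.abundance[:, :, c] * self.gene_lengths[:, None]
        totals = mass.sum(axis=0)
        if extraction == "composite":
            w = self.mass_fractions if weights is None else np.asarray(weights, float)
            with np.errstate(invalid="ignore", divide="ignore"):
                per_tissue = np.where(totals > 0, mass / totals, 0.0)
            share = per_tissue @ w
            live = w[totals > 0].sum()
            if live <= 0:
                raise ValidationError("composite mixture has no expressed tissue")
            return share / live
        t = self.tissue_index(extraction)
        if totals[t] <= 0:
            raise ValidationError(
                f"no expressed genes in extraction={extraction!r}, condition={condition!r}"
            )
        return mass[:, t] / totals[t]

    def expected_rpkm(self, extraction: str, condition: str) -> np.ndarray:
        """Analytic expected RPKM per gene under perfect homogenization."""
        return 1e9 * self.read_shares(extraction, condition) / self.gene_lengths

    def simulate_extraction(self, *args, **kwargs) -> CountMatrix:
        """Alias for :func:`simulate_extraction_counts` on this model."""
        return simulate_extraction_counts(self, *args, **kwargs)


def build_mixture_model(
    effect_config: EffectConfig,
    tissue_spec=DEFAULT_TISSUES,
) -> TissueMixtureModel:
    """Draw a ground-truth mixture model from an effect configuration.

    ``tissue_spec`` is a sequence of (name, mass_fraction, dispersion)
    triples whose mass fractions sum to 1.  Deterministic given
    ``effect_config.seed``.
    """
    tissues = [t[0] for t in tissue_spec]
    w = np.array([t[1] for t in tissue_spec], dtype=float)
    phi = np.array([t[2] for t in tissue_spec], dtype=float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("tissue mass fractions must be >= 0 and sum to 1")
    cfg = effect_config
    G, T = cfg.n_genes, len(tissues)
    rng = derived_rng(cfg.seed, "build_mixture_model")

    gene_ids = [f"g{i:05d}" for i in range(G)]
    lengths = rng.integers(cfg.min_length, cfg.max_length + 1, size=G).astype(float)

    # Baseline abundance: shared lognormal gene-level expression, modulated by
    # an independent lognormal tissue factor so tissues differ but overlap.
    base = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, size=G)
    tissue_factor = rng.lognormal(0.0, 0.5, size=(G, T))
    lam = np.repeat(base[:, None, None], T, axis=1).repeat(2, axis=2)
    lam *= tissue_factor[:, :, None]

    labels = np.full((G, T), "not_DE", dtype=object)
    log2fc = np.zeros((G, T))
    n_de = int(round(cfg.de_fraction * G))
    if n_de * T > G:
        raise ValidationError("de_fraction too high for disjoint per-tissue DE sets")
    claimed: set = set()
    for t in range(T):
        free = np.array(sorted(set(range(G)) - claimed))
        de_genes = rng.choice(free, size=n_de, replace=False)
        claimed.update(int(g) for g in de_genes)
        effects = rng.normal(cfg.log2fc_loc, cfg.log2fc_scale, size=n_de)
        effects = np.abs(effects) * rng.choice([-1.0, 1.0], size=n_de)
        subtype = rng.random(n_de)
        for g, eff, u in zip(de_genes, effects, subtype):
            if eff == 0.0:  # pathological draw; treat as not DE
                continue
            lam[g, t, 0] *= 2.0 ** (eff / 2.0)
            lam[g, t, 1] *= 2.0 ** (-eff / 2.0)
            labels[g, t] = "up_in_condition1" if eff > 0 else "up_in_condition2"
            log2fc[g, t] = eff
            if u < cfg.exclusive_fraction:
                # tissue-exclusive specialist: silent everywhere else
                for s in range(T):
                    if s != t:
                        lam[g, s, :] = 0.0
                        labels[g, s] = "not_DE"
                        log2fc[g, s] = 0.0
            elif u < cfg.exclusive_fraction + cfg.opposite_fraction and T > 1:
                # contrasting signal in one other tissue
                other = int(rng.choice([s for s in range(T) if s != t]))
                lam[g, other, 0] *= 2.0 ** (-eff / 2.0)
                lam[g, other, 1] *= 2.0 ** (eff / 2.0)
                labels[g, other] = "up_in_condition2" if eff > 0 else "up_in_condition1"
                log2fc[g, other] = -eff

    truth = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, T),
            "tissue": tissues * G,
            "label": labels.ravel(),
            "log2fc": log2fc.ravel(),
        }
    )
    return TissueMixtureModel(gene_ids, lengths, tissues, w, lam, phi, truth)


def sample_homogenization_fractions(
    spec: HomogenizationSpec,
    mass_fractions: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Realized per-tissue fractions of one extraction aliquot.

    Draws ``grain_count`` grains multinomially with probabilities equal to
    the nominal mass fractions and returns grain shares; the infinite-grain
    limit returns the nominal fractions unchanged.
    """
    w = np.asarray(mass_fractions, dtype=float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("mass fractions must be >= 0 and sum to 1")
    if spec.grain_count == "infinite":
        return w.copy()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    grains = rng.multinomial(spec.grain_count, w)
    return grains / spec.grain_count


def simulate_extraction_counts(
    model: TissueMixtureModel,
    extraction: str,
    condition: str,
    n_replicates: int = 2,
    depth: int = 12_000_000,
    homogenization: HomogenizationSpec | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Simulate a count matrix for one extraction under one condition.

    For a tissue-specific extraction the expected read share of gene g is
    proportional to lambda[g, t, c] * L_g.  For ``extraction="composite"``
    each replicate first draws realized tissue fractions w' from the
    homogenization model, then mixes the per-tissue mass-normalized profiles
    with those weights (see :meth:`TissueMixtureModel.read_shares`).
    Counts are negative binomial with mean depth * share and the tissue's
    dispersion (composite: mass-weighted mean dispersion).  Per-sample random
    streams are keyed by (extraction, condition, replicate) under the master
    seed.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if condition not in CONDITIONS:
        raise ValidationError(f"condition must be one of {CONDITIONS}")
    if homogenization is None:
        homogenization = HomogenizationSpec()

    if extraction == "composite":
        phi = float(model.dispersion @ model.mass_fractions)
    else:
        t = model.tissue_index(extraction)
        phi = float(model.dispersion[t])

    cols = {}
    meta_rows = []
    for rep in range(1, n_replicates + 1):
        rng = derived_rng(seed, extraction, condition, rep)
        if extraction == "composite":
            w_real = sample_homogenization_fractions(homogenization, model.mass_fractions, rng)
            share = model.read_shares("composite", condition, weights=w_real)
        else:
            share = model.read_shares(extraction, condition)
        mu = depth * share
        if phi < 1e-8:
            counts = rng.poisson(mu)
        else:
            size = 1.0 / phi
            counts = np.where(
                mu > 0, rng.negative_binomial(size, size / (size + np.maximum(mu, 1e-300))), 0
            )
        sample_id = f"{extraction}_{condition}_rep{rep}"
        cols[sample_id] = counts.astype(np.int64)
        meta_rows.append((sample_id, extraction, condition, rep))

    counts_df = pd.DataFrame(cols, index=model.gene_ids)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "extraction", "condition", "replicate"]
    ).set_index("sample_id")
    lengths = pd.Series(model.gene_lengths, index=model.gene_ids)
    return CountMatrix(counts_df, meta, lengths, model.truth_labels)


def simulate_experiment(
    model: TissueMixtureModel,
    extractions=None,
    conditions=CONDITIONS,
    n_replicates: int = 2,
    depth: int = 12_000_000,
    homogenization: HomogenizationSpec | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Simulate every (extraction, condition) and merge into one CountMatrix.

    ``extractions`` defaults to all tissues plus the composite.
    """
    if extractions is None:
        extractions = list(model.tissues) + ["composite"]
    pieces = [
        simulate_extraction_counts(
            model, ext, cond, n_replicates, depth, homogenization, seed
        )
        for ext in extractions
        for cond in conditions
    ]
    counts = pd.concat([p.counts for p in pieces], axis=1)
    meta = pd.concat([p.metadata for p in pieces], axis=0)
    lengths = pd.Series(model.gene_lengths, index=model.gene_ids)
    return CountMatrix(counts, meta, lengths, model.truth_labels)
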