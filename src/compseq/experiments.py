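"""Canned simulation studies of the composite-extraction phenomena.

Each function sets up a seeded mixture model, runs the pipeline's own
operations, and returns the headline quantity: how strongly a small organ's
signal is diluted (focal/composite RPKM ratio near 1/w), how many
focal-tissue DE genes turn into composite false negatives as the organ's
mass fraction shrinks, whether an opposite-direction gene is called along
the mass-weighted net effect, and the exact test's false-discovery
behaviour on null data.  The published honey-bee sting-gland / digestive-
tract contingency tables are also provided as constants so the Fisher
comparisons can be reproduced from the printed counts alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .concord import (
    ConcordanceTable,
    DilutionRatioSet,
    classify_cross_extraction,
    dilution_ratios,
)
from .countdata import CountMatrix
from .detest import DEConfig, DifferentialExpression, nb_exact_test
from .quantify import compute_rpkm
from .simulate import TissueMixtureModel, simulate_extraction_counts, simulate_experiment
from ._seeds import derived_rng

__all__ = [
    "STING_GLAND_CONCORDANCE",
    "DIGESTIVE_TRACT_CONCORDANCE",
    "STING_GLAND_DILUTION",
    "DIGESTIVE_TRACT_DILUTION",
    "two_tissue_model",
    "dilution_ratio_study",
    "false_negative_study",
    "opposite_direction_study",
    "null_fdp_study",
]

# Observed counts from the honey-bee study of nurse-vs-forager differential
# expression: of 932 sting-gland DE genes, 754 were not significant in the
# whole-abdomen extraction and 25 flipped direction; of 493 digestive-tract
# DE genes, 340 were not significant and 7 flipped.  642/932 sting-gland and
# 197/493 digestive-tract DE genes had focal/composite RPKM ratios above 1.
STING_GLAND_CONCORDANCE = ConcordanceTable.from_counts(
    "sting_gland", "abdomen", n_not_sig=754, n_same=153, n_opposite=25
)
DIGESTIVE_TRACT_CONCORDANCE = ConcordanceTable.from_counts(
    "digestive_tract", "abdomen", n_not_sig=340, n_same=146, n_opposite=7
)
STING_GLAND_DILUTION = DilutionRatioSet.from_counts(
    "sting_gland", "abdomen", n_above_1=642, n_at_or_below_1=290
)
DIGESTIVE_TRACT_DILUTION = DilutionRatioSet.from_counts(
    "digestive_tract", "abdomen", n_above_1=197, n_at_or_below_1=296
)


def two_tissue_model(
    focal_fraction: float,
    n_genes: int = 2000,
    n_exclusive_de: int = 50,
    log2fc: float = 2.0,
    baseline_meanlog: float = 2.5,
    baseline_sdlog: float = 1.0,
    phi: float = 0.05,
    seed: int = 0,
) -> TissueMixtureModel:
    """Focal tissue of mass fraction w plus a remainder, with
    ``n_exclusive_de`` focal-exclusive DE genes at |log2FC| = ``log2fc``
    (alternating direction) on a shared log-normal background."""
    rng = derived_rng(seed, "two_tissue_model", focal_fraction)
    lam = np.zeros((n_genes, 2, 2))
    base_f = rng.lognormal(baseline_meanlog, baseline_sdlog, size=n_genes)
    base_r = rng.lognormal(baseline_meanlog, baseline_sdlog, size=n_genes)
    lam[:, 0, :] = base_f[:, None]
    lam[:, 1, :] = base_r[:, None]
    de = rng.choice(n_genes, size=n_exclusive_de, replace=False)
    signs = np.where(np.arange(n_exclusive_de) % 2 == 0, 1.0, -1.0)
    lam[de, 1, :] = 0.0
    lam[de, 0, 0] = base_f[de] * 2.0 ** (signs * log2fc / 2.0)
    lam[de, 0, 1] = base_f[de] * 2.0 ** (-signs * log2fc / 2.0)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    labels = np.full((n_genes, 2), "not_DE", dtype=object)
    fc = np.zeros((n_genes, 2))
    labels[de, 0] = np.where(signs > 0, "up_in_condition1", "up_in_condition2")
    fc[de, 0] = signs * log2fc
    truth = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, 2),
            "tissue": ["focal", "remainder"] * n_genes,
            "label": labels.ravel(),
            "log2fc": fc.ravel(),
        }
    )
    return TissueMixtureModel(
        gene_ids,
        np.full(n_genes, 1000.0),
        ["focal", "remainder"],
        np.array([focal_fraction, 1.0 - focal_fraction]),
        lam,
        np.array([phi, phi]),
        truth,
    )


def dilution_ratio_study(
    focal_fraction: float = 0.02,
    n_seeds: int = 500,
    n_genes: int = 200,
    depth: int = 500_000,
    phi: float = 0.005,
    seed: int = 0,
) -> float:
    """Mean focal/composite RPKM ratio of one tissue-exclusive gene.

    Deep sequencing and low dispersion keep the per-seed ratio close to its
    analytic expectation 1/w, so the returned mean approaches 1/w (50 at the
    default w = 0.02).
    """
    lam = np.full((n_genes, 2, 2), 10.0)
    lam[0, 0, :] = 40.0
    lam[0, 1, :] = 0.0
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    truth = pd.DataFrame(
        {"gene_id": gene_ids[:1], "tissue": ["focal"], "label": ["not_DE"], "log2fc": [0.0]}
    )
    model = TissueMixtureModel(
        gene_ids, np.full(n_genes, 1000.0), ["focal", "remainder"],
        np.array([focal_fraction, 1.0 - focal_fraction]), lam,
        np.array([phi, phi]), truth,
    )
    ratios = np.empty(n_seeds)
    for i in range(n_seeds):
        sub_seed = int(derived_rng(seed, "dilution_study", i).integers(2**31))
        f = simulate_extraction_counts(model, "focal", "condition1", 2, depth, seed=sub_seed)
        c = simulate_extraction_counts(
            model, "composite", "condition1", 2, depth, seed=sub_seed
        )
        merged = CountMatrix(
            pd.concat([f.counts, c.counts], axis=1),
            pd.concat([f.metadata, c.metadata]),
            f.gene_lengths,
        )
        d = dilution_ratios(
            compute_rpkm(merged), "focal", "composite", "condition1", [gene_ids[0]]
        )
        ratios[i] = d.ratios.iloc[0]
    return float(ratios.mean())


def false_negative_study(
    focal_fractions=(0.5, 0.1, 0.02),
    n_genes: int = 2000,
    n_exclusive_de: int = 50,
    log2fc: float = 2.0,
    depth: int = 2_000_000,
    n_replicates: int = 2,
    method: str = "noiseq_like",
    seed: int = 0,
) -> dict:
    """Composite false-negative fraction at each focal mass fraction.

    For each w, simulates focal and composite extractions, calls DE in both,
    classifies the focal-DE genes across extractions, and returns
    {w: ConcordanceTable}.  The not-significant share grows as w shrinks.
    """
    out = {}
    cfg = DEConfig(method=method)
    for w in focal_fractions:
        model = two_tissue_model(
            w, n_genes=n_genes, n_exclusive_de=n_exclusive_de, log2fc=log2fc, seed=seed
        )
        cm = simulate_experiment(
            model, extractions=["focal", "composite"], n_replicates=n_replicates,
            depth=depth, seed=seed,
        )
        focal = DifferentialExpression(cm, "focal", config=cfg).fit()
        comp = DifferentialExpression(cm, "composite", config=cfg).fit()
        out[w] = classify_cross_extraction(focal, comp)
    return out


def opposite_direction_study(
    focal_fraction: float = 0.1,
    n_genes: int = 300,
    depth: int = 1_000_000,
    seed: int = 0,
) -> dict:
    """One gene up-regulated in a small tissue and down-regulated in the large
    remainder: returns the focal and composite calls for that gene.

    The composite direction should follow the mass-weighted net effect, i.e.
    the larger tissue's direction.
    """
    lam = np.full((n_genes, 2, 2), 20.0)
    lam[0, 0, 0], lam[0, 0, 1] = 80.0, 20.0     # focal: up in condition1
    lam[0, 1, 0], lam[0, 1, 1] = 20.0, 80.0     # remainder: down in condition1
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    truth = pd.DataFrame(
        {
            "gene_id": [gene_ids[0]] * 2,
            "tissue": ["focal", "remainder"],
            "label": ["up_in_condition1", "up_in_condition2"],
            "log2fc": [2.0, -2.0],
        }
    )
    model = TissueMixtureModel(
        gene_ids, np.full(n_genes, 1000.0), ["focal", "remainder"],
        np.array([focal_fraction, 1.0 - focal_fraction]), lam,
        np.array([0.02, 0.02]), truth,
    )
    cm = simulate_experiment(
        model, extractions=["focal", "composite"], n_replicates=3, depth=depth, seed=seed
    )
    cfg = DEConfig(method="noiseq_like")
    focal = DifferentialExpression(cm, "focal", config=cfg).fit()
    comp = DifferentialExpression(cm, "composite", config=cfg).fit()
    tab = classify_cross_extraction(focal, comp)
    g = gene_ids[0]
    return {
        "gene": g,
        "focal_direction": focal.direction_of(g),
        "composite_call": comp.table.at[g, "call"],
        "composite_direction": comp.direction_of(g),
        "category": tab.categories.get(g),
    }


def null_fdp_study(
    n_genes: int = 2000,
    n_seeds: int = 20,
    n_replicates: int = 2,
    depth: int = 100_000,
    phi: float = 0.05,
    seed: int = 0,
) -> float:
    """Mean fraction of null genes with exact-test p <= 0.05.

    Counts are negative binomial with no condition effect and the true phi is
    supplied to the test, so the returned fraction measures the test's
    type-I/FDP behaviour (the conditional exact test is slightly
    conservative: expect a value at or below 0.05).
    """
    fractions = []
    for i in range(n_seeds):
        rng = derived_rng(seed, "null_fdp", i)
        mu = rng.lognormal(3.5, 1.0, size=n_genes)
        mu = depth * mu / mu.sum()
        size = 1.0 / phi
        counts = rng.negative_binomial(
            size, size / (size + mu[:, None]), size=(n_genes, 2 * n_replicates)
        )
        libs = counts.sum(axis=0).astype(float)
        pvals = np.array(
            [
                nb_exact_test(
                    counts[g, :n_replicates], counts[g, n_replicates:],
                    libs[:n_replicates], libs[n_replicates:], phi,
                )
                for g in range(n_genes)
            ]
        )
        fractions.append(float((pvals <= 0.05).mean()))
    return float(np.mean(fractions))
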