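import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from compseq import (
    CountMatrix,
    EffectConfig,
    TissueMixtureModel,
    build_mixture_model,
    simulate_experiment,
)


def make_model(abundance, tissues=("gland", "rest"), w=(0.02, 0.98), phi=(0.05, 0.05),
               lengths=None):
    """Hand-built mixture model from an explicit (G, T, 2) abundance array."""
    abundance = np.asarray(abundance, dtype=float)
    G, T, _ = abundance.shape
    gene_ids = [f"g{i:03d}" for i in range(G)]
    if lengths is None:
        lengths = np.full(G, 1000.0)
    rows = []
    for i, gid in enumerate(gene_ids):
        for t, tis in enumerate(tissues):
            lam1, lam2 = abundance[i, t]
            if lam1 > lam2:
                label, fc = "up_in_condition1", np.log2((lam1 + 1e-12) / (lam2 + 1e-12))
            elif lam2 > lam1:
                label, fc = "up_in_condition2", -np.log2((lam2 + 1e-12) / (lam1 + 1e-12))
            else:
                label, fc = "not_DE", 0.0
            rows.append((gid, tis, label, fc))
    truth = pd.DataFrame(rows, columns=["gene_id", "tissue", "label", "log2fc"])
    return TissueMixtureModel(
        gene_ids, lengths, list(tissues), np.asarray(w, float), abundance,
        np.asarray(phi, float), truth,
    )


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """4 genes x 4 samples, two extractions x two conditions, no replication."""
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 5, 85],
            "s2": [20, 0, 10, 70],
            "s3": [1, 1, 1, 97],
            "s4": [2, 2, 2, 94],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    meta = pd.DataFrame(
        {
            "extraction": ["gland", "gland", "composite", "composite"],
            "condition": ["condition1", "condition2", "condition1", "condition2"],
            "replicate": [1, 1, 1, 1],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    lengths = pd.Series([1000.0, 2000.0, 500.0, 1000.0], index=counts.index)
    return CountMatrix(counts, meta, lengths)


@pytest.fixture(scope="session")
def demo_experiment():
    """Moderate seeded three-tissue experiment used by several test modules."""
    eff = EffectConfig(n_genes=1500, de_fraction=0.05, seed=11)
    model = build_mixture_model(eff)
    cm = simulate_experiment(
        model, extractions=["gland", "gut", "composite"], n_replicates=2,
        depth=1_000_000, seed=11,
    )
    return model, cm
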