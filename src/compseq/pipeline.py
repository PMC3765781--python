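"""End-to-end orchestration: simulate an experiment, then run the full
composite-extraction analysis (depth equalization -> RPKM -> transcriptome
membership -> differential expression -> concordance / presence-absence /
dilution -> Fisher comparisons), writing per-analysis TSVs, a JSON summary
and a provenance manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .countdata import CountMatrix, ValidationError
from .quantify import compute_rpkm, downsample_counts, transcriptome_membership
from .simulate import (
    DEFAULT_TISSUES,
    EffectConfig,
    HomogenizationSpec,
    build_mixture_model,
    simulate_extraction_counts,
)
from .detest import DEConfig, DifferentialExpression
from .concord import (
    DEFAULT_BIN_EDGES,
    classify_cross_extraction,
    compare_focal_tissues,
    dilution_ratios,
    presence_absence_table,
    subset_analysis,
)

__all__ = ["PipelineConfig", "run_simulate", "run_full_analysis"]

logger = logging.getLogger("compseq")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; loadable from a YAML file.

    Either point ``counts`` / ``metadata`` / ``lengths`` at existing TSVs, or
    leave them unset and provide ``simulation`` parameters to generate data.
    """

    # input files (analysis mode)
    counts: str | None = None
    metadata: str | None = None
    lengths: str | None = None
    truth: str | None = None
    gene_list: str | None = None
    # simulation parameters (simulate mode)
    effect: dict = field(default_factory=dict)
    tissues: list = field(default_factory=lambda: [list(t) for t in DEFAULT_TISSUES])
    grain_count: int | str = "infinite"
    n_replicates: int = 2
    depth: int = 12_000_000
    conditions: tuple = ("condition1", "condition2")
    # analysis parameters
    focal_extractions: list = field(default_factory=list)
    composite_extraction: str = "composite"
    membership_threshold: float = 10.0
    bin_edges: tuple = DEFAULT_BIN_EDGES
    target_depth: int | None = None
    methods: tuple = ("noiseq_like", "nb_exact")
    alpha: float = 0.05
    q_cut: float = 0.8
    pseudo_count: float = 0.5
    # bookkeeping
    outdir: str = "compseq_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["package"] = "compseq"
        return d


def _write_manifest(outdir: Path, config: PipelineConfig, extra: dict | None = None) -> None:
    manifest = config.to_manifest()
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_simulate(config: PipelineConfig) -> dict:
    """Generate a full simulated experiment and write its TSVs + manifest.

    Returns a dict of output paths.  Simulates every focal tissue plus the
    composite, for both conditions.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    effect = EffectConfig(**{**config.effect, "seed": config.seed})
    model = build_mixture_model(effect, [tuple(t) for t in config.tissues])
    hom = HomogenizationSpec(config.grain_count)

    extractions = [t[0] for t in config.tissues] + ["composite"]
    pieces = []
    for ext in extractions:
        for cond in config.conditions:
            pieces.append(
                simulate_extraction_counts(
                    model, ext, cond, config.n_replicates, config.depth, hom, config.seed
                )
            )
    counts = pd.concat([p.counts for p in pieces], axis=1)
    meta = pd.concat([p.metadata for p in pieces], axis=0)
    merged = CountMatrix(counts, meta, pieces[0].gene_lengths, model.truth_labels)

    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "samples.tsv",
        "lengths": outdir / "gene_lengths.tsv",
        "truth": outdir / "truth_labels.tsv",
    }
    merged.to_tsv(paths["counts"], paths["metadata"], paths["lengths"], paths["truth"])
    _write_manifest(outdir, config, {"stage": "simulate", "n_samples": len(meta)})
    logger.info("simulated %d samples x %d genes -> %s", len(meta), len(counts), outdir)
    return {k: str(v) for k, v in paths.items()}


def _load_counts(config: PipelineConfig) -> CountMatrix:
    if config.counts is None:
        raise ValidationError("config must provide counts/metadata/lengths paths")
    for name in ("counts", "metadata", "lengths"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise ValidationError(f"input file for {name!r} missing: {p}")
    return CountMatrix.from_tsv(config.counts, config.metadata, config.lengths, config.truth)


def run_full_analysis(config: PipelineConfig, counts: CountMatrix | None = None) -> dict:
    """Run the whole composite-extraction analysis and return the summary dict.

    Stages: optional depth equalization, RPKM, transcriptome membership,
    DE per method and extraction, cross-extraction concordance,
    presence/absence, dilution ratios, and Fisher comparisons between the
    focal tissues.  Writes per-analysis TSVs plus ``summary.json``; on
    failure a FAILED marker naming the stage is left in the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "load"
    try:
        if counts is None:
            counts = _load_counts(config)
        composite = config.composite_extraction
        extractions = set(counts.metadata["extraction"])
        focals = list(config.focal_extractions) or sorted(extractions - {composite})
        if composite not in extractions:
            raise ValidationError(
                f"composite extraction {composite!r} absent from metadata "
                f"(found {sorted(extractions)})"
            )
        if not focals:
            raise ValidationError("no focal extractions present besides the composite")
        conditions = tuple(config.conditions)

        stage = "downsample"
        if config.target_depth is not None:
            counts = downsample_counts(counts, config.target_depth, config.seed)

        stage = "rpkm"
        rpkm = compute_rpkm(counts)
        rpkm.to_tsv(outdir / "rpkm.tsv")

        stage = "membership"
        summary: dict = {"transcriptome_sizes": {}, "methods": {}}
        for ext in focals + [composite]:
            for cond in conditions:
                ts = transcriptome_membership(rpkm, ext, cond, config.membership_threshold)
                summary["transcriptome_sizes"][f"{ext}/{cond}"] = len(ts)
                ts.to_tsv(outdir / f"transcriptome_{ext}_{cond}.tsv")

        stage = "presence_absence"
        summary["presence_absence"] = {}
        for focal in focals:
            pa = presence_absence_table(
                rpkm, focal, composite, conditions[0], config.membership_threshold,
                config.bin_edges,
            )
            summary["presence_absence"][focal] = {
                "focal_only": len(pa.focal_only),
                "composite_only": len(pa.composite_only),
                "focal_only_bins": {str(k): int(v) for k, v in pa.bins_focal_only.items()},
                "composite_only_bins": {
                    str(k): int(v) for k, v in pa.bins_composite_only.items()
                },
            }

        gene_list = None
        if config.gene_list:
            gene_list = [
                line.strip()
                for line in Path(config.gene_list).read_text().splitlines()
                if line.strip() and not line.startswith("#")
            ]

        for method in config.methods:
            stage = f"detest[{method}]"
            cfg = DEConfig(
                method=method, alpha=config.alpha, q_cut=config.q_cut,
                pseudo_count=config.pseudo_count,
            )
            results = {}
            for ext in focals + [composite]:
                res = DifferentialExpression(counts, ext, conditions, cfg).fit()
                res.to_tsv(outdir / f"detest_{method}_{ext}.tsv")
                results[ext] = res
            msum: dict = {"n_de": {e: int(len(r.de_genes)) for e, r in results.items()}}

            stage = f"concordance[{method}]"
            tables = {}
            for focal in focals:
                tab = classify_cross_extraction(results[focal], results[composite])
                tab.to_frame().to_csv(
                    outdir / f"concordance_{method}_{focal}.tsv", sep="\t", index=False
                )
                tables[focal] = tab
                msum[f"concordance_{focal}"] = {
                    "n_focal_de": tab.n_focal_de,
                    "not_sig": tab.n_not_sig,
                    "same_direction": tab.n_same_direction,
                    "opposite_direction": tab.n_opposite_direction,
                    "proportions": tab.proportions(),
                }
                if gene_list:
                    sub = subset_analysis(results[focal], results[composite], gene_list)
                    msum[f"subset_{focal}"] = {
                        "n_focal_de": sub.n_focal_de,
                        "not_sig": sub.n_not_sig,
                        "same_direction": sub.n_same_direction,
                        "opposite_direction": sub.n_opposite_direction,
                        "unresolved": len(sub.unresolved),
                    }

            stage = f"dilution[{method}]"
            dil = {}
            for focal in focals:
                de_genes = list(results[focal].de_genes)
                if not de_genes:
                    logger.info("no %s DE genes in %s; dilution skipped", method, focal)
                    continue
                d = dilution_ratios(rpkm, focal, composite, conditions[0], de_genes)
                dil[focal] = d
                msum[f"dilution_{focal}"] = {
                    "n_above_1": d.n_above_1,
                    "n_at_or_below_1": d.n_at_or_below_1,
                    "n_undefined": d.n_undefined,
                    "proportions": d.proportions(),
                }

            stage = f"fisher[{method}]"
            if len(focals) >= 2:
                a, b = focals[0], focals[1]
                if tables[a].n_focal_de and tables[b].n_focal_de:
                    fr = compare_focal_tissues(tables[a], tables[b])
                    msum["fisher_concordance"] = {
                        "table": fr.table, "odds_ratio": fr.odds_ratio, "p": fr.p_value,
                    }
                else:
                    logger.info("empty concordance table; Fisher comparison skipped")
                if a in dil and b in dil and len(dil[a].ratios) and len(dil[b].ratios):
                    fr = compare_focal_tissues(dil[a], dil[b])
                    msum["fisher_dilution"] = {
                        "table": fr.table, "odds_ratio": fr.odds_ratio, "p": fr.p_value,
                    }
                else:
                    logger.info("empty dilution set; Fisher comparison skipped")
            summary["methods"][method] = msum

        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        _write_manifest(outdir, config, {"stage": "run_full_analysis"})
        return summary
    except Exception as exc:
        failed_marker.write_text(f"stage={stage}: {exc}\n")
        raise
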