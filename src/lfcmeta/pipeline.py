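"""End-to-end orchestration: simulate -> ingest -> effects -> pooling -> report.

Functions here tie the stages together exactly as the CLI exposes them and
write the tab-separated result tables plus a YAML sidecar recording the
configuration hash, so a run can be reproduced byte for byte from its
output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .effects import effects_table
from .genesets import (
    DEFAULT_UNIVERSE, GeneSetPair, OverlapResult, overlap_test, read_gene_list,
    write_overlap_report,
)
from .ingest import (
    DataError, ExpressionDataset, filter_datasets, read_expression_table,
    read_metadata_table, collapse_duplicate_genes, ensure_log2,
)
from .meta import (
    LFC_THRESHOLD, P_THRESHOLD, add_bh_fdr, forest_table, meta_analyze,
    meta_analyze_gene, significant_genes,
)
from .metareg import DEFAULT_REGION_MAP, RegressionResult, regress_gene_effects
from .synth import SyntheticConfig, generate_studies, write_bundle

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Configuration for the pooled analysis and its reports."""

    data_dir: str | None = None
    out_dir: str = "lfcmeta_out"
    min_fraction: float = 0.5
    p_threshold: float = P_THRESHOLD
    lfc_threshold: float = LFC_THRESHOLD
    universe_n: int = DEFAULT_UNIVERSE
    region_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_REGION_MAP))
    seed: int = 0
    use_t: bool = False
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_threshold < 0 or self.lfc_threshold < 0:
            raise ConfigError("thresholds must be non-negative")
        if not (0.0 < self.min_fraction <= 1.0):
            raise ConfigError("min_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_sidecar(config: PipelineConfig, out: Path) -> None:
    sidecar = {
        "lfcmeta_version": __version__,
        "config_sha256_16": config.digest(),
        "config": asdict(config),
    }
    (out / "run_info.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))


def load_bundle(data_dir: str | Path) -> list[ExpressionDataset]:
    """Read every cohort of a bundle directory written by ``run_simulate``
    (metadata.tsv plus per-study ``<geo_id>_expr.tsv`` / ``_labels.tsv``)."""
    data_dir = Path(data_dir)
    metas = read_metadata_table(data_dir / "metadata.tsv")
    datasets = []
    for meta in metas:
        ds = read_expression_table(
            data_dir / f"{meta.geo_id}_expr.tsv",
            data_dir / f"{meta.geo_id}_labels.tsv",
            meta,
        )
        datasets.append(collapse_duplicate_genes(ensure_log2(ds)))
    return datasets


def run_simulate(config: PipelineConfig, overwrite: bool = False) -> Path:
    """Generate a synthetic cohort bundle consumable by :func:`run_mega`."""
    sim = dict(config.simulate)
    sim.setdefault("seed", config.seed)
    if "true_lfc" in sim:
        sim["true_lfc"] = {str(k): float(v) for k, v in sim["true_lfc"].items()}
    syn = SyntheticConfig(**sim)
    datasets = generate_studies(syn)
    out = Path(config.out_dir)
    write_bundle(datasets, syn, out, overwrite=overwrite)
    _write_sidecar(config, out)
    logger.info("wrote %d synthetic studies to %s", len(datasets), out)
    return out


def run_mega(config: PipelineConfig) -> pd.DataFrame:
    """Filter cohorts, compute effects, pool per gene, filter significant.

    Writes ``effects.tsv``, ``meta_results.tsv`` (with an informational
    BH-FDR column) and ``significant_genes.tsv`` under the output
    directory; returns the full results table.
    """
    if not config.data_dir:
        raise ConfigError("data_dir is required for the pooled analysis")
    data_dir = Path(config.data_dir)
    if not data_dir.exists():
        raise DataError(f"data directory not found: {data_dir}")
    metas = read_metadata_table(data_dir / "metadata.tsv")
    qualifying = filter_datasets(metas)
    if len(qualifying) < 2:
        raise DataError(
            f"only {len(qualifying)} dataset(s) pass the selection filter; need >= 2"
        )
    keep_ids = {m.geo_id for m in qualifying}
    datasets = [ds for ds in load_bundle(data_dir) if ds.meta.geo_id in keep_ids]

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    effects = effects_table(datasets)
    effects.to_csv(out / "effects.tsv", sep="\t", index=False)

    results = meta_analyze(
        effects, total_studies=len(qualifying),
        min_fraction=config.min_fraction, use_t=config.use_t,
    )
    excluded = set(effects["gene_id"].unique()) - set(results["gene_id"])
    for g in sorted(excluded):
        logger.info("excluded gene %s: insufficient_coverage", g)
    results = add_bh_fdr(results)
    results.to_csv(out / "meta_results.tsv", sep="\t", index=False)

    sig = significant_genes(results, config.p_threshold, config.lfc_threshold)
    sig.to_csv(out / "significant_genes.tsv", sep="\t", index=False)
    _write_sidecar(config, out)
    logger.info(
        "pooled %d genes across %d cohorts; %d significant",
        len(results), len(qualifying), len(sig),
    )
    return results


def run_forest(config: PipelineConfig, gene_id: str) -> pd.DataFrame:
    """Forest-plot table (per-study LFC, CI, weight %) for one gene."""
    effects = pd.read_csv(Path(config.out_dir) / "effects.tsv", sep="\t")
    sub = effects[effects["gene_id"] == gene_id]
    if sub.empty:
        raise DataError(f"gene {gene_id} has no effects in {config.out_dir}")
    metas = read_metadata_table(Path(config.data_dir) / "metadata.tsv")
    result = meta_analyze_gene(
        sub, total_studies=len(filter_datasets(metas)),
        min_fraction=config.min_fraction, use_t=config.use_t,
    )
    if result is None:
        raise DataError(f"gene {gene_id}: insufficient coverage for pooling")
    table = forest_table(result, sub)
    table.to_csv(Path(config.out_dir) / f"forest_{gene_id}.tsv", sep="\t", index=False)
    return table


def run_overlap(
    list_a_path: str | Path,
    list_b_path: str | Path,
    universe_n: int = DEFAULT_UNIVERSE,
    out_path: str | Path | None = None,
) -> OverlapResult:
    """Overlap report for two gene-list files (plain text or xlsx sheet)."""
    for p in (list_a_path, list_b_path):
        if not Path(p).exists():
            raise DataError(f"gene list not found: {p}")
    pair = GeneSetPair(
        read_gene_list(list_a_path), read_gene_list(list_b_path), universe_n
    )
    result = overlap_test(pair)
    if out_path is not None:
        write_overlap_report(result, out_path)
    return result


def run_mlr(config: PipelineConfig, gene_id: str) -> RegressionResult:
    """Meta-regression of one gene's per-study LFCs on sample size, region
    and study age; writes the coefficient table."""
    if not config.data_dir:
        raise ConfigError("data_dir is required for meta-regression")
    data_dir = Path(config.data_dir)
    metas = filter_datasets(read_metadata_table(data_dir / "metadata.tsv"))
    keep = {m.geo_id for m in metas}
    datasets = [ds for ds in load_bundle(data_dir) if ds.meta.geo_id in keep]
    effects = effects_table(datasets, genes=[gene_id])
    if effects.empty:
        raise DataError(f"gene {gene_id} measured in no qualifying cohort")
    result = regress_gene_effects(effects, metas, config.region_map)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out / f"mlr_{gene_id}.tsv", sep="\t", index=False)
    return result
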