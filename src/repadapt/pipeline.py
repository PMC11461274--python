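"""End-to-end orchestration: climate -> GEA -> WZA -> Fisher ->
paralogue collapse -> repeatability -> outputs.

The pipeline operates on dataset records (one allele-frequency matrix +
gene annotation + site climate table per dataset; several datasets may
belong to one species, in which case per-gene p-values are Fisher-combined)
plus an orthogroup map.  Every stage writes a TSV that its own reader can
parse back, and a JSON manifest records configuration hash, seeds and
per-stage row counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .gea import assign_snps_to_genes, empirical_p, kendall_gea, maf_filter
from .repeatability import (
    EmpiricalNull,
    PicMinConfig,
    build_empirical_null,
    collapse_paralogues,
    contribution_matrices,
    picmin_scan,
)
from .wza import fisher_combine, wza_correct, wza_scan

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "DatasetRecord", "gea_dataset_scan", "combine_species_datasets", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and sizes for a full run (defaults follow the study design)."""

    maf_min: float = 0.05
    mac_min: int = 5
    flank: int = 500
    min_species: int = 20
    max_paralogues: int = 10
    fdr_threshold: float = 0.5
    per_variable_cutoff: float = 0.005
    interaction_support: float = 0.4
    edge_keep_positive: float = 2.33
    edge_keep_negative: float = -5.0
    duplication_support: float = 0.7
    wza_bins: int = 25
    null_size: int = 1_000_000
    n_eff_sims: int = 100_000
    seed: int = 0
    variables: list[str] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must lie in (0, 1]")
        if self.flank < 0 or self.min_species < 3 or self.max_paralogues < 1:
            raise ValueError("invalid threshold configuration")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DatasetRecord:
    """One GEA dataset: a species' frequencies, genes and site climate."""

    species: str
    dataset_id: str
    frequencies: pd.DataFrame
    genes: pd.DataFrame
    climate: pd.DataFrame  # indexed by site_id


def records_from_synthetic(dataset) -> list[DatasetRecord]:
    """Wrap a :class:`~repadapt.synthetic.SyntheticDataset` as dataset records."""
    return [
        DatasetRecord(sp, f"{sp}_ds1", dataset.frequencies[sp], dataset.genes[sp], dataset.climate[sp])
        for sp in dataset.species
    ]


def gea_dataset_scan(record: DatasetRecord, config: PipelineConfig) -> pd.DataFrame:
    """Per-gene corrected WZA scores for one dataset, all variables.

    Steps: MAF filter; SNP -> gene assignment (genes + flanks); per-variable
    Kendall tau GEA; empirical p over the assigned SNPs; heterozygosity-
    weighted Z per gene; SNP-count correction within the (dataset, variable)
    stratum.  Returns ``species, dataset, gene_id, variable, n_snps, z_raw,
    z_corrected, p, ep_wza``.
    """
    freqs = maf_filter(record.frequencies, config.maf_min, config.mac_min)
    if freqs.empty:
        logger.warning("dataset %s: no SNPs pass the MAF filter", record.dataset_id)
        return pd.DataFrame()
    assignment = assign_snps_to_genes(freqs, record.genes, flank=config.flank)
    if assignment.empty:
        logger.warning("dataset %s: no SNPs fall inside genes", record.dataset_id)
        return pd.DataFrame()
    variables = config.variables or [
        c for c in record.climate.columns if c not in ("lat", "lon")
    ]
    in_genes = freqs[freqs["snp_id"].isin(assignment["snp_id"])]
    out = []
    for variable in variables:
        res = kendall_gea(in_genes, record.climate, variable)
        if res is None:
            continue
        res["ep"] = empirical_p(res["p_value"].to_numpy())
        snp_table = assignment.merge(res[["snp_id", "ep"]], on="snp_id").merge(
            in_genes[["snp_id", "mean_freq"]], on="snp_id"
        )
        scores = wza_scan(snp_table)
        scores = wza_correct(scores, n_bins=config.wza_bins)
        scores.insert(0, "species", record.species)
        scores.insert(1, "dataset", record.dataset_id)
        scores.insert(3, "variable", variable)
        out.append(scores)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def combine_species_datasets(gene_scores: pd.DataFrame) -> pd.DataFrame:
    """Merge multiple datasets per species by Fisher-combining gene p-values.

    Species with a single dataset pass through unchanged.  The combined p is
    re-ranked into a fresh within-(species, variable) empirical p so the
    downstream collapse sees a uniform marginal either way.
    """
    n_datasets = gene_scores.groupby("species")["dataset"].nunique()
    single = gene_scores[gene_scores["species"].map(n_datasets) == 1].copy()
    multi = gene_scores[gene_scores["species"].map(n_datasets) > 1]
    parts = [single[["species", "gene_id", "variable", "p", "ep_wza"]]]
    for (species, variable), sub in multi.groupby(["species", "variable"], sort=False):
        combined = (
            sub.groupby("gene_id")["p"].apply(lambda ps: fisher_combine(ps.to_numpy())).rename("p").reset_index()
        )
        combined["species"] = species
        combined["variable"] = variable
        combined["ep_wza"] = empirical_p(combined["p"].to_numpy())
        parts.append(combined[["species", "gene_id", "variable", "p", "ep_wza"]])
    return pd.concat(parts, ignore_index=True)


def run_pipeline(
    records: list[DatasetRecord],
    orthogroups: dict[str, dict[str, list[str]]],
    config: PipelineConfig,
    outdir: str | Path,
    null: EmpiricalNull | None = None,
) -> dict:
    """Run GEA -> WZA -> collapse -> repeatability and write all outputs.

    Returns a dict with the per-gene scores, collapsed table, repeatability
    results, contribution matrices and the empirical null used.  Outputs
    land in ``outdir`` (gene_scores.tsv, collapsed.tsv, repeatability.tsv,
    contribution_by_variable.tsv, contribution_by_pair.tsv, rao_counts.tsv,
    manifest.json, null_store.npz).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, int] = {}

    per_dataset = []
    for record in records:
        scores = gea_dataset_scan(record, config)
        if len(scores):
            per_dataset.append(scores)
    gene_scores = pd.concat(per_dataset, ignore_index=True)
    stages["gene_scores"] = len(gene_scores)
    gene_scores.to_csv(outdir / "gene_scores.tsv", sep="\t", index=False, float_format="%.6g")

    combined = combine_species_datasets(gene_scores)
    filtered = rio.filter_orthogroups(
        orthogroups, max_paralogues=config.max_paralogues, min_species=config.min_species
    )
    collapsed = collapse_paralogues(combined, filtered)
    stages["collapsed"] = len(collapsed)
    collapsed.to_csv(outdir / "collapsed.tsv", sep="\t", index=False, float_format="%.6g")

    if null is None:
        counts = collapsed.groupby(["orthogroup", "variable"])["species"].size()
        n_max = int(counts.max()) if len(counts) else config.min_species
        pm_cfg = PicMinConfig(
            min_species=config.min_species,
            max_species=n_max,
            null_size=config.null_size,
            n_eff_sims=config.n_eff_sims,
            seed=config.seed,
        )
        null = build_empirical_null(pm_cfg)
        null.save(outdir / "null_store.npz")

    results = picmin_scan(
        collapsed, null, min_species=config.min_species, fdr_threshold=config.fdr_threshold
    )
    stages["repeatability"] = len(results)
    to_write = results.copy()
    to_write["contributing_species"] = to_write["contributing_species"].map(",".join)
    to_write.to_csv(outdir / "repeatability.tsv", sep="\t", index=False, float_format="%.6g")

    by_var, by_pair = contribution_matrices(results)
    by_var.to_csv(outdir / "contribution_by_variable.tsv", sep="\t", float_format="%.4f")
    by_pair.to_csv(outdir / "contribution_by_pair.tsv", sep="\t", float_format="%.4f")

    rao_counts = (
        results[results["rao"]].groupby("variable").size().rename("n_rao").reset_index()
    )
    rao_counts.to_csv(outdir / "rao_counts.tsv", sep="\t", index=False)
    stages["rao_total"] = int(results["rao"].sum())
    stages["rao_unique"] = int(results.loc[results["rao"], "orthogroup"].nunique())

    rio.write_manifest(
        outdir / "manifest.json",
        config.to_dict(),
        {"pipeline_seed": config.seed, "null_seed": null.seed},
        stages,
    )
    logger.info("pipeline finished: %s", stages)
    return {
        "gene_scores": gene_scores,
        "combined": combined,
        "collapsed": collapsed,
        "repeatability": results,
        "contribution_by_variable": by_var,
        "contribution_by_pair": by_pair,
        "null": null,
        "stages": stages,
    }
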