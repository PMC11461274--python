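"""File formats: allele-frequency TSV, VCF + population map, GFF3,
Orthogroups.tsv, climate and property tables, and the run manifest.

Conventions: internal gene coordinates are 0-based half-open; GFF3 and VCF
positions are 1-based on disk.  Every writer's output is re-readable by the
matching reader (round-trip tested).
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_allele_frequencies",
    "write_allele_frequencies",
    "read_allele_frequencies_vcf",
    "read_popmap",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_orthogroups",
    "write_orthogroups",
    "filter_orthogroups",
    "read_climate_table",
    "write_climate_table",
    "read_monthly_series",
    "write_monthly_series",
    "write_manifest",
]

_META_COLUMNS = {"snp_id", "chrom", "pos", "mean_freq"}


def read_allele_frequencies(path: str | Path) -> pd.DataFrame:
    """Allele-frequency TSV: ``snp_id, chrom, pos, <site columns...>``.

    Frequencies are validated into [0, 1]; a ``mean_freq`` column (mean over
    site columns) is added if absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
    site_cols = [c for c in df.columns if c not in _META_COLUMNS]
    for line, row in enumerate(df[site_cols].itertuples(index=False), start=2):
        for v in row:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{path}: line {line}: frequency {v} outside [0, 1]")
    if "mean_freq" not in df.columns:
        df["mean_freq"] = df[site_cols].mean(axis=1)
    return df


def write_allele_frequencies(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_popmap(path: str | Path) -> pd.DataFrame:
    """Population map TSV: ``sample, site_id``."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_allele_frequencies_vcf(vcf_path: str | Path, popmap: pd.DataFrame) -> pd.DataFrame:
    """Per-site alternate-allele frequencies from a VCF.

    Individuals with the same ``site_id`` in the popmap are pooled; the
    frequency is alt-dosage sum / called allele count, with missing
    genotypes excluded from the denominator.  Sites (columns) with zero
    called genotypes at a SNP get NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    site_of = dict(zip(popmap["sample"], popmap["site_id"]))
    sites = sorted(set(site_of.values()))
    idx_by_site = {
        s: [i for i, name in enumerate(samples) if site_of.get(name) == s] for s in sites
    }
    records = []
    for var in vcf:
        gts = var.genotype.array()  # (n_samples, ploidy+1); -1 = missing
        alleles = gts[:, :-1]
        row = {
            "snp_id": var.ID or f"{var.CHROM}_{var.POS}",
            "chrom": var.CHROM,
            "pos": var.POS,
        }
        for s in sites:
            sub = alleles[idx_by_site[s]]
            called = sub >= 0
            n_called = int(called.sum())
            row[s] = float(sub[called].sum()) / n_called if n_called else np.nan
        records.append(row)
    df = pd.DataFrame(records)
    df["mean_freq"] = df[sites].mean(axis=1)
    return df


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene features from a GFF3 file, as 0-based half-open intervals.

    Uses gffutils (in-memory db).  Returns ``gene_id, chrom, start, end``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append({"gene_id": gene_id, "chrom": feat.seqid, "start": feat.start - 1, "end": feat.end})
    return pd.DataFrame(rows)


def write_gff3_genes(genes: pd.DataFrame, path: str | Path, source: str = "repadapt") -> None:
    """Write gene intervals (0-based half-open in memory) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{int(row.start) + 1}\t{int(row.end)}\t.\t+\t.\t"
                f"ID={row.gene_id}\n"
            )


def read_orthogroups(path: str | Path) -> dict[str, dict[str, list[str]]]:
    """Orthogroups.tsv dialect: first column orthogroup id, one column per
    species, comma-separated gene ids; empty cell = species absent.

    A gene id appearing in two orthogroups raises.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    species = list(df.columns[1:])
    seen: dict[str, str] = {}
    out: dict[str, dict[str, list[str]]] = {}
    for row in df.itertuples(index=False):
        og = row[0]
        by_sp: dict[str, list[str]] = {}
        for sp, cell in zip(species, row[1:]):
            genes = [g.strip() for g in str(cell).split(",") if g.strip()]
            if genes:
                for g in genes:
                    if g in seen:
                        raise ValueError(f"gene {g!r} appears in both {seen[g]!r} and {og!r}")
                    seen[g] = og
                by_sp[sp] = genes
        out[og] = by_sp
    return out


def write_orthogroups(
    orthogroups: dict[str, dict[str, list[str]]], path: str | Path, species: list[str] | None = None
) -> None:
    species = species or sorted({sp for m in orthogroups.values() for sp in m})
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(species) + "\n")
        for og, by_sp in orthogroups.items():
            cells = [", ".join(by_sp.get(sp, [])) for sp in species]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


def filter_orthogroups(
    orthogroups: dict[str, dict[str, list[str]]],
    max_paralogues: int = 10,
    min_species: int = 20,
) -> dict[str, dict[str, list[str]]]:
    """Drop species with too many paralogues, then orthogroups with too few
    species."""
    out = {}
    for og, by_sp in orthogroups.items():
        kept = {sp: genes for sp, genes in by_sp.items() if len(genes) <= max_paralogues}
        if len(kept) >= min_species:
            out[og] = kept
    return out


def read_climate_table(path: str | Path) -> pd.DataFrame:
    """Site climate TSV (``site_id, lat, lon, bio1..[, change cols]``),
    indexed by site id."""
    return pd.read_csv(path, sep="\t", dtype={"site_id": str}).set_index("site_id")


def write_climate_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.reset_index() if table.index.name == "site_id" else table
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_monthly_series(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"site_id": str, "variable": str, "decade": str})


def write_monthly_series(series: pd.DataFrame, path: str | Path) -> None:
    series.to_csv(path, sep="\t", index=False, float_format="%.6f")


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seeds: dict, stages: dict) -> dict:
    """Run manifest: config hash, seeds, versions, per-stage row counts."""
    from . import __version__

    manifest = {
        "config_hash": config_hash(config),
        "config": config,
        "seeds": seeds,
        "versions": {
            "repadapt": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": stages,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
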