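#!/usr/bin/env python
"""Per-SNP associations and gene-level weighted-Z scores for every species.

Reads the simulated inputs back from disk exactly as a real-data run would,
then for each species: MAF filter, SNP-to-gene assignment (genes + 500 bp
flanks), Kendall tau against each climate variable, empirical p conversion,
heterozygosity-weighted Z per gene and SNP-count correction.
"""

from pathlib import Path

import pandas as pd

from repadapt import io as rio
from repadapt.pipeline import DatasetRecord, PipelineConfig, gea_dataset_scan

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig(seed=2024)
    parts = []
    for freq_file in sorted((BASE / "synthetic").glob("*_freqs.tsv")):
        sp = freq_file.name[: -len("_freqs.tsv")]
        record = DatasetRecord(
            species=sp,
            dataset_id=f"{sp}_ds1",
            frequencies=rio.read_allele_frequencies(freq_file),
            genes=rio.read_gff3_genes(BASE / "synthetic" / f"{sp}_genes.gff3"),
            climate=rio.read_climate_table(BASE / "synthetic" / f"{sp}_climate.tsv"),
        )
        parts.append(gea_dataset_scan(record, cfg))
    scores = pd.concat(parts, ignore_index=True)
    (BASE / "tables").mkdir(exist_ok=True)
    scores.to_csv(BASE / "tables" / "gene_scores.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"scored {scores['gene_id'].nunique()} genes x {scores['variable'].nunique()} variables "
          f"across {scores['species'].nunique()} species ({len(scores)} rows)")
    print("corrected-score summary: mean z_corrected = "
          f"{scores['z_corrected'].mean():.3f}, SD = {scores['z_corrected'].std():.3f} "
          "(near 0/1 by construction on null genes)")


if __name__ == "__main__":
    main()
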