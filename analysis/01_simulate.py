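#!/usr/bin/env python
"""Generate the synthetic multi-species GEA study all later steps analyse.

Emulates the real study's shape at desk scale: 22 species sampled at 15
sites each, 500 orthogroups (20-22 species present, paralogues up to 10),
5 climate variables (3 correlated gradients + 2 decade-change variables
derived from monthly series), with 5% of orthogroups implanted as
repeatable across 8 contributing species.  Writes every input file in the
same formats a real-data run would consume, plus the implant truth.
"""

from pathlib import Path

from repadapt import io as rio
from repadapt.synthetic import SimulationConfig, simulate_gea_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

CONFIG = SimulationConfig(
    n_species=22,
    species_presence=(20, 22),
    n_orthogroups=500,
    n_variables=5,
    n_sites_per_species=15,
    adaptive_fraction=0.05,
    n_contributing_species=8,
    effect_size=2.0,
    seed=2024,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds = simulate_gea_dataset(CONFIG)
    for sp in ds.species:
        rio.write_allele_frequencies(ds.frequencies[sp], OUT / f"{sp}_freqs.tsv")
        rio.write_gff3_genes(ds.genes[sp], OUT / f"{sp}_genes.gff3")
        rio.write_climate_table(ds.climate[sp], OUT / f"{sp}_climate.tsv")
        rio.write_monthly_series(ds.monthly_series[sp], OUT / f"{sp}_monthly.tsv")
    rio.write_orthogroups(ds.orthogroups, OUT / "Orthogroups.tsv", species=ds.species)
    with open(OUT / "truth.tsv", "w") as fh:
        fh.write("orthogroup\tcontributing_species\n")
        for og in sorted(ds.truth.implanted_orthogroups):
            fh.write(f"{og}\t{','.join(sorted(ds.truth.contributing_species[og]))}\n")
    n_snps = sum(len(ds.frequencies[sp]) for sp in ds.species)
    print(f"wrote {len(ds.species)} species, {CONFIG.n_orthogroups} orthogroups, "
          f"{n_snps} SNPs, {len(ds.truth.implanted_orthogroups)} implanted orthogroups -> {OUT}")


if __name__ == "__main__":
    main()
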