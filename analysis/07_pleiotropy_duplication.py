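#!/usr/bin/env python
"""Are repeatable gene families more pleiotropic?  More duplicated?

Condenses per-gene tissue-specificity tau and co-expression centralities to
orthogroup-level Z-scores, groups orthogroups into deciles by their
strongest repeatability evidence, and Stouffer-combines each decile
(positive Z = more pleiotropic than expected).  Duplication metrics are
summarised per decile the same way.
"""

from pathlib import Path

import pandas as pd

from repadapt import io as rio
from repadapt.genefamily import (
    coexpression_centrality,
    decile_means,
    decile_stouffer,
    duplication_metrics,
    gene_tau_table,
    orthogroup_level_z,
)

BASE = Path(__file__).resolve().parent.parent / "results"
REF = "sp01"


def main() -> None:
    res = pd.read_csv(BASE / "tables" / "repeatability.tsv", sep="\t")
    ogs = rio.read_orthogroups(BASE / "synthetic" / "Orthogroups.tsv")
    rep_p = res.groupby("orthogroup")["calibrated_p"].min()

    taus = gene_tau_table(pd.read_csv(BASE / "synthetic" / f"{REF}_expression.tsv", sep="\t"))
    tau_z = orthogroup_level_z(taus, ogs, REF, "tau", high_is_pleiotropic=False)
    tau_dec = decile_stouffer(tau_z, rep_p)
    tau_dec.to_csv(BASE / "tables" / "tau_deciles.tsv", sep="\t", index=False, float_format="%.4g")
    print("tissue specificity (tau) by repeatability decile (1 = most repeatable):")
    print(tau_dec.round(3).to_string(index=False))

    cent = coexpression_centrality(
        pd.read_csv(BASE / "synthetic" / f"{REF}_coexpression.tsv", sep="\t")
    )
    for metric in ("degree", "strength", "closeness", "betweenness"):
        z = orthogroup_level_z(cent, ogs, REF, metric, high_is_pleiotropic=True)
        dec = decile_stouffer(z, rep_p)
        dec.to_csv(BASE / "tables" / f"{metric}_deciles.tsv", sep="\t", index=False,
                   float_format="%.4g")
        print(f"{metric}: top-decile Stouffer Z = {dec['stouffer_z'].iloc[0]:+.2f} "
              f"(P = {dec['p'].iloc[0]:.2g}), bottom decile {dec['stouffer_z'].iloc[-1]:+.2f}")

    dup_table = pd.read_csv(BASE / "synthetic" / f"{REF}_duplications.tsv", sep="\t")
    species = sorted({sp for m in ogs.values() for sp in m})
    dups = duplication_metrics(dup_table, gea_species=set(species), known_species=set(species))
    dup_dec = decile_means(dups, rep_p, ["n_duplications", "n_species_specific"])
    dup_dec.to_csv(BASE / "tables" / "duplication_deciles.tsv", sep="\t", index=False,
                   float_format="%.4g")
    print("mean duplication events per decile:")
    print(dup_dec.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
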