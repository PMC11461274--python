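"""Functional enrichment of repeatedly associated orthogroups (RAOs).

Two tests: an interaction-permutation test asking whether genes from RAOs
carry more protein-protein interactions *between* orthogroups than random
orthogroup sets of equal size (one random gene per orthogroup, so
within-orthogroup edges never count), and a hypergeometric GO-term
enrichment against a custom background in which each orthogroup's term set
is the deduplicated union over its member genes in the reference species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .repeatability import bh_adjust

__all__ = [
    "build_orthogroup_annotation",
    "interaction_enrichment",
    "go_enrichment",
]


def build_orthogroup_annotation(
    orthogroups: dict[str, dict[str, list[str]]],
    go_map: pd.DataFrame,
    reference_species: str,
) -> dict[str, set[str]]:
    """Deduplicated union of GO terms over the reference species' members."""
    terms_of_gene: dict[str, set[str]] = {}
    for row in go_map.itertuples():
        terms_of_gene.setdefault(row.gene_id, set()).add(row.term_id)
    out = {}
    for og, by_sp in orthogroups.items():
        terms: set[str] = set()
        for gene in by_sp.get(reference_species, []):
            terms |= terms_of_gene.get(gene, set())
        out[og] = terms
    return out


def _edge_set(network: pd.DataFrame, threshold: float) -> set[frozenset]:
    edges = set()
    for row in network.itertuples():
        if row.gene_a != row.gene_b and row.score > threshold:
            edges.add(frozenset((row.gene_a, row.gene_b)))
    return edges


def _mean_interactions(
    groups: list[list[str]],
    edges: set[frozenset],
    n_draws: int,
    rng: np.random.Generator,
) -> float:
    """Mean edge count over one-random-gene-per-orthogroup networks."""
    total = 0
    for _ in range(n_draws):
        sample = [g[rng.integers(len(g))] for g in groups]
        total += sum(
            1
            for i in range(len(sample))
            for j in range(i + 1, len(sample))
            if frozenset((sample[i], sample[j])) in edges
        )
    return total / n_draws


def interaction_enrichment(
    rao_set: list[str],
    background: list[str],
    network: pd.DataFrame,
    orthogroups: dict[str, dict[str, list[str]]],
    reference_species: str,
    score_threshold: float = 0.4,
    n_gene_draws: int = 1000,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Permutation test for excess between-orthogroup interactions in RAOs.

    ``observed`` is the mean, over ``n_gene_draws`` samplings of one random
    gene per RAO orthogroup, of the number of network edges with support
    above ``score_threshold`` among the sampled genes.  The null draws
    ``n_perm`` random background orthogroup sets of the same size and scores
    them identically (one gene-draw each).  Genes absent from the network
    simply contribute no edges.  ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if not rao_set or not background:
        raise ValueError("rao_set and background must be nonempty")
    if len(background) < len(rao_set):
        raise ValueError("background smaller than the RAO set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = _edge_set(network, score_threshold)

    def genes_of(ogs: list[str]) -> list[list[str]]:
        out = []
        for og in ogs:
            members = orthogroups.get(og, {}).get(reference_species, [])
            if members:
                out.append(list(members))
        return out

    observed = _mean_interactions(genes_of(rao_set), edges, n_gene_draws, rng)
    bg = np.array(background, dtype=object)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pick = bg[rng.choice(bg.size, size=len(rao_set), replace=False)]
        null[i] = _mean_interactions(genes_of(list(pick)), edges, 1, rng)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return {
        "observed_mean": float(observed),
        "null_mean": float(null.mean()),
        "null_counts": null,
        "p": float(p),
    }


def go_enrichment(
    rao_orthogroups: list[str],
    annotation: dict[str, set[str]],
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """One-tailed hypergeometric GO enrichment on an orthogroup background.

    ``annotation`` maps every background orthogroup to its collapsed term
    set; orthogroups in ``rao_orthogroups`` must be part of the background.
    For each term with at least one background carrier, the upper-tail
    hypergeometric p of the RAO carrier count is computed; BH correction is
    applied across terms.  Returns one row per term with observed/expected
    carrier fractions, p, q and a significance flag at ``fdr_threshold``.
    """
    rao = [og for og in rao_orthogroups if og in annotation]
    missing = set(rao_orthogroups) - set(rao)
    if missing:
        raise ValueError(f"RAO orthogroups absent from background: {sorted(missing)[:5]}")
    m_bg = len(annotation)
    n_draw = len(rao)
    carriers: dict[str, int] = {}
    for terms in annotation.values():
        for t in terms:
            carriers[t] = carriers.get(t, 0) + 1
    rao_carriers: dict[str, int] = {}
    for og in rao:
        for t in annotation[og]:
            rao_carriers[t] = rao_carriers.get(t, 0) + 1
    rows = []
    for term, k_bg in sorted(carriers.items()):
        k_obs = rao_carriers.get(term, 0)
        p = float(hypergeom.sf(k_obs - 1, m_bg, k_bg, n_draw))
        rows.append(
            {
                "term_id": term,
                "n_rao": k_obs,
                "n_background": k_bg,
                "observed_fraction": k_obs / n_draw if n_draw else np.nan,
                "expected_fraction": k_bg / m_bg,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr_threshold
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
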