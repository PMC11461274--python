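"""Gene-family properties: pleiotropy metrics, duplication history and their
association with repeatability.

Pleiotropy is proxied two ways: tissue specificity tau (low tau = broadly
expressed = more pleiotropic) and centrality in a signed co-expression
network (degree, strength = sum |z|, closeness = 1 / total shortest-path
distance to reachable nodes, betweenness).  Per-gene values are condensed to
orthogroup level exactly like the GEA scores: rank-based eP oriented so the
most-pleiotropic extreme gets the lowest eP, minimum over paralogues with a
Dunn-Sidak correction, then a rank-based inverse-normal transform across
orthogroups standardised to mean 0, SD 1.  Orthogroups are finally grouped
into repeatability deciles (by their minimum PicMin p across variables) and
each decile's Z-scores are Stouffer-combined.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .repeatability import dunn_sidak

__all__ = [
    "tissue_tau",
    "mean_tissue_profiles",
    "coexpression_centrality",
    "orthogroup_level_z",
    "decile_stouffer",
    "duplication_metrics",
    "decile_means",
]


def tissue_tau(profile: np.ndarray) -> float:
    """Tissue-specificity tau of a per-tissue mean-TPM profile.

    ``tau = sum(1 - x_i) / (n - 1)`` with x the profile scaled by its
    maximum; 0 = uniformly expressed (most pleiotropic), 1 = single-tissue.
    All-zero profiles are undefined (ValueError).
    """
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two tissues")
    if np.any(x < 0):
        raise ValueError("TPM values must be nonnegative")
    m = x.max()
    if m == 0:
        raise ValueError("tau undefined for an all-zero profile")
    scaled = x / m
    return float((1.0 - scaled).sum() / (x.size - 1))


def mean_tissue_profiles(expression: pd.DataFrame) -> pd.DataFrame:
    """Mean TPM per (gene, tissue), averaging over stages and subtissues.

    ``expression`` needs columns ``gene_id, tissue, stage, subtissue, tpm``.
    Returns a wide gene x tissue frame; genes with all-zero profiles are
    dropped with a warning.
    """
    mean = expression.groupby(["gene_id", "tissue"], sort=True)["tpm"].mean().unstack(fill_value=0.0)
    zero = (mean.max(axis=1) == 0)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} gene(s) with all-zero expression excluded from tau")
        mean = mean[~zero]
    return mean


def gene_tau_table(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene tau from a long expression table."""
    profiles = mean_tissue_profiles(expression)
    taus = [tissue_tau(row) for row in profiles.to_numpy()]
    return pd.DataFrame({"gene_id": profiles.index, "tau": taus})


def coexpression_centrality(
    edges: pd.DataFrame,
    keep_positive: float = 2.33,
    keep_negative: float = -5.0,
    weighted_paths: bool = False,
    path_metrics: bool = True,
) -> pd.DataFrame:
    """Node centralities on the significant-co-expression network.

    Edges with ``keep_negative < z < keep_positive`` are discarded; both
    retained signs contribute |z| to strength and are equivalent for path
    metrics.  Degree and strength follow directly; closeness is
    ``1 / sum(shortest-path distances to reachable nodes)`` and betweenness
    the shortest-path pass-through count, both on the unweighted retained
    graph by default (``weighted_paths`` switches to 1/|z| distances).
    Isolated genes get closeness = betweenness = 0.  ``path_metrics=False``
    skips the (costly) closeness/betweenness computation on large networks.
    """
    kept = edges[(edges["z"] >= keep_positive) | (edges["z"] <= keep_negative)]
    g = nx.Graph()
    g.add_nodes_from(pd.unique(edges[["gene_a", "gene_b"]].to_numpy().ravel()))
    for row in kept.itertuples():
        if row.gene_a == row.gene_b:
            continue
        g.add_edge(row.gene_a, row.gene_b, weight=abs(row.z), dist=1.0 / abs(row.z))
    strength = {n: 0.0 for n in g.nodes}
    for a, b, w in g.edges(data="weight"):
        strength[a] += w
        strength[b] += w
    out = {
        "gene_id": list(g.nodes),
        "degree": [g.degree(n) for n in g.nodes],
        "strength": [strength[n] for n in g.nodes],
    }
    if path_metrics:
        dist_attr = "dist" if weighted_paths else None
        betweenness = nx.betweenness_centrality(g, normalized=False, weight=dist_attr)
        closeness = {}
        for node in g.nodes:
            if weighted_paths:
                lengths = nx.single_source_dijkstra_path_length(g, node, weight="dist")
            else:
                lengths = nx.single_source_shortest_path_length(g, node)
            total = sum(d for n, d in lengths.items() if n != node)
            closeness[node] = 1.0 / total if total > 0 else 0.0
        out["closeness"] = [closeness[n] for n in g.nodes]
        out["betweenness"] = [betweenness[n] for n in g.nodes]
    return pd.DataFrame(out)


def orthogroup_level_z(
    gene_values: pd.DataFrame,
    orthogroups: dict[str, dict[str, list[str]]],
    reference_species: str,
    value_column: str,
    high_is_pleiotropic: bool,
) -> pd.DataFrame:
    """Condense a per-gene metric to standardised orthogroup Z-scores.

    Gene values are converted to rank-based eP values oriented so the
    most-pleiotropic extreme receives the lowest eP (``high_is_pleiotropic``
    states which end that is: True for centralities, False for tau).  Per
    orthogroup the minimum eP over measured paralogues is Dunn-Sidak
    corrected for their number, and corrected eP values are mapped through a
    rank-based inverse-normal transform, then standardised to mean 0 / SD 1
    exactly.  Higher Z = more pleiotropic.  Orthogroups without measured
    genes are absent.
    """
    vals = gene_values.set_index("gene_id")[value_column]
    v = vals.to_numpy(dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 measured genes")
    ranks = rankdata(-v if high_is_pleiotropic else v, method="average")
    ep = pd.Series(np.clip(ranks / n, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)), index=vals.index)
    rows = []
    for og, by_sp in orthogroups.items():
        members = [g for g in by_sp.get(reference_species, []) if g in ep.index]
        if not members:
            continue
        corrected = float(dunn_sidak(ep[members].min(), len(members)))
        rows.append({"orthogroup": og, "ep_corrected": corrected, "n_measured": len(members)})
    out = pd.DataFrame(rows)
    if len(out) < 2:
        raise ValueError("need at least 2 orthogroups with measured genes")
    m = len(out)
    r = rankdata(out["ep_corrected"].to_numpy(), method="average")
    z = ndtri(1.0 - (r - 0.5) / m)  # low eP -> high z (more pleiotropic)
    z = (z - z.mean()) / z.std(ddof=0)
    out["z"] = z
    out["metric"] = value_column
    return out


def decile_stouffer(
    orthogroup_z: pd.DataFrame,
    repeatability_p: pd.Series,
    n_groups: int = 10,
) -> pd.DataFrame:
    """Stouffer-combined pleiotropy Z per repeatability decile.

    ``repeatability_p`` maps orthogroup -> strongest repeatability evidence
    (minimum PicMin p across variables).  Orthogroups are ranked from most
    to least repeatable (ties broken by orthogroup id for determinism) and
    split into ``n_groups`` equal-occupancy groups; each group's Z-scores
    combine as ``sum(z) / sqrt(k)`` with a two-sided normal p.
    """
    df = orthogroup_z.merge(
        repeatability_p.rename("rep_p"), left_on="orthogroup", right_index=True, how="inner"
    )
    if df.empty:
        raise ValueError("no orthogroups shared between Z table and repeatability table")
    df = df.sort_values(["rep_p", "orthogroup"], kind="stable").reset_index(drop=True)
    splits = np.array_split(np.arange(len(df)), n_groups)
    rows = []
    for d, idx in enumerate(splits, start=1):
        z = df.loc[idx, "z"].to_numpy()
        if z.size == 0:
            rows.append({"decile": d, "n": 0, "stouffer_z": np.nan, "p": np.nan})
            continue
        sz = float(z.sum() / np.sqrt(z.size))
        rows.append({"decile": d, "n": int(z.size), "stouffer_z": sz, "p": float(2 * ndtr(-abs(sz)))})
    return pd.DataFrame(rows)


def stouffer_for_selection(orthogroup_z: pd.DataFrame, selected: set[str]) -> tuple[float, float]:
    """Stouffer Z and two-sided p for an explicit orthogroup selection.

    Used for the per-variable mode (orthogroups with at least one
    repeatability p below a cutoff for that variable); an empty selection
    returns (nan, nan).
    """
    z = orthogroup_z.loc[orthogroup_z["orthogroup"].isin(selected), "z"].to_numpy()
    if z.size == 0:
        return float("nan"), float("nan")
    sz = float(z.sum() / np.sqrt(z.size))
    return sz, float(2 * ndtr(-abs(sz)))


def duplication_metrics(
    duplications: pd.DataFrame,
    gea_species: set[str],
    known_species: set[str] | None = None,
    support_threshold: float = 0.7,
) -> pd.DataFrame:
    """Per-orthogroup duplication counts.

    Events qualify when node support exceeds ``support_threshold`` and the
    species set under the node overlaps the species that contributed GEA
    p-values.  ``species_under_node`` is a comma-separated list;
    ``tips_single_genome`` marks events whose tips all come from one genome
    (species-specific duplications).  Unknown species names raise.
    Returns ``orthogroup_id, n_duplications, n_species_specific``.
    """
    df = duplications.copy()
    if known_species is not None:
        seen = {sp for cell in df["species_under_node"] for sp in str(cell).split(",") if sp}
        unknown = sorted(seen - known_species)
        if unknown:
            raise ValueError(f"unknown species in duplication table: {unknown}")
    qualifying = []
    for row in df.itertuples():
        if row.support <= support_threshold:
            continue
        under = {sp for sp in str(row.species_under_node).split(",") if sp}
        if not (under & gea_species):
            continue
        qualifying.append((row.orthogroup_id, int(row.tips_single_genome)))
    qual = pd.DataFrame(qualifying, columns=["orthogroup_id", "species_specific"])
    if qual.empty:
        return pd.DataFrame(columns=["orthogroup_id", "n_duplications", "n_species_specific"])
    out = qual.groupby("orthogroup_id").agg(
        n_duplications=("species_specific", "size"),
        n_species_specific=("species_specific", "sum"),
    )
    return out.reset_index()


def decile_means(
    values: pd.DataFrame,
    repeatability_p: pd.Series,
    columns: list[str],
    id_column: str = "orthogroup_id",
    n_groups: int = 10,
) -> pd.DataFrame:
    """Mean of each metric per repeatability decile (most repeatable first)."""
    df = values.merge(
        repeatability_p.rename("rep_p"), left_on=id_column, right_index=True, how="right"
    )
    df[columns] = df[columns].fillna(0)
    df = df.sort_values(["rep_p", id_column], kind="stable").reset_index(drop=True)
    splits = np.array_split(np.arange(len(df)), n_groups)
    rows = []
    for d, idx in enumerate(splits, start=1):
        row = {"decile": d, "n": len(idx)}
        for c in columns:
            row[f"mean_{c}"] = float(df.loc[idx, c].mean()) if len(idx) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
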