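"""Synthetic data with the statistical structure the pipeline assumes.

Generates every input the analysis consumes — per-species population
allele-frequency matrices with gene annotations, site-by-climate tables
(correlated bioclim-style gradients plus two-decade monthly series for the
climate-change variables), orthogroup maps with paralogues, per-species
gene-level p-value tables, expression/co-expression/interaction/GO/
duplication tables — together with a ground-truth record of the implanted
repeatable orthogroups, so every downstream stage is testable without any
download.

Model sketch
------------
* Climate: each site carries a latent environmental gradient g ~ N(0,1);
  every bioclim-style variable is ``sqrt(rho) * g + sqrt(1-rho) * noise`` so
  all pairs correlate at about ``climate_corr``.  Monthly tmax/precipitation
  series shift between the 1960s and 2010s by a site-specific amount, from
  which the two change variables are computed with the climate module.
* Allele frequencies live on the logit scale: a SNP's base frequency
  (clamped into [0.01, 0.99] so MAF filtering does not annihilate loci)
  plus a shared per-site random effect (weight ``drift_sd``, the spatial
  structure) plus SNP-site noise.  Adaptive SNPs add
  ``effect_size * standardised coupled variable``.
* Repeatability: a fraction of orthogroups is implanted; in each, a set of
  contributing species carries one adaptive paralogue whose SNPs are
  climate-coupled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .climate import CHANGE_VARIABLES, climate_change_effect_size, attach_change_variables

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_gea_dataset",
    "simulate_orthogroup_pvalues",
    "simulate_gene_properties",
    "simulate_monthly_series",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the real study's shape where it is fixed (21 climate
    variables, 20-25 species per orthogroup, at most 10 paralogues, at
    least 5 sampling sites) and otherwise sit at realistic mid-range values
    for a pooled-sequencing GEA study.
    """

    n_species: int = 25
    species_presence: tuple[int, int] = (20, 25)  # species per orthogroup (min, max)
    n_orthogroups: int = 2_000
    max_paralogues: int = 10
    paralogue_geom_p: float = 0.7  # truncated geometric over 1..max_paralogues
    n_sites_per_species: int = 20
    n_snps_per_gene: float = 6.0  # Poisson mean (floor 1)
    n_variables: int = 21
    climate_corr: float = 0.5
    adaptive_fraction: float = 0.025
    n_contributing_species: int = 8
    effect_size: float = 2.0
    drift_sd: float = 1.0
    snp_noise_sd: float = 0.5
    gene_length: int = 2_000
    gene_gap: int = 1_000
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_species", "n_orthogroups", "max_paralogues",
            "n_sites_per_species", "n_variables",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"configuration error: {name} must be positive")
        if self.n_sites_per_species < 5:
            raise ValueError("configuration error: n_sites_per_species must be >= 5")
        if not 0.0 <= self.adaptive_fraction <= 1.0:
            raise ValueError("configuration error: adaptive_fraction must lie in [0, 1]")
        if not -1.0 <= self.climate_corr <= 1.0:
            raise ValueError("configuration error: climate_corr must lie in [-1, 1]")
        lo, hi = self.species_presence
        if not 1 <= lo <= hi <= self.n_species:
            raise ValueError("configuration error: species_presence out of range")
        if self.n_contributing_species > lo:
            raise ValueError(
                "configuration error: n_contributing_species exceeds minimum species presence"
            )
        if not 0.0 < self.paralogue_geom_p <= 1.0:
            raise ValueError("configuration error: paralogue_geom_p must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of the implants (artifact bookkeeping, not an input)."""

    implanted_orthogroups: set[str] = field(default_factory=set)
    contributing_species: dict[str, set[str]] = field(default_factory=dict)
    adaptive_genes: dict[str, set[str]] = field(default_factory=dict)  # species -> genes
    coupled_variable: str = ""


@dataclass
class SyntheticDataset:
    """Everything :func:`simulate_gea_dataset` produces."""

    config: SimulationConfig
    species: list[str]
    frequencies: dict[str, pd.DataFrame]  # species -> snp_id, chrom, pos, gene hint, site cols
    genes: dict[str, pd.DataFrame]  # species -> gene_id, chrom, start, end (0-based half-open)
    climate: dict[str, pd.DataFrame]  # species -> site table (site_id index, variables)
    monthly_series: dict[str, pd.DataFrame]
    orthogroups: dict[str, dict[str, list[str]]]
    truth: SyntheticTruth

    def site_columns(self, species: str) -> list[str]:
        return list(self.climate[species].index)


def _species_names(k: int) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(k)]


def _truncated_geometric(rng, p, kmax, size):
    """Paralogue counts on 1..kmax, P(k) proportional to (1-p)**(k-1)."""
    k = np.arange(1, kmax + 1)
    w = (1 - p) ** (k - 1)
    return rng.choice(k, size=size, p=w / w.sum())


def simulate_monthly_series(
    site_ids: list[str],
    rng: np.random.Generator,
    months_per_decade: int = 120,
    base_shift_sd: float = 1.0,
) -> pd.DataFrame:
    """Two-decade monthly tmax/precipitation series per site.

    Each site's 2010s distribution is the 1960s one shifted by a
    site-specific amount (N(0, base_shift_sd) on the within-decade SD
    scale), so the attached change variables vary across sites.
    """
    rows = []
    for site in site_ids:
        for variable, (mu, sd) in {"tmax": (25.0, 5.0), "precipitation": (80.0, 30.0)}.items():
            shift = rng.normal(0.0, base_shift_sd) * sd
            for decade, offset in (("1960s", 0.0), ("2010s", shift)):
                vals = rng.normal(mu + offset, sd, size=months_per_decade)
                if variable == "precipitation":
                    vals = np.maximum(vals, 0.0)
                rows.append(
                    pd.DataFrame(
                        {
                            "site_id": site,
                            "variable": variable,
                            "decade": decade,
                            "month_index": np.arange(1, months_per_decade + 1),
                            "value": vals,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def _simulate_climate(cfg: SimulationConfig, species: list[str], rng) -> tuple[dict, dict]:
    """Per-species site tables with correlated variables plus change columns."""
    n_grad = max(cfg.n_variables - 2, 1) if cfg.n_variables >= 3 else cfg.n_variables
    names = [f"bio{i + 1}" for i in range(n_grad)]
    climate: dict[str, pd.DataFrame] = {}
    series: dict[str, pd.DataFrame] = {}
    rho = abs(cfg.climate_corr)
    sign = 1.0 if cfg.climate_corr >= 0 else -1.0
    for s_idx, sp in enumerate(species):
        sites = [f"{sp}_site{j + 1:02d}" for j in range(cfg.n_sites_per_species)]
        g = rng.normal(size=cfg.n_sites_per_species)
        data = {}
        for v_idx, name in enumerate(names):
            eps = rng.normal(size=cfg.n_sites_per_species)
            coef = np.sqrt(rho) * (sign**v_idx)
            data[name] = coef * g + np.sqrt(1 - rho) * eps
        table = pd.DataFrame(data, index=pd.Index(sites, name="site_id"))
        table.insert(0, "lat", rng.uniform(-60, 60, cfg.n_sites_per_species).round(4))
        table.insert(1, "lon", rng.uniform(-180, 180, cfg.n_sites_per_species).round(4))
        if cfg.n_variables >= 3:
            ms = simulate_monthly_series(sites, rng)
            change = climate_change_effect_size(ms)
            table = attach_change_variables(table.reset_index(), change).set_index("site_id")
            series[sp] = ms
        climate[sp] = table
    return climate, series


def _simulate_orthogroup_structure(cfg: SimulationConfig, species: list[str], rng):
    """Orthogroup map plus per-species ordered gene tables."""
    lo, hi = cfg.species_presence
    og_ids = [f"OG{i:07d}" for i in range(cfg.n_orthogroups)]
    orthogroups: dict[str, dict[str, list[str]]] = {}
    genes_per_species: dict[str, list[str]] = {sp: [] for sp in species}
    for og in og_ids:
        n_present = int(rng.integers(lo, hi + 1))
        present = rng.choice(species, size=n_present, replace=False)
        by_sp: dict[str, list[str]] = {}
        for sp in present:
            k = int(_truncated_geometric(rng, cfg.paralogue_geom_p, cfg.max_paralogues, 1)[0])
            ids = [f"{sp}_g{len(genes_per_species[sp]) + j + 1:06d}" for j in range(k)]
            genes_per_species[sp].extend(ids)
            by_sp[sp] = ids
        orthogroups[og] = by_sp
    gene_tables = {}
    for sp, ids in genes_per_species.items():
        starts = np.arange(len(ids)) * (cfg.gene_length + cfg.gene_gap) + cfg.gene_gap
        gene_tables[sp] = pd.DataFrame(
            {
                "gene_id": ids,
                "chrom": "chr1",
                "start": starts,  # 0-based half-open
                "end": starts + cfg.gene_length,
            }
        )
    return orthogroups, gene_tables


def simulate_gea_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete multi-species GEA study.

    Returns per-species allele-frequency matrices (with gene annotations and
    site-by-climate tables) plus the orthogroup map and the implant truth.
    Identical configs (same seed) give identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = _species_names(config.n_species)
    climate, series = _simulate_climate(config, species, rng)
    orthogroups, gene_tables = _simulate_orthogroup_structure(config, species, rng)

    n_implant = int(round(config.adaptive_fraction * config.n_orthogroups))
    og_ids = list(orthogroups)
    implanted = list(rng.choice(og_ids, size=n_implant, replace=False)) if n_implant else []
    coupled_variable = "bio1"
    truth = SyntheticTruth(
        implanted_orthogroups=set(implanted),
        coupled_variable=coupled_variable,
        adaptive_genes={sp: set() for sp in species},
    )
    for og in implanted:
        present = list(orthogroups[og])
        chosen = rng.choice(present, size=min(config.n_contributing_species, len(present)), replace=False)
        truth.contributing_species[og] = set(map(str, chosen))
        for sp in chosen:
            gene = str(rng.choice(orthogroups[og][sp]))
            truth.adaptive_genes[sp].add(gene)

    frequencies = {}
    for sp in species:
        genes = gene_tables[sp]
        env = climate[sp][coupled_variable].to_numpy(dtype=float)
        env_std = (env - env.mean()) / env.std() if env.std() > 0 else np.zeros_like(env)
        n_sites = config.n_sites_per_species
        site_effect = rng.normal(size=n_sites)  # shared across SNPs
        adaptive = truth.adaptive_genes.get(sp, set())
        n_snps = np.maximum(rng.poisson(config.n_snps_per_gene, size=len(genes)), 1)
        total = int(n_snps.sum())
        pos_parts = []
        for g_idx, row in enumerate(genes.itertuples()):
            pos_parts.append(
                np.sort(
                    rng.choice(
                        np.arange(row.start + 1, row.end + 1), size=int(n_snps[g_idx]), replace=False
                    )
                )
            )
        pos = np.concatenate(pos_parts)  # 1-based
        is_adaptive = np.repeat(genes["gene_id"].isin(adaptive).to_numpy(), n_snps)
        base = np.clip(expit(rng.normal(0.0, 1.5, size=total)), 0.01, 0.99)
        mu = logit(base)[:, None] + config.drift_sd * site_effect[None, :]
        mu[is_adaptive] += config.effect_size * env_std[None, :]
        freq = expit(mu + rng.normal(0.0, config.snp_noise_sd, size=(total, n_sites)))
        table = pd.DataFrame(freq, columns=list(climate[sp].index))
        table.insert(0, "snp_id", [f"{sp}_chr1_{p}" for p in pos])
        table.insert(1, "chrom", "chr1")
        table.insert(2, "pos", pos)
        table["mean_freq"] = freq.mean(axis=1)
        frequencies[sp] = table
    logger.info(
        "simulated %d species, %d orthogroups (%d implanted)",
        config.n_species, config.n_orthogroups, n_implant,
    )
    return SyntheticDataset(
        config=config,
        species=species,
        frequencies=frequencies,
        genes=gene_tables,
        climate=climate,
        monthly_series=series,
        orthogroups=orthogroups,
        truth=truth,
    )


def simulate_orthogroup_pvalues(
    n_orthogroups: int,
    species_counts: np.ndarray | tuple[int, int],
    n_implanted: int = 0,
    n_contributing: int = 8,
    implant_beta: tuple[float, float] = (0.1, 1.0),
    seed: int | np.random.Generator = 0,
    n_species_total: int = 25,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-orthogroup, per-species gene-level eP table.

    Non-implanted entries are i.i.d. Uniform(0, 1); in each of the
    ``n_implanted`` orthogroups, ``n_contributing`` random present species
    draw from Beta(*implant_beta*) instead (heavy mass near zero).
    ``species_counts`` is either a per-orthogroup array of species counts or
    an inclusive (lo, hi) range sampled uniformly.  Returns a tidy frame
    ``orthogroup, species, ep`` plus the implant truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(species_counts, tuple):
        lo, hi = species_counts
        counts = rng.integers(lo, hi + 1, size=n_orthogroups)
    else:
        counts = np.asarray(species_counts)
        if counts.size != n_orthogroups:
            raise ValueError("species_counts length must equal n_orthogroups")
    if counts.max() > n_species_total:
        raise ValueError("species count exceeds total species pool")
    species = np.array(_species_names(n_species_total))
    og_ids = [f"OG{i:07d}" for i in range(n_orthogroups)]
    implanted = set(
        map(str, np.random.default_rng(rng.integers(2**31)).choice(og_ids, size=n_implanted, replace=False))
    ) if n_implanted else set()
    truth = SyntheticTruth(implanted_orthogroups=implanted)
    recs_og, recs_sp, recs_ep = [], [], []
    for og, n in zip(og_ids, counts):
        present = species[np.sort(rng.choice(n_species_total, size=int(n), replace=False))]
        ep = rng.random(int(n))
        if og in implanted:
            chosen = rng.choice(int(n), size=min(n_contributing, int(n)), replace=False)
            ep[chosen] = rng.beta(*implant_beta, size=chosen.size)
            truth.contributing_species[og] = set(present[chosen])
        ep = np.clip(ep, np.finfo(float).tiny, 1.0)
        recs_og.extend([og] * int(n))
        recs_sp.extend(present)
        recs_ep.extend(ep)
    table = pd.DataFrame({"orthogroup": recs_og, "species": recs_sp, "ep": recs_ep})
    return table, truth


def simulate_gene_properties(
    orthogroups: dict[str, dict[str, list[str]]],
    n_tissues: int = 23,
    repeatability_link: float = 0.0,
    flagged: set[str] | None = None,
    reference_species: str | None = None,
    n_go_terms: int = 40,
    enriched_term: str = "GO:9999999",
    seed: int | np.random.Generator = 0,
) -> dict[str, pd.DataFrame]:
    """Expression, network, GO and duplication tables for a reference species.

    Genes of ``flagged`` orthogroups have their expression breadth and
    network-degree propensity shifted by ``repeatability_link`` (positive =
    broader expression / higher centrality, i.e. more pleiotropic) and carry
    the implanted ``enriched_term`` in the GO map.  With a zero link, flagged
    and unflagged genes are exchangeable.

    Returns a dict with keys ``expression`` (gene_id, tissue, stage,
    subtissue, tpm), ``coexpression`` (gene_a, gene_b, z), ``interactions``
    (gene_a, gene_b, score), ``go`` (gene_id, term_id) and ``duplications``
    (orthogroup_id, support, species_under_node, tips_single_genome).
    """
    if n_tissues < 2:
        raise ValueError("n_tissues must be at least 2")
    if not orthogroups:
        raise ValueError("orthogroup map is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flagged = flagged or set()
    if reference_species is None:
        reference_species = sorted({sp for m in orthogroups.values() for sp in m})[0]
    gene_og = [
        (gene, og)
        for og, by_sp in orthogroups.items()
        for gene in by_sp.get(reference_species, [])
    ]
    genes = [g for g, _ in gene_og]
    og_of = dict(gene_og)
    is_flagged = np.array([og_of[g] in flagged for g in genes])

    # --- expression: Dirichlet profile, concentration sets breadth ---------
    log_alpha = rng.normal(-0.5, 1.0, size=len(genes)) + repeatability_link * is_flagged
    alpha = np.exp(log_alpha)
    totals = np.exp(rng.normal(3.0, 1.0, size=len(genes)))
    expr_rows = []
    for i, gene in enumerate(genes):
        profile = rng.dirichlet(np.full(n_tissues, alpha[i])) * totals[i]
        for t in range(n_tissues):
            for stage in ("seedling", "mature"):
                tpm = max(profile[t] * np.exp(rng.normal(0, 0.2)), 0.0)
                expr_rows.append((gene, f"tissue{t + 1:02d}", stage, "whole", tpm))
    expression = pd.DataFrame(expr_rows, columns=["gene_id", "tissue", "stage", "subtissue", "tpm"])

    # --- networks: degree propensity shifted for flagged genes -------------
    prop = np.exp(rng.normal(0.0, 0.8, size=len(genes)) + repeatability_link * is_flagged)
    prop /= prop.sum()
    n_edges = max(3 * len(genes), 10)
    coexp, seen = [], set()
    idx = np.arange(len(genes))
    a_draw = rng.choice(idx, size=2 * n_edges, p=prop)
    b_draw = rng.choice(idx, size=2 * n_edges, p=prop)
    for a, b in zip(a_draw, b_draw):
        if a == b or (min(a, b), max(a, b)) in seen:
            continue
        seen.add((min(a, b), max(a, b)))
        if rng.random() < 0.9:
            z = 2.33 + rng.exponential(2.0)
        else:
            z = -5.0 - rng.exponential(1.0)
        coexp.append((genes[a], genes[b], z))
        if len(coexp) >= n_edges:
            break
    coexpression = pd.DataFrame(coexp, columns=["gene_a", "gene_b", "z"])
    inter = [
        (ga, gb, float(np.clip(rng.beta(2, 2) + 0.2 * (abs(z) > 4), 0, 1)))
        for ga, gb, z in coexp
    ]
    interactions = pd.DataFrame(inter, columns=["gene_a", "gene_b", "score"])

    # --- GO map: background terms everywhere, one term implanted -----------
    terms = [f"GO:{i:07d}" for i in range(1, n_go_terms + 1)]
    go_rows = []
    for i, gene in enumerate(genes):
        k = 1 + rng.poisson(2)
        for term in rng.choice(terms, size=min(k, len(terms)), replace=False):
            go_rows.append((gene, term))
        if is_flagged[i] and rng.random() < 0.8:
            go_rows.append((gene, enriched_term))
        elif rng.random() < 0.05:
            go_rows.append((gene, enriched_term))
    go = pd.DataFrame(go_rows, columns=["gene_id", "term_id"]).drop_duplicates()

    # --- duplication events -------------------------------------------------
    dup_rows = []
    for og, by_sp in orthogroups.items():
        total_paralogues = sum(len(g) for g in by_sp.values())
        n_events = rng.poisson(max(total_paralogues - len(by_sp), 0) * 0.5)
        for _ in range(n_events):
            support = float(rng.uniform(0.3, 1.0))
            n_under = int(rng.integers(1, max(len(by_sp), 2)))
            under = sorted(rng.choice(sorted(by_sp), size=min(n_under, len(by_sp)), replace=False))
            dup_rows.append(
                (og, round(support, 3), ",".join(under), int(len(under) == 1))
            )
    duplications = pd.DataFrame(
        dup_rows, columns=["orthogroup_id", "support", "species_under_node", "tips_single_genome"]
    )
    return {
        "expression": expression,
        "coexpression": coexpression,
        "interactions": interactions,
        "go": go,
        "duplications": duplications,
    }
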