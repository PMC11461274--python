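"""Order-statistic repeatability testing across species.

Given one gene-level empirical p-value (eP) per species per orthogroup, the
test asks whether low eP values cluster across species more than expected if
adaptation touched at most one species.  The procedure (PicMin):

1. Within each orthogroup and species, paralogue scores are collapsed to the
   single strongest association, Dunn-Sidak corrected for the number of
   paralogues: ``eP' = 1 - (1 - min eP)**k``.
2. Per orthogroup the n species eP values are sorted, the minimum dropped,
   and each remaining order statistic ``p_(a+1)`` is scored against the CDF
   of the a-th order statistic of n-1 uniforms, ``I_p(a, n-a)`` (regularized
   incomplete beta).  The minimum over a is Tippett-combined using a
   Dunn-Sidak correction with an *effective* number of tests that accounts
   for the correlation among order statistics.
3. Because the raw statistic is conservatively biased upward under the null,
   p-values are re-calibrated against a large simulated empirical null (one
   per species-count configuration), then Benjamini-Hochberg corrected within
   each climate variable.  Orthogroups with q below the FDR threshold are
   flagged as repeatedly associated (RAOs).

The rank of the minimising order statistic (``a_star``) estimates how many
species drive the signal; those species are attributed by taking the
``a_star + 1`` smallest collapsed eP values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betainc

logger = logging.getLogger(__name__)

__all__ = [
    "PicMinConfig",
    "EmpiricalNull",
    "dunn_sidak",
    "collapse_paralogues",
    "picmin_raw",
    "picmin_raw_matrix",
    "estimate_n_eff",
    "build_empirical_null",
    "bh_adjust",
    "bh_reject_count",
    "calibrate_and_fdr",
    "attribute_species",
    "contribution_matrices",
    "simulate_null_rao_counts",
    "permutation_enrichment",
    "leave_one_out",
    "picmin_scan",
]


def dunn_sidak(p: np.ndarray | float, k: np.ndarray | int) -> np.ndarray | float:
    """Dunn-Sidak correction ``1 - (1 - p)**k``, computed stably."""
    with np.errstate(divide="ignore"):  # p = 1 -> log1p(-1) = -inf -> result 1
        return -np.expm1(np.asarray(k, dtype=float) * np.log1p(-np.asarray(p, dtype=float)))


@dataclass
class PicMinConfig:
    """Configuration for the repeatability scan.

    Parameters
    ----------
    min_species, max_species:
        Range of species-count configurations handled (inclusive).
    null_size:
        Number of simulated null orthogroups per configuration used for
        empirical calibration.
    n_eff_sims:
        Monte-Carlo sample size for estimating the effective number of
        independent order-statistic tests per configuration.
    fdr_threshold:
        Benjamini-Hochberg q cutoff below which an orthogroup-variable pair
        counts as repeatedly associated.
    seed:
        Seed for null simulation and n_eff estimation.
    """

    min_species: int = 20
    max_species: int = 25
    null_size: int = 1_000_000
    n_eff_sims: int = 100_000
    fdr_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3 <= self.min_species <= self.max_species:
            raise ValueError("require 3 <= min_species <= max_species")
        if self.null_size < 100:
            raise ValueError("null_size too small for calibration")


def picmin_raw_matrix(eps: np.ndarray, n_eff: float) -> tuple[np.ndarray, np.ndarray]:
    """Raw repeatability p-values for a matrix of per-species eP values.

    Parameters
    ----------
    eps:
        Array of shape (m, n): m orthogroups, n species each, values in (0, 1].
    n_eff:
        Effective number of tests for the Dunn-Sidak step over the n-1 order
        statistics.

    Returns
    -------
    raw_p, a_star:
        ``raw_p[i]`` is the Tippett-combined p for row i; ``a_star[i]`` is the
        1-based rank of the minimising order statistic (ties broken toward
        the smallest rank), so the estimated number of contributing species
        is ``a_star + 1``.
    """
    eps = np.asarray(eps, dtype=float)
    if eps.ndim != 2:
        raise ValueError("eps must be 2-D (orthogroups x species)")
    m, n = eps.shape
    if n < 3:
        raise ValueError("need at least 3 species per orthogroup")
    if np.any(eps <= 0) or np.any(eps > 1):
        raise ValueError("eP values must lie in (0, 1]")
    tail = np.sort(eps, axis=1)[:, 1:]  # drop the minimum
    a = np.arange(1, n)
    # CDF of the a-th order statistic of n-1 uniforms, evaluated at p_(a+1)
    q = betainc(a[None, :], (n - a)[None, :], tail)
    a_star = np.argmin(q, axis=1)  # argmin takes the first index on ties
    p_tippett = q[np.arange(m), a_star]
    raw_p = dunn_sidak(p_tippett, n_eff)
    return np.clip(raw_p, np.finfo(float).tiny, 1.0), a_star + 1


def picmin_raw(eps: np.ndarray, n_eff: float) -> tuple[float, int]:
    """Scalar convenience wrapper around :func:`picmin_raw_matrix`."""
    raw, a_star = picmin_raw_matrix(np.asarray(eps, dtype=float)[None, :], n_eff)
    return float(raw[0]), int(a_star[0])


def estimate_n_eff(n: int, n_sims: int = 100_000, seed: int | np.random.Generator = 0) -> float:
    """Effective number of independent order-statistic tests for n species.

    Simulates null q-vectors (the n-1 beta-CDF scores of uniform eP rows),
    takes the eigenvalues of their correlation matrix and sums
    ``min(lambda_i, 1)``; the result is clipped to [1, n-1].  Order statistics
    are positively correlated, so n_eff is well below n-1.
    """
    if n_sims < 1_000:
        raise ValueError("n_sims must be at least 1000 for a stable estimate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random((n_sims, n))
    tail = np.sort(u, axis=1)[:, 1:]
    a = np.arange(1, n)
    q = betainc(a[None, :], (n - a)[None, :], tail)
    return n_eff_from_scores(q, upper=n - 1)


def n_eff_from_scores(q: np.ndarray, upper: float | None = None) -> float:
    """Effective number of tests from a matrix of per-test scores."""
    corr = np.corrcoef(q, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    n_eff = float(np.minimum(lam, 1.0).sum())
    hi = upper if upper is not None else q.shape[1]
    return float(np.clip(n_eff, 1.0, hi))


@dataclass
class EmpiricalNull:
    """Sorted null raw-p samples and n_eff, per species-count configuration."""

    sorted_null: dict[int, np.ndarray] = field(default_factory=dict)
    n_eff: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def configurations(self) -> list[int]:
        return sorted(self.sorted_null)

    def calibrate(self, raw_p: np.ndarray, n: int) -> np.ndarray:
        """Empirical p: ``(1 + #{null <= raw}) / (1 + N_null)``."""
        if n not in self.sorted_null:
            raise KeyError(f"no empirical null for configuration n={n}")
        null = self.sorted_null[n]
        counts = np.searchsorted(null, np.asarray(raw_p, dtype=float), side="right")
        return (1.0 + counts) / (1.0 + null.size)

    def save(self, path) -> None:
        arrays = {f"null_{n}": v for n, v in self.sorted_null.items()}
        arrays.update({f"neff_{n}": np.array([v]) for n, v in self.n_eff.items()})
        arrays["seed"] = np.array([self.seed])
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "EmpiricalNull":
        data = np.load(path)
        out = cls(seed=int(data["seed"][0]))
        for key in data.files:
            if key.startswith("null_"):
                out.sorted_null[int(key[5:])] = data[key]
            elif key.startswith("neff_"):
                out.n_eff[int(key[5:])] = float(data[key][0])
        return out


def build_empirical_null(
    config: PicMinConfig, chunk: int = 250_000, rng: np.random.Generator | None = None
) -> EmpiricalNull:
    """Simulate the per-configuration null distribution of raw p-values.

    For each species count n in the configured range, draws ``null_size``
    rows of i.i.d. uniform eP values and runs them through
    :func:`picmin_raw_matrix`.  Samples are stored sorted for binary-search
    calibration lookups.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    null = EmpiricalNull(seed=config.seed)
    for n in range(config.min_species, config.max_species + 1):
        null.n_eff[n] = estimate_n_eff(n, config.n_eff_sims, rng)
        parts = []
        remaining = config.null_size
        while remaining > 0:
            m = min(chunk, remaining)
            raw, _ = picmin_raw_matrix(rng.random((m, n)), null.n_eff[n])
            parts.append(raw)
            remaining -= m
        null.sorted_null[n] = np.sort(np.concatenate(parts))
        logger.info("empirical null built for n=%d (n_eff=%.2f)", n, null.n_eff[n])
    return null


# ---------------------------------------------------------------------------
# Paralogue collapse
# ---------------------------------------------------------------------------

def collapse_paralogues(gene_scores: pd.DataFrame, orthogroups: dict[str, dict[str, list[str]]]) -> pd.DataFrame:
    """Collapse per-gene eP values to one score per orthogroup and species.

    ``gene_scores`` needs columns ``species, gene_id, variable, ep_wza``.
    Within each (orthogroup, species, variable) the strongest association is
    kept and Dunn-Sidak corrected for the number of scored paralogues k:
    ``eP_collapsed = 1 - (1 - min eP)**k``.  Species with no scored paralogue
    in an orthogroup are absent from the output.

    Returns a frame with columns
    ``orthogroup, species, variable, best_gene, n_paralogues, ep_collapsed``.
    """
    membership = [
        (og, sp, gene)
        for og, by_sp in orthogroups.items()
        for sp, genes in by_sp.items()
        for gene in genes
    ]
    mem = pd.DataFrame(membership, columns=["orthogroup", "species", "gene_id"])
    merged = mem.merge(gene_scores, on=["species", "gene_id"], how="inner")
    if merged.empty:
        return pd.DataFrame(
            columns=["orthogroup", "species", "variable", "best_gene", "n_paralogues", "ep_collapsed"]
        )
    grp = merged.groupby(["orthogroup", "species", "variable"], sort=False)
    out = grp["ep_wza"].agg(["min", "size"]).reset_index()
    best = merged.loc[grp["ep_wza"].idxmin(), ["orthogroup", "species", "variable", "gene_id"]]
    out = out.merge(best, on=["orthogroup", "species", "variable"])
    out = out.rename(columns={"size": "n_paralogues", "gene_id": "best_gene"})
    out["ep_collapsed"] = dunn_sidak(out["min"].to_numpy(), out["n_paralogues"].to_numpy())
    # guard against an exact zero after correction: keep values usable downstream
    out["ep_collapsed"] = out["ep_collapsed"].clip(lower=np.finfo(float).tiny)
    return out.drop(columns=["min"])


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bh_reject_count(p: np.ndarray, alpha: float) -> int:
    """Number of BH rejections at level alpha (no q-values materialised)."""
    p = np.sort(np.asarray(p, dtype=float))
    thresh = alpha * np.arange(1, p.size + 1) / p.size
    passing = np.nonzero(p <= thresh)[0]
    return int(passing[-1] + 1) if passing.size else 0


# ---------------------------------------------------------------------------
# Scan over a collapsed table
# ---------------------------------------------------------------------------

def picmin_scan(
    collapsed: pd.DataFrame,
    null: EmpiricalNull,
    min_species: int = 20,
    fdr_threshold: float = 0.5,
) -> pd.DataFrame:
    """Run the repeatability test on a collapsed eP table.

    ``collapsed`` needs columns ``orthogroup, species, variable, ep_collapsed``
    (the output of :func:`collapse_paralogues`).  Orthogroup-variable pairs
    with fewer than ``min_species`` scored species are dropped; pairs whose
    species count has no entry in ``null`` raise.

    Returns one row per tested (orthogroup, variable):
    ``orthogroup, variable, n_species, raw_p, a_star, n_contributing,
    calibrated_p, q, rao, contributing_species``.
    """
    rows: list[pd.DataFrame] = []
    for variable, sub in collapsed.groupby("variable", sort=False):
        counts = sub.groupby("orthogroup", sort=False)["species"].size()
        tested = counts[counts >= min_species]
        if tested.empty:
            continue
        for n in sorted(tested.unique()):
            ogs = tested[tested == n].index
            block = sub[sub["orthogroup"].isin(ogs)].sort_values(["orthogroup", "species"], kind="stable")
            eps = block["ep_collapsed"].to_numpy().reshape(len(ogs), n)
            species = block["species"].to_numpy().reshape(len(ogs), n)
            if n not in null.n_eff:
                raise KeyError(f"species count n={n} outside configured null range")
            raw, a_star = picmin_raw_matrix(eps, null.n_eff[n])
            cal = null.calibrate(raw, n)
            contrib = _contributing_sets(eps, species, a_star)
            rows.append(
                pd.DataFrame(
                    {
                        "orthogroup": sorted(ogs),
                        "variable": variable,
                        "n_species": n,
                        "raw_p": raw,
                        "a_star": a_star,
                        "n_contributing": a_star + 1,
                        "calibrated_p": cal,
                        "contributing_species": contrib,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "orthogroup", "variable", "n_species", "raw_p", "a_star",
                "n_contributing", "calibrated_p", "q", "rao", "contributing_species",
            ]
        )
    res = pd.concat(rows, ignore_index=True)
    res["q"] = np.nan
    for variable, idx in res.groupby("variable", sort=False).groups.items():
        res.loc[idx, "q"] = bh_adjust(res.loc[idx, "calibrated_p"].to_numpy())
    res["rao"] = res["q"] < fdr_threshold
    return res


def _contributing_sets(eps: np.ndarray, species: np.ndarray, a_star: np.ndarray) -> list[list[str]]:
    """Species with the a_star + 1 smallest eP values per row.

    Ties across the inclusion boundary pull in every tied species, so a set
    may exceed a_star + 1.
    """
    out = []
    for i in range(eps.shape[0]):
        k = int(a_star[i]) + 1
        srt = np.sort(eps[i])
        cut = srt[k - 1]
        keep = eps[i] <= cut
        if keep.sum() > k:
            logger.debug("tie across contributing-species boundary; set enlarged to %d", keep.sum())
        out.append(sorted(species[i][keep]))
    return out


def calibrate_and_fdr(
    results: pd.DataFrame, null: EmpiricalNull, fdr_threshold: float = 0.5
) -> pd.DataFrame:
    """Attach calibrated p, per-variable BH q and the RAO flag to raw results.

    ``results`` needs columns ``orthogroup, variable, n_species, raw_p``.
    """
    res = results.copy()
    cal = np.empty(len(res))
    for n, idx in res.groupby("n_species").groups.items():
        cal[res.index.get_indexer(idx)] = null.calibrate(res.loc[idx, "raw_p"].to_numpy(), int(n))
    res["calibrated_p"] = cal
    res["q"] = np.nan
    for variable, idx in res.groupby("variable", sort=False).groups.items():
        res.loc[idx, "q"] = bh_adjust(res.loc[idx, "calibrated_p"].to_numpy())
    res["rao"] = res["q"] < fdr_threshold
    return res


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------

def attribute_species(eps: np.ndarray, species: np.ndarray, a_star: int) -> list[str]:
    """Contributing species for one orthogroup: the a_star + 1 smallest ePs."""
    return _contributing_sets(
        np.asarray(eps, dtype=float)[None, :],
        np.asarray(species, dtype=object)[None, :],
        np.asarray([a_star]),
    )[0]


def contribution_matrices(results: pd.DataFrame, species_order: list[str] | None = None):
    """Aggregate contribution of species to RAOs.

    Returns ``(by_variable, by_pair)``: the proportion of RAOs (rows with
    ``rao`` True) to which each species contributes, per climate variable,
    and the proportion to which each *pair* of species jointly contributes.
    """
    raos = results[results["rao"]]
    all_species = species_order or sorted(
        {sp for lst in results["contributing_species"] for sp in lst}
    )
    variables = sorted(results["variable"].unique())
    by_var = pd.DataFrame(0.0, index=all_species, columns=variables)
    by_pair = pd.DataFrame(0.0, index=all_species, columns=all_species)
    if raos.empty:
        return by_var, by_pair
    for variable in variables:
        sub = raos[raos["variable"] == variable]
        if sub.empty:
            continue
        for lst in sub["contributing_species"]:
            for sp in lst:
                by_var.loc[sp, variable] += 1
        by_var[variable] /= len(sub)
    n_rao = len(raos)
    for lst in raos["contributing_species"]:
        for i, sp_a in enumerate(lst):
            for sp_b in lst[i:]:
                by_pair.loc[sp_a, sp_b] += 1
                if sp_a != sp_b:
                    by_pair.loc[sp_b, sp_a] += 1
    by_pair /= n_rao
    return by_var, by_pair


# ---------------------------------------------------------------------------
# Null permutations
# ---------------------------------------------------------------------------

def simulate_null_rao_counts(
    species_counts: np.ndarray,
    n_variables: int,
    null: EmpiricalNull,
    n_reps: int,
    rng: np.random.Generator,
    fdr_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """RAO counts under the complete null, per permutation replicate.

    Each replicate draws fresh i.i.d. uniform eP values for every orthogroup
    (species counts fixed by ``species_counts``), runs the repeatability test
    for each of ``n_variables`` variables, calibrates against ``null``,
    applies BH within each variable and counts flagged orthogroup-variable
    pairs.  Returns ``(totals, uniques)``: per-replicate total counts (RAO
    duplicated across variables) and unique-orthogroup counts.
    """
    species_counts = np.asarray(species_counts)
    ns, ns_counts = np.unique(species_counts, return_counts=True)
    m_total = species_counts.size
    totals = np.empty(n_reps, dtype=int)
    uniques = np.empty(n_reps, dtype=int)
    for r in range(n_reps):
        cal_blocks = []
        for n, m in zip(ns, ns_counts):
            u = rng.random((m * n_variables, int(n)))
            raw, _ = picmin_raw_matrix(u, null.n_eff[int(n)])
            cal_blocks.append(null.calibrate(raw, int(n)).reshape(m, n_variables))
        cal = np.vstack(cal_blocks)  # (m_total, n_variables)
        total = 0
        flagged = np.zeros(m_total, dtype=bool)
        for v in range(n_variables):
            p = cal[:, v]
            k = bh_reject_count(p, fdr_threshold)
            total += k
            if k:
                cutoff = np.sort(p)[k - 1]
                flagged |= p <= cutoff
        totals[r] = total
        uniques[r] = int(flagged.sum())
    return totals, uniques


def expected_null_rao_count(
    n_orthogroups: int = 8_470,
    n_variables: int = 21,
    species_range: tuple[int, int] = (20, 25),
    n_reps: int = 200,
    null: EmpiricalNull | None = None,
    null_size: int = 1_000_000,
    fdr_threshold: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Expected number of RAOs under a complete null at full study scale.

    Draws per-orthogroup species counts uniformly from ``species_range``,
    builds (or reuses) the empirical calibration null, and runs ``n_reps``
    complete-null permutations of the test -> calibration -> per-variable BH
    pipeline, counting flagged orthogroup-variable pairs.  Returns the
    per-replicate totals plus their median — the chance expectation the
    observed RAO count is compared against.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if null is None:
        cfg = PicMinConfig(
            min_species=species_range[0],
            max_species=species_range[1],
            null_size=null_size,
            seed=int(rng.integers(2**31)),
        )
        null = build_empirical_null(cfg, rng=rng)
    counts = rng.integers(species_range[0], species_range[1] + 1, size=n_orthogroups)
    totals, uniques = simulate_null_rao_counts(
        counts, n_variables, null, n_reps, rng, fdr_threshold
    )
    return {
        "totals": totals,
        "uniques": uniques,
        "median_total": float(np.median(totals)),
        "median_unique": float(np.median(uniques)),
        "null": null,
    }


def permutation_enrichment(
    observed_count: int,
    species_counts: np.ndarray,
    n_variables: int,
    null: EmpiricalNull,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    fdr_threshold: float = 0.5,
) -> dict:
    """Compare an observed total RAO count against complete-null permutations.

    Each permutation regenerates uniform eP values for the whole orthogroup
    structure and reruns test -> calibration -> per-variable BH.  The p-value
    is ``(1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable permutation p-value floor")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals, uniques = simulate_null_rao_counts(
        species_counts, n_variables, null, n_perm, rng, fdr_threshold
    )
    p = (1.0 + np.sum(totals >= observed_count)) / (1.0 + n_perm)
    return {
        "null_totals": totals,
        "null_uniques": uniques,
        "median_total": float(np.median(totals)),
        "median_unique": float(np.median(uniques)),
        "p": float(p),
    }


def leave_one_out(
    collapsed: pd.DataFrame,
    null: EmpiricalNull,
    min_species: int = 20,
    fdr_thresholds: tuple[float, ...] = (0.5, 0.3),
) -> pd.DataFrame:
    """Drop each species in turn and rerun the full repeatability scan.

    Orthogroup-variable pairs that fall below the species floor after the
    drop are excluded from that rerun.  Returns one row per dropped species
    with RAO counts at each threshold.
    """
    species = sorted(collapsed["species"].unique())
    rows = []
    for sp in species:
        sub = collapsed[collapsed["species"] != sp]
        res = picmin_scan(sub, null, min_species=min_species, fdr_threshold=fdr_thresholds[0])
        row = {"dropped_species": sp, "n_tested": len(res)}
        for thr in fdr_thresholds:
            row[f"raos_q{thr}"] = int((res["q"] < thr).sum()) if len(res) else 0
        rows.append(row)
    return pd.DataFrame(rows)
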