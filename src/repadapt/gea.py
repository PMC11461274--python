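"""Per-SNP genotype-environment association (GEA).

Associations are non-parametric Kendall tau-b correlations between
population allele frequencies and a site-level climate variable, with no
correction for population structure.  P-values come from exact enumeration
for small tie-free samples (n <= 9) and from the tie-corrected normal
approximation otherwise.  P-values are then converted to empirical
p-values (rank / N, average ranks on ties) within each (dataset, variable)
over the SNPs assigned to genes, which is the uniformity the downstream
weighted-Z and repeatability stages rely on.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import ndtr
from scipy.stats import kendalltau, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "maf_filter",
    "kendall_gea",
    "kendall_tau_matrix",
    "empirical_p",
    "assign_snps_to_genes",
]


def maf_filter(
    freqs: pd.DataFrame,
    maf_min: float = 0.05,
    mac_min: int = 5,
    allele_counts: pd.Series | None = None,
) -> pd.DataFrame:
    """Drop SNPs with low folded mean frequency (and low count when known).

    ``freqs`` needs a ``mean_freq`` column (mean alternate-allele frequency
    across sites).  A SNP is retained when its folded frequency
    ``min(pbar, 1 - pbar)`` exceeds ``maf_min``; when per-SNP minor allele
    counts are supplied the count must additionally exceed ``mac_min``.
    """
    pbar = freqs["mean_freq"].to_numpy(dtype=float)
    folded = np.minimum(pbar, 1.0 - pbar)
    keep = folded > maf_min
    if allele_counts is not None:
        keep &= allele_counts.reindex(freqs.index).to_numpy() > mac_min
    return freqs[keep]


def _tie_term(counts: np.ndarray, fn) -> float:
    return float(sum(fn(t) for t in counts if t > 1))


def _row_tie_counts(sorted_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row sums of t(t-1)/2, t(t-1)(2t+5) and t(t-1)(t-2) over tied runs."""
    m, n = sorted_rows.shape
    eq = sorted_rows[:, 1:] == sorted_rows[:, :-1]
    n1 = np.zeros(m)
    vt = np.zeros(m)
    tt = np.zeros(m)
    rows_with_ties = np.nonzero(eq.any(axis=1))[0]
    for i in rows_with_ties:
        _, counts = np.unique(sorted_rows[i], return_counts=True)
        n1[i] = _tie_term(counts, lambda t: t * (t - 1) / 2)
        vt[i] = _tie_term(counts, lambda t: t * (t - 1) * (2 * t + 5))
        tt[i] = _tie_term(counts, lambda t: t * (t - 1) * (t - 2))
    return n1, vt, tt


def kendall_tau_matrix(freqs: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised tau-b and two-sided asymptotic p for many SNPs at once.

    ``freqs`` has shape (n_snps, n_sites); ``y`` is the climate vector.  Uses
    the tie-corrected normal approximation on the Kendall score; degenerate
    rows (constant frequency, or a constant y) get tau = 0, p = 1.
    """
    F = np.asarray(freqs, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = F.shape
    dy = np.sign(y[None, :] - y[:, None])
    dF = np.sign(F[:, None, :] - F[:, :, None])
    S = (dF * dy[None, :, :]).sum(axis=(1, 2)) / 2.0

    n0 = n * (n - 1) / 2.0
    n1x, vtx, ttx = _row_tie_counts(np.sort(F, axis=1))
    ys = np.sort(y)
    n1y = _tie_term(np.unique(ys, return_counts=True)[1], lambda t: t * (t - 1) / 2)
    vty = _tie_term(np.unique(ys, return_counts=True)[1], lambda t: t * (t - 1) * (2 * t + 5))
    tty = _tie_term(np.unique(ys, return_counts=True)[1], lambda t: t * (t - 1) * (t - 2))

    denom = np.sqrt((n0 - n1x) * (n0 - n1y))
    degenerate = (denom == 0) | (n0 == n1y)
    tau = np.zeros(m)
    np.divide(S, denom, out=tau, where=~degenerate)

    v0 = n * (n - 1) * (2 * n + 5)
    var = (v0 - vtx - vty) / 18.0
    var += n1x * (2 * n1y) / (n * (n - 1))  # sum t(t-1) = 2 * n1
    if n > 2:
        var += ttx * tty / (9.0 * n * (n - 1) * (n - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = S / np.sqrt(var)
    p = 2.0 * ndtr(-np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[degenerate] = 1.0
    tau[degenerate] = 0.0
    return tau, p, degenerate


def kendall_gea(
    freqs: pd.DataFrame,
    climate: pd.DataFrame,
    variable: str,
    site_columns: list[str] | None = None,
    min_sites: int = 5,
    exact_max_n: int = 9,
) -> pd.DataFrame | None:
    """Kendall tau GEA of every SNP against one climate variable.

    ``freqs`` carries one frequency column per site (``site_columns``, or
    every column of ``climate``'s index found in ``freqs``); ``climate`` is
    indexed by site id.  Sites missing the variable are dropped; fewer than
    ``min_sites`` usable sites skips the variable (returns None with a
    warning).  For n <= ``exact_max_n`` with no ties in either vector the
    exact enumeration p (scipy ``method="exact"``) replaces the normal
    approximation.  Returns ``snp_id, variable, kendall_tau, p_value,
    degenerate``.
    """
    values = climate[variable]
    usable = values.dropna()
    if site_columns is None:
        site_columns = [c for c in freqs.columns if c in climate.index]
    sites = [s for s in site_columns if s in usable.index]
    if len(sites) < min_sites:
        warnings.warn(
            f"variable {variable!r}: only {len(sites)} usable sites (< {min_sites}); skipped"
        )
        return None
    F = freqs[sites].to_numpy(dtype=float)
    y = usable[sites].to_numpy(dtype=float)
    tau, p, degenerate = kendall_tau_matrix(F, y)
    n = len(sites)
    if n <= exact_max_n and np.unique(y).size == n:
        for i in range(F.shape[0]):
            row = F[i]
            if np.unique(row).size == n:
                res = kendalltau(row, y, method="exact")
                tau[i], p[i] = res.statistic, res.pvalue
    return pd.DataFrame(
        {
            "snp_id": freqs["snp_id"].to_numpy(),
            "variable": variable,
            "kendall_tau": tau,
            "p_value": p,
            "degenerate": degenerate,
        }
    )


def empirical_p(p_values: np.ndarray, clamp: bool = True) -> np.ndarray:
    """Rank-based empirical p-values: rank / N with average ranks on ties.

    The largest value maps to eP = 1 under the plain convention, which the
    downstream normal-quantile transform cannot use, so values are clamped
    symmetrically into ``[1/(2N), 1 - 1/(2N)]`` (rank order preserved).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    n = p.size
    ep = rankdata(p, method="average") / n
    if clamp:
        ep = np.clip(ep, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    return ep


def assign_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, flank: int = 500
) -> pd.DataFrame:
    """Assign SNPs to every gene whose flanked interval contains them.

    ``snps`` needs ``snp_id, chrom, pos`` (1-based positions); ``genes``
    needs ``gene_id, chrom, start, end`` with 0-based half-open intervals.
    Gene intervals are extended by ``flank`` on both sides and clipped at
    the chromosome start.  SNPs inside no interval are dropped; a SNP in two
    overlapping genes yields two rows.  SNP chromosomes entirely disjoint
    from the annotation raise.
    """
    gene_chroms = set(genes["chrom"].unique())
    snp_chroms = set(snps["chrom"].unique())
    if snp_chroms and gene_chroms and not (snp_chroms & gene_chroms):
        raise ValueError(
            f"chromosome names do not match between SNPs and genes: "
            f"snps={sorted(snp_chroms)}, genes={sorted(gene_chroms)}"
        )
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        tree = IntervalTree()
        for row in sub.itertuples():
            start = max(0, int(row.start) - flank)
            end = int(row.end) + flank
            tree.addi(start, end, row.gene_id)
        trees[chrom] = tree
    out_snp, out_gene = [], []
    for row in snps.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in tree.at(int(row.pos) - 1):  # 1-based pos -> 0-based coordinate
            out_snp.append(row.snp_id)
            out_gene.append(hit.data)
    return pd.DataFrame({"snp_id": out_snp, "gene_id": out_gene})
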