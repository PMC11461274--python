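"""Gene-level weighted-Z combination of SNP empirical p-values (WZA).

Each SNP's empirical p-value is transformed to a normal quantile
``z_i = ndtri(1 - eP_i)`` and combined within a gene as

    z_raw = sum(w_i * z_i) / sqrt(sum(w_i ** 2)),

with weights proportional to the SNP's expected heterozygosity
``w_i = pbar_i * (1 - pbar_i)`` (the constant factor 2 cancels).  Because the
variance of ``z_raw`` drifts with the number of SNPs per gene in real data,
scores are re-standardised within equal-occupancy SNP-count bins (robust
location/scale: median and 1.4826*MAD) with linear interpolation between bin
centres, giving ``z_corrected`` and an upper-tail p.  When one species has
several independent datasets, per-gene p-values are merged with Fisher's
method.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import chi2

from .gea import empirical_p

logger = logging.getLogger(__name__)

__all__ = ["wza_score", "wza_scan", "wza_correct", "fisher_combine"]


def wza_score(snp_eps: np.ndarray, weights: np.ndarray) -> float:
    """Weighted-Z statistic for one gene.

    ``snp_eps`` are clamped empirical p-values in (0, 1); ``weights`` the
    per-SNP heterozygosity weights.  Invariant to SNP order and to uniform
    rescaling of the weights.
    """
    eps = np.asarray(snp_eps, dtype=float)
    w = np.asarray(weights, dtype=float)
    if eps.size == 0:
        raise ValueError("need at least one SNP")
    denom = np.sqrt((w**2).sum())
    if denom == 0:
        raise ValueError("all weights are zero")
    return float((w * ndtri(1.0 - eps)).sum() / denom)


def wza_scan(snp_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene raw WZA scores from an assigned SNP table.

    ``snp_table`` needs columns ``gene_id, ep, mean_freq`` with one row per
    (SNP, gene) assignment; SNPs shared by overlapping genes contribute to
    every gene they are assigned to.  Returns ``gene_id, n_snps, z_raw``.
    Genes whose weights are all zero are dropped with a warning.
    """
    df = snp_table.copy()
    pbar = df["mean_freq"].to_numpy(dtype=float)
    df["_w"] = pbar * (1.0 - pbar)
    df["_wz"] = df["_w"] * ndtri(1.0 - df["ep"].to_numpy(dtype=float))
    df["_w2"] = df["_w"] ** 2
    agg = df.groupby("gene_id", sort=False).agg(
        n_snps=("ep", "size"), _wz=("_wz", "sum"), _w2=("_w2", "sum")
    )
    zero = agg["_w2"] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} gene(s) dropped: all SNP weights zero")
        agg = agg[~zero]
    agg["z_raw"] = agg["_wz"] / np.sqrt(agg["_w2"])
    return agg.reset_index()[["gene_id", "n_snps", "z_raw"]]


def _robust_loc_scale(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med, mad * 1.4826


def wza_correct(
    scores: pd.DataFrame,
    n_bins: int = 25,
    min_genes: int = 200,
) -> pd.DataFrame:
    """Standardise raw scores against SNP-count-dependent null moments.

    Genes (one (species, variable) stratum at a time) are sorted by SNP
    count and split into ``n_bins`` equal-occupancy bins; each bin's robust
    location (median) and scale (1.4826*MAD) are interpolated linearly
    between bin centres (mean SNP count per bin) to give per-gene null
    moments.  Adds ``z_corrected``, upper-tail ``p`` and the within-stratum
    empirical p ``ep_wza``.

    Fewer genes than two bins' worth triggers a global-standardisation
    fallback; a zero bin MAD falls back to the global scale.
    """
    df = scores.copy()
    n = len(df)
    if n == 0:
        raise ValueError("no gene scores to correct")
    if n < min_genes:
        logger.info("only %d genes in stratum (< %d); bin estimates may be unstable", n, min_genes)
    z = df["z_raw"].to_numpy(dtype=float)
    counts = df["n_snps"].to_numpy(dtype=float)
    g_loc, g_scale = _robust_loc_scale(z)
    if g_scale == 0:
        g_scale = float(np.std(z)) or 1.0
    k = min(n_bins, n // 8)
    if k < 2:
        warnings.warn("too few genes for binned correction; global standardisation used")
        df["z_corrected"] = (z - g_loc) / g_scale
    else:
        order = np.argsort(counts, kind="stable")
        splits = np.array_split(order, k)
        centres = np.array([counts[s].mean() for s in splits])
        locs = np.empty(k)
        scales = np.empty(k)
        for i, s in enumerate(splits):
            locs[i], scales[i] = _robust_loc_scale(z[s])
            if scales[i] == 0:
                scales[i] = g_scale
        # np.interp needs increasing x; equal-occupancy centres are sorted
        loc_i = np.interp(counts, centres, locs)
        scale_i = np.interp(counts, centres, scales)
        df["z_corrected"] = (z - loc_i) / scale_i
    df["p"] = ndtr(-df["z_corrected"].to_numpy())
    df["ep_wza"] = empirical_p(df["p"].to_numpy())
    return df


def fisher_combine(dataset_ps: np.ndarray) -> float:
    """Fisher combination of k independent per-dataset p-values for a gene.

    ``X2 = -2 * sum(log p_i)`` referred to chi-square with 2k df.  Zero
    inputs are clamped to the smallest positive float with a warning.
    """
    p = np.asarray(dataset_ps, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0):
        warnings.warn("p = 0 input clamped to smallest positive representable value")
        p = np.maximum(p, np.finfo(float).tiny)
    x2 = -2.0 * float(np.log(p).sum())
    return float(chi2.sf(x2, 2 * p.size))
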