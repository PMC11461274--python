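"""Site-level climate variables and recent-climate-change effect sizes.

The analysed variables are the 19 standard bioclim summaries plus two
derived "recent change" variables: for each sampling site the monthly
maximum-temperature and precipitation series of the 1960s are compared with
those of the 2010s using a rank-sum (Mann-Whitney) test, and the
non-parametric effect size ``r = |Z_W| / sqrt(n1 + n2)`` is attached to the
site table as ``tmax_clim_change`` / ``prec_clim_change``.  The normal
approximation uses tie correction and no continuity correction; being
rank-based, r is invariant to monotone transforms of the monthly values and
symmetric in the two decades.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "BIOCLIM_VARIABLES",
    "CHANGE_VARIABLES",
    "rank_sum_effect_size",
    "climate_change_effect_size",
    "attach_change_variables",
]

BIOCLIM_VARIABLES = [f"bio{i}" for i in range(1, 20)]
CHANGE_VARIABLES = {"tmax": "tmax_clim_change", "precipitation": "prec_clim_change"}

#: temperature- vs precipitation-related variable grouping used for pooled
#: enrichment analyses (bio1-11 are temperature summaries, bio12-19 precipitation)
TEMPERATURE_GROUP = [f"bio{i}" for i in range(1, 12)] + ["tmax_clim_change"]
PRECIPITATION_GROUP = [f"bio{i}" for i in range(12, 20)] + ["prec_clim_change"]


@dataclass
class ClimateChangeResult:
    site_id: str
    variable: str
    effect_size_r: float
    n1: int
    n2: int


def rank_sum_effect_size(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Rank-sum effect size r and signed Z for two samples.

    Z is the Mann-Whitney normal-approximation statistic with tie
    correction and no continuity correction; ``r = |Z| / sqrt(n1 + n2)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two values per decade")
    pooled = np.concatenate([a, b])
    n = n1 + n2
    ranks = rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(((counts**3) - counts).sum())
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    if var_u <= 0:
        return 0.0, 0.0
    z = (u1 - mean_u) / np.sqrt(var_u)
    return float(np.abs(z) / np.sqrt(n)), float(z)


def climate_change_effect_size(series: pd.DataFrame) -> pd.DataFrame:
    """Decade-to-decade change effect size per (site, variable).

    ``series`` needs columns ``site_id, variable, decade, value`` with the
    decade labels ``1960s`` and ``2010s`` (nominally 120 monthly values
    each).  Sites missing either decade for a variable are skipped with a
    warning.  Returns ``site_id, variable, effect_size_r, n1, n2``.
    """
    rows = []
    for (site, variable), sub in series.groupby(["site_id", "variable"], sort=False):
        early = sub.loc[sub["decade"] == "1960s", "value"].to_numpy(dtype=float)
        late = sub.loc[sub["decade"] == "2010s", "value"].to_numpy(dtype=float)
        if early.size < 2 or late.size < 2:
            warnings.warn(f"site {site!r} variable {variable!r}: a decade is missing; skipped")
            continue
        if not (np.isfinite(early).all() and np.isfinite(late).all()):
            warnings.warn(f"site {site!r} variable {variable!r}: non-finite values; skipped")
            continue
        r, _ = rank_sum_effect_size(early, late)
        rows.append(
            {"site_id": site, "variable": variable, "effect_size_r": r,
             "n1": early.size, "n2": late.size}
        )
    return pd.DataFrame(rows, columns=["site_id", "variable", "effect_size_r", "n1", "n2"])


def attach_change_variables(table: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    """Add ``tmax_clim_change`` / ``prec_clim_change`` columns to a site table.

    ``table`` is indexed by (or carries a column) ``site_id``.  Sites scored
    in ``results`` receive their r; unscored sites are left missing.  Result
    site ids absent from the table raise.
    """
    out = table.copy()
    index = out["site_id"] if "site_id" in out.columns else out.index.to_series()
    known = set(index)
    unknown = sorted(set(results["site_id"]) - known) if len(results) else []
    if unknown:
        raise ValueError(f"unmatched site ids in change results: {unknown}")
    for variable, column in CHANGE_VARIABLES.items():
        sub = results[results["variable"] == variable] if len(results) else results
        if len(sub) == 0:
            continue
        if column not in out.columns:
            out[column] = np.nan
        mapping = dict(zip(sub["site_id"], sub["effect_size_r"]))
        out[column] = index.map(mapping).to_numpy()
    return out
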