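"""BestKeeper descriptive stability statistics.

BestKeeper judges candidates directly on the Cq scale: for each gene it
reports the geometric and arithmetic mean Cq, the extreme Cq values, a
dispersion SD[+-Cq] (by default the mean absolute deviation around the
arithmetic mean, as in the original tool; the classical sample SD is
available as an option), the coefficient of variation CV[%Cq], and the
same quantities transported to the expression scale as x-fold
regulation coefficients via the amplification factor E (sd_xfold =
E**sd_cq, etc.).  It then builds the BestKeeper index — the per-sample
geometric mean of all candidates' Cq values — and correlates each gene
with it (Pearson r with a two-sided t-test p-value).

Genes are ranked by ascending SD[+-Cq] (ties by CV[%Cq], then by gene
identifier); a candidate is conventionally acceptable when SD[+-Cq] < 1
and SD[+-x-fold] < 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import CqTable, EfficiencyTable, RefstabError

STAT_COLUMNS = [
    "geo_mean_cq", "arith_mean_cq", "min_cq", "max_cq",
    "sd_cq", "cv_pct_cq", "min_xfold", "max_xfold", "sd_xfold",
]


def descriptive_stats(
    table: CqTable | pd.DataFrame,
    efficiencies: EfficiencyTable | None = None,
    dispersion: str = "mad",
) -> pd.DataFrame:
    """Per-gene BestKeeper descriptive statistics (without correlations).

    ``dispersion`` selects the SD[+-Cq] estimator: ``"mad"`` (mean
    absolute deviation from the arithmetic mean, the original tool's
    definition) or ``"sd"`` (sample standard deviation, n-1).

    x-fold values are anchored at the geometric mean Cq: ``max_xfold =
    E**(max_cq - geo_mean)`` and ``min_xfold`` is reported as the negative
    reciprocal fold ``-E**(geo_mean - min_cq)`` (under-expression shown as
    a fold below -1).
    """
    if dispersion not in ("mad", "sd"):
        raise RefstabError(f"unknown dispersion estimator {dispersion!r}")
    wide = table.to_wide() if isinstance(table, CqTable) else table
    if (wide.to_numpy() <= 0).any():
        raise RefstabError("geometric mean undefined: Cq values must be > 0")
    if efficiencies is None:
        efficiencies = EfficiencyTable.constant(wide.index)
    eff = efficiencies.for_genes(wide.index)

    arr = wide.to_numpy(dtype=float)
    arith = arr.mean(axis=1)
    geo = np.exp(np.log(arr).mean(axis=1))
    if dispersion == "mad":
        sd = np.abs(arr - arith[:, None]).mean(axis=1)
    else:
        sd = arr.std(axis=1, ddof=1)
    out = pd.DataFrame(index=wide.index)
    out["geo_mean_cq"] = geo
    out["arith_mean_cq"] = arith
    out["min_cq"] = arr.min(axis=1)
    out["max_cq"] = arr.max(axis=1)
    out["sd_cq"] = sd
    out["cv_pct_cq"] = 100.0 * sd / arith
    out["min_xfold"] = -(eff.to_numpy() ** (geo - out["min_cq"].to_numpy()))
    out["max_xfold"] = eff.to_numpy() ** (out["max_cq"].to_numpy() - geo)
    out["sd_xfold"] = eff.to_numpy() ** sd
    out["efficiency"] = eff.to_numpy()
    return out


def bestkeeper_index(table: CqTable | pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean of all candidate genes' Cq values."""
    wide = table.to_wide() if isinstance(table, CqTable) else table
    if wide.shape[0] < 1:
        raise RefstabError("index needs at least one gene")
    idx = np.exp(np.log(wide.to_numpy(dtype=float)).mean(axis=0))
    return pd.Series(idx, index=wide.columns, name="bestkeeper_index")


def index_correlations(
    table: CqTable | pd.DataFrame, index: pd.Series
) -> pd.DataFrame:
    """Pearson r of each gene's Cq profile against the BestKeeper index.

    Two-sided p-values from the exact t transform with n-2 degrees of
    freedom.  Genes (or an index) with zero variance get NaN r and p,
    with a warning.
    """
    wide = table.to_wide() if isinstance(table, CqTable) else table
    if wide.shape[1] < 3:
        raise RefstabError("correlations need at least 3 samples")
    idx = index.loc[wide.columns].to_numpy(dtype=float)
    rows = {}
    idx_constant = np.ptp(idx) == 0
    for gene, row in wide.iterrows():
        vals = row.to_numpy(dtype=float)
        if idx_constant or np.ptp(vals) == 0:
            warnings.warn(
                f"zero variance for gene {gene!r} or the index; r undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            rows[gene] = (np.nan, np.nan)
        else:
            r, p = sps.pearsonr(vals, idx)
            rows[gene] = (float(r), float(p))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["r", "p_value"])
    out.index.name = "gene"
    return out


def rank_genes_bestkeeper(stats: pd.DataFrame) -> pd.DataFrame:
    """Rank by ascending (sd_cq, cv_pct_cq), ties sharing the smaller rank.

    Adds ``rank`` (competition ranking on the (sd, cv) key) and the
    ``suitable`` flag (sd_cq < 1 and sd_xfold < 2); rows come back sorted
    by (sd_cq, cv_pct_cq, gene).
    """
    keys = list(zip(stats["sd_cq"], stats["cv_pct_cq"]))
    rank = [1 + sum(other < key for other in keys) for key in keys]
    out = stats.copy()
    out["rank"] = rank
    out["suitable"] = (out["sd_cq"] < 1.0) & (out["sd_xfold"] < 2.0)
    order = sorted(out.index, key=lambda g: (out.loc[g, "sd_cq"], out.loc[g, "cv_pct_cq"], g))
    return out.loc[order]


@dataclass(frozen=True)
class BestKeeperResults:
    """Descriptive statistics, index correlations and ranking."""

    stats: pd.DataFrame           # Table-style per-gene statistics + rank + flags
    index: pd.Series              # per-sample BestKeeper index
    dispersion: str
    ranks: pd.Series

    @property
    def suitable_genes(self) -> list[str]:
        return list(self.stats.index[self.stats["suitable"]])

    def summary(self) -> pd.DataFrame:
        cols = ["rank"] + STAT_COLUMNS + ["r", "p_value", "suitable"]
        return self.stats[cols]

    def __repr__(self) -> str:
        best = self.stats.index[0]
        return (
            f"<BestKeeperResults: {len(self.stats)} genes "
            f"(dispersion={self.dispersion!r}), most stable {best} "
            f"(SD[+-Cq]={self.stats.loc[best, 'sd_cq']:.2f})>"
        )


class BestKeeper:
    """BestKeeper model for a collapsed, complete Cq table."""

    def __init__(
        self,
        table: CqTable,
        efficiencies: EfficiencyTable | None = None,
        dispersion: str = "mad",
    ):
        self.table = table if table.collapsed else table.collapse()
        self.wide = self.table.to_wide()
        self.efficiencies = efficiencies
        self.dispersion = dispersion

    def fit(self) -> BestKeeperResults:
        stats = descriptive_stats(self.wide, self.efficiencies, self.dispersion)
        index = bestkeeper_index(self.wide)
        corr = index_correlations(self.wide, index)
        stats = rank_genes_bestkeeper(stats.join(corr))
        return BestKeeperResults(
            stats=stats,
            index=index,
            dispersion=self.dispersion,
            ranks=stats["rank"],
        )
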