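"""Candidate reference-gene screening.

Two admission stages precede any stability algorithm:

1. From a genes x samples expression matrix (RPKM-like), discard genes
   with low expression (mean RPKM below a threshold, default 3) and rank
   the remainder by the coefficient of variation of their expression over
   all replicate values of all treatments.  The lower the CV, the more
   stable the gene; the n lowest-CV genes (default 9) become candidates.
2. From the Cq measurements, admit only genes whose mean Cq over all
   samples lies strictly inside the recommended window (15, 30); genes
   amplifying too late (low abundance) or too early are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CqTable, ExpressionTable, RefstabError


class UndefinedCVError(RefstabError):
    """A gene's mean expression is zero, so its CV is undefined."""


class ShortfallError(RefstabError):
    """Fewer genes pass the expression filter than were requested."""


def expression_cv(table: ExpressionTable) -> pd.Series:
    """Per-gene coefficient of variation in percent.

    ``cv_percent = 100 * sd / mean`` over all replicate values of all
    treatments, with the sample (n-1) standard deviation.
    """
    values = table.values
    if values.shape[1] < 2:
        raise RefstabError("CV needs at least 2 values per gene")
    mean = values.mean(axis=1)
    zero = mean.index[mean == 0].tolist()
    if zero:
        raise UndefinedCVError(f"zero mean expression, CV undefined for: {zero}")
    sd = values.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean
    cv.name = "cv_percent"
    return cv


def filter_low_expression(table: ExpressionTable, threshold: float = 3.0) -> list[str]:
    """Genes whose mean RPKM across all samples is at least ``threshold``.

    The boundary is inclusive: a gene sitting exactly at the threshold is
    kept.
    """
    mean = table.values.mean(axis=1)
    return list(mean.index[mean >= threshold])


def select_candidates(
    table: ExpressionTable,
    n: int = 9,
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Screen an expression matrix for the ``n`` most stable candidates.

    Returns one row per gene with columns ``mean_rpkm``, ``cv_percent``,
    ``passed_expression_filter``, ``rank`` (among passing genes, ascending
    CV, ties broken by gene identifier) and ``selected``.
    """
    mean = table.values.mean(axis=1)
    passing = filter_low_expression(table, threshold)
    if len(passing) < n:
        raise ShortfallError(
            f"only {len(passing)} gene(s) pass the expression filter; {n} requested"
        )
    # CV is reported for every gene with non-zero mean (NaN otherwise);
    # only passing genes are ranked.
    sd = table.values.std(axis=1, ddof=1)
    cv = (100.0 * sd / mean).where(mean > 0)
    order = sorted(passing, key=lambda g: (cv[g], g))
    rank = pd.Series({g: i + 1 for i, g in enumerate(order)})

    result = pd.DataFrame(index=pd.Index(sorted(table.genes), name="gene"))
    result["mean_rpkm"] = mean
    result["passed_expression_filter"] = result.index.isin(passing)
    result["cv_percent"] = cv.reindex(result.index)
    result["rank"] = rank.reindex(result.index).astype("Int64")
    result["selected"] = result["rank"].notna() & (result["rank"] <= n)
    return result


def cq_range_filter(
    table: CqTable,
    low: float = 15.0,
    high: float = 30.0,
) -> pd.DataFrame:
    """Admit genes by mean Cq strictly inside ``(low, high)``.

    Returns per-gene ``mean_cq``, ``min_cq``, ``max_cq``, ``range_cq`` and
    the boolean ``admitted``; a gene with mean Cq of exactly 30 is
    excluded (strict bounds).
    """
    work = table if table.collapsed else table.collapse()
    grouped = work.measurements.groupby("gene")["cq"]
    stats = pd.DataFrame(
        {
            "mean_cq": grouped.mean(),
            "min_cq": grouped.min(),
            "max_cq": grouped.max(),
        }
    ).loc[sorted(work.genes)]
    stats["range_cq"] = stats["max_cq"] - stats["min_cq"]
    stats["admitted"] = (stats["mean_cq"] > low) & (stats["mean_cq"] < high)
    stats.index.name = "gene"
    return stats
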