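"""Consensus ranking across the three stability algorithms.

geNorm, NormFinder and BestKeeper frequently disagree on the exact order
of candidates (they measure different things: co-variation, a variance
decomposition, raw dispersion).  A simple and widely used aggregate is
the arithmetic mean of the three competition ranks; the gene with the
lowest mean rank is the overall most stable candidate.  The minimal
number of reference genes is then re-derived from the geNorm
pairwise-variation curve evaluated under the consensus ordering.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .data import RefstabError
from .genorm import VCurve, pairwise_v_curve


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (2.335 -> 2.34), for reported mean ranks."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def competition_rank(
    scores: pd.Series,
    ascending: bool = True,
    tie_group: tuple[str, str] | None = None,
) -> pd.Series:
    """Standard competition ranking ("1, 1, 3, ...").

    Tied items share the minimum rank and the following rank skips.
    ``tie_group`` forces two items (e.g. geNorm's final pair, which the
    stepwise procedure cannot separate) to be tied at their better score.
    """
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise RefstabError("scores must be finite")
    values = scores.astype(float).copy()
    if tie_group is not None:
        a, b = tie_group
        best = min(values[a], values[b]) if ascending else max(values[a], values[b])
        values[a] = values[b] = best
    arr = values.to_numpy()
    if ascending:
        ranks = 1 + (arr[None, :] < arr[:, None]).sum(axis=1)
    else:
        ranks = 1 + (arr[None, :] > arr[:, None]).sum(axis=1)
    return pd.Series(ranks, index=scores.index, name="rank")


def aggregate_ranks(
    genorm_ranks: pd.Series,
    normfinder_ranks: pd.Series,
    bestkeeper_ranks: pd.Series,
) -> pd.DataFrame:
    """Mean-of-ranks consensus table.

    Columns: the three per-algorithm ranks, ``mean_rank`` (reported with
    half-up rounding to 2 decimals) and ``global_rank``.  Ordering uses
    the full-precision mean; exact ties are broken by the NormFinder rank
    and then by gene identifier.
    """
    sets = [set(s.index) for s in (genorm_ranks, normfinder_ranks, bestkeeper_ranks)]
    union = set.union(*sets)
    inter = set.intersection(*sets)
    if union != inter:
        raise RefstabError(
            f"gene sets disagree between algorithms; symmetric difference: "
            f"{sorted(union - inter)}"
        )
    genes = sorted(union)
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    out["genorm_rank"] = genorm_ranks.loc[genes].astype(int)
    out["normfinder_rank"] = normfinder_ranks.loc[genes].astype(int)
    out["bestkeeper_rank"] = bestkeeper_ranks.loc[genes].astype(int)
    exact = out[["genorm_rank", "normfinder_rank", "bestkeeper_rank"]].mean(axis=1)
    out["mean_rank"] = [round_half_up(x, 2) for x in exact]
    order = sorted(
        genes, key=lambda g: (exact[g], out.loc[g, "normfinder_rank"], g)
    )
    out = out.loc[order]
    out["global_rank"] = range(1, len(genes) + 1)
    return out


def optimal_reference_count(
    q: pd.DataFrame,
    consensus_order: list[str],
    v_threshold: float = 0.15,
) -> tuple[int | None, VCurve]:
    """Minimal number of reference genes under the consensus ordering.

    Recomputes the geNorm V curve introducing genes in consensus order
    and returns the smallest n with V_{n,n+1} <= ``v_threshold`` (None
    when no n passes), together with the curve itself.
    """
    if len(consensus_order) < 3:
        raise RefstabError("optimal reference count needs at least 3 genes")
    curve = pairwise_v_curve(q, list(consensus_order), v_threshold, label="consensus")
    return curve.n_optimal, curve
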