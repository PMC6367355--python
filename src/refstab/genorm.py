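"""geNorm expression-stability analysis.

The geNorm measure of stability for gene *i* is the mean M_i of the
pairwise variations V_ik — the sample standard deviations, over samples,
of the log2 expression ratios of gene *i* against every other candidate
*k*.  Because a ratio of two genes cancels any per-sample loading effect,
a low M means the gene co-varies tightly with the rest of the panel.

Genes are ranked by stepwise exclusion: the gene with the highest M is
removed, M is recomputed on the remaining set, and so on until two genes
remain; these share rank 1 (their mutual M cannot distinguish them).

The minimal number of reference genes is read off the pairwise-variation
curve V_{n,n+1}: the standard deviation of the log2 ratio of
normalization factors built from the top n and top n+1 genes.  Once
V_{n,n+1} falls under a cut-off (conventionally 0.15), adding the
(n+1)-th gene no longer changes the normalization materially.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CqTable, EfficiencyTable, RefstabError


def relative_quantities(
    table: CqTable | pd.DataFrame,
    efficiencies: EfficiencyTable | None = None,
) -> pd.DataFrame:
    """Genes x samples matrix of relative quantities Q.

    Q_ij = E_i ** (min_j' Cq_ij' - Cq_ij): each gene's best (lowest) Cq
    maps to 1 and every other sample to its efficiency-corrected fraction
    of that maximum, so Q_ij is in (0, 1].
    """
    wide = table.to_wide() if isinstance(table, CqTable) else table
    if efficiencies is None:
        efficiencies = EfficiencyTable.constant(wide.index)
    eff = efficiencies.for_genes(wide.index).to_numpy()[:, None]
    cq = wide.to_numpy(dtype=float)
    q = eff ** (cq.min(axis=1, keepdims=True) - cq)
    return pd.DataFrame(q, index=wide.index, columns=wide.columns)


def pairwise_variation_matrix(q: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix V with V_ik = sd over samples of log2(Q_i / Q_k).

    Sample standard deviation (n-1 denominator); V_ii = 0.
    """
    if q.shape[0] < 2 or q.shape[1] < 2:
        raise RefstabError("pairwise variation needs >= 2 genes and >= 2 samples")
    logq = np.log2(q.to_numpy(dtype=float))
    k = logq.shape[0]
    v = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        v[i, j] = v[j, i] = np.std(logq[i] - logq[j], ddof=1)
    return pd.DataFrame(v, index=q.index, columns=q.index)


def m_values(v: pd.DataFrame, active: list[str] | None = None) -> pd.Series:
    """Average stability M_i = mean of V_ik over the other active genes."""
    genes = list(v.index) if active is None else list(active)
    if len(genes) < 2:
        raise RefstabError("M values need at least 2 active genes")
    sub = v.loc[genes, genes]
    m = sub.sum(axis=1) / (len(genes) - 1)
    m.name = "M"
    return m


def normalization_factors(
    q: pd.DataFrame, ordered_genes: list[str], n: int
) -> pd.Series:
    """Per-sample NF_n: geometric mean of the top-n genes' Q values."""
    if not 1 <= n <= len(ordered_genes):
        raise RefstabError(f"n={n} out of range 1..{len(ordered_genes)}")
    top = q.loc[ordered_genes[:n]].to_numpy(dtype=float)
    nf = np.exp(np.log(top).mean(axis=0))
    return pd.Series(nf, index=q.columns, name=f"NF_{n}")


@dataclass(frozen=True)
class VCurve:
    """Pairwise-variation curve V_{n,n+1} under a given gene ordering."""

    ordered_genes: list[str]
    values: pd.Series          # indexed by n, for n = 2..k-1
    threshold: float = 0.15
    label: str = "total"

    @property
    def n_optimal(self) -> int | None:
        """Smallest n with V_{n,n+1} <= threshold, or None if none passes."""
        passing = self.values.index[self.values <= self.threshold]
        return int(passing.min()) if len(passing) else None


def pairwise_v_curve(
    q: pd.DataFrame,
    ordered_genes: list[str],
    v_threshold: float = 0.15,
    samples: list[str] | None = None,
    label: str = "total",
) -> VCurve:
    """V_{n,n+1} for n = 2..k-1 under ``ordered_genes``.

    When ``samples`` restricts the analysis to a subset, Q is re-anchored
    within the subset (each gene's maximum over the retained samples maps
    back to 1), which is equivalent to recomputing relative quantities
    from the subset's Cq values.
    """
    if len(ordered_genes) < 3:
        raise RefstabError("the V curve needs at least 3 genes")
    work = q
    if samples is not None:
        if len(samples) < 2:
            raise RefstabError("subset must retain at least 2 samples")
        work = q[list(samples)]
        work = work.div(work.max(axis=1), axis=0)
    values = {}
    for n in range(2, len(ordered_genes)):
        nf_n = normalization_factors(work, ordered_genes, n)
        nf_n1 = normalization_factors(work, ordered_genes, n + 1)
        values[n] = float(np.std(np.log2(nf_n / nf_n1), ddof=1))
    series = pd.Series(values, name="V")
    series.index.name = "n"
    return VCurve(list(ordered_genes), series, v_threshold, label)


@dataclass(frozen=True)
class GeNormResults:
    """Outcome of the stepwise geNorm ranking.

    ``m_at_exclusion`` records each gene's M at the moment it was removed
    (the final pair shares its mutual pairwise variation); ``ranks`` are
    competition-style, with both final-pair genes at rank 1 and the next
    gene at rank 3.
    """

    q: pd.DataFrame
    efficiencies: pd.Series
    pairwise_v: pd.DataFrame
    m_full_panel: pd.Series
    exclusion_order: list[str]
    m_at_exclusion: pd.Series
    final_pair: tuple[str, str]
    stability_order: list[str]
    ranks: pd.Series
    m_threshold: float
    v_curve: VCurve

    @property
    def unstable_genes(self) -> list[str]:
        """Genes whose M at exclusion exceeds the M threshold."""
        flagged = self.m_at_exclusion[self.m_at_exclusion > self.m_threshold]
        return [g for g in self.stability_order if g in flagged.index]

    def v_curve_for(self, samples: list[str], label: str) -> VCurve:
        return pairwise_v_curve(
            self.q, self.stability_order, self.v_curve.threshold, samples, label
        )

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(index=pd.Index(self.stability_order, name="gene"))
        out["rank"] = self.ranks.loc[out.index]
        out["M"] = self.m_at_exclusion.loc[out.index]
        out["unstable"] = out["M"] > self.m_threshold
        return out

    def __repr__(self) -> str:
        pair = " / ".join(self.final_pair)
        return (
            f"<GeNormResults: {len(self.stability_order)} genes, best pair {pair} "
            f"(M={self.m_at_exclusion[self.final_pair[0]]:.3f}), "
            f"n*={self.v_curve.n_optimal}>"
        )


class GeNorm:
    """geNorm stability model for a collapsed, complete Cq table.

    Parameters
    ----------
    table : CqTable
        Collapsed (or collapsible) Cq table; the matrix must be complete.
    efficiencies : EfficiencyTable, optional
        Per-gene amplification factors; defaults to 2.0 for every gene.
    """

    def __init__(self, table: CqTable, efficiencies: EfficiencyTable | None = None):
        self.table = table if table.collapsed else table.collapse()
        wide = self.table.to_wide()
        if wide.shape[0] < 3:
            raise RefstabError("geNorm ranking needs at least 3 genes")
        if efficiencies is None:
            efficiencies = EfficiencyTable.constant(wide.index)
        self.efficiencies = efficiencies.for_genes(wide.index)
        self.q = relative_quantities(wide, efficiencies)

    def fit(self, m_threshold: float = 0.5, v_threshold: float = 0.15) -> GeNormResults:
        """Run the stepwise exclusion and the V curve."""
        v = pairwise_variation_matrix(self.q)
        m_full = m_values(v)

        active = list(self.q.index)
        exclusion_order: list[str] = []
        m_at_exclusion: dict[str, float] = {}
        while len(active) > 2:
            m = m_values(v, active)
            worst = m.max()
            # ties: remove the lexicographically later gene id first
            candidates = sorted(m.index[m == worst])
            gene = candidates[-1]
            m_at_exclusion[gene] = float(m[gene])
            exclusion_order.append(gene)
            active.remove(gene)

        pair = tuple(sorted(active))
        shared_m = float(v.loc[pair[0], pair[1]])
        m_at_exclusion[pair[0]] = shared_m
        m_at_exclusion[pair[1]] = shared_m

        stability_order = list(pair) + list(reversed(exclusion_order))
        ranks = pd.Series(
            [1, 1] + list(range(3, len(stability_order) + 1)),
            index=stability_order,
            name="rank",
        )
        curve = pairwise_v_curve(self.q, stability_order, v_threshold)
        return GeNormResults(
            q=self.q,
            efficiencies=self.efficiencies,
            pairwise_v=v,
            m_full_panel=m_full,
            exclusion_order=exclusion_order,
            m_at_exclusion=pd.Series(m_at_exclusion, name="M"),
            final_pair=pair,
            stability_order=stability_order,
            ranks=ranks,
            m_threshold=m_threshold,
            v_curve=curve,
        )


def rank_genes_genorm(
    q: pd.DataFrame, m_threshold: float = 0.5, v_threshold: float = 0.15
) -> GeNormResults:
    """Functional entry point on a precomputed relative-quantity matrix."""
    model = GeNorm.__new__(GeNorm)
    model.table = None
    model.q = q
    model.efficiencies = pd.Series(np.nan, index=q.index)
    if q.shape[0] < 3:
        raise RefstabError("geNorm ranking needs at least 3 genes")
    return GeNorm.fit(model, m_threshold, v_threshold)
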