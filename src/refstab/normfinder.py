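"""NormFinder model-based stability estimation.

The model treats the (log-scale) expression signal y of gene *i* in
sample *j* of experimental group *g* as

    y_igj = alpha_ig + mu_gj + eps_igj,   eps ~ N(0, sigma^2_ig)

where mu_gj is a shared per-sample effect (loading) and alpha_ig carries
both the gene's baseline and a gene-by-group interaction d_ig (systematic
regulation in group g).  A good reference gene has both a small
intragroup variance sigma^2_ig and a small |d_ig|.

Estimation is by the method of moments:

* two-way centering within each group removes the gene baseline and the
  sample effect; the residual mean squares v_ig are de-biased across
  genes (the centering mixes a 1/k share of every other gene's variance
  into each residual) to give sigma^2 estimates, truncated at zero;
* group deviations d_ig are centered across genes within group and
  across groups within gene; their dispersion in excess of the sampling
  noise estimates the interaction variance gamma^2, and each d_ig is
  linearly shrunk toward zero by gamma^2 / (gamma^2 + sigma^2_ig/n_g);
* the stability value rho_i averages, over groups, the shrunken |d|
  plus the posterior spread of d.  With a single group rho reduces to
  the intragroup standard deviation.

Cq values are already on a log2-like scale, so y = -Cq (the sign is
irrelevant to every variance-based quantity and is chosen so that larger
y means more transcript).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CqTable, DesignError, RefstabError


def log_expression(
    table: CqTable, group_by: tuple[str, ...] = ("group", "timepoint")
) -> dict[str, pd.DataFrame]:
    """Split the collapsed Cq matrix into per-group y = -Cq matrices.

    Groups are the distinct combinations of the requested annotation
    columns (default treatment x timepoint); every group needs at least
    two samples for its intragroup variance to exist.
    """
    work = table if table.collapsed else table.collapse()
    wide = work.to_wide()
    ann = work.annotations.set_index("sample_id")
    for col in group_by:
        if col not in ann.columns:
            raise DesignError(f"unknown grouping column {col!r}")
    labels = ann[list(group_by)].astype(str).agg(":".join, axis=1)
    y: dict[str, pd.DataFrame] = {}
    for label in sorted(labels.unique()):
        cols = labels.index[labels == label]
        if len(cols) < 2:
            raise DesignError(
                f"group {label!r} has {len(cols)} sample(s); intragroup variance "
                "needs at least 2"
            )
        y[label] = -wide[list(cols)]
    return y


def intragroup_variances(
    y: dict[str, pd.DataFrame], truncate: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residual mean squares v_ig and de-biased variance estimates.

    Within each group, residuals are r_igj = y_igj - mean_j - mean_i +
    grand mean; v_ig = sum_j r^2 / (n_g - 1).  Because centering across k
    genes leaks variance between genes, E[v_ig] = sigma^2_ig (1 - 2/k) +
    (sum_i sigma^2_ig) / k^2, and the unbiased estimate is

        sigma^2_ig = max(0, (v_ig - vbar_g / (k-1)) * k / (k-2))

    which requires k >= 3 genes.  ``truncate=False`` skips the max(0, .)
    and returns the raw unbiased moment estimate: truncation is the right
    thing for downstream use (it keeps the shrinkage weights real) but
    introduces an upward bias for genes whose true variance is near zero,
    so bias checks should run untruncated.
    """
    genes = next(iter(y.values())).index
    k = len(genes)
    if k < 3:
        raise RefstabError("intragroup variance de-biasing needs at least 3 genes")
    v = {}
    sigma2 = {}
    for label, frame in y.items():
        arr = frame.to_numpy(dtype=float)
        n_g = arr.shape[1]
        resid = (
            arr
            - arr.mean(axis=1, keepdims=True)
            - arr.mean(axis=0, keepdims=True)
            + arr.mean()
        )
        v_g = (resid**2).sum(axis=1) / (n_g - 1)
        v[label] = v_g
        raw = (v_g - v_g.mean() / (k - 1)) * k / (k - 2)
        sigma2[label] = np.maximum(0.0, raw) if truncate else raw
    v_df = pd.DataFrame(v, index=genes)
    s_df = pd.DataFrame(sigma2, index=genes)
    return v_df, s_df


def intergroup_variation(
    y: dict[str, pd.DataFrame], sigma2: pd.DataFrame
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Gene-by-group deviations d_ig, gamma^2 and the shrunken deviations.

    d_ig is the group mean of gene i relative to the group's overall
    level, centered across groups so that a gene's average deviation is
    zero; gamma^2 is the moment estimate of the interaction variance
    (truncated at 0), and d is shrunk by gamma^2 / (gamma^2 + sigma^2/n).
    """
    labels = list(y.keys())
    if len(labels) < 2:
        raise DesignError("intergroup variation needs at least 2 groups")
    genes = sigma2.index
    k = len(genes)
    n_g = pd.Series({label: y[label].shape[1] for label in labels})
    z = pd.DataFrame(
        {label: y[label].mean(axis=1) - y[label].to_numpy().mean() for label in labels},
        index=genes,
    )
    d = z.sub(z.mean(axis=1), axis=0)
    L = len(labels)
    u = sigma2 / n_g  # per-cell sampling variance of d's ingredients
    gamma2 = max(
        0.0,
        float((d.to_numpy() ** 2).sum() / ((k - 1) * (L - 1)) - u.to_numpy().mean()),
    )
    denom = gamma2 + u
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(denom.to_numpy() > 0, gamma2 / denom.to_numpy(), 0.0)
    d_shrunk = d * factor
    return d, gamma2, d_shrunk


@dataclass(frozen=True)
class NormFinderResults:
    """Per-gene stability values and the fitted variance components."""

    rho: pd.Series                 # stability value, lower = more stable
    ranks: pd.Series               # competition ranks, ascending rho
    v: pd.DataFrame                # residual mean squares (genes x groups)
    sigma2: pd.DataFrame           # de-biased intragroup variances
    d: pd.DataFrame | None         # intergroup deviations (None if single group)
    d_shrunk: pd.DataFrame | None
    gamma2: float | None
    group_sizes: pd.Series
    grouping: tuple[str, ...]
    single_group: bool

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.rho.sort_values().index)
        out.index.name = "gene"
        out["rank"] = self.ranks.loc[out.index]
        out["stability"] = self.rho.loc[out.index]
        out["mean_intragroup_sd"] = np.sqrt(self.sigma2.loc[out.index]).mean(axis=1)
        if self.d is not None:
            out["max_abs_d"] = self.d.loc[out.index].abs().max(axis=1)
        return out

    def __repr__(self) -> str:
        best = self.rho.idxmin()
        mode = "single-group" if self.single_group else f"{len(self.group_sizes)} groups"
        return (
            f"<NormFinderResults: {len(self.rho)} genes, {mode}, "
            f"best {best} (rho={self.rho[best]:.3f})>"
        )


class NormFinder:
    """NormFinder stability model for a collapsed, complete Cq table.

    Parameters
    ----------
    table : CqTable
    group_by : tuple of annotation column names
        Defines the experimental groups (default treatment x timepoint).
    """

    def __init__(
        self, table: CqTable, group_by: tuple[str, ...] = ("group", "timepoint")
    ):
        self.table = table if table.collapsed else table.collapse()
        self.group_by = tuple(group_by)
        self.y = log_expression(self.table, self.group_by)

    def fit(self) -> NormFinderResults:
        v, sigma2 = intragroup_variances(self.y)
        group_sizes = pd.Series({g: frame.shape[1] for g, frame in self.y.items()})
        single = len(self.y) < 2
        if single:
            rho = np.sqrt(sigma2.iloc[:, 0])
            d = d_shrunk = None
            gamma2 = None
        else:
            d, gamma2, d_shrunk = intergroup_variation(self.y, sigma2)
            u = sigma2 / group_sizes
            with np.errstate(invalid="ignore", divide="ignore"):
                post_var = np.where(
                    (gamma2 + u.to_numpy()) > 0,
                    gamma2 * u.to_numpy() / (gamma2 + u.to_numpy()),
                    0.0,
                )
            s = np.sqrt(post_var)
            rho = (d_shrunk.abs().to_numpy() + s).mean(axis=1)
            rho = pd.Series(rho, index=sigma2.index)
        rho = rho.rename("stability")
        from .consensus import competition_rank

        ranks = competition_rank(rho, ascending=True)
        return NormFinderResults(
            rho=rho,
            ranks=ranks,
            v=v,
            sigma2=sigma2,
            d=d,
            d_shrunk=d_shrunk,
            gamma2=gamma2,
            group_sizes=group_sizes,
            grouping=self.group_by,
            single_group=single,
        )


def stability_values(
    table: CqTable, group_by: tuple[str, ...] = ("group", "timepoint")
) -> NormFinderResults:
    """Functional entry point: fit NormFinder on a Cq table."""
    return NormFinder(table, group_by).fit()
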