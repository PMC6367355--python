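"""Efficiency estimation and efficiency-corrected relative quantification.

A standard curve regresses mean Cq on log10(template amount) over a
dilution series; the amplification factor is E = 10**(-1/slope) (slope
-3.3219 corresponds to perfect doubling, E = 2, i.e. 100% efficiency).

Relative expression of a target gene against one or two reference genes
follows the efficiency-corrected ddCq model: with dCq = Cq(sample) -
Cq(calibrator),

    ratio = E_target**(-dCq_target) / E_ref**(-dCq_ref)

For a pair of reference genes the combined reference Cq at each sample
is the geometric mean of the two genes' Cq values and the combined
efficiency the arithmetic mean of the two amplification factors (an
alternative mode instead combines the two genes' relative quantities by
geometric mean).  Group differences are assessed with a two-sample
Student t-test on per-biological-replicate ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import CqTable, EfficiencyTable, MissingDataError, RefstabError


class ImplausibleSeriesError(RefstabError):
    """The dilution-series slope is not consistent with PCR amplification."""


@dataclass(frozen=True)
class DilutionSeries:
    """Cq readings over known relative template amounts for one gene."""

    gene: str
    points: pd.DataFrame  # columns: amount, cq (replicates as repeated rows)

    def __post_init__(self):
        pts = self.points.reset_index(drop=True)
        for col in ("amount", "cq"):
            if col not in pts.columns:
                raise RefstabError(f"dilution series needs column {col!r}")
        if (pts["amount"] <= 0).any():
            raise RefstabError("template amounts must be strictly positive")
        if pts["amount"].nunique() < 3:
            raise RefstabError("dilution series needs at least 3 distinct levels")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class EfficiencyFit:
    """Standard-curve fit: slope, amplification factor, percent, r^2."""

    gene: str
    slope: float
    efficiency: float
    percent: float
    r_squared: float


def amplification_efficiency(series: DilutionSeries) -> EfficiencyFit:
    """Estimate E = 10**(-1/slope) from an ordinary least-squares fit.

    The regression uses the mean Cq per dilution level against
    log10(amount).  A non-negative or very shallow slope (|slope| < 1)
    cannot come from exponential amplification and raises
    :class:`ImplausibleSeriesError`.
    """
    means = series.points.groupby("amount")["cq"].mean()
    fit = sps.linregress(np.log10(means.index.to_numpy(dtype=float)),
                         means.to_numpy(dtype=float))
    slope = float(fit.slope)
    if slope >= 0 or abs(slope) < 1:
        raise ImplausibleSeriesError(
            f"slope {slope:.3f} is implausible for a PCR standard curve"
        )
    e = 10.0 ** (-1.0 / slope)
    return EfficiencyFit(
        gene=series.gene,
        slope=slope,
        efficiency=e,
        percent=(e - 1.0) * 100.0,
        r_squared=float(fit.rvalue**2),
    )


@dataclass(frozen=True)
class RelativeExpressionResult:
    """Per-sample efficiency-corrected expression ratios for one target."""

    target: str
    references: tuple[str, ...]
    calibrator: str
    mode: str
    table: pd.DataFrame  # per sample: cq_target, cq_reference, dcq_*, ddcq, ratio

    @property
    def ratios(self) -> pd.Series:
        return self.table["ratio"]

    def __repr__(self) -> str:
        refs = "+".join(self.references)
        return (
            f"<RelativeExpressionResult: {self.target} vs {refs}, "
            f"calibrator {self.calibrator}, {len(self.table)} samples>"
        )


def relative_expression(
    table: CqTable,
    target: str,
    references: list[str] | tuple[str, ...] | str,
    efficiencies: EfficiencyTable | None = None,
    calibrator: str | None = None,
    mode: str = "cq-geomean",
) -> RelativeExpressionResult:
    """Efficiency-corrected relative expression (E**-ddCq model).

    ``references`` may name one or two genes.  With two, the default
    ``mode="cq-geomean"`` combines them by the geometric mean of their Cq
    values and the arithmetic mean of their efficiencies;
    ``mode="quantity-geomean"`` instead combines the per-gene relative
    quantities E**(-dCq) by geometric mean.
    """
    if isinstance(references, str):
        references = (references,)
    references = tuple(references)
    if not 1 <= len(references) <= 2:
        raise RefstabError("1 or 2 reference genes are supported")
    if mode not in ("cq-geomean", "quantity-geomean"):
        raise RefstabError(f"unknown dual-reference mode {mode!r}")
    work = table if table.collapsed else table.collapse()
    wide = work.to_wide()
    for gene in (target, *references):
        if gene not in wide.index:
            raise MissingDataError(f"gene {gene!r} absent from the Cq table")
    if efficiencies is None:
        efficiencies = EfficiencyTable.constant(wide.index)
    eff = efficiencies.for_genes([target, *references])
    if calibrator is None or calibrator not in wide.columns:
        raise MissingDataError(f"calibrator sample {calibrator!r} has no Cq data")

    cq_t = wide.loc[target]
    dcq_t = cq_t - cq_t[calibrator]
    e_t = float(eff[target])

    if len(references) == 1:
        ref = references[0]
        cq_r = wide.loc[ref]
        e_r = float(eff[ref])
        dcq_r = cq_r - cq_r[calibrator]
        ref_quantity = e_r ** (-dcq_r)
    else:
        r1, r2 = references
        e_r = float((eff[r1] + eff[r2]) / 2.0)
        cq_r = np.sqrt(wide.loc[r1] * wide.loc[r2])
        dcq_r = cq_r - cq_r[calibrator]
        if mode == "cq-geomean":
            ref_quantity = e_r ** (-dcq_r)
        else:
            q1 = float(eff[r1]) ** (-(wide.loc[r1] - wide.loc[r1][calibrator]))
            q2 = float(eff[r2]) ** (-(wide.loc[r2] - wide.loc[r2][calibrator]))
            ref_quantity = np.sqrt(q1 * q2)

    ratio = e_t ** (-dcq_t) / ref_quantity
    out = pd.DataFrame(
        {
            "cq_target": cq_t,
            "cq_reference": cq_r,
            "dcq_target": dcq_t,
            "dcq_reference": dcq_r,
            "ddcq": dcq_t - dcq_r,
            "ratio": ratio,
        }
    )
    out.index.name = "sample_id"
    return RelativeExpressionResult(
        target=target,
        references=references,
        calibrator=calibrator,
        mode=mode,
        table=out,
    )


def significance_stars(p: float) -> str:
    """'**' for p < 0.01, '*' for p < 0.05, '' otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    result: RelativeExpressionResult | pd.Series,
    group_a: list[str],
    group_b: list[str],
    equal_var: bool = True,
) -> tuple[float, float, str]:
    """Two-sample t-test on per-biological-replicate expression ratios.

    Classical Student (equal variance) by default; ``equal_var=False``
    gives Welch.  Returns (t, p, stars).
    """
    ratios = result.ratios if isinstance(result, RelativeExpressionResult) else result
    a = ratios.loc[list(group_a)].to_numpy(dtype=float)
    b = ratios.loc[list(group_b)].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise RefstabError("each group needs at least 2 biological replicates")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), significance_stars(float(p))
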