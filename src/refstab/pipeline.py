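"""End-to-end orchestration: screen -> Cq filter -> three algorithms ->
consensus -> minimal reference count.

Every stage writes one delimited file into the output directory plus a
machine-readable ``summary.json``; all numbers in the summary are
recomputable from the stage files.  Threshold defaults follow common
practice for reference-gene work: RPKM filter 3, admissible mean Cq in
(15, 30), geNorm instability flag at M > 0.5, pairwise-variation cut-off
0.15.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bestkeeper as bk
from . import consensus as cns
from . import genorm as gn
from . import normfinder as nf
from . import screening as scr
from .data import (
    CqTable,
    EfficiencyTable,
    RefstabError,
    read_cq_table,
    read_efficiency_table,
    read_expression_table,
)

logger = logging.getLogger("refstab")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and modes for :func:`run_pipeline`."""

    cq_path: str
    out_dir: str
    sample_sheet: str | None = None
    expression_path: str | None = None
    expression_sample_sheet: str | None = None
    efficiency_path: str | None = None
    delimiter: str = ","
    rpkm_threshold: float = 3.0
    n_candidates: int = 9
    cq_low: float = 15.0
    cq_high: float = 30.0
    m_threshold: float = 0.5
    v_threshold: float = 0.15
    group_by: tuple[str, ...] = ("group", "timepoint")
    dispersion: str = "mad"
    #: name -> (groups or None, timepoints or None); None uses an automatic
    #: set: total plus one subset per timepoint.
    subsets: dict[str, tuple[list[str] | None, list[str] | None]] | None = None

    def __post_init__(self):
        import math

        for name in ("rpkm_threshold", "cq_low", "cq_high", "m_threshold", "v_threshold"):
            if not math.isfinite(float(getattr(self, name))):
                raise RefstabError(f"threshold {name} must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "group_by" in raw and isinstance(raw["group_by"], list):
            raw["group_by"] = tuple(raw["group_by"])
        return cls(**raw)

    def validate_paths(self) -> None:
        paths = [self.cq_path, self.sample_sheet, self.expression_path,
                 self.expression_sample_sheet, self.efficiency_path]
        missing = [p for p in paths if p is not None and not Path(p).exists()]
        if missing:
            raise RefstabError(f"input path(s) do not exist: {missing}")


def _default_subsets(table: CqTable):
    subsets = {"total": (None, None)}
    for tp in sorted(table.annotations["timepoint"].unique()):
        subsets[str(tp)] = (None, [tp])
    return subsets


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write the report bundle.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sep = config.delimiter
    summary: dict = {"config": _jsonable(dataclasses.asdict(config))}

    # -- optional screening stage ---------------------------------------
    if config.expression_path is not None:
        expr = read_expression_table(
            config.expression_path, config.expression_sample_sheet, sep
        )
        screen = scr.select_candidates(expr, config.n_candidates, config.rpkm_threshold)
        screen.to_csv(out / "screening.csv", sep=sep)
        selected = list(screen.index[screen["selected"]])
        logger.info("screening: %d/%d genes pass RPKM >= %g; selected %s",
                    int(screen["passed_expression_filter"].sum()), len(screen),
                    config.rpkm_threshold, selected)
        summary["screening"] = {
            "n_genes": len(screen),
            "n_passing": int(screen["passed_expression_filter"].sum()),
            "selected": selected,
        }

    # -- Cq input and range filter --------------------------------------
    table = read_cq_table(config.cq_path, config.sample_sheet, sep)
    collapsed = table.collapse()
    cq_stats = scr.cq_range_filter(collapsed, config.cq_low, config.cq_high)
    cq_stats.to_csv(out / "cq_filter.csv", sep=sep)
    admitted = list(cq_stats.index[cq_stats["admitted"]])
    excluded = list(cq_stats.index[~cq_stats["admitted"]])
    if excluded:
        logger.info("Cq filter: excluded %s (mean Cq outside (%g, %g))",
                    excluded, config.cq_low, config.cq_high)
    if len(admitted) < 3:
        raise RefstabError("fewer than 3 genes admitted by the Cq range filter")
    panel = CqTable(
        collapsed.measurements[collapsed.measurements["gene"].isin(admitted)].reset_index(drop=True),
        collapsed.annotations,
        collapsed=True,
    )
    summary["cq_filter"] = {"admitted": admitted, "excluded": excluded}

    eff = (
        read_efficiency_table(config.efficiency_path, sep)
        if config.efficiency_path
        else None
    )

    # -- three stability algorithms -------------------------------------
    genorm_res = gn.GeNorm(panel, eff).fit(config.m_threshold, config.v_threshold)
    genorm_res.summary().to_csv(out / "genorm.csv", sep=sep)
    logger.info("geNorm: best pair %s (M=%.3f); flagged unstable: %s",
                "/".join(genorm_res.final_pair),
                genorm_res.m_at_exclusion[genorm_res.final_pair[0]],
                genorm_res.unstable_genes)

    normfinder_res = nf.NormFinder(panel, config.group_by).fit()
    normfinder_res.summary().to_csv(out / "normfinder.csv", sep=sep)

    bestkeeper_res = bk.BestKeeper(panel, eff, config.dispersion).fit()
    bestkeeper_res.summary().to_csv(out / "bestkeeper.csv", sep=sep)

    # -- consensus and minimal reference count --------------------------
    consensus = cns.aggregate_ranks(
        genorm_res.ranks, normfinder_res.ranks, bestkeeper_res.ranks
    )
    consensus.to_csv(out / "consensus.csv", sep=sep)
    order = list(consensus.index)
    n_star, curve = cns.optimal_reference_count(
        genorm_res.q, order, config.v_threshold
    )

    # V curves: geNorm ordering per subset + consensus ordering
    subsets = config.subsets if config.subsets is not None else _default_subsets(panel)
    curves = {"consensus": curve}
    for label, (groups, timepoints) in subsets.items():
        sub = panel.subset(groups=groups, timepoints=timepoints)
        curves[label] = genorm_res.v_curve_for(sub.samples, label)
    curve_frame = pd.DataFrame(
        {label: c.values for label, c in curves.items()}
    )
    curve_frame.index.name = "n"
    curve_frame.to_csv(out / "v_curves.csv", sep=sep)

    summary.update(
        {
            "genorm": {
                "final_pair": list(genorm_res.final_pair),
                "best_pair_m": float(genorm_res.m_at_exclusion[genorm_res.final_pair[0]]),
                "ranks": {g: int(r) for g, r in genorm_res.ranks.items()},
                "unstable": genorm_res.unstable_genes,
            },
            "normfinder": {
                "grouping": list(normfinder_res.grouping),
                "stability": {g: float(v) for g, v in normfinder_res.rho.items()},
                "ranks": {g: int(r) for g, r in normfinder_res.ranks.items()},
            },
            "bestkeeper": {
                "dispersion": bestkeeper_res.dispersion,
                "ranks": {g: int(r) for g, r in bestkeeper_res.ranks.items()},
                "suitable": bestkeeper_res.suitable_genes,
            },
            "consensus": {
                "order": order,
                "mean_ranks": {g: float(m) for g, m in consensus["mean_rank"].items()},
                "n_optimal": n_star,
                "v_curves": {
                    label: {int(n): float(v) for n, v in c.values.items()}
                    for label, c in curves.items()
                },
            },
        }
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("consensus: top gene %s; minimal reference count n*=%s",
                order[0], n_star)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
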