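"""Core data containers and delimited-text I/O.

The universal input of every stability algorithm is a tidy table of
quantification-cycle (Cq) measurements annotated with the experimental
design (treatment group, timepoint, biological replicate, technical
replicate).  Expression screening additionally consumes a genes x samples
abundance matrix (RPKM-like units) with a companion sample sheet, and
quantification consumes a per-gene amplification-efficiency table.

All tables are plain pandas objects wrapped in small dataclasses that
enforce the invariants the downstream algorithms rely on (uniqueness of
measurement keys, completeness of the collapsed matrix, positivity of
Cq values and efficiencies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["sample_id", "group", "timepoint", "bio_rep"]
MEASUREMENT_COLUMNS = ["sample_id", "gene", "tech_rep", "cq"]
LONG_COLUMNS = ["sample_id", "gene", "group", "timepoint", "bio_rep", "tech_rep", "cq"]

#: Accepted field delimiters for all delimited-text readers/writers.
DIALECTS = (",", "\t", ";")


class RefstabError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RefstabError):
    """A file does not conform to the documented external interface."""


class ParseError(FormatError):
    """A value could not be parsed; carries the offending line numbers."""

    def __init__(self, message: str, lines: Sequence[int] = ()):
        self.lines = list(lines)
        if self.lines:
            message = f"{message} (line(s) {', '.join(map(str, self.lines))})"
        super().__init__(message)


class DesignError(RefstabError):
    """The experimental design annotation is inconsistent or unusable."""


class MissingDataError(RefstabError):
    """Required measurements are absent."""


class IncompleteMatrixError(RefstabError):
    """The collapsed Cq matrix has missing (sample, gene) cells.

    geNorm and NormFinder assume a complete matrix; missing cells are a
    hard error rather than silently imputed.
    """

    def __init__(self, missing: Sequence[tuple]):
        self.missing = list(missing)
        preview = ", ".join(f"({s}, {g})" for s, g in self.missing[:5])
        more = "" if len(self.missing) <= 5 else f" and {len(self.missing) - 5} more"
        super().__init__(
            f"Cq matrix is incomplete: {len(self.missing)} missing cell(s): {preview}{more}"
        )


def _check_delimiter(delimiter: str) -> str:
    if delimiter not in DIALECTS:
        raise FormatError(
            f"unsupported delimiter {delimiter!r}; accepted: comma, tab, semicolon"
        )
    return delimiter


@dataclass(frozen=True)
class CqTable:
    """Tidy Cq measurements plus per-sample design annotation.

    Parameters
    ----------
    measurements : DataFrame
        Columns ``sample_id, gene, tech_rep, cq`` (uncollapsed) or
        ``sample_id, gene, cq`` (collapsed).
    annotations : DataFrame
        Columns ``sample_id, group, timepoint, bio_rep``; one row per sample.
    collapsed : bool
        True once technical replicates have been averaged.
    """

    measurements: pd.DataFrame
    annotations: pd.DataFrame
    collapsed: bool = False

    def __post_init__(self):
        ann = self.annotations.reset_index(drop=True)
        for col in ANNOTATION_COLUMNS:
            if col not in ann.columns:
                raise FormatError(f"sample annotation is missing column {col!r}")
        if ann["sample_id"].duplicated().any():
            dups = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicated sample_id(s) in annotation: {dups}")
        if (ann["group"].astype(str).str.len() == 0).any() or ann["group"].isna().any():
            raise DesignError("every sample must carry a non-empty group label")

        meas = self.measurements.reset_index(drop=True)
        needed = ["sample_id", "gene", "cq"] if self.collapsed else MEASUREMENT_COLUMNS
        for col in needed:
            if col not in meas.columns:
                raise FormatError(f"measurement table is missing column {col!r}")
        cq = pd.to_numeric(meas["cq"], errors="coerce")
        bad = meas.index[~np.isfinite(cq)].tolist()
        if bad:
            raise ParseError("non-finite Cq value(s)", [i + 1 for i in bad])
        if (cq <= 0).any():
            raise ParseError(
                "Cq values must be > 0",
                [i + 1 for i in meas.index[cq <= 0].tolist()],
            )
        key = ["sample_id", "gene"] + ([] if self.collapsed else ["tech_rep"])
        if meas.duplicated(subset=key).any():
            dups = meas.loc[meas.duplicated(subset=key), key].to_records(index=False)
            raise FormatError(
                f"duplicated measurement key(s) {key}: {list(dups)[:5]}"
            )
        unknown = set(meas["sample_id"]) - set(ann["sample_id"])
        if unknown:
            raise DesignError(f"measurements reference unannotated sample(s): {sorted(unknown)}")
        object.__setattr__(self, "measurements", meas.assign(cq=cq.astype(float)))
        object.__setattr__(self, "annotations", ann)

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return sorted(self.measurements["gene"].unique())

    @property
    def samples(self) -> list[str]:
        return list(self.annotations["sample_id"])

    def __len__(self) -> int:
        return len(self.measurements)

    # -- transformations -------------------------------------------------
    def collapse(self) -> "CqTable":
        """Average technical replicates; see :func:`collapse_technical_replicates`."""
        return collapse_technical_replicates(self)

    def missing_cells(self) -> list[tuple[str, str]]:
        """See :func:`validate_complete_matrix`."""
        return validate_complete_matrix(self)

    def to_wide(self) -> pd.DataFrame:
        """Collapsed genes x samples Cq matrix.

        Raises :class:`IncompleteMatrixError` when any (sample, gene) cell
        is missing, since the stability algorithms assume complete data.
        """
        table = self if self.collapsed else self.collapse()
        missing = table.missing_cells()
        if missing:
            raise IncompleteMatrixError(missing)
        wide = table.measurements.pivot(index="gene", columns="sample_id", values="cq")
        return wide.loc[sorted(wide.index), table.samples]

    def subset(
        self,
        groups: Iterable[str] | None = None,
        timepoints: Iterable[str] | None = None,
        samples: Iterable[str] | None = None,
    ) -> "CqTable":
        """Restrict to samples matching the given design filters."""
        ann = self.annotations
        keep = pd.Series(True, index=ann.index)
        if groups is not None:
            keep &= ann["group"].isin(list(groups))
        if timepoints is not None:
            keep &= ann["timepoint"].isin(list(timepoints))
        if samples is not None:
            keep &= ann["sample_id"].isin(list(samples))
        ann = ann[keep]
        if ann.empty:
            raise DesignError("subset filter matches no samples")
        meas = self.measurements[self.measurements["sample_id"].isin(ann["sample_id"])]
        return CqTable(meas.reset_index(drop=True), ann.reset_index(drop=True), self.collapsed)

    # -- I/O --------------------------------------------------------------
    def write(
        self,
        path: str | Path,
        sample_sheet: str | Path | None = None,
        delimiter: str = ",",
    ) -> None:
        """Write the table back to delimited text (round-trip safe)."""
        _check_delimiter(delimiter)
        if sample_sheet is not None:
            self.measurements.to_csv(path, sep=delimiter, index=False)
            self.annotations.to_csv(sample_sheet, sep=delimiter, index=False)
        else:
            merged = self.measurements.merge(self.annotations, on="sample_id")
            cols = [c for c in LONG_COLUMNS if c in merged.columns]
            merged[cols].to_csv(path, sep=delimiter, index=False)


def read_cq_table(
    path: str | Path,
    sample_sheet: str | Path | None = None,
    delimiter: str = ",",
) -> CqTable:
    """Read a long-format Cq file, optionally with a companion sample sheet.

    Without a sample sheet the file must carry the full design inline
    (columns ``sample_id, gene, group, timepoint, bio_rep, tech_rep, cq``);
    with one, the measurement file needs only
    ``sample_id, gene, tech_rep, cq``.
    """
    _check_delimiter(delimiter)
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    raw.columns = [c.strip() for c in raw.columns]

    if sample_sheet is not None:
        needed = MEASUREMENT_COLUMNS
    else:
        needed = LONG_COLUMNS
    missing_cols = [c for c in needed if c not in raw.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required column(s) {missing_cols}")

    cq = pd.to_numeric(raw["cq"], errors="coerce")
    bad = raw.index[cq.isna()].tolist()
    if bad:
        # +2: header line plus 1-based indexing
        raise ParseError(f"{path}: non-numeric Cq value(s)", [i + 2 for i in bad])

    if sample_sheet is not None:
        ann = pd.read_csv(sample_sheet, sep=delimiter, dtype=str)
        ann.columns = [c.strip() for c in ann.columns]
        miss = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
        if miss:
            raise FormatError(f"{sample_sheet}: missing required column(s) {miss}")
        ann = ann[ANNOTATION_COLUMNS].copy()
    else:
        ann = raw[ANNOTATION_COLUMNS].drop_duplicates("sample_id").reset_index(drop=True)

    ann["bio_rep"] = _parse_positive_int(ann["bio_rep"], "bio_rep", str(path))
    meas = raw[["sample_id", "gene", "tech_rep"]].copy()
    meas["tech_rep"] = _parse_positive_int(meas["tech_rep"], "tech_rep", str(path))
    meas["cq"] = cq.astype(float)
    return CqTable(meas, ann, collapsed=False)


def _parse_positive_int(series: pd.Series, name: str, origin: str) -> pd.Series:
    values = pd.to_numeric(series, errors="coerce")
    bad = series.index[values.isna() | (values < 1) | (values % 1 != 0)].tolist()
    if bad:
        raise ParseError(f"{origin}: column {name!r} must hold positive integers",
                         [i + 2 for i in bad])
    return values.astype(int)


def collapse_technical_replicates(table: CqTable) -> CqTable:
    """Average technical replicates to one Cq per (sample, gene).

    The arithmetic mean of Cq equals the geometric mean of the underlying
    template quantities (Cq is log-scale); no outlier rejection is applied.
    """
    if table.collapsed:
        raise RefstabError("table is already collapsed")
    grouped = (
        table.measurements.groupby(["sample_id", "gene"], sort=False)["cq"]
        .mean()
        .reset_index()
    )
    if grouped["cq"].isna().any():
        raise MissingDataError("a (sample, gene) combination has no technical replicates")
    return CqTable(grouped, table.annotations, collapsed=True)


def validate_complete_matrix(table: CqTable) -> list[tuple[str, str]]:
    """List the missing (sample, gene) cells of a collapsed table.

    Returns an empty list iff the matrix is complete.
    """
    work = table if table.collapsed else table.collapse()
    genes = work.genes
    present = set(zip(work.measurements["sample_id"], work.measurements["gene"]))
    missing = [
        (s, g)
        for s in work.samples
        for g in genes
        if (s, g) not in present
    ]
    return missing


def ntc_flag(
    ntc_cq: float | None,
    min_template_cq: float,
    margin: float = 9.4,
) -> bool:
    """Flag a no-template-control amplification as potential contamination.

    A late NTC signal at least ``margin`` cycles beyond the earliest
    template Cq is ignored (typical practice treats ~10 cycles as
    background); the default margin of 9.4 keeps a signal 9.45 cycles out
    in the "ignore" region.
    """
    if not np.isfinite(min_template_cq):
        raise RefstabError("min_template_cq must be finite")
    if ntc_cq is None or (isinstance(ntc_cq, float) and math.isnan(ntc_cq)):
        return False
    return (ntc_cq - min_template_cq) < margin


# ---------------------------------------------------------------------------
# Expression matrix (screening input)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTable:
    """Genes x samples abundance matrix (RPKM-like, non-negative)."""

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self):
        vals = self.values
        ann = self.annotations.reset_index(drop=True)
        for col in ANNOTATION_COLUMNS:
            if col not in ann.columns:
                raise FormatError(f"sample sheet is missing column {col!r}")
        if ann["sample_id"].duplicated().any():
            raise DesignError("duplicated sample_id in sample sheet")
        if set(vals.columns) != set(ann["sample_id"]):
            raise DesignError(
                "expression matrix columns and sample sheet sample_ids disagree"
            )
        arr = vals.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ParseError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise ParseError("expression values must be non-negative")
        object.__setattr__(self, "values", vals.astype(float)[list(ann["sample_id"])])
        object.__setattr__(self, "annotations", ann)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path, sample_sheet, delimiter: str = ",") -> None:
        _check_delimiter(delimiter)
        out = self.values.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep=delimiter, index=False)
        self.annotations.to_csv(sample_sheet, sep=delimiter, index=False)


def read_expression_table(
    path: str | Path,
    sample_sheet: str | Path,
    delimiter: str = ",",
) -> ExpressionTable:
    """Read a genes-as-rows expression matrix plus companion sample sheet."""
    _check_delimiter(delimiter)
    raw = pd.read_csv(path, sep=delimiter)
    if raw.columns[0] != "gene":
        raise FormatError(f"{path}: first column must be 'gene'")
    values = raw.set_index("gene")
    ann = pd.read_csv(sample_sheet, sep=delimiter, dtype=str)
    ann.columns = [c.strip() for c in ann.columns]
    miss = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if miss:
        raise FormatError(f"{sample_sheet}: missing required column(s) {miss}")
    ann["bio_rep"] = _parse_positive_int(ann["bio_rep"], "bio_rep", str(sample_sheet))
    return ExpressionTable(values, ann)


# ---------------------------------------------------------------------------
# Amplification efficiencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EfficiencyTable:
    """Per-gene amplification factor E, with 1 < E <= 2.2.

    E = 2 is perfect doubling per cycle (100% efficiency); percent
    efficiency is (E - 1) x 100.
    """

    efficiencies: pd.Series

    def __post_init__(self):
        eff = self.efficiencies.astype(float)
        if eff.index.duplicated().any():
            raise FormatError("duplicated gene in efficiency table")
        if ((eff <= 1.0) | (eff > 2.2)).any():
            bad = eff[(eff <= 1.0) | (eff > 2.2)]
            raise FormatError(
                f"amplification factors must lie in (1, 2.2]; offending: {dict(bad)}"
            )
        object.__setattr__(self, "efficiencies", eff)

    @classmethod
    def constant(cls, genes: Iterable[str], value: float = 2.0) -> "EfficiencyTable":
        genes = list(genes)
        return cls(pd.Series([value] * len(genes), index=genes, dtype=float))

    def for_genes(self, genes: Iterable[str]) -> pd.Series:
        genes = list(genes)
        missing = [g for g in genes if g not in self.efficiencies.index]
        if missing:
            raise MissingDataError(f"no efficiency for gene(s): {missing}")
        return self.efficiencies.loc[genes]

    @property
    def percent(self) -> pd.Series:
        return (self.efficiencies - 1.0) * 100.0

    def write(self, path, delimiter: str = ",") -> None:
        _check_delimiter(delimiter)
        pd.DataFrame(
            {"gene": self.efficiencies.index, "efficiency": self.efficiencies.values}
        ).to_csv(path, sep=delimiter, index=False)


def read_efficiency_table(path: str | Path, delimiter: str = ",") -> EfficiencyTable:
    """Read a two-column gene/efficiency file.

    An optional ``percent`` column, when present, must be consistent with
    the amplification factor to within 0.1.
    """
    _check_delimiter(delimiter)
    raw = pd.read_csv(path, sep=delimiter)
    for col in ("gene", "efficiency"):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    eff = pd.Series(raw["efficiency"].to_numpy(dtype=float), index=raw["gene"])
    table = EfficiencyTable(eff)
    if "percent" in raw.columns:
        implied = (eff.to_numpy() - 1.0) * 100.0
        stated = raw["percent"].to_numpy(dtype=float)
        # percentage points; 0.1 tolerance
        if np.any(np.abs(implied - stated) > 0.1 + 1e-12):
            raise FormatError(f"{path}: percent column inconsistent with efficiency")
    return table
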