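"""Domain containers and table I/O.

Every table the pipeline touches is plain text: TSV with a mandatory header
row for library/count/expression/RPPA/result tables, CSV for plate-reader
and qPCR cycle-threshold tables. Decimal point is ".", encoding UTF-8.
Gene and sample labels are opaque, case-sensitive strings.

The containers here are thin validated wrappers around pandas objects; all
science lives in :mod:`erktools.screen`, :mod:`erktools.scan` and
:mod:`erktools.viability`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("erktools")

#: Reserved gene label carried by non-targeting control guides.
CONTROL_GENE = "CONTROL"

_FLOAT_FMT = "%.12g"  # >= 10 significant digits for lossless-enough round trips


def configure_logging(quiet: bool = False) -> None:
    """Route package logs to stderr at INFO (WARNING with ``quiet``)."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.WARNING if quiet else logging.INFO)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuideLibrary:
    """Maps each sgRNA to its target gene; control guides are flagged.

    ``frame`` columns: guide_id, gene, sequence (optional, may be empty),
    is_control (bool). Control guides carry the reserved gene label
    :data:`CONTROL_GENE`.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"guide_id", "gene", "is_control"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"guide library missing columns: {sorted(missing)}")
        dup = self.frame["guide_id"][self.frame["guide_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate guide_id: {dup.iloc[0]!r}")
        if (self.frame["gene"].astype(str).str.len() == 0).any():
            raise ValueError("every guide needs a non-empty gene label")
        bad = self.frame["is_control"] & (self.frame["gene"] != CONTROL_GENE)
        if bad.any():
            raise ValueError(
                f"control guides must carry gene label {CONTROL_GENE!r}; "
                f"offender: {self.frame.loc[bad, 'guide_id'].iloc[0]!r}"
            )

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.frame["guide_id"])

    def gene_of(self) -> pd.Series:
        """guide_id -> gene mapping."""
        return self.frame.set_index("guide_id")["gene"]


@dataclass(frozen=True)
class ScreenCountMatrix:
    """Raw integer sgRNA read counts, guides x samples.

    One column (``reference_sample``) holds the plasmid-library counts that
    every screen sample is compared against.
    """

    counts: pd.DataFrame
    reference_sample: str

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("guide and sample labels must be unique")
        if self.reference_sample not in self.counts.columns:
            raise ValueError(
                f"reference sample {self.reference_sample!r} not among samples "
                f"{list(self.counts.columns)}"
            )
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise ValueError("counts must be non-negative integers")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def guide_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass(frozen=True)
class ExpressionTable:
    """Gene expression matrix, genes x samples, RSEM-like non-negative units."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("gene and sample labels must be unique")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample boolean mutation flags (plus optional ``tissue`` label).

    ``frame`` is indexed by sample_id; every non-``tissue`` column is a
    boolean flag named after the mutated gene (EGFR, KRAS, ...).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValueError("annotated sample_ids must be unique")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def mutation_mask(self, predicate: str) -> pd.Series:
        """Boolean mask for samples mutant in ANY gene of ``predicate``.

        ``predicate`` is a ``|``-separated list of flag columns, e.g.
        ``"EGFR|KRAS"``.
        """
        genes = [g.strip() for g in predicate.split("|") if g.strip()]
        missing = [g for g in genes if g not in self.frame.columns]
        if missing:
            raise KeyError(f"unknown mutation flags: {missing}")
        mask = pd.Series(False, index=self.frame.index)
        for g in genes:
            mask |= self.frame[g].astype(bool)
        return mask


@dataclass(frozen=True)
class RPPATable:
    """Phospho-protein levels, markers x samples, replicate-base-normalized."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("marker and sample labels must be unique")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("RPPA values must be finite")


@dataclass(frozen=True)
class PlateReadings:
    """Long-format plate-reader fluorescence signals.

    Columns: cell_line, condition, dose (µM), replicate, signal, and an
    optional timepoint (days). Replicate indices are unique within each
    (cell_line, condition, dose, timepoint) well group.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cell_line", "condition", "dose", "replicate", "signal"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"plate readings missing columns: {sorted(missing)}")
        if not np.all(np.isfinite(self.frame["signal"].to_numpy(dtype=float))):
            raise ValueError("signals must be finite")
        if (self.frame["dose"].to_numpy(dtype=float) < 0).any():
            raise ValueError("doses must be non-negative")
        keys = ["cell_line", "condition", "dose", "replicate"]
        if "timepoint" in self.frame.columns:
            keys.append("timepoint")
        if self.frame.duplicated(subset=keys).any():
            raise ValueError("replicate indices must be unique within a well group")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_guide_library(path: str | Path) -> GuideLibrary:
    """Read a guide→gene TSV (columns guide_id, gene [, sequence, is_control]).

    Unknown columns are ignored with a logged warning; duplicate guide_ids and
    missing mandatory columns are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("guide_id", "gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    known = {"guide_id", "gene", "sequence", "is_control"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)
    out = pd.DataFrame({"guide_id": df["guide_id"], "gene": df["gene"]})
    out["sequence"] = df["sequence"] if "sequence" in df.columns else ""
    if "is_control" in df.columns:
        out["is_control"] = df["is_control"].str.lower().isin(["true", "1", "yes"])
    else:
        out["is_control"] = out["gene"] == CONTROL_GENE
    return GuideLibrary(out)


def read_count_matrix(path: str | Path, reference_sample: str) -> ScreenCountMatrix:
    """Read a guides x samples count TSV; first column is guide_id.

    Any non-integral cell is a hard error naming its row and column, as is a
    ``reference_sample`` absent from the header.
    """
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "guide_id"
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            guide = df.index[bad.to_numpy()][0]
            raise ValueError(
                f"{path}: non-integer count at guide {guide!r}, sample {col!r}: "
                f"{df.loc[guide, col]!r}"
            )
    return ScreenCountMatrix(df.astype(np.int64), reference_sample)


def read_expression_table(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "gene"
    return ExpressionTable(df.astype(float))


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "sample_id"
    for col in df.columns:
        if col != "tissue":
            if df[col].dtype == object:
                df[col] = df[col].astype(str).str.lower().isin(["true", "1", "yes"])
            else:
                df[col] = df[col].astype(bool)
    return SampleAnnotation(df)


def read_rppa_table(path: str | Path) -> RPPATable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "marker"
    return RPPATable(df.astype(float))


def read_plate_readings(path: str | Path) -> PlateReadings:
    df = pd.read_csv(path, comment="#")
    return PlateReadings(df)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR cycle-threshold CSV with columns gene, condition, replicate, ct."""
    df = pd.read_csv(path, comment="#")
    required = {"gene", "condition", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_results_table(
    table: pd.DataFrame,
    path: str | Path,
    comments: list[str] | None = None,
    index: bool = False,
) -> None:
    """Write a result table as TSV, floats at 12 significant digits.

    Optional ``comments`` lines are prefixed with ``#`` above the header so a
    round-trip read skips them; ``write_results_table`` then
    :func:`read_results_table` reproduces labels exactly and numeric values
    to better than 1e-9 relative error.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, index=index)


def read_results_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
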