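"""Shared domain types and TSV plumbing.

Expression values throughout the package are log2-scale normalized
intensities (the GC-RMA convention).  Operations that need the linear
scale state their own ``2**x`` transform; the matrix itself never does.
Gene identifiers are opaque strings — probe-set or symbol, the package
does not care — and missing values are rejected rather than imputed.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExposureAnnotation",
    "CohortAnnotation",
    "MarkerPanel",
    "Direction",
    "Arm",
    "Status",
    "PrfPipeError",
    "IdentifierError",
    "ParseError",
    "FormatError",
    "AlignmentError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_tsv",
    "align_annotation",
]


class PrfPipeError(Exception):
    """Base class for package errors."""


class IdentifierError(PrfPipeError):
    """Duplicate or otherwise invalid gene/sample identifiers."""


class ParseError(PrfPipeError):
    """A cell in a data file could not be parsed."""


class FormatError(PrfPipeError):
    """Structurally malformed file or degenerate matrix."""


class AlignmentError(PrfPipeError):
    """Matrix and annotation do not describe the same samples."""


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"

    def flipped(self) -> "Direction":
        return Direction.DOWN if self is Direction.UP else Direction.UP


class Arm(str, enum.Enum):
    CONTROL = "control"
    SUBSTANCE = "substance"
    AQE = "aqe"


class Status(str, enum.Enum):
    NS = "NS"
    SMK = "SMK"
    COPD = "COPD"


# Decimal places used by write_expression_tsv; chosen so that float64
# round-trips value-exactly through repr-style shortest text.
_TSV_FLOAT_FORMAT = "%.17g"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene × sample grid of normalized log2 intensities.

    Parameters
    ----------
    gene_ids : sequence of unique strings, one per row.
    sample_ids : sequence of unique strings, one per column.
    values : 2-D float array, shape ``(len(gene_ids), len(sample_ids))``,
        all finite.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __init__(self, gene_ids: Sequence[str], sample_ids: Sequence[str], values) -> None:
        gene_ids = tuple(str(g) for g in gene_ids)
        sample_ids = tuple(str(s) for s in sample_ids)
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2 or arr.shape != (len(gene_ids), len(sample_ids)):
            raise FormatError(
                f"values shape {arr.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise IdentifierError("duplicate gene identifiers")
        if len(set(sample_ids)) != len(sample_ids):
            raise IdentifierError("duplicate sample identifiers")
        if not np.all(np.isfinite(arr)):
            raise FormatError("matrix contains non-finite values")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "values", arr)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = []
        for g in gene_ids:
            if g not in lookup:
                raise IdentifierError(f"gene {g!r} not in matrix")
            idx.append(lookup[g])
        return np.asarray(idx, dtype=int)

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = []
        for s in sample_ids:
            if s not in lookup:
                raise IdentifierError(f"sample {s!r} not in matrix")
            idx.append(lookup[s])
        return np.asarray(idx, dtype=int)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(list(gene_ids), self.sample_ids, self.values[idx, :])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_index(sample_ids)
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class ExposureAnnotation:
    """One exposure-study sample: arm, substance, dose, time, replicate."""

    sample_id: str
    arm: Arm
    substance: str = ""
    dose_level: str | float | None = None  # "low"/"high" for substances, cigarettes/L for aqe
    time_h: float | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.arm is Arm.CONTROL:
            if self.substance or self.dose_level is not None:
                raise FormatError(
                    f"control sample {self.sample_id!r} must have no substance/dose"
                )
        if self.time_h is not None and self.time_h not in (4, 24):
            raise FormatError(f"time_h must be 4 or 24, got {self.time_h}")
        if self.replicate < 1:
            raise FormatError("replicate must be a positive integer")


@dataclass(frozen=True)
class CohortAnnotation:
    """One cohort subject: NS/SMK/COPD status with age and pack-years."""

    sample_id: str
    status: Status
    age: float | None = None
    pack_years: float | None = None
    study: str = ""

    def __post_init__(self) -> None:
        if self.pack_years is not None and self.pack_years < 0:
            raise FormatError("pack_years must be non-negative")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered set of (gene_id, direction) marker entries."""

    entries: tuple[tuple[str, Direction], ...]

    def __init__(self, entries: Iterable[tuple[str, Direction | str]]) -> None:
        norm = tuple((str(g), Direction(d)) for g, d in entries)
        ids = [g for g, _ in norm]
        if len(set(ids)) != len(ids):
            raise IdentifierError("duplicate gene in marker panel")
        object.__setattr__(self, "entries", norm)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    @property
    def directions(self) -> dict[str, Direction]:
        return dict(self.entries)

    def genes(self, direction: Direction | None = None) -> tuple[str, ...]:
        if direction is None:
            return self.gene_ids
        return tuple(g for g, d in self.entries if d is direction)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.directions

    def __iter__(self):
        return iter(self.entries)

    def to_records(self) -> list[dict]:
        return [{"gene_id": g, "direction": d.value} for g, d in self.entries]

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "MarkerPanel":
        return cls((r["gene_id"], Direction(r["direction"])) for r in records)


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a gene × sample TSV (first column gene id, header of sample ids).

    Raises
    ------
    IdentifierError on duplicate ids, ParseError naming the offending cell
    on non-numeric entries, FormatError on ragged rows.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise FormatError(f"{path}: header has no sample columns")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        gene = fields[0]
        row = []
        for col, cell in zip(sample_ids, fields[1:]):
            try:
                row.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at gene {gene!r}, sample {col!r}"
                ) from None
        gene_ids.append(gene)
        rows.append(row)
    if not gene_ids:
        raise FormatError(f"{path}: no gene rows")
    values = np.array(rows, dtype=float)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ParseError(
            f"{path}: non-finite value at gene {gene_ids[bad[0]]!r}, sample {sample_ids[bad[1]]!r}"
        )
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix in the format read_expression_tsv expects.

    Floats are written with ``%.17g`` (shortest exact repr), so a
    write/read round-trip reproduces the matrix bit-for-value.
    """
    if matrix.n_genes == 0:
        raise FormatError("refusing to write a matrix with no genes")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            cells = "\t".join(_TSV_FLOAT_FORMAT % v for v in row)
            fh.write(f"{gene}\t{cells}\n")


_EXPOSURE_COLUMNS = ["sample_id", "arm", "substance", "dose_level", "time_h", "replicate"]
_COHORT_COLUMNS = ["sample_id", "status", "age", "pack_years", "study"]


def annotation_to_frame(annotations: Sequence[ExposureAnnotation | CohortAnnotation]) -> pd.DataFrame:
    if not annotations:
        raise FormatError("empty annotation table")
    records = [dataclasses.asdict(a) for a in annotations]
    df = pd.DataFrame.from_records(records)
    for col in ("arm", "status"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: v.value if isinstance(v, enum.Enum) else v)
    return df


def write_annotation_tsv(annotations: Sequence[ExposureAnnotation | CohortAnnotation], path) -> None:
    annotation_to_frame(annotations).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotation_tsv(path, kind: str) -> list[ExposureAnnotation] | list[CohortAnnotation]:
    """Read an annotation TSV. ``kind`` is 'exposure' or 'cohort'."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    out: list = []
    if kind == "exposure":
        for rec in df.to_dict("records"):
            dose = rec.get("dose_level")
            if pd.isna(dose):
                dose = None
            elif isinstance(dose, str):
                try:
                    dose = float(dose)
                except ValueError:
                    pass
            time_h = rec.get("time_h")
            out.append(
                ExposureAnnotation(
                    sample_id=str(rec["sample_id"]),
                    arm=Arm(rec["arm"]),
                    substance="" if pd.isna(rec.get("substance")) else str(rec["substance"]),
                    dose_level=dose,
                    time_h=None if pd.isna(time_h) else float(time_h),
                    replicate=int(rec.get("replicate", 1)),
                )
            )
    elif kind == "cohort":
        for rec in df.to_dict("records"):
            age = rec.get("age")
            py = rec.get("pack_years")
            out.append(
                CohortAnnotation(
                    sample_id=str(rec["sample_id"]),
                    status=Status(rec["status"]),
                    age=None if pd.isna(age) else float(age),
                    pack_years=None if pd.isna(py) else float(py),
                    study="" if pd.isna(rec.get("study")) else str(rec["study"]),
                )
            )
    else:
        raise ValueError(f"unknown annotation kind {kind!r}")
    ids = [a.sample_id for a in out]
    if len(set(ids)) != len(ids):
        raise IdentifierError("duplicate sample_id in annotation")
    return out


def align_annotation(matrix: ExpressionMatrix, annotations: Sequence) -> tuple[ExpressionMatrix, list]:
    """Validate and order a matrix against its annotation table.

    Every matrix sample must have exactly one annotation row and vice
    versa; the matrix columns are reordered to annotation order.
    """
    ids = [a.sample_id for a in annotations]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise IdentifierError(f"duplicate sample_id in annotation: {dupes}")
    matrix_set = set(matrix.sample_ids)
    ann_set = set(ids)
    missing_ann = sorted(matrix_set - ann_set)
    missing_mat = sorted(ann_set - matrix_set)
    if missing_ann or missing_mat:
        parts = []
        if missing_ann:
            parts.append(f"samples without annotation: {missing_ann}")
        if missing_mat:
            parts.append(f"annotations without sample: {missing_mat}")
        raise AlignmentError("; ".join(parts))
    return matrix.subset_samples(ids), list(annotations)
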