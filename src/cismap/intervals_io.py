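"""Domain types, genomic-interval arithmetic and flat-file readers/writers.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  A TSS position is a single 0-based base.  Chromosome
names are compared by exact string equality; no ``chr`` normalisation is
attempted (see :func:`diagnose_chromosome_mismatch`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TSS",
    "CRM",
    "SignalMatrix",
    "ExpressionMatrix",
    "ParseError",
    "ValidationError",
    "read_crms_bed",
    "write_crms_bed",
    "read_regions_bed",
    "read_tss_table",
    "write_tss_table",
    "read_matrix",
    "write_matrix",
    "signed_relative_position",
    "midpoint",
    "diagnose_chromosome_mismatch",
]

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} in {self.chrom}")
        if not self.start < self.end:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True, order=True)
class TSS:
    """An annotated transcription start site tied to a gene."""

    tss_id: str
    chrom: str
    position: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"TSS {self.tss_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.position < 0:
            raise ValidationError(f"TSS {self.tss_id}: negative position")


@dataclass(frozen=True, order=True)
class CRM:
    """A cis-regulatory module predicted in a single source tissue."""

    crm_id: str
    interval: GenomicInterval
    source_tissue: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(f"CRM {self.crm_id}: negative score")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def midpoint(self) -> int:
        return midpoint(self.interval)


def midpoint(interval: GenomicInterval) -> int:
    """Floor midpoint of a half-open interval."""
    return (interval.start + interval.end) // 2


class _TissueMatrix:
    """Dense non-negative matrix with row ids and tissue columns.

    Thin wrapper around a pandas DataFrame that enforces completeness,
    non-negativity and unique labels on construction.
    """

    row_kind = "row"

    def __init__(self, values, row_ids: Sequence[str], tissue_ids: Sequence[str]):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("matrix values must be 2-dimensional")
        if arr.shape != (len(row_ids), len(tissue_ids)):
            raise ValidationError(
                f"shape {arr.shape} does not match {len(row_ids)} rows "
                f"x {len(tissue_ids)} tissues"
            )
        if len(set(row_ids)) != len(row_ids):
            raise ValidationError(f"duplicate {self.row_kind} ids")
        if len(set(tissue_ids)) != len(tissue_ids):
            raise ValidationError("duplicate tissue ids")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("matrix contains missing or non-finite cells")
        if np.any(arr < 0):
            raise ValidationError("matrix contains negative values")
        self._df = pd.DataFrame(arr, index=list(row_ids), columns=list(tissue_ids))

    @property
    def row_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def row(self, row_id: str) -> np.ndarray:
        return self._df.loc[row_id].to_numpy()

    def drop_tissue(self, tissue: str) -> "_TissueMatrix":
        if tissue not in self._df.columns:
            raise ValidationError(f"tissue {tissue!r} not present in matrix")
        sub = self._df.drop(columns=[tissue])
        return type(self)(sub.to_numpy(), list(sub.index), list(sub.columns))

    def subset_tissues(self, tissues: Sequence[str]) -> "_TissueMatrix":
        sub = self._df.loc[:, list(tissues)]
        return type(self)(sub.to_numpy(), list(sub.index), list(sub.columns))

    def __contains__(self, row_id: str) -> bool:
        return row_id in self._df.index

    def __eq__(self, other) -> bool:
        return isinstance(other, _TissueMatrix) and self._df.equals(other._df)


class SignalMatrix(_TissueMatrix):
    """Histone-modification level per CRM (rows) per tissue (columns)."""

    row_kind = "CRM"


class ExpressionMatrix(_TissueMatrix):
    """Expression level per TSS (rows) per tissue (columns)."""

    row_kind = "TSS"


class TFBindingMatrix(_TissueMatrix):
    """TF-binding signal per region (rows) per TF (columns) in the test tissue.

    ``tissue_ids`` holds TF names here; the container semantics (complete,
    non-negative, unique labels) are identical.
    """

    row_kind = "region"

    @property
    def tf_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def region_ids(self) -> list[str]:
        return list(self._df.index)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

PathLike = Union[str, Path]


def _bed_records(path: PathLike):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            yield lineno, chrom, start, end, fields


def read_crms_bed(path: PathLike, source_tissue: str) -> set[CRM]:
    """Read CRMs from a BED3/BED5 file, tagging them with a source tissue.

    Column 4 (name) supplies ``crm_id`` when present, otherwise an id of
    the form ``<tissue>:<chrom>:<start>-<end>`` is synthesised; column 5
    supplies the score (default 0).
    """
    crms: set[CRM] = set()
    seen: set[str] = set()
    for lineno, chrom, start, end, fields in _bed_records(path):
        if len(fields) >= 4 and fields[3] not in ("", "."):
            crm_id = fields[3]
        else:
            crm_id = f"{source_tissue}:{chrom}:{start}-{end}"
        score = 0.0
        if len(fields) >= 5 and fields[4] not in ("", "."):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
        if crm_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate CRM id {crm_id!r}")
        seen.add(crm_id)
        crms.add(
            CRM(crm_id, GenomicInterval(chrom, start, end), source_tissue, score)
        )
    return crms


def write_crms_bed(path: PathLike, crms: Iterable[CRM]) -> None:
    ordered = sorted(crms, key=lambda c: (c.chrom, c.interval.start, c.crm_id))
    with open(path, "w") as fh:
        for c in ordered:
            fh.write(
                f"{c.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.crm_id}\t{c.score:g}\n"
            )


def read_regions_bed(path: PathLike) -> set[GenomicInterval]:
    """Read a plain region set (GRBs, super enhancers, ...) from BED."""
    regions = set()
    for _, chrom, start, end, fields in _bed_records(path):
        strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
        regions.add(GenomicInterval(chrom, start, end, strand))
    return regions


_TSS_HEADER = ["tss_id", "chrom", "position", "strand", "gene_id"]


def read_tss_table(path: PathLike) -> set[TSS]:
    """Read a tab-delimited TSS annotation with a fixed documented header."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSS_HEADER:
            raise ParseError(
                f"{path}:1: expected header {_TSS_HEADER}, got {header}"
            )
        out: set[TSS] = set()
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            tss_id, chrom, pos_s, strand, gene_id = fields
            if tss_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate tss_id {tss_id!r}")
            seen.add(tss_id)
            try:
                position = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer position") from exc
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            out.add(TSS(tss_id, chrom, position, strand, gene_id))
    return out


def write_tss_table(path: PathLike, tss_set: Iterable[TSS]) -> None:
    ordered = sorted(tss_set, key=lambda t: (t.chrom, t.position, t.tss_id))
    with open(path, "w") as fh:
        fh.write("\t".join(_TSS_HEADER) + "\n")
        for t in ordered:
            fh.write(f"{t.tss_id}\t{t.chrom}\t{t.position}\t{t.strand}\t{t.gene_id}\n")


def read_matrix(path: PathLike, kind: str = "signal") -> _TissueMatrix:
    """Read a tab-delimited matrix (first column row ids, header = tissues).

    ``kind`` selects the container: ``signal``, ``expression`` or
    ``tf_binding``.
    """
    cls = {
        "signal": SignalMatrix,
        "expression": ExpressionMatrix,
        "tf_binding": TFBindingMatrix,
    }[kind]
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: unreadable matrix: {exc}") from exc
    try:
        arr = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell in matrix") from exc
    if np.any(pd.isna(arr)):
        raise ParseError(f"{path}: missing cell in matrix")
    return cls(arr, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_matrix(path: PathLike, matrix: _TissueMatrix, float_format: str = "%.10g") -> None:
    matrix.df.to_csv(path, sep="\t", index_label="id", float_format=float_format)


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def signed_relative_position(tss: TSS, crm: CRM) -> int:
    """Signed distance from a TSS to a CRM midpoint, in transcription orientation.

    Positive values are downstream of the TSS, negative upstream; the sign
    is flipped for '-'-strand TSSs so the convention is strand-independent.
    """
    if tss.chrom != crm.chrom:
        raise ValidationError(
            f"TSS {tss.tss_id} ({tss.chrom}) and CRM {crm.crm_id} "
            f"({crm.chrom}) are on different chromosomes"
        )
    rel = crm.midpoint - tss.position
    return -rel if tss.strand == "-" else rel


def diagnose_chromosome_mismatch(
    tss_set: Iterable[TSS], crms: Iterable[CRM]
) -> dict[str, list[str]]:
    """Report chromosome names present on only one side of a TSS/CRM pairing.

    Chromosomes are matched by exact string equality, so e.g. ``chr1`` and
    ``1`` never pair; this diagnostic surfaces such naming mismatches.
    """
    tss_chroms = {t.chrom for t in tss_set}
    crm_chroms = {c.chrom for c in crms}
    return {
        "tss_only": sorted(tss_chroms - crm_chroms),
        "crm_only": sorted(crm_chroms - tss_chroms),
    }
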