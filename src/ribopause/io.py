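"""Genomic file formats and the transcription-unit coordinate frame.

All internal coordinates are 0-based half-open. Unit coordinates run 5'->3'
along the transcription unit regardless of genomic strand, so position 0 is
the transcription start site on either strand; this matches the positional
language used for rDNA landmarks ("+36", "+7715").

Supported formats: BED6 and GFF3 annotations, BED6 and BAM alignments,
bedGraph tracks (read/write), TSV/CSV sample sheets. BED-family files are
plain TSVs and are read through pandas; BAM goes through pysam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BUILTIN_UNIT_RESOURCE = "rdna_unit_synthetic.gff3"


class AnnotationError(ValueError):
    """Raised when an annotation fails validation (overlaps, bad ranges...)."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the declared format."""


@dataclass(frozen=True)
class Region:
    """A named subregion of a transcription unit, in unit coordinates."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.name:
            raise AnnotationError("region name must be nonempty")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"region {self.name!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptionUnit:
    """A genomic interval with ordered named subregions (5'ETS ... 3'ETS).

    The unit defines the coordinate frame of every per-nucleotide track in
    the package: unit position 0 is the 5' end of the nascent transcript.
    """

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "transcription_unit"
    regions: tuple[Region, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"unknown strand {self.strand!r}")
        if self.end <= self.start:
            raise AnnotationError(
                f"unit {self.name!r}: end ({self.end}) must exceed start ({self.start})"
            )
        seen: set[str] = set()
        prev_end = 0
        for region in self.regions:
            if region.name in seen:
                raise AnnotationError(f"duplicate region name {region.name!r}")
            seen.add(region.name)
            if region.end > self.length:
                raise AnnotationError(
                    f"region {region.name!r} ends at {region.end}, beyond the "
                    f"{self.length}-nt unit"
                )
            if region.start < prev_end:
                raise AnnotationError(
                    f"region {region.name!r} overlaps the preceding region "
                    f"(starts at {region.start}, previous ends at {prev_end})"
                )
            prev_end = region.end

    @property
    def length(self) -> int:
        return self.end - self.start

    def region(self, name: str) -> Region:
        for region in self.regions:
            if region.name == name:
                return region
        raise KeyError(name)

    def unit_to_genomic(self, position: int) -> int:
        """Genomic coordinate of a unit position (identity-inverse of
        :func:`to_unit_coordinates` on the 3'-end convention)."""
        if not (0 <= position < self.length):
            raise ValueError(f"unit position {position} outside [0, {self.length})")
        if self.strand == "+":
            return self.start + position
        return self.end - 1 - position

    def genomic_to_unit(self, coordinate: int) -> int:
        if not (self.start <= coordinate < self.end):
            raise ValueError(
                f"genomic coordinate {coordinate} outside [{self.start}, {self.end})"
            )
        if self.strand == "+":
            return coordinate - self.start
        return self.end - 1 - coordinate


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read; its 3' end marks the polymerase active site."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"read {self.name!r}: start ({self.start}) must precede end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"read {self.name!r}: unknown strand {self.strand!r}")
        if self.weight < 0:
            raise FormatError(f"read {self.name!r}: negative weight {self.weight}")

    def three_prime_genomic(self) -> int:
        """Genomic coordinate of the rightmost (plus) / leftmost (minus)
        aligned base, i.e. the read 3' end."""
        return self.end - 1 if self.strand == "+" else self.start


def to_unit_coordinates(read: ReadRecord, unit: TranscriptionUnit) -> int | None:
    """Unit position of the read's 3' end, or None if it falls outside.

    Reads on the opposite strand or on another chromosome do not report a
    position (returned as None, logged at debug level) because their 3' end
    cannot correspond to the polymerase transcribing this unit.
    """
    if read.chrom != unit.chrom:
        logger.debug("read %s on %s does not match unit chrom %s",
                     read.name, read.chrom, unit.chrom)
        return None
    if read.strand != unit.strand:
        return None
    if unit.strand == "+":
        position = read.end - 1 - unit.start
    else:
        position = unit.end - 1 - read.start
    if 0 <= position < unit.length:
        return position
    return None


# ---------------------------------------------------------------------------
# annotations


def _gff_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in raw.strip().rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"malformed GFF3 attribute {item!r}")
        key, value = item.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _read_interval_table(path: str | Path, fmt: str) -> pd.DataFrame:
    """Rows of (chrom, start, end, name, strand) in 0-based half-open
    coordinates, from a BED6 or GFF3 file."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty annotation file") from None
    if fmt == "bed":
        if table.shape[1] < 3:
            raise FormatError(f"{path}: BED needs at least 3 columns")
        rows = pd.DataFrame({
            "chrom": table[0],
            "start": pd.to_numeric(table[1], errors="raise").astype(int),
            "end": pd.to_numeric(table[2], errors="raise").astype(int),
            "name": table[3] if table.shape[1] > 3 else "region",
            "strand": table[5] if table.shape[1] > 5 else "+",
        })
    elif fmt == "gff3":
        if table.shape[1] < 9:
            raise FormatError(f"{path}: GFF3 needs 9 columns")
        names = []
        for raw in table[8]:
            attrs = _gff_attributes(raw)
            names.append(attrs.get("Name", attrs.get("ID", "region")))
        rows = pd.DataFrame({
            "chrom": table[0],
            # GFF3 is 1-based inclusive; convert to 0-based half-open
            "start": pd.to_numeric(table[3], errors="raise").astype(int) - 1,
            "end": pd.to_numeric(table[4], errors="raise").astype(int),
            "name": names,
            "strand": table[6],
        })
    else:
        raise FormatError(f"unknown annotation format {fmt!r}")
    return rows


def _guess_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return "gff3"
    if suffix == ".bed":
        return "bed"
    raise FormatError(f"cannot infer annotation format from {path}")


def read_annotation(path: str | Path, fmt: str | None = None) -> TranscriptionUnit:
    """Read a transcription-unit annotation from BED6 or GFF3.

    Exactly one record must span all others; it defines the unit, and the
    remaining records become its named subregions (converted to unit
    coordinates, strand-aware).
    """
    rows = _read_interval_table(path, _guess_format(path, fmt))
    spans = rows["end"] - rows["start"]
    is_unit = spans == spans.max()
    if is_unit.sum() != 1:
        raise AnnotationError(
            f"{path}: expected exactly one unit-level record (the longest), "
            f"found {int(is_unit.sum())} records of span {int(spans.max())}"
        )
    unit_row = rows[is_unit].iloc[0]
    regions = []
    for _, row in rows[~is_unit].iterrows():
        if row["chrom"] != unit_row["chrom"]:
            raise AnnotationError(
                f"region {row['name']!r} on {row['chrom']}, unit on {unit_row['chrom']}"
            )
        if row["start"] < unit_row["start"] or row["end"] > unit_row["end"]:
            raise AnnotationError(
                f"region {row['name']!r} [{row['start']}, {row['end']}) extends "
                f"outside the unit [{unit_row['start']}, {unit_row['end']})"
            )
        if unit_row["strand"] == "+":
            ustart = row["start"] - unit_row["start"]
            uend = row["end"] - unit_row["start"]
        else:
            ustart = unit_row["end"] - row["end"]
            uend = unit_row["end"] - row["start"]
        regions.append(Region(str(row["name"]), int(ustart), int(uend)))
    regions.sort(key=lambda r: r.start)
    return TranscriptionUnit(
        chrom=str(unit_row["chrom"]),
        start=int(unit_row["start"]),
        end=int(unit_row["end"]),
        strand=str(unit_row["strand"]),
        name=str(unit_row["name"]),
        regions=tuple(regions),
    )


def load_builtin_unit() -> TranscriptionUnit:
    """The packaged rDNA transcription-unit annotation.

    A synthetic stand-in for the fission yeast 35S pre-rRNA gene: 7800 nt
    with the 5'ETS spanning the first 1300 nt. The internal 18S/ITS1/5.8S/
    ITS2/25S/3'ETS boundaries are not published for this coordinate frame
    and use plausible S. pombe subunit lengths.
    """
    ref = resources.files("ribopause.data").joinpath(_BUILTIN_UNIT_RESOURCE)
    with resources.as_file(ref) as path:
        return read_annotation(path, fmt="gff3")


# ---------------------------------------------------------------------------
# alignments


def _reads_from_bed(path: Path) -> list[ReadRecord]:
    try:
        table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    reads = []
    for index, row in enumerate(table.itertuples(index=False), start=1):
        fields = tuple(row)
        if len(fields) < 3:
            raise FormatError(f"{path} line {index}: fewer than 3 BED columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path} line {index}: non-numeric coordinates {fields[1]!r}, {fields[2]!r}"
            ) from None
        name = str(fields[3]) if len(fields) > 3 and pd.notna(fields[3]) else "."
        strand = str(fields[5]) if len(fields) > 5 and pd.notna(fields[5]) else "+"
        try:
            reads.append(ReadRecord(str(fields[0]), start, end, strand, name))
        except FormatError as err:
            raise FormatError(f"{path} line {index}: {err}") from None
    return reads


def _reads_from_bam(
    path: Path, unit: TranscriptionUnit | None, multimap_policy: str
) -> list[ReadRecord]:
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        if unit is not None and bam.has_index():
            iterator = bam.fetch(unit.chrom, unit.start, unit.end)
        else:
            iterator = bam.fetch(until_eof=True)
        for aln in iterator:
            if aln.is_unmapped:
                continue
            if multimap_policy == "primary-only" and (
                aln.is_secondary or aln.is_supplementary
            ):
                continue
            weight = 1.0
            if multimap_policy == "fractional":
                nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
                weight = 1.0 / max(int(nh), 1)
            reads.append(
                ReadRecord(
                    chrom=aln.reference_name,
                    # reference_start/end exclude soft-clipped bases, which
                    # are not template-engaged
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    name=aln.query_name or ".",
                    weight=weight,
                )
            )
    return reads


def read_alignments(
    path: str | Path,
    fmt: str | None = None,
    unit: TranscriptionUnit | None = None,
    multimap_policy: str = "keep-all",
) -> list[ReadRecord]:
    """Load aligned reads from BED6 or BAM.

    multimap_policy: "keep-all" keeps every alignment at weight 1 (the
    default, appropriate for the multi-copy rDNA collapsed onto a single
    representative repeat), "primary-only" drops secondary/supplementary
    BAM records, and "fractional" down-weights each alignment by 1/NH.
    If a unit is given, only reads overlapping it are returned.
    """
    if multimap_policy not in ("keep-all", "primary-only", "fractional"):
        raise ValueError(f"unknown multimap policy {multimap_policy!r}")
    path = Path(path)
    if fmt is None:
        fmt = "bam" if path.suffix.lower() == ".bam" else "bed"
    fmt = fmt.lower()
    if fmt == "bed":
        reads = _reads_from_bed(path)
    elif fmt == "bam":
        reads = _reads_from_bam(path, unit, multimap_policy)
    else:
        raise FormatError(f"unknown alignment format {fmt!r}")
    if unit is not None:
        reads = [
            r for r in reads
            if r.chrom == unit.chrom and r.start < unit.end and r.end > unit.start
        ]
    return reads


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet with columns sample_id, condition, replicate, path and
    optionally format; (condition, replicate) pairs must be unique."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    sheet = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "condition", "replicate", "path"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if "format" not in sheet.columns:
        sheet["format"] = None
    if sheet["path"].isna().any() or (sheet["path"].str.len() == 0).any():
        raise FormatError(f"{path}: sample sheet contains empty paths")
    pairs = list(zip(sheet["condition"], sheet["replicate"]))
    if len(pairs) != len(set(pairs)):
        raise FormatError(f"{path}: duplicate (condition, replicate) pairs")
    return sheet


# ---------------------------------------------------------------------------
# tracks


def write_track(
    values: Sequence[float] | np.ndarray,
    unit: TranscriptionUnit,
    path: str | Path,
    precision: int | None = None,
    name: str | None = None,
) -> Path:
    """Write a per-position track as bedGraph in genomic coordinates.

    Unit position 0 is written at the unit's 5' end (genomic start for plus
    strand, end-1 for minus strand). Runs of equal values are merged. With
    precision=None values are written with full float precision and the
    track round-trips bit-exactly through :func:`read_bedgraph`.
    """
    values = np.asarray(getattr(values, "values", values), dtype=float)
    if values.shape != (unit.length,):
        raise AnnotationError(
            f"track length {values.shape} does not match unit length {unit.length}"
        )
    genomic = values if unit.strand == "+" else values[::-1]
    path = Path(path)

    def render(v: float) -> str:
        return repr(float(v)) if precision is None else f"{v:.{precision}f}"

    with open(path, "w") as handle:
        if name:
            handle.write(f'track type=bedGraph name="{name}"\n')
        run_start = 0
        for i in range(1, unit.length + 1):
            if i == unit.length or genomic[i] != genomic[run_start]:
                handle.write(
                    f"{unit.chrom}\t{unit.start + run_start}\t{unit.start + i}\t"
                    f"{render(genomic[run_start])}\n"
                )
                run_start = i
    return path


def read_bedgraph(path: str | Path, unit: TranscriptionUnit) -> np.ndarray:
    """Read a bedGraph into a unit-coordinate track (uncovered positions 0)."""
    values = np.zeros(unit.length)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path} line {lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom != unit.chrom:
                continue
            lo, hi = max(start, unit.start), min(end, unit.end)
            if lo >= hi:
                continue
            if unit.strand == "+":
                values[lo - unit.start:hi - unit.start] = value
            else:
                values[unit.end - hi:unit.end - lo] = value
    return values
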