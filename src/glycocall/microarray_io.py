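"""Spot-level microarray I/O in a GenePix-compatible GPR/ATF dialect.

A GenePix Results (GPR) file is an Axon Text Format (ATF) tab-delimited
file: line 1 is ``ATF<tab>1.0``, line 2 gives the number of optional
header records and the number of data columns, then the quoted header
records, a column-header row, and one row per printed spot.  This module
reads and writes the subset of that dialect the competition pipeline
needs (grid coordinates, feature name, single-channel foreground and
background medians, quality flags) and loads the packaged 23-row
candidate table published with the original WGA screen.

The scan *condition* (competitor present or absent) is never guessed
from file content: GPR files carry no competitor field, so it must be
supplied explicitly by the caller (CLI flag or sidecar metadata).
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import FormatError, IntegrityError, ParseError

__all__ = [
    "Condition",
    "SpotKind",
    "SpotRecord",
    "ArrayScan",
    "Table1Row",
    "Table1Fixture",
    "DEFAULT_CONTROL_NAMES",
    "read_gpr",
    "write_gpr",
    "load_table1_fixture",
]

#: Feature names treated as positive-control spots (calf histones printed
#: on every array to confirm the probing worked).
DEFAULT_CONTROL_NAMES: frozenset[str] = frozenset({"Histone_H3", "Histone_H4"})


class Condition(str, enum.Enum):
    """Probing condition of one scan: glycan competitor absent or present."""

    MINUS_COMPETITOR = "minus_competitor"
    PLUS_COMPETITOR = "plus_competitor"


class SpotKind(str, enum.Enum):
    SAMPLE = "sample"
    POSITIVE_CONTROL = "positive_control"
    BUFFER = "buffer"


@dataclass(frozen=True, slots=True)
class SpotRecord:
    """One printed spot of one scanned array.

    ``fg_median`` and ``bg_median`` are the scanner's median foreground
    and local-background intensities for the configured wavelength
    (scanner counts, ≥ 0).  ``flag`` follows the GenePix convention:
    0 is good, negative values mark bad/absent/not-found spots.
    """

    block: int
    row: int
    column: int
    protein_id: str
    spot_kind: SpotKind
    fg_median: float
    bg_median: float
    flag: int = 0

    def __post_init__(self) -> None:
        if self.block < 1 or self.row < 1 or self.column < 1:
            raise IntegrityError(
                f"grid indices must be positive, got "
                f"({self.block}, {self.row}, {self.column})"
            )
        if self.fg_median < 0 or self.bg_median < 0:
            raise IntegrityError(
                f"negative intensity on spot ({self.block}, {self.row}, "
                f"{self.column}): fg={self.fg_median}, bg={self.bg_median}"
            )

    @property
    def coordinates(self) -> tuple[int, int, int]:
        return (self.block, self.row, self.column)


@dataclass(slots=True)
class ArrayScan:
    """One scanned microarray under one probing condition."""

    scan_id: str
    condition: Condition
    spots: list[SpotRecord] = field(default_factory=list)
    lectin_name: str = "WGA"
    competitor_name: str | None = None

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        has_competitor = bool(self.competitor_name)
        if (self.condition is Condition.PLUS_COMPETITOR) != has_competitor:
            raise IntegrityError(
                f"scan {self.scan_id!r}: condition {self.condition.value} "
                f"inconsistent with competitor_name={self.competitor_name!r}"
            )
        seen: set[tuple[int, int, int]] = set()
        for spot in self.spots:
            if spot.coordinates in seen:
                raise IntegrityError(
                    f"scan {self.scan_id!r}: duplicate grid coordinates "
                    f"{spot.coordinates}"
                )
            seen.add(spot.coordinates)

    def __iter__(self) -> Iterator[SpotRecord]:
        return iter(self.spots)

    def __len__(self) -> int:
        return len(self.spots)

    def sample_spots(self) -> list[SpotRecord]:
        return [s for s in self.spots if s.spot_kind is SpotKind.SAMPLE]

    def to_frame(self) -> pd.DataFrame:
        """Spot table as a DataFrame (one row per spot, scan order)."""
        return pd.DataFrame(
            {
                "block": [s.block for s in self.spots],
                "row": [s.row for s in self.spots],
                "column": [s.column for s in self.spots],
                "protein_id": [s.protein_id for s in self.spots],
                "spot_kind": [s.spot_kind.value for s in self.spots],
                "fg_median": [s.fg_median for s in self.spots],
                "bg_median": [s.bg_median for s in self.spots],
                "flag": [s.flag for s in self.spots],
            }
        )


# --------------------------------------------------------------------------
# GPR reading / writing
# --------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("Block", "Row", "Column", "F{w} Median", "B{w} Median", "Flags")


def _classify(name: str, control_names: Iterable[str]) -> SpotKind:
    if not name:
        return SpotKind.BUFFER
    if name in control_names:
        return SpotKind.POSITIVE_CONTROL
    return SpotKind.SAMPLE


def _parse_number(cell: str, line_no: int, column: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(
            f"line {line_no}: non-numeric value {cell!r} in column {column!r}"
        ) from None


def read_gpr(
    path: str | Path,
    *,
    condition: Condition | str,
    lectin_name: str = "WGA",
    competitor_name: str | None = None,
    scan_id: str | None = None,
    wavelength: int = 635,
    control_names: Iterable[str] = DEFAULT_CONTROL_NAMES,
) -> ArrayScan:
    """Read one GPR file into an :class:`ArrayScan`.

    The probing condition and competitor identity are caller-supplied
    metadata.  ``wavelength`` selects which intensity columns are read
    (default 635 nm, the Cy5 channel the screen quantified).  The
    identifier column is "Name" when present, otherwise "ID".

    Raises
    ------
    FormatError
        Missing ATF header, or a required column absent.
    ParseError
        A non-numeric intensity or coordinate cell (with line number).
    IntegrityError
        Duplicate (block, row, column) coordinates; duplicates are
        rejected, never repaired.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise FormatError(f"{path}: not ASCII/UTF-8 encoded ({exc})") from None
    lines = text.splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise FormatError(f"{path}: first line is not an ATF header")
    try:
        n_header = int(lines[1].split("\t")[0])
    except (IndexError, ValueError):
        raise FormatError(f"{path}: malformed ATF record-count line") from None

    header_row_idx = 2 + n_header
    if header_row_idx >= len(lines):
        raise FormatError(f"{path}: truncated before column header row")
    columns = lines[header_row_idx].rstrip("\n").split("\t")
    columns = [c.strip().strip('"') for c in columns]
    col_idx = {c: i for i, c in enumerate(columns)}

    fg_col = f"F{wavelength} Median"
    bg_col = f"B{wavelength} Median"
    for required in ("Block", "Row", "Column", fg_col, bg_col, "Flags"):
        if required not in col_idx:
            raise FormatError(f"{path}: required column {required!r} missing")
    if "Name" in col_idx:
        id_col = "Name"
    elif "ID" in col_idx:
        id_col = "ID"
    else:
        raise FormatError(f"{path}: required column 'Name' (or 'ID') missing")

    control_names = frozenset(control_names)
    spots: list[SpotRecord] = []
    seen: set[tuple[int, int, int]] = set()
    for offset, line in enumerate(lines[header_row_idx + 1 :]):
        if not line.strip():
            continue
        line_no = header_row_idx + 2 + offset
        cells = line.split("\t")
        if len(cells) < len(columns):
            raise ParseError(f"line {line_no}: expected {len(columns)} cells")

        def cell(col: str) -> str:
            return cells[col_idx[col]].strip().strip('"')

        coords = tuple(
            int(_parse_number(cell(c), line_no, c)) for c in ("Block", "Row", "Column")
        )
        if coords in seen:
            raise IntegrityError(
                f"{path}: duplicate grid coordinates {coords} at line {line_no}"
            )
        seen.add(coords)
        name = cell(id_col)
        spots.append(
            SpotRecord(
                block=coords[0],
                row=coords[1],
                column=coords[2],
                protein_id=name,
                spot_kind=_classify(name, control_names),
                fg_median=_parse_number(cell(fg_col), line_no, fg_col),
                bg_median=_parse_number(cell(bg_col), line_no, bg_col),
                flag=int(_parse_number(cell("Flags"), line_no, "Flags")),
            )
        )

    return ArrayScan(
        scan_id=scan_id if scan_id is not None else path.stem,
        condition=Condition(condition),
        spots=spots,
        lectin_name=lectin_name,
        competitor_name=competitor_name,
    )


def _format_intensity(x: float) -> str:
    # repr round-trips floats exactly; integers print without the trailing .0
    # so files look like real scanner output when intensities are integral.
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_gpr(scan: ArrayScan, path: str | Path, *, wavelength: int = 635) -> None:
    """Write an :class:`ArrayScan` as a GPR/ATF file.

    Output is bit-stable: the same scan always serializes to identical
    bytes, and ``read_gpr(write_gpr(scan))`` reproduces every required
    field exactly.
    """
    path = Path(path)
    header_records = [
        f'"Scan={scan.scan_id}"',
        f'"Lectin={scan.lectin_name}"',
    ]
    columns = [
        "Block",
        "Row",
        "Column",
        "Name",
        f"F{wavelength} Median",
        f"B{wavelength} Median",
        "Flags",
    ]
    lines = [
        "ATF\t1.0",
        f"{len(header_records)}\t{len(columns)}",
        *header_records,
        "\t".join(columns),
    ]
    for s in scan.spots:
        lines.append(
            "\t".join(
                (
                    str(s.block),
                    str(s.row),
                    str(s.column),
                    f'"{s.protein_id}"',
                    _format_intensity(s.fg_median),
                    _format_intensity(s.bg_median),
                    str(s.flag),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Packaged candidate table
# --------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class Table1Row:
    """One published candidate row, with printed values preserved verbatim.

    ``protein_id`` keeps the table's spelling (including the "EentC"
    typo in row 1); ``alias`` carries the normalized gene symbol for
    joins.  ``calling_score_printed`` is the score as printed, which for
    two rows differs by 0.01 from the ratio of the printed SNR columns
    (the original analysis evidently divided unrounded SNRs).
    """

    rank: int
    protein_id: str
    alias: str
    snr_minus: float
    snr_plus: float
    calling_score_printed: float
    annotation: str


@dataclass(frozen=True)
class Table1Fixture:
    """The packaged 23-row WGA candidate table."""

    rows: tuple[Table1Row, ...]

    def __iter__(self) -> Iterator[Table1Row]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def by_id(self, protein_id: str) -> Table1Row:
        for row in self.rows:
            if row.protein_id == protein_id or row.alias == protein_id:
                return row
        raise KeyError(protein_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.rows])


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged published candidate table (23 rows).

    Deterministic and side-effect free; raises :class:`IntegrityError`
    if the packaged data is corrupted.
    """
    ref = resources.files("glycocall.data").joinpath("wga_candidates.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype={"protein_id": str, "alias": str})
    expected_cols = {
        "rank", "protein_id", "alias", "snr_minus", "snr_plus",
        "calling_score_printed", "annotation",
    }
    if set(df.columns) != expected_cols:
        raise IntegrityError("packaged candidate table has unexpected columns")
    if len(df) != 23 or sorted(df["rank"]) != list(range(1, 24)):
        raise IntegrityError("packaged candidate table must have ranks 1..23")
    if df["protein_id"].duplicated().any():
        raise IntegrityError("duplicate protein_id in packaged candidate table")
    rows = tuple(
        Table1Row(
            rank=int(r["rank"]),
            protein_id=r["protein_id"],
            alias=r["alias"],
            snr_minus=float(r["snr_minus"]),
            snr_plus=float(r["snr_plus"]),
            calling_score_printed=float(r["calling_score_printed"]),
            annotation=r["annotation"],
        )
        for r in df.sort_values("rank").to_dict("records")
    )
    return Table1Fixture(rows=rows)
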