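"""Tabular input/output: generic breakpoint files, caller outputs, reports.

The generic inference input is an N x 4 tab-separated file (5' contig, 5'
coordinate, 3' contig, 3' coordinate); the retraining input adds a fifth
0/1 oncogenicity label column.  A header row is sniffed: if the coordinate
fields of the first row are non-numeric the row is treated as a header.

Native outputs of fusion-detection callers are mapped through a registry of
adapters keyed by format name; a STAR-Fusion-style adapter ships by default
and the registry makes adding formats a data-only change.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from .errors import ParseError
from .fusions import Breakpoint, FusionInput

REPORT_COLUMNS = [
    "FusionPair",
    "OncogenicProbability",
    "Gene5pId",
    "Gene5pName",
    "Gene5pDescription",
    "Gene3pId",
    "Gene3pName",
    "Gene3pDescription",
    "MainProteinLength",
    "TruncatedProtein",
    "Gene5pComplete",
    "Gene3pComplete",
    "NumCandidates",
    "MainProtein",
]


@dataclass
class LabeledFusionInput:
    fusion: FusionInput
    label: int  # 0 = not oncogenic, 1 = oncogenic


@dataclass
class FusionResult:
    """One row of the ranked report (one (gene5, gene3) pair of one fusion)."""

    fusion_pair: str
    onc_prob: float | None  # None rendered as NA (no protein could be built)
    gene5_id: str = ""
    gene5_name: str = ""
    gene5_description: str = ""
    gene3_id: str = ""
    gene3_name: str = ""
    gene3_description: str = ""
    main_protein_length: int = 0
    truncated: bool = False
    five_prime_complete: bool = False
    three_prime_complete: bool = False
    main_protein: str = ""
    n_candidates: int = 0
    reason: str = ""
    source_row: int = 0


def _is_int(text: str) -> bool:
    try:
        int(text)
        return True
    except ValueError:
        return False


def parse_generic(path, labeled: bool = False):
    """Parse the N x 4 (or N x 5 labeled) generic breakpoint file.

    Returns ``list[FusionInput]`` or ``list[LabeledFusionInput]``.  Row
    numbers in errors and ``source_row`` are 0-based data-row indices.
    """
    want = 5 if labeled else 4
    out = []
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if rows and len(rows[0]) >= 2 and not (_is_int(rows[0][1]) if len(rows[0]) > 1 else False):
        rows = rows[1:]  # header sniffed: coordinate field non-numeric
    for i, row in enumerate(rows):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != want:
            raise ParseError(f"row {i}: expected {want} tab-separated columns, got {len(row)}")
        c5, p5, c3, p3 = row[:4]
        if not _is_int(p5) or not _is_int(p3):
            raise ParseError(f"row {i}: non-integer coordinate ({p5!r}, {p3!r})")
        fusion = FusionInput(
            bp5=Breakpoint(c5, int(p5), "five_prime"),
            bp3=Breakpoint(c3, int(p3), "three_prime"),
            source_row=i,
        )
        if labeled:
            if row[4] not in ("0", "1"):
                raise ParseError(f"row {i}: label must be 0 or 1, got {row[4]!r}")
            out.append(LabeledFusionInput(fusion=fusion, label=int(row[4])))
        else:
            out.append(fusion)
    return out


# ---------------------------------------------------------------------------
# caller adapters

@dataclass
class CallerAdapter:
    """Column mapping for a caller's native output (header-based TSV).

    ``bp5_column``/``bp3_column`` name columns holding ``contig:pos[:strand]``
    breakpoint strings; all other columns become opaque caller metadata.
    """

    name: str
    bp5_column: str
    bp3_column: str

    def parse(self, path) -> list[FusionInput]:
        out: list[FusionInput] = []
        with open(path, newline="") as fh:
            first = fh.readline()
            header = first.lstrip("#").rstrip("\n").split("\t")
            for col in (self.bp5_column, self.bp3_column):
                if col not in header:
                    raise ParseError(f"{self.name}: missing column {col!r} in header")
            for i, line in enumerate(r.rstrip("\n") for r in fh):
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != len(header):
                    raise ParseError(
                        f"row {i}: expected {len(header)} columns, got {len(fields)}"
                    )
                rec = dict(zip(header, fields))
                bp5 = self._breakpoint(rec[self.bp5_column], "five_prime", i)
                bp3 = self._breakpoint(rec[self.bp3_column], "three_prime", i)
                meta = {k: v for k, v in rec.items() if k not in (self.bp5_column, self.bp3_column)}
                out.append(FusionInput(bp5=bp5, bp3=bp3, source_row=i, caller_metadata=meta))
        return out

    @staticmethod
    def _breakpoint(text: str, role: str, row: int) -> Breakpoint:
        parts = text.split(":")
        if len(parts) < 2 or not _is_int(parts[1]):
            raise ParseError(f"row {row}: malformed breakpoint {text!r}")
        return Breakpoint(parts[0], int(parts[1]), role)


CALLER_FORMATS: dict[str, CallerAdapter] = {
    "star-fusion": CallerAdapter(
        name="star-fusion", bp5_column="LeftBreakpoint", bp3_column="RightBreakpoint"
    ),
}


def parse_caller(path, format_name: str) -> list[FusionInput]:
    """Parse a caller's native output via the registered adapter."""
    if format_name not in CALLER_FORMATS:
        raise ParseError(
            f"unknown caller format {format_name!r}; registered: {sorted(CALLER_FORMATS)}"
        )
    return CALLER_FORMATS[format_name].parse(path)


# ---------------------------------------------------------------------------
# report

def _flag(value: bool) -> str:
    return "Yes" if value else "No"


def write_report(results: list[FusionResult], path) -> None:
    """Write the ranked report as TSV with the fixed 14-column header.

    ``results`` must already be ranked; probabilities are rendered with two
    decimals and NA for fusions with no buildable protein.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REPORT_COLUMNS)
        for r in results:
            w.writerow(
                [
                    r.fusion_pair,
                    "NA" if r.onc_prob is None else f"{r.onc_prob:.2f}",
                    r.gene5_id,
                    r.gene5_name,
                    r.gene5_description,
                    r.gene3_id,
                    r.gene3_name,
                    r.gene3_description,
                    r.main_protein_length,
                    _flag(r.truncated),
                    _flag(r.five_prime_complete),
                    _flag(r.three_prime_complete),
                    r.n_candidates,
                    r.main_protein,
                ]
            )


def read_report(path) -> list[FusionResult]:
    """Parse a report written by :func:`write_report` (round-trip support)."""
    out: list[FusionResult] = []
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or rows[0] != REPORT_COLUMNS:
        raise ParseError(f"{path}: not a report file (bad header)")
    for i, row in enumerate(rows[1:]):
        if len(row) != len(REPORT_COLUMNS):
            raise ParseError(f"row {i}: expected {len(REPORT_COLUMNS)} columns")
        out.append(
            FusionResult(
                fusion_pair=row[0],
                onc_prob=None if row[1] == "NA" else float(row[1]),
                gene5_id=row[2],
                gene5_name=row[3],
                gene5_description=row[4],
                gene3_id=row[5],
                gene3_name=row[6],
                gene3_description=row[7],
                main_protein_length=int(row[8]),
                truncated=row[9] == "Yes",
                five_prime_complete=row[10] == "Yes",
                three_prime_complete=row[11] == "Yes",
                n_candidates=int(row[12]),
                main_protein=row[13],
                source_row=i,
            )
        )
    return out
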