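"""Input parsing: configuration tables, FASTA sequences and BED annotations.

Two input dialects are supported.  The primary one is a CSV/TSV
configuration table with one row per sequence and columns ``Fasta``,
``SampleID``, ``Label`` (mandatory) plus ``Annotation`` and ``Strand``
(optional).  The simplified dialect is a single multi-record FASTA whose
headers serve as sample ids, optionally paired with one combined BED file
whose first column names the owning header.

All coordinates in this package are 0-based half-open, the native BED and
PAF convention.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import ConfigurationError, InputValidationError

log = logging.getLogger("quiltplot.config")

MANDATORY_COLUMNS = ("Fasta", "SampleID", "Label")
OPTIONAL_COLUMNS = ("Annotation", "Strand")


@dataclass
class AnnotationInterval:
    """One BED feature on a sequence: 0-based half-open, optional display color."""

    sample_id: str
    start: int
    end: int
    name: str | None = None
    color: tuple[int, int, int] | None = None
    line_no: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputValidationError(
                f"annotation interval [{self.start}, {self.end}) on "
                f"{self.sample_id!r} violates 0 <= start < end"
            )


@dataclass
class SequenceEntry:
    """One input sequence: identity, label, paths, declared strand and length.

    ``order_index`` 0 is the reference sequence every other sequence is
    oriented against.
    """

    sample_id: str
    label: str
    fasta_path: Path
    annotation_path: Path | None = None
    declared_strand: str | None = None
    length: int = 0
    order_index: int = 0
    annotations: list[AnnotationInterval] = field(default_factory=list)


def _detect_delimiter(path: Path, header: str) -> str:
    ext = path.suffix.lower()
    if ext == ".csv":
        delim = ","
    elif ext in (".tsv", ".tab"):
        delim = "\t"
    else:  # sniff the header line
        if "\t" in header:
            delim = "\t"
        elif "," in header:
            delim = ","
        else:
            raise ConfigurationError(
                f"cannot detect delimiter of {path}: header has neither tab nor comma"
            )
    other = "\t" if delim == "," else ","
    if other in header:
        raise ConfigurationError(
            f"mixed delimiters in {path}: header contains both tab and comma"
        )
    return delim


def parse_config(path: str | Path) -> list[SequenceEntry]:
    """Parse a configuration table into ordered :class:`SequenceEntry` values.

    Relative FASTA/BED paths are resolved against the table's directory.
    Raises :class:`ConfigurationError` for schema problems and
    :class:`InputValidationError` for duplicate ids, bad strands or missing
    FASTA files.
    """
    path = Path(path)
    if not path.is_file():
        raise InputValidationError(f"configuration file not found: {path}")
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise InputValidationError(f"configuration file {path} is empty")
    delim = _detect_delimiter(path, lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    header = [h.strip() for h in rows[0]]
    for col in MANDATORY_COLUMNS:
        if col not in header:
            raise ConfigurationError(f"configuration table missing mandatory column {col!r}")
    idx = {name: header.index(name) for name in header}

    def cell(row: list[str], col: str) -> str:
        i = idx.get(col)
        if i is None or i >= len(row):
            return ""
        return row[i].strip()

    entries: list[SequenceEntry] = []
    base = path.parent
    for order, row in enumerate(rows[1:]):
        fasta = cell(row, "Fasta")
        sid = cell(row, "SampleID")
        label = cell(row, "Label")
        if not (fasta and sid and label):
            raise InputValidationError(
                f"row {order + 1} of {path.name}: Fasta, SampleID and Label must be non-empty"
            )
        fasta_path = (base / fasta) if not Path(fasta).is_absolute() else Path(fasta)
        if not fasta_path.is_file():
            raise InputValidationError(
                f"row {order + 1} ({sid}): FASTA path does not exist: {fasta_path}"
            )
        annot = cell(row, "Annotation")
        annot_path = None
        if annot:
            annot_path = (base / annot) if not Path(annot).is_absolute() else Path(annot)
            if not annot_path.is_file():
                raise InputValidationError(
                    f"row {order + 1} ({sid}): annotation path does not exist: {annot_path}"
                )
        strand = cell(row, "Strand") or None
        if strand is not None and strand not in ("+", "-"):
            raise InputValidationError(
                f"row {order + 1} ({sid}): Strand must be '+' or '-', got {strand!r}"
            )
        entries.append(
            SequenceEntry(
                sample_id=sid,
                label=label,
                fasta_path=fasta_path,
                annotation_path=annot_path,
                declared_strand=strand,
                order_index=order,
            )
        )
    if not entries:
        raise InputValidationError(f"configuration file {path} has no data rows")
    dupes = sorted({e.sample_id for e in entries if [x.sample_id for x in entries].count(e.sample_id) > 1})
    if dupes:
        raise InputValidationError(f"duplicate SampleID values: {', '.join(dupes)}")
    return entries


def parse_simplified_input(
    fasta_path: str | Path, bed_path: str | Path | None = None
) -> list[SequenceEntry]:
    """Parse the simplified dialect: one multi-FASTA plus one combined BED.

    Sample ids and labels are the FASTA header tokens; BED lines are
    assigned to the entry named by their first column.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.is_file():
        raise InputValidationError(f"FASTA file not found: {fasta_path}")
    entries: list[SequenceEntry] = []
    seen: set[str] = set()
    for order, rec in enumerate(SeqIO.parse(str(fasta_path), "fasta")):
        if rec.id in seen:
            raise InputValidationError(f"duplicate FASTA header {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise InputValidationError(f"empty sequence for FASTA record {rec.id!r}")
        entries.append(
            SequenceEntry(
                sample_id=rec.id,
                label=rec.id,
                fasta_path=fasta_path,
                length=len(rec.seq),
                order_index=order,
            )
        )
    if not entries:
        raise InputValidationError(f"no FASTA records in {fasta_path}")
    if bed_path is not None:
        by_id = {e.sample_id: e for e in entries}
        for iv in parse_bed(bed_path):
            entry = by_id.get(iv.sample_id)
            if entry is None:
                raise InputValidationError(
                    f"BED line {iv.line_no} references unknown sequence id {iv.sample_id!r}"
                )
            entry.annotations.append(iv)
    return entries


def load_lengths(entries: list[SequenceEntry]) -> list[SequenceEntry]:
    """Fill ``length`` for each entry from its FASTA file (in place; returned).

    In per-sequence mode a multi-record FASTA contributes the record whose
    id equals the SampleID when present, otherwise its first record with a
    logged warning.
    """
    cache: dict[Path, list] = {}
    for entry in entries:
        recs = cache.get(entry.fasta_path)
        if recs is None:
            recs = list(SeqIO.parse(str(entry.fasta_path), "fasta"))
            cache[entry.fasta_path] = recs
        if not recs:
            raise InputValidationError(f"no FASTA records in {entry.fasta_path}")
        chosen = next((r for r in recs if r.id == entry.sample_id), None)
        if chosen is None:
            if len(recs) > 1:
                log.warning(
                    "FASTA %s has %d records and none matches SampleID %r; using the first (%r)",
                    entry.fasta_path, len(recs), entry.sample_id, recs[0].id,
                )
            chosen = recs[0]
        if len(chosen.seq) == 0:
            raise InputValidationError(
                f"empty sequence for {entry.sample_id!r} in {entry.fasta_path}"
            )
        entry.length = len(chosen.seq)
    return entries


def read_sequence(entry: SequenceEntry) -> str:
    """Return the residue string for an entry (same record choice as load_lengths)."""
    recs = list(SeqIO.parse(str(entry.fasta_path), "fasta"))
    if not recs:
        raise InputValidationError(f"no FASTA records in {entry.fasta_path}")
    chosen = next((r for r in recs if r.id == entry.sample_id), recs[0])
    return str(chosen.seq)


def parse_bed(path: str | Path) -> list[AnnotationInterval]:
    """Parse a BED file (3-9 columns) into annotation intervals.

    Column 4 becomes the name and a 9th-column ``itemRgb`` triple the
    display color; a malformed itemRgb logs a warning and leaves the color
    unset.  Coordinate errors raise with the 1-based line number.
    """
    path = Path(path)
    if not path.is_file():
        raise InputValidationError(f"BED file not found: {path}")
    intervals: list[AnnotationInterval] = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise InputValidationError(
                f"{path.name} line {line_no}: expected >=3 tab-separated columns"
            )
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise InputValidationError(
                f"{path.name} line {line_no}: non-integer coordinates"
            ) from exc
        if start < 0 or start >= end:
            raise InputValidationError(
                f"{path.name} line {line_no}: invalid interval [{start}, {end})"
            )
        name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else None
        color: tuple[int, int, int] | None = None
        if len(cols) >= 9 and cols[8] not in ("", ".", "0"):
            try:
                r, g, b = (int(x) for x in cols[8].split(","))
                if not all(0 <= v <= 255 for v in (r, g, b)):
                    raise ValueError
                color = (r, g, b)
            except ValueError:
                log.warning("%s line %d: malformed itemRgb %r; color left unset",
                            path.name, line_no, cols[8])
        intervals.append(
            AnnotationInterval(
                sample_id=cols[0], start=start, end=end,
                name=name, color=color, line_no=line_no,
            )
        )
    return intervals


def attach_annotations(entries: list[SequenceEntry]) -> None:
    """Load per-entry BED files (config-table mode) into ``entry.annotations``.

    Intervals are re-keyed to the entry's sample id: in per-sequence BED
    files the first column is a contig name that need not match SampleID.
    """
    for entry in entries:
        if entry.annotation_path is None or entry.annotations:
            continue
        for iv in parse_bed(entry.annotation_path):
            iv.sample_id = entry.sample_id
            entry.annotations.append(iv)


def validate_annotations(entries: list[SequenceEntry]) -> None:
    """Check every annotation interval against its sequence length."""
    for entry in entries:
        for iv in entry.annotations:
            if iv.end > entry.length:
                raise InputValidationError(
                    f"annotation [{iv.start}, {iv.end}) exceeds length "
                    f"{entry.length} of sequence {entry.sample_id!r}"
                )
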