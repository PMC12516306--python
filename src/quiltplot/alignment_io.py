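"""Pairwise alignment records: PAF / LastZ-general parsing, aligner invocation, caching.

A local alignment between a target sequence S1 and a query sequence S2 is
the line segment from (x, y) to (x + l1, y + l2) of a dot plot, where x
and y are the start positions on S1 and S2 and l1, l2 the aligned
substring lengths.  Records store 0-based half-open intervals on both
sequences, with query coordinates always on the forward strand (the PAF
convention), plus a percent identity in [0, 100].

For the ordered pair (i, j) with i <= j by input order, sequence i is the
target and sequence j the query; this fixes cell geometry downstream.
Raw aligner output is cached verbatim under
``<out_dir>/alignments/<idA>__<idB>.<aligner>.txt`` and reused on rerun.
"""

from __future__ import annotations

import logging
import re
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .config_io import SequenceEntry, read_sequence
from .errors import AlignerError, ContractError, ParseError

log = logging.getLogger("quiltplot.align")

ALIGNERS = ("lastz", "minimap2", "mashmap")

#: Command templates, user-overridable; {target} and {query} are FASTA paths.
DEFAULT_TEMPLATES = {
    "minimap2": "minimap2 -c -x asm20 -t 1 {target} {query}",
    "lastz": (
        "lastz {target} {query} --format=general:"
        "name1,zstart1,end1,size1,strand1,name2,zstart2+,end2+,size2,strand2,id%"
    ),
    "mashmap": "mashmap -r {target} -q {query} -t 1 --noSplit -o /dev/stdout",
}

LASTZ_REQUIRED = ("name1", "zstart1", "end1", "name2", "strand2", "zstart2+", "end2+", "id%")


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment between a target (S1) and a query (S2) sequence."""

    target_id: str
    query_id: str
    t_start: int
    t_end: int
    q_start: int
    q_end: int
    strand: str
    percent_identity: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.t_start < self.t_end):
            raise ContractError(f"bad target interval [{self.t_start}, {self.t_end})")
        if not (0 <= self.q_start < self.q_end):
            raise ContractError(f"bad query interval [{self.q_start}, {self.q_end})")
        if self.strand not in ("+", "-"):
            raise ContractError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ContractError(f"percent identity {self.percent_identity} outside [0, 100]")

    @property
    def l1(self) -> int:
        return self.t_end - self.t_start

    @property
    def l2(self) -> int:
        return self.q_end - self.q_start

    @property
    def span(self) -> int:
        """Alignment length used by display thresholds: max(l1, l2)."""
        return max(self.l1, self.l2)


@dataclass
class AlignmentSet:
    """All alignments for one ordered (target, query) pair."""

    target_id: str
    query_id: str
    records: list[AlignmentRecord] = field(default_factory=list)

    @property
    def pair_key(self) -> tuple[str, str]:
        return (self.target_id, self.query_id)

    @property
    def is_self(self) -> bool:
        return self.target_id == self.query_id


def parse_paf(stream: Iterable[str], pair: tuple[str, str]) -> list[AlignmentRecord]:
    """Parse PAF lines, keeping records for ``pair = (target_id, query_id)``.

    Percent identity is 100 * matches (col 10) / block length (col 11); a
    MashMap ``id:f:`` tag, when present, overrides that estimate.  Lines
    for other pairs are skipped (count logged); zero block length skips
    the record with a warning.
    """
    target_id, query_id = pair
    records: list[AlignmentRecord] = []
    skipped = 0
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ParseError(f"PAF line {line_no}: expected >=12 columns, got {len(cols)}")
        qname, tname = cols[0], cols[5]
        if (tname, qname) != (target_id, query_id):
            skipped += 1
            continue
        try:
            qlen, qs, qe = int(cols[1]), int(cols[2]), int(cols[3])
            tlen, ts, te = int(cols[6]), int(cols[7]), int(cols[8])
            matches, block = int(cols[9]), int(cols[10])
        except ValueError as exc:
            raise ParseError(f"PAF line {line_no}: non-integer coordinate field") from exc
        strand = cols[4]
        if strand not in ("+", "-"):
            raise ParseError(f"PAF line {line_no}: bad strand {strand!r}")
        if block == 0:
            log.warning("PAF line %d: zero block length; record skipped", line_no)
            continue
        if te > tlen or qe > qlen:
            raise ParseError(f"PAF line {line_no}: interval exceeds stated sequence length")
        pi = 100.0 * matches / block
        for tag in cols[12:]:
            if tag.startswith("id:f:"):
                val = float(tag[5:])
                pi = val * 100.0 if val <= 1.0 else val
        records.append(
            AlignmentRecord(
                target_id=tname, query_id=qname,
                t_start=ts, t_end=te, q_start=qs, q_end=qe,
                strand=strand, percent_identity=pi, source="paf",
            )
        )
    if skipped:
        log.info("pair (%s, %s): skipped %d PAF lines for other pairs",
                 target_id, query_id, skipped)
    return records


def parse_lastz_general(stream: Iterable[str], pair: tuple[str, str]) -> list[AlignmentRecord]:
    """Parse LastZ "general" tabular output for one (target, query) pair.

    The header line names the fields; ``zstart*``/``end*`` coordinates are
    0-based half-open.  ``id%`` values like ``"97.3%"`` parse to 97.3.
    Minus-strand query coordinates are converted to forward-strand
    coordinates with the query length from the ``size2`` column.
    """
    from .errors import InputValidationError

    target_id, query_id = pair
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    if not lines:
        return []
    header = lines[0].lstrip("#").strip()
    fields = header.split("\t") if "\t" in header else header.split()
    index = {name: i for i, name in enumerate(fields)}
    for name in LASTZ_REQUIRED:
        if name not in index:
            raise ParseError(f"LastZ general header missing required field {name!r}")
    records: list[AlignmentRecord] = []
    skipped = 0
    for line_no, line in enumerate(lines[1:], start=2):
        cols = line.split("\t") if "\t" in line else line.split()
        row = {name: cols[i] for name, i in index.items() if i < len(cols)}
        if (row.get("name1"), row.get("name2")) != (target_id, query_id):
            skipped += 1
            continue
        ts, te = int(row["zstart1"]), int(row["end1"])
        qs, qe = int(row["zstart2+"]), int(row["end2+"])
        strand = row["strand2"]
        if strand not in ("+", "-"):
            raise ParseError(f"LastZ line {line_no}: bad strand2 {strand!r}")
        if strand == "-":
            if "size2" not in row:
                raise ParseError(
                    f"LastZ line {line_no}: minus-strand row needs the 'size2' field"
                )
            qlen = int(row["size2"])
            qs, qe = qlen - qe, qlen - qs
        pi = float(row["id%"].rstrip("%"))
        if not (0.0 <= pi <= 100.0):
            raise InputValidationError(f"LastZ line {line_no}: id% {pi} outside [0, 100]")
        records.append(
            AlignmentRecord(
                target_id=target_id, query_id=query_id,
                t_start=ts, t_end=te, q_start=qs, q_end=qe,
                strand=strand, percent_identity=pi, source="lastz",
            )
        )
    if skipped:
        log.info("pair (%s, %s): skipped %d LastZ rows for other pairs",
                 target_id, query_id, skipped)
    return records


def to_paf_line(rec: AlignmentRecord, query_length: int, target_length: int) -> str:
    """Serialize a record as one 12-column PAF line (used for caches/round trips)."""
    block = rec.span
    matches = round(rec.percent_identity / 100.0 * block)
    cols = [
        rec.query_id, query_length, rec.q_start, rec.q_end, rec.strand,
        rec.target_id, target_length, rec.t_start, rec.t_end, matches, block, 60,
    ]
    return "\t".join(str(c) for c in cols)


_SANITIZE_RE = re.compile(r"[^A-Za-z0-9._-]")


def sanitize_id(sample_id: str) -> str:
    return _SANITIZE_RE.sub("_", sample_id)


def cache_path(out_dir: str | Path, target_id: str, query_id: str, aligner: str) -> Path:
    """Deterministic cache file path, unique per unordered pair and aligner."""
    if aligner not in ALIGNERS:
        raise ContractError(f"unknown aligner {aligner!r}")
    a, b = sanitize_id(target_id), sanitize_id(query_id)
    if a == b and target_id != query_id:
        raise ContractError(
            f"sample ids {target_id!r} and {query_id!r} sanitize to the same token {a!r}"
        )
    first, second = sorted((a, b))
    return Path(out_dir) / "alignments" / f"{first}__{second}.{aligner}.txt"


def _parser_for(aligner: str):
    return parse_lastz_general if aligner == "lastz" else parse_paf


def _ensure_pair_fasta(entry: SequenceEntry, out_dir: Path) -> Path:
    """Materialize a single-record FASTA (header = sample id) for aligner input."""
    path = out_dir / "seqs" / f"{sanitize_id(entry.sample_id)}.fasta"
    if path.is_file():
        return path
    path.parent.mkdir(parents=True, exist_ok=True)
    seq = read_sequence(entry)
    with path.open("w") as fh:
        fh.write(f">{entry.sample_id}\n")
        for k in range(0, len(seq), 80):
            fh.write(seq[k : k + 80] + "\n")
    return path


def run_pairwise_alignments(
    entries: list[SequenceEntry],
    aligner: str,
    out_dir: str | Path,
    templates: dict[str, str] | None = None,
) -> dict[tuple[str, str], AlignmentSet]:
    """Compute or load alignments for all n(n+1)/2 ordered pairs (i <= j).

    A cached raw output file is loaded when present; otherwise the aligner
    is invoked and its stdout stored under a deterministic name before
    parsing.  An unparseable cache file is an error, never silently
    regenerated.
    """
    if aligner not in ALIGNERS:
        raise ContractError(f"unknown aligner {aligner!r}; choose from {ALIGNERS}")
    out_dir = Path(out_dir)
    template = (templates or {}).get(aligner, DEFAULT_TEMPLATES[aligner])
    parser = _parser_for(aligner)
    sets: dict[tuple[str, str], AlignmentSet] = {}
    invocations = 0
    for i, target in enumerate(entries):
        for query in entries[i:]:
            pair = (target.sample_id, query.sample_id)
            cpath = cache_path(out_dir, *pair, aligner)
            if cpath.is_file():
                text = cpath.read_text()
            else:
                t_fa = _ensure_pair_fasta(target, out_dir)
                q_fa = _ensure_pair_fasta(query, out_dir)
                cmd = template.format(target=str(t_fa), query=str(q_fa))
                log.info("running: %s", cmd)
                try:
                    proc = subprocess.run(
                        shlex.split(cmd), capture_output=True, text=True, check=False
                    )
                except FileNotFoundError as exc:
                    raise AlignerError(f"aligner executable not found: {exc}") from exc
                if proc.returncode != 0:
                    raise AlignerError(
                        f"{aligner} failed on pair {pair} (exit {proc.returncode}): "
                        f"{proc.stderr.strip()[:2000]}"
                    )
                invocations += 1
                cpath.parent.mkdir(parents=True, exist_ok=True)
                cpath.write_text(proc.stdout)
                text = proc.stdout
            try:
                records = parser(text.splitlines(), pair)
            except (ParseError, ValueError) as exc:
                raise ParseError(f"cannot parse cached alignment file {cpath}: {exc}") from exc
            sets[pair] = AlignmentSet(target_id=pair[0], query_id=pair[1], records=records)
    log.info("%d pairs: %d aligner invocation(s), %d loaded from cache",
             len(sets), invocations, len(sets) - invocations)
    return sets


def replace_records(aset: AlignmentSet, records: list[AlignmentRecord]) -> AlignmentSet:
    return AlignmentSet(target_id=aset.target_id, query_id=aset.query_id, records=records)


__all__ = [
    "AlignmentRecord", "AlignmentSet", "ALIGNERS", "DEFAULT_TEMPLATES",
    "parse_paf", "parse_lastz_general", "to_paf_line",
    "cache_path", "sanitize_id", "run_pairwise_alignments", "replace_records",
]
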