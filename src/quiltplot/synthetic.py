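"""Synthetic multi-sequence loci with known duplication/inversion structure.

Each sequence is a concatenation of copies drawn from a shared block
library, each copy optionally reverse-complemented and point-mutated at
an exact number of distinct positions, separated by short random spacers
that share no homology.  Because substitutions are enumerated (sampled
without replacement, always to a different base), the percent identity
between any two copies of a block is an exact count, not an expectation,
and ground-truth alignment records can be emitted for every pair of
copies sharing a block — these stand in for aligner output (exported in
the PAF dialect), so the full pipeline is testable without external
binaries or downloads.

Defaults model a repeat-rich locus of a few hundred kbp: five haplotypes
sharing 8-30 kbp segments, a tandem duplication, a local inversion, one
globally reverse-complemented haplotype, and per-copy divergences of
2-8% — the regime where display defaults (5 kbp minimum alignment span,
85-100% identity range) are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import AlignmentRecord, to_paf_line, cache_path
from .config_io import SequenceEntry
from .errors import InputValidationError

BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BlockPlacement:
    """One copy of a library block inside a sequence."""

    block_id: str
    strand: str = "+"
    divergence: float = 0.0  # substitutions per bp, exact count applied


@dataclass
class LocusSpec:
    """Recipe for a deterministic synthetic locus set."""

    seed: int
    block_library: list[tuple[str, int]]
    sequence_orders: list[list[BlockPlacement]]
    sample_ids: list[str] | None = None
    gene_blocks: tuple[str, ...] = ()
    block_colors: dict[str, tuple[int, int, int] | None] = field(default_factory=dict)
    declared_strands: dict[str, str] = field(default_factory=dict)
    spacer_len: int = 200

    def __post_init__(self) -> None:
        if not self.sequence_orders:
            raise InputValidationError("spec needs at least one sequence")
        ids = {bid for bid, _ in self.block_library}
        for bid, length in self.block_library:
            if length <= 0:
                raise InputValidationError(f"block {bid!r} has non-positive length")
        for order in self.sequence_orders:
            for pl in order:
                if pl.block_id not in ids:
                    raise InputValidationError(f"unknown block id {pl.block_id!r}")
                if not (0.0 <= pl.divergence <= 0.3):
                    raise InputValidationError(
                        f"divergence {pl.divergence} outside [0, 0.3] for block {pl.block_id!r}"
                    )
                if pl.strand not in ("+", "-"):
                    raise InputValidationError(f"bad strand {pl.strand!r}")
        if self.sample_ids is not None and len(self.sample_ids) != len(self.sequence_orders):
            raise InputValidationError("sample_ids length must match sequence_orders")

    @property
    def n_sequences(self) -> int:
        return len(self.sequence_orders)


@dataclass(frozen=True)
class BlockCopy:
    """Realized copy of a block: location, strand and mutated forward string."""

    block_id: str
    start: int
    end: int
    strand: str
    forward_block_seq: str  # block-forward orientation, mutations applied


@dataclass
class LocusSet:
    """A generated locus: sequences, annotations and ground-truth alignments."""

    spec: LocusSpec
    sample_ids: list[str]
    sequences: dict[str, str]
    copies: dict[str, list[BlockCopy]]
    fasta_text: str
    bed_text: str
    records: dict[tuple[str, str], list[AlignmentRecord]]

    @property
    def lengths(self) -> dict[str, int]:
        return {sid: len(seq) for sid, seq in self.sequences.items()}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    n_sub = int(round(divergence * len(seq)))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = bytearray(seq, "ascii")
    for pos in positions:
        current = chr(out[pos])
        alternatives = [b for b in "ACGT" if b != current]
        out[pos] = ord(alternatives[rng.integers(0, 3)])
    return out.decode()


def generate_locus_set(spec: LocusSpec) -> LocusSet:
    """Build sequences, BED annotations and exact ground-truth alignments.

    For every unordered sequence pair (i, j), i <= j, a record is emitted
    for each pair of copies sharing a block id; its percent identity is
    100 x (matching positions) / (block length), counted directly on the
    realized copies.  Self pairs additionally carry the trivial
    full-length identity alignment aligners report.
    """
    rng = np.random.default_rng(spec.seed)
    block_seqs = {bid: _random_seq(rng, length) for bid, length in spec.block_library}
    sample_ids = spec.sample_ids or [f"seq{k + 1}" for k in range(spec.n_sequences)]
    if len(set(sample_ids)) != len(sample_ids):
        raise InputValidationError("sample ids must be unique")

    sequences: dict[str, str] = {}
    copies: dict[str, list[BlockCopy]] = {}
    for sid, order in zip(sample_ids, spec.sequence_orders):
        parts: list[str] = []
        cursor = 0
        seq_copies: list[BlockCopy] = []
        for pl in order:
            spacer = _random_seq(rng, spec.spacer_len)
            parts.append(spacer)
            cursor += len(spacer)
            mutated = _mutate(rng, block_seqs[pl.block_id], pl.divergence)
            emitted = mutated if pl.strand == "+" else revcomp(mutated)
            parts.append(emitted)
            seq_copies.append(
                BlockCopy(
                    block_id=pl.block_id, start=cursor, end=cursor + len(emitted),
                    strand=pl.strand, forward_block_seq=mutated,
                )
            )
            cursor += len(emitted)
        parts.append(_random_seq(rng, spec.spacer_len))
        sequences[sid] = "".join(parts)
        copies[sid] = seq_copies

    records: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for i, sid_i in enumerate(sample_ids):
        for sid_j in sample_ids[i:]:
            pair_records: list[AlignmentRecord] = []
            for a in copies[sid_i]:
                for b in copies[sid_j]:
                    if a.block_id != b.block_id:
                        continue
                    if sid_i == sid_j and a is b:
                        continue  # covered by the full-length self record
                    matches = sum(
                        x == y for x, y in zip(a.forward_block_seq, b.forward_block_seq)
                    )
                    length = len(a.forward_block_seq)
                    pair_records.append(
                        AlignmentRecord(
                            target_id=sid_i, query_id=sid_j,
                            t_start=a.start, t_end=a.end,
                            q_start=b.start, q_end=b.end,
                            strand="+" if a.strand == b.strand else "-",
                            percent_identity=100.0 * matches / length,
                            source="ground-truth",
                        )
                    )
            if sid_i == sid_j:
                L = len(sequences[sid_i])
                pair_records.append(
                    AlignmentRecord(
                        target_id=sid_i, query_id=sid_i,
                        t_start=0, t_end=L, q_start=0, q_end=L,
                        strand="+", percent_identity=100.0, source="ground-truth",
                    )
                )
            records[(sid_i, sid_j)] = pair_records

    fasta_lines: list[str] = []
    for sid in sample_ids:
        fasta_lines.append(f">{sid}")
        seq = sequences[sid]
        fasta_lines += [seq[k : k + 80] for k in range(0, len(seq), 80)]
    fasta_text = "\n".join(fasta_lines) + "\n"

    bed_lines: list[str] = []
    for sid in sample_ids:
        for copy in copies[sid]:
            if copy.block_id not in spec.gene_blocks:
                continue
            color = spec.block_colors.get(copy.block_id)
            if color is None:
                bed_lines.append(f"{sid}\t{copy.start}\t{copy.end}\t{copy.block_id}")
            else:
                rgb = ",".join(str(c) for c in color)
                bed_lines.append(
                    f"{sid}\t{copy.start}\t{copy.end}\t{copy.block_id}\t0\t"
                    f"{copy.strand}\t{copy.start}\t{copy.end}\t{rgb}"
                )
    bed_text = "\n".join(bed_lines) + ("\n" if bed_lines else "")

    return LocusSet(
        spec=spec, sample_ids=sample_ids, sequences=sequences, copies=copies,
        fasta_text=fasta_text, bed_text=bed_text, records=records,
    )


def default_locus_spec(seed: int = 0) -> LocusSpec:
    """Five haplotypes of a duplication-rich locus (~400 kbp total).

    seq4 is a global reverse complement of the reference architecture
    (planted inversion); seq2 carries a tandem duplication; seq3 a local
    inversion; seq5 an inverted duplicate and a private block.
    """
    library = [
        ("A", 30_000), ("B", 20_000), ("C", 15_000),
        ("D", 25_000), ("E", 10_000), ("F", 8_000),
    ]
    orders = [
        [BlockPlacement("A"), BlockPlacement("B"), BlockPlacement("C"), BlockPlacement("E")],
        [
            BlockPlacement("A", divergence=0.03), BlockPlacement("B", divergence=0.03),
            BlockPlacement("B", divergence=0.05), BlockPlacement("C", divergence=0.03),
            BlockPlacement("E", divergence=0.02),
        ],
        [
            BlockPlacement("A", divergence=0.05), BlockPlacement("C", "-", 0.05),
            BlockPlacement("D", divergence=0.05), BlockPlacement("E", divergence=0.05),
        ],
        [
            BlockPlacement("E", "-", 0.04), BlockPlacement("C", "-", 0.04),
            BlockPlacement("B", "-", 0.04), BlockPlacement("A", "-", 0.04),
        ],
        [
            BlockPlacement("A", divergence=0.08), BlockPlacement("B", "-", 0.08),
            BlockPlacement("C", divergence=0.08), BlockPlacement("F"),
        ],
    ]
    return LocusSpec(
        seed=seed,
        block_library=library,
        sequence_orders=orders,
        sample_ids=["hap1", "hap2", "hap3", "hap4", "hap5"],
        gene_blocks=("B", "E"),
        block_colors={"E": (0, 128, 0)},
    )


def write_config(entries: list[SequenceEntry], out_dir: str | Path,
                 filename: str = "config.tsv") -> Path:
    """Emit a configuration table that round-trips through ``parse_config``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with_annot = any(e.annotation_path is not None for e in entries)
    with_strand = any(e.declared_strand is not None for e in entries)
    header = ["Fasta", "SampleID", "Label"]
    if with_annot:
        header.append("Annotation")
    if with_strand:
        header.append("Strand")
    lines = ["\t".join(header)]
    for e in entries:
        row = [str(e.fasta_path), e.sample_id, e.label]
        if with_annot:
            row.append(str(e.annotation_path) if e.annotation_path else "")
        if with_strand:
            row.append(e.declared_strand or "")
        lines.append("\t".join(row))
    path = out_dir / filename
    path.write_text("\n".join(lines) + "\n")
    return path


def write_inputs(locus: LocusSet, out_dir: str | Path, mode: str = "config") -> Path:
    """Write the locus to disk in one of the two input dialects.

    ``config`` mode writes per-sequence FASTA/BED files plus a TSV table
    and returns the table path; ``simplified`` writes one combined FASTA
    (and BED when annotations exist) and returns the FASTA path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if mode == "simplified":
        fasta = out_dir / "locus.fasta"
        fasta.write_text(locus.fasta_text)
        if locus.bed_text:
            (out_dir / "locus.bed").write_text(locus.bed_text)
        return fasta
    if mode != "config":
        raise InputValidationError(f"unknown input mode {mode!r}")
    seq_dir = (out_dir / "seqs").resolve()
    seq_dir.mkdir(exist_ok=True)
    bed_by_sid: dict[str, list[str]] = {}
    for line in locus.bed_text.splitlines():
        bed_by_sid.setdefault(line.split("\t", 1)[0], []).append(line)
    entries: list[SequenceEntry] = []
    for order, sid in enumerate(locus.sample_ids):
        fasta = seq_dir / f"{sid}.fasta"
        seq = locus.sequences[sid]
        with fasta.open("w") as fh:
            fh.write(f">{sid}\n")
            for k in range(0, len(seq), 80):
                fh.write(seq[k : k + 80] + "\n")
        annot = None
        if sid in bed_by_sid:
            annot = seq_dir / f"{sid}.bed"
            annot.write_text("\n".join(bed_by_sid[sid]) + "\n")
        entries.append(
            SequenceEntry(
                sample_id=sid, label=sid, fasta_path=fasta,
                annotation_path=annot,
                declared_strand=locus.spec.declared_strands.get(sid),
                length=len(seq), order_index=order,
            )
        )
    return write_config(entries, out_dir)


def write_ground_truth_cache(locus: LocusSet, out_dir: str | Path,
                             aligner: str = "minimap2") -> list[Path]:
    """Store ground-truth records as PAF cache files under ``out_dir``.

    A subsequent `run_pairwise_alignments` on the same directory then
    loads them with zero aligner invocations.
    """
    lengths = locus.lengths
    paths: list[Path] = []
    for (tid, qid), recs in locus.records.items():
        path = cache_path(out_dir, tid, qid, aligner)
        path.parent.mkdir(parents=True, exist_ok=True)
        lines = [to_paf_line(r, lengths[qid], lengths[tid]) for r in recs]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths.append(path)
    return paths
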