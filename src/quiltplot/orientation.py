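"""Display orientation of each sequence relative to the first (reference) sequence.

A sequence whose alignments to the reference are predominantly on the
minus strand is displayed reverse-complemented.  "Predominantly" is
measured as total aligned reference-span bp per strand; the strand with
the larger total wins, ties and missing evidence fall back to '+'.  A
strand declared in the input always wins over inference.

Reversal is pure coordinate algebra on 0-based half-open intervals:
[s, e) on a sequence of length L maps to [L - e, L - s), an involution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .alignment_io import AlignmentRecord, AlignmentSet, replace_records
from .config_io import AnnotationInterval, SequenceEntry
from .errors import ContractError

log = logging.getLogger("quiltplot.orient")


@dataclass(frozen=True)
class OrientationDecision:
    """Outcome of orienting one sequence against the reference."""

    sample_id: str
    strand: str  # '+' or '-'
    basis: str  # 'declared' | 'inferred' | 'fallback'
    forward_support: int = 0  # total bp of '+' alignments on the reference
    reverse_support: int = 0  # total bp of '-' alignments on the reference


def infer_orientation(
    records: list[AlignmentRecord], reference_id: str, sample_id: str
) -> OrientationDecision:
    """Decide the strand of ``sample_id`` from its alignments to the reference.

    Support per strand is the summed target-span (reference-side) length;
    '-' wins only with strictly greater support.  No records at all falls
    back to '+' with a warning.
    """
    if sample_id == reference_id:
        raise ContractError("cannot infer orientation of the reference against itself")
    fwd = rev = 0
    for rec in records:
        if {rec.target_id, rec.query_id} != {reference_id, sample_id}:
            raise ContractError(
                f"record for pair ({rec.target_id}, {rec.query_id}) passed while "
                f"inferring orientation of {sample_id!r} vs {reference_id!r}"
            )
        if rec.strand == "+":
            fwd += rec.l1
        else:
            rev += rec.l1
    if not records:
        log.warning("%s: no alignments to reference %s; defaulting to '+'",
                    sample_id, reference_id)
        return OrientationDecision(sample_id, "+", "fallback", 0, 0)
    strand = "-" if rev > fwd else "+"
    return OrientationDecision(sample_id, strand, "inferred", fwd, rev)


def resolve_orientations(
    entries: list[SequenceEntry], sets: dict[tuple[str, str], AlignmentSet]
) -> dict[str, OrientationDecision]:
    """Orientation decision for every entry: declared strand wins, the
    reference is always '+', everything else is inferred."""
    if not entries:
        raise ContractError("resolve_orientations needs at least one entry")
    ref = entries[0]
    decisions: dict[str, OrientationDecision] = {}
    if ref.declared_strand == "-":
        log.warning("reference %s declared '-' is ignored; the reference is always '+'",
                    ref.sample_id)
    decisions[ref.sample_id] = OrientationDecision(
        ref.sample_id, "+", "declared" if ref.declared_strand else "fallback", 0, 0
    )
    for entry in entries[1:]:
        key = (ref.sample_id, entry.sample_id)
        records = sets[key].records if key in sets else []
        if entry.declared_strand is not None:
            fwd = sum(r.l1 for r in records if r.strand == "+")
            rev = sum(r.l1 for r in records if r.strand == "-")
            decisions[entry.sample_id] = OrientationDecision(
                entry.sample_id, entry.declared_strand, "declared", fwd, rev
            )
        else:
            decisions[entry.sample_id] = infer_orientation(
                records, ref.sample_id, entry.sample_id
            )
    for d in decisions.values():
        log.info("orientation %s: %s (%s; +%d bp / -%d bp)",
                 d.sample_id, d.strand, d.basis, d.forward_support, d.reverse_support)
    return decisions


def reverse_interval(start: int, end: int, length: int) -> tuple[int, int]:
    """Map the half-open interval [start, end) to reverse-complement coordinates."""
    if not (0 <= start < end <= length):
        raise ContractError(
            f"interval [{start}, {end}) invalid on a sequence of length {length}"
        )
    return (length - end, length - start)


def reorient_alignments(
    aset: AlignmentSet,
    flip_target: bool,
    flip_query: bool,
    target_len: int,
    query_len: int,
) -> AlignmentSet:
    """Rewrite a set's coordinates for reversed sequences.

    Flipped sides get reversed intervals; the strand toggles iff exactly
    one side flips.  Percent identity and record count are unchanged.
    """
    if not (flip_target or flip_query):
        return aset
    out: list[AlignmentRecord] = []
    toggle = flip_target != flip_query
    for rec in aset.records:
        ts, te = (reverse_interval(rec.t_start, rec.t_end, target_len)
                  if flip_target else (rec.t_start, rec.t_end))
        qs, qe = (reverse_interval(rec.q_start, rec.q_end, query_len)
                  if flip_query else (rec.q_start, rec.q_end))
        strand = rec.strand
        if toggle:
            strand = "-" if strand == "+" else "+"
        out.append(
            AlignmentRecord(
                target_id=rec.target_id, query_id=rec.query_id,
                t_start=ts, t_end=te, q_start=qs, q_end=qe,
                strand=strand, percent_identity=rec.percent_identity,
                source=rec.source,
            )
        )
    return replace_records(aset, out)


def reorient_annotations(
    intervals: list[AnnotationInterval], length: int
) -> list[AnnotationInterval]:
    """Map annotation intervals to reverse-complement coordinates (order kept)."""
    out: list[AnnotationInterval] = []
    for iv in intervals:
        try:
            s, e = reverse_interval(iv.start, iv.end, length)
        except ContractError as exc:
            raise ContractError(
                f"annotation {iv.name or ''}[{iv.start}, {iv.end}) on "
                f"{iv.sample_id!r}: {exc}"
            ) from exc
        out.append(
            AnnotationInterval(
                sample_id=iv.sample_id, start=s, end=e,
                name=iv.name, color=iv.color, line_no=iv.line_no,
            )
        )
    return out


def apply_orientations(
    entries: list[SequenceEntry],
    sets: dict[tuple[str, str], AlignmentSet],
    decisions: dict[str, OrientationDecision],
) -> dict[tuple[str, str], AlignmentSet]:
    """Rewrite all alignment sets and entry annotations for reversed sequences.

    Entries' annotation lists are replaced in place; a new set map is
    returned.
    """
    lengths = {e.sample_id: e.length for e in entries}
    flipped = {sid for sid, d in decisions.items() if d.strand == "-"}
    out: dict[tuple[str, str], AlignmentSet] = {}
    for key, aset in sets.items():
        out[key] = reorient_alignments(
            aset,
            flip_target=aset.target_id in flipped,
            flip_query=aset.query_id in flipped,
            target_len=lengths[aset.target_id],
            query_len=lengths[aset.query_id],
        )
    for entry in entries:
        if entry.sample_id in flipped and entry.annotations:
            entry.annotations = reorient_annotations(entry.annotations, entry.length)
    return out
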