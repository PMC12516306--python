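# Methods

## Problem and model

Given n annotated sequences, the tool draws every pairwise dot plot in one
triangular matrix. A dot plot between a target S1 and a query S2 renders
each local alignment of substring lengths l1 and l2 as the line segment
from (x, y) to (x + l1, y + l2); reverse-strand alignments get negative
slope by swapping the query endpoints. Cell (i, j), i ≤ j, holds the dot
plot of sequences i and j; the diagonal holds self-alignments, including
the trivial full-length identity alignment when the aligner reports it
(no special suppression — off-diagonal self-hits are exactly the tandem
and segmental duplications the figure exists to expose).

Alignments are consumed, not computed: minimap2 and MashMap via PAF,
LastZ via its "general" tabular format. All internal coordinates are
0-based half-open; PAF query coordinates are forward-strand by
definition and LastZ minus-strand query intervals are converted to
forward-strand via [s, e) → [L − e, L − s) using the `size2` column.
Percent identity comes from PAF as 100·matches/block-length, overridden
by a MashMap `id:f:` tag when present (trusted verbatim), and from LastZ
as the `id%` field.

## Orientation

The first input sequence fixes the display orientation; every other
sequence is compared to it. The decision statistic is the total aligned
reference-span bp per strand over *all* parsed records (not only those
passing the display length filter — orientation is a data property, not a
styling property). The minus strand wins only with strictly greater
support; ties and sequences with no alignment to the reference stay '+'
(with a warning), and there is no transitive orientation through third
sequences. The aggregate was chosen over the single longest record
because one spurious long hit should not flip a sequence. A declared
strand in the input always wins; the reference itself is always '+'.

Reversal rewrites alignment intervals on the flipped side(s), toggles the
strand iff exactly one side flips, and maps annotation intervals the same
way. All three operations are involutions, which the property tests
exercise directly.

## Styling

Display filtering keeps alignments with max(l1, l2) ≥ min-len
(default 5000 bp); breakpoint lines use the same rule with their own
threshold (default 10 000 bp). The max-span reading is symmetric in the
pair and conservative toward showing structure; counts quoted in logs
depend on it. Thresholds are inclusive ("passing" read as ≥).

PI is clamped into [min-pi, max-pi] (defaults 85, 100), mapped affinely
to u ∈ [0, 1], and colored as colormap(1 − u) under the default reversed
orientation — implementing reversal on the unit value keeps the legend
axis in PI units. A single color may replace the colormap; unit values
are still computed so the legend can state the range. Colors are resolved
at styling time, not render time, so tests assert on RGBA values without
a graphics backend.

## Layout and rendering

Column sequences sit on x, row sequences on y; lower-triangle mode is the
transpose of upper. For the pair (i, j) ordered by input position,
sequence i is the alignment target, so lower mode has the target on x.
Cell extents are proportional to sequence lengths at a common scale
(default 50 kbp/inch, with the total data extent clamped to 3–30 inches
for readability); equal-length sequences therefore get equal-size, square
diagonal cells. Annotation strips (one per sequence) sit on the outer
margin adjacent to the sequence's axis — above the columns in upper mode,
left of the rows in lower mode — with rectangles spanning [start, end),
black unless the BED line carries an itemRgb color. Breakpoint guide
lines are drawn beneath the alignment segments, span only their own cell,
and are deduplicated per (axis, coordinate).

Output is a combined PNG (300 dpi, optionally transparent) and PDF plus
one PNG/PDF per pair. The PDF creation timestamp is suppressed so vector
output is byte-stable across reruns; the end-to-end tests assert this.

## Caching

Raw aligner stdout is stored verbatim (never a re-serialization) under
`alignments/<idA>__<idB>.<aligner>.txt`, keyed by the unordered sanitized
id pair; a rerun on the same output directory performs zero aligner
invocations. An unparseable cache file is an error, never silently
regenerated, because silent regeneration would mask aligner/version
drift. Aligner flags live in per-aligner command templates
(`alignment_io.DEFAULT_TEMPLATES`) that callers may override.

## Synthetic data

The generator concatenates copies of shared library blocks — optionally
reverse-complemented and point-mutated — separated by short random
spacers with no homology. Substitutions are sampled without replacement
at distinct positions and always change the base, so the percent identity
between two copies is an exact count over the realized strings, not an
expectation; ground-truth alignment records (exported in the PAF dialect
as a pre-seeded cache) follow from the construction. The default locus
models five haplotypes of a duplication-rich region (~400 kbp total,
blocks 8–30 kbp, divergences 2–8%, a tandem duplication, a local
inversion, one globally reverse-complemented haplotype) — the regime
where the default display thresholds are meaningful, and small enough
that the full pipeline including rendering completes in a few seconds on
one CPU.

What the generator does not emulate: indels (ground-truth alignments are
ungapped, so l1 = l2 always, whereas real aligners report gapped blocks),
nested/overlapping repeats, mosaic block boundaries, and realistic repeat
families. Passing tests therefore demonstrate coordinate, orientation and
rendering correctness on exactly-known structure, not aligner robustness
on biological sequence; the one real-aligner integration test (minimap2
on a shared 30 kbp block) covers the subprocess path but not large-locus
behavior.

## Numerical and degenerate-input choices

- Orientation ties break to '+'; empty alignment sets fall back to '+'.
- `min_pi == max_pi` is rejected rather than special-cased.
- Multi-record FASTA in per-sequence mode: a record whose id equals the
  SampleID wins, otherwise the first record is used with a warning.
- BED intervals with start ≥ end, or extending past the sequence end,
  are hard errors with the line/interval named; a malformed itemRgb only
  warns and falls back to black.
- Sample ids are sanitized to `[A-Za-z0-9._-]` for file names; two ids
  colliding after sanitization is an error.

## Limitations

No SAM/BAM ingestion, no CIGAR-level identity recomputation, no built-in
aligner, no per-block partial reversal of a sequence, no GFF/GTF
annotations, and no interactive output. Very alignment-dense inputs
(millions of records) render but are bounded by matplotlib's segment
drawing, not by this package's data handling.
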