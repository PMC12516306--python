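# quiltplot

Automated, publication-ready visualization of pairwise local alignments
across many annotated sequences, arranged as a single triangular matrix of
dot plots.

Comparing a structurally complex locus — a segmental-duplication-rich
immunoglobulin locus, a polymorphic inversion, a centromere — across
several haplotypes or species quickly outgrows a single pairwise dot plot.
`quiltplot` takes *n* sequences, computes (or reuses) all n(n+1)/2 pairwise
local alignments with an external aligner (minimap2, LastZ or MashMap),
auto-orients every sequence against the first one, and renders every dot
plot into one matrix figure with percent-identity coloring, BED annotation
tracks and optional breakpoint guide lines.

## The model

A dot plot of sequences S1 and S2 draws each local alignment of substrings
of lengths l1 and l2 as a line segment from (x, y) to (x + l1, y + l2),
where x and y are the alignment start positions in S1 and S2; a
reverse-strand alignment has negative slope. `quiltplot` arranges the dot
plots of all pairs (i, j), i ≤ j, in the upper (or lower) triangle of an
n × n grid, with self-alignments on the diagonal and cell sizes
proportional to sequence lengths so one bp scale holds figure-wide.

Each alignment passing a minimum length (`--min-len`, default 5 kbp) is
colored by percent identity PI clamped into [`--min-pi`, `--max-pi`]
(defaults 85% and 100%) and projected into a matplotlib colormap (default
`rainbow`, reversed). A sequence whose alignments to the first sequence
are predominantly reverse-strand (by total aligned bp) is displayed
reverse-complemented, with its annotations and alignment coordinates
rewritten accordingly; a strand declared in the input always wins.

All raw aligner outputs are cached under the output directory and reused
verbatim on rerun, so re-styling a figure costs seconds, not an alignment
run.

## Worked example

The built-in generator creates a five-haplotype synthetic locus
(~400 kbp total) with shared blocks, a tandem duplication, a local
inversion and one globally reverse-complemented haplotype, plus exact
ground-truth alignments exported as a PAF cache:

```python
from pathlib import Path
from quiltplot.synthetic import (default_locus_spec, generate_locus_set,
                                 write_inputs, write_ground_truth_cache)
from quiltplot.cli import main

locus = generate_locus_set(default_locus_spec(seed=1))
cfg = write_inputs(locus, Path("demo/inputs"), mode="config")
write_ground_truth_cache(locus, Path("demo/run"))
main(["-i", str(cfg), "-o", "demo/run", "--show-annot", "--show-bp"])
```

which logs:

```
INFO | cli | config | 5 sequences
INFO | cli | lengths | total 403200 bp, 9 annotations
INFO | align | 15 pairs: 0 aligner invocation(s), 15 loaded from cache
INFO | cli | alignments | 15 pairs, 42 records
INFO | orient | orientation hap1: + (fallback; +0 bp / -0 bp)
INFO | orient | orientation hap2: + (inferred; +95000 bp / -0 bp)
INFO | orient | orientation hap3: + (inferred; +40000 bp / -15000 bp)
INFO | orient | orientation hap4: - (inferred; +0 bp / -75000 bp)
INFO | orient | orientation hap5: + (inferred; +45000 bp / -20000 bp)
INFO | cli | orientation | 1 reversed
INFO | cli | styling | 42 of 42 records pass min-len 5000
INFO | cli | layout | 15 cells (upper)
INFO | render | wrote 32 files under demo/run
INFO | cli | render | 32 files written
```

Five sequences give 15 dot plots; all 42 ground-truth alignments pass the
5 kbp display threshold; `hap4` — built as a global reverse complement of
the reference architecture — is detected as reverse-oriented from its
75 000 bp of minus-strand alignment support and is drawn flipped. The run
writes `demo/run/quiltplot.png` and `.pdf` (the combined matrix), one
PNG + PDF per pair under `demo/run/pairwise/`, and a machine-readable
`run_summary.json`.

Real data runs the same way, from a configuration table (columns `Fasta`,
`SampleID`, `Label`, optional `Annotation` BED paths and `Strand`), or
from one combined FASTA + BED:

```sh
quiltplot -i config.tsv -o out --aligner minimap2 --show-annot --lower
quiltplot -i all_loci.fasta --bed all_genes.bed -o out
```

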