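"""PAF / LastZ-general parsing, caching and aligner invocation."""

import subprocess

import pytest

from quiltplot import alignment_io
from quiltplot.alignment_io import (
    AlignmentRecord,
    cache_path,
    parse_lastz_general,
    parse_paf,
    run_pairwise_alignments,
    to_paf_line,
)
from quiltplot.config_io import SequenceEntry
from quiltplot.errors import AlignerError, ContractError, ParseError
from quiltplot.synthetic import (
    BlockPlacement,
    LocusSpec,
    generate_locus_set,
    write_ground_truth_cache,
    write_inputs,
)

from conftest import write_fasta


def paf_line(q="B", qlen=1000, qs=400, qe=450, strand="+", t="A", tlen=2000,
             ts=100, te=200, matches=90, block=100, extra=()):
    cols = [q, qlen, qs, qe, strand, t, tlen, ts, te, matches, block, 60, *extra]
    return "\t".join(str(c) for c in cols)


class TestParsePaf:
    def test_percent_identity_from_matches_over_block(self):
        (rec,) = parse_paf([paf_line(matches=90, block=100)], ("A", "B"))
        assert rec.percent_identity == pytest.approx(90.0)
        assert (rec.t_start, rec.t_end, rec.q_start, rec.q_end) == (100, 200, 400, 450)

    def test_minus_strand_keeps_forward_query_coords(self):
        (rec,) = parse_paf([paf_line(strand="-")], ("A", "B"))
        assert rec.strand == "-"
        assert (rec.q_start, rec.q_end) == (400, 450)

    def test_full_identity(self):
        (rec,) = parse_paf([paf_line(matches=100, block=100)], ("A", "B"))
        assert rec.percent_identity == 100.0

    def test_other_pairs_skipped(self):
        lines = [paf_line(), paf_line(q="C"), paf_line(t="Z")]
        assert len(parse_paf(lines, ("A", "B"))) == 1

    def test_short_line_is_parse_error_with_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_paf([paf_line(), "A\tB\tC"], ("A", "B"))

    def test_zero_block_length_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="quiltplot.align"):
            recs = parse_paf([paf_line(matches=0, block=0)], ("A", "B"))
        assert recs == []
        assert any("zero block" in r.message for r in caplog.records)

    def test_mashmap_identity_tag_overrides_ratio(self):
        (rec,) = parse_paf([paf_line(matches=50, block=100, extra=["id:f:97.5"])],
                           ("A", "B"))
        assert rec.percent_identity == pytest.approx(97.5)


LASTZ_HEADER = "#name1\tzstart1\tend1\tsize1\tname2\tstrand2\tzstart2+\tend2+\tsize2\tid%"


class TestParseLastzGeneral:
    def test_plus_strand_row(self):
        row = "A\t100\t200\t2000\tB\t+\t400\t450\t1000\t90.0%"
        (rec,) = parse_lastz_general([LASTZ_HEADER, row], ("A", "B"))
        assert rec.percent_identity == pytest.approx(90.0)
        assert (rec.t_start, rec.t_end, rec.q_start, rec.q_end) == (100, 200, 400, 450)
        assert rec.strand == "+"

    def test_minus_strand_converted_to_forward_coords(self):
        # interval-reversal oracle: s' = L - e, e' = L - s with L = 100
        row = "A\t0\t10\t2000\tB\t-\t10\t20\t100\t95.0%"
        (rec,) = parse_lastz_general([LASTZ_HEADER, row], ("A", "B"))
        assert (rec.q_start, rec.q_end) == (100 - 20, 100 - 10)
        assert rec.strand == "-"

    def test_missing_required_field_named(self):
        header = LASTZ_HEADER.replace("\tid%", "")
        with pytest.raises(ParseError, match="id%"):
            parse_lastz_general([header, "A\t0\t1\t10\tB\t+\t0\t1\t10"], ("A", "B"))

    def test_dialect_equivalence_with_paf(self):
        """The same alignment emitted in both dialects parses identically."""
        paf = paf_line(qs=400, qe=450, ts=100, te=200, matches=45, block=50)
        lz = "A\t100\t200\t2000\tB\t+\t400\t450\t1000\t90.0%"
        (from_paf,) = parse_paf([paf], ("A", "B"))
        (from_lz,) = parse_lastz_general([LASTZ_HEADER, lz], ("A", "B"))
        for attr in ("target_id", "query_id", "t_start", "t_end",
                     "q_start", "q_end", "strand"):
            assert getattr(from_paf, attr) == getattr(from_lz, attr)
        assert from_paf.percent_identity == pytest.approx(from_lz.percent_identity)


def test_paf_round_trip():
    rec = AlignmentRecord("A", "B", 100, 200, 400, 450, "-", 92.0)
    (back,) = parse_paf([to_paf_line(rec, query_length=1000, target_length=2000)],
                        ("A", "B"))
    assert back.t_start == rec.t_start and back.q_end == rec.q_end
    assert back.strand == "-"
    assert back.percent_identity == pytest.approx(rec.percent_identity)


class TestCachePath:
    def test_deterministic_and_order_insensitive(self, tmp_path):
        p1 = cache_path(tmp_path, "A", "B", "minimap2")
        assert p1 == cache_path(tmp_path, "A", "B", "minimap2")
        assert p1 == cache_path(tmp_path, "B", "A", "minimap2")

    def test_distinct_pairs_and_aligners_distinct(self, tmp_path):
        paths = {
            cache_path(tmp_path, "A", "B", "minimap2"),
            cache_path(tmp_path, "A", "C", "minimap2"),
            cache_path(tmp_path, "A", "B", "lastz"),
        }
        assert len(paths) == 3

    def test_sanitization_collision_is_an_error(self, tmp_path):
        with pytest.raises(ContractError, match="sanitize"):
            cache_path(tmp_path, "a/b", "a_b", "minimap2")


class TestRunPairwiseAlignments:
    def _entries(self, tmp_path, locus):
        from quiltplot.config_io import load_lengths, parse_config

        cfg = write_inputs(locus, tmp_path / "in", mode="config")
        return load_lengths(parse_config(cfg))

    def test_full_cache_loads_without_invocation(self, tmp_path, tiny_locus, monkeypatch):
        entries = self._entries(tmp_path, tiny_locus)
        out = tmp_path / "out"
        write_ground_truth_cache(tiny_locus, out)

        def boom(*a, **k):  # any aligner call is a failure here
            raise AssertionError("aligner invoked despite full cache")

        monkeypatch.setattr(alignment_io.subprocess, "run", boom)
        sets = run_pairwise_alignments(entries, "minimap2", out)
        assert len(sets) == 6  # n=3 -> n(n+1)/2
        assert sum(len(s.records) for s in sets.values()) == sum(
            len(r) for r in tiny_locus.records.values()
        )

    def test_cache_idempotence(self, tmp_path, tiny_locus, monkeypatch):
        """A rerun on the same out_dir performs zero invocations and yields
        identical record sets."""
        entries = self._entries(tmp_path, tiny_locus)
        out = tmp_path / "out"
        write_ground_truth_cache(tiny_locus, out)
        first = run_pairwise_alignments(entries, "minimap2", out)
        calls = []
        monkeypatch.setattr(
            alignment_io.subprocess, "run",
            lambda *a, **k: calls.append(a) or (_ for _ in ()).throw(AssertionError),
        )
        second = run_pairwise_alignments(entries, "minimap2", out)
        assert calls == []
        assert {k: v.records for k, v in first.items()} == {
            k: v.records for k, v in second.items()
        }

    def test_single_sequence_yields_one_self_set(self, tmp_path):
        fa = write_fasta(tmp_path / "s.fa", [("s1", "ACGT" * 500)])
        entry = SequenceEntry("s1", "s1", fa, length=2000)
        out = tmp_path / "out"
        cache_path(out, "s1", "s1", "minimap2").parent.mkdir(parents=True)
        cache_path(out, "s1", "s1", "minimap2").write_text(
            paf_line(q="s1", qlen=2000, qs=0, qe=2000, t="s1", tlen=2000,
                     ts=0, te=2000, matches=2000, block=2000) + "\n"
        )
        sets = run_pairwise_alignments([entry], "minimap2", out)
        assert list(sets) == [("s1", "s1")]
        assert sets[("s1", "s1")].is_self

    def test_failing_aligner_reports_stderr(self, tmp_path):
        fa = write_fasta(tmp_path / "s.fa", [("s1", "ACGT" * 100)])
        entry = SequenceEntry("s1", "s1", fa, length=400)
        with pytest.raises(AlignerError, match="exit"):
            run_pairwise_alignments(
                [entry], "minimap2", tmp_path / "out",
                templates={"minimap2": "sh -c 'echo oops >&2; exit 3' x {target} {query}"},
            )

    def test_unparseable_cache_is_an_error(self, tmp_path):
        fa = write_fasta(tmp_path / "s.fa", [("s1", "ACGT" * 100)])
        entry = SequenceEntry("s1", "s1", fa, length=400)
        out = tmp_path / "out"
        cpath = cache_path(out, "s1", "s1", "minimap2")
        cpath.parent.mkdir(parents=True)
        cpath.write_text("not\tpaf\n")
        with pytest.raises(ParseError, match=str(cpath.name)):
            run_pairwise_alignments([entry], "minimap2", out)


def test_minimap2_integration(tmp_path):
    """Real minimap2 on two sequences sharing a 30 kbp block: records found,
    raw output cached, strands consistent with the planted structure."""
    spec = LocusSpec(
        seed=3,
        block_library=[("S", 30_000)],
        sequence_orders=[
            [BlockPlacement("S")],
            [BlockPlacement("S", "-", 0.02)],
        ],
        sample_ids=["ref", "flip"],
        spacer_len=500,
    )
    locus = generate_locus_set(spec)
    from quiltplot.config_io import load_lengths, parse_config

    cfg = write_inputs(locus, tmp_path / "in", mode="config")
    entries = load_lengths(parse_config(cfg))
    out = tmp_path / "out"
    sets = run_pairwise_alignments(entries, "minimap2", out)
    assert cache_path(out, "ref", "flip", "minimap2").is_file()
    cross = sets[("ref", "flip")].records
    assert cross, "minimap2 found no alignments for a 30 kbp shared block"
    longest = max(cross, key=lambda r: r.span)
    assert longest.strand == "-"
    assert longest.percent_identity > 90.0
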