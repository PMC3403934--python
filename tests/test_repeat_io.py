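import io
import random

import pytest

from retroscape import repeat_io, tint_activity
from retroscape.repeat_io import RepeatAnnotation, RepeatMaskerParseError

HEADER = (
    "   SW  perc perc perc  query     position in query    matching repeat\n"
    "score  div. del. ins.  sequence  begin  end   (left)  repeat  class/family\n"
    "\n"
)


class TestParseOut:
    def test_header_only_stream_is_empty(self):
        assert repeat_io.parse_repeatmasker_out(io.StringIO(HEADER)) == []
        assert repeat_io.parse_repeatmasker_out(io.StringIO("")) == []

    def test_plus_strand_line(self):
        line = "239 25.0 1.2 0.0 scaf1 1001 1180 (5000) + WSINE1 SINE 1 180 (0) 7\n"
        (ann,) = repeat_io.parse_repeatmasker_out(io.StringIO(line))
        assert (ann.query_id, ann.q_start, ann.q_end) == ("scaf1", 1001, 1180)
        assert (ann.family, ann.c_start, ann.c_end, ann.link_id) == ("WSINE1", 1, 180, 7)
        assert ann.sw_score == 239 and ann.divergence_pct == 25.0

    def test_c_strand_consensus_normalized(self):
        line = "239 25.0 1.2 0.0 scaf1 1001 1180 (5000) C WSINE1 SINE (0) 180 1\n"
        (ann,) = repeat_io.parse_repeatmasker_out(io.StringIO(line))
        assert (ann.c_start, ann.c_end, ann.strand) == (1, 180, "C")

    def test_star_column_tolerated(self):
        line = "239 25.0 1.2 0.0 scaf1 1001 1180 (5000) + WSINE1 SINE 1 180 (0) 7 *\n"
        (ann,) = repeat_io.parse_repeatmasker_out(io.StringIO(line))
        assert ann.link_id == 7

    def test_malformed_line_names_line_number(self):
        text = HEADER + "239 25.0 1.2 0.0 scaf1 ABC 1180 (5000) + WSINE1 SINE 1 180 (0)\n"
        with pytest.raises(RepeatMaskerParseError, match="line 4"):
            repeat_io.parse_repeatmasker_out(io.StringIO(text))

    def test_parse_write_parse_round_trip(self, bundle):
        text = repeat_io.format_repeatmasker_out(bundle.annotations, header=True)
        again = repeat_io.parse_repeatmasker_out(io.StringIO(text))
        assert len(again) == len(bundle.annotations)
        for a, b in zip(bundle.annotations, again):
            for f in ("query_id", "q_start", "q_end", "strand", "family",
                      "c_start", "c_end", "link_id", "sw_score"):
                assert getattr(a, f) == getattr(b, f)


class TestFasta:
    def test_empty_stream(self):
        assert repeat_io.read_fasta(io.StringIO("")) == []

    def test_round_trip_and_normalization(self):
        buf = io.StringIO()
        repeat_io.write_fasta([("x", "ACGT"), ("y", "TTTT")], buf)
        buf.seek(0)
        assert repeat_io.read_fasta(buf) == [("x", "ACGT"), ("y", "TTTT")]
        recs = repeat_io.read_fasta(io.StringIO(">z\nacgu\n"))
        assert recs == [("z", "ACGT")]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="dup"):
            repeat_io.read_fasta(io.StringIO(">dup\nAC\n>dup\nGT\n"))


class TestExtract:
    GENOME = {"s": "AAACGTACGTCCCCGGGGTTTT"}

    def test_plus_strand_is_verbatim_slice(self):
        ann = RepeatAnnotation("s", 4, 10, "+", "F", 1, 7, 0)
        (cid, seq), = repeat_io.extract_element_copies(self.GENOME, [ann])
        assert seq == "CGTACGT"

    def test_c_strand_is_reverse_complement(self):
        ann = RepeatAnnotation("s", 4, 10, "C", "F", 1, 7, 0)
        (_, seq), = repeat_io.extract_element_copies(self.GENOME, [ann])
        assert seq == "ACGTACG"

    def test_linked_fragments_concatenate_in_consensus_order(self):
        # fragment 2 of the element comes first on the genome
        a1 = RepeatAnnotation("s", 4, 10, "+", "F", 8, 14, 0, link_id=3)
        a2 = RepeatAnnotation("s", 15, 18, "+", "F", 1, 4, 0, link_id=3)
        (_, seq), = repeat_io.extract_element_copies(self.GENOME, [a1, a2])
        assert seq == self.GENOME["s"][14:18] + self.GENOME["s"][3:10]

    def test_out_of_bounds_named(self):
        ann = RepeatAnnotation("s", 4, 99, "+", "F", 1, 96, 0)
        with pytest.raises(ValueError, match="s:4-99"):
            repeat_io.extract_element_copies(self.GENOME, [ann])


def _bulk_annotations(n, family, link=True):
    return [
        RepeatAnnotation(
            f"q{i}", 100, 300, "+", family, 1, 201, 0,
            link_id=(i if link else None),
        )
        for i in range(n)
    ]


class TestSummarize:
    def test_devil_wallsi1a_density(self):
        rows = repeat_io.summarize_families(
            _bulk_annotations(47_889, "WALLSI1a"), 2_984.5e6
        )
        assert rows[0].copy_number == 47_889
        assert rows[0].density_rounded == 16

    def test_wallaby_wallsi1a_density(self):
        rows = repeat_io.summarize_families(
            _bulk_annotations(36_886, "WALLSI1a"), 2_591.3e6
        )
        assert rows[0].density_rounded == 14

    def test_empty_input(self):
        assert repeat_io.summarize_families([], 1e6) == []

    def test_totals_and_permutation_invariance(self):
        anns = _bulk_annotations(50, "A") + [
            RepeatAnnotation(f"p{i}", 10, 59, "+", "B", 1, 50, 0) for i in range(20)
        ]
        rows = repeat_io.summarize_families(anns, 1e6)
        by_fam = {r.family: r for r in rows}
        assert by_fam["A"].total_nt == 50 * 201
        assert by_fam["B"].total_nt == 20 * 50
        assert abs(by_fam["A"].pct_genome - 100 * 50 * 201 / 1e6) < 1e-12
        shuffled = anns[:]
        random.Random(7).shuffle(shuffled)
        assert repeat_io.summarize_families(shuffled, 1e6) == rows

    def test_fragment_chain_counts_once(self):
        a1 = RepeatAnnotation("q", 100, 200, "+", "F", 1, 101, 0, link_id=5)
        a2 = RepeatAnnotation("q", 900, 1000, "+", "F", 102, 202, 0, link_id=5)
        (row,) = repeat_io.summarize_families([a1, a2], 1e6)
        assert row.copy_number == 1
        assert row.total_nt == 202

    def test_sim_truth_copy_counts(self, bundle):
        rows = repeat_io.summarize_families(
            bundle.annotations, sum(len(s) for s in bundle.genome.values())
        )
        truth_counts = bundle.truth.groupby("family").size().to_dict()
        assert {r.family: r.copy_number for r in rows} == truth_counts

    def test_bad_assembly_size(self):
        with pytest.raises(ValueError):
            repeat_io.summarize_families([], 0)
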