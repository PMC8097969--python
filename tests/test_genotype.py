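"""Deduplication, mismatch filter, evidence rules, genotype logic."""
import numpy as np
import pandas as pd
import pysam
import pytest

from svdiverge.records import BreakpointEvidence, GenotypeCall, SVRecord
from svdiverge.genotype import (call_genotype, deduplicate_read_pairs,
                                filter_alignments, genotype_matrix,
                                mismatch_fraction)


def _pair(seq1, seq2, name="r"):
    return ((f"@{name}/1", seq1, "I" * len(seq1)),
            (f"@{name}/2", seq2, "I" * len(seq2)))


def _random_read(rng, n=150):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestDedup:
    def test_prefix_rule_150bp_reads(self):
        rng = np.random.default_rng(0)
        base1, base2 = _random_read(rng), _random_read(rng)
        # identical first 100 bp of both mates, difference at position 120
        variant1 = base1[:119] + ("A" if base1[119] != "A" else "C") + base1[120:]
        pairs = [_pair(base1, base2, "a"), _pair(variant1, base2, "b")]
        kept, dups = deduplicate_read_pairs(pairs, read_length=150)
        assert len(kept) == 1 and dups == 1
        assert kept[0][0][0] == "@a/1"  # first occurrence kept

    def test_difference_at_position_95_keeps_both(self):
        rng = np.random.default_rng(1)
        base1, base2 = _random_read(rng), _random_read(rng)
        variant1 = base1[:94] + ("A" if base1[94] != "A" else "C") + base1[95:]
        pairs = [_pair(base1, base2, "a"), _pair(variant1, base2, "b")]
        kept, dups = deduplicate_read_pairs(pairs, read_length=150)
        assert len(kept) == 2 and dups == 0

    def test_prefix_rule_100bp_reads_uses_90(self):
        rng = np.random.default_rng(2)
        base1, base2 = _random_read(rng, 100), _random_read(rng, 100)
        tail_variant = base1[:95] + ("A" if base1[95] != "A" else "C") + base1[96:]
        kept, dups = deduplicate_read_pairs(
            [_pair(base1, base2, "a"), _pair(tail_variant, base2, "b")],
            read_length=100)
        assert len(kept) == 1 and dups == 1

    def test_empty_stream(self):
        kept, dups = deduplicate_read_pairs([], read_length=150)
        assert kept == [] and dups == 0

    def test_mixed_read_lengths_error(self):
        rng = np.random.default_rng(3)
        pairs = [_pair(_random_read(rng, 150), _random_read(rng, 100))]
        with pytest.raises(ValueError, match="mixed"):
            deduplicate_read_pairs(pairs, read_length=150)

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(4)
        pairs = [_pair(_random_read(rng), _random_read(rng), f"r{i}")
                 for i in range(20)]
        pairs += pairs[:5]
        once, d1 = deduplicate_read_pairs(pairs, 150)
        twice, d2 = deduplicate_read_pairs(once, 150)
        assert len(once) <= len(pairs)
        assert twice == once and d2 == 0


def _aln(seq_len=150, nm=0, cigar=None, name="q"):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100_000}]})
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = "A" * seq_len
    a.reference_id = 0
    a.reference_start = 1000
    a.cigarstring = cigar or f"{seq_len}M"
    a.set_tag("NM", nm)
    a.mapping_quality = 60
    return a


class TestMismatchFilter:
    def test_three_percent_boundary(self):
        kept = list(filter_alignments([_aln(nm=4)]))   # 4/150 = 0.027
        assert len(kept) == 1
        dropped = list(filter_alignments([_aln(nm=6)]))  # 6/150 = 0.04
        assert dropped == []

    def test_perfect_alignment_kept(self):
        assert len(list(filter_alignments([_aln(nm=0)]))) == 1

    def test_indels_not_counted_as_mismatches(self):
        # 60-bp deletion contributes 60 to NM but zero mismatches
        a = _aln(nm=60, cigar="75M60D75M")
        assert mismatch_fraction(a) == 0.0
        assert len(list(filter_alignments([a]))) == 1

    def test_missing_nm_tag_is_error(self):
        a = _aln()
        a.set_tag("NM", None)
        with pytest.raises(ValueError, match="NM"):
            list(filter_alignments([a]))


def _ev(sv_id="sv1", genome="A", left=0, right=0, total=None, event=1.0,
        flank=0.0, point=False):
    return BreakpointEvidence(
        sv_id=sv_id, genome=genome, split_reads_left=left,
        split_reads_right=right,
        split_reads_total=total if total is not None else max(left, right),
        depth_fraction_event=event, depth_fraction_flank_best=flank,
        point_event=point)


class TestCallGenotype:
    def test_split_support_on_one_genome_only(self):
        # split reads on genome B evidence the A allele
        call = call_genotype(_ev(genome="A"), _ev(genome="B", left=4, right=4,
                                                  total=4))
        assert call.genotype == "A" and call.basis == "split_read"

    def test_insufficient_splits_fall_back_to_depth(self):
        # 2 split reads only, but the deleted interval on genome A is bare
        ev_a = _ev(genome="A", left=2, right=2, total=2, event=0.1, flank=0.9)
        call = call_genotype(ev_a, _ev(genome="B"))
        assert call.genotype == "B" and call.basis == "depth"

    def test_depth_rule_requires_covered_flank(self):
        ev_a = _ev(genome="A", event=0.1, flank=0.2)  # zero-coverage accession
        call = call_genotype(ev_a, _ev(genome="B"))
        assert call.genotype == "U" and call.basis == "none"

    def test_both_alleles_supported_is_het(self):
        call = call_genotype(_ev(genome="A", left=5, right=5, total=5),
                             _ev(genome="B", left=4, right=6, total=6))
        assert call.genotype == "H"

    def test_no_evidence_is_undetermined(self):
        call = call_genotype(_ev(genome="A"), _ev(genome="B"))
        assert call.genotype == "U" and call.basis == "none"

    def test_label_swap_symmetry(self):
        ev1 = _ev(genome="A", left=5, right=5, total=5)
        ev2 = _ev(genome="B", event=0.2, flank=0.8)
        fwd = call_genotype(ev1, ev2)
        rev = call_genotype(ev2, ev1)
        swap = {"A": "B", "B": "A", "H": "H", "U": "U"}
        assert rev.genotype == swap[fwd.genotype]


class TestMatrix:
    def test_rates(self):
        calls = []
        for i, g in enumerate(["A"] * 4 + ["B"] * 2 + ["H"] * 1 + ["U"] * 3):
            calls.append(GenotypeCall("acc1", f"sv{i}", g,
                                      "none" if g == "U" else "split_read"))
        mat, rate, per_sv = genotype_matrix(calls)
        assert rate["acc1"] == pytest.approx(0.7)
        assert mat.shape == (1, 10)

    def test_all_undetermined(self):
        calls = [GenotypeCall("acc1", f"sv{i}", "U", "none") for i in range(5)]
        _, rate, _ = genotype_matrix(calls)
        assert rate["acc1"] == 0.0

    def test_duplicate_call_rejected(self):
        calls = [GenotypeCall("acc1", "sv1", "A", "split_read"),
                 GenotypeCall("acc1", "sv1", "B", "split_read")]
        with pytest.raises(ValueError, match="duplicate"):
            genotype_matrix(calls)


def test_hom_call_with_contrary_evidence_is_undetermined():
    """Two contrary junction reads block a homozygous call (ambiguity)."""
    from svdiverge.genotype import call_genotype
    supported = _ev(genome="B", left=5, right=5, total=5)   # A allele: strong
    contrary0 = _ev(genome="A", total=0)
    contrary2 = _ev(genome="A", total=2)
    assert call_genotype(contrary0, supported).genotype == "A"
    assert call_genotype(contrary2, supported).genotype == "U"
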