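"""Caller, gap filter, flank validation, refinement, merging, VCF round trip."""
import copy

import pytest

from svdiverge.records import AlignmentBlock, SVRecord
from svdiverge.discovery import (BlastFlankAligner, apply_flank_validation,
                                 call_svs_from_alignment, filter_near_gaps,
                                 find_n_runs, left_normalize, merge_callsets,
                                 read_sv_set, refine_complex_svs,
                                 validate_by_flanks, write_sv_set)

from conftest import small_config
from svdiverge.synthetic import generate_genome_pair


def _block(qs, qe, ts, te, ops=None, qname="chrB", tname="chrA", unique=True):
    return AlignmentBlock(
        query_name=qname, query_start=qs, query_end=qe, target_name=tname,
        target_start=ts, target_end=te, strand="+", n_matches=qe - qs,
        block_length=max(qe - qs, te - ts), base_ops=ops, mapping_unique=unique)


def _sv(sv_id, sv_type, start, end, len_a, len_b, **kw):
    return SVRecord(sv_id=sv_id, sv_type=sv_type, chrom=kw.pop("chrom", "chrA"),
                    start=start, end=end, len_a=len_a, len_b=len_b, **kw)


class TestCaller:
    def test_identical_genomes_give_no_calls(self):
        seq = "ACGT" * 5000
        genomes = {"chrA": seq}
        block = _block(0, 20_000, 0, 20_000, ops=[("match", 20_000)],
                       tname="chrA", qname="chrA")
        assert call_svs_from_alignment([block], genomes, genomes) == []

    def test_within_alignment_indels_typed_and_placed(self):
        seq_a = "".join("ACGTTGCA"[i % 8] for i in range(5000))
        ops = [("match", 2000), ("del", 120), ("match", 1500),
               ("ins", 55), ("match", 1380)]
        genome_a = {"chrA": seq_a}
        genome_b = {"chrB": seq_a[:2000] + seq_a[2120:3620] + "T" * 55 + seq_a[3620:]}
        block = _block(0, 4935, 0, 5000, ops=ops)
        calls = call_svs_from_alignment([block], genome_a, genome_b)
        by_type = {c.sv_type: c for c in calls}
        assert set(by_type) == {"insertion", "deletion"}
        assert by_type["deletion"].len_a == 120
        assert by_type["insertion"].len_b == 55
        assert by_type["insertion"].start == by_type["insertion"].end

    def test_min_size_excludes_nine_bp_events(self):
        seq = "".join("ACGTTGCA"[i % 8] for i in range(4000))
        ops = [("match", 2000), ("del", 9), ("match", 1991)]
        block = _block(0, 3991, 0, 4000, ops=ops)
        calls = call_svs_from_alignment([block], {"chrA": seq}, {}, min_size=10)
        assert calls == []
        ops10 = [("match", 2000), ("del", 10), ("match", 1990)]
        block10 = _block(0, 3990, 0, 4000, ops=ops10)
        calls10 = call_svs_from_alignment([block10], {"chrA": seq}, {}, min_size=10)
        assert len(calls10) == 1

    def test_min_size_below_ten_rejected(self):
        with pytest.raises(ValueError):
            call_svs_from_alignment([], {}, {}, min_size=5)

    def test_between_anchor_gap_signatures(self):
        import numpy as np
        rng = np.random.default_rng(0)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        a = rng.choice(bases, 30_000).tobytes().decode()
        sub_b = rng.choice(bases, 300).tobytes().decode()
        # deletion: target gap 500, query gap 0; substitution: 400 -> 300
        genome_a = {"chrA": a}
        genome_b = {"chrB": a[:10_000] + a[10_500:20_000] + sub_b + a[20_400:]}
        blocks = [
            _block(0, 10_000, 0, 10_000),
            _block(10_000, 19_500, 10_500, 20_000),
            _block(19_800, 29_400, 20_400, 30_000),
        ]
        calls = call_svs_from_alignment(blocks, genome_a, genome_b)
        by_type = {c.sv_type: c for c in calls}
        assert by_type["deletion"].interval() == ("chrA", 10_000, 10_500)
        # boundary bases identical by coincidence may be trimmed; the
        # length difference is preserved exactly
        sub = by_type["substitution"]
        assert sub.len_a - sub.len_b == 100
        assert abs(sub.len_a - 400) <= 5

    def test_non_unique_anchors_skipped(self):
        seq = "".join("ACGTTGCA"[i % 8] for i in range(4000))
        ops = [("match", 2000), ("del", 100), ("match", 1900)]
        block = _block(0, 3900, 0, 4000, ops=ops, unique=False)
        assert call_svs_from_alignment([block], {"chrA": seq}, {}) == []

    def test_planted_deletion_recovered_within_one_bp(self, small_pair):
        # alignment blocks constructed from truth, no aligner involved
        _, ga, gb, truth = small_pair
        dels = [s for s in truth.planted_svs if s.sv_type == "deletion"]
        assert dels
        ops = []
        cursor_a = cursor_b = 0
        for sv in sorted(truth.planted_svs, key=lambda s: s.start):
            ops.append(("match", sv.start - cursor_a))
            if sv.len_a:
                ops.append(("del", sv.len_a))
            if sv.len_b:
                ops.append(("ins", sv.len_b))
            cursor_a = sv.end
            cursor_b = sv.mate_coords[2]
        ops.append(("match", len(ga["chr1"]) - cursor_a))
        block = _block(0, len(gb["chr1"]), 0, len(ga["chr1"]), ops=ops,
                       qname="chr1", tname="chr1")
        calls = call_svs_from_alignment([block], ga, gb)
        called_dels = [c for c in calls if c.sv_type == "deletion"]
        for sv in dels:
            # calls are left-normalized; normalize the planted breakpoint too
            norm_start, _ = left_normalize(
                ga[sv.chrom], sv.start, ga[sv.chrom][sv.start:sv.end])
            assert any(c.start == norm_start and c.len_a == sv.len_a
                       for c in called_dels), sv


def test_left_normalize_shifts_through_repeat():
    seq = "AAAACGTACGTACGTTTTT"
    # deleting one unit anywhere in the array normalizes to the leftmost
    # placement (index 3, allele rotated to ACGT: seq[3:7] == "ACGT")
    pos, allele = left_normalize(seq, 8, "CGTA")
    assert (pos, allele) == (3, "ACGT")
    assert seq[:pos] + seq[pos + 4:] == seq[:8] + seq[12:]


class TestGapFilter:
    def _genomes(self):
        a = "A" * 1000 + "N" * 100 + "C" * 5000
        return {"chrA": a}, {"chrB": "A" * 6100}

    def test_sv_near_gap_removed_and_far_retained(self):
        ga, gb = self._genomes()
        near = _sv("near", "deletion", 1110, 1160, 50, 0,
                   mate_coords=("chrB", 500, 500))  # 10 bp from N run end
        far = _sv("far", "deletion", 1160, 1220, 60, 0,
                  mate_coords=("chrB", 800, 800))  # 60 bp away
        kept = filter_near_gaps([near, far], ga, gb, max_distance=50)
        assert [s.sv_id for s in kept] == ["far"]

    def test_sv_spanning_gap_removed(self):
        ga, gb = self._genomes()
        spanning = _sv("span", "deletion", 900, 1300, 400, 0,
                       mate_coords=("chrB", 500, 500))
        assert filter_near_gaps([spanning], ga, gb) == []

    def test_no_gaps_returns_input_unchanged(self):
        ga = {"chrA": "ACGT" * 1000}
        gb = {"chrB": "ACGT" * 1000}
        svs = [_sv("x", "insertion", 100, 100, 0, 50,
                   mate_coords=("chrB", 100, 150))]
        assert filter_near_gaps(svs, ga, gb) == svs

    def test_mate_interval_near_gap_also_removed(self):
        ga = {"chrA": "ACGT" * 2000}
        gb = {"chrB": "C" * 1000 + "N" * 50 + "G" * 3000}
        sv = _sv("m", "insertion", 4000, 4000, 0, 60,
                 mate_coords=("chrB", 1060, 1120))
        assert filter_near_gaps([sv], ga, gb) == []

    def test_find_n_runs_length_threshold(self):
        runs = find_n_runs({"c": "AANNNNNNNNNNAA" + "N" * 9}, min_n_run=10)
        assert runs["c"] == [(2, 12)]


@pytest.fixture(scope="module")
def planted():
    cfg = small_config(seed=3)
    ga, gb, truth = generate_genome_pair(cfg)
    aligner = BlastFlankAligner(gb)
    return ga, gb, truth, aligner


class TestFlankValidation:

    def test_planted_svs_pass_with_zero_deviation(self, planted):
        ga, gb, truth, aligner = planted
        results = validate_by_flanks(truth.planted_svs, ga, gb, flank=3000,
                                     aligner=aligner)
        verdicts = {r.sv_id: r for r in results}
        assert all(r.passed for r in results), \
            [(r.sv_id, r.verdict) for r in results if not r.passed]
        for sv in truth.planted_svs:
            r = verdicts[sv.sv_id]
            assert r.expected_gap == sv.len_b
            assert abs(r.observed_gap - r.expected_gap) <= 2

    def test_insertion_deviation_rule_20_percent(self, planted):
        ga, gb, truth, aligner = planted
        ins = next(s for s in truth.planted_svs
                   if s.sv_type == "insertion" and s.len_b > 100)
        # claim a size whose deviation is just under/over 20%
        under = copy.deepcopy(ins)
        under.sv_id += "_under"
        under.len_b = int(ins.len_b / 1.15)  # observed deviates by 15%
        over = copy.deepcopy(ins)
        over.sv_id += "_over"
        over.len_b = int(ins.len_b / 1.45)
        res = validate_by_flanks([under, over], ga, gb, flank=3000,
                                 aligner=aligner)
        assert res[0].passed
        assert not res[1].passed and res[1].verdict == "fail_size"

    def test_deletion_three_bp_slop(self, planted):
        ga, gb, truth, aligner = planted
        deln = next(s for s in truth.planted_svs if s.sv_type == "deletion")
        # shrink the claimed interval: the projected flank hits now overlap
        # by 5 bp on the other genome
        shrunk = copy.deepcopy(deln)
        shrunk.sv_id = deln.sv_id + "_shrunk"
        shrunk.start += 5
        res = validate_by_flanks([deln, shrunk], ga, gb, flank=3000,
                                 aligner=aligner)
        assert res[0].passed
        assert not res[1].passed and res[1].verdict == "fail_size"
        assert res[1].observed_gap == -5

    def test_deviation_is_scale_free(self):
        from svdiverge.records import FlankCheckResult
        # deviation definition: |obs - exp| / max(exp, 1)
        d1 = abs(850 - 1000) / max(1000, 1)
        d2 = abs(1700 - 2000) / max(2000, 1)
        assert d1 == d2 == pytest.approx(0.15)

    def test_missing_flank_hit_is_fail_no_hit(self, planted):
        ga, gb, truth, aligner = planted
        fake = _sv("nohit", "deletion", 50_000, 50_100, 100, 0, chrom="chr1")
        fake.seq = None
        # flanks replaced by genome from elsewhere cannot be simulated here;
        # instead query an SV against an empty aligner genome
        empty = BlastFlankAligner({"chrZ": "ACGT" * 2000})
        res = validate_by_flanks([fake], ga, {"chrZ": "ACGT" * 2000},
                                 flank=500, aligner=empty)
        assert res[0].verdict == "fail_no_hit"


class TestRefine:
    def test_complex_replaced_by_contained_read_indels(self):
        complex_sv = _sv("cx", "tandem_expansion", 1000, 1100, 100, 220,
                         precise=False)
        read_ins = _sv("rd1", "insertion", 1050, 1050, 0, 120, source="reads")
        out = refine_complex_svs([complex_sv], [read_ins])
        assert len(out) == 1
        assert out[0].sv_type == "insertion"
        assert out[0].source == "merged" and out[0].precise

    def test_complex_without_support_passes_through(self):
        complex_sv = _sv("cx", "repeat_contraction", 1000, 1600, 600, 100,
                         precise=False)
        out = refine_complex_svs([complex_sv], [])
        assert out == [complex_sv]

    def test_two_read_indels_both_emitted(self):
        complex_sv = _sv("cx", "repeat_expansion", 1000, 1400, 400, 1000,
                         precise=False)
        r1 = _sv("rd1", "insertion", 1100, 1100, 0, 350, source="reads")
        r2 = _sv("rd2", "insertion", 1300, 1300, 0, 250, source="reads")
        out = refine_complex_svs([complex_sv], [r1, r2])
        assert [o.sv_type for o in out] == ["insertion", "insertion"]
        assert all(o.precise and o.source == "merged" for o in out)

    def test_inconsistent_read_support_keeps_complex_call(self):
        complex_sv = _sv("cx", "repeat_expansion", 1000, 1400, 400, 5000,
                         precise=False)
        tiny = _sv("rd1", "insertion", 1100, 1100, 0, 30, source="reads")
        out = refine_complex_svs([complex_sv], [tiny])
        assert out == [complex_sv]


class TestMerge:
    def test_reciprocal_overlap_examples(self):
        a = _sv("a", "deletion", 1000, 2000, 1000, 0)
        b = _sv("b", "deletion", 1400, 2400, 1000, 0)
        merged = merge_callsets([a], [b])
        assert len(merged) == 1  # reciprocal 0.6 both ways

        c = _sv("c", "deletion", 1800, 2800, 1000, 0)
        kept = merge_callsets([a], [c])
        assert len(kept) == 2  # reciprocal 0.2

    def test_self_merge_is_identity(self):
        svs = [_sv("a", "deletion", 1000, 2000, 1000, 0, source="assembly"),
               _sv("b", "insertion", 5000, 5000, 0, 300, source="assembly")]
        merged = merge_callsets(svs, svs)
        assert merged == svs

    def test_order_invariance(self):
        s1 = [_sv("a", "deletion", 1000, 2000, 1000, 0)]
        s2 = [_sv("b", "deletion", 1400, 2400, 1000, 0),
              _sv("c", "insertion", 9000, 9000, 0, 120)]
        m12 = merge_callsets(s1, list(reversed(s2)))
        m21 = merge_callsets(s1, s2)
        key = lambda s: (s.chrom, s.start, s.sv_type)
        assert sorted((key(s) for s in m12)) == sorted((key(s) for s in m21))

    def test_retained_records_pairwise_fail_criterion(self):
        import numpy as np
        rng = np.random.default_rng(0)
        svs = []
        for i in range(40):
            start = int(rng.integers(0, 50_000))
            ln = int(rng.integers(50, 800))
            svs.append(_sv(f"s{i}", "deletion", start, start + ln, ln, 0))
        merged = merge_callsets(svs[:20], svs[20:])
        from svdiverge.discovery import _reciprocal_overlap
        for i, x in enumerate(merged):
            for y in merged[i + 1:]:
                if x.chrom == y.chrom and x.sv_type == y.sv_type:
                    assert _reciprocal_overlap(x, y) < 0.5

    def test_different_classes_never_merge(self):
        # an equal-length substitution is its own class: no net length
        # change, so it cannot be another caller's view of an indel
        a = _sv("a", "deletion", 1000, 2000, 1000, 0)
        b = _sv("b", "substitution", 1000, 2000, 1000, 1000)
        assert len(merge_callsets([a], [b])) == 2
        # opposite-sign events never merge either
        c = _sv("c", "insertion", 1500, 1500, 0, 1000)
        assert len(merge_callsets([a], [c])) == 2


class TestVcfRoundTrip:
    def test_round_trip_of_planted_svs(self, tmp_path, small_pair):
        _, ga, _, truth = small_pair
        path = tmp_path / "svs.vcf"
        write_sv_set(truth.planted_svs, path, genome=ga)
        back = read_sv_set(path)
        assert len(back) == len(truth.planted_svs)
        for x, y in zip(back, sorted(truth.planted_svs,
                                     key=lambda s: (s.chrom, s.start, s.sv_id))):
            assert (x.sv_id, x.sv_type, x.chrom, x.start, x.end,
                    x.len_a, x.len_b, x.precise) == \
                   (y.sv_id, y.sv_type, y.chrom, y.start, y.end,
                    y.len_a, y.len_b, y.precise)
            assert x.mate_coords == y.mate_coords

    def test_empty_set_valid_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_sv_set([], path)
        assert read_sv_set(path) == []
        assert open(path).readline().startswith("##fileformat=VCF")

    def test_long_event_symbolic_with_consistent_fields(self, tmp_path):
        sv = _sv("big", "deletion", 10_000, 677_000, 667_000, 0,
                 mate_coords=("chrB", 10_000, 10_000))
        path = tmp_path / "big.vcf"
        write_sv_set([sv], path)
        line = [l for l in open(path) if not l.startswith("#")][0]
        fields = line.split("\t")
        assert fields[4] == "<DEL>"
        info = dict(kv.split("=") for kv in fields[7].split(";") if "=" in kv)
        assert int(info["END"]) == 677_000
        assert int(info["SVLEN"]) == -667_000
        (back,) = read_sv_set(path)
        assert back.end - back.start == back.len_a == 667_000
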