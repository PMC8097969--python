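"""Generator invariants: determinism, breakpoint bookkeeping, reads."""
import gzip

import numpy as np
import pytest

from svdiverge.records import SV_TYPES
from svdiverge.synthetic import (SimulationConfig, accession_haplotypes,
                                 generate_accession_reads,
                                 generate_genome_pair, read_truth,
                                 write_truth)

from conftest import small_config


def test_no_svs_yields_identical_genomes():
    cfg = small_config(sv_counts={t: 0 for t in SV_TYPES})
    ga, gb, truth = generate_genome_pair(cfg)
    assert ga == gb
    assert truth.planted_svs == []


def test_seed_determinism_byte_identical():
    a1, b1, t1 = generate_genome_pair(small_config(seed=7))
    a2, b2, t2 = generate_genome_pair(small_config(seed=7))
    assert a1 == a2 and b1 == b2
    assert [s.__dict__ for s in t1.planted_svs] == [s.__dict__ for s in t2.planted_svs]
    assert t1.genotype_matrix.equals(t2.genotype_matrix)
    a3, _, _ = generate_genome_pair(small_config(seed=8))
    assert a3 != a1


def test_length_bookkeeping_and_allele_slices(small_pair):
    _, ga, gb, truth = small_pair
    delta = sum(s.len_b - s.len_a for s in truth.planted_svs)
    assert delta == sum(map(len, gb.values())) - sum(map(len, ga.values()))
    for sv in truth.planted_svs:
        mc, bs, be = sv.mate_coords
        assert be - bs == sv.len_b
        if sv.seq:
            assert gb[mc][bs:be] == sv.seq
        if sv.sv_type == "deletion":
            # genome B lacks the deleted substring at the recorded breakpoint
            assert gb[mc][bs:be] == ""
            deleted = ga[sv.chrom][sv.start:sv.end]
            assert gb[mc][bs:bs + sv.len_a] != deleted


def test_single_deletion_shortens_genome_by_its_length():
    cfg = small_config(sv_counts={"deletion": 1},
                       sv_size_range={"deletion": (500, 500)})
    ga, gb, truth = generate_genome_pair(cfg)
    (sv,) = truth.planted_svs
    assert sv.len_a == 500 and sv.len_b == 0
    assert len(gb["chr1"]) == len(ga["chr1"]) - 500


def test_gap_runs_planted_in_both_genomes():
    cfg = small_config(gap_runs=[("chr1", 50_000, 120)])
    ga, gb, _ = generate_genome_pair(cfg)
    assert ga["chr1"][50_000:50_120] == "N" * 120
    assert "N" * 120 in gb["chr1"]


def test_min_sv_size_enforced():
    cfg = small_config(sv_size_range={t: (5, 100) for t in SV_TYPES})
    with pytest.raises(ValueError, match=">= 10"):
        generate_genome_pair(cfg)


def test_placement_exhaustion_raises():
    cfg = small_config(genome_length=40_000,
                       sv_counts={"deletion": 30},
                       min_sv_spacing=5000, edge_margin=6000)
    with pytest.raises(RuntimeError, match="retries exhausted"):
        generate_genome_pair(cfg)


def test_reads_coverage_and_purity(tmp_path, small_pair):
    cfg, ga, gb, truth = small_pair
    import dataclasses
    cfg0 = dataclasses.replace(
        cfg, sequencing_error_rate=0.0, short_read_depth=8.0)
    acc = truth.genotype_matrix.index[0]
    paths = generate_accession_reads(ga, gb, truth, cfg0, tmp_path,
                                     accessions=[acc])
    hap1, hap2 = accession_haplotypes(ga, truth, acc)
    r1, r2 = paths[acc]
    n_pairs = 0
    n_bases = 0
    with gzip.open(r1, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                n_pairs += 1
                n_bases += len(line.strip())
                if n_pairs <= 50:  # error-free reads are exact substrings
                    seq = line.strip()
                    assert any(seq in h["chr1"] or _rc(seq) in h["chr1"]
                               for h in (hap1, hap2))
    genome_len = np.mean([sum(map(len, hap1.values())),
                          sum(map(len, hap2.values()))])
    coverage = 2 * n_bases / genome_len  # both mates
    assert abs(coverage - 8.0) / 8.0 < 0.2


def _rc(seq):
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def test_reads_require_positive_depth(tmp_path, small_pair):
    cfg, ga, gb, truth = small_pair
    import dataclasses
    bad = dataclasses.replace(cfg, short_read_depth=0.0)
    with pytest.raises(ValueError, match="depth"):
        generate_accession_reads(ga, gb, truth, bad, tmp_path)


def test_het_locus_emits_both_alleles(tmp_path):
    cfg = small_config(sv_counts={"deletion": 1},
                       sv_size_range={"deletion": (300, 300)},
                       het_fraction=1.0, n_accessions=1,
                       short_read_depth=30.0, sequencing_error_rate=0.0)
    ga, gb, truth = generate_genome_pair(cfg)
    (sv,) = truth.planted_svs
    assert truth.genotype_matrix.iloc[0, 0] == "H"
    generate_accession_reads(ga, gb, truth, cfg, tmp_path)
    prov = truth.read_provenance[truth.genotype_matrix.index[0]]
    # reads from both haplotypes span the deletion locus
    spanning = prov[(prov.frag_start < sv.start - 20)
                    & (prov.frag_end > sv.start + 20)]
    assert set(spanning.haplotype) == {0, 1}


def test_truth_round_trip(tmp_path, small_pair):
    _, _, _, truth = small_pair
    write_truth(truth, tmp_path)
    back = read_truth(tmp_path)
    assert back.genotype_matrix.equals(truth.genotype_matrix)
    assert len(back.planted_svs) == len(truth.planted_svs)
    for x, y in zip(back.planted_svs, truth.planted_svs):
        assert x == y
    assert back.chrom_lengths_a == truth.chrom_lengths_a


def test_truth_round_trip_empty(tmp_path):
    cfg = small_config(sv_counts={t: 0 for t in SV_TYPES})
    _, _, truth = generate_genome_pair(cfg)
    write_truth(truth, tmp_path)
    back = read_truth(tmp_path)
    assert back.planted_svs == []
    assert back.genotype_matrix.shape[1] == 0
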