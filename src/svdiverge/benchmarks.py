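"""Self-contained benchmark workflows on synthetic data.

Each function generates its inputs from a seed, runs one stage of the
package end to end at desk scale, and returns the measured quantities.
They are used both by the test suite and by ``scripts/acceptance.py``.
"""
from __future__ import annotations

import tempfile
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from . import discovery as disc
from . import genotype as gt
from . import popgen as pg
from . import synthetic as syn
from .evaluate import (DiscoveryScore, GenotypeScore, score_discovery,
                       score_genotypes)
from .pipeline import align_genomes, align_long_reads, bwa_index, bwa_mem_sorted
from .records import SV_TYPES


def discovery_benchmark(seed: int, workdir: str | Path | None = None,
                        genome_length: int = 2_000_000,
                        svs_per_type: int = 15,
                        size_range: tuple[int, int] = (10, 10_000),
                        ) -> DiscoveryScore:
    """Planted-SV recovery through the full discovery chain.

    A 2-Mb genome pair with planted events of all seven classes (zero
    background divergence, as the chain is validated against exact truth),
    aligned with minimap2; calls go through gap filtering, flank
    validation, read-based refinement of complex calls and merging, and are
    scored against the planted truth.
    """
    with tempfile.TemporaryDirectory() as tmp:
        d = Path(workdir) if workdir else Path(tmp)
        d.mkdir(parents=True, exist_ok=True)
        cfg = syn.SimulationConfig(
            seed=seed, genome_length=genome_length, n_chromosomes=2,
            sv_counts={t: svs_per_type for t in SV_TYPES},
            sv_size_range={t: size_range for t in SV_TYPES},
            background_divergence=0.0, n_accessions=2,
        )
        genome_a, genome_b, truth = syn.generate_genome_pair(cfg)
        fa = syn.write_fasta(genome_a, d / "A.fa")
        fb = syn.write_fasta(genome_b, d / "B.fa")
        paf = align_genomes(fa, fb, d / "b_vs_a.paf")
        blocks = disc.read_paf(paf)
        calls = disc.call_svs_from_alignment(blocks, genome_a, genome_b)
        calls = disc.filter_near_gaps(calls, genome_a, genome_b)
        results = disc.validate_by_flanks(calls, genome_a, genome_b)
        calls = disc.apply_flank_validation(calls, results)
        lr = syn.simulate_long_reads(genome_b, cfg, d / "lr.fastq.gz")
        lr_paf = align_long_reads(fa, lr, d / "lr_vs_a.paf")
        read_calls = disc.call_svs_from_reads(
            disc.read_paf(lr_paf, min_mapq=20), genome_a)
        refined = disc.refine_complex_svs(calls, read_calls)
        read_calls = disc.exclude_reads_in_complex_regions(read_calls, refined)
        final = disc.merge_callsets(refined, read_calls)
        return score_discovery(truth.planted_svs, final)


@dataclass
class GenotypingBenchmark:
    score: GenotypeScore
    matrix: pd.DataFrame
    truth: syn.TruthSet


def genotyping_benchmark(seed: int, workdir: str | Path | None = None,
                         n_accessions: int = 12, n_svs: int = 40,
                         depth: float = 30.0, error_rate: float = 0.005,
                         het_fraction: float = 0.25,
                         ) -> GenotypingBenchmark:
    """Genotype recovery for a synthetic accession panel.

    The reference SV set (the planted truth, with both-genome breakpoints)
    is genotyped in each accession from deduplicated bwa alignments to both
    genomes, and the determined calls are scored against the planted
    genotype matrix.
    """
    with tempfile.TemporaryDirectory() as tmp:
        d = Path(workdir) if workdir else Path(tmp)
        d.mkdir(parents=True, exist_ok=True)
        per_type = {t: n_svs // len(SV_TYPES) for t in SV_TYPES}
        for i, t in enumerate(SV_TYPES):
            if i < n_svs % len(SV_TYPES):
                per_type[t] += 1
        cfg = syn.SimulationConfig(
            seed=seed, genome_length=600_000, n_chromosomes=1,
            sv_counts=per_type,
            sv_size_range={t: (10, 3000) for t in SV_TYPES},
            n_accessions=n_accessions, het_fraction=het_fraction,
            short_read_depth=depth, sequencing_error_rate=error_rate,
            min_sv_spacing=5000, edge_margin=7000,
        )
        genome_a, genome_b, truth = syn.generate_genome_pair(cfg)
        fa = syn.write_fasta(genome_a, d / "A.fa")
        fb = syn.write_fasta(genome_b, d / "B.fa")
        bwa_index(fa)
        bwa_index(fb)
        read_paths = syn.generate_accession_reads(genome_a, genome_b, truth,
                                                  cfg, d / "reads")
        calls_all = []
        for acc, (fq1, fq2) in read_paths.items():
            d1 = d / "reads" / f"{acc}_d1.fastq.gz"
            d2 = d / "reads" / f"{acc}_d2.fastq.gz"
            gt.deduplicate_fastq_pair(fq1, fq2, d1, d2, cfg.short_read_length)
            bam_a = bwa_mem_sorted(fa, d1, d2, d / f"{acc}_A.bam")
            bam_b = bwa_mem_sorted(fb, d1, d2, d / f"{acc}_B.bam")
            calls_all.extend(gt.genotype_accession(
                bam_a, bam_b, truth.planted_svs, acc))
            bam_a.unlink()
            bam_b.unlink()
        matrix, _, _ = gt.genotype_matrix(calls_all)
        score = score_genotypes(truth, matrix)
        return GenotypingBenchmark(score=score, matrix=matrix, truth=truth)


def _oracle_margin_probs(r1: int, r2: int, c1: int) -> dict[int, Fraction]:
    """Exact-Fraction probability of every table with the given margins."""
    n = r1 + r2
    total = comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = Fraction(comb(r1, k) * comb(r2, c1 - k), total)
    return probs


def fisher_oracle_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher p: enumerate every table with the
    observed margins and sum exact-Fraction probabilities of tables no more
    probable than the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    probs = _oracle_margin_probs(r1, r2, c1)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def fisher_benchmark(max_total: int = 60) -> tuple[float, int]:
    """Max |p_implementation - p_oracle| over all 2x2 tables with
    total <= max_total; returns (max deviation, number of tables)."""
    worst = 0.0
    n_tables = 0
    for n in range(max_total + 1):
        for r1 in range(n + 1):
            r2 = n - r1
            for c1 in range(n + 1):
                lo = max(0, c1 - r2)
                hi = min(r1, c1)
                if lo > hi:
                    continue
                degenerate = r1 == 0 or r2 == 0 or c1 == 0 or c1 == n
                probs = None if degenerate else _oracle_margin_probs(r1, r2, c1)
                for a in range(lo, hi + 1):
                    bq = r1 - a
                    cq = c1 - a
                    dq = r2 - cq
                    n_tables += 1
                    p_impl = pg.fisher_exact([[a, bq], [cq, dq]])
                    if degenerate:
                        p_oracle = 1.0
                    else:
                        p_obs = probs[a]
                        p_oracle = float(sum(p for p in probs.values()
                                             if p <= p_obs))
                    dev = abs(p_impl - p_oracle)
                    if dev > worst:
                        worst = dev
    return worst, n_tables


@dataclass
class ScanBenchmark:
    power: float
    false_positives: int
    n_contrast: int
    n_null: int


def scan_benchmark(seed: int, group_size: int = 50, n_contrast: int = 50,
                   n_null: int = 450,
                   contrast: tuple[float, float] = (0.9, 0.1),
                   alpha: float = 0.001, min_fold: float = 2.0
                   ) -> ScanBenchmark:
    """Power and size of the differentiation scan on a synthetic cohort.

    Two groups of ``group_size`` accessions; ``n_contrast`` SVs with
    planted A-allele frequencies 0.9 vs 0.1 and ``n_null`` SVs with a
    common frequency of 0.5 drawn under Hardy-Weinberg sampling.
    """
    rng = np.random.default_rng(seed)
    n_acc = 2 * group_size
    accessions = [f"acc{i:03d}" for i in range(n_acc)]
    labels = pd.Series(["g1"] * group_size + ["g2"] * group_size,
                       index=accessions)
    sv_ids = ([f"hit{i:04d}" for i in range(n_contrast)]
              + [f"null{i:04d}" for i in range(n_null)])
    data = np.empty((n_acc, n_contrast + n_null), dtype="U1")
    for j in range(n_contrast + n_null):
        for i in range(n_acc):
            if j < n_contrast:
                fa = contrast[0] if i < group_size else contrast[1]
            else:
                fa = 0.5
            dose = rng.binomial(2, fa)
            data[i, j] = "A" if dose == 2 else ("H" if dose == 1 else "B")
    matrix = pd.DataFrame(data, index=accessions, columns=sv_ids)
    records = pg.differentiation_scan(matrix, labels, "g1", "g2",
                                      alpha=alpha, min_fold=min_fold)
    selected = {r.sv_id for r in records if r.selected}
    power = len([s for s in selected if s.startswith("hit")]) / n_contrast
    fp = len([s for s in selected if s.startswith("null")])
    return ScanBenchmark(power=power, false_positives=fp,
                         n_contrast=n_contrast, n_null=n_null)
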