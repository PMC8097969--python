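"""End-to-end orchestration: simulate -> align -> discover -> genotype ->
popgen -> annotate, with a config file, per-stage seeds, structured logging
and a checksum manifest.

External aligners (minimap2, bwa, samtools) are invoked for the alignment
inputs the analysis stages consume; the analysis itself is this package's
code. All randomness fans out deterministically from the single global
seed, so a rerun with the same config reproduces identical manifests.
"""
from __future__ import annotations

import configparser
import hashlib
import json
import logging
import shutil
import subprocess
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import annotate as ann
from . import discovery as disc
from . import genotype as gt
from . import popgen as pg
from . import synthetic as syn
from .evaluate import score_discovery, score_genotypes
from .records import SV_TYPES

log = logging.getLogger("svdiverge.pipeline")


class ConfigError(Exception):
    """Invalid or unparseable pipeline configuration."""


class DataError(Exception):
    """Missing or malformed data for an enabled stage."""


@dataclass
class PipelineConfig:
    """All stage parameters; defaults mirror the reference workflow."""

    seed: int = 1
    # stage toggles
    run_simulate: bool = True
    run_discover: bool = True
    run_genotype: bool = True
    run_popgen: bool = True
    run_annotate: bool = True
    # simulation
    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    sv_count_per_type: int = 15
    sv_min_size: int = 10
    sv_max_size: int = 10_000
    n_accessions: int = 12
    het_fraction: float = 0.25
    short_read_depth: float = 30.0
    short_read_length: int = 150
    sequencing_error_rate: float = 0.005
    background_divergence: float = 0.0
    long_read_depth: float = 15.0
    long_read_mean_length: int = 12_000
    n_genes: int = 40
    min_sv_spacing: int = 10_000
    edge_margin: int = 12_000
    # discovery
    min_size: int = 10
    max_size: int = 700_000
    flank: int = 5000
    gap_distance: int = 50
    min_n_run: int = 10
    min_reciprocal: float = 0.5
    # genotyping
    min_split: int = 3
    split_window: int = 10
    max_mismatch_fraction: float = 0.03
    # popgen
    window: int = 25_000
    alpha: float = 0.001
    min_fold: float = 2.0
    min_determined: float = 0.5
    group1: str = "group1"
    group2: str = "group2"
    # annotation
    promoter: int = 2000
    mu: float = 1.5e-8
    # paths (optional external inputs when simulate is disabled)
    genome_a: str = ""
    genome_b: str = ""

    def validate(self) -> list[str]:
        errors = []
        if self.window <= 0:
            errors.append(f"window must be positive, got {self.window}")
        if self.min_size < 10:
            errors.append(f"min_size must be >= 10, got {self.min_size}")
        if not 0 < self.alpha <= 1:
            errors.append(f"alpha must be in (0,1], got {self.alpha}")
        if self.min_fold < 1:
            errors.append(f"min_fold must be >= 1, got {self.min_fold}")
        if self.mu <= 0:
            errors.append(f"mu must be positive, got {self.mu}")
        if self.flank <= 0:
            errors.append(f"flank must be positive, got {self.flank}")
        if self.min_split < 1:
            errors.append(f"min_split must be >= 1, got {self.min_split}")
        if self.promoter < 0:
            errors.append(f"promoter must be >= 0, got {self.promoter}")
        if not 0 <= self.min_reciprocal <= 1:
            errors.append(f"min_reciprocal must be in [0,1], got {self.min_reciprocal}")
        if self.short_read_length not in (100, 150):
            errors.append("short_read_length must be 100 or 150")
        return errors


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a key=value config file (INI sections).

    Unknown keys are rejected; every violated constraint is reported with
    its key and reason in one error.
    """
    parser = configparser.ConfigParser()
    try:
        read = parser.read(str(path))
    except configparser.Error as exc:
        raise ConfigError(f"cannot parse config file: {exc}") from exc
    if not read:
        raise ConfigError(f"cannot read config file {path}")
    known = {f.name: f.type for f in fields(PipelineConfig)}
    kwargs = {}
    errors = []
    for section in parser.sections():
        for key, value in parser.items(section):
            if key not in known:
                errors.append(f"unknown key {key!r} in section [{section}]")
                continue
            ftype = known[key]
            try:
                if ftype == "bool":
                    kwargs[key] = value.strip().lower() in ("1", "true", "yes", "on")
                elif ftype == "int":
                    kwargs[key] = int(value)
                elif ftype == "float":
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
            except ValueError:
                errors.append(f"key {key!r}: cannot convert {value!r} to {ftype}")
    if errors:
        raise ConfigError("; ".join(errors))
    config = PipelineConfig(**kwargs)
    violations = config.validate()
    if violations:
        raise ConfigError("; ".join(violations))
    return config


def write_default_config(path: str | Path) -> Path:
    """Write a config file with all documented defaults."""
    cfg = PipelineConfig()
    path = Path(path)
    sections = {
        "global": ["seed"],
        "stages": ["run_simulate", "run_discover", "run_genotype",
                    "run_popgen", "run_annotate"],
        "simulate": ["genome_length", "n_chromosomes", "sv_count_per_type",
                     "sv_min_size", "sv_max_size", "n_accessions",
                     "het_fraction", "short_read_depth", "short_read_length",
                     "sequencing_error_rate", "background_divergence",
                     "long_read_depth", "long_read_mean_length", "n_genes"],
        "discover": ["min_size", "max_size", "flank", "gap_distance",
                     "min_n_run", "min_reciprocal", "genome_a", "genome_b"],
        "genotype": ["min_split", "split_window", "max_mismatch_fraction"],
        "popgen": ["window", "alpha", "min_fold", "min_determined",
                   "group1", "group2"],
        "annotate": ["promoter", "mu"],
    }
    with open(path, "w") as fh:
        for section, keys in sections.items():
            fh.write(f"[{section}]\n")
            for k in keys:
                fh.write(f"{k} = {getattr(cfg, k)}\n")
            fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# external tools
# ---------------------------------------------------------------------------

def _require(tool: str) -> str:
    path = shutil.which(tool)
    if path is None:
        raise DataError(f"required tool {tool!r} not found on PATH")
    return path


def _run(cmd: list[str], out_path: Optional[Path] = None) -> None:
    log.debug("running: %s", " ".join(cmd))
    if out_path is not None:
        with open(out_path, "wb") as fh:
            subprocess.run(cmd, check=True, stdout=fh,
                           stderr=subprocess.DEVNULL)
    else:
        subprocess.run(cmd, check=True, capture_output=True)


def align_genomes(genome_a_fa: Path, genome_b_fa: Path, out_paf: Path) -> Path:
    """Whole-genome alignment (asm preset, cs tags) of B against A."""
    _require("minimap2")
    _run(["minimap2", "-cx", "asm5", "--cs", "-t1", str(genome_a_fa),
          str(genome_b_fa)], out_paf)
    return out_paf


def align_long_reads(genome_fa: Path, reads_fq: Path, out_paf: Path) -> Path:
    _require("minimap2")
    _run(["minimap2", "-cx", "map-pb", "--cs", "-t1", str(genome_fa),
          str(reads_fq)], out_paf)
    return out_paf


def bwa_index(genome_fa: Path) -> None:
    _require("bwa")
    if not Path(str(genome_fa) + ".bwt").exists():
        _run(["bwa", "index", str(genome_fa)])


def bwa_mem_sorted(genome_fa: Path, fq1: Path, fq2: Path, out_bam: Path) -> Path:
    _require("bwa")
    _require("samtools")
    sam = out_bam.with_suffix(".sam")
    with open(sam, "wb") as fh:
        subprocess.run(["bwa", "mem", "-t", "1", str(genome_fa), str(fq1),
                        str(fq2)], check=True, stdout=fh,
                       stderr=subprocess.DEVNULL)
    subprocess.run(["samtools", "sort", "-@", "1", "-o", str(out_bam),
                    str(sam)], check=True, capture_output=True)
    sam.unlink()
    subprocess.run(["samtools", "index", str(out_bam)], check=True,
                   capture_output=True)
    return out_bam


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _content_checksum(path: Path) -> str:
    """sha256 of semantic file content.

    BAM/SAM files are hashed on their alignment records (headers carry
    command lines with absolute paths); gzip files on decompressed bytes.
    """
    h = hashlib.sha256()
    suffix = path.suffix
    if suffix in (".bam", ".sam", ".cram"):
        res = subprocess.run(["samtools", "view", str(path)],
                             check=True, capture_output=True)
        h.update(res.stdout)
    elif suffix == ".gz":
        import gzip
        with gzip.open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
    else:
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
    return h.hexdigest()


def write_manifest(run_dir: Path) -> Path:
    rows = []
    skip_suffixes = {".bai", ".fai", ".bwt", ".pac", ".ann", ".amb", ".sa"}
    # reports carrying wall-clock times are not data outputs
    skip_names = {"manifest.tsv", "summary.json", "pipeline.log"}
    for p in sorted(run_dir.rglob("*")):
        if not p.is_file() or p.name in skip_names:
            continue
        if p.suffix in skip_suffixes:
            continue
        rows.append((str(p.relative_to(run_dir)), _content_checksum(p)))
    manifest = run_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("path\tsha256\n")
        for rel, digest in rows:
            fh.write(f"{rel}\t{digest}\n")
    return manifest


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the summary dict (also written to ``summary.json``); every
    output file is listed with a content checksum in ``manifest.tsv``.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(run_dir / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("svdiverge")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    summary: dict = {"config": {f.name: getattr(config, f.name)
                                for f in fields(PipelineConfig)}}
    timers: dict[str, float] = {}

    genome_a = genome_b = None
    truth = None
    genes = None
    read_paths: dict[str, tuple[Path, Path]] = {}
    try:
        if config.run_simulate:
            t0 = time.perf_counter()
            log.info("stage simulate: genome_length=%d, %d SVs/type, %d accessions",
                     config.genome_length, config.sv_count_per_type,
                     config.n_accessions)
            sim = syn.SimulationConfig(
                seed=_stage_seed(config.seed, "simulate"),
                genome_length=config.genome_length,
                n_chromosomes=config.n_chromosomes,
                sv_counts={t: config.sv_count_per_type for t in SV_TYPES},
                sv_size_range={t: (config.sv_min_size, config.sv_max_size)
                               for t in SV_TYPES},
                n_accessions=config.n_accessions,
                het_fraction=config.het_fraction,
                short_read_length=config.short_read_length,
                short_read_depth=config.short_read_depth,
                sequencing_error_rate=config.sequencing_error_rate,
                background_divergence=config.background_divergence,
                long_read_mean_length=config.long_read_mean_length,
                long_read_depth=config.long_read_depth,
                min_sv_spacing=config.min_sv_spacing,
                edge_margin=config.edge_margin,
            )
            genome_a, genome_b, truth = syn.generate_genome_pair(sim)
            gdir = run_dir / "genomes"
            gdir.mkdir(exist_ok=True)
            fa_a = syn.write_fasta(genome_a, gdir / "genomeA.fa")
            fa_b = syn.write_fasta(genome_b, gdir / "genomeB.fa")
            syn.write_truth(truth, run_dir / "truth", include_provenance=False)
            genes = syn.generate_gene_models(truth.chrom_lengths_a,
                                             config.n_genes, sim.seed)
            ann.write_gff3(genes, gdir / "genes.gff3")
            labels = syn.accession_groups(truth)
            labels.to_csv(run_dir / "truth" / "groups.tsv", sep="\t",
                          index_label="accession")
            if config.run_genotype:
                read_paths = syn.generate_accession_reads(
                    genome_a, genome_b, truth, sim, run_dir / "reads")
            if config.run_discover:
                syn.simulate_long_reads(genome_b, sim,
                                        run_dir / "reads" / "longreads_b.fastq.gz")
            timers["simulate"] = time.perf_counter() - t0
        else:
            if config.run_discover or config.run_genotype or config.run_annotate:
                if not (config.genome_a and config.genome_b):
                    raise DataError(
                        "stage discover requires genomes: enable simulate or "
                        "set genome_a/genome_b paths")
                genome_a = syn.load_genome(config.genome_a)
                genome_b = syn.load_genome(config.genome_b)
                fa_a, fa_b = Path(config.genome_a), Path(config.genome_b)

        svs = None
        if config.run_discover:
            t0 = time.perf_counter()
            adir = run_dir / "align"
            adir.mkdir(exist_ok=True)
            paf = align_genomes(fa_a, fa_b, adir / "b_vs_a.paf")
            blocks = disc.read_paf(paf)
            log.info("stage discover: %d alignment blocks; min_size=%d, "
                     "gap_distance=%d, flank=%d", len(blocks),
                     config.min_size, config.gap_distance, config.flank)
            calls = disc.call_svs_from_alignment(
                blocks, genome_a, genome_b,
                min_size=config.min_size, max_size=config.max_size)
            calls = disc.filter_near_gaps(
                calls, genome_a, genome_b,
                max_distance=config.gap_distance, min_n_run=config.min_n_run)
            flank_results = disc.validate_by_flanks(
                calls, genome_a, genome_b, flank=config.flank)
            calls = disc.apply_flank_validation(calls, flank_results)
            lr_fq = run_dir / "reads" / "longreads_b.fastq.gz"
            read_calls: list = []
            if lr_fq.exists():
                lr_paf = align_long_reads(fa_a, lr_fq, adir / "longreads_vs_a.paf")
                lr_blocks = disc.read_paf(lr_paf, min_mapq=20, min_block=1000)
                read_calls = disc.call_svs_from_reads(
                    lr_blocks, genome_a,
                    min_size=config.min_size, max_size=config.max_size)
            refined = disc.refine_complex_svs(calls, read_calls)
            read_calls_m = disc.exclude_reads_in_complex_regions(read_calls,
                                                                 refined)
            merged = disc.merge_callsets(refined, read_calls_m,
                                         min_reciprocal=config.min_reciprocal)
            svs = disc.fill_mate_coords(merged, blocks)
            ddir = run_dir / "discovery"
            ddir.mkdir(exist_ok=True)
            disc.write_sv_set(svs, ddir / "svs.vcf", genome=genome_a)
            disc.write_bed(svs, ddir / "svs.bed")
            summary["discovery"] = {
                "n_assembly_calls": len(calls), "n_read_calls": len(read_calls),
                "n_final": len(svs)}
            if truth is not None:
                sc = score_discovery(truth.planted_svs, svs)
                summary["discovery"].update({
                    "recall": sc.recall, "precision": sc.precision,
                    "max_breakpoint_error": sc.max_breakpoint_error})
            timers["discover"] = time.perf_counter() - t0

        matrix = None
        if config.run_genotype:
            t0 = time.perf_counter()
            if svs is None:
                vcf = run_dir / "discovery" / "svs.vcf"
                if not vcf.exists():
                    raise DataError("stage genotype requires discovery output "
                                    "(discovery/svs.vcf missing)")
                svs = disc.read_sv_set(vcf)
            if not read_paths:
                raise DataError("stage genotype requires simulated reads "
                                "(enable simulate)")
            log.info("stage genotype: %d SVs x %d accessions; min_split=%d, "
                     "mismatch cap=%.2f", len(svs), len(read_paths),
                     config.min_split, config.max_mismatch_fraction)
            bwa_index(fa_a)
            bwa_index(fa_b)
            adir = run_dir / "align"
            adir.mkdir(exist_ok=True)
            calls_all = []
            for acc, (fq1, fq2) in read_paths.items():
                d1 = run_dir / "reads" / f"{acc}_dedup_1.fastq.gz"
                d2 = run_dir / "reads" / f"{acc}_dedup_2.fastq.gz"
                ndup = gt.deduplicate_fastq_pair(fq1, fq2, d1, d2,
                                                 config.short_read_length)
                log.info("%s: %d duplicate pairs removed", acc, ndup)
                bam_a = bwa_mem_sorted(fa_a, d1, d2, adir / f"{acc}_A.bam")
                bam_b = bwa_mem_sorted(fa_b, d1, d2, adir / f"{acc}_B.bam")
                calls_all.extend(gt.genotype_accession(
                    bam_a, bam_b, svs, acc, min_split=config.min_split,
                    window=config.split_window,
                    max_mismatch_fraction=config.max_mismatch_fraction))
            matrix, rate, per_sv = gt.genotype_matrix(calls_all)
            gdir2 = run_dir / "genotype"
            gdir2.mkdir(exist_ok=True)
            gt.write_genotype_matrix(matrix, gdir2 / "matrix.tsv")
            gt.write_evidence_table(calls_all, gdir2 / "evidence.tsv")
            rate.to_csv(gdir2 / "genotyping_rate.tsv", sep="\t",
                        index_label="accession")
            summary["genotype"] = {
                "n_calls": len(calls_all),
                "mean_genotyping_rate": float(rate.mean())}
            if truth is not None:
                sc = score_genotypes(truth, matrix, calls=svs)
                summary["genotype"].update({
                    "accuracy": sc.accuracy, "false_rate": sc.false_rate,
                    "determined_rate": sc.determined_rate})
            timers["genotype"] = time.perf_counter() - t0

        if config.run_popgen:
            t0 = time.perf_counter()
            if matrix is None:
                mpath = run_dir / "genotype" / "matrix.tsv"
                if not mpath.exists():
                    raise DataError("stage popgen requires the genotype matrix")
                matrix = gt.read_genotype_matrix(mpath)
            lpath = run_dir / "truth" / "groups.tsv"
            if not lpath.exists():
                raise DataError("stage popgen requires group labels")
            labels = pd.read_csv(lpath, sep="\t", index_col="accession")["group"]
            log.info("stage popgen: window=%d, alpha=%g, min_fold=%g",
                     config.window, config.alpha, config.min_fold)
            if svs is None:
                svs = disc.read_sv_set(run_dir / "discovery" / "svs.vcf")
            thinned = pg.thin_by_windows(svs, window=config.window,
                                         seed=_stage_seed(config.seed, "thin"))
            thin_ids = [s.sv_id for s in thinned if s.sv_id in matrix.columns]
            structure_matrix = matrix[thin_ids] if thin_ids else matrix
            records = pg.differentiation_scan(
                matrix, labels, config.group1, config.group2,
                alpha=config.alpha, min_fold=config.min_fold,
                min_determined=config.min_determined)
            dist_df, coords, explained, newick = pg.distance_and_pca(structure_matrix)
            pdir = run_dir / "popgen"
            pg.export_popgen(pdir, dist_df, coords, explained, newick, records)
            per_acc, group_means = pg.genotype_composition(matrix, labels)
            per_acc.to_csv(pdir / "composition_per_accession.tsv", sep="\t",
                           index_label="accession")
            group_means.to_csv(pdir / "composition_group_means.tsv", sep="\t")
            summary["popgen"] = {
                "n_tested": len(records),
                "n_selected": sum(r.selected for r in records),
                "n_thinned": len(thinned)}
            timers["popgen"] = time.perf_counter() - t0

        if config.run_annotate:
            t0 = time.perf_counter()
            if svs is None:
                vcf = run_dir / "discovery" / "svs.vcf"
                if not vcf.exists():
                    raise DataError("stage annotate requires discovery output")
                svs = disc.read_sv_set(vcf)
            gff = run_dir / "genomes" / "genes.gff3"
            if genes is None:
                if not gff.exists():
                    raise DataError("stage annotate requires gene models")
                genes = ann.read_gff3(gff)
            chrom_lengths = {c: len(s) for c, s in genome_a.items()}
            log.info("stage annotate: %d genes, promoter=%d bp",
                     len(genes), config.promoter)
            table, affected = ann.classify_sv_gene_overlap(
                svs, genes, promoter_length=config.promoter,
                chrom_lengths=chrom_lengths)
            fractions = ann.sv_genome_fractions(svs, chrom_lengths, genes)
            adir2 = run_dir / "annotate"
            adir2.mkdir(exist_ok=True)
            table.to_csv(adir2 / "sv_gene_overlaps.tsv", sep="\t", index=False)
            affected.to_csv(adir2 / "gene_affected.tsv", sep="\t",
                            index_label="gene_id")
            pd.Series(fractions).to_csv(adir2 / "sv_fractions.tsv", sep="\t",
                                        index_label="fraction")
            summary["annotate"] = {
                "n_overlaps": len(table),
                "fraction_genes_affected": float(affected.mean())
                if len(affected) else 0.0,
                **fractions}
            timers["annotate"] = time.perf_counter() - t0

        summary["timers_sec"] = {k: round(v, 2) for k, v in timers.items()}
        with open(run_dir / "summary.json", "w") as jh:
            json.dump(summary, jh, indent=2, default=str)
        write_manifest(run_dir)
        return summary
    finally:
        root.removeHandler(fh)
        fh.close()
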