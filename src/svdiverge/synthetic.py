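"""Synthetic genome pairs with planted structural variants.

Emulates a pair of diverged chromosome-scale assemblies (genome A, genome B)
carrying insertions, deletions, substitutions, and repeat/tandem copy-number
changes of 10 bp and up, plus a panel of accession genomes drawn as mosaics
of the two haplotypes with known genotypes, and simulated paired-end and
long reads. Every output is a deterministic function of the seed.

Genome B is derived from genome A by applying the planted events left to
right, so each event's breakpoints are known exactly in both coordinate
systems. Background divergence (point substitutions outside event loci)
can be layered on genome B to mimic two independently evolved assemblies
without breaking alignability.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .records import SVRecord, SV_TYPES, GeneModel

BASES = np.frombuffer(b"ACGT", dtype="S1")

DEFAULT_SV_SIZE_RANGE: dict[str, tuple[int, int]] = {t: (10, 10_000) for t in SV_TYPES}


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the outputs."""

    seed: int = 1
    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    gc_content: float = 0.38
    sv_counts: dict[str, int] = field(
        default_factory=lambda: {t: 15 for t in SV_TYPES}
    )
    sv_size_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SV_SIZE_RANGE)
    )
    n_accessions: int = 12
    het_fraction: float = 0.25
    short_read_length: int = 150
    short_read_depth: float = 30.0
    long_read_mean_length: int = 12_000
    long_read_depth: float = 15.0
    sequencing_error_rate: float = 0.005
    gap_runs: list[tuple[str, int, int]] = field(default_factory=list)
    # divergence between the two assemblies outside planted events
    background_divergence: float = 0.005
    # placement: minimum spacing between planted events (2x flank length by
    # default so flank validation is unambiguous)
    min_sv_spacing: int = 10_000
    edge_margin: int = 12_000
    fragment_mean: int = 500
    fragment_sd: int = 60
    # population structure of the accession panel
    n_groups: int = 2
    contrast_fraction: float = 0.2
    contrast_freqs: tuple[float, float] = (0.9, 0.1)
    base_freq_a: float = 0.5

    def validate(self) -> None:
        errors = []
        for t, (lo, hi) in self.sv_size_range.items():
            if lo < 10:
                errors.append(f"min SV size for {t} is {lo}, must be >= 10 bp")
            if hi > self.genome_length // 10:
                errors.append(f"max SV size for {t} exceeds genome_length/10")
        if not 0 <= self.gc_content <= 1:
            errors.append("gc_content outside [0,1]")
        if self.short_read_length not in (100, 150):
            errors.append("short_read_length must be 100 or 150")
        if not 0 <= self.het_fraction <= 1:
            errors.append("het_fraction outside [0,1]")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class TruthSet:
    """Planted SVs, the accession x SV genotype matrix, and read provenance."""

    planted_svs: list[SVRecord]
    genotype_matrix: pd.DataFrame  # accessions x sv_ids, symbols A/B/H
    read_provenance: dict[str, pd.DataFrame] = field(default_factory=dict)
    chrom_lengths_a: dict[str, int] = field(default_factory=dict)
    chrom_lengths_b: dict[str, int] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(BASES, size=length, p=p)
    return arr.tobytes().decode()


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass
class _Event:
    chrom: str
    a_start: int
    sv_type: str
    a_seg: str  # sequence on genome A at [a_start, a_start+len(a_seg))
    b_seg: str  # sequence on genome B at the homologous locus


def _build_event(rng: np.random.Generator, sv_type: str, size: int,
                 template_slice: str, gc: float) -> tuple[str, str]:
    """Return (a_seg, b_seg) realizing one event of the requested net size."""
    if sv_type == "deletion":
        return template_slice[:size], ""
    if sv_type == "insertion":
        return "", _random_seq(rng, size, gc)
    if sv_type == "substitution":
        ratio = rng.uniform(0.4, 2.5)
        len_b = max(10, int(round(size * ratio)))
        return template_slice[:size], _random_seq(rng, len_b, gc)
    if sv_type in ("tandem_expansion", "tandem_contraction"):
        unit_len = int(rng.integers(10, min(60, max(11, size)) + 1))
        unit = _random_seq(rng, unit_len, gc)
        extra = max(1, int(round(size / unit_len)))
        short, long = unit * 2, unit * (2 + extra)
        return (short, long) if sv_type == "tandem_expansion" else (long, short)
    if sv_type in ("repeat_expansion", "repeat_contraction"):
        unit_len = int(rng.integers(30, max(31, min(300, size)) + 1))
        unit = _random_seq(rng, unit_len, gc)
        per_copy = unit_len + 20
        extra = max(1, int(round(size / per_copy)))
        def array(n: int) -> str:
            parts = [unit]
            for _ in range(n - 1):
                parts.append(_random_seq(rng, 20, gc))
                parts.append(unit)
            return "".join(parts)
        short, long = array(2), array(2 + extra)
        return (short, long) if sv_type == "repeat_expansion" else (long, short)
    raise ValueError(f"unknown sv_type {sv_type!r}")


def generate_genome_pair(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Generate genome A, genome B and the truth set of planted events.

    Raises ``RuntimeError`` if event placement cannot satisfy the spacing
    constraint after a bounded number of retries.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    chrom_len = config.genome_length // config.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    templates = {c: _random_seq(rng, chrom_len, config.gc_content) for c in chrom_names}

    # plant assembly gaps (N runs) in both genomes
    for chrom, pos, run in config.gap_runs:
        t = templates[chrom]
        templates[chrom] = t[:pos] + "N" * run + t[pos + run:]

    # ---- event placement by rejection sampling -------------------------
    events: list[_Event] = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for chrom, pos, run in config.gap_runs:
        # keep planted events away from gaps so gap filtering is testable
        placed[chrom].append((pos - config.min_sv_spacing, pos + run + config.min_sv_spacing))

    order = [t for t in SV_TYPES for _ in range(config.sv_counts.get(t, 0))]
    rng.shuffle(order)
    requests = []
    for sv_type in order:
        lo, hi = config.sv_size_range.get(sv_type, DEFAULT_SV_SIZE_RANGE[sv_type])
        # log-uniform sizes: short events dominate, as in real SV spectra
        size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        requests.append((sv_type, min(max(size, lo), hi)))
    # place the largest events first: packing then rarely exhausts retries
    requests.sort(key=lambda r: -r[1])
    for i, (sv_type, size) in enumerate(requests):
        for _attempt in range(5000):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            # a-side footprint: the event size plus at most two extra array
            # copies (tandem/repeat classes keep 2 base copies on each side)
            max_span = size + 800
            hi_pos = chrom_len - config.edge_margin - max_span
            if hi_pos <= config.edge_margin:
                continue
            pos = int(rng.integers(config.edge_margin, hi_pos))
            ok = all(
                pos + max_span + config.min_sv_spacing <= s or pos >= e + config.min_sv_spacing
                for s, e in placed[chrom]
            )
            if not ok:
                continue
            a_seg, b_seg = _build_event(
                rng, sv_type, size, templates[chrom][pos:pos + max_span], config.gc_content
            )
            if "N" in templates[chrom][pos:pos + max(len(a_seg), 1)]:
                continue
            events.append(_Event(chrom, pos, sv_type, a_seg, b_seg))
            placed[chrom].append((pos, pos + len(a_seg)))
            break
        else:
            raise RuntimeError(
                f"could not place event {i} ({sv_type}, {size} bp): "
                "placement retries exhausted; reduce counts/sizes or spacing"
            )

    events.sort(key=lambda e: (e.chrom, e.a_start))

    # ---- materialize genomes and record both-coordinate breakpoints ----
    genome_a: dict[str, str] = {}
    genome_b: dict[str, str] = {}
    svs: list[SVRecord] = []
    counter = 0
    for chrom in chrom_names:
        t = templates[chrom]
        a_parts: list[str] = []
        b_parts: list[str] = []
        cursor = 0
        a_off = 0
        b_off = 0
        for ev in (e for e in events if e.chrom == chrom):
            gap = t[cursor:ev.a_start]
            a_parts.append(gap)
            b_parts.append(gap)
            a_off += len(gap)
            b_off += len(gap)
            la, lb = len(ev.a_seg), len(ev.b_seg)
            counter += 1
            svs.append(SVRecord(
                sv_id=f"sv{counter:05d}",
                sv_type=ev.sv_type,
                chrom=chrom,
                start=a_off,
                end=a_off + la,
                len_a=la,
                len_b=lb,
                anchor_genome="A",
                source="truth",
                precise=ev.sv_type not in ("repeat_expansion", "repeat_contraction",
                                           "tandem_expansion", "tandem_contraction"),
                mate_coords=(chrom, b_off, b_off + lb),
                seq=ev.b_seg if 0 < lb <= 100_000 else None,
            ))
            a_parts.append(ev.a_seg)
            b_parts.append(ev.b_seg)
            a_off += la
            b_off += lb
            cursor = ev.a_start + la
        tail = t[cursor:]
        a_parts.append(tail)
        b_parts.append(tail)
        genome_a[chrom] = "".join(a_parts)
        genome_b[chrom] = "".join(b_parts)

    if config.background_divergence > 0:
        genome_b = _apply_divergence(rng, genome_b, svs, config.background_divergence)

    matrix = _draw_genotypes(rng, config, [s.sv_id for s in svs])
    truth = TruthSet(
        planted_svs=svs,
        genotype_matrix=matrix,
        chrom_lengths_a={c: len(s) for c, s in genome_a.items()},
        chrom_lengths_b={c: len(s) for c, s in genome_b.items()},
    )
    return genome_a, genome_b, truth


def _apply_divergence(rng: np.random.Generator, genome_b: dict[str, str],
                      svs: list[SVRecord], rate: float,
                      buffer: int = 100) -> dict[str, str]:
    """Point substitutions on genome B outside planted loci (+/- buffer)."""
    out = {}
    for chrom, seq in genome_b.items():
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        n = len(arr)
        mask = np.zeros(n, dtype=bool)
        for sv in svs:
            if sv.mate_coords and sv.mate_coords[0] == chrom:
                _, bs, be = sv.mate_coords
                mask[max(0, bs - buffer):min(n, be + buffer)] = True
        k = rng.binomial(n, rate)
        pos = rng.integers(0, n, size=k)
        pos = pos[~mask[pos]]
        pos = pos[arr[pos] != b"N"]
        shift = rng.integers(1, 4, size=len(pos))
        base_idx = np.searchsorted(BASES, arr[pos])
        arr[pos] = BASES[(base_idx + shift) % 4]
        out[chrom] = arr.tobytes().decode()
    return out


def _draw_genotypes(rng: np.random.Generator, config: SimulationConfig,
                    sv_ids: list[str]) -> pd.DataFrame:
    """Accession x SV genotype matrix with optional two-group frequency contrast."""
    n_acc = config.n_accessions
    accessions = [f"acc{i + 1:03d}" for i in range(n_acc)]
    groups = np.array([i * config.n_groups // n_acc for i in range(n_acc)])
    n_sv = len(sv_ids)
    n_contrast = int(round(config.contrast_fraction * n_sv))
    contrast = np.zeros(n_sv, dtype=bool)
    if n_contrast and config.n_groups >= 2:
        contrast[rng.choice(n_sv, size=n_contrast, replace=False)] = True

    data = np.empty((n_acc, n_sv), dtype="U1")
    for j in range(n_sv):
        for i in range(n_acc):
            if contrast[j]:
                fa = config.contrast_freqs[0] if groups[i] == 0 else config.contrast_freqs[1]
            else:
                fa = config.base_freq_a
            if rng.random() < config.het_fraction:
                data[i, j] = "H"
            else:
                data[i, j] = "A" if rng.random() < fa else "B"
    return pd.DataFrame(data, index=accessions, columns=sv_ids)


def accession_groups(truth: TruthSet, n_groups: int = 2) -> pd.Series:
    """Group labels matching the generator's assignment (first half group1...)."""
    acc = list(truth.genotype_matrix.index)
    n = len(acc)
    return pd.Series(
        [f"group{i * n_groups // n + 1}" for i in range(n)], index=acc, name="group"
    )


# ---------------------------------------------------------------------------
# accession haplotypes and reads
# ---------------------------------------------------------------------------

def accession_haplotypes(genome_a: dict[str, str], truth: TruthSet,
                         accession_id: str) -> tuple[dict[str, str], dict[str, str]]:
    """Two haplotype sequence sets for one accession.

    The backbone is genome A; at each planted locus the allele dictated by
    the genotype matrix is substituted (both haplotypes for homozygous
    calls, one for heterozygous).
    """
    genotypes = truth.genotype_matrix.loc[accession_id]
    haps: list[dict[str, str]] = []
    for hap_idx in range(2):
        chroms: dict[str, str] = {}
        for chrom, seq in genome_a.items():
            parts = []
            cursor = 0
            for sv in truth.planted_svs:
                if sv.chrom != chrom:
                    continue
                g = genotypes[sv.sv_id]
                use_b = g == "B" or (g == "H" and hap_idx == 1)
                parts.append(seq[cursor:sv.start])
                if use_b:
                    parts.append(sv.seq or "")
                else:
                    parts.append(seq[sv.start:sv.end])
                cursor = sv.end
            parts.append(seq[cursor:])
            chroms[chrom] = "".join(parts)
        haps.append(chroms)
    return haps[0], haps[1]


def _apply_read_errors(rng: np.random.Generator, reads: np.ndarray, rate: float) -> None:
    """In-place substitution errors on a 2-D byte array of reads."""
    if rate <= 0:
        return
    err = rng.random(reads.shape) < rate
    err &= reads != b"N"
    idx = np.searchsorted(BASES, reads[err])
    shift = rng.integers(1, 4, size=err.sum())
    reads[err] = BASES[(idx + shift) % 4]


def generate_accession_reads(
    genome_a: dict[str, str],
    genome_b: dict[str, str],
    truth: TruthSet,
    config: SimulationConfig,
    out_dir: str | Path,
    accessions: Optional[list[str]] = None,
) -> dict[str, tuple[Path, Path]]:
    """Simulate paired-end reads for each accession; returns FASTQ paths.

    Reads are sampled uniformly from each haplotype (heterozygous loci
    therefore emit both alleles at ~50:50), with per-base substitution
    errors at ``sequencing_error_rate``. Read provenance (source haplotype
    and fragment interval) is recorded in the truth set.
    """
    if config.short_read_depth <= 0:
        raise ValueError("short_read_depth must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7001]))
    rl = config.short_read_length
    paths: dict[str, tuple[Path, Path]] = {}
    if accessions is None:
        accessions = list(truth.genotype_matrix.index)
    for acc in accessions:
        hap1, hap2 = accession_haplotypes(genome_a, truth, acc)
        prov_rows = []
        r1_path = out_dir / f"{acc}_1.fastq.gz"
        r2_path = out_dir / f"{acc}_2.fastq.gz"
        with gzip.GzipFile(r1_path, "wb", mtime=0) as f1, \
                gzip.GzipFile(r2_path, "wb", mtime=0) as f2:
            serial = 0
            for hap_idx, hap in enumerate((hap1, hap2)):
                chroms = list(hap)
                lens = np.array([len(hap[c]) for c in chroms], dtype=float)
                n_pairs = int(round((config.short_read_depth / 2) * lens.sum() / (2 * rl)))
                which = rng.choice(len(chroms), size=n_pairs, p=lens / lens.sum())
                frag_lens = rng.normal(config.fragment_mean, config.fragment_sd, n_pairs)
                frag_lens = np.clip(frag_lens.round().astype(int), 2 * rl, None)
                for ci, fl in zip(which, frag_lens):
                    chrom = chroms[ci]
                    seq = hap[chrom]
                    fl = min(fl, len(seq))
                    start = int(rng.integers(0, len(seq) - fl + 1))
                    frag = seq[start:start + fl]
                    r1 = np.frombuffer(frag[:rl].encode(), dtype="S1").copy()
                    r2 = np.frombuffer(_revcomp(frag[-rl:]).encode(), dtype="S1").copy()
                    _apply_read_errors(rng, r1, config.sequencing_error_rate)
                    _apply_read_errors(rng, r2, config.sequencing_error_rate)
                    serial += 1
                    name = f"{acc}_p{serial}"
                    qual = "I" * rl
                    f1.write(f"@{name}/1\n{r1.tobytes().decode()}\n+\n{qual}\n".encode())
                    f2.write(f"@{name}/2\n{r2.tobytes().decode()}\n+\n{qual}\n".encode())
                    prov_rows.append((name, hap_idx, chrom, start, start + fl))
        truth.read_provenance[acc] = pd.DataFrame(
            prov_rows, columns=["read", "haplotype", "chrom", "frag_start", "frag_end"]
        )
        paths[acc] = (r1_path, r2_path)
    return paths


def simulate_long_reads(
    genome: dict[str, str],
    config: SimulationConfig,
    out_path: str | Path,
    seed_tag: int = 7002,
) -> Path:
    """Long single-end reads from one genome (substitution errors only)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed_tag]))
    out_path = Path(out_path)
    chroms = list(genome)
    lens = np.array([len(genome[c]) for c in chroms], dtype=float)
    total = config.long_read_depth * lens.sum()
    n_reads = int(round(total / config.long_read_mean_length))
    with gzip.GzipFile(out_path, "wb", mtime=0) as fh:
        for i in range(n_reads):
            ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
            seq = genome[chroms[ci]]
            length = int(np.clip(rng.gamma(8, config.long_read_mean_length / 8),
                                 1000, len(seq)))
            start = int(rng.integers(0, len(seq) - length + 1))
            read = np.frombuffer(seq[start:start + length].encode(), dtype="S1").copy()
            _apply_read_errors(rng, read, config.sequencing_error_rate)
            fh.write(f"@lr{i + 1}\n{read.tobytes().decode()}\n+\n{'I' * length}\n".encode())
    return out_path


# ---------------------------------------------------------------------------
# gene models (toy annotation for the annotate stage)
# ---------------------------------------------------------------------------

def generate_gene_models(chrom_lengths: dict[str, int], n_genes: int,
                         seed: int) -> list[GeneModel]:
    """Random non-overlapping gene models with 1-3 CDS exons each."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7003]))
    genes: list[GeneModel] = []
    chroms = list(chrom_lengths)
    counter = 0
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while counter < n_genes and attempts < n_genes * 200:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1000, 6000))
        lo = int(rng.integers(3000, max(3001, chrom_lengths[chrom] - length - 3000)))
        hi = lo + length
        if any(lo < e + 2500 and hi > s - 2500 for s, e in occupied[chrom]):
            continue
        n_exons = int(rng.integers(1, 4))
        bounds = np.sort(rng.choice(np.arange(lo, hi), size=2 * n_exons, replace=False))
        cds = [(int(bounds[2 * k]), int(bounds[2 * k + 1]))
               for k in range(n_exons) if bounds[2 * k + 1] > bounds[2 * k]]
        if not cds:
            continue
        counter += 1
        genes.append(GeneModel(
            gene_id=f"gene{counter:04d}", chrom=chrom, start=lo, end=hi,
            strand="+" if rng.random() < 0.5 else "-", cds_intervals=cds,
        ))
        occupied[chrom].append((lo, hi))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# truth table serialization
# ---------------------------------------------------------------------------

SV_TABLE_COLUMNS = [
    "sv_id", "sv_type", "chrom", "start", "end", "len_a", "len_b",
    "anchor_genome", "source", "precise", "mate_chrom", "mate_start",
    "mate_end", "seq",
]


def write_truth(truth: TruthSet, out_dir: str | Path,
                include_provenance: bool = True) -> dict[str, Path]:
    """Write the truth set as tab-separated files; round-trips via read_truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sv in truth.planted_svs:
        mc = sv.mate_coords or ("", "", "")
        rows.append((sv.sv_id, sv.sv_type, sv.chrom, sv.start, sv.end,
                     sv.len_a, sv.len_b, sv.anchor_genome, sv.source,
                     int(sv.precise), mc[0], mc[1], mc[2], sv.seq or ""))
    sv_df = pd.DataFrame(rows, columns=SV_TABLE_COLUMNS)
    paths = {"svs": out_dir / "truth_svs.tsv",
             "genotypes": out_dir / "truth_genotypes.tsv",
             "chroms": out_dir / "truth_chroms.tsv"}
    sv_df.to_csv(paths["svs"], sep="\t", index=False)
    truth.genotype_matrix.to_csv(paths["genotypes"], sep="\t", index_label="accession")
    chrom_df = pd.DataFrame(
        [(c, truth.chrom_lengths_a.get(c, 0), truth.chrom_lengths_b.get(c, 0))
         for c in sorted(set(truth.chrom_lengths_a) | set(truth.chrom_lengths_b))],
        columns=["chrom", "len_a", "len_b"])
    chrom_df.to_csv(paths["chroms"], sep="\t", index=False)
    if include_provenance and truth.read_provenance:
        for acc, df in truth.read_provenance.items():
            p = out_dir / f"truth_reads_{acc}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[f"reads_{acc}"] = p
    return paths


def read_truth(in_dir: str | Path) -> TruthSet:
    in_dir = Path(in_dir)
    sv_df = pd.read_csv(in_dir / "truth_svs.tsv", sep="\t",
                        dtype={"seq": str, "mate_chrom": str}, keep_default_na=False)
    svs = []
    for r in sv_df.itertuples(index=False):
        svs.append(SVRecord(
            sv_id=r.sv_id, sv_type=r.sv_type, chrom=r.chrom,
            start=int(r.start), end=int(r.end), len_a=int(r.len_a),
            len_b=int(r.len_b), anchor_genome=r.anchor_genome, source=r.source,
            precise=bool(int(r.precise)),
            mate_coords=(r.mate_chrom, int(r.mate_start), int(r.mate_end))
            if r.mate_chrom else None,
            seq=r.seq or None,
        ))
    matrix = pd.read_csv(in_dir / "truth_genotypes.tsv", sep="\t", index_col="accession")
    chrom_df = pd.read_csv(in_dir / "truth_chroms.tsv", sep="\t")
    prov = {}
    for p in sorted(in_dir.glob("truth_reads_*.tsv")):
        acc = p.stem.replace("truth_reads_", "")
        prov[acc] = pd.read_csv(p, sep="\t")
    return TruthSet(
        planted_svs=svs, genotype_matrix=matrix, read_provenance=prov,
        chrom_lengths_a=dict(zip(chrom_df.chrom, chrom_df.len_a)),
        chrom_lengths_b=dict(zip(chrom_df.chrom, chrom_df.len_b)),
    )


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA into an in-memory dict of upper-case sequences."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}
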