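"""Dual-reference split-read / read-depth SV genotyping.

Each reference SV is genotyped in one accession from short-read alignments
to both genomes. The evidence is interpreted cross-wise: an accession
carrying the genome-A allele produces split reads on genome B (where its
sequence differs from the reference being mapped to) and clean coverage on
genome A, and vice versa. An allele requires at least ``min_split``
supporting reads — split reads on the genome it disagrees with plus reads
cleanly spanning its full interval on its own genome; when junction reads
are insufficient, deletions fall back to a read-depth rule (< 50% of the
deleted interval covered at >= 2x while > 50% of a same-length flank is
covered). A homozygous call additionally requires the near-absence of
contrary evidence for the other allele.

Genotype classes: ``A`` (homozygous genome-A allele), ``B``, ``H``
(heterozygous), ``U`` (undetermined).
"""
from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .records import BreakpointEvidence, GenotypeCall, SVRecord

log = logging.getLogger(__name__)

#: duplicate-definition prefix length by read length class
DEDUP_PREFIX = {100: 90, 150: 100}


# ---------------------------------------------------------------------------
# read-pair deduplication (FASTQ level)
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                return
            seq = fh.readline().rstrip()
            fh.readline()
            qual = fh.readline().rstrip()
            yield header, seq, qual


def deduplicate_read_pairs(
    pairs: Iterable[tuple[tuple[str, str, str], tuple[str, str, str]]],
    read_length: int,
) -> tuple[list[tuple[tuple[str, str, str], tuple[str, str, str]]], int]:
    """Consolidate duplicated read pairs into unique read pairs.

    Two pairs are duplicates when both mates are identical over the first
    90 bp (100-bp reads) or 100 bp (150-bp reads). The first occurrence is
    kept; survivor order is preserved. Returns (survivors, duplicate count).
    """
    if read_length not in DEDUP_PREFIX:
        raise ValueError(f"unsupported read length {read_length}; expected 100 or 150")
    k = DEDUP_PREFIX[read_length]
    seen: set[tuple[str, str]] = set()
    survivors = []
    dups = 0
    for r1, r2 in pairs:
        if len(r1[1]) != read_length or len(r2[1]) != read_length:
            raise ValueError(
                f"mixed read lengths: expected {read_length}, got "
                f"{len(r1[1])}/{len(r2[1])} for {r1[0]}"
            )
        key = (r1[1][:k], r2[1][:k])
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        survivors.append((r1, r2))
    return survivors, dups


def deduplicate_fastq_pair(in1: str | Path, in2: str | Path,
                           out1: str | Path, out2: str | Path,
                           read_length: int) -> int:
    """Stream two mate FASTQ files through pair deduplication."""
    if read_length not in DEDUP_PREFIX:
        raise ValueError(f"unsupported read length {read_length}")
    k = DEDUP_PREFIX[read_length]
    seen: set[tuple[str, str]] = set()
    dups = 0
    with gzip.GzipFile(str(out1), "wb", mtime=0) as o1, \
            gzip.GzipFile(str(out2), "wb", mtime=0) as o2:
        for r1, r2 in zip(_iter_fastq(in1), _iter_fastq(in2)):
            if len(r1[1]) != read_length or len(r2[1]) != read_length:
                raise ValueError("mixed read lengths in input FASTQ")
            key = (r1[1][:k], r2[1][:k])
            if key in seen:
                dups += 1
                continue
            seen.add(key)
            o1.write(f"{r1[0]}\n{r1[1]}\n+\n{r1[2]}\n".encode())
            o2.write(f"{r2[0]}\n{r2[1]}\n+\n{r2[2]}\n".encode())
    return dups


# ---------------------------------------------------------------------------
# alignment filtering
# ---------------------------------------------------------------------------

def mismatch_fraction(read: pysam.AlignedSegment) -> float:
    """Substitution fraction of the aligned portion.

    The aligner's edit-distance tag counts indel bases; those are subtracted
    so the filter constrains base mismatches only.
    """
    if not read.has_tag("NM"):
        raise ValueError(f"read {read.query_name} lacks the NM tag")
    nm = read.get_tag("NM")
    aligned = 0
    indel = 0
    for op, n in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            aligned += n
        elif op in (1, 2):   # I, D
            indel += n
    if aligned == 0:
        return 1.0
    return max(0, nm - indel) / aligned


def passes_alignment_filter(read: pysam.AlignedSegment,
                            max_mismatch_fraction: float = 0.03) -> bool:
    if read.is_unmapped:
        return False
    return mismatch_fraction(read) <= max_mismatch_fraction


def filter_alignments(alignments: Iterable[pysam.AlignedSegment],
                      max_mismatch_fraction: float = 0.03
                      ) -> Iterator[pysam.AlignedSegment]:
    """Retain mapped records whose mismatch fraction is within the cap."""
    for read in alignments:
        if read.is_unmapped:
            continue
        if mismatch_fraction(read) <= max_mismatch_fraction:
            yield read


# ---------------------------------------------------------------------------
# breakpoint evidence
# ---------------------------------------------------------------------------

def _allele_interval_on(sv: SVRecord, genome: str) -> tuple[str, int, int]:
    """The SV locus on the requested genome (0-based half-open)."""
    anchor = sv.anchor_genome
    if genome == anchor:
        return sv.chrom, sv.start, sv.end
    if sv.mate_coords is None:
        raise ValueError(f"SV {sv.sv_id} has no mate coordinates for genome {genome}")
    return sv.mate_coords


def _junctions(read: pysam.AlignedSegment, min_clip: int, min_indel: int
               ) -> list[tuple[str, int]]:
    """Split junctions of one read: (kind, reference position).

    Kinds: ``clip_left`` (alignment starts here, clipped before),
    ``clip_right`` (alignment ends here, clipped after), ``del_l``/``del_r``
    (deletion-op edges), ``ins`` (insertion op position).
    """
    out = []
    ct = read.cigartuples or ()
    if not ct:
        return out
    if ct[0][0] in (4, 5) and ct[0][1] >= min_clip:
        out.append(("clip_left", read.reference_start))
    if ct[-1][0] in (4, 5) and ct[-1][1] >= min_clip:
        out.append(("clip_right", read.reference_end))
    pos = read.reference_start
    for op, n in ct:
        if op in (0, 7, 8):
            pos += n
        elif op == 2:  # D
            if n >= min_indel:
                out.append(("del_l", pos))
                out.append(("del_r", pos + n))
            pos += n
        elif op == 1 and n >= min_indel:  # I
            out.append(("ins", pos))
    return out


def collect_split_reads(
    bam: pysam.AlignmentFile,
    sv: SVRecord,
    genome: str,
    window: int = 10,
    min_clip: int = 10,
    min_indel: int = 8,
    max_mismatch_fraction: float = 0.03,
) -> tuple[int, int, int]:
    """Count split reads at the SV breakpoints on one reference genome.

    A read supports the left breakpoint when it is clipped coming from the
    left (trailing clip) or carries an indel op inside the locus, and the
    right breakpoint symmetrically. Junctions are accepted within
    ``window`` bp of the locus, padded by the event size: in repetitive
    context the aligner can place the junction anywhere within the array,
    so breakpoint placement is ambiguous up to the event's own scale. Each
    read contributes at most once per side.
    """
    chrom, start, end = _allele_interval_on(sv, genome)
    if chrom not in bam.references:
        raise ValueError(f"chromosome {chrom} not in BAM references")
    if start > bam.get_reference_length(chrom):
        raise ValueError(f"SV {sv.sv_id} coordinates outside reference")
    point = end - start <= 1
    pad = window + sv.size
    lo, hi = start - pad, end + pad
    fetch_lo = max(0, lo - 200)
    fetch_hi = min(bam.get_reference_length(chrom), hi + 200)
    left = right = total = 0
    for read in bam.fetch(chrom, fetch_lo, fetch_hi):
        if read.is_secondary or read.is_unmapped:
            continue
        if not passes_alignment_filter(read, max_mismatch_fraction):
            continue
        has_left = has_right = False
        for kind, pos in _junctions(read, min_clip, min_indel):
            if not lo <= pos <= hi:
                continue
            if point:
                # allele absent here: extra sequence shows as clips or I ops
                if kind in ("clip_right", "ins"):
                    has_left = True
                elif kind == "clip_left":
                    has_right = True
            else:
                # allele interval present here: its absence in the read
                # shows as a deletion/insertion op (evidences the whole
                # junction) or as a clip. Edge clips are side-specific;
                # clips in the interval interior arise from the retained
                # part of the other allele aligning into the array, where
                # side assignment is meaningless, so they count for both.
                if kind in ("ins", "del_l", "del_r"):
                    has_left = has_right = True
                elif kind == "clip_right":
                    has_left = True
                    if pos > start + window:
                        has_right = True
                elif kind == "clip_left":
                    has_right = True
                    if pos < end - window:
                        has_left = True
        left += has_left
        right += has_right
        total += has_left or has_right
    return left, right, total


def collect_spanning_reads(
    bam: pysam.AlignmentFile,
    sv: SVRecord,
    genome: str,
    window: int = 10,
    min_clip: int = 10,
    min_indel: int = 8,
    max_mismatch_fraction: float = 0.03,
    max_span: int = 500,
) -> int:
    """Count reads cleanly spanning the allele's full interval on this genome.

    A read that covers the interval plus ``window`` bp on both sides and
    matches the reference perfectly inside that region (no mismatch, no
    indel of any length, no large clips) must carry this genome's allele:
    any other allele differs somewhere within the interval. Sequencing
    errors outside the region are tolerated up to the usual mismatch cap.
    Point loci and intervals longer than a read return 0 (span evidence is
    then simply unavailable, not negative).
    """
    chrom, start, end = _allele_interval_on(sv, genome)
    if end - start < 1 or end - start > max_span:
        return 0
    lo, hi = start - window, end + window
    count = 0
    for read in bam.fetch(chrom, max(0, lo), hi):
        if read.is_secondary or read.is_supplementary or read.is_unmapped:
            continue
        if read.reference_start > lo or read.reference_end < hi:
            continue
        ct = read.cigartuples or ()
        if any(op in (4, 5) and n >= min_clip for op, n in ct):
            continue
        if not passes_alignment_filter(read, max_mismatch_fraction):
            continue
        # no indel op of any length whose junction falls inside the region
        pos = read.reference_start
        indel_inside = False
        for op, n in ct:
            if op in (0, 7, 8):
                pos += n
            elif op == 2:  # D
                if pos <= hi and pos + n >= lo:
                    indel_inside = True
                    break
                pos += n
            elif op == 1 and lo <= pos <= hi:  # I
                indel_inside = True
                break
        if indel_inside:
            continue
        if _mismatch_in_region(read, lo, hi):
            continue
        count += 1
    return count


def _mismatch_in_region(read: pysam.AlignedSegment, lo: int, hi: int) -> bool:
    """Any base mismatch within [lo, hi] on the reference (via the MD tag).

    Falls back to requiring a mismatch-free read when MD is unavailable.
    """
    try:
        pairs = read.get_aligned_pairs(with_seq=True)
    except ValueError:
        nm = read.get_tag("NM") if read.has_tag("NM") else 1
        indel = sum(n for op, n in (read.cigartuples or ()) if op in (1, 2))
        return nm - indel > 0
    for _, rpos, ref_base in pairs:
        if (rpos is not None and ref_base is not None
                and lo <= rpos <= hi and ref_base.islower()):
            return True
    return False


def depth_evidence_for_deletion(
    bam: pysam.AlignmentFile,
    sv: SVRecord,
    genome: str,
    depth_threshold: int = 2,
    max_mismatch_fraction: float = 0.03,
) -> tuple[float, float]:
    """Coverage fractions over the deleted interval and its best flank.

    Returns (fraction of event bases with depth >= threshold, max over the
    two adjacent same-length flanks of the fraction of covered bases).
    """
    chrom, start, end = _allele_interval_on(sv, genome)
    if end - start < 1:
        raise ValueError(f"SV {sv.sv_id} has no interval on genome {genome}")
    ref_len = bam.get_reference_length(chrom)
    length = end - start

    def covered_fraction(lo: int, hi: int, thr: int) -> float:
        lo_c, hi_c = max(0, lo), min(ref_len, hi)
        if hi_c <= lo_c:
            return 0.0
        if (lo, hi) != (lo_c, hi_c):
            log.debug("flank truncated at chromosome end for %s", sv.sv_id)
        depth = np.zeros(hi_c - lo_c, dtype=np.int32)
        for read in bam.fetch(chrom, lo_c, hi_c):
            if read.is_secondary or read.is_unmapped:
                continue
            if not passes_alignment_filter(read, max_mismatch_fraction):
                continue
            for bs, be in read.get_blocks():
                s, e = max(bs, lo_c), min(be, hi_c)
                if e > s:
                    depth[s - lo_c:e - lo_c] += 1
        return float((depth >= thr).mean())

    event = covered_fraction(start, end, depth_threshold)
    flank_left = covered_fraction(start - length, start, 1)
    flank_right = covered_fraction(end, end + length, 1)
    return event, max(flank_left, flank_right)


def gather_evidence(
    bam: pysam.AlignmentFile,
    sv: SVRecord,
    genome: str,
    window: int = 10,
    min_depth_event_len: int = 50,
    max_mismatch_fraction: float = 0.03,
) -> BreakpointEvidence:
    """Split-read counts plus (for interval loci >= 50 bp) depth fractions."""
    chrom, start, end = _allele_interval_on(sv, genome)
    left, right, total = collect_split_reads(
        bam, sv, genome, window=window, max_mismatch_fraction=max_mismatch_fraction)
    spans = collect_spanning_reads(
        bam, sv, genome, window=window,
        max_mismatch_fraction=max_mismatch_fraction)
    ev = BreakpointEvidence(
        sv_id=sv.sv_id, genome=genome, split_reads_left=left,
        split_reads_right=right, split_reads_total=total,
        spanning_reads=spans, point_event=end - start <= 1,
    )
    if end - start >= min_depth_event_len:
        event, flank = depth_evidence_for_deletion(
            bam, sv, genome, max_mismatch_fraction=max_mismatch_fraction)
        ev.depth_fraction_event = event
        ev.depth_fraction_flank_best = flank
    return ev


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

def _split_rule(ev: BreakpointEvidence, min_split: int) -> bool:
    """At least ``min_split`` distinct reads must support the junction.

    Side-resolved counts are kept as reported evidence, but the decision is
    made on distinct reads: a read whose alignment carries the indel op
    evidences both breakpoints at once, and in repetitive context the
    aligner smears junction placement across the array, so the two per-side
    counts are not independent observations.
    """
    return ev.split_reads_total >= min_split


def _depth_rule(ev: BreakpointEvidence) -> bool:
    # interval absent from the accession: < 50% of it covered at the depth
    # threshold, while > 50% of a same-length flank is covered
    return (not ev.point_event
            and ev.depth_fraction_event < 0.5
            and ev.depth_fraction_flank_best > 0.5)


def call_genotype(
    evidence_a: BreakpointEvidence,
    evidence_b: BreakpointEvidence,
    min_split: int = 3,
    accession_id: str = "",
    use_depth: bool = True,
) -> GenotypeCall:
    """Combine dual-reference evidence into one genotype call.

    Split reads on genome A evidence the B allele (and vice versa): the
    mapped reads that disagree with a reference at the locus come from the
    allele that reference does not carry. Reads cleanly spanning the
    allele's full interval on its own genome are equally diagnostic (no
    other allele can produce them) and count toward the same threshold.
    When split reads are insufficient the depth rule (deletions relative to
    that reference) is consulted.
    """
    support = {}
    reads_for = {}
    for allele, ev_other, ev_own in (("B", evidence_a, evidence_b),
                                     ("A", evidence_b, evidence_a)):
        reads_for[allele] = (ev_other.split_reads_total
                             + ev_own.spanning_reads)
        if reads_for[allele] >= min_split:
            support[allele] = "split_read"
        elif use_depth and _depth_rule(ev_other):
            support[allele] = "depth"
    if not support:
        return GenotypeCall(accession_id, evidence_a.sv_id, "U", "none",
                            evidence_a, evidence_b)
    if len(support) == 2:
        genotype = "H"
    else:
        genotype = next(iter(support))
        other = "A" if genotype == "B" else "B"
        # a homozygous call asserts the other allele is absent; two or more
        # contrary junction/span reads (below the support threshold) leave
        # the genotype ambiguous rather than homozygous
        if reads_for[other] >= max(2, min_split - 1):
            return GenotypeCall(accession_id, evidence_a.sv_id, "U", "none",
                                evidence_a, evidence_b)
    basis = "split_read" if "split_read" in support.values() else "depth"
    return GenotypeCall(accession_id, evidence_a.sv_id, genotype, basis,
                        evidence_a, evidence_b)


def genotype_accession(
    bam_a_path: str | Path,
    bam_b_path: str | Path,
    svs: Sequence[SVRecord],
    accession_id: str,
    min_split: int = 3,
    window: int = 10,
    max_mismatch_fraction: float = 0.03,
) -> list[GenotypeCall]:
    """Genotype all reference SVs in one accession from its two BAMs."""
    calls = []
    with pysam.AlignmentFile(str(bam_a_path)) as bam_a, \
            pysam.AlignmentFile(str(bam_b_path)) as bam_b:
        for sv in svs:
            ev_a = gather_evidence(bam_a, sv, "A", window=window,
                                   max_mismatch_fraction=max_mismatch_fraction)
            ev_b = gather_evidence(bam_b, sv, "B", window=window,
                                   max_mismatch_fraction=max_mismatch_fraction)
            calls.append(call_genotype(ev_a, ev_b, min_split=min_split,
                                       accession_id=accession_id))
    return calls


def genotype_matrix(calls: Sequence[GenotypeCall]
                    ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Accession x SV matrix plus genotyping rates.

    Returns (matrix with symbols A/B/H/U, per-accession genotyping rate,
    per-SV determined fraction). Raises on duplicate (accession, SV).
    """
    seen = set()
    for c in calls:
        key = (c.accession_id, c.sv_id)
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen.add(key)
    acc_ids = sorted({c.accession_id for c in calls})
    sv_ids = sorted({c.sv_id for c in calls})
    mat = pd.DataFrame("U", index=acc_ids, columns=sv_ids, dtype=object)
    for c in calls:
        mat.loc[c.accession_id, c.sv_id] = c.genotype
    determined = mat != "U"
    rate = determined.mean(axis=1)
    per_sv = determined.mean(axis=0)
    rate.name = "genotyping_rate"
    per_sv.name = "determined_fraction"
    return mat, rate, per_sv


def write_genotype_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, sep="\t", index_label="accession")
    return path


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession")


def write_evidence_table(calls: Sequence[GenotypeCall], path: str | Path) -> Path:
    rows = []
    for c in calls:
        ea, eb = c.evidence_a, c.evidence_b
        rows.append({
            "accession": c.accession_id, "sv_id": c.sv_id,
            "genotype": c.genotype, "basis": c.basis,
            "split_a_left": ea.split_reads_left if ea else None,
            "split_a_right": ea.split_reads_right if ea else None,
            "split_b_left": eb.split_reads_left if eb else None,
            "split_b_right": eb.split_reads_right if eb else None,
            "depth_event_a": ea.depth_fraction_event if ea else None,
            "depth_flank_a": ea.depth_fraction_flank_best if ea else None,
            "depth_event_b": eb.depth_fraction_event if eb else None,
            "depth_flank_b": eb.depth_fraction_flank_best if eb else None,
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
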