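"""Structural-variant discovery from whole-genome alignments.

The caller consumes alignment blocks between two assemblies (genome B as
query against genome A as target, e.g. minimap2 ``-cx asm5 --cs``) and
emits unbalanced SVs anchored on genome A:

* within-alignment events from the base-level operations (clusters of
  non-match ops separated by long match runs) — precise insertions,
  deletions and substitutions;
* between-anchor events from the gap signature of consecutive blocks —
  indels when one side's gap is ~zero, substitutions when both gaps are
  substantial and non-repetitive, and the four complex classes
  (repeat/tandem expansion/contraction) when the gap sequence is
  repeat-like; complex calls carry ``precise=False``.

Downstream steps mirror the reference workflow: removal of calls near
assembly gaps, flank re-alignment validation, refinement of complex calls
with precise read-based calls, and >= 50% reciprocal-overlap merging.
"""
from __future__ import annotations

import logging
import re
import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .records import AlignmentBlock, COMPLEX_TYPES, FlankCheckResult, SVRecord

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_CS_RE = re.compile(r"(:[0-9]+|\*[a-zA-Z][a-zA-Z]|\+[a-zA-Z]+|-[a-zA-Z]+)")


# ---------------------------------------------------------------------------
# PAF input
# ---------------------------------------------------------------------------

def _ops_from_cs(cs: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    for tok in _CS_RE.findall(cs):
        kind = tok[0]
        if kind == ":":
            ops.append(("match", int(tok[1:])))
        elif kind == "*":
            if ops and ops[-1][0] == "mismatch":
                ops[-1] = ("mismatch", ops[-1][1] + 1)
            else:
                ops.append(("mismatch", 1))
        elif kind == "+":
            ops.append(("ins", len(tok) - 1))
        elif kind == "-":
            ops.append(("del", len(tok) - 1))
    return ops


def _ops_from_cigar(cg: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    for n, op in _CIGAR_RE.findall(cg):
        n = int(n)
        if op in "M=":
            ops.append(("match", n))
        elif op == "X":
            ops.append(("mismatch", n))
        elif op == "I":
            ops.append(("ins", n))
        elif op in "DN":
            ops.append(("del", n))
    return ops


def read_paf(path: str | Path, min_mapq: int = 30,
             min_block: int = 1000) -> list[AlignmentBlock]:
    """Parse a PAF file (with cs/cg tags when present) into alignment blocks.

    Blocks from secondary alignments or with mapping quality below
    ``min_mapq`` are flagged non-unique rather than dropped, so the caller
    can skip them with a warning.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            tags = dict((t.split(":", 1)[0], t.split(":", 2)[2]) for t in f[12:])
            if int(f[10]) < min_block:
                continue
            ops = None
            if "cs" in tags:
                ops = _ops_from_cs(tags["cs"])
            elif "cg" in tags:
                ops = _ops_from_cigar(tags["cg"])
            unique = int(f[11]) >= min_mapq and tags.get("tp", "P") == "P"
            blocks.append(AlignmentBlock(
                query_name=f[0], query_start=int(f[2]), query_end=int(f[3]),
                strand=f[4], target_name=f[5], target_start=int(f[7]),
                target_end=int(f[8]), n_matches=int(f[9]),
                block_length=int(f[10]), base_ops=ops, mapping_unique=unique,
            ))
    return blocks


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def left_normalize(seq: str, pos: int, allele: str) -> tuple[int, str]:
    """Shift an indel allele left through identical sequence.

    ``pos`` is the 0-based position where ``allele`` is inserted into (or
    deleted from) ``seq``; returns the left-most equivalent placement.
    """
    if not allele:
        return pos, allele
    allele = list(allele)
    while pos > 0 and seq[pos - 1] == allele[-1]:
        allele.insert(0, allele.pop())
        pos -= 1
    return pos, "".join(allele)


def _is_repetitive(seq: str, min_unit: int = 2, max_unit: int = 500) -> bool:
    """Crude tandem periodicity check: does a unit <= half the length
    reproduce >= 80% of the sequence when tiled?"""
    n = len(seq)
    if n < 2 * min_unit:
        return False
    for unit_len in range(min_unit, min(max_unit, n // 2) + 1):
        unit = seq[:unit_len]
        tiled = (unit * (n // unit_len + 1))[:n]
        matches = sum(a == b for a, b in zip(seq, tiled))
        if matches >= 0.8 * n:
            return True
    return False


def _shares_flank_repeat(gap_a: str, gap_b: str) -> bool:
    """Do the two gap sequences share substantial content (repeat copies)?"""
    if not gap_a or not gap_b:
        return False
    short, long_ = (gap_a, gap_b) if len(gap_a) <= len(gap_b) else (gap_b, gap_a)
    k = min(30, len(short))
    probes = {short[i:i + k] for i in range(0, len(short) - k + 1, max(1, k // 2))}
    return any(p in long_ for p in probes)


# ---------------------------------------------------------------------------
# the caller
# ---------------------------------------------------------------------------

@dataclass
class _OpCluster:
    """A run of variant ops with absolute coordinates on both genomes."""

    t0: int
    t1: int
    q0: int
    q1: int
    content_a: int  # variant bases consumed on the target (mismatch + del)
    content_b: int  # variant bases consumed on the query (mismatch + ins)
    n_ops: int
    only_op: Optional[str]


def _cluster_ops(base_ops: list[tuple[str, int]], t_start: int, q_start: int,
                 tight_gap: int, join_distance: int,
                 min_join_content: int = 5) -> list[_OpCluster]:
    """Two-pass clustering of non-match ops.

    Variant ops separated by at most ``tight_gap`` matched bases form tight
    clusters; neighbouring tight clusters closer than ``join_distance`` are
    merged only when both carry at least ``min_join_content`` variant bases,
    so isolated sequencing-error mismatches neither seed events nor drag
    the breakpoints of real ones.
    """
    clusters: list[_OpCluster] = []
    t_pos, q_pos = t_start, q_start
    gap = 0
    current: Optional[_OpCluster] = None
    for op, n in base_ops:
        if op == "match":
            gap += n
            t_pos += n
            q_pos += n
            continue
        ca = n if op in ("mismatch", "del") else 0
        cb = n if op in ("mismatch", "ins") else 0
        t_next = t_pos + (n if op in ("mismatch", "del") else 0)
        q_next = q_pos + (n if op in ("mismatch", "ins") else 0)
        if current is not None and gap <= tight_gap:
            current.t1 = t_next
            current.q1 = q_next
            current.content_a += ca
            current.content_b += cb
            current.n_ops += 1
            current.only_op = current.only_op if current.only_op == op else None
        else:
            current = _OpCluster(t_pos, t_next, q_pos, q_next, ca, cb, 1, op)
            clusters.append(current)
        gap = 0
        t_pos, q_pos = t_next, q_next

    merged: list[_OpCluster] = []
    for c in clusters:
        prev = merged[-1] if merged else None
        if (prev is not None and c.t0 - prev.t1 < join_distance
                and min(prev.content_a + prev.content_b,
                        c.content_a + c.content_b) >= min_join_content):
            prev.t1, prev.q1 = c.t1, c.q1
            prev.content_a += c.content_a
            prev.content_b += c.content_b
            prev.n_ops += c.n_ops
            prev.only_op = prev.only_op if prev.only_op == c.only_op else None
        else:
            merged.append(c)
    return merged


def _within_alignment_events(block: AlignmentBlock, genome_a: dict[str, str],
                             min_size: int, max_size: int,
                             genome_b: Optional[dict[str, str]] = None,
                             join_distance: int = 50,
                             tight_gap: int = 10,
                             min_content_fraction: float = 0.3) -> list[SVRecord]:
    """Events from clusters of non-match base ops inside one alignment."""
    if not block.base_ops or block.strand != "+":
        return []
    events: list[SVRecord] = []
    chrom = block.target_name
    for cl in _cluster_ops(block.base_ops, block.target_start,
                           block.query_start, tight_gap, join_distance):
        len_a = cl.t1 - cl.t0
        len_b = cl.q1 - cl.q0
        size = max(len_a, len_b)
        content = max(cl.content_a, cl.content_b)
        if size < min_size or size > max_size:
            continue
        if content < min_size or content < min_content_fraction * size:
            continue  # sparse mismatch scatter, not a variant
        t0, t1, q0, q1 = cl.t0, cl.t1, cl.q0, cl.q1
        seq_a = genome_a[chrom][t0:t1] if chrom in genome_a else ""
        if len_a < min_size and len_b >= min_size:
            events.append(SVRecord(
                sv_id="", sv_type="insertion", chrom=chrom, start=t0,
                end=t0, len_a=0, len_b=len_b, source="assembly",
                precise=True, mate_coords=(block.query_name, q0, q1),
            ))
        elif len_b < min_size and len_a >= min_size:
            start, end = t0, t1
            if cl.only_op == "del" and chrom in genome_a:
                start, _ = left_normalize(genome_a[chrom], t0, seq_a)
                end = start + len_a
            events.append(SVRecord(
                sv_id="", sv_type="deletion", chrom=chrom, start=start,
                end=end, len_a=len_a, len_b=0, source="assembly",
                precise=True, mate_coords=(block.query_name, q0, q1),
            ))
        elif len_a >= min_size and len_b >= min_size:
            seq_b = ""
            if genome_b is not None and block.query_name in genome_b:
                seq_b = genome_b[block.query_name][q0:q1]
            repeatlike = (_shares_flank_repeat(seq_a, seq_b)
                          or _is_repetitive(seq_a) or _is_repetitive(seq_b))
            balanced = 0.1 <= len_b / len_a <= 10
            if balanced and not repeatlike:
                events.append(SVRecord(
                    sv_id="", sv_type="substitution", chrom=chrom, start=t0,
                    end=t1, len_a=len_a, len_b=len_b, source="assembly",
                    precise=True, mate_coords=(block.query_name, q0, q1),
                ))
            else:
                sv_type = ("repeat_expansion" if len_b > len_a
                           else "repeat_contraction")
                events.append(SVRecord(
                    sv_id="", sv_type=sv_type, chrom=chrom, start=t0,
                    end=t1, len_a=len_a, len_b=len_b, source="assembly",
                    precise=False, mate_coords=(block.query_name, q0, q1),
                ))
    return events


def _between_anchor_events(blocks: list[AlignmentBlock], genome_a: dict[str, str],
                           genome_b: dict[str, str], min_size: int,
                           max_size: int, max_anchor_gap: int = 100_000,
                           small_gap: int = 10) -> list[SVRecord]:
    """Events implied by the gap signature between consecutive anchors."""
    events: list[SVRecord] = []
    by_pair: dict[tuple[str, str, str], list[AlignmentBlock]] = defaultdict(list)
    for b in blocks:
        by_pair[(b.target_name, b.query_name, b.strand)].append(b)
    for (t_name, q_name, strand), group in by_pair.items():
        if strand != "+":
            continue  # unbalanced SV calling assumes colinear anchors
        group.sort(key=lambda b: b.target_start)
        for prev, nxt in zip(group, group[1:]):
            t_gap = nxt.target_start - prev.target_end
            q_gap = nxt.query_start - prev.query_end
            if t_gap > max_anchor_gap or q_gap > max_anchor_gap:
                continue
            if max(t_gap, q_gap) < min_size or max(t_gap, q_gap) > max_size:
                continue
            if t_gap < -max_anchor_gap or q_gap < -max_anchor_gap:
                continue
            chrom = t_name
            t0, t1 = prev.target_end, nxt.target_start
            q0, q1 = prev.query_end, nxt.query_start
            la, lb = max(t_gap, 0), max(q_gap, 0)
            mate = (q_name, min(q0, q1), max(q0, q1))
            if min(t_gap, q_gap) < 0:
                # anchors overlap on one genome: tandem copy-number change
                sv_type = ("tandem_expansion" if q_gap > t_gap
                           else "tandem_contraction")
                start, end = min(t0, t1), max(t1, t0 + 1)
                events.append(SVRecord(
                    sv_id="", sv_type=sv_type, chrom=chrom, start=start,
                    end=end, len_a=max(t_gap, 0), len_b=max(q_gap, 0),
                    source="assembly", precise=False, mate_coords=mate,
                ))
            elif t_gap <= small_gap and q_gap >= min_size:
                start = t1 if t_gap <= 0 else t0
                events.append(SVRecord(
                    sv_id="", sv_type="insertion", chrom=chrom, start=start,
                    end=start, len_a=0, len_b=q_gap, source="assembly",
                    precise=True, mate_coords=mate,
                ))
            elif q_gap <= small_gap and t_gap >= min_size:
                events.append(SVRecord(
                    sv_id="", sv_type="deletion", chrom=chrom, start=t0,
                    end=t1, len_a=t_gap, len_b=0, source="assembly",
                    precise=True, mate_coords=mate,
                ))
            else:
                gap_a = genome_a.get(chrom, "")[t0:t1]
                gap_b = genome_b.get(q_name, "")[q0:q1]
                # anchors often stop short of the true junction, leaving
                # identical flank residue in both gaps: trim it so typing
                # sees only the divergent sequence and breakpoints are exact
                lcp = 0
                limit = min(len(gap_a), len(gap_b))
                while lcp < limit and gap_a[lcp] == gap_b[lcp]:
                    lcp += 1
                lcs = 0
                while (lcs < limit - lcp
                       and gap_a[-1 - lcs] == gap_b[-1 - lcs]):
                    lcs += 1
                t0 += lcp
                q0 += lcp
                t1 -= lcs
                q1 -= lcs
                gap_a = gap_a[lcp:len(gap_a) - lcs]
                gap_b = gap_b[lcp:len(gap_b) - lcs]
                t_gap, q_gap = t1 - t0, q1 - q0
                mate = (q_name, q0, q1)
                if max(t_gap, q_gap) < min_size:
                    continue
                repeatlike = (_shares_flank_repeat(gap_a, gap_b)
                              or _is_repetitive(gap_a) or _is_repetitive(gap_b))
                if t_gap < min_size <= q_gap:
                    events.append(SVRecord(
                        sv_id="", sv_type="insertion", chrom=chrom, start=t0,
                        end=t0, len_a=0, len_b=q_gap, source="assembly",
                        precise=True, mate_coords=mate,
                    ))
                elif q_gap < min_size <= t_gap:
                    events.append(SVRecord(
                        sv_id="", sv_type="deletion", chrom=chrom, start=t0,
                        end=t1, len_a=t_gap, len_b=0, source="assembly",
                        precise=True, mate_coords=mate,
                    ))
                elif repeatlike:
                    sv_type = ("repeat_expansion" if q_gap > t_gap
                               else "repeat_contraction")
                    events.append(SVRecord(
                        sv_id="", sv_type=sv_type, chrom=chrom, start=t0,
                        end=t1, len_a=t_gap, len_b=q_gap, source="assembly",
                        precise=False, mate_coords=mate,
                    ))
                elif 0.1 <= q_gap / max(t_gap, 1) <= 10:
                    events.append(SVRecord(
                        sv_id="", sv_type="substitution", chrom=chrom,
                        start=t0, end=t1, len_a=t_gap, len_b=q_gap,
                        source="assembly", precise=True, mate_coords=mate,
                    ))
    return events


def call_svs_from_alignment(
    blocks: Sequence[AlignmentBlock],
    genome_a: dict[str, str],
    genome_b: dict[str, str],
    min_size: int = 10,
    max_size: int = 700_000,
    id_prefix: str = "asm",
) -> list[SVRecord]:
    """Call unbalanced SVs (anchored on genome A) from alignment blocks."""
    if min_size < 10:
        raise ValueError("min_size must be >= 10 bp")
    unique = [b for b in blocks if b.mapping_unique]
    skipped = len(blocks) - len(unique)
    if skipped:
        log.warning("skipping %d non-unique alignment blocks", skipped)
    events: list[SVRecord] = []
    for b in unique:
        events.extend(_within_alignment_events(b, genome_a, min_size, max_size,
                                               genome_b=genome_b))
    events.extend(_between_anchor_events(unique, genome_a, genome_b,
                                         min_size, max_size))
    events.sort(key=lambda s: (s.chrom, s.start, s.end))
    deduped: list[SVRecord] = []
    seen: set[tuple] = set()
    for ev in events:
        key = (ev.chrom, ev.start, ev.end, ev.sv_type, ev.len_a, ev.len_b)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(ev)
    deduped = merge_callsets(deduped, [])
    for i, ev in enumerate(deduped, 1):
        ev.sv_id = f"{id_prefix}{i:05d}"
    return deduped


# ---------------------------------------------------------------------------
# gap filtering
# ---------------------------------------------------------------------------

def find_n_runs(genome: dict[str, str], min_n_run: int = 10) -> dict[str, list[tuple[int, int]]]:
    """0-based half-open intervals of N runs of at least ``min_n_run`` bp."""
    runs: dict[str, list[tuple[int, int]]] = {}
    pat = re.compile(f"N{{{min_n_run},}}")
    for chrom, seq in genome.items():
        runs[chrom] = [(m.start(), m.end()) for m in pat.finditer(seq)]
    return runs


def _near_any_gap(chrom: str, start: int, end: int,
                  runs: dict[str, list[tuple[int, int]]], max_distance: int) -> bool:
    for gs, ge in runs.get(chrom, ()):
        # spanning, or closer than max_distance on either side
        if start < ge + max_distance and end > gs - max_distance:
            return True
    return False


def filter_near_gaps(
    svs: Sequence[SVRecord],
    genome_a: dict[str, str],
    genome_b: dict[str, str],
    max_distance: int = 50,
    min_n_run: int = 10,
) -> list[SVRecord]:
    """Drop SVs spanning or within ``max_distance`` bp of an assembly gap
    (N run) in either genome."""
    runs_a = find_n_runs(genome_a, min_n_run)
    runs_b = find_n_runs(genome_b, min_n_run)
    kept = []
    for sv in svs:
        anchor_runs, mate_runs = (runs_a, runs_b) if sv.anchor_genome == "A" else (runs_b, runs_a)
        if _near_any_gap(sv.chrom, sv.start, max(sv.end, sv.start + 1),
                         anchor_runs, max_distance):
            continue
        if sv.mate_coords is not None:
            mc, ms, me = sv.mate_coords
            if _near_any_gap(mc, ms, max(me, ms + 1), mate_runs, max_distance):
                continue
        kept.append(sv)
    return kept


# ---------------------------------------------------------------------------
# flank validation
# ---------------------------------------------------------------------------

class BlastFlankAligner:
    """Aligns flank sequences against a genome with blastn.

    Builds the database once; ``search`` maps query sequences to hit lists
    of (chrom, start, end, identity_fraction, aligned_length, evalue),
    coordinates 0-based half-open on the subject genome.
    """

    def __init__(self, genome: dict[str, str], workdir: Optional[str | Path] = None):
        if shutil.which("makeblastdb") is None or shutil.which("blastn") is None:
            raise RuntimeError("blastn/makeblastdb not found on PATH")
        self._tmp = tempfile.TemporaryDirectory() if workdir is None else None
        self.workdir = Path(self._tmp.name if self._tmp else workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        from .synthetic import write_fasta

        db_fa = self.workdir / "subject.fa"
        write_fasta(genome, db_fa)
        subprocess.run(
            ["makeblastdb", "-in", str(db_fa), "-dbtype", "nucl",
             "-out", str(self.workdir / "subject")],
            check=True, capture_output=True,
        )
        self.db = str(self.workdir / "subject")

    def search(self, queries: dict[str, str]) -> dict[str, list[tuple]]:
        qfa = self.workdir / "queries.fa"
        with open(qfa, "w") as fh:
            for name, seq in queries.items():
                fh.write(f">{name}\n{seq}\n")
        res = subprocess.run(
            ["blastn", "-query", str(qfa), "-db", self.db, "-outfmt",
             "6 qseqid sseqid sstart send pident length evalue bitscore qstart qend",
             "-max_target_seqs", "20", "-evalue", "1e-5"],
            check=True, capture_output=True, text=True,
        )
        hits: dict[str, list[tuple]] = defaultdict(list)
        for line in res.stdout.splitlines():
            q, s, ss, se, pid, length, ev, bits, qs, qe = line.split("\t")
            ss, se = int(ss), int(se)
            strand = "+" if se >= ss else "-"
            lo, hi = (ss - 1, se) if strand == "+" else (se - 1, ss)
            hits[q].append((s, lo, hi, float(pid) / 100.0, int(length),
                            float(ev), float(bits), strand, int(qs), int(qe)))
        return dict(hits)


def _reliable(hit: tuple, min_len: int = 50, min_ident: float = 0.90,
              max_evalue: float = 1e-10) -> bool:
    return hit[4] > min_len and hit[3] > min_ident and hit[5] < max_evalue


def validate_by_flanks(
    svs: Sequence[SVRecord],
    genome_a: dict[str, str],
    genome_b: dict[str, str],
    flank: int = 5000,
    aligner: Optional[BlastFlankAligner] = None,
    max_insertion_deviation: float = 0.20,
    max_deletion_slop: int = 3,
) -> list[FlankCheckResult]:
    """Validate SVs by re-aligning their two flanks to the other genome.

    For each SV anchored on genome A the 5-kb sequences flanking the anchor
    interval are searched against genome B. The SV passes when both flanks
    have reliable hits (alignment length > 50 bp, identity > 90%, e-value
    < 1e-10) in the expected region (same chromosome and strand, inner ends
    facing, within 10x SV size + 20 kb), and the inter-hit gap matches the
    expected allele length on genome B: deviation < 20% for insertions and
    other sequence-gaining events, absolute gap-or-overlap < 3 bp for
    deletions.
    """
    svs = list(svs)
    if aligner is None:
        aligner = BlastFlankAligner(genome_b)
    queries: dict[str, str] = {}
    for sv in svs:
        seq = genome_a[sv.chrom]
        lf = seq[max(0, sv.start - flank):sv.start]
        rf = seq[sv.end:sv.end + flank]
        if lf:
            queries[f"{sv.sv_id}|L"] = lf
        if rf:
            queries[f"{sv.sv_id}|R"] = rf
    all_hits = aligner.search(queries)

    results = []
    for sv in svs:
        lhits = [h for h in all_hits.get(f"{sv.sv_id}|L", []) if _reliable(h)]
        rhits = [h for h in all_hits.get(f"{sv.sv_id}|R", []) if _reliable(h)]
        if not lhits or not rhits:
            results.append(FlankCheckResult(sv.sv_id, "fail_no_hit"))
            continue
        expected_gap = sv.len_b if sv.anchor_genome == "A" else sv.len_a
        window = 10 * sv.size + 20_000
        qlen_l = len(queries.get(f"{sv.sv_id}|L", ""))
        best: Optional[tuple] = None
        for lh in lhits:
            for rh in rhits:
                if lh[0] != rh[0] or lh[7] != rh[7]:
                    continue
                # project the hits' inner ends, extending through any
                # unaligned query tail so local-alignment trimming does not
                # bias the observed gap
                if lh[7] == "+":
                    inner_l = lh[2] + (qlen_l - lh[9])
                    inner_r = rh[1] - (rh[8] - 1)
                    observed = inner_r - inner_l
                else:
                    inner_l = lh[1] - (qlen_l - lh[9])
                    inner_r = rh[2] + (rh[8] - 1)
                    observed = inner_l - inner_r
                if abs(observed) > window:
                    continue
                score = lh[6] + rh[6]
                if best is None or score > best[0]:
                    best = (score, lh, rh, observed)
        if best is None:
            results.append(FlankCheckResult(
                sv.sv_id, "fail_wrong_region",
                left_hit=lhits[0][:6], right_hit=rhits[0][:6]))
            continue
        _, lh, rh, observed = best
        deviation = abs(observed - expected_gap) / max(expected_gap, 1)
        if sv.sv_type == "deletion" or expected_gap < max_deletion_slop:
            ok = abs(observed - expected_gap) < max_deletion_slop
        else:
            ok = deviation < max_insertion_deviation
        results.append(FlankCheckResult(
            sv.sv_id, "pass" if ok else "fail_size",
            left_hit=lh[:6], right_hit=rh[:6], observed_gap=observed,
            expected_gap=expected_gap, deviation=deviation,
        ))
    return results


def apply_flank_validation(svs: Sequence[SVRecord],
                           results: Sequence[FlankCheckResult]) -> list[SVRecord]:
    passed = {r.sv_id for r in results if r.passed}
    return [sv for sv in svs if sv.sv_id in passed]


# ---------------------------------------------------------------------------
# complex-SV refinement and merging
# ---------------------------------------------------------------------------

def refine_complex_svs(assembly_svs: Sequence[SVRecord],
                       read_svs: Sequence[SVRecord],
                       pad: int = 100) -> list[SVRecord]:
    """Replace complex assembly calls by precise read-based indels they contain.

    A complex call (repeat/tandem expansion/contraction, no defined
    breakpoints) containing one or more precise read calls within its anchor
    region (padded by ``pad`` bp, as copy-number breakpoints are ambiguous
    within the array) is converted into those simple indels (source
    ``merged``, ``precise=True``). Complex calls without read support pass
    through unchanged; simple assembly calls are untouched.
    """
    out: list[SVRecord] = []
    used_reads: set[str] = set()
    for sv in assembly_svs:
        if sv.sv_type not in COMPLEX_TYPES:
            out.append(sv)
            continue
        lo = sv.start - pad
        hi = max(sv.end, sv.start + sv.size) + pad
        inside = [r for r in read_svs
                  if r.precise and r.sv_type in ("insertion", "deletion")
                  and r.chrom == sv.chrom
                  and r.start >= lo and max(r.end, r.start) <= hi]
        # the read indels must explain the copy-number change; otherwise the
        # complex call is better kept as the (imprecise) primary evidence
        net_complex = sv.len_b - sv.len_a
        net_reads = sum(r.len_b - r.len_a for r in inside)
        consistent = abs(net_reads - net_complex) <= max(20, 0.5 * abs(net_complex))
        if not inside or not consistent:
            out.append(sv)
            continue
        for k, r in enumerate(inside, 1):
            used_reads.add(r.sv_id)
            out.append(SVRecord(
                sv_id=f"{sv.sv_id}.{k}", sv_type=r.sv_type, chrom=r.chrom,
                start=r.start, end=r.end, len_a=r.len_a, len_b=r.len_b,
                anchor_genome=r.anchor_genome, source="merged", precise=True,
                mate_coords=r.mate_coords, seq=r.seq,
            ))
    return out


def exclude_reads_in_complex_regions(read_svs: Sequence[SVRecord],
                                     refined: Sequence[SVRecord],
                                     pad: int = 100) -> list[SVRecord]:
    """Drop read calls lying inside retained complex-call regions.

    A read indel inside a copy-number region that refinement could not
    resolve is a fragmentary view of that event, not an independent SV;
    keeping it alongside the complex call would double-count the locus.
    """
    regions = [(s.chrom, s.start - pad, max(s.end, s.start + s.size) + pad)
               for s in refined if s.sv_type in COMPLEX_TYPES]
    out = []
    for r in read_svs:
        inside = any(r.chrom == c and r.start >= lo
                     and max(r.end, r.start) <= hi
                     for c, lo, hi in regions)
        if not inside:
            out.append(r)
    return out


def _reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    """Min of the two overlap fractions.

    Interval events are compared on [start, start + size) (a copy-number
    event is padded to the longer of its two alleles); a point insertion is
    padded by its allele length on both sides, since the aligner may place
    it at any offset within a surrounding array. Records describing the
    same sequence then gain overlap regardless of how much of it each
    caller anchored on genome A."""
    def iv(sv: SVRecord) -> tuple[int, int]:
        if sv.end - sv.start <= 1 and sv.other_len > 0:
            return sv.start - sv.other_len, sv.start + sv.other_len
        return sv.start, sv.start + max(sv.size, 1)

    a0, a1 = iv(a)
    b0, b1 = iv(b)
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def _merge_equiv(sv: SVRecord) -> str:
    """Equivalence class for same-type merging.

    Copy-number expansions are net sequence gains and merge with
    insertions; contractions with deletions. Substitutions join the class
    matching the sign of their net length change (two callers may describe
    one event as a substitution and an expansion), and only equal-length
    substitutions form their own class."""
    t = sv.sv_type
    if "expansion" in t:
        return "insertion"
    if "contraction" in t:
        return "deletion"
    if t == "substitution":
        if sv.len_b > sv.len_a:
            return "insertion"
        if sv.len_b < sv.len_a:
            return "deletion"
    return t


def merge_callsets(set1: Sequence[SVRecord], set2: Sequence[SVRecord],
                   min_reciprocal: float = 0.5) -> list[SVRecord]:
    """Merge two same-anchor call sets by >= ``min_reciprocal`` reciprocal
    overlap within equivalent types.

    Overlapping pairs collapse to one record; the first set's coordinates
    are preferred (assembly evidence first). The result is deterministic,
    order-invariant across inputs, and merging a set with itself returns
    the set.
    """
    pool = sorted(
        list(set1) + list(set2),
        key=lambda s: (s.chrom, s.start, s.end, s.sv_type, s.sv_id),
    )
    prefer = {id(s) for s in set1}
    kept: list[SVRecord] = []
    for sv in pool:
        hit = None
        for i, k in enumerate(kept):
            if k.chrom != sv.chrom:
                continue
            if _merge_equiv(k) != _merge_equiv(sv):
                continue
            if _reciprocal_overlap(k, sv) >= min_reciprocal:
                hit = i
                break
        if hit is None:
            kept.append(sv)
        else:
            k = kept[hit]
            same_record = (k.chrom, k.start, k.end, k.sv_type, k.len_a, k.len_b) == \
                          (sv.chrom, sv.start, sv.end, sv.sv_type, sv.len_a, sv.len_b)
            # prefer set1 (assembly) coordinates; keep source for exact duplicates
            winner = sv if (id(sv) in prefer and id(k) not in prefer) else k
            kept[hit] = _merged_copy(winner, keep_source=same_record)
    return kept


def _merged_copy(sv: SVRecord, keep_source: bool = False) -> SVRecord:
    return SVRecord(
        sv_id=sv.sv_id, sv_type=sv.sv_type, chrom=sv.chrom, start=sv.start,
        end=sv.end, len_a=sv.len_a, len_b=sv.len_b,
        anchor_genome=sv.anchor_genome,
        source=sv.source if keep_source else "merged",
        precise=sv.precise, mate_coords=sv.mate_coords, seq=sv.seq,
    )


# ---------------------------------------------------------------------------
# coordinate liftover through the genome alignment
# ---------------------------------------------------------------------------

class Liftover:
    """Target -> query coordinate projection through alignment base ops.

    Built from whole-genome alignment blocks (query = genome B, target =
    genome A); positions inside target-only stretches project to the query
    junction point.
    """

    def __init__(self, blocks: Sequence[AlignmentBlock]):
        from bisect import bisect_right

        self._bisect = bisect_right
        self._segments: dict[str, list[tuple[int, int, int, str]]] = defaultdict(list)
        for b in blocks:
            if not b.mapping_unique or b.strand != "+":
                continue
            t, q = b.target_start, b.query_start
            if not b.base_ops:
                self._segments[b.target_name].append(
                    (t, b.target_end, q, b.query_name))
                continue
            for op, n in b.base_ops:
                if op in ("match", "mismatch"):
                    self._segments[b.target_name].append((t, t + n, q, b.query_name))
                    t += n
                    q += n
                elif op == "del":
                    self._segments[b.target_name].append((t, t + n, q, b.query_name))
                    t += n
                elif op == "ins":
                    q += n
        for chrom in self._segments:
            self._segments[chrom].sort()
        self._starts = {c: [s[0] for s in v] for c, v in self._segments.items()}

    def project(self, chrom: str, pos: int) -> Optional[tuple[str, int]]:
        segs = self._segments.get(chrom)
        if not segs:
            return None
        i = self._bisect(self._starts[chrom], pos) - 1
        if i < 0:
            return None
        t0, t1, q0, qname = segs[i]
        if pos >= t1:
            # beyond the last covered base: clamp to the segment end
            return qname, q0 + (t1 - t0)
        return qname, q0 + min(pos - t0, t1 - t0)


def fill_mate_coords(svs: Sequence[SVRecord],
                     blocks: Sequence[AlignmentBlock]) -> list[SVRecord]:
    """Project anchor coordinates to the other genome where missing."""
    lift = Liftover(blocks)
    out = []
    for sv in svs:
        if sv.mate_coords is None:
            if sv.end - sv.start <= 1 and sv.other_len > 0:
                # point insertion: project the base before the junction so
                # the mate interval covers the inserted sequence
                proj = lift.project(sv.chrom, max(sv.start - 1, 0))
                if proj is not None:
                    qname, qpos = proj
                    sv.mate_coords = (qname, qpos + 1, qpos + 1 + sv.other_len)
            else:
                proj = lift.project(sv.chrom, sv.start)
                if proj is not None:
                    qname, qpos = proj
                    sv.mate_coords = (qname, qpos, qpos + sv.other_len)
        out.append(sv)
    return out


# ---------------------------------------------------------------------------
# read-based calling (long reads aligned to one genome)
# ---------------------------------------------------------------------------

def _as_net_indel(ev: SVRecord, genome: dict[str, str],
                  min_size: int) -> Optional[SVRecord]:
    """Reduce a per-read event to its net indel, or None if balanced."""
    if ev.sv_type in ("insertion", "deletion"):
        return ev
    if ev.sv_type == "substitution":
        return None
    net = ev.len_b - ev.len_a
    if abs(net) < min_size:
        return None
    if net > 0:
        return SVRecord(
            sv_id="", sv_type="insertion", chrom=ev.chrom, start=ev.start,
            end=ev.start, len_a=0, len_b=net, source="reads", precise=True,
        )
    start = ev.start
    if ev.chrom in genome:
        start, _ = left_normalize(genome[ev.chrom], ev.start,
                                  genome[ev.chrom][ev.start:ev.start - net])
    return SVRecord(
        sv_id="", sv_type="deletion", chrom=ev.chrom, start=start,
        end=start - net, len_a=-net, len_b=0, source="reads", precise=True,
    )


def call_svs_from_reads(blocks: Sequence[AlignmentBlock], genome: dict[str, str],
                        min_size: int = 10, max_size: int = 700_000,
                        min_support: int = 3, window: int = 20,
                        id_prefix: str = "rd") -> list[SVRecord]:
    """Cluster per-read indel events from long-read alignments into calls.

    Each read alignment contributes within-alignment events, reduced to net
    simple indels (balanced substitution-like clusters are alignment noise
    at this error rate and are dropped; copy-number clusters reduce to their
    net length change, left-normalized). Events of the same type agreeing in
    position (+/- ``window``) and size (+/- 20%) across >= ``min_support``
    reads become one precise call at the median breakpoint, anchored on the
    reference the reads were mapped to.
    """
    per_read: list[SVRecord] = []
    for b in blocks:
        if not b.mapping_unique:
            continue
        for ev in _within_alignment_events(b, genome, min_size, max_size):
            ev = _as_net_indel(ev, genome, min_size)
            if ev is not None:
                per_read.append(ev)
    by_type: dict[tuple[str, str], list[SVRecord]] = defaultdict(list)
    for ev in per_read:
        by_type[(ev.chrom, ev.sv_type)].append(ev)
    calls: list[SVRecord] = []
    for (chrom, sv_type), evs in sorted(by_type.items()):
        evs.sort(key=lambda e: (e.start, e.size))
        cluster: list[SVRecord] = []
        for ev in evs + [None]:  # type: ignore[list-item]
            if cluster and (
                ev is None
                or ev.start - cluster[-1].start > window
                or not (0.8 <= ev.size / max(cluster[0].size, 1) <= 1.25)
            ):
                if len(cluster) >= min_support:
                    starts = sorted(c.start for c in cluster)
                    mid = cluster[len(cluster) // 2]
                    start = starts[len(starts) // 2]
                    shift = start - mid.start
                    calls.append(SVRecord(
                        sv_id="", sv_type=sv_type, chrom=chrom, start=start,
                        end=mid.end + shift, len_a=mid.len_a, len_b=mid.len_b,
                        source="reads", precise=True, mate_coords=None,
                    ))
                cluster = []
            if ev is not None:
                cluster.append(ev)
    calls.sort(key=lambda s: (s.chrom, s.start, s.end))
    for i, c in enumerate(calls, 1):
        c.sv_id = f"{id_prefix}{i:05d}"
    return calls


# ---------------------------------------------------------------------------
# VCF round trip
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=svdiverge
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=SUB,Description="Substitution">
##ALT=<ID=CNV,Description="Repeat or tandem copy-number change">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed allele length difference (B minus A)">
##INFO=<ID=END,Number=1,Type=Integer,Description="End of the anchor interval (1-based inclusive)">
##INFO=<ID=END0,Number=1,Type=Integer,Description="End of the anchor interval (0-based exclusive)">
##INFO=<ID=LEN_A,Number=1,Type=Integer,Description="Allele length on genome A">
##INFO=<ID=LEN_B,Number=1,Type=Integer,Description="Allele length on genome B">
##INFO=<ID=ANCHOR,Number=1,Type=String,Description="Anchor genome (A or B)">
##INFO=<ID=SOURCE,Number=1,Type=String,Description="Call source (assembly/reads/merged/truth)">
##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Breakpoints are base-precise">
##INFO=<ID=MATE,Number=3,Type=String,Description="Locus on the other genome: chrom,start0,end0">
"""

_TYPE_TO_ALT = {"insertion": "INS", "deletion": "DEL", "substitution": "SUB",
                "repeat_expansion": "CNV", "repeat_contraction": "CNV",
                "tandem_expansion": "CNV", "tandem_contraction": "CNV"}


def write_sv_set(svs: Sequence[SVRecord], path: str | Path,
                 genome: Optional[dict[str, str]] = None,
                 contigs: Optional[dict[str, int]] = None) -> Path:
    """Write SVs as VCF 4.2 (1-based, anchored-base convention).

    Full allele sequences are emitted when available and short; long or
    sequence-less events use symbolic ALTs with END/SVLEN fields.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if contigs is None and genome is not None:
            contigs = {c: len(s) for c, s in genome.items()}
        for c, ln in (contigs or {}).items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for sv in sorted(svs, key=lambda s: (s.chrom, s.start, s.sv_id)):
            pos1 = sv.start  # 1-based anchor base = 0-based start-1 base; POS=start
            anchor_base = "N"
            if genome is not None and sv.start > 0:
                anchor_base = genome[sv.chrom][sv.start - 1]
            use_seq = (sv.seq is not None and sv.sv_type == "insertion"
                       and len(sv.seq) <= 1000 and genome is not None)
            if use_seq:
                ref = anchor_base
                alt = anchor_base + sv.seq
            elif (sv.sv_type == "deletion" and genome is not None
                  and sv.len_a <= 1000 and sv.start > 0):
                ref = anchor_base + genome[sv.chrom][sv.start:sv.end]
                alt = anchor_base
            else:
                ref = anchor_base
                alt = f"<{_TYPE_TO_ALT[sv.sv_type]}>"
            info = [
                f"SVTYPE={sv.sv_type}",
                f"SVLEN={sv.len_b - sv.len_a}",
                f"END={max(sv.end, sv.start)}",
                f"END0={sv.end}",
                f"LEN_A={sv.len_a}",
                f"LEN_B={sv.len_b}",
                f"ANCHOR={sv.anchor_genome}",
                f"SOURCE={sv.source}",
            ]
            if sv.precise:
                info.append("PRECISE")
            if sv.mate_coords is not None:
                mc, ms, me = sv.mate_coords
                info.append(f"MATE={mc},{ms},{me}")
            fh.write(f"{sv.chrom}\t{max(pos1, 1)}\t{sv.sv_id}\t{ref}\t{alt}"
                     f"\t.\tPASS\t{';'.join(info)}\n")
    return path


def read_sv_set(path: str | Path) -> list[SVRecord]:
    """Read a VCF written by :func:`write_sv_set` back into records."""
    import pysam

    svs: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf, 1):
            info = rec.info
            try:
                sv_type = info["SVTYPE"]
                len_a = int(info["LEN_A"])
                len_b = int(info["LEN_B"])
                # htslib derives rec.stop from SVLEN for symbolic alleles
                # (VCF 4.4 semantics), so the anchor end travels in END0
                end = int(info["END0"])
            except KeyError as exc:
                raise ValueError(f"malformed SV record at line ~{i} "
                                 f"({rec.chrom}:{rec.pos}): missing {exc}") from exc
            mate = None
            if "MATE" in info:
                m = info["MATE"]
                mate = (m[0], int(m[1]), int(m[2]))
            seq = None
            alt = rec.alts[0] if rec.alts else ""
            if sv_type == "insertion" and alt and not alt.startswith("<"):
                seq = alt[1:]
            svs.append(SVRecord(
                sv_id=rec.id or f"sv{i}", sv_type=sv_type, chrom=rec.chrom,
                start=rec.pos, end=end, len_a=len_a, len_b=len_b,
                anchor_genome=info.get("ANCHOR", "A"),
                source=info.get("SOURCE", "assembly"),
                precise="PRECISE" in info, mate_coords=mate, seq=seq,
            ))
    return svs


def write_bed(svs: Sequence[SVRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for sv in sorted(svs, key=lambda s: (s.chrom, s.start)):
            fh.write(f"{sv.chrom}\t{sv.start}\t{max(sv.end, sv.start + 1)}"
                     f"\t{sv.sv_id}\t{sv.size}\t{sv.sv_type}\n")
    return path
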