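"""SV-to-gene annotation and the LTR insertion-time estimator.

Relates SV intervals to gene models (CDS / intron-UTR / promoter
categories), computes the fractions of the genome, gene space and coding
space covered by SVs, and dates long-terminal-repeat retrotransposon
insertions from the divergence of their two LTRs.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .records import GeneModel, SVRecord


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models (gene spans + CDS intervals) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="merge")
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        cds = [(c.start - 1, c.end) for c in
               db.children(g, featuretype="CDS", order_by="start")]
        genes.append(GeneModel(
            gene_id=g.id, chrom=g.seqid, start=g.start - 1, end=g.end,
            strand=g.strand, cds_intervals=cds,
        ))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.chrom}\t.\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n")
            for k, (s, e) in enumerate(g.cds_intervals, 1):
                fh.write(f"{g.chrom}\t.\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                         f"ID={g.gene_id}.cds{k};Parent={g.gene_id}.t1\n")
    return path


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _sv_interval(sv: SVRecord) -> tuple[int, int]:
    return sv.start, max(sv.end, sv.start + 1)


def classify_sv_gene_overlap(
    svs: Sequence[SVRecord],
    genes: Sequence[GeneModel],
    promoter_length: int = 2000,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign each SV the genes it hits and the category of each hit.

    Categories (most severe reported per SV-gene pair): ``CDS`` when the SV
    interval intersects a coding exon, ``intron/UTR`` when inside the gene
    body but outside CDS, ``promoter`` when inside the strand-aware
    upstream window. Any overlap counts. Returns a per-hit table and a
    per-gene affected flag (hit in body or promoter).
    """
    sv_chroms = {sv.chrom for sv in svs}
    gene_chroms = {g.chrom for g in genes}
    if chrom_lengths is not None:
        unknown = (sv_chroms | gene_chroms) - set(chrom_lengths)
        if unknown:
            raise ValueError(f"unknown chromosomes: {sorted(unknown)}")

    body_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    prom_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    cds_by_gene: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        body_trees[g.chrom][g.start:g.end] = g
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        plo, phi = g.promoter(promoter_length, clen)
        if phi > plo:
            prom_trees[g.chrom][plo:phi] = g
        cds_by_gene[g.gene_id] = g.cds_intervals

    rows = []
    affected = {g.gene_id: False for g in genes}
    for sv in svs:
        lo, hi = _sv_interval(sv)
        hits: dict[str, str] = {}
        for iv in body_trees.get(sv.chrom, IntervalTree()).overlap(lo, hi):
            g = iv.data
            in_cds = any(lo < ce and hi > cs for cs, ce in cds_by_gene[g.gene_id])
            hits[g.gene_id] = "CDS" if in_cds else "intron/UTR"
        for iv in prom_trees.get(sv.chrom, IntervalTree()).overlap(lo, hi):
            g = iv.data
            hits.setdefault(g.gene_id, "promoter")
        for gene_id, category in sorted(hits.items()):
            affected[gene_id] = True
            rows.append((sv.sv_id, gene_id, category))
    table = pd.DataFrame(rows, columns=["sv_id", "gene_id", "category"])
    return table, pd.Series(affected, name="affected")


# ---------------------------------------------------------------------------
# genome fractions
# ---------------------------------------------------------------------------

def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def _union_overlap(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    """Length of intersection of two interval unions (merged sweeps)."""
    def merge(iv):
        out = []
        for s, e in sorted(iv):
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    a, b = merge(a), merge(b)
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def sv_genome_fractions(svs: Sequence[SVRecord], chrom_lengths: dict[str, int],
                        genes: Sequence[GeneModel]) -> dict[str, float]:
    """Fractions of the genome, gene regions and CDS covered by SV intervals.

    Coverage is computed on the union of SV intervals, so duplicated or
    overlapping calls are not double-counted.
    """
    sv_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for sv in svs:
        sv_by_chrom[sv.chrom].append(_sv_interval(sv))
    gene_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    cds_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for g in genes:
        gene_by_chrom[g.chrom].append((g.start, g.end))
        cds_by_chrom[g.chrom].extend(g.cds_intervals)

    genome_total = sum(chrom_lengths.values())
    sv_total = sum(_union_length(v) for v in sv_by_chrom.values())
    gene_total = sum(_union_length(v) for v in gene_by_chrom.values())
    cds_total = sum(_union_length(v) for v in cds_by_chrom.values())
    sv_in_gene = sum(_union_overlap(sv_by_chrom[c], gene_by_chrom[c])
                     for c in gene_by_chrom if c in sv_by_chrom)
    sv_in_cds = sum(_union_overlap(sv_by_chrom[c], cds_by_chrom[c])
                    for c in cds_by_chrom if c in sv_by_chrom)
    return {
        "genome_fraction": sv_total / genome_total if genome_total else 0.0,
        "gene_fraction": sv_in_gene / gene_total if gene_total else 0.0,
        "cds_fraction": sv_in_cds / cds_total if cds_total else 0.0,
    }


# ---------------------------------------------------------------------------
# LTR insertion time
# ---------------------------------------------------------------------------

@dataclass
class LTRPair:
    """One intact LTR retrotransposon with the divergence of its two LTRs."""

    element_id: str
    substitution_rate: float  # S: substitutions per site between the LTRs
    mutation_rate: float = 1.5e-8  # mu: per site per year

    @property
    def insertion_time(self) -> float:
        return ltr_insertion_time(self.substitution_rate, self.mutation_rate)


def ltr_insertion_time(S: float, mu: float = 1.5e-8) -> float:
    """Insertion age in years from the divergence of an element's two LTRs.

    The two long terminal repeats are identical at insertion and diverge
    independently, so T = S / (2 * mu) with S the substitution rate between
    them and mu the per-site annual mutation rate.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if S < 0:
        raise ValueError("S must be non-negative")
    return S / (2.0 * mu)
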