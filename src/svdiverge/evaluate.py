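"""Scoring of calls and genotypes against a synthetic truth set."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .records import SVRecord
from .synthetic import TruthSet


@dataclass
class DiscoveryScore:
    n_truth: int
    n_calls: int
    n_matched_truth: int
    n_matched_calls: int
    breakpoint_errors: list[int]

    @property
    def recall(self) -> float:
        return self.n_matched_truth / self.n_truth if self.n_truth else 1.0

    @property
    def precision(self) -> float:
        return self.n_matched_calls / self.n_calls if self.n_calls else 1.0

    @property
    def max_breakpoint_error(self) -> int:
        return max(self.breakpoint_errors) if self.breakpoint_errors else 0

    @property
    def mean_breakpoint_error(self) -> float:
        if not self.breakpoint_errors:
            return 0.0
        return sum(self.breakpoint_errors) / len(self.breakpoint_errors)


def _net(sv: SVRecord) -> int:
    return sv.len_b - sv.len_a


def _match(truth: SVRecord, call: SVRecord, bp_tol: int, size_tol: float) -> bool:
    """A call matches a planted event when it falls at the planted locus
    and reproduces the net allele-length change.

    Events with defined breakpoints must agree within ``bp_tol`` bp; the
    repeat/tandem classes have no defined breakpoints (a copy-number change
    is placeable anywhere within the array), so the call must lie within
    the planted array (padded by ``bp_tol``).
    """
    if call.chrom != truth.chrom:
        return False
    nt, nc = _net(truth), _net(call)
    size_ok = abs(nc - nt) <= max(3, size_tol * max(abs(nt), 1))
    if truth.sv_type == "substitution":
        # substitutions may be reported with slightly trimmed edges; compare
        # both allele lengths instead of the (near-zero) net change
        size_ok = (abs(call.len_a - truth.len_a) <= max(3, size_tol * truth.len_a)
                   and abs(call.len_b - truth.len_b) <= max(3, size_tol * truth.len_b))
    if not size_ok:
        return False
    if truth.precise:
        return (abs(call.start - truth.start) <= bp_tol
                and abs(max(call.end, call.start) - max(truth.end, truth.start)) <= bp_tol)
    lo, hi = truth.start - bp_tol, max(truth.end, truth.start) + bp_tol
    return call.start >= lo and max(call.end, call.start) <= hi


def score_discovery(truth_svs: Sequence[SVRecord], calls: Sequence[SVRecord],
                    bp_tol: int = 10, size_tol: float = 0.2) -> DiscoveryScore:
    """Match calls to planted events.

    Precise planted events (defined breakpoints) are matched one-to-one.
    A copy-number event has no defined breakpoints and may be reported as
    one or more simple indels inside its array, so all calls within its
    region jointly match it when their net length changes sum to the
    planted change.
    """
    used: set[str] = set()
    errors: list[int] = []
    matched_truth = 0
    for t in truth_svs:
        if not t.precise:
            continue
        best = None
        for c in calls:
            if c.sv_id in used or not _match(t, c, bp_tol, size_tol):
                continue
            err = abs(c.start - t.start)
            if best is None or err < best[0]:
                best = (err, c)
        if best is not None:
            used.add(best[1].sv_id)
            matched_truth += 1
            errors.append(best[0])
    for t in truth_svs:
        if t.precise:
            continue
        lo, hi = t.start - bp_tol, max(t.end, t.start) + bp_tol
        group = [c for c in calls if c.sv_id not in used and c.chrom == t.chrom
                 and c.start >= lo and max(c.end, c.start) <= hi]
        nt = _net(t)
        tol = max(3, size_tol * max(abs(nt), 1))
        if group and abs(sum(_net(c) for c in group) - nt) <= tol:
            used.update(c.sv_id for c in group)
            matched_truth += 1
            continue
        best = None
        for c in group:
            if abs(_net(c) - nt) <= tol:
                err = abs(c.start - t.start)
                if best is None or err < best[0]:
                    best = (err, c)
        if best is not None:
            used.add(best[1].sv_id)
            matched_truth += 1
    return DiscoveryScore(
        n_truth=len(truth_svs), n_calls=len(calls),
        n_matched_truth=matched_truth, n_matched_calls=len(used),
        breakpoint_errors=errors,
    )


@dataclass
class GenotypeScore:
    n_calls: int
    n_determined: int
    n_correct: int
    n_wrong: int

    @property
    def determined_rate(self) -> float:
        return self.n_determined / self.n_calls if self.n_calls else 0.0

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_determined if self.n_determined else 1.0

    @property
    def false_rate(self) -> float:
        """Determined-but-wrong calls as a fraction of all calls."""
        return self.n_wrong / self.n_calls if self.n_calls else 0.0


def map_calls_to_truth(truth_svs: Sequence[SVRecord],
                       calls: Sequence[SVRecord],
                       bp_tol: int = 10, size_tol: float = 0.2
                       ) -> dict[str, str]:
    """One-to-one mapping call id -> planted id by locus and size."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for t in truth_svs:
        best = None
        for c in calls:
            if c.sv_id in used or not _match(t, c, bp_tol, size_tol):
                continue
            err = abs(c.start - t.start)
            if best is None or err < best[0]:
                best = (err, c)
        if best is not None:
            used.add(best[1].sv_id)
            mapping[best[1].sv_id] = t.sv_id
    return mapping


def score_genotypes(truth: TruthSet, matrix: pd.DataFrame,
                    calls: Sequence[SVRecord] | None = None) -> GenotypeScore:
    """Compare a called genotype matrix against the planted one.

    When the matrix columns are call ids rather than planted ids, pass the
    call records so columns can be mapped to planted loci first.
    """
    tm = truth.genotype_matrix
    if calls is not None:
        mapping = map_calls_to_truth(truth.planted_svs, calls)
        matrix = matrix.rename(columns=mapping)
        matrix = matrix.loc[:, matrix.columns.isin(mapping.values())]
    common_acc = matrix.index.intersection(tm.index)
    common_sv = matrix.columns.intersection(tm.columns)
    n = det = correct = wrong = 0
    for acc in common_acc:
        for sv in common_sv:
            n += 1
            called = matrix.loc[acc, sv]
            if called == "U":
                continue
            det += 1
            if called == tm.loc[acc, sv]:
                correct += 1
            else:
                wrong += 1
    return GenotypeScore(n_calls=n, n_determined=det, n_correct=correct, n_wrong=wrong)
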