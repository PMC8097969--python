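"""Population-level analyses over the SV genotype matrix.

Implements 25-kb window thinning, per-group genotype composition,
allele-frequency estimation (heterozygotes count one copy of each allele),
two-sided Fisher's exact test with Bonferroni correction, the
differentiation scan (q < 0.001 and fold change >= 2), and allele-sharing
distance / PCA / neighbour-joining exports for population structure.
"""
from __future__ import annotations

import logging
from functools import lru_cache
from math import comb
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import DifferentiationRecord, SVRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# window thinning
# ---------------------------------------------------------------------------

def thin_by_windows(svs: Sequence[SVRecord], window: int = 25_000,
                    seed: int = 0) -> list[SVRecord]:
    """Randomly keep one SV per non-overlapping genomic window.

    Deterministic under a fixed seed; every window containing at least one
    SV contributes exactly one survivor.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rng = np.random.default_rng(seed)
    buckets: dict[tuple[str, int], list[SVRecord]] = {}
    for sv in svs:
        buckets.setdefault((sv.chrom, sv.start // window), []).append(sv)
    out = []
    for key in sorted(buckets):
        group = sorted(buckets[key], key=lambda s: (s.start, s.sv_id))
        out.append(group[int(rng.integers(len(group)))])
    out.sort(key=lambda s: (s.chrom, s.start))
    return out


# ---------------------------------------------------------------------------
# genotype composition and allele frequencies
# ---------------------------------------------------------------------------

def genotype_composition(matrix: pd.DataFrame, labels: pd.Series
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fractions of A/B/H among genotyped calls per accession and group means.

    The undetermined fraction (over all SVs) is reported alongside. An
    accession with no determined calls has NaN fractions and is flagged by
    that NaN.
    """
    missing = set(matrix.index) - set(labels.index)
    if missing:
        raise ValueError(f"unlabeled accessions: {sorted(missing)}")
    counts = pd.DataFrame({
        g: (matrix == g).sum(axis=1) for g in ("A", "B", "H", "U")
    })
    det = counts[["A", "B", "H"]].sum(axis=1)
    per_acc = counts[["A", "B", "H"]].div(det, axis=0)
    per_acc["U"] = counts["U"] / matrix.shape[1]
    per_acc["group"] = labels.reindex(per_acc.index)
    group_means = per_acc.groupby("group")[["A", "B", "H", "U"]].mean()
    return per_acc, group_means


def _allele_counts(col: pd.Series) -> tuple[int, int, int, int]:
    vc = col.value_counts()
    return (int(vc.get("A", 0)), int(vc.get("B", 0)),
            int(vc.get("H", 0)), int(vc.get("U", 0)))


def allele_frequencies(matrix: pd.DataFrame, labels: pd.Series,
                       group1: str, group2: str,
                       min_determined: float = 0.5) -> pd.DataFrame:
    """Per-SV A-allele frequency in two groups (diploid counting).

    SVs whose genotype is determined in fewer than ``min_determined`` of
    the accessions of either group are excluded. Frequency of the A allele
    is (2*nA + nH) / (2*(nA + nB + nH)).
    """
    for g in (group1, group2):
        if (labels == g).sum() == 0:
            raise ValueError(f"group {g!r} has no accessions")
    acc1 = labels.index[labels == group1].intersection(matrix.index)
    acc2 = labels.index[labels == group2].intersection(matrix.index)
    rows = []
    for sv_id in matrix.columns:
        c1 = _allele_counts(matrix.loc[acc1, sv_id])
        c2 = _allele_counts(matrix.loc[acc2, sv_id])
        det1 = sum(c1[:3]) / len(acc1)
        det2 = sum(c2[:3]) / len(acc2)
        if det1 < min_determined or det2 < min_determined:
            continue
        f1 = (2 * c1[0] + c1[2]) / (2 * sum(c1[:3]))
        f2 = (2 * c2[0] + c2[2]) / (2 * sum(c2[:3]))
        rows.append((sv_id, *c1, *c2, f1, f2))
    return pd.DataFrame(rows, columns=[
        "sv_id", "n1_A", "n1_B", "n1_H", "n1_U",
        "n2_A", "n2_B", "n2_H", "n2_U", "freq1_A", "freq2_A",
    ]).set_index("sv_id")


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided, probability ordering)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        log.debug("degenerate 2x2 margin; p = 1 by convention")
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # integer hypergeometric weights: exact comparison, no float ties
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return num / comb(n, c1)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins that are no more probable than the observed table, using exact
    integer weights so ties are handled without floating-point slack.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(x != int(x) for x in (a, b, c, d)):
        raise ValueError("table entries must be non-negative integers")
    return _fisher_cached(int(a), int(b), int(c), int(d))


def bonferroni(p: np.ndarray | Sequence[float], n_tests: Optional[int] = None
               ) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if n_tests is None:
        n_tests = p.size
    return np.minimum(1.0, p * n_tests)


# ---------------------------------------------------------------------------
# differentiation scan
# ---------------------------------------------------------------------------

def differentiation_scan(matrix: pd.DataFrame, labels: pd.Series,
                         group1: str, group2: str,
                         alpha: float = 0.001, min_fold: float = 2.0,
                         min_determined: float = 0.5
                         ) -> list[DifferentiationRecord]:
    """Exact-test scan for SVs with differentiated allele frequencies.

    For each SV passing the determination filter, a 2x2 table of A/B allele
    counts (heterozygotes contributing one copy each) in the two groups is
    tested with Fisher's exact test; raw p-values are Bonferroni-corrected
    over the number of SVs tested. An SV is selected when q < ``alpha`` and
    the frequency fold change is >= ``min_fold``. Zero frequencies are
    floored at 1/(2 * group size) when computing the fold change.
    """
    freqs = allele_frequencies(matrix, labels, group1, group2, min_determined)
    n_tests = len(freqs)
    n1 = int((labels == group1).sum())
    n2 = int((labels == group2).sum())
    records = []
    raw_p = []
    for sv_id, r in freqs.iterrows():
        a1 = 2 * r.n1_A + r.n1_H
        b1 = 2 * r.n1_B + r.n1_H
        a2 = 2 * r.n2_A + r.n2_H
        b2 = 2 * r.n2_B + r.n2_H
        raw_p.append(fisher_exact([[int(a1), int(b1)], [int(a2), int(b2)]]))
    q = bonferroni(raw_p, n_tests)
    for (sv_id, r), p, qv in zip(freqs.iterrows(), raw_p, q):
        eps = 1.0 / (2 * max(min(n1, n2), 1))
        f1, f2 = float(r.freq1_A), float(r.freq2_A)
        fold = max(f1, f2) / max(min(f1, f2), eps)
        selected = bool(qv < alpha and fold >= min_fold)
        records.append(DifferentiationRecord(
            sv_id=sv_id,
            n1_A=int(r.n1_A), n1_B=int(r.n1_B), n1_H=int(r.n1_H), n1_U=int(r.n1_U),
            n2_A=int(r.n2_A), n2_B=int(r.n2_B), n2_H=int(r.n2_H), n2_U=int(r.n2_U),
            freq1_A=f1, freq2_A=f2, fisher_p=float(p), q=float(qv),
            fold_change=float(fold), selected=selected,
            direction=group1 if f1 >= f2 else group2,
        ))
    return records


def differentiation_table(records: Sequence[DifferentiationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records]).set_index("sv_id")


# ---------------------------------------------------------------------------
# distance, PCA, neighbour joining
# ---------------------------------------------------------------------------

_NUMERIC = {"A": 0.0, "H": 1.0, "B": 2.0, "U": np.nan}


def encode_numeric(matrix: pd.DataFrame) -> pd.DataFrame:
    """Genotypes as allele dosages of the B allele (A=0, H=1, B=2, U=NaN)."""
    return matrix.apply(lambda col: col.map(_NUMERIC))


def distance_and_pca(matrix: pd.DataFrame, n_components: int = 10
                     ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, str]:
    """Allele-sharing distance, principal components, and an NJ tree.

    Distance between two accessions is the mean absolute dosage difference
    over pairwise-complete SVs, scaled to [0, 1]. PCA is run on the
    mean-imputed, centred dosage matrix; components are orthonormal.
    Returns (distance matrix, PC coordinates, explained variances, newick).
    """
    num = encode_numeric(matrix)
    keep = num.notna().sum(axis=1) > 0
    dropped = num.index[~keep]
    if len(dropped):
        log.warning("excluding accessions with no determined calls: %s",
                    list(dropped))
    num = num.loc[keep]
    # columns with no determined call carry no information and break
    # mean imputation
    num = num.loc[:, num.notna().any(axis=0)]
    X = num.to_numpy(dtype=float)
    n = X.shape[0]

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(X[i]) & ~np.isnan(X[j])
            if both.sum() == 0:
                d = np.nan
            else:
                d = float(np.abs(X[i, both] - X[j, both]).mean()) / 2.0
            dist[i, j] = dist[j, i] = d
    dist_df = pd.DataFrame(dist, index=num.index, columns=num.index)

    col_means = np.nanmean(X, axis=0)
    Xi = np.where(np.isnan(X), col_means, X)
    Xc = Xi - Xi.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    # deterministic sign: largest-magnitude loading positive
    for j in range(k):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    coords = pd.DataFrame(
        u[:, :k] * s[:k], index=num.index,
        columns=[f"PC{i + 1}" for i in range(k)])
    explained = (s ** 2) / max(n - 1, 1)

    newick = _nj_newick(dist_df)
    return dist_df, coords, explained[:k], newick


def _nj_newick(dist_df: pd.DataFrame) -> str:
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if dist_df.isna().any().any():
        log.warning("NJ tree skipped: distance matrix has missing entries")
        return ""
    if len(dist_df) < 3:
        return ""
    dm = DistanceMatrix(dist_df.to_numpy(), ids=list(dist_df.index))
    tree = nj(dm)
    return str(tree.write_nwk() if hasattr(tree, "write_nwk") else tree).strip()


def export_popgen(out_dir: str | Path, dist_df: pd.DataFrame,
                  coords: pd.DataFrame, explained: np.ndarray, newick: str,
                  diff_records: Optional[Sequence[DifferentiationRecord]] = None
                  ) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["distance"] = out_dir / "distance_matrix.tsv"
    dist_df.to_csv(paths["distance"], sep="\t", index_label="accession")
    paths["pca"] = out_dir / "pc_coordinates.tsv"
    pc = coords.copy()
    pc.to_csv(paths["pca"], sep="\t", index_label="accession")
    paths["explained"] = out_dir / "pc_variances.tsv"
    pd.Series(explained, index=[f"PC{i+1}" for i in range(len(explained))],
              name="variance").to_csv(paths["explained"], sep="\t",
                                      index_label="component")
    paths["tree"] = out_dir / "accessions_nj.nwk"
    paths["tree"].write_text(newick + ("\n" if newick else ""))
    if diff_records is not None:
        paths["differentiation"] = out_dir / "differentiation.tsv"
        differentiation_table(diff_records).to_csv(paths["differentiation"], sep="\t")
    return paths
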