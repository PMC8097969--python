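"""Thinning, composition, frequencies, exact test, scan, distance/PCA."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scipy.stats as st_scipy

from svdiverge.records import SVRecord
from svdiverge.benchmarks import fisher_oracle_enumeration, scan_benchmark
from svdiverge.popgen import (allele_frequencies, bonferroni,
                              differentiation_scan, distance_and_pca,
                              fisher_exact, genotype_composition,
                              thin_by_windows)


def _sv(sv_id, start, chrom="chr1"):
    return SVRecord(sv_id=sv_id, sv_type="deletion", chrom=chrom,
                    start=start, end=start + 50, len_a=50, len_b=0)


class TestThinning:
    def test_one_survivor_per_window(self):
        svs = [_sv("a", 1000), _sv("b", 5000), _sv("c", 20_000)]
        out = thin_by_windows(svs, window=25_000, seed=1)
        assert len(out) == 1

    def test_different_windows_both_kept(self):
        svs = [_sv("a", 10_000), _sv("b", 30_000)]
        assert len(thin_by_windows(svs, window=25_000, seed=1)) == 2

    def test_empty_input(self):
        assert thin_by_windows([], seed=0) == []

    def test_deterministic_and_subset(self):
        rng = np.random.default_rng(0)
        svs = [_sv(f"s{i}", int(rng.integers(0, 500_000))) for i in range(100)]
        out1 = thin_by_windows(svs, seed=42)
        out2 = thin_by_windows(svs, seed=42)
        assert [s.sv_id for s in out1] == [s.sv_id for s in out2]
        assert set(s.sv_id for s in out1) <= set(s.sv_id for s in svs)
        windows = {(s.chrom, s.start // 25_000) for s in svs}
        assert len(out1) == len(windows)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            thin_by_windows([], window=0, seed=0)


class TestComposition:
    def test_fractions_over_genotyped_calls(self):
        mat = pd.DataFrame([["A"] * 8 + ["B"] + ["H"] + ["U"] * 10],
                           index=["acc1"], columns=[f"s{i}" for i in range(20)])
        labels = pd.Series({"acc1": "g"})
        per_acc, _ = genotype_composition(mat, labels)
        assert per_acc.loc["acc1", "A"] == pytest.approx(0.8)
        assert per_acc.loc["acc1", "U"] == pytest.approx(0.5)

    def test_all_undetermined_flagged_nan(self):
        mat = pd.DataFrame([["U", "U"]], index=["acc1"], columns=["a", "b"])
        per_acc, _ = genotype_composition(mat, pd.Series({"acc1": "g"}))
        assert np.isnan(per_acc.loc["acc1", "A"])

    def test_unlabeled_accession_is_error(self):
        mat = pd.DataFrame([["A"]], index=["acc1"], columns=["s"])
        with pytest.raises(ValueError, match="unlabeled"):
            genotype_composition(mat, pd.Series(dtype=object))

    def test_group_mean_reflects_construction(self, toy_matrix):
        mat, labels = toy_matrix
        _, means = genotype_composition(mat, labels)
        assert means.loc["g1", "A"] > means.loc["g2", "A"]


class TestAlleleFrequencies:
    def _matrix(self, col, n=10):
        acc = [f"a{i}" for i in range(n)]
        return (pd.DataFrame({"sv": col}, index=acc),
                pd.Series(["g1"] * (n // 2) + ["g2"] * (n - n // 2), index=acc))

    def test_diploid_counting(self):
        mat, labels = self._matrix(["A"] * 4 + ["B"] + ["A"] * 4 + ["B"])
        freqs = allele_frequencies(mat, labels, "g1", "g2")
        assert freqs.loc["sv", "freq1_A"] == pytest.approx(0.8)

    def test_het_counts_one_copy_each(self):
        mat, labels = self._matrix(["A", "A", "B", "B", "H"] * 2)
        freqs = allele_frequencies(mat, labels, "g1", "g2")
        assert freqs.loc["sv", "freq1_A"] == pytest.approx(0.5)

    def test_min_determined_exclusion(self):
        col = ["U"] * 3 + ["A"] * 2 + ["A"] * 5  # 40% determined in g1
        mat, labels = self._matrix(col)
        freqs = allele_frequencies(mat, labels, "g1", "g2")
        assert len(freqs) == 0

    def test_empty_group_is_error(self):
        mat, labels = self._matrix(["A"] * 10)
        with pytest.raises(ValueError, match="no accessions"):
            allele_frequencies(mat, labels, "g1", "nonexistent")


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_two_table_enumeration_case(self):
        # [[1,0],[0,1]]: both off-diagonal tables equally probable
        assert fisher_exact([[1, 0], [0, 1]]) == 1.0

    def test_strong_association_matches_oracle(self):
        p = fisher_exact([[95, 5], [10, 90]])
        oracle = fisher_oracle_enumeration(95, 5, 10, 90)
        assert p == pytest.approx(oracle, abs=1e-15)

    def test_degenerate_margin_convention(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])

    @given(st.integers(0, 25), st.integers(0, 25),
           st.integers(0, 25), st.integers(0, 25))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_enumeration_oracle(self, a, b, c, d):
        assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
            fisher_oracle_enumeration(a, b, c, d), abs=1e-12)

    @given(st.integers(0, 15), st.integers(0, 15),
           st.integers(0, 15), st.integers(1, 15))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_scipy(self, a, b, c, d):
        ours = fisher_exact([[a, b], [c, d]])
        theirs = st_scipy.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestBonferroni:
    def test_cap_and_monotonicity(self):
        p = np.array([1e-6, 0.01, 0.5])
        q = bonferroni(p)
        assert np.all(q <= 1)
        assert np.all(np.diff(q) >= 0)
        assert q[0] == pytest.approx(3e-6)

    def test_selection_count_nonincreasing_in_alpha(self, toy_matrix):
        mat, labels = toy_matrix
        counts = []
        for alpha in (0.05, 0.01, 0.001):
            recs = differentiation_scan(mat, labels, "g1", "g2", alpha=alpha)
            counts.append(sum(r.selected for r in recs))
        assert counts == sorted(counts, reverse=True)


class TestScan:
    def test_fold_change_threshold_blocks_weak_contrast(self):
        acc = [f"a{i}" for i in range(40)]
        labels = pd.Series(["g1"] * 20 + ["g2"] * 20, index=acc)
        rng = np.random.default_rng(0)
        # ~0.6 vs ~0.4: fold 1.5, never selected regardless of p
        col = (["A"] * 12 + ["B"] * 8) + (["A"] * 8 + ["B"] * 12)
        mat = pd.DataFrame({"weak": col}, index=acc)
        recs = differentiation_scan(mat, labels, "g1", "g2", alpha=1.0)
        assert recs[0].fold_change == pytest.approx(1.5)
        assert not recs[0].selected

    def test_identical_groups_select_nothing(self):
        acc = [f"a{i}" for i in range(20)]
        labels = pd.Series(["g1"] * 10 + ["g2"] * 10, index=acc)
        mat = pd.DataFrame({"s": ["A", "B"] * 10}, index=acc)
        recs = differentiation_scan(mat, labels, "g1", "g2")
        assert not any(r.selected for r in recs)

    def test_strong_contrast_selected_with_direction(self):
        acc = [f"a{i}" for i in range(100)]
        labels = pd.Series(["g1"] * 50 + ["g2"] * 50, index=acc)
        col = ["A"] * 45 + ["B"] * 5 + ["B"] * 45 + ["A"] * 5
        mat = pd.DataFrame({"hit": col}, index=acc)
        (rec,) = differentiation_scan(mat, labels, "g1", "g2")
        assert rec.selected and rec.direction == "g1"
        assert rec.q == pytest.approx(min(1.0, rec.fisher_p * 1))

    def test_power_and_size_on_synthetic_cohort(self):
        bench = scan_benchmark(seed=123)
        assert bench.power >= 0.9
        assert bench.false_positives <= 1


class TestDistancePca:
    def test_identical_accessions_distance_zero(self):
        mat = pd.DataFrame([["A", "B", "H"]] * 2 + [["B", "A", "B"]],
                           index=["x", "y", "z"], columns=["a", "b", "c"])
        dist, coords, _, _ = distance_and_pca(mat)
        assert dist.loc["x", "y"] == 0.0
        assert np.allclose(coords.loc["x"], coords.loc["y"])
        assert dist.loc["x", "z"] > 0

    def test_symmetric_zero_diagonal(self, toy_matrix):
        mat, _ = toy_matrix
        dist, _, _, _ = distance_and_pca(mat)
        assert np.allclose(dist, dist.T)
        assert np.allclose(np.diag(dist), 0)

    def test_groups_separate_on_pc1(self, toy_matrix):
        mat, labels = toy_matrix
        _, coords, _, _ = distance_and_pca(mat)
        g1 = coords.loc[labels == "g1", "PC1"]
        g2 = coords.loc[labels == "g2", "PC1"]
        # silhouette-like check: groups on opposite sides
        assert (g1.mean() - g2.mean()) * (g1.mean() - g2.mean()) > 0
        assert max(g1.max(), g2.max()) != min(g1.min(), g2.min())
        assert (g1.mean() < g2.min()) or (g1.mean() > g2.max())

    def test_permutation_leaves_eigenvalues_unchanged(self, toy_matrix):
        mat, _ = toy_matrix
        _, _, ev1, _ = distance_and_pca(mat)
        perm = mat.sample(frac=1.0, random_state=0)
        _, _, ev2, _ = distance_and_pca(perm)
        assert np.allclose(sorted(ev1), sorted(ev2))

    def test_components_orthonormal(self, toy_matrix):
        mat, _ = toy_matrix
        _, coords, ev, _ = distance_and_pca(mat)
        X = coords.to_numpy()
        # scores are orthogonal; normalizing by singular values gives ONB
        gram = X.T @ X
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0, atol=1e-8)

    def test_newick_tree_contains_all_accessions(self, toy_matrix):
        mat, _ = toy_matrix
        _, _, _, nwk = distance_and_pca(mat)
        assert nwk.endswith(";")
        for acc in mat.index:
            assert acc in nwk
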