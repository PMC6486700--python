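"""Normalization, rollups, krona/chord exports, clustering and t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from metaprofiler.metaproteins import Metaprotein
from metaprofiler.profiles import (
    AbundanceMatrix,
    chord_matrix,
    cluster_samples,
    compare_groups,
    joint_family_process_counts,
    krona_rows,
    normalize,
    rollup,
)


def mp(group_id, counts, lca=None, processes=()):
    m = Metaprotein(group_id=group_id, member_accessions={group_id})
    m.spectral_counts = dict(counts)
    m.lca_tax_id = lca
    m.biological_processes = set(processes)
    return m


def matrix(values, rows, cols, mode="raw-counts"):
    return AbundanceMatrix(
        data=pd.DataFrame(values, index=rows, columns=cols, dtype=float),
        mode=mode,
    )


class TestNormalize:
    def test_column_fractions(self):
        out = normalize(matrix([[2], [2]], ["a", "b"], ["s1"]))
        assert out.data["s1"].tolist() == [0.5, 0.5]
        assert out.mode == "fractions"

    def test_zero_column_stays_zero_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = normalize(matrix([[0], [0]], ["a", "b"], ["s1"]))
        assert out.data["s1"].tolist() == [0.0, 0.0]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            normalize(matrix([[-1]], ["a"], ["s1"]))

    def test_random_matrix_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.integers(1, 20, size=(5, 3)), list("abcde"),
                   ["s1", "s2", "s3"])
        out = normalize(m)
        assert np.allclose(out.data.sum(axis=0), 1.0, atol=1e-9)


class TestRollup:
    def test_family_rollup_with_unassigned_bucket(self, small_tree):
        mps = [
            mp("g1", {"s1": 3}, lca=13),  # Bacillaceae
            mp("g2", {"s1": 2}, lca=16),  # Paenibacillaceae
            mp("g3", {"s1": 5}, lca=10),  # order level -> unassigned
        ]
        out = rollup(mps, small_tree, "family")
        assert out.data.loc["Bacillaceae", "s1"] == 3
        assert out.data.loc["Paenibacillaceae", "s1"] == 2
        assert out.data.loc["unassigned", "s1"] == 5

    def test_family_rollup_conserves_spectra(self, small_tree):
        rng = np.random.default_rng(1)
        mps = [
            mp(f"g{i}", {"s1": int(rng.integers(0, 9)),
                         "s2": int(rng.integers(0, 9))},
               lca=int(rng.choice([13, 16, 10, 1, 33])))
            for i in range(20)
        ]
        out = rollup(mps, small_tree, "family")
        for sample in ("s1", "s2"):
            assert out.data[sample].sum() == sum(
                m.spectral_counts.get(sample, 0) for m in mps
            )

    def test_process_rollup_duplicates_counts(self, small_tree):
        mps = [mp("g1", {"s1": 10}, lca=13, processes=("Transport", "Methanogenesis"))]
        out = rollup(mps, small_tree, "biological-process")
        assert out.data.loc["Transport", "s1"] == 10
        assert out.data.loc["Methanogenesis", "s1"] == 10


class TestKrona:
    def test_rows_agree_with_family_rollup(self, small_tree):
        mps = [mp("g1", {"s1": 3}, lca=13), mp("g2", {"s1": 2}, lca=16),
               mp("g3", {"s1": 4}, lca=10)]
        rows = krona_rows(mps, small_tree)
        assert len(rows) == 3
        fam_totals = {}
        for count, names in rows:
            fam_totals[names[-1]] = fam_totals.get(names[-1], 0) + count
        out = rollup(mps, small_tree, "family")
        assert fam_totals == out.data["s1"].to_dict()

    def test_empty_and_root_rows(self, small_tree):
        assert krona_rows([], small_tree) == []
        (count, names), = krona_rows([mp("g", {"s1": 1}, lca=1)], small_tree)
        assert set(names) == {"unassigned"}


class TestChord:
    def test_k1_winner_plus_bucket(self, small_tree):
        mps = [
            mp("g1", {"s1": 10}, lca=13, processes=("Transport",)),
            mp("g2", {"s1": 1}, lca=13, processes=("Methanogenesis",)),
        ]
        fam = rollup(mps, small_tree, "family")
        proc = rollup(mps, small_tree, "biological-process")
        chord = chord_matrix(fam, proc, joint_family_process_counts(mps, small_tree), k=1)
        assert chord.families == ["Bacillaceae"]
        assert chord.processes == ["Transport", "Other_Functions"]
        assert chord.cells.loc["Bacillaceae", "Other_Functions"] == 1

    def test_no_bucket_when_k_covers_everything(self, small_tree):
        mps = [mp("g1", {"s1": 5}, lca=13, processes=("Transport",))]
        fam = rollup(mps, small_tree, "family")
        proc = rollup(mps, small_tree, "biological-process")
        chord = chord_matrix(fam, proc, joint_family_process_counts(mps, small_tree), k=5)
        assert "Other_Functions" not in chord.processes

    def test_all_equal_abundances_select_lexicographically(self, small_tree):
        mps = [
            mp("g1", {"s1": 5}, lca=13, processes=("Zeta",)),
            mp("g2", {"s1": 5}, lca=16, processes=("Alpha",)),
        ]
        fam = rollup(mps, small_tree, "family")
        proc = rollup(mps, small_tree, "biological-process")
        chord = chord_matrix(fam, proc, joint_family_process_counts(mps, small_tree), k=1)
        assert chord.families == ["Bacillaceae"]
        assert chord.processes[0] == "Alpha"

    def test_bucket_conserves_process_totals(self, small_tree):
        rng = np.random.default_rng(3)
        mps = [
            mp(f"g{i}", {"s1": int(rng.integers(1, 9))}, lca=13,
               processes=(f"P{rng.integers(0, 6)}",))
            for i in range(15)
        ]
        fam = rollup(mps, small_tree, "family")
        proc = rollup(mps, small_tree, "biological-process")
        chord = chord_matrix(fam, proc, joint_family_process_counts(mps, small_tree), k=2)
        assert chord.cells.values.sum() == proc.data.values.sum()


class TestClustering:
    def test_identical_columns_merge_at_zero(self):
        m = matrix([[0.5, 0.5, 0.1], [0.5, 0.5, 0.9]], ["a", "b"],
                   ["s1", "s2", "s3"], mode="fractions")
        dendrogram = cluster_samples(m)
        first = dendrogram.merges[0]
        assert set(first[0] + first[1]) == {"s1", "s2"}
        assert first[2] == 0.0

    def test_four_point_hand_computation(self):
        # cityblock distances: AB=0.1, CD=0.2, then UPGMA joins the two
        # pairs at (0.95 + 1.15) / 2 = 1.05
        m = matrix(
            [[0.0, 0.1, 1.0, 1.0], [0.0, 0.0, 0.0, 0.2]],
            ["e1", "e2"], ["A", "B", "C", "D"], mode="fractions",
        )
        dendrogram = cluster_samples(m)
        got = [(tuple(sorted(l + r)), h) for l, r, h in dendrogram.merges]
        assert got[0] == (("A", "B"), pytest.approx(0.1))
        assert got[1] == (("C", "D"), pytest.approx(0.2))
        assert got[2] == (("A", "B", "C", "D"), pytest.approx(1.05))

    def test_matches_scipy_average_linkage_heights(self):
        rng = np.random.default_rng(9)
        values = rng.random((6, 5))
        m = matrix(values, [f"e{i}" for i in range(6)],
                   [f"s{i}" for i in range(5)], mode="fractions")
        dendrogram = cluster_samples(m)
        heights = sorted(h for _, _, h in dendrogram.merges)
        scipy_heights = sorted(linkage(values.T, method="average",
                                       metric="cityblock")[:, 2])
        assert np.allclose(heights, scipy_heights)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(10)
        values = rng.random((8, 4))
        rows = [f"e{i}" for i in range(8)]
        cols = list("wxyz")
        a = cluster_samples(matrix(values, rows, cols, mode="fractions"))
        perm = rng.permutation(8)
        b = cluster_samples(matrix(values[perm], [rows[i] for i in perm],
                                   cols, mode="fractions"))
        # identical topology; heights equal up to summation-order rounding
        assert [(l, r) for l, r, _ in a.merges] == [(l, r) for l, r, _ in b.merges]
        assert np.allclose([h for _, _, h in a.merges],
                           [h for _, _, h in b.merges])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cluster_samples(matrix([[1.0]], ["a"], ["s1"], mode="fractions"))

    def test_newick_heights_non_decreasing(self):
        rng = np.random.default_rng(12)
        m = matrix(rng.random((5, 6)), [f"e{i}" for i in range(5)],
                   [f"s{i}" for i in range(6)], mode="fractions")
        dendrogram = cluster_samples(m)
        heights = [h for _, _, h in dendrogram.merges]
        assert heights == sorted(heights)
        assert dendrogram.to_newick().endswith(";")


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        t, p, sig = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0 and not sig

    def test_extreme_separation_significant(self):
        _, p, sig = compare_groups([0.0, 0.0, 0.0], [10.0, 10.0, 10.0001])
        assert sig and p < 1e-6

    def test_matches_pooled_variance_formula(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0, 8.0]
        t, p, _ = compare_groups(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
            na + nb - 2
        )
        expected_t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(expected_t)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
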