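"""Toxin deduplication, p-distances, NJ trees and event counting."""

import numpy as np
import pytest

from tnta.acquisition import (ToxinEntry, ToxinSet, build_nj_tree,
                              count_acquisition_events, dedupe_identical,
                              pairwise_distances)
from tnta.simulate import simulate_toxin_origins

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _entry(i, seq, origin="tn_associated"):
    return ToxinEntry(f"e{i:02d}", seq, origin, "F")


class TestDedupe:
    def test_four_identical_collapse_to_one_representative(self):
        # mirrors a set of four transposons sharing one toxin sequence
        seq = "MKLYEDA" * 10
        toxins = ToxinSet([_entry(i, seq) for i in range(4)])
        reps, members = dedupe_identical(toxins)
        assert len(reps) == 1
        assert reps[0].id == "e00"
        assert members["e00"] == ["e00", "e01", "e02", "e03"]

    def test_all_distinct_stay_distinct(self):
        rng = np.random.default_rng(1)
        toxins = ToxinSet([_entry(i, "M" + "".join(rng.choice(AA, 40)))
                           for i in range(6)])
        reps, _ = dedupe_identical(toxins)
        assert len(reps) == 6

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        seqs = ["M" + "".join(rng.choice(AA, 30)) for _ in range(4)] * 2
        entries = [_entry(i, s) for i, s in enumerate(seqs)]
        baseline = dedupe_identical(ToxinSet(entries))[0]
        for _ in range(10):
            shuffled = list(entries)
            rng.shuffle(shuffled)
            assert dedupe_identical(ToxinSet(shuffled))[0] == baseline

    def test_mixed_families_rejected(self):
        with pytest.raises(ValueError):
            ToxinSet([ToxinEntry("a", "MK", "seed", "F1"),
                      ToxinEntry("b", "MK", "seed", "F2")])


class TestPairwiseDistances:
    def test_identical_pair_is_zero(self):
        e = _entry(0, "MKLYEDARW" * 10)
        ids, d = pairwise_distances([e, _entry(1, e.aa_sequence)])
        assert d[0, 1] == 0.0

    def test_two_of_hundred_residues_is_002(self):
        rng = np.random.default_rng(3)
        a = "M" + "".join(rng.choice(AA, 99))
        b = list(a)
        b[10] = "W" if a[10] != "W" else "Y"
        b[50] = "W" if a[50] != "W" else "Y"
        _, d = pairwise_distances([_entry(0, a), _entry(1, "".join(b))])
        assert d[0, 1] == pytest.approx(0.02)

    def test_matrix_is_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(4)
        entries = [_entry(i, "M" + "".join(rng.choice(AA, 60))) for i in range(5)]
        _, d = pairwise_distances(entries)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)


class TestBuildNjTree:
    def test_additive_four_taxon_matrix_recovers_topology(self):
        # tree ((a,b),(c,d)) with internal branch 3: additive distances
        d = np.array([
            [0, 2, 9, 9],
            [2, 0, 9, 9],
            [9, 9, 0, 2],
            [9, 9, 2, 0],
        ], dtype=float)
        tree = build_nj_tree(["a", "b", "c", "d"], d)
        pairs = set()
        for node in tree.non_tips():
            tips = frozenset(t.name for t in node.tips())
            pairs.add(tips)
        assert frozenset({"a", "b"}) in pairs or frozenset({"c", "d"}) in pairs

    def test_three_taxa_is_minimum(self):
        d = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], dtype=float)
        tree = build_nj_tree(["a", "b", "c"], d)
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}
        with pytest.raises(ValueError):
            build_nj_tree(["a", "b"], d[:2, :2])

    def test_taxon_order_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(5)
        ts = simulate_toxin_origins(3, n_per_origin=2, divergence=0.1, seed=5)
        reps, _ = dedupe_identical(ts)
        ids, d = pairwise_distances(reps)

        def clades(tree):
            return {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}

        baseline = build_nj_tree(ids, d, origins=ts.origins)
        for _ in range(5):
            perm = rng.permutation(len(ids))
            pids = [ids[i] for i in perm]
            pd = d[np.ix_(perm, perm)]
            again = build_nj_tree(pids, pd, origins=ts.origins)
            assert clades(again) == clades(baseline)

    def test_negative_branch_lengths_clamped(self):
        d = np.array([
            [0.0, 0.1, 0.4, 0.45],
            [0.1, 0.0, 0.45, 0.4],
            [0.4, 0.45, 0.0, 0.05],
            [0.45, 0.4, 0.05, 0.0],
        ])
        tree = build_nj_tree(list("abcd"), d)
        for node in tree.traverse():
            assert node.length is None or node.length >= 0


class TestCountEvents:
    def _tree(self, k, seed, **kw):
        ts = simulate_toxin_origins(k, seed=seed, **kw)
        reps, _ = dedupe_identical(ts)
        ids, d = pairwise_distances(reps)
        return build_nj_tree(ids, d, origins=ts.origins), ts.origins

    def test_single_origin_counts_one(self):
        tree, origins = self._tree(1, seed=13)
        assert count_acquisition_events(tree, origins) == 1

    def test_no_tn_leaves_counts_zero(self):
        ts = simulate_toxin_origins(3, n_per_origin=1, seed=14)
        only_seeds = ToxinSet([e for e in ts.entries if e.origin == "seed"])
        reps, _ = dedupe_identical(only_seeds)
        ids, d = pairwise_distances(reps)
        tree = build_nj_tree(ids, d, origins=only_seeds.origins)
        assert count_acquisition_events(tree, only_seeds.origins) == 0

    def test_three_origins_recovered(self):
        tree, origins = self._tree(3, seed=13, divergence=0.3)
        assert count_acquisition_events(tree, origins) == 3

    def test_singleton_origins_counted_individually(self):
        tree, origins = self._tree(5, seed=15, n_per_origin=1)
        assert count_acquisition_events(tree, origins) == 5

    def test_count_bounded_by_tn_leaf_count(self):
        for seed in range(5):
            tree, origins = self._tree(2, seed=seed)
            n_tn = sum(1 for v in origins.values() if v == "tn_associated")
            count = count_acquisition_events(tree, origins)
            assert 1 <= count <= n_tn

    def test_collapsing_duplicates_does_not_change_count(self):
        ts = simulate_toxin_origins(3, n_per_origin=2, divergence=0.2, seed=16)
        dup = ToxinSet(ts.entries + [ToxinEntry("zz_dup", ts.entries[0].aa_sequence,
                                                ts.entries[0].origin, ts.family)])
        for toxins in (ts, dup):
            reps, _ = dedupe_identical(toxins)
            ids, d = pairwise_distances(reps)
            tree = build_nj_tree(ids, d, origins=toxins.origins)
            assert count_acquisition_events(tree, toxins.origins) == 3

    def test_unlabeled_leaf_rejected(self):
        tree, origins = self._tree(1, seed=17)
        bad = dict(origins)
        bad.pop(next(iter(bad)))
        with pytest.raises(ValueError):
            count_acquisition_events(tree, bad)
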