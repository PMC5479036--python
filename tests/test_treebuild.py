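import numpy as np
import pytest

from conftest import random_binary_tree
from orthored.seqdata import SequenceRecord
from orthored.treebuild import (
    Alignment,
    NewickParseError,
    align_cluster,
    alignment_distances,
    infer_tree,
    read_newick,
    select_alignment_mode,
    tree_from_distances,
    write_newick,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def rec(seq_id, residues):
    return SequenceRecord(seq_id, seq_id.split("|")[0], residues)


def nontrivial_splits(tree):
    """Unrooted bipartitions (as canonical frozensets) of a tree's tips."""
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for n in tree.traverse(include_self=False):
        if n.is_tip():
            continue
        below = frozenset(t.name for t in n.tips())
        if 1 < len(below) < len(all_tips) - 1:
            out.add(min(below, all_tips - below, key=sorted))
    return out


class TestModeSwitch:
    @pytest.mark.parametrize("n, expected", [(2, "accurate"), (199, "accurate"), (200, "fast"), (500, "fast")])
    def test_switch_at_200_sequences(self, n, expected):
        assert select_alignment_mode(n) == expected


class TestAlignCluster:
    def test_identical_sequences_align_gapless(self):
        seq = "MKVLHEAGAWGHEELLIAM"
        aln = align_cluster([rec("A|1", seq), rec("B|2", seq)])
        assert aln.rows[0] == aln.rows[1] == seq

    def test_rows_equal_length_and_ungap_to_inputs(self, rng):
        records = []
        base = "".join(rng.choice(list(AA), size=80))
        for i in range(6):
            s = list(base)
            for _ in range(int(rng.integers(0, 8))):
                s[int(rng.integers(0, len(s)))] = str(rng.choice(list(AA)))
            if rng.random() < 0.5:  # short internal deletion
                start = int(rng.integers(5, 60))
                del s[start : start + int(rng.integers(1, 6))]
            records.append(rec(f"S{i}|g{i}", "".join(s)))
        aln = align_cluster(records)
        assert len({len(r) for r in aln.rows}) == 1
        for row, record in zip(aln.rows, records):
            assert row.replace("-", "") == record.residues

    def test_single_sequence_warns(self):
        with pytest.warns(UserWarning):
            aln = align_cluster([rec("A|1", "MKV")])
        assert aln.rows == ["MKV"]

    def test_deterministic(self):
        records = [rec("A|1", "MKVLHEAGAWGHEE"), rec("B|2", "MKVLHEAWGHEE"), rec("C|3", "MKVGGHEAGAWGHEE")]
        a1 = align_cluster(records)
        a2 = align_cluster(records)
        assert a1.rows == a2.rows


class TestAlignmentDistances:
    def test_zero_iff_identical_and_symmetric(self):
        aln = Alignment(["a", "b", "c"], ["MKVL", "MKVL", "MAVL"])
        d = alignment_distances(aln)
        assert d[0, 1] == 0.0
        assert d[0, 2] > 0
        assert np.allclose(d, d.T)

    def test_disjoint_rows_get_cap_with_warning(self):
        aln = Alignment(["a", "b"], ["MK--", "--VL"])
        with pytest.warns(UserWarning, match="no aligned columns"):
            d = alignment_distances(aln)
        assert d[0, 1] == 10.0


class TestInferTree:
    def test_two_similar_pairs_topology(self):
        s1 = "MKVLHEAGAWGHEELLIAMKVLHEAGAWGHEELLIA"
        s2 = "MPPTSSIRQVCYWNDCLKMPPTSSIRQVCYWNDCLK"
        records = {
            "A|p1a": s1,
            "B|p1b": s1[:-1] + "M",
            "C|p2a": s2,
            "D|p2b": s2[:-1] + "W",
        }
        aln = align_cluster([rec(k, v) for k, v in records.items()])
        tree = infer_tree(aln)
        # the two near-identical pairs must be sisters with near-zero branches
        for pair in (("A|p1a", "B|p1b"), ("C|p2a", "D|p2b")):
            tips = [t for t in tree.tips() if t.name in pair]
            assert tips[0].distance(tips[1]) < 0.2
        cross = [t for t in tree.tips() if t.name in ("A|p1a", "C|p2a")]
        assert cross[0].distance(cross[1]) > 1.0

    def test_identical_rows_give_zero_length_star(self):
        aln = Alignment(["a", "b", "c", "d"], ["MKVL"] * 4)
        tree = infer_tree(aln)
        assert {t.name for t in tree.tips()} == {"a", "b", "c", "d"}
        assert all((n.length or 0.0) == 0.0 for n in tree.traverse(include_self=False))

    def test_deterministic_newick(self):
        records = [rec(f"S{i}|g", "".join(np.random.default_rng(i).choice(list(AA), size=50))) for i in range(5)]
        aln = align_cluster(records)
        assert write_newick(infer_tree(aln)) == write_newick(infer_tree(aln))

    def test_leaf_set_matches_alignment(self, rng):
        records = [
            rec(f"S{i}|g", "".join(rng.choice(list(AA), size=60))) for i in range(6)
        ]
        aln = align_cluster(records)
        tree = infer_tree(aln)
        assert {t.name for t in tree.tips()} == set(aln.seq_ids)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            infer_tree(Alignment(["a"], ["MKVL"]))


class TestAdditiveRecovery:
    def test_nj_recovers_generating_topology(self, rng):
        # distances read off random trees are additive; NJ must recover them
        for k in range(15):
            n = int(rng.integers(4, 9))
            names = [f"L{i}" for i in range(n)]
            true = random_binary_tree(rng, names, min_len=0.1, max_len=1.0)
            dm = true.tip_tip_distances()
            d = np.array([[dm[a, b] for b in names] for a in names])
            est = tree_from_distances(d, names)
            assert nontrivial_splits(est) == nontrivial_splits(true)
            # and the fitted branch lengths reproduce the additive distances
            dm2 = est.tip_tip_distances()
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    assert dm2[a, b] == pytest.approx(dm[a, b], abs=1e-6)


class TestNewickIO:
    def test_parse_small_tree(self):
        t = read_newick("((A:1,B:1):0.5,C:2);")
        assert {l.name for l in t.tips()} == {"A", "B", "C"}

    @pytest.mark.parametrize("bad", ["(A:1,B:1", "(A:1,B:1));", "(A,B)"])
    def test_malformed_newick_raises(self, bad):
        with pytest.raises(NewickParseError):
            read_newick(bad)

    def test_round_trip_50_random_trees(self, rng):
        for k in range(50):
            n = int(rng.integers(3, 12))
            t = random_binary_tree(rng, [f"L{i}" for i in range(n)])
            text = write_newick(t)
            t2 = read_newick(text)
            assert nontrivial_splits(t2) == nontrivial_splits(t)
            dm, dm2 = t.tip_tip_distances(), t2.tip_tip_distances()
            names = sorted(dm.ids)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    assert dm2[a, b] == pytest.approx(dm[a, b], rel=1e-6)
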