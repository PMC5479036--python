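import numpy as np
import pytest

from _oracles import (
    enumerate_species_trees,
    label_extract_oracle,
    leaf_paths,
    max_root_depth,
    midpoint_optimum_oracle,
    rt_winner_oracle,
    shape_to_newick,
)
from conftest import make_dataset, random_binary_tree
from orthored.orthology import (
    EVENT_DUPLICATION,
    EVENT_SINGLE_SPECIES,
    EVENT_SPECIATION,
    extract_orthologs,
    label_events,
    prune_long_branches,
    reintroduce_isoforms,
    root_midpoint,
    root_rt,
)
from orthored.treebuild import read_newick, write_newick


def events_by_leafsets(tree):
    return {
        frozenset(t.name for t in n.tips()): n.event
        for n in tree.traverse(include_self=True)
        if not n.is_tip()
    }


class TestLabelEvents:
    def test_shared_species_across_children_is_duplication(self):
        t = read_newick("((A|1:1,B|1:1):1,(A|2:1,B|2:1):1);")
        ds = make_dataset(["A|1", "B|1", "A|2", "B|2"])
        label_events(t, ds)
        ev = events_by_leafsets(t)
        assert ev[frozenset({"A|1", "B|1", "A|2", "B|2"})] == EVENT_DUPLICATION
        assert ev[frozenset({"A|1", "B|1"})] == EVENT_SPECIATION
        assert ev[frozenset({"A|2", "B|2"})] == EVENT_SPECIATION

    def test_single_species_clade_is_not_a_duplication(self):
        t = read_newick("((A|1a:1,A|1b:1):1,B|1:1);")
        ds = make_dataset(["A|1a", "A|1b", "B|1"])
        label_events(t, ds)
        ev = events_by_leafsets(t)
        assert ev[frozenset({"A|1a", "A|1b"})] == EVENT_SINGLE_SPECIES
        assert ev[frozenset({"A|1a", "A|1b", "B|1"})] == EVENT_SPECIATION

    def test_ancestral_overwrite_propagates_to_root(self):
        t = read_newick("(((A|1:1,B|1:1):1,(A|2:1,C|1:1):1):1,D|1:1);")
        ds = make_dataset(["A|1", "B|1", "A|2", "C|1", "D|1"])
        label_events(t, ds)
        ev = events_by_leafsets(t)
        assert ev[frozenset({"A|1", "B|1"})] == EVENT_SPECIATION
        assert ev[frozenset({"A|2", "C|1"})] == EVENT_SPECIATION
        assert ev[frozenset({"A|1", "B|1", "A|2", "C|1"})] == EVENT_DUPLICATION
        # root was a clean speciation ({A,B,C} vs {D}) but is overwritten
        assert ev[frozenset({"A|1", "B|1", "A|2", "C|1", "D|1"})] == EVENT_DUPLICATION

    def test_duplications_upward_closed(self, rng):
        for _ in range(20):
            names = [f"{rng.choice(list('ABC'))}|x{i}" for i in range(int(rng.integers(3, 9)))]
            t = random_binary_tree(rng, names)
            ds = make_dataset(names)
            label_events(t, ds)
            for n in t.traverse(include_self=True):
                if n.is_tip() or n.event != EVENT_DUPLICATION:
                    continue
                anc = n.parent
                while anc is not None:
                    assert anc.event != EVENT_SPECIATION
                    anc = anc.parent


class TestExtractOrthologs:
    def test_daughter_clade_of_nearest_duplication(self):
        t = read_newick("((A|1:1,B|1:1):1,(A|2:1,B|2:1):1);")
        ds = make_dataset(["A|1", "B|1", "A|2", "B|2"])
        label_events(t, ds)
        oset = extract_orthologs(t, "A|1", ds)
        assert oset.orthologs == {"A|1", "B|1"}

    def test_no_duplication_returns_all_leaves(self):
        t = read_newick("((A|1:1,B|1:1):1,C|1:1);")
        ds = make_dataset(["A|1", "B|1", "C|1"])
        label_events(t, ds)
        for q in ["A|1", "B|1", "C|1"]:
            assert extract_orthologs(t, q, ds).orthologs == {"A|1", "B|1", "C|1"}

    def test_overwritten_parent_bounds_the_clade(self):
        t = read_newick("(((A|1:1,B|1:1):1,(A|2:1,C|1:1):1):1,D|1:1);")
        ds = make_dataset(["A|1", "B|1", "A|2", "C|1", "D|1"])
        label_events(t, ds)
        assert extract_orthologs(t, "B|1", ds).orthologs == {"A|1", "B|1"}

    def test_exhaustive_small_trees_match_recursive_oracle(self):
        checked = 0
        for shape in enumerate_species_trees(5):
            newick = shape_to_newick(shape)
            leaves = list(leaf_paths(shape))
            if len(leaves) < 2:
                continue
            ds = make_dataset([name for name, _ in leaves])
            t = read_newick(newick)
            label_events(t, ds)
            for name, path in leaves:
                got = {s for s in extract_orthologs(t, name, ds).seq_members}
                expected = label_extract_oracle(shape, path) | {name}
                assert got == expected, f"{newick} query={name}"
                checked += 1
        assert checked > 500


class TestReintroduceIsoforms:
    def test_isoforms_added_at_sequence_level(self):
        ds = make_dataset(
            ["A|g1.a", "A|g1.b", "B|g2"], isoform_map={"g1": {"A|g1.a", "A|g1.b"}}
        )
        t = read_newick("(A|g1.a:1,B|g2:1);")
        label_events(t, ds)
        oset = extract_orthologs(t, "A|g1.a", ds)
        full = reintroduce_isoforms(oset, ds)
        assert full.seq_members >= {"A|g1.a", "A|g1.b", "B|g2"}
        assert full.orthologs == oset.orthologs  # gene level unchanged


class TestMidpointRooting:
    def test_two_leaf_arithmetic(self):
        # midpoint of the 4-long A-B path is 2.0 from each leaf
        rooted = root_midpoint(read_newick("(A:1,B:3);"))
        lengths = {c.name: c.length for c in rooted.children}
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["A"] == pytest.approx(2.0)

    def test_symmetric_quartet_roots_on_central_edge(self):
        rooted = root_midpoint(read_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        sides = [frozenset(t.name for t in c.tips()) or frozenset({c.name}) for c in rooted.children]
        assert frozenset({"A", "B"}) in sides or frozenset({"C", "D"}) in sides
        assert max_root_depth(rooted) == pytest.approx(2.0)

    def test_matches_brute_force_on_random_trees(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 12))
            t = random_binary_tree(rng, [f"L{i:02d}" for i in range(n)])
            optimum = midpoint_optimum_oracle(t)
            rooted = root_midpoint(t)
            assert max_root_depth(rooted) == pytest.approx(optimum, abs=1e-9)

    def test_all_zero_lengths_is_deterministic_with_warning(self):
        nwk = "((A:0,B:0):0,C:0);"
        with pytest.warns(UserWarning):
            r1 = root_midpoint(read_newick(nwk))
        with pytest.warns(UserWarning):
            r2 = root_midpoint(read_newick(nwk))
        assert write_newick(r1) == write_newick(r2)


class TestRtRooting:
    def test_single_outgroup_leaf_is_the_root(self):
        t = read_newick("((A|1:1,B|1:1):1,(C|1:1,OUT|x:1):1);")
        ds = make_dataset(["A|1", "B|1", "C|1", "OUT|x"], outgroup="OUT")
        rooted = root_rt(t, "A|1", "OUT", ds)
        assert "OUT|x" in {c.name for c in rooted.children}

    def test_prefers_rooting_with_more_ingroup_species(self):
        # rooting at OUT|1 keeps {A,B,C} with the query; rooting at OUT|2 only {A}
        nwk = "(((A|q:1,OUT|2:1):1,(B|1:1,C|1:1):1):1,OUT|1:1);"
        t = read_newick(nwk)
        ds = make_dataset(["A|q", "OUT|2", "B|1", "C|1", "OUT|1"], outgroup="OUT")
        rooted = root_rt(t, "A|q", "OUT", ds)
        assert "OUT|1" in {c.name for c in rooted.children}

    def test_tie_broken_by_distance_then_name(self):
        # both candidates isolate the same single-species subtree {A|q}
        nwk = "((OUT|far:3.0,A|q:1.0):1.0,OUT|near:1.5);"
        t = read_newick(nwk)
        ds = make_dataset(["OUT|far", "A|q", "OUT|near"], outgroup="OUT")
        rooted = root_rt(t, "A|q", "OUT", ds)
        assert "OUT|far" in {c.name for c in rooted.children}

    def test_no_outgroup_leaf_returns_none(self):
        t = read_newick("((A|1:1,B|1:1):1,C|1:1);")
        ds = make_dataset(["A|1", "B|1", "C|1"])
        assert root_rt(t, "A|1", "OUT", ds) is None

    def test_matches_enumeration_oracle_on_random_trees(self, rng):
        for k in range(30):
            n_in = int(rng.integers(3, 8))
            n_out = int(rng.integers(1, 4))
            names = [f"S{i%3}|g{i}" for i in range(n_in)] + [f"OUT|o{j}" for j in range(n_out)]
            t = random_binary_tree(rng, names)
            ds = make_dataset(names, outgroup="OUT")
            rooted = root_rt(t, names[0], "OUT", ds)
            winner = next(c.name for c in rooted.children if c.name and c.name.startswith("OUT|"))
            expected = rt_winner_oracle(t, names[0], "OUT", lambda s: s.split("|")[0])
            assert winner == expected

    def test_deterministic_across_runs(self, rng):
        names = ["S0|a", "S1|b", "S2|c", "OUT|o1", "OUT|o2"]
        t = random_binary_tree(rng, names)
        ds = make_dataset(names, outgroup="OUT")
        r1 = root_rt(t, "S0|a", "OUT", ds)
        r2 = root_rt(t, "S0|a", "OUT", ds)
        assert write_newick(r1) == write_newick(r2)


class TestPruneLongBranches:
    def test_no_long_branches_is_identity(self):
        t = read_newick("((A|1:1,B|1:1):0.5,C|1:1);")
        ds = make_dataset(["A|1", "B|1", "C|1"])
        pruned = prune_long_branches(t, "A|1", cutoff=2.0, dataset=ds)
        assert {l.name for l in pruned.tips()} == {"A|1", "B|1", "C|1"}

    def test_long_external_branch_removes_leaf(self):
        t = read_newick("((A|1:1,X|1:2.5):0.5,(B|1:1,C|1:1):0.5);")
        ds = make_dataset(["A|1", "X|1", "B|1", "C|1"])
        pruned = prune_long_branches(t, "A|1", cutoff=2.0, dataset=ds)
        assert {l.name for l in pruned.tips()} == {"A|1", "B|1", "C|1"}

    def test_long_internal_branch_keeps_query_side(self):
        t = read_newick("((A|q:1,B|1:1):3.0,(C|1:1,D|1:1):0.5);")
        ds = make_dataset(["A|q", "B|1", "C|1", "D|1"])
        pruned = prune_long_branches(t, "A|q", cutoff=2.0, dataset=ds)
        assert {l.name for l in pruned.tips()} == {"A|q", "B|1"}

    def test_query_pendant_branch_long_leaves_singleton(self):
        t = read_newick("((A|q:2.5,B|1:1):0.5,C|1:1);")
        ds = make_dataset(["A|q", "B|1", "C|1"])
        pruned = prune_long_branches(t, "A|q", cutoff=2.0, dataset=ds)
        assert {l.name for l in pruned.tips()} == {"A|q"}

    def test_matches_connected_component_oracle(self, rng):
        from _oracles import prune_survivors_oracle

        for _ in range(30):
            n = int(rng.integers(4, 12))
            names = [f"S{i%4}|g{i}" for i in range(n)]
            t = random_binary_tree(rng, names, min_len=0.2, max_len=3.0)
            ds = make_dataset(names)
            expected = prune_survivors_oracle(t, names[0], 2.0)
            pruned = prune_long_branches(t, names[0], cutoff=2.0, dataset=ds)
            assert {l.name for l in pruned.tips()} == expected

    def test_idempotent(self, rng):
        from orthored.treebuild import write_newick

        for _ in range(30):
            n = int(rng.integers(4, 12))
            names = [f"S{i%4}|g{i}" for i in range(n)]
            t = random_binary_tree(rng, names, min_len=0.2, max_len=3.0)
            ds = make_dataset(names)
            once = prune_long_branches(t, names[0], cutoff=2.0, dataset=ds)
            twice = prune_long_branches(once.copy(), names[0], cutoff=2.0, dataset=ds)
            assert {l.name for l in twice.tips()} == {l.name for l in once.tips()}
            assert all((nd.length or 0.0) <= 2.0 for nd in once.traverse(include_self=False))
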