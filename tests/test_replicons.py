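"""Replicon architecture: co-inheritance groups, assembly, merge, restoration."""

import networkx as nx
import pytest

from paleogen.replicons import (
    Group,
    MergeProposal,
    RepliconAssignment,
    apply_merges,
    assemble_replicons,
    build_group_graph,
    cluster_proposals,
    co_inheritance_groups,
    cross_link,
    leaf_groups,
    pool_proposals,
    restore_chromosomes,
    run_merge_signal,
)


def assignment(node_id, members):
    return RepliconAssignment(node_id, {k: set(v) for k, v in members.items()})


class TestGroups:
    def test_identical_children_give_one_group_per_replicon(self):
        c1 = assignment("X", {"C": "abc", "P": "de"})
        c2 = assignment("Y", {"C": "abc", "P": "de"})
        groups, unplaced = co_inheritance_groups("abcde", [c1, c2])
        assert len(groups) == 2 and not unplaced
        assert sorted(len(g.members) for g in groups) == [2, 3]

    def test_one_child_only_families_are_unplaced(self):
        c1 = assignment("X", {"C": "abc"})
        c2 = assignment("Y", {"C": "ab"})
        groups, unplaced = co_inheritance_groups("abc", [c1, c2])
        assert unplaced == {"c"}
        assert len(groups) == 1

    def test_pattern_sharing_adds_edges(self):
        groups = [
            Group(0, frozenset("ab"), ("C", "C")),
            Group(1, frozenset("cd"), ("P1", "C")),
            Group(2, frozenset("ef"), ("P1", "P2")),
            Group(3, frozenset("gh"), ("Q", "R")),
        ]
        g = build_group_graph(groups)
        assert g.has_edge(0, 1)  # shared C in child 2
        assert g.has_edge(1, 2)  # shared P1 in child 1
        assert not g.has_edge(0, 2) and not g.has_edge(0, 3)


class TestAssembly:
    def worked_example(self):
        """Four target groups, two-group outgroup, as in the replicon
        reconstruction walkthrough: linked groups connected in the
        target graph merge; the unlinked group keeps its own replicon."""
        targets = [
            Group(0, frozenset(("a", "b", "c")), ("C", "C")),
            Group(1, frozenset(("g", "h", "i")), ("P1", "C")),
            Group(2, frozenset(("d", "e", "f")), ("C", "P1")),
            Group(3, frozenset(("x", "y")), ("P2", "P2")),
        ]
        outgroup = [
            Group(0, frozenset(("a", "b", "c", "g", "h", "i")), ("C", "C")),
            Group(1, frozenset(("d", "e", "f")), ("P", "P")),
        ]
        return targets, outgroup

    def test_worked_example_architecture(self):
        targets, outgroup = self.worked_example()
        tg = build_group_graph(targets)
        og = build_group_graph(outgroup)
        links = cross_link(targets, outgroup, 3)
        assert {(ti, oi) for ti, oi, _ in links} == {(0, 0), (1, 0), (2, 1)}
        a = assemble_replicons("N", targets, tg, links)
        reps = sorted(sorted(m) for m in a.members.values())
        assert reps == [
            ["a", "b", "c", "g", "h", "i"],  # linked to common anchor, merged
            ["d", "e", "f"],  # different anchor: own replicon
            ["x", "y"],  # unlinked: own replicon
        ]

    def test_identical_children_and_outgroup_reproduce_architecture(self):
        c = assignment("X", {"C": "abcdef", "P": "ghi"})
        groups, unplaced = co_inheritance_groups("abcdefghi", [c, c])
        tg = build_group_graph(groups)
        og = leaf_groups(assignment("O", {"C": "abcdef", "P": "ghi"}))
        links = cross_link(groups, og, 3)
        a = assemble_replicons("N", groups, tg, links, unplaced)
        reps = sorted(sorted(m) for m in a.members.values())
        assert reps == [list("abcdef"), list("ghi")]

    def test_sharing_below_cutoff_is_not_linked(self):
        outgroup = [Group(0, frozenset("abcdefgh"), ("C",))]
        targets = [Group(0, frozenset("abxy"), ("C", "C"))]
        assert cross_link(targets, outgroup, 3) == []  # 2 of 4 shared: too few
        targets = [Group(0, frozenset("abcx"), ("C", "C"))]
        assert cross_link(targets, outgroup, 3) == [(0, 0, 3)]  # >= convention
        # a group smaller than the absolute cutoff links when contained
        targets = [Group(0, frozenset("ab"), ("C", "C"))]
        assert cross_link(targets, outgroup, 3) == [(0, 0, 2)]
        targets = [Group(0, frozenset("ax"), ("C", "C"))]
        assert cross_link(targets, outgroup, 3) == []  # 1 of 2: not contained

    def test_unplaced_follow_run_majority(self):
        from paleogen.runs import GeneRun, RunSet

        targets = [
            Group(0, frozenset("abc"), ("C", "C")),
            Group(1, frozenset("de"), ("P", "P")),
        ]
        og = leaf_groups(assignment("O", {"C": "abc", "P": "de"}))
        links = cross_link(targets, og, 3)
        runs = RunSet("N", [GeneRun([("d", "+"), ("e", "+"), ("z", "+")], 3.0)])
        a = assemble_replicons(
            "N", targets, build_group_graph(targets),
            links, unplaced={"z"}, runs=runs,
        )
        rep_of = a.replicon_of()
        assert rep_of["z"] == rep_of["d"]


class TestMergeSignals:
    def test_split_run_yields_documented_signal(self):
        a = assignment("N", {"R1": "abcdef", "R2": "ghij"})
        run = list("abcdefghij")  # 6 on R1, 4 on R2
        p = run_merge_signal(run, a)
        assert p.relative == pytest.approx(0.4)
        assert p.absolute == 10.0
        assert p.pair == ("R1", "R2")

    def test_single_replicon_run_gives_none(self):
        a = assignment("N", {"R1": "abcd"})
        assert run_merge_signal(list("abcd"), a) is None

    def test_short_run_ignored(self):
        a = assignment("N", {"R1": "ab", "R2": "c"})
        assert run_merge_signal(list("abc"), a, min_run_length=4) is None

    def test_low_signal_floor(self):
        a = assignment("N", {"R1": "abcdefghi", "R2": "j"})
        assert run_merge_signal(list("abcdefghij"), a, low_signal=0.15) is None

    def test_pooling_sums_absolute_strength(self):
        p1 = MergeProposal("N", ("R1", "R2"), 10.0, 0.4)
        p2 = MergeProposal("N", ("R1", "R2"), 6.0, 0.2)
        (pooled,) = pool_proposals([p1, p2])
        assert pooled.absolute == 16.0
        assert pooled.relative == pytest.approx((0.4 * 10 + 0.2 * 6) / 16)

    def test_separated_clusters_accept_strong_side(self):
        strong = [MergeProposal(f"N{i}", ("A", "B"), 40.0 + i, 0.45) for i in range(5)]
        weak = [MergeProposal(f"M{i}", ("C", "D"), 4.0, 0.12) for i in range(5)]
        accepted = cluster_proposals(strong + weak, seed=0)
        assert set(p.node_id for p in accepted) == {f"N{i}" for i in range(5)}

    def test_identical_proposals_reject_all(self):
        props = [MergeProposal(f"N{i}", ("A", "B"), 10.0, 0.3) for i in range(4)]
        assert cluster_proposals(props, seed=0) == []

    def test_clustering_deterministic_under_seed(self, rng):
        props = [
            MergeProposal(f"N{i}", ("A", "B"), float(rng.uniform(2, 50)),
                          float(rng.uniform(0.1, 0.5)))
            for i in range(20)
        ]
        a1 = cluster_proposals(props, seed=7)
        a2 = cluster_proposals(props, seed=7)
        assert [p.node_id for p in a1] == [p.node_id for p in a2]

    def test_apply_merges_is_transitive(self):
        a = assignment("N", {"R1": "ab", "R2": "cd", "R3": "ef"})
        merged = apply_merges(
            a,
            [MergeProposal("N", ("R1", "R2"), 9, 0.4), MergeProposal("N", ("R2", "R3"), 9, 0.4)],
        )
        assert merged.n_replicons() == 1
        assert merged.families() == set("abcdef")

    def test_no_accepted_proposals_leaves_assignment_unchanged(self):
        a = assignment("N", {"R1": "ab", "R2": "cd"})
        assert apply_merges(a, []) is a

    def test_merge_never_increases_replicon_count(self, rng):
        a = assignment("N", {f"R{i}": [f"f{i}{j}" for j in range(3)] for i in range(5)})
        pairs = [("R0", "R3"), ("R1", "R2")]
        merged = apply_merges(a, [MergeProposal("N", p, 9, 0.4) for p in pairs])
        assert merged.n_replicons() <= a.n_replicons()


class TestChromosomeRestoration:
    def test_five_percent_boundary(self):
        core = {f"c{i}" for i in range(1000)}
        a = assignment(
            "N",
            {
                "big": [f"c{i}" for i in range(900)],
                "at5pct": [f"c{i}" for i in range(900, 950)],  # exactly 5%
                "below": [f"c{i}" for i in range(950, 999)] + ["x"],  # 4.9%
            },
        )
        restored = restore_chromosomes(a, core, threshold=0.05)
        assert restored.roles["big"] == "main_chromosome"
        assert restored.roles["at5pct"] == "secondary_chromosome"
        assert restored.roles["below"] == "plasmid"

    def test_single_replicon_is_main_chromosome(self):
        a = assignment("N", {"only": "abc"})
        assert restore_chromosomes(a, set("abc")).roles["only"] == "main_chromosome"

    def test_core_tie_broken_by_gene_count(self):
        a = assignment("N", {"R1": ["c1", "x1"], "R2": ["c2", "x2", "x3"]})
        restored = restore_chromosomes(a, {"c1", "c2"})
        assert restored.roles["R2"] == "main_chromosome"
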