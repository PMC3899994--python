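"""Ancestral state reconstruction: parsimony and likelihood engines."""

import numpy as np
import pandas as pd
import pytest

from paleogen.ancestral import (
    Cutoffs,
    RateModel,
    call_presence,
    ml_fit_rates,
    ml_marginal_posteriors,
    ml_posteriors_brute_force,
    mp_min_changes_exhaustive,
    mp_reconstruct,
    prune_likelihood,
    prune_loglik,
)
from paleogen.genome_io import SpeciesTree

from conftest import random_binary_tree


def leaf_frame(tree, states):
    return pd.DataFrame({leaf: [states[leaf]] for leaf in tree.leaf_ids()})


class TestParsimony:
    def test_agreeing_children_fix_parent_state(self):
        tree = SpeciesTree.from_newick("((A:1,B:1):1,C:1);")
        m = pd.DataFrame({"A": [1], "B": [1], "C": [0]})
        states, changes = mp_reconstruct(tree, m)
        assert states.at["A_B", 0] == 1
        assert changes.iloc[0] == 1

    def test_single_presence_in_four_leaf_tree_reconstructs_absent(self):
        tree = SpeciesTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = pd.DataFrame({"A": [1], "B": [0], "C": [0], "D": [0]})
        states, changes = mp_reconstruct(tree, m)
        assert states.iloc[:, 0].sum() == 0
        assert changes.iloc[0] == 1

    def test_change_count_matches_exhaustive_minimum_on_random_trees(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 7))
            tree = random_binary_tree(rng, n)
            states = {leaf: int(rng.integers(0, 2)) for leaf in tree.leaf_ids()}
            m = pd.DataFrame({k: [v] for k, v in states.items()})
            _, changes = mp_reconstruct(tree, m)
            assert changes.iloc[0] == mp_min_changes_exhaustive(tree, states)


class TestLikelihood:
    def test_two_leaf_tree_matches_closed_form(self):
        tree = SpeciesTree.from_newick("(A:0.3,B:0.7);")
        rates = RateModel(0.4, 0.9)
        pi = rates.stationary
        pa, pb = rates.transition(0.3), rates.transition(0.7)
        expected = sum(pi[r] * pa[r, 1] * pb[r, 0] for r in (0, 1))
        got = prune_likelihood(tree, {"A": 1, "B": 0}, rates)
        assert got == pytest.approx(np.log(expected), abs=1e-12)

    def test_likelihood_matches_enumeration_on_four_leaves(self, rng):
        tree = SpeciesTree.from_newick("((A:0.2,B:0.5):0.3,(C:0.1,D:0.9):0.4);")
        rates = RateModel(0.7, 0.3)
        for _ in range(8):
            states = {l: int(rng.integers(0, 2)) for l in "ABCD"}
            # enumeration: sum over internal assignments of the joint
            mats = {
                n.id: rates.transition(n.length)
                for n in tree.preorder()
                if n.parent is not None
            }
            internal = [n.id for n in tree.internal_nodes()]
            total = 0.0
            for bits in range(2 ** len(internal)):
                lab = dict(states)
                for i, nid in enumerate(internal):
                    lab[nid] = (bits >> i) & 1
                p = rates.stationary[lab[tree.root.id]]
                for n in tree.preorder():
                    if n.parent is not None:
                        p *= mats[n.id][lab[n.parent.id], lab[n.id]]
                total += p
            assert prune_likelihood(tree, states, rates) == pytest.approx(
                np.log(total), abs=1e-10
            )

    def test_posteriors_match_enumeration_on_random_trees(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 7))  # at most 5 internal nodes
            tree = random_binary_tree(rng, n, 0.1, 2.0)
            rates = RateModel(float(rng.uniform(0.1, 2)), float(rng.uniform(0.1, 2)))
            states = {l: int(rng.integers(0, 2)) for l in tree.leaf_ids()}
            m = pd.DataFrame({k: [v] for k, v in states.items()})
            got = ml_marginal_posteriors(tree, m, rates)
            want = ml_posteriors_brute_force(tree, states, rates)
            for nid, p in want.items():
                assert abs(got.at[nid, 0] - p) < 1e-8

    def test_posteriors_approach_one_when_loss_vanishes(self):
        tree = SpeciesTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = pd.DataFrame({l: [1] for l in "ABCD"})
        post = ml_marginal_posteriors(tree, m, RateModel(0.5, 1e-6))
        assert (post.iloc[:, 0] > 0.999).all()

    def test_rate_recovery_from_simulated_characters(self, rng):
        tree = random_binary_tree(rng, 20, 0.2, 1.0)
        true = RateModel(0.8, 1.6)
        cols = {}
        order = list(tree.preorder())
        for c in range(500):
            lab = {}
            for node in order:
                if node.parent is None:
                    lab[node.id] = int(rng.random() < true.stationary[1])
                else:
                    row = true.transition(node.length)[lab[node.parent.id]]
                    lab[node.id] = int(rng.random() < row[1])
            cols[c] = [lab[l] for l in tree.leaf_ids()]
        matrix = pd.DataFrame(cols, index=tree.leaf_ids()).T
        fit = ml_fit_rates(tree, matrix)
        assert fit.q01 == pytest.approx(true.q01, rel=0.5)
        assert fit.q10 == pytest.approx(true.q10, rel=0.5)

    def test_fitted_rates_swap_under_label_swap(self, rng):
        tree = random_binary_tree(rng, 10, 0.2, 1.0)
        data = (np.arange(40).reshape(4, 10) % 2).astype(np.int8)
        rng.shuffle(data.ravel())
        m = pd.DataFrame(data, columns=tree.leaf_ids())
        fit = ml_fit_rates(tree, m)
        fit_swapped = ml_fit_rates(tree, 1 - m)
        assert fit.q01 == pytest.approx(fit_swapped.q10, rel=1e-3)
        assert fit.q10 == pytest.approx(fit_swapped.q01, rel=1e-3)


class TestCallPresence:
    def make_scores(self, gene, ngp):
        g = pd.DataFrame(gene, index=["N"])
        n = pd.DataFrame(ngp, index=["N"])
        return g, n

    def test_below_cutoff_removed_and_boundary_kept(self):
        g, n = self.make_scores(
            {"1": [0.95], "2": [0.95]}, {"1:t~2:h": [0.89]}
        )
        calls = call_presence(g, n, Cutoffs(0.9, 0.9))
        assert calls["N"].ngps == {}
        g, n = self.make_scores({"1": [0.9], "2": [0.9]}, {"1:t~2:h": [0.9]})
        calls = call_presence(g, n, Cutoffs(0.9, 0.9))
        assert set(calls["N"].ngps) == {"1:t~2:h"}
        assert calls["N"].families == {"1", "2"}

    def test_consistency_filter_drops_ngp_with_absent_family(self):
        g, n = self.make_scores({"1": [0.95], "2": [0.2]}, {"1:t~2:h": [0.99]})
        calls = call_presence(g, n, Cutoffs(0.9, 0.9))
        assert calls["N"].ngps == {}
        assert calls["N"].dropped_ngps == ["1:t~2:h"]

    def test_raising_pair_cutoff_never_adds_ngps(self):
        rng = np.random.default_rng(7)
        fams = {str(i): rng.uniform(0.5, 1.0, 3).tolist() for i in range(6)}
        ngps = {
            f"{i}:t~{i + 1}:h": rng.uniform(0.5, 1.0, 3).tolist() for i in range(5)
        }
        g = pd.DataFrame(fams, index=list("XYZ"))
        n = pd.DataFrame(ngps, index=list("XYZ"))
        previous = None
        for cut in (0.55, 0.7, 0.85, 0.95):
            calls = call_presence(g, n, Cutoffs(cut, 0.6))
            current = {nid: set(c.ngps) for nid, c in calls.items()}
            if previous is not None:
                assert all(current[nid] <= previous[nid] for nid in current)
            previous = current
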