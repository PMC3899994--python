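"""Ancestral presence/absence reconstruction for binary characters.

Two engines are provided, matching the two reconstruction criteria:

* Maximum parsimony: Fitch's algorithm on binary states, with a
  determinate up-pass (within an ambiguity set the parent's resolved
  state is preferred, and root ambiguity resolves to absence — the
  conservative choice).

* Maximum likelihood: a two-state continuous-time Markov chain with
  gain rate ``q01`` and loss rate ``q10``; Felsenstein pruning for the
  likelihood, bounded multi-start optimization for the rates, and the
  standard two-pass (below-partials / above-contributions) computation
  of per-node marginal posteriors.  The root prior defaults to the
  chain's stationary distribution.

All computations are vectorized across characters: matrices are
pandas DataFrames with one row per character and one column per genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from paleogen.characters import NGP
from paleogen.genome_io import SpeciesTree, TreeNode

BRANCH_EPSILON = 1e-6  # substitute for zero/missing branch lengths in ML
RATE_BOUNDS = (1e-6, 1e3)


@dataclass
class RateModel:
    """Two-state gain/loss rate model (rates per unit branch length)."""

    q01: float  # gain: absent -> present
    q10: float  # loss: present -> absent

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0 or (self.q01 == 0 and self.q10 == 0):
            raise ValueError("rates must be >= 0 and not both zero")

    @property
    def stationary(self) -> np.ndarray:
        s = self.q01 + self.q10
        return np.array([self.q10 / s, self.q01 / s])

    def transition(self, t: float) -> np.ndarray:
        """Closed-form 2x2 transition matrix P(t)."""
        s = self.q01 + self.q10
        e = np.exp(-s * max(t, BRANCH_EPSILON))
        return np.array(
            [
                [(self.q10 + self.q01 * e) / s, self.q01 * (1 - e) / s],
                [self.q10 * (1 - e) / s, (self.q01 + self.q10 * e) / s],
            ]
        )


@dataclass
class Cutoffs:
    """Posterior thresholds for calling presence (>= convention)."""

    gene_pair_cutoff: float = 0.9
    gene_occurrence_cutoff: float = 0.9

    def __post_init__(self) -> None:
        for v in (self.gene_pair_cutoff, self.gene_occurrence_cutoff):
            if not 0.0 < v < 1.0:
                raise ValueError("cutoffs must lie in (0, 1)")


# ---------------------------------------------------------------------------
# maximum parsimony

def mp_reconstruct(tree: SpeciesTree, matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Fitch reconstruction of all characters at all internal nodes.

    Returns ``(states, changes)``: a 0/1 DataFrame indexed by internal
    node ID, and the per-character minimum change count.
    """
    n_chars = len(matrix)
    masks: dict[str, np.ndarray] = {}  # state-set bitmask: 1={0}, 2={1}, 3={0,1}
    changes = np.zeros(n_chars, dtype=np.int64)
    for node in tree.postorder():
        if node.is_leaf:
            obs = matrix[node.id].to_numpy()
            masks[node.id] = np.where(obs == 1, 2, 1).astype(np.int8)
        else:
            left, right = (masks[c.id] for c in node.children)
            inter = left & right
            union = left | right
            masks[node.id] = np.where(inter > 0, inter, union).astype(np.int8)
            changes += inter == 0

    resolved: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        mask = masks[node.id]
        if node.parent is None:
            # root ambiguity resolves to absence
            state = np.where(mask == 2, 1, 0)
        else:
            parent = resolved[node.parent.id]
            state = np.where(mask == 3, parent, np.where(mask == 2, 1, 0))
        resolved[node.id] = state.astype(np.int8)

    internal = [n.id for n in tree.internal_nodes()]
    states = pd.DataFrame(
        {nid: resolved[nid] for nid in internal}, index=matrix.index
    ).T
    return states, pd.Series(changes, index=matrix.index)


def mp_min_changes_exhaustive(tree: SpeciesTree, leaf_states: dict[str, int]) -> int:
    """Brute-force minimum change count over all internal labelings.

    Independent oracle for small trees (exponential in node count).
    """
    internal = [n.id for n in tree.internal_nodes()]
    edges = [
        (n.parent.id, n.id) for n in tree.preorder() if n.parent is not None
    ]
    best = None
    for bits in range(2 ** len(internal)):
        lab = dict(leaf_states)
        for i, nid in enumerate(internal):
            lab[nid] = (bits >> i) & 1
        cost = sum(lab[a] != lab[b] for a, b in edges)
        best = cost if best is None else min(best, cost)
    return int(best)


# ---------------------------------------------------------------------------
# maximum likelihood

def _branch_matrices(tree: SpeciesTree, rates: RateModel) -> dict[str, np.ndarray]:
    return {
        node.id: rates.transition(node.length)
        for node in tree.preorder()
        if node.parent is not None
    }


def _below_partials(
    tree: SpeciesTree, obs: dict[str, np.ndarray], rates: RateModel
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Scaled below-partials per node and per-child upward messages.

    Returns (partials, logscale, messages) where ``messages[child_id]``
    is the child's partial propagated through its branch, evaluated at
    the parent: M_c[i] = sum_j P_c[i, j] * L_c[j].
    """
    mats = _branch_matrices(tree, rates)
    partials: dict[str, np.ndarray] = {}
    logscale: dict[str, np.ndarray] = {}
    messages: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            states = obs[node.id]
            part = np.zeros((len(states), 2))
            part[np.arange(len(states)), states] = 1.0
            partials[node.id] = part
            logscale[node.id] = np.zeros(len(states))
        else:
            prod = None
            scale = None
            for child in node.children:
                msg = partials[child.id] @ mats[child.id].T
                messages[child.id] = msg
                prod = msg if prod is None else prod * msg
                scale = (
                    logscale[child.id]
                    if scale is None
                    else scale + logscale[child.id]
                )
            mx = prod.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            partials[node.id] = prod / mx[:, None]
            logscale[node.id] = scale + np.log(mx)
    return partials, logscale, messages


def prune_loglik(tree: SpeciesTree, matrix: pd.DataFrame, rates: RateModel) -> np.ndarray:
    """Per-character log-likelihood of the leaf states (pruning algorithm)."""
    obs = {leaf.id: matrix[leaf.id].to_numpy() for leaf in tree.leaves()}
    partials, logscale, _ = _below_partials(tree, obs, rates)
    root = tree.root.id
    lik = partials[root] @ rates.stationary
    return np.log(lik) + logscale[root]


def prune_likelihood(tree: SpeciesTree, leaf_states: dict[str, int], rates: RateModel) -> float:
    """Log-likelihood of a single character (thin wrapper)."""
    matrix = pd.DataFrame({k: [v] for k, v in leaf_states.items()})
    return float(prune_loglik(tree, matrix, rates)[0])


def ml_fit_rates(
    tree: SpeciesTree,
    matrix: pd.DataFrame,
    bounds: tuple[float, float] = RATE_BOUNDS,
) -> RateModel:
    """Fit (q01, q10) by maximizing the summed pruning log-likelihood.

    Characters are pattern-compressed first; the search runs in log-rate
    space with several starts to dodge local optima.
    """
    leaf_ids = [leaf.id for leaf in tree.leaves()]
    cols = matrix[leaf_ids].to_numpy()
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    if len(patterns) == 1 and (patterns[0].min() == patterns[0].max()):
        warnings.warn("all characters constant; returning boundary minimum-rate model")
        return RateModel(bounds[0], bounds[0])
    compressed = pd.DataFrame(patterns, columns=leaf_ids)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def neg_ll(x: np.ndarray) -> float:
        rates = RateModel(float(np.exp(x[0])), float(np.exp(x[1])))
        ll = prune_loglik(tree, compressed, rates)
        return float(-(counts * ll).sum())

    starts = [(-2.3, -2.3), (0.0, 0.0), (-4.6, -1.0), (-1.0, -4.6)]
    best = None
    for x0 in starts:
        res = minimize(
            neg_ll, np.array(x0), method="L-BFGS-B", bounds=[(lo, hi), (lo, hi)]
        )
        if best is None or res.fun < best.fun:
            best = res
    return RateModel(float(np.exp(best.x[0])), float(np.exp(best.x[1])))


def ml_marginal_posteriors(
    tree: SpeciesTree,
    matrix: pd.DataFrame,
    rates: RateModel,
    root_prior: str = "stationary",
) -> pd.DataFrame:
    """Marginal posterior P(present) per internal node and character."""
    obs = {leaf.id: matrix[leaf.id].to_numpy() for leaf in tree.leaves()}
    partials, _, messages = _below_partials(tree, obs, rates)
    mats = _branch_matrices(tree, rates)
    if root_prior == "stationary":
        prior = rates.stationary
    elif root_prior == "uniform":
        prior = np.array([0.5, 0.5])
    else:
        raise ValueError(f"unknown root prior {root_prior!r}")

    n = len(matrix)
    above: dict[str, np.ndarray] = {tree.root.id: np.tile(prior, (n, 1))}
    for node in tree.preorder():
        for child in node.children:
            sib = tree.sibling(child)
            contrib = above[node.id] * messages[sib.id]
            down = contrib @ mats[child.id]
            mx = down.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            above[child.id] = down / mx[:, None]

    internal = [nd.id for nd in tree.internal_nodes()]
    out = {}
    for nid in internal:
        joint = above[nid] * partials[nid]
        total = joint.sum(axis=1)
        total = np.where(total > 0, total, 1.0)
        out[nid] = joint[:, 1] / total
    return pd.DataFrame(out, index=matrix.index).T


def ml_posteriors_brute_force(
    tree: SpeciesTree,
    leaf_states: dict[str, int],
    rates: RateModel,
    root_prior: str = "stationary",
) -> dict[str, float]:
    """Enumeration oracle: P(node=1 | leaves) by summing over all internal
    state assignments.  Exponential; for small trees only."""
    internal = [n.id for n in tree.internal_nodes()]
    mats = _branch_matrices(tree, rates)
    prior = rates.stationary if root_prior == "stationary" else np.array([0.5, 0.5])
    total = 0.0
    node_mass = {nid: 0.0 for nid in internal}
    for bits in range(2 ** len(internal)):
        lab = dict(leaf_states)
        for i, nid in enumerate(internal):
            lab[nid] = (bits >> i) & 1
        p = prior[lab[tree.root.id]]
        for node in tree.preorder():
            if node.parent is not None:
                p *= mats[node.id][lab[node.parent.id], lab[node.id]]
        total += p
        for nid in internal:
            if lab[nid] == 1:
                node_mass[nid] += p
    return {nid: node_mass[nid] / total for nid in internal}


# ---------------------------------------------------------------------------
# presence calling

@dataclass
class NodeCall:
    """Called character content of one ancestral node."""

    node_id: str
    families: set[str]
    ngps: dict[str, float]  # canonical NGP key -> score used for run weights
    dropped_ngps: list[str]  # NGPs removed by the family-consistency filter


def call_presence(
    gene_scores: pd.DataFrame,
    ngp_scores: pd.DataFrame,
    cutoffs: Cutoffs,
) -> dict[str, NodeCall]:
    """Threshold per-node scores into presence calls (>= convention).

    ``gene_scores``/``ngp_scores`` are internal-node-by-character frames
    holding ML posteriors, or 0/1 states for parsimony (which the same
    thresholds handle, as 1 >= cutoff > 0).  An NGP survives only if
    both member families are called present at the node.
    """
    calls: dict[str, NodeCall] = {}
    for nid in gene_scores.index:
        fams = {
            f
            for f, score in gene_scores.loc[nid].items()
            if score >= cutoffs.gene_occurrence_cutoff
        }
        ngps: dict[str, float] = {}
        dropped: list[str] = []
        for key, score in ngp_scores.loc[nid].items():
            if score < cutoffs.gene_pair_cutoff:
                continue
            fa, fb = NGP.from_key(key).families
            if fa in fams and fb in fams:
                ngps[key] = float(score)
            else:
                dropped.append(key)
        calls[nid] = NodeCall(nid, fams, ngps, dropped)
    return calls
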