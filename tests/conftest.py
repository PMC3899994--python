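"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from paleogen.genome_io import GeneRecord, Genome, GenomeSet, Replicon, SpeciesTree
from paleogen.simulator import DEFAULT_RATES


def make_replicon(replicon_id, spec, genome_id="G", role="unknown", circular=False):
    """Build a replicon from a spec like [("1", "+"), ("*", "+"), ("2", "-")]."""
    genes = [
        GeneRecord(
            gene_id=f"{genome_id}.{replicon_id}.{i + 1}",
            genome_id=genome_id,
            replicon_id=replicon_id,
            position=i + 1,
            strand=strand,
            family=family,
        )
        for i, (family, strand) in enumerate(spec)
    ]
    return Replicon(replicon_id=replicon_id, genes=genes, role=role, circular=circular)


def make_genome(genome_id, replicon_specs, **kw):
    """replicon_specs: dict replicon_id -> list of (family, strand)."""
    g = Genome(genome_id=genome_id)
    for rid, spec in replicon_specs.items():
        g.replicons[rid] = make_replicon(rid, spec, genome_id=genome_id, **kw)
    return g


def zero_rates():
    return {k: 0.0 for k in DEFAULT_RATES}


def gene_only_rates(scale=1.0):
    """Moderate gene-scale event rates with replicon-scale events off."""
    rates = dict(DEFAULT_RATES)
    for k in ("replicon_gain", "replicon_merge", "replicon_split", "replicon_loss"):
        rates[k] = 0.0
    for k in rates:
        rates[k] *= scale
    return rates


def random_binary_tree(rng, n_leaves, branch_low=0.05, branch_high=1.0):
    """Random rooted binary tree with uniform branch lengths, own labels."""
    from paleogen.genome_io import TreeNode

    labels = [f"L{i}" for i in range(n_leaves)]

    def build(sub):
        node = TreeNode(length=float(rng.uniform(branch_low, branch_high)))
        if len(sub) == 1:
            node.id = sub[0]
            return node
        k = int(rng.integers(1, len(sub)))
        for part in (sub[:k], sub[k:]):
            child = build(part)
            child.parent = node
            node.children.append(child)
        return node

    root = build(labels)
    root.length = 0.0
    return SpeciesTree(root)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
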