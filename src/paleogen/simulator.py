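"""Genome evolution simulator: ground truth for reconstruction studies.

A random rooted bifurcating tree is generated, a root genome (by
default a 1,000-family chromosome plus a 200-family plasmid) is placed
at the root, and genomes evolve down every branch under Poisson counts
of gene-scale events (gain, loss, duplication, reversal, translocation,
transposition) and replicon-scale events (gain, merge, split, loss).
Every node's genome is retained along with a chronological event log
whose operands are fully concrete, so replaying the log from the root
reproduces every genome exactly.

Duplicated copies are emitted as singletons (``*``) by default, so the
simulator's output honors the no-paralog input contract of the
reconstruction pipeline; a flag emits true same-family copies for
studying upstream family refinement instead.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from paleogen.genome_io import (
    GeneRecord,
    Genome,
    GenomeSet,
    Replicon,
    SpeciesTree,
    TreeNode,
)

# genome representation: dict replicon_id -> list of [gene_id, family, strand]
SimGenome = dict

GENE_EVENTS = (
    "gene_gain",
    "gene_loss",
    "gene_duplication",
    "reversal",
    "translocation",
    "transposition",
)
REPLICON_EVENTS = ("replicon_gain", "replicon_merge", "replicon_split", "replicon_loss")

DEFAULT_RATES = {
    "gene_gain": 40.0,
    "gene_loss": 40.0,
    "gene_duplication": 5.0,
    "reversal": 20.0,
    "translocation": 2.0,
    "transposition": 8.0,
    "replicon_gain": 0.6,
    "replicon_merge": 0.4,
    "replicon_split": 0.4,
    "replicon_loss": 0.6,
}


@dataclass
class SimConfig:
    n_leaves: int = 21
    n_outgroup: int = 2
    root_chromosome: int = 1000
    root_plasmid: int = 200
    rates: dict = field(default_factory=lambda: dict(DEFAULT_RATES))
    branch_mean: float = 0.05  # exponential branch-length mean
    segment_p: float = 0.2  # geometric parameter for segment lengths
    duplicate_as_singleton: bool = True
    forced_events: dict = field(default_factory=dict)  # child node ID -> [event kind]

    def __post_init__(self) -> None:
        if self.n_leaves < 3:
            raise ValueError("need at least 3 leaves")
        bad = [k for k, v in self.rates.items() if v < 0]
        if bad:
            raise ValueError(f"negative rates: {bad}")


@dataclass
class Event:
    branch: str  # child node ID of the branch the event occurred on
    kind: str
    operands: tuple


@dataclass
class SimResult:
    tree: SpeciesTree
    genomes: dict  # node ID -> SimGenome
    events: list
    config: SimConfig

    def leaf_genomes(self) -> GenomeSet:
        """Extant genomes as the reconstruction would receive them.

        Families observed in exactly one leaf genome have no homologous
        counterpart elsewhere, so — as an ortholog-identification
        pipeline would — they are emitted as singleton genes (``*``).
        """
        counts: dict[str, int] = {}
        leaf_ids = self.tree.leaf_ids()
        for lid in leaf_ids:
            for fams in ({fam for _, fam, _ in genes if fam != "*"}
                         for genes in [sum(self.genomes[lid].values(), [])]):
                for fam in fams:
                    counts[fam] = counts.get(fam, 0) + 1
        out = []
        for lid in leaf_ids:
            sim = {
                rid: [
                    [gid, fam if counts.get(fam, 0) >= 2 else "*", strand]
                    for gid, fam, strand in genes
                ]
                for rid, genes in self.genomes[lid].items()
            }
            out.append(sim_to_genome(sim, lid))
        return GenomeSet(out)

    def node_genome(self, node_id: str) -> Genome:
        return sim_to_genome(self.genomes[node_id], node_id)

    def ancestor_genomes(self) -> GenomeSet:
        return GenomeSet(
            sim_to_genome(self.genomes[n.id], n.id)
            for n in self.tree.internal_nodes()
        )

    def outgroup_ids(self) -> list[str]:
        leaves = self.tree.leaf_ids()
        return leaves[-self.config.n_outgroup :] if self.config.n_outgroup else []


def sim_to_genome(sim: SimGenome, genome_id: str) -> Genome:
    genome = Genome(genome_id=genome_id)
    for rid, genes in sim.items():
        records = [
            GeneRecord(
                gene_id=gid,
                genome_id=genome_id,
                replicon_id=rid,
                position=i + 1,
                strand=strand,
                family=fam,
            )
            for i, (gid, fam, strand) in enumerate(genes)
        ]
        genome.replicons[rid] = Replicon(replicon_id=rid, genes=records)
    return genome


# ---------------------------------------------------------------------------
# tree generation

def generate_tree(
    n_leaves: int,
    rng: np.random.Generator,
    branch_mean: float = 0.05,
    n_outgroup: int = 0,
) -> SpeciesTree:
    """Random rooted binary topology by uniform recursive splitting.

    With ``n_outgroup`` > 0 the root separates an outgroup clade (the
    last labels) from the ingroup, mirroring study designs where
    designated outgroups anchor the root architecture.
    """
    labels = [f"G{i + 1:02d}" for i in range(n_leaves)]

    def build(sub: list[str]) -> TreeNode:
        node = TreeNode(length=float(rng.exponential(branch_mean)))
        if len(sub) == 1:
            node.id = sub[0]
            return node
        k = int(rng.integers(1, len(sub)))
        for part in (sub[:k], sub[k:]):
            child = build(part)
            child.parent = node
            node.children.append(child)
        return node

    if 0 < n_outgroup < n_leaves - 1:
        ingroup = build(labels[: n_leaves - n_outgroup])
        outclade = build(labels[n_leaves - n_outgroup :])
        root = TreeNode(length=0.0)
        for child in (ingroup, outclade):
            child.parent = root
            root.children.append(child)
    else:
        root = build(labels)
        root.length = 0.0
    return SpeciesTree(root)


# ---------------------------------------------------------------------------
# event application (pure functions of operands -> replay determinism)

def _total_genes(sim: SimGenome) -> int:
    return sum(len(g) for g in sim.values())


def _main_replicon(sim: SimGenome) -> str:
    return sorted(sim, key=lambda r: (-len(sim[r]), r))[0]


def apply_event(sim: SimGenome, kind: str, operands: tuple) -> None:
    """Apply one logged event in place.  Operands are fully concrete."""
    if kind == "gene_gain":
        rid, pos, family, gene_id = operands
        sim[rid].insert(pos, [gene_id, family, "+"])
    elif kind == "gene_loss":
        rid, pos = operands
        del sim[rid][pos]
        if not sim[rid] and len(sim) > 1:
            del sim[rid]
    elif kind == "gene_duplication":
        src_rid, src_pos, dst_rid, dst_pos, family, gene_id = operands
        strand = sim[src_rid][src_pos][2]
        sim[dst_rid].insert(dst_pos, [gene_id, family, strand])
    elif kind == "reversal":
        rid, start, length = operands
        seg = sim[rid][start : start + length]
        flip = {"+": "-", "-": "+"}
        sim[rid][start : start + length] = [
            [gid, fam, flip[s]] for gid, fam, s in reversed(seg)
        ]
    elif kind == "translocation":
        src_rid, start, length, dst_rid, dst_pos = operands
        seg = sim[src_rid][start : start + length]
        del sim[src_rid][start : start + length]
        sim[dst_rid][dst_pos:dst_pos] = seg
        if not sim[src_rid] and len(sim) > 1:
            del sim[src_rid]
    elif kind == "transposition":
        rid, start, length, dst_pos = operands
        seg = sim[rid][start : start + length]
        del sim[rid][start : start + length]
        sim[rid][dst_pos:dst_pos] = seg
    elif kind == "replicon_gain":
        src_rid, start, length, new_rid = operands
        seg = sim[src_rid][start : start + length]
        del sim[src_rid][start : start + length]
        sim[new_rid] = seg
        if not sim[src_rid] and len(sim) > 1:
            del sim[src_rid]
    elif kind == "replicon_merge":
        rid_a, rid_b = operands
        sim[rid_a].extend(sim[rid_b])
        del sim[rid_b]
    elif kind == "replicon_split":
        rid, boundary, new_rid = operands
        sim[new_rid] = sim[rid][boundary:]
        sim[rid] = sim[rid][:boundary]
    elif kind == "replicon_loss":
        (rid,) = operands
        del sim[rid]
    elif kind == "skipped":
        pass
    else:
        raise ValueError(f"unknown event kind {kind!r}")


class _Namer:
    """Deterministic fresh IDs for genes, families, and replicons."""

    def __init__(self) -> None:
        self.gene = 0
        self.family = 0
        self.replicon = 0

    def new_gene(self) -> str:
        self.gene += 1
        return f"g{self.gene:06d}"

    def new_family(self) -> str:
        self.family += 1
        return f"N{self.family:05d}"

    def new_replicon(self) -> str:
        self.replicon += 1
        return f"p{self.replicon:03d}"


def _sample_operands(
    sim: SimGenome,
    kind: str,
    rng: np.random.Generator,
    namer: _Namer,
    segment_p: float,
    duplicate_as_singleton: bool,
) -> tuple | None:
    """Draw concrete operands for one event, or None if inapplicable."""
    rids = sorted(sim)
    sizes = np.array([len(sim[r]) for r in rids], dtype=float)
    n = int(sizes.sum())

    def pick_replicon(weights: np.ndarray) -> str:
        total = weights.sum()
        if total <= 0:
            return rids[int(rng.integers(0, len(rids)))]
        return rids[int(rng.choice(len(rids), p=weights / total))]

    def seg_length(maximum: int) -> int:
        return int(min(1 + rng.geometric(segment_p), maximum))

    if kind == "gene_gain":
        rid = pick_replicon(sizes + 1.0)
        pos = int(rng.integers(0, len(sim[rid]) + 1))
        return (rid, pos, namer.new_family(), namer.new_gene())
    if kind == "gene_loss":
        if n == 0:
            return None
        rid = pick_replicon(sizes)
        return (rid, int(rng.integers(0, len(sim[rid]))))
    if kind == "gene_duplication":
        if n == 0:
            return None
        src = pick_replicon(sizes)
        src_pos = int(rng.integers(0, len(sim[src])))
        dst = pick_replicon(sizes + 1.0)
        dst_pos = int(rng.integers(0, len(sim[dst]) + 1))
        family = "*" if duplicate_as_singleton else sim[src][src_pos][1]
        return (src, src_pos, dst, dst_pos, family, namer.new_gene())
    if kind == "reversal":
        candidates = [r for r in rids if len(sim[r]) >= 2]
        if not candidates:
            return None
        weights = np.array([len(sim[r]) for r in candidates], dtype=float)
        rid = candidates[int(rng.choice(len(candidates), p=weights / weights.sum()))]
        length = seg_length(len(sim[rid]))
        start = int(rng.integers(0, len(sim[rid]) - length + 1))
        return (rid, start, length)
    if kind == "translocation":
        if len(rids) < 2 or n == 0:
            return None
        src_candidates = [r for r in rids if len(sim[r]) >= 1]
        src = src_candidates[int(rng.integers(0, len(src_candidates)))]
        length = seg_length(len(sim[src]))
        start = int(rng.integers(0, len(sim[src]) - length + 1))
        others = [r for r in rids if r != src]
        dst = others[int(rng.integers(0, len(others)))]
        dst_pos = int(rng.integers(0, len(sim[dst]) + 1))
        return (src, start, length, dst, dst_pos)
    if kind == "transposition":
        candidates = [r for r in rids if len(sim[r]) >= 2]
        if not candidates:
            return None
        rid = candidates[int(rng.integers(0, len(candidates)))]
        length = seg_length(max(len(sim[rid]) - 1, 1))
        start = int(rng.integers(0, len(sim[rid]) - length + 1))
        dst_pos = int(rng.integers(0, len(sim[rid]) - length + 1))
        return (rid, start, length, dst_pos)
    if kind == "replicon_gain":
        candidates = [r for r in rids if len(sim[r]) >= 3]
        if not candidates:
            return None
        src = candidates[int(rng.integers(0, len(candidates)))]
        length = seg_length(len(sim[src]) - 1)
        start = int(rng.integers(0, len(sim[src]) - length + 1))
        return (src, start, length, namer.new_replicon())
    if kind == "replicon_merge":
        if len(rids) < 2:
            return None
        a, b = rng.choice(len(rids), size=2, replace=False)
        return (rids[int(a)], rids[int(b)])
    if kind == "replicon_split":
        candidates = [r for r in rids if len(sim[r]) >= 2]
        if not candidates:
            return None
        rid = candidates[int(rng.integers(0, len(candidates)))]
        boundary = int(rng.integers(1, len(sim[rid])))
        return (rid, boundary, namer.new_replicon())
    if kind == "replicon_loss":
        main = _main_replicon(sim)
        others = [r for r in rids if r != main]
        if not others:
            return None  # the main chromosome is immune; a genome keeps >= 1 replicon
        return (others[int(rng.integers(0, len(others)))],)
    raise ValueError(f"unknown event kind {kind!r}")


def evolve_branch(
    sim: SimGenome,
    t: float,
    config: SimConfig,
    rng: np.random.Generator,
    namer: _Namer,
    branch_id: str = "",
    forced: Iterable[str] = (),
) -> tuple[SimGenome, list[Event]]:
    """Evolve a genome along one branch; returns (new genome, events)."""
    genome = copy.deepcopy(sim)
    kinds: list[str] = []
    for kind in GENE_EVENTS + REPLICON_EVENTS:
        rate = config.rates.get(kind, 0.0)
        kinds.extend([kind] * int(rng.poisson(rate * t)))
    kinds.extend(forced)
    kinds = list(np.array(kinds, dtype=object)[rng.permutation(len(kinds))]) if kinds else []
    events: list[Event] = []
    for kind in kinds:
        operands = _sample_operands(
            genome, kind, rng, namer, config.segment_p, config.duplicate_as_singleton
        )
        if operands is None:
            events.append(Event(branch_id, "skipped", (kind,)))
            continue
        apply_event(genome, kind, operands)
        events.append(Event(branch_id, kind, operands))
    return genome, events


def root_genome(config: SimConfig, rng: np.random.Generator, namer: _Namer) -> SimGenome:
    sim: SimGenome = {}
    specs = [("chr", config.root_chromosome), ("pls", config.root_plasmid)]
    fam = 0
    for rid, size in specs:
        if size <= 0:
            continue
        genes = []
        for _ in range(size):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append([namer.new_gene(), f"F{fam:04d}", strand])
            fam += 1
        sim[rid] = genes
    return sim


def simulate(config: SimConfig, seed: int = 0) -> SimResult:
    """Full simulation: tree, root genome, branch-wise evolution."""
    rng = np.random.default_rng(seed)
    namer = _Namer()
    tree = generate_tree(config.n_leaves, rng, config.branch_mean, config.n_outgroup)
    genomes: dict[str, SimGenome] = {tree.root.id: root_genome(config, rng, namer)}
    events: list[Event] = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        child_genome, evs = evolve_branch(
            genomes[node.parent.id],
            node.length,
            config,
            rng,
            namer,
            branch_id=node.id,
            forced=config.forced_events.get(node.id, ()),
        )
        genomes[node.id] = child_genome
        events.extend(evs)
    return SimResult(tree, genomes, events, config)


def replay(result: SimResult) -> dict:
    """Re-derive every node genome from the root genome and event log."""
    by_branch: dict[str, list[Event]] = {}
    for ev in result.events:
        by_branch.setdefault(ev.branch, []).append(ev)
    genomes = {result.tree.root.id: copy.deepcopy(result.genomes[result.tree.root.id])}
    for node in result.tree.preorder():
        if node.parent is None:
            continue
        genome = copy.deepcopy(genomes[node.parent.id])
        for ev in by_branch.get(node.id, []):
            apply_event(genome, ev.kind, ev.operands)
        genomes[node.id] = genome
    return genomes


def write_events_tsv(events: Iterable[Event], path) -> None:
    from pathlib import Path

    lines = ["branch\tkind\toperands"]
    for ev in events:
        lines.append(f"{ev.branch}\t{ev.kind}\t{','.join(map(str, ev.operands))}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
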