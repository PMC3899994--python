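"""Replicon architecture reconstruction for ancestral genomes.

Families called present at a node are partitioned into co-inheritance
groups — sets of genes sitting on the same replicon pair in the node's
two children.  Groups become vertices of a group graph (edges where two
patterns share a replicon in the same child); an outgroup's group graph
says which groups belonged together ancestrally: for each connected
component of the outgroup graph, the target groups linked to it (by
sharing at least ``min_shared_genes`` families) are merged wherever the
target graph connects them.  Unmerged groups become their own replicons.

Because this procedure over-splits in practice, a correction step scans
the reconstructed gene runs for replicon discrepancies: a run of at
least ``min_run_length`` genes spread over two replicons yields a merge
proposal with absolute strength = run length (summed per replicon pair
and node) and relative strength N2/(N1+N2), where N1 genes sit on the
run's modal replicon and N2 on the challenger.  Proposals pooled over
all nodes are split by 2-means clustering on the standardized signal
pair; the stronger cluster is accepted and its replicon pairs merged.

Finally chromosomes are restored from core genes: the replicon with the
most core genes is the main chromosome, and any other replicon carrying
at least 5% of all core genes is a secondary chromosome; the rest are
plasmids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
from sklearn.cluster import KMeans

from paleogen.genome_io import Genome


class ArchitectureError(ValueError):
    pass


@dataclass
class RepliconAssignment:
    """Partition of one node's families across named replicons."""

    node_id: str
    members: dict[str, set[str]] = field(default_factory=dict)  # replicon -> families
    roles: dict[str, str] = field(default_factory=dict)

    def replicon_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for rid, fams in self.members.items():
            for f in fams:
                out[f] = rid
        return out

    def n_replicons(self) -> int:
        return len(self.members)

    def families(self) -> set[str]:
        out: set[str] = set()
        for fams in self.members.values():
            out |= fams
        return out

    @classmethod
    def from_genome(cls, genome: Genome) -> "RepliconAssignment":
        members = {
            rid: rep.family_set() for rid, rep in genome.replicons.items()
        }
        roles = {rid: rep.role for rid, rep in genome.replicons.items()}
        return cls(genome.genome_id, members, roles)


@dataclass(frozen=True)
class Group:
    """Co-inheritance group: families sharing one inheritance pattern."""

    index: int
    members: frozenset
    pattern: tuple  # one (slot-aligned) replicon ID or None per child


def co_inheritance_groups(
    called_families: Iterable[str],
    child_assignments: Sequence[RepliconAssignment],
) -> tuple[list[Group], set[str]]:
    """Group the node's families by their (replicon-in-child1,
    replicon-in-child2) pattern.

    Only families residing on a replicon in *both* children are
    co-inherited; the rest (absent from one or both children) carry no
    joint inheritance signal and are returned as unplaced, to be
    attached after assembly via their gene-run companions.
    """
    if not child_assignments:
        raise ArchitectureError("child replicon assignments missing (bottom-up order)")
    maps = [a.replicon_of() for a in child_assignments]
    by_pattern: dict[tuple, set[str]] = {}
    unplaced: set[str] = set()
    for fam in sorted(set(called_families)):
        pattern = tuple(m.get(fam) for m in maps)
        if any(p is None for p in pattern):
            unplaced.add(fam)
        else:
            by_pattern.setdefault(pattern, set()).add(fam)
    groups = [
        Group(i, frozenset(mem), pat)
        for i, (pat, mem) in enumerate(
            sorted(by_pattern.items(), key=lambda kv: tuple(str(p) for p in kv[0]))
        )
    ]
    return groups, unplaced


def leaf_groups(assignment: RepliconAssignment) -> list[Group]:
    """Observed genome as trivial groups: one per replicon."""
    return [
        Group(i, frozenset(fams), (rid,))
        for i, (rid, fams) in enumerate(sorted(assignment.members.items()))
    ]


def build_group_graph(groups: Sequence[Group]) -> nx.Graph:
    """Edges between groups whose patterns share a replicon in some child."""
    g = nx.Graph()
    g.add_nodes_from(gr.index for gr in groups)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            if len(ga.pattern) != len(gb.pattern):
                continue
            if any(
                pa is not None and pa == pb
                for pa, pb in zip(ga.pattern, gb.pattern)
            ):
                g.add_edge(ga.index, gb.index)
    return g


def cross_link(
    target_groups: Sequence[Group],
    outgroup_groups: Sequence[Group],
    min_shared_genes: int = 3,
    min_shared_frac: float = 0.2,
) -> list[tuple[int, int, int]]:
    """Links (target index, outgroup index, n shared) between groups
    sharing enough families: at least ``min_shared_genes`` (or the whole
    smaller group, when it has fewer members than that) and at least
    ``min_shared_frac`` of the smaller group (>= convention).

    The relative component keeps a large group from anchoring to a
    foreign outgroup group through a few stray (translocated) genes;
    capping the absolute demand at the smaller group's size lets a
    fully-contained small group (e.g. a short translocated segment)
    still find its anchor instead of stranding as its own replicon.
    """
    import math

    links: list[tuple[int, int, int]] = []
    for tg in target_groups:
        for og in outgroup_groups:
            smaller = min(len(tg.members), len(og.members))
            need = max(
                min(min_shared_genes, smaller),
                math.ceil(min_shared_frac * smaller),
            )
            shared = len(tg.members & og.members)
            if shared >= need:
                links.append((tg.index, og.index, shared))
    return links


def assemble_replicons(
    node_id: str,
    target_groups: Sequence[Group],
    target_graph: nx.Graph,
    links: Sequence[tuple[int, int, int]],
    unplaced: Iterable[str] = (),
    runs=None,
) -> RepliconAssignment:
    """Merge target groups back into replicons under outgroup guidance.

    Each linked target group follows its *dominant* anchor — the
    outgroup group it shares the most genes with.  Two target groups
    merge when they are adjacent in the target graph and their dominant
    anchors coincide.  (Merging every pair that falls in the same
    outgroup component is too transitive: one small translocated group
    on either side chains the chromosome and plasmid groups into a
    single replicon, and over-merging — unlike over-splitting — cannot
    be corrected downstream.  A group pooling translocations from both
    child lineages may genuinely link to two outgroup groups; majority
    sharing decides its ancestral home.)  Groups never linked or never
    merged form their own replicons.  Unplaced families attach to the
    replicon holding the majority of their gene-run companions, else to
    the largest replicon.
    """
    by_index = {g.index: g for g in target_groups}
    best_link: dict[int, tuple[int, int]] = {}  # target -> (shared, -outgroup)
    for ti, oi, shared in links:
        cand = (shared, -oi)
        if ti not in best_link or cand > best_link[ti]:
            best_link[ti] = cand
    dominant = {ti: -neg for ti, (_, neg) in best_link.items()}

    uf = nx.utils.UnionFind(by_index.keys())
    for ti, tj in sorted(tuple(sorted(e)) for e in target_graph.edges):
        if ti in dominant and tj in dominant and dominant[ti] == dominant[tj]:
            uf.union(ti, tj)

    clusters: dict[int, list[int]] = {}
    for idx in by_index:
        clusters.setdefault(uf[idx], []).append(idx)
    merged = sorted(
        (sorted(set().union(*(by_index[i].members for i in idxs))) for idxs in clusters.values()),
        key=lambda fams: fams[0],
    )
    assignment = RepliconAssignment(node_id)
    for k, fams in enumerate(merged):
        assignment.members[f"{node_id}|r{k}"] = set(fams)

    unplaced = sorted(set(unplaced))
    if unplaced:
        rep_of = assignment.replicon_of()
        run_index: dict[str, list[str]] = {}
        if runs is not None:
            for run in runs.runs:
                for fam in run.families:
                    run_index[fam] = run.families
        largest = max(
            assignment.members,
            key=lambda rid: (len(assignment.members[rid]), rid),
            default=None,
        )
        for fam in unplaced:
            target = None
            mates = run_index.get(fam, [])
            votes: dict[str, int] = {}
            for mate in mates:
                rid = rep_of.get(mate)
                if rid is not None:
                    votes[rid] = votes.get(rid, 0) + 1
            if votes:
                target = max(sorted(votes), key=lambda r: votes[r])
            elif largest is not None:
                target = largest
            if target is None:
                target = f"{node_id}|r0"
                assignment.members.setdefault(target, set())
            assignment.members[target].add(fam)
            rep_of[fam] = target
    return assignment


# ---------------------------------------------------------------------------
# gene-run-driven replicon merge

@dataclass
class MergeProposal:
    node_id: str
    pair: tuple[str, str]  # sorted replicon IDs
    absolute: float  # summed supporting run lengths
    relative: float  # N2 / (N1 + N2)


def run_merge_signal(
    run_families: Sequence[str],
    assignment: RepliconAssignment,
    min_run_length: int = 4,
    low_signal: float = 0.1,
) -> MergeProposal | None:
    """Merge proposal from one gene run's replicon discrepancy, if any."""
    if len(run_families) < min_run_length:
        return None
    rep_of = assignment.replicon_of()
    counts: dict[str, int] = {}
    for fam in run_families:
        rid = rep_of.get(fam)
        if rid is not None:
            counts[rid] = counts.get(rid, 0) + 1
    if len(counts) < 2:
        return None
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    (r1, n1), (r2, n2) = ranked[0], ranked[1]
    relative = n2 / (n1 + n2)
    if relative < low_signal:
        return None
    return MergeProposal(
        assignment.node_id, tuple(sorted((r1, r2))), float(len(run_families)), relative
    )


def pool_proposals(proposals: Iterable[MergeProposal]) -> list[MergeProposal]:
    """Sum absolute strengths per (node, replicon pair); the relative
    signal becomes the strength-weighted mean."""
    acc: dict[tuple[str, tuple[str, str]], list[MergeProposal]] = {}
    for p in proposals:
        acc.setdefault((p.node_id, p.pair), []).append(p)
    pooled: list[MergeProposal] = []
    for (nid, pair), plist in sorted(acc.items()):
        total = sum(p.absolute for p in plist)
        rel = sum(p.relative * p.absolute for p in plist) / total
        pooled.append(MergeProposal(nid, pair, total, rel))
    return pooled


def cluster_proposals(
    proposals: Sequence[MergeProposal],
    seed: int = 0,
    degenerate_abs: float = 8.0,
    degenerate_rel: float = 0.25,
) -> list[MergeProposal]:
    """Accept the stronger of two K-means clusters of pooled proposals.

    Signals are z-scored before clustering; the cluster whose centroid
    has the larger norm is accepted.  With fewer than two distinct
    signal points no separation exists: a lone proposal is accepted iff
    it clears both fixed fallback thresholds, identical proposals are
    all rejected.
    """
    if not proposals:
        return []
    x = np.array([[p.absolute, p.relative] for p in proposals], dtype=float)
    distinct = np.unique(x, axis=0)
    if len(proposals) < 2:
        p = proposals[0]
        ok = p.absolute >= degenerate_abs and p.relative >= degenerate_rel
        return [p] if ok else []
    if len(distinct) < 2:
        return []
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(z)
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    # accepted cluster: centroid farther along (+abs, +rel); compare on
    # the summed standardized coordinates so "stronger" is directional
    strength = km.cluster_centers_.sum(axis=1)
    accept = int(np.argmax(strength)) if strength[0] != strength[1] else int(np.argmax(norms))
    return [p for p, lab in zip(proposals, km.labels_) if lab == accept]


def apply_merges(
    assignment: RepliconAssignment, accepted: Iterable[MergeProposal]
) -> RepliconAssignment:
    """Union accepted replicon pairs (transitively) for one node."""
    pairs = [p.pair for p in accepted if p.node_id == assignment.node_id]
    if not pairs:
        return assignment
    uf = nx.utils.UnionFind(assignment.members.keys())
    for a, b in pairs:
        if a in assignment.members and b in assignment.members:
            uf.union(a, b)
    merged: dict[str, set[str]] = {}
    for rid in sorted(assignment.members):
        merged.setdefault(uf[rid], set()).update(assignment.members[rid])
    out = RepliconAssignment(assignment.node_id)
    for k, root in enumerate(sorted(merged, key=lambda r: min(merged[r]) if merged[r] else r)):
        out.members[f"{assignment.node_id}|R{k}"] = merged[root]
    return out


def restore_chromosomes(
    assignment: RepliconAssignment,
    core: set[str],
    threshold: float = 0.05,
) -> RepliconAssignment:
    """Label replicons: most core genes -> main chromosome; at least
    ``threshold`` of all core genes -> secondary chromosome; else plasmid.
    Ties for the main chromosome break by total gene count, then ID."""
    if not assignment.members:
        return assignment
    n_core = max(len(core), 1)

    def core_count(rid: str) -> int:
        return len(assignment.members[rid] & core)

    main = sorted(
        assignment.members,
        key=lambda rid: (-core_count(rid), -len(assignment.members[rid]), rid),
    )[0]
    roles: dict[str, str] = {}
    for rid in assignment.members:
        if rid == main:
            roles[rid] = "main_chromosome"
        elif core_count(rid) >= threshold * n_core:
            roles[rid] = "secondary_chromosome"
        else:
            roles[rid] = "plasmid"
    assignment.roles = roles
    return assignment
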