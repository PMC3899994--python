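"""Branch-wise evolutionary event inference.

Parent and child reconstructions are compared along every branch:
family set differences give gene gains and losses; a bipartite mapping
of replicons by shared families yields replicon splits, merges, gains
and losses; parent gene runs are tracked into the child to classify
their fate (conserved / extended / fragmented / lost) and to detect
reversals — maximal shared run segments whose order and strands are
both inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from paleogen.replicons import RepliconAssignment
from paleogen.runs import GeneRun, RunSet


@dataclass
class RepliconEvent:
    kind: str  # "split" | "merge" | "gain" | "loss"
    parents: tuple[str, ...]
    children: tuple[str, ...]


@dataclass
class Reversal:
    parent_run: GeneRun
    child_run: GeneRun
    segment: tuple[str, ...]  # families of the inverted stretch


@dataclass
class BranchEvents:
    parent_id: str
    child_id: str
    gains: set[str] = field(default_factory=set)
    losses: set[str] = field(default_factory=set)
    replicon_events: list[RepliconEvent] = field(default_factory=list)
    reversals: list[Reversal] = field(default_factory=list)
    run_fates: list[tuple[GeneRun, object]] = field(default_factory=list)


def gene_flux(parent_set: set[str], child_set: set[str]) -> tuple[set[str], set[str]]:
    """(gains, losses) of families along a branch."""
    return child_set - parent_set, parent_set - child_set


def map_replicons(
    parent: RepliconAssignment,
    child: RepliconAssignment,
    min_shared: int = 3,
    min_frac: float = 0.2,
) -> list[RepliconEvent]:
    """Replicon-scale events from a shared-family bipartite mapping.

    Two replicons correspond when they share at least
    ``max(min_shared, min_frac * size of the smaller)`` families.  A
    parent mapping to two or more children is a split; two or more
    parents collapsing onto one child is a merge; unmapped replicons
    are losses (parent side) or gains (child side).
    """
    links: dict[str, list[str]] = {p: [] for p in parent.members}
    rlinks: dict[str, list[str]] = {c: [] for c in child.members}
    for pid in sorted(parent.members):
        pfam = parent.members[pid]
        for cid in sorted(child.members):
            cfam = child.members[cid]
            smaller = min(len(pfam), len(cfam))
            if smaller == 0:
                continue
            need = max(min_shared, min_frac * smaller)
            if len(pfam & cfam) >= need:
                links[pid].append(cid)
                rlinks[cid].append(pid)
    events: list[RepliconEvent] = []
    for pid in sorted(parent.members):
        if len(links[pid]) >= 2:
            events.append(RepliconEvent("split", (pid,), tuple(links[pid])))
        elif not links[pid]:
            events.append(RepliconEvent("loss", (pid,), ()))
    for cid in sorted(child.members):
        if len(rlinks[cid]) >= 2:
            events.append(RepliconEvent("merge", tuple(rlinks[cid]), (cid,)))
        elif not rlinks[cid]:
            events.append(RepliconEvent("gain", (), (cid,)))
    return events


def _oriented_overlap(parent_run: GeneRun, child_run: GeneRun) -> GeneRun:
    """Child run oriented to maximize same-order agreement with the parent."""
    ppos = {f: i for i, (f, _) in enumerate(parent_run.genes)}

    def agreement(run: GeneRun) -> int:
        idx = [ppos[f] for f, _ in run.genes if f in ppos]
        return sum(1 for a, b in zip(idx, idx[1:]) if b > a)

    rev = child_run.reversed_()
    return child_run if agreement(child_run) >= agreement(rev) else rev


def detect_reversals(
    parent_runs: RunSet, child_runs: RunSet, min_segment: int = 2
) -> list[Reversal]:
    """Maximal shared segments inverted in both order and strand."""
    out: list[Reversal] = []
    for prun in parent_runs.runs:
        pfams = set(prun.families)
        for crun in child_runs.runs:
            if len(pfams & set(crun.families)) < 2:
                continue
            oriented = _oriented_overlap(prun, crun)
            cidx = {f: (i, s) for i, (f, s) in enumerate(oriented.genes)}
            pstrand = dict(prun.genes)
            shared = [(i, f) for i, (f, _) in enumerate(prun.genes) if f in cidx]
            seg: list[str] = []
            prev: int | None = None
            for fam in [f for _, f in shared] + [None]:
                if fam is not None:
                    ci, cs = cidx[fam]
                    flipped = cs != pstrand[fam]
                    if flipped and (prev is None or ci == prev - 1):
                        seg.append(fam)
                        prev = ci
                        continue
                if len(seg) >= min_segment:
                    out.append(Reversal(prun, crun, tuple(seg)))
                if fam is not None and cidx[fam][1] != pstrand[fam]:
                    seg, prev = [fam], cidx[fam][0]
                else:
                    seg, prev = [], None
    return out


def run_fate(
    parent_run: GeneRun, child_runs: Sequence[GeneRun], share: float = 0.8
) -> object:
    """Fate of a parent run in the child: "conserved", "extended",
    ("fragmented", k) or "lost" under the 80% gene-sharing rule."""
    pfams = set(parent_run.families)
    overlaps = sorted(
        (len(pfams & set(c.families)), len(c)) for c in child_runs
    )[::-1]
    if overlaps and overlaps[0][0] >= share * len(pfams):
        return "extended" if overlaps[0][1] > len(parent_run) else "conserved"
    covered = 0
    k = 0
    for ov, _ in overlaps:
        if ov == 0:
            break
        covered += ov
        k += 1
        if covered >= share * len(pfams):
            return ("fragmented", k)
    return "lost"


def branch_events(
    parent_id: str,
    child_id: str,
    parent_families: set[str],
    child_families: set[str],
    parent_assignment: RepliconAssignment,
    child_assignment: RepliconAssignment,
    parent_runs: RunSet,
    child_runs: RunSet,
    min_shared: int = 3,
    min_frac: float = 0.2,
) -> BranchEvents:
    gains, losses = gene_flux(parent_families, child_families)
    ev = BranchEvents(parent_id, child_id, gains, losses)
    ev.replicon_events = map_replicons(
        parent_assignment, child_assignment, min_shared, min_frac
    )
    ev.reversals = detect_reversals(parent_runs, child_runs)
    ev.run_fates = [
        (prun, run_fate(prun, child_runs.runs)) for prun in parent_runs.runs
    ]
    return ev
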