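"""Assembly of called NGPs into contiguous, stranded gene runs.

Every called family contributes its two ends as graph nodes joined by
an intra-gene edge (weight 1); every called NGP contributes one
inter-gene edge weighted by the reciprocal of its posterior (1 under
parsimony).  A minimum spanning forest (Kruskal, deterministic
tie-break) removes cycles; runs are then peeled off each fragment as
the best *legitimate* path — one whose edges strictly alternate
intra/inter and whose terminal edges are intra-gene, so every reported
gene is wholly included and carries an orientation.  Path scores equal
the sum of edge weights; on a tree all pairwise paths are unique, so a
linear dynamic program replaces explicit all-pairs shortest paths.

The default selection rule is the longest legitimate path (ties by
lowest score, then canonical key).  The alternative ``lowest-score``
rule — the literal cheapest path, which with all weights >= 1 is always
a two-gene run built from the cheapest inter-gene edge — is kept for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from paleogen.characters import HEAD, TAIL, NGP, GeneEnd

INTRA = "intra"
INTER = "inter"


class AssemblyError(ValueError):
    pass


@dataclass
class GeneRun:
    """An ordered, stranded string of families reconstructed as contiguous."""

    genes: list[tuple[str, str]]  # (family, strand)
    weight: float

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def families(self) -> list[str]:
        return [f for f, _ in self.genes]

    def signed_string(self) -> str:
        return "_".join(f"{s}{f}" for f, s in self.genes)

    def reversed_(self) -> "GeneRun":
        flip = {"+": "-", "-": "+"}
        return GeneRun([(f, flip[s]) for f, s in reversed(self.genes)], self.weight)

    def canonical(self) -> "GeneRun":
        rev = self.reversed_()
        return self if self.genes <= rev.genes else rev


@dataclass
class RunSet:
    """Gene runs of one node plus families left out of every run."""

    node_id: str
    runs: list[GeneRun] = field(default_factory=list)
    leftovers: set[str] = field(default_factory=set)

    def covered_families(self) -> set[str]:
        out: set[str] = set()
        for r in self.runs:
            out |= set(r.families)
        return out


def build_adjacency_graph(
    families: Iterable[str], ngps: Mapping[str, float]
) -> nx.Graph:
    """Weighted gene-end graph of one node's called content."""
    fams = set(families)
    g = nx.Graph()
    for fam in fams:
        h, t = GeneEnd(fam, HEAD), GeneEnd(fam, TAIL)
        g.add_edge(h, t, weight=1.0, kind=INTRA)
    for key, prob in ngps.items():
        ngp = NGP.from_key(key)
        fa, fb = ngp.families
        if fa not in fams or fb not in fams:
            raise AssemblyError(
                f"NGP {key} references a family not called present"
            )
        if not 0.0 < prob <= 1.0:
            raise AssemblyError(f"NGP {key} has probability {prob} outside (0, 1]")
        if g.has_edge(ngp.a, ngp.b):
            continue  # duplicate adjacency evidence; keep the first
        g.add_edge(ngp.a, ngp.b, weight=1.0 / prob, kind=INTER)
    return g


def _edge_key(u: GeneEnd, v: GeneEnd) -> tuple:
    a, b = sorted((u, v))
    return (a.family, a.end, b.family, b.end)


def minimum_spanning_forest(graph: nx.Graph) -> nx.Graph:
    """Kruskal spanning forest with deterministic tie-breaking.

    Edges are taken in order of (weight, canonical edge key), so equal
    weights always resolve the same way.
    """
    forest = nx.Graph()
    forest.add_nodes_from(graph.nodes)
    uf = nx.utils.UnionFind(graph.nodes)
    edges = sorted(
        graph.edges(data=True), key=lambda e: (e[2]["weight"], _edge_key(e[0], e[1]))
    )
    for u, v, data in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            forest.add_edge(u, v, **data)
    return forest


# ---------------------------------------------------------------------------
# legitimate paths

def _other(kind: str) -> str:
    return INTER if kind == INTRA else INTRA


@dataclass(frozen=True)
class _Path:
    genes: int
    weight: float
    nodes: tuple  # GeneEnd sequence

    @property
    def rank(self) -> tuple:
        # prefer more genes, then lower weight, then canonical node key
        return (-self.genes, self.weight, _canonical_nodes(self.nodes))


def _canonical_nodes(nodes: tuple) -> tuple:
    fwd = tuple((n.family, n.end) for n in nodes)
    rev = tuple(reversed(fwd))
    return min(fwd, rev)


def best_legitimate_path(tree: nx.Graph, nodes: Iterable[GeneEnd]) -> _Path | None:
    """Best alternating intra/inter path with intra terminal edges.

    Dynamic program over the tree fragment induced by ``nodes``:
    ``down[v][k]`` is the best path starting at v whose first edge has
    kind k and whose last edge is intra-gene; a through-path at v glues
    an intra-first and an inter-first branch (an end node has at most
    one intra edge, so the two branches are always distinct).
    Iterative traversal — fragments can be thousands of nodes deep.
    """
    nodes = sorted(set(nodes))
    if not nodes:
        return None
    adj: dict[GeneEnd, list[tuple[GeneEnd, str, float]]] = {n: [] for n in nodes}
    node_set = set(nodes)
    for u in nodes:
        for v in tree.neighbors(u):
            if v in node_set:
                data = tree.edges[u, v]
                adj[u].append((v, data["kind"], data["weight"]))
        adj[u].sort(key=lambda item: (item[0].family, item[0].end))

    root = nodes[0]
    order: list[GeneEnd] = []
    parent: dict[GeneEnd, GeneEnd | None] = {root: None}
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for v, _, _ in adj[u]:
            if v not in parent:
                parent[v] = u
                stack.append(v)

    down: dict[GeneEnd, dict[str, _Path | None]] = {}
    best: _Path | None = None

    def consider(p: _Path | None) -> None:
        nonlocal best
        if p is None or p.genes < 1:
            return
        if best is None or p.rank < best.rank:
            best = p

    for u in reversed(order):
        entry: dict[str, _Path | None] = {INTRA: None, INTER: None}
        for v, kind, w in adj[u]:
            if parent.get(v) is not u:
                continue  # only tree children
            cands: list[_Path] = []
            if kind == INTRA:
                cands.append(_Path(1, w, (u, v)))
                sub = down[v][INTER]
                if sub is not None:
                    cands.append(_Path(1 + sub.genes, w + sub.weight, (u,) + sub.nodes))
            else:
                sub = down[v][INTRA]
                if sub is not None:
                    cands.append(_Path(sub.genes, w + sub.weight, (u,) + sub.nodes))
            for c in cands:
                cur = entry[kind]
                if cur is None or c.rank < cur.rank:
                    entry[kind] = c
        down[u] = entry
        a, b = entry[INTRA], entry[INTER]
        consider(a)
        if a is not None and b is not None:
            consider(
                _Path(
                    a.genes + b.genes,
                    a.weight + b.weight,
                    tuple(reversed(a.nodes)) + b.nodes[1:],
                )
            )
    return best


def _cheapest_pair_path(tree: nx.Graph, nodes: list[GeneEnd]) -> _Path | None:
    """Literal lowest-score rule: cheapest inter edge plus its two genes."""
    node_set = set(nodes)
    best: tuple | None = None
    for u, v, data in tree.edges(data=True):
        if data["kind"] != INTER or u not in node_set or v not in node_set:
            continue
        ua = GeneEnd(u.family, HEAD if u.end == TAIL else TAIL)
        vb = GeneEnd(v.family, HEAD if v.end == TAIL else TAIL)
        if not (tree.has_edge(ua, u) and tree.has_edge(v, vb)):
            continue
        if ua not in node_set or vb not in node_set:
            continue
        path = _Path(2, 2.0 + data["weight"], (ua, u, v, vb))
        key = (path.weight, _canonical_nodes(path.nodes))
        if best is None or key < best[0]:
            best = (key, path)
    return None if best is None else best[1]


def _path_to_run(path: _Path) -> GeneRun:
    genes: list[tuple[str, str]] = []
    seq = path.nodes
    for i in range(0, len(seq), 2):
        left = seq[i]
        strand = "+" if left.end == HEAD else "-"
        genes.append((left.family, strand))
    return GeneRun(genes, path.weight).canonical()


def extract_gene_runs(
    forest: nx.Graph,
    node_id: str = "",
    min_run_genes: int = 2,
    path_rule: str = "longest",
) -> RunSet:
    """Peel legitimate paths off each fragment until nothing assembles.

    Selected paths are emitted as runs, their nodes deleted, and the
    fragment re-split; fragments that reduce to a single gene, or that
    admit no legitimate path of ``min_run_genes`` genes, surrender their
    families to the leftover set.
    """
    out = RunSet(node_id)
    components = sorted(
        (sorted(c) for c in nx.connected_components(forest)), key=lambda c: c[0]
    )
    work = list(components)
    while work:
        comp = work.pop(0)
        fams = {n.family for n in comp}
        if len(fams) < 2:
            out.leftovers |= fams
            continue
        if path_rule == "lowest-score":
            path = _cheapest_pair_path(forest, comp)
        else:
            path = best_legitimate_path(forest, comp)
        if path is None or path.genes < min_run_genes:
            out.leftovers |= fams
            continue
        out.runs.append(_path_to_run(path))
        removed = set(path.nodes)
        remaining = [n for n in comp if n not in removed]
        if remaining:
            sub = forest.subgraph(remaining)
            frags = sorted(
                (sorted(c) for c in nx.connected_components(sub)), key=lambda c: c[0]
            )
            work = frags + work
    return out


def assemble_node_runs(
    families: Iterable[str],
    ngps: Mapping[str, float],
    node_id: str = "",
    min_run_genes: int = 2,
    path_rule: str = "longest",
) -> RunSet:
    """Convenience wrapper: graph -> spanning forest -> runs."""
    graph = build_adjacency_graph(families, ngps)
    forest = minimum_spanning_forest(graph)
    return extract_gene_runs(forest, node_id, min_run_genes, path_rule)


def genome_segments(genome, min_run_genes: int = 2) -> RunSet:
    """Maximal singleton-free segments of an extant genome, as runs.

    Used to compare reconstructed ancestral runs against observed leaf
    gene order on the same footing.
    """
    out = RunSet(genome.genome_id)
    for rep in genome.replicons.values():
        seg: list[tuple[str, str]] = []
        for g in rep.genes + [None]:
            if g is None or g.is_singleton:
                if len(seg) >= min_run_genes:
                    out.runs.append(GeneRun(seg, float(len(seg))).canonical())
                elif seg:
                    out.leftovers |= {f for f, _ in seg}
                seg = []
            else:
                seg.append((g.family, g.strand))
    return out
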