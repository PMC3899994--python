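"""Domain types and I/O for gene-order tables and species trees.

A genome is modeled as a set of replicons, each an ordered, stranded
string over the orthologous-family alphabet Sigma; singleton genes
(no homolog in any other input genome) carry the family symbol ``*``.
The no-paralog contract — no non-singleton family occurs twice within
one genome — is enforced at read time because every downstream step
relies on it.

The gene-order dialect is a UTF-8 TSV with header columns
``genome_id, replicon_id, replicon_role, circular, position, strand,
family_id, gene_id`` and ``#`` comment lines.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import dendropy

SINGLETON = "*"
STRANDS = ("+", "-")
ROLES = ("main_chromosome", "secondary_chromosome", "plasmid", "unknown")

TABLE_COLUMNS = (
    "genome_id",
    "replicon_id",
    "replicon_role",
    "circular",
    "position",
    "strand",
    "family_id",
    "gene_id",
)


class FormatError(ValueError):
    """Malformed input table or tree."""


class ParalogError(FormatError):
    """A non-singleton family occurs more than once in one genome."""


class TopologyError(ValueError):
    """Species tree violates the rooted-bifurcating requirement."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene occurrence: a position on a replicon with a strand and family."""

    gene_id: str
    genome_id: str
    replicon_id: str
    position: int  # 1-based along the replicon
    strand: str  # "+" or "-"
    family: str  # family ID from Sigma, or "*" for singletons

    @property
    def is_singleton(self) -> bool:
        return self.family == SINGLETON


@dataclass
class Replicon:
    """One DNA molecule (chromosome or plasmid) as an ordered gene string."""

    replicon_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    role: str = "unknown"
    circular: bool = False

    def __len__(self) -> int:
        return len(self.genes)

    def families(self) -> list[str]:
        """Non-singleton family IDs in replicon order."""
        return [g.family for g in self.genes if not g.is_singleton]

    def family_set(self) -> set[str]:
        return set(self.families())


@dataclass
class Genome:
    """A genome: a set of replicons over the family alphabet."""

    genome_id: str
    replicons: dict[str, Replicon] = field(default_factory=dict)

    def family_set(self) -> set[str]:
        out: set[str] = set()
        for rep in self.replicons.values():
            out |= rep.family_set()
        return out

    def n_genes(self) -> int:
        return sum(len(r) for r in self.replicons.values())

    def validate(self) -> None:
        seen: set[str] = set()
        for rep in self.replicons.values():
            positions = [g.position for g in rep.genes]
            if positions != list(range(1, len(rep.genes) + 1)):
                raise FormatError(
                    f"replicon {rep.replicon_id!r} of genome {self.genome_id!r}: "
                    f"positions are not a contiguous 1..n sequence"
                )
            for g in rep.genes:
                if g.strand not in STRANDS:
                    raise FormatError(f"bad strand {g.strand!r} for gene {g.gene_id!r}")
                if g.is_singleton:
                    continue
                if g.family in seen:
                    raise ParalogError(
                        f"genome {self.genome_id!r}: family {g.family!r} occurs "
                        f"more than once (paralogs must be refined upstream)"
                    )
                seen.add(g.family)
        mains = [r for r in self.replicons.values() if r.role == "main_chromosome"]
        if len(mains) > 1:
            raise FormatError(
                f"genome {self.genome_id!r} declares {len(mains)} main chromosomes"
            )


class GenomeSet:
    """An ordered collection of genomes sharing one family alphabet."""

    def __init__(self, genomes: Iterable[Genome] = ()):
        self.genomes: dict[str, Genome] = {}
        for g in genomes:
            self.add(g)

    def add(self, genome: Genome) -> None:
        if genome.genome_id in self.genomes:
            raise FormatError(f"duplicate genome_id {genome.genome_id!r}")
        genome.validate()
        self.genomes[genome.genome_id] = genome

    def __len__(self) -> int:
        return len(self.genomes)

    def __iter__(self) -> Iterator[Genome]:
        return iter(self.genomes.values())

    def __getitem__(self, genome_id: str) -> Genome:
        return self.genomes[genome_id]

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.genomes

    def ids(self) -> list[str]:
        return list(self.genomes)

    def alphabet(self) -> set[str]:
        """All non-singleton family IDs observed in any genome."""
        out: set[str] = set()
        for g in self:
            out |= g.family_set()
        return out

    def core_families(self) -> set[str]:
        """Families present in every genome of the set."""
        sets = [g.family_set() for g in self]
        if not sets:
            return set()
        return set.intersection(*sets)


# ---------------------------------------------------------------------------
# gene-order table I/O

def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("1", "true", "yes"):
        return True
    if t in ("0", "false", "no"):
        return False
    raise FormatError(f"cannot parse boolean field {text!r}")


def read_genome_table(path: str | Path | io.TextIOBase) -> GenomeSet:
    """Read the gene-order TSV dialect into a validated :class:`GenomeSet`."""
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not rows:
        raise FormatError("empty gene-order table")
    header = tuple(rows[0].rstrip("\n").split("\t"))
    if header != TABLE_COLUMNS:
        raise FormatError(
            f"bad header: expected {list(TABLE_COLUMNS)}, got {list(header)}"
        )

    # group rows by (genome, replicon) preserving first-appearance order
    by_rep: dict[tuple[str, str], list[dict]] = {}
    for ln in rows[1:]:
        fields = ln.rstrip("\n").split("\t")
        if len(fields) != len(TABLE_COLUMNS):
            raise FormatError(f"row has {len(fields)} fields: {ln!r}")
        rec = dict(zip(TABLE_COLUMNS, fields))
        by_rep.setdefault((rec["genome_id"], rec["replicon_id"]), []).append(rec)

    genomes: dict[str, Genome] = {}
    for (gid, rid), recs in by_rep.items():
        genome = genomes.setdefault(gid, Genome(genome_id=gid))
        roles = {r["replicon_role"] for r in recs}
        circs = {r["circular"] for r in recs}
        if len(roles) > 1 or len(circs) > 1:
            raise FormatError(
                f"replicon {rid!r} of {gid!r} has inconsistent role/circular fields"
            )
        role = roles.pop()
        if role not in ROLES:
            raise FormatError(f"unknown replicon_role {role!r}")
        try:
            recs.sort(key=lambda r: int(r["position"]))
        except ValueError as exc:
            raise FormatError(f"non-integer position in replicon {rid!r}") from exc
        genes = [
            GeneRecord(
                gene_id=r["gene_id"],
                genome_id=gid,
                replicon_id=rid,
                position=int(r["position"]),
                strand=r["strand"],
                family=r["family_id"],
            )
            for r in recs
        ]
        genome.replicons[rid] = Replicon(
            replicon_id=rid, genes=genes, role=role, circular=_parse_bool(circs.pop())
        )
    return GenomeSet(genomes.values())


def write_genome_table(genomes: GenomeSet, path: str | Path | io.TextIOBase) -> None:
    """Write a :class:`GenomeSet` back to the gene-order TSV dialect."""
    out = ["\t".join(TABLE_COLUMNS)]
    for genome in genomes:
        for rep in genome.replicons.values():
            for g in rep.genes:
                out.append(
                    "\t".join(
                        (
                            genome.genome_id,
                            rep.replicon_id,
                            rep.role,
                            "1" if rep.circular else "0",
                            str(g.position),
                            g.strand,
                            g.family,
                            g.gene_id,
                        )
                    )
                )
    text = "\n".join(out) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# species tree

class TreeNode:
    """Node of a rooted bifurcating species tree."""

    __slots__ = ("id", "children", "parent", "length")

    def __init__(self, node_id: str = "", length: float = 0.0):
        self.id = node_id
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length  # branch length above this node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_ids(self) -> list[str]:
        if self.is_leaf:
            return [self.id]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_ids())
        return out


class SpeciesTree:
    """Rooted bifurcating species tree with underscore-join internal IDs.

    Internal node IDs are the underscore join of descendant leaf labels
    in left-to-right order (e.g. the parent of leaves ``14`` and ``8``
    with sibling ``20`` below it is ``14_8_20``), so reconstruction
    reports can be traced back to the clade they describe.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._assign_ids(root)
        self.nodes: dict[str, TreeNode] = {}
        for node in self.preorder():
            if node.id in self.nodes:
                raise TopologyError(f"duplicate node ID {node.id!r}")
            self.nodes[node.id] = node
        self._validate()

    @staticmethod
    def _assign_ids(node: TreeNode) -> list[str]:
        if node.is_leaf:
            if not node.id:
                raise FormatError("unlabeled leaf in species tree")
            return [node.id]
        leaves: list[str] = []
        for c in node.children:
            leaves.extend(SpeciesTree._assign_ids(c))
        node.id = "_".join(leaves)
        return leaves

    def _validate(self) -> None:
        for node in self.preorder():
            if node.children and len(node.children) != 2:
                raise TopologyError(
                    f"node {node.id!r} has {len(node.children)} children; "
                    f"only bifurcating trees are supported"
                )

    # -- traversal -----------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    def node(self, node_id: str) -> TreeNode:
        return self.nodes[node_id]

    def sibling(self, node: TreeNode) -> TreeNode | None:
        if node.parent is None:
            return None
        a, b = node.parent.children
        return b if a is node else a

    def lca(self, leaf_ids: Iterable[str]) -> TreeNode:
        wanted = set(leaf_ids)
        for node in self.postorder():
            if wanted <= set(node.leaf_ids()):
                return node
        raise KeyError(f"no node covering leaves {sorted(wanted)}")

    # -- construction / serialization ---------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def convert(dnode) -> TreeNode:
            node = TreeNode()
            node.length = float(dnode.edge.length or 0.0)
            if dnode.is_leaf():
                if dnode.taxon is None or not dnode.taxon.label:
                    raise FormatError("unlabeled leaf in Newick input")
                node.id = dnode.taxon.label
            for dchild in dnode.child_nodes():
                child = convert(dchild)
                child.parent = node
                node.children.append(child)
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.id}:{node.length:g}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}):{node.length:g}"

        inner = ",".join(render(c) for c in self.root.children)
        return f"({inner});"

    def prune_leaf(self, leaf_id: str) -> "SpeciesTree":
        """Return a new tree with one leaf removed and its attachment
        node suppressed (sibling absorbs the freed branch length)."""

        def copy(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                if node.id == leaf_id:
                    return None
                fresh = TreeNode(node.id, node.length)
                return fresh
            kids = [copy(c) for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            fresh = TreeNode(length=node.length)
            for k in kids:
                k.parent = fresh
            fresh.children = kids
            return fresh

        if leaf_id not in self.nodes or not self.nodes[leaf_id].is_leaf:
            raise KeyError(f"no leaf {leaf_id!r}")
        if len(self.leaves()) <= 3:
            raise TopologyError("pruning would leave fewer than 3 leaves")
        root = copy(self.root)
        assert root is not None
        root.length = 0.0
        return SpeciesTree(root)


def read_newick(path: str | Path) -> SpeciesTree:
    return SpeciesTree.from_newick(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# validation report

@dataclass
class ValidationReport:
    issues: list[tuple[str, str]] = field(default_factory=list)  # (level, message)
    n_families: int = 0
    n_core: int = 0

    @property
    def fatal(self) -> bool:
        return any(level == "fatal" for level, _ in self.issues)


def validate_inputs(tree: SpeciesTree, genomes: GenomeSet) -> ValidationReport:
    """Cross-check a tree and a genome set before reconstruction."""
    report = ValidationReport()
    leaf_ids = set(tree.leaf_ids())
    genome_ids = set(genomes.ids())
    for missing in sorted(leaf_ids - genome_ids):
        report.issues.append(("fatal", f"tree leaf {missing!r} has no input genome"))
    for extra in sorted(genome_ids - leaf_ids):
        report.issues.append(("warning", f"genome {extra!r} is not a tree leaf"))
    report.n_families = len(genomes.alphabet())
    report.n_core = len(genomes.core_families())
    return report
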