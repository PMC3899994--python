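"""End-to-end reconstruction pipeline.

Order of operations for a genome set and a rooted bifurcating tree:

1. extract gene-content and NGP presence matrices;
2. reconstruct ancestral states (parsimony, or likelihood with one
   shared rate model per character class) and call presence at the
   cutoffs, dropping NGPs whose member families are absent;
3. assemble each node's called NGPs into gene runs;
4. rebuild replicon architecture bottom-up from co-inheritance groups
   with outgroup guidance, then apply the pooled gene-run merge
   correction and restore chromosome labels from core genes;
5. infer gene-, run- and replicon-scale events along every branch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from paleogen import ancestral, characters, events as ev, replicons as ra, runs as gr
from paleogen.genome_io import GenomeSet, SpeciesTree


class ConfigurationError(ValueError):
    pass


@dataclass
class RunConfig:
    """All tunables of one reconstruction run (serialized for provenance)."""

    method: str = "ml"  # "ml" or "mp"
    gene_pair_cutoff: float = 0.9
    gene_occurrence_cutoff: float = 0.9
    skip_singletons: bool = False
    min_run_genes: int = 2
    path_rule: str = "longest"  # or "lowest-score"
    merge_min_run_length: int = 4
    merge_low_signal: float = 0.1
    cross_link_min_shared: int = 3
    cross_link_min_frac: float = 0.2
    secondary_chrom_threshold: float = 0.05
    mapping_min_shared: int = 3
    mapping_min_frac: float = 0.2
    per_character_rates: bool = False
    root_prior: str = "stationary"
    outgroups: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("ml", "mp"):
            raise ConfigurationError(f"unknown method {self.method!r}")

    def to_text(self) -> str:
        return "\n".join(
            f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)
        )


@dataclass
class Reconstruction:
    """Per-node reconstruction products plus per-branch events."""

    tree: SpeciesTree
    config: RunConfig
    calls: dict  # internal node -> ancestral.NodeCall
    runs: dict  # internal node -> runs.RunSet
    assignments: dict  # node (incl. leaves) -> replicons.RepliconAssignment
    branch_events: dict = field(default_factory=dict)  # child -> events.BranchEvents
    gene_scores: pd.DataFrame | None = None
    ngp_scores: pd.DataFrame | None = None
    core: set = field(default_factory=set)
    rate_models: dict = field(default_factory=dict)

    def node_families(self, node_id: str) -> set:
        node = self.tree.node(node_id)
        if node.is_leaf:
            return self.assignments[node_id].families()
        return self.calls[node_id].families


def ancestral_scores(
    genomes: GenomeSet, tree: SpeciesTree, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Internal-node score frames for gene and NGP characters."""
    gene_matrix = characters.extract_gene_content(genomes)
    ngp_matrix = characters.extract_ngp_matrix(genomes, config.skip_singletons)
    rate_models: dict = {}
    if config.method == "mp":
        gene_scores, _ = ancestral.mp_reconstruct(tree, gene_matrix)
        ngp_scores, _ = ancestral.mp_reconstruct(tree, ngp_matrix)
        return gene_scores.astype(float), ngp_scores.astype(float), rate_models

    frames = []
    for label, matrix in (("gene", gene_matrix), ("ngp", ngp_matrix)):
        rates = ancestral.ml_fit_rates(tree, matrix)
        rate_models[label] = rates
        frames.append(
            ancestral.ml_marginal_posteriors(tree, matrix, rates, config.root_prior)
        )
    return frames[0], frames[1], rate_models


def _architecture_pass(
    tree: SpeciesTree,
    calls: dict,
    run_sets: dict,
    assignments: dict,
    config: RunConfig,
) -> None:
    """Assemble replicons for every internal node, scheduling each node
    once its outgroup's inputs (sibling's children, or the designated
    root outgroups) are available; terminates by induction on subtree
    size."""
    outgroups = [g for g in config.outgroups if g in tree.nodes and tree.node(g).is_leaf]
    pending = [n for n in tree.postorder() if not n.is_leaf]
    groups_cache: dict = {}

    def node_groups(node_id):
        if node_id not in groups_cache:
            node = tree.node(node_id)
            if node.is_leaf:
                groups_cache[node_id] = ra.leaf_groups(assignments[node_id])
            else:
                child_assign = [assignments[c.id] for c in node.children]
                groups, unplaced = ra.co_inheritance_groups(
                    calls[node_id].families, child_assign
                )
                groups_cache[node_id] = (groups, unplaced)
        return groups_cache[node_id]

    def ready(node) -> bool:
        if all(c.id in assignments for c in node.children) is False:
            return False
        sib = tree.sibling(node)
        if sib is None:  # root: needs only the designated outgroup genomes
            return True
        if sib.is_leaf:
            return True
        return all(c.id in assignments for c in sib.children)

    guard = 0
    while pending:
        guard += 1
        if guard > len(tree.nodes) + 2:
            raise RuntimeError("replicon assembly scheduling did not converge")
        progressed = []
        for node in list(pending):
            if not ready(node):
                continue
            groups, unplaced = node_groups(node.id)
            target_graph = ra.build_group_graph(groups)
            sib = tree.sibling(node)
            if sib is not None:
                if sib.is_leaf:
                    og = ra.leaf_groups(assignments[sib.id])
                else:
                    og, _ = node_groups(sib.id)
            else:
                og = []
                for gid in outgroups:
                    base = len(og)
                    for g in ra.leaf_groups(assignments[gid]):
                        og.append(ra.Group(base + g.index, g.members, g.pattern))
            links = ra.cross_link(
                groups, og, config.cross_link_min_shared, config.cross_link_min_frac
            )
            assignments[node.id] = ra.assemble_replicons(
                node.id,
                groups,
                target_graph,
                links,
                unplaced,
                run_sets.get(node.id),
            )
            progressed.append(node)
        for node in progressed:
            pending.remove(node)
        if not progressed and pending:
            raise RuntimeError("replicon assembly deadlocked (tree inconsistent?)")


def reconstruct(
    genomes: GenomeSet, tree: SpeciesTree, config: RunConfig | None = None
) -> Reconstruction:
    """Run the full reconstruction pipeline."""
    config = config or RunConfig()
    missing = set(tree.leaf_ids()) - set(genomes.ids())
    if missing:
        raise ConfigurationError(f"tree leaves without genomes: {sorted(missing)}")

    gene_scores, ngp_scores, rate_models = ancestral_scores(genomes, tree, config)
    cutoffs = ancestral.Cutoffs(config.gene_pair_cutoff, config.gene_occurrence_cutoff)
    calls = ancestral.call_presence(gene_scores, ngp_scores, cutoffs)

    run_sets = {
        nid: gr.assemble_node_runs(
            call.families,
            call.ngps,
            node_id=nid,
            min_run_genes=config.min_run_genes,
            path_rule=config.path_rule,
        )
        for nid, call in calls.items()
    }

    assignments = {
        leaf.id: ra.RepliconAssignment.from_genome(genomes[leaf.id])
        for leaf in tree.leaves()
    }
    _architecture_pass(tree, calls, run_sets, assignments, config)

    # pooled gene-run merge correction
    proposals = []
    for nid, rs in sorted(run_sets.items()):
        for run in rs.runs:
            p = ra.run_merge_signal(
                run.families,
                assignments[nid],
                config.merge_min_run_length,
                config.merge_low_signal,
            )
            if p is not None:
                proposals.append(p)
    accepted = ra.cluster_proposals(ra.pool_proposals(proposals), seed=config.seed)
    core = genomes.core_families()
    for node in tree.internal_nodes():
        merged = ra.apply_merges(assignments[node.id], accepted)
        assignments[node.id] = ra.restore_chromosomes(
            merged, core, config.secondary_chrom_threshold
        )

    rec = Reconstruction(
        tree=tree,
        config=config,
        calls=calls,
        runs=run_sets,
        assignments=assignments,
        gene_scores=gene_scores,
        ngp_scores=ngp_scores,
        core=core,
        rate_models=rate_models,
    )

    for node in tree.internal_nodes():
        for child in node.children:
            child_runs = (
                run_sets[child.id]
                if child.id in run_sets
                else gr.genome_segments(genomes[child.id], config.min_run_genes)
            )
            rec.branch_events[child.id] = ev.branch_events(
                node.id,
                child.id,
                rec.node_families(node.id),
                rec.node_families(child.id),
                assignments[node.id],
                assignments[child.id],
                run_sets[node.id],
                child_runs,
                config.mapping_min_shared,
                config.mapping_min_frac,
            )
    return rec


# ---------------------------------------------------------------------------
# report writers

def write_reports(rec: Reconstruction, outdir: str | Path) -> None:
    """TSV reports: presence calls, runs, architecture, events, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.txt").write_text(rec.config.to_text() + "\n", encoding="utf-8")

    lines = ["node_id\tcharacter\tkind\tscore\tcalled"]
    for nid in sorted(rec.calls):
        call = rec.calls[nid]
        for fam in sorted(rec.gene_scores.columns):
            score = rec.gene_scores.at[nid, fam]
            lines.append(f"{nid}\t{fam}\tgene\t{score:.6g}\t{int(fam in call.families)}")
        for key in sorted(rec.ngp_scores.columns):
            score = rec.ngp_scores.at[nid, key]
            lines.append(f"{nid}\t{key}\tngp\t{score:.6g}\t{int(key in call.ngps)}")
    (outdir / "presence.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = ["node_id\trun_index\tlength\tweight\tgenes"]
    for nid in sorted(rec.runs):
        for i, run in enumerate(rec.runs[nid].runs):
            lines.append(
                f"{nid}\t{i}\t{len(run)}\t{run.weight:.6g}\t{run.signed_string()}"
            )
    (outdir / "runs.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = ["node_id\treplicon_id\trole\tn_genes\tn_core_genes"]
    for nid in sorted(rec.assignments):
        a = rec.assignments[nid]
        for rid in sorted(a.members):
            fams = a.members[rid]
            lines.append(
                f"{nid}\t{rid}\t{a.roles.get(rid, 'unknown')}\t{len(fams)}"
                f"\t{len(fams & rec.core)}"
            )
    (outdir / "architecture.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = ["parent\tchild\tkind\tdetail"]
    for cid in sorted(rec.branch_events):
        b = rec.branch_events[cid]
        for fam in sorted(b.gains):
            lines.append(f"{b.parent_id}\t{cid}\tgene_gain\t{fam}")
        for fam in sorted(b.losses):
            lines.append(f"{b.parent_id}\t{cid}\tgene_loss\t{fam}")
        for rev in b.replicon_events:
            lines.append(
                f"{b.parent_id}\t{cid}\treplicon_{rev.kind}\t"
                f"{'+'.join(rev.parents)}->{'+'.join(rev.children)}"
            )
        for r in b.reversals:
            lines.append(f"{b.parent_id}\t{cid}\treversal\t{'_'.join(r.segment)}")
        for run, fate in b.run_fates:
            tag = fate if isinstance(fate, str) else f"fragmented({fate[1]})"
            lines.append(f"{b.parent_id}\t{cid}\trun_{tag}\t{run.signed_string()}")
    (outdir / "events.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
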