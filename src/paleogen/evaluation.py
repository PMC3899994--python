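"""Scoring reconstructions against simulated truth and operon evidence.

Includes gene-pair precision/recall, gene-run coverage summaries,
operon-pair conservation classes (HC/MC/LC) with the 60% run-support
criterion, the leave-one-out stability protocol (1- and 2-fragment
recovery rules at 80% gene sharing), and consensus functional
annotation transfer for families.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from paleogen.genome_io import GenomeSet, SpeciesTree
from paleogen.runs import GeneRun, RunSet

# operon-pair conservation classes by genome occurrence count
HC_MIN = 10
MC_RANGE = (6, 9)
LC_RANGE = (2, 5)

RUN_SUPPORT_THRESHOLD = 0.6
LOO_SHARE = 0.8
LOO_RECOVERY_FRACTION = 0.818  # generalizes the 18-of-22 replicate rule


def pair_precision_recall(
    reconstructed: set, true: set
) -> tuple[float | None, float]:
    """Precision and recall of a reconstructed NGP set against truth.

    Precision is None (NA) when nothing was reconstructed; recall is
    1.0 against an empty truth set (nothing to recover).
    """
    inter = len(reconstructed & true)
    precision = inter / len(reconstructed) if reconstructed else None
    recall = inter / len(true) if true else 1.0
    return precision, recall


def coverage_stats(run_set: RunSet, n_called: int) -> tuple[int, int, int, float]:
    """(number of runs, longest run, genes on runs, coverage %) for one node."""
    n_runs = len(run_set.runs)
    longest = max((len(r) for r in run_set.runs), default=0)
    genes = len(run_set.covered_families())
    pct = 100.0 * genes / n_called if n_called else 0.0
    return n_runs, longest, genes, pct


# ---------------------------------------------------------------------------
# operon evidence

def classify_operon_pairs(
    per_genome_pairs: Mapping[str, Iterable[frozenset]]
) -> pd.DataFrame:
    """Conservation classes of operon gene pairs by occurrence count.

    Pairs are unordered family pairs; a pair seen in a single genome is
    dropped for lack of conservation.
    """
    counts: Counter = Counter()
    for pairs in per_genome_pairs.values():
        for pair in set(pairs):
            counts[pair] += 1
    rows = []
    for pair, n in sorted(counts.items(), key=lambda kv: sorted(kv[0])):
        if n < LC_RANGE[0]:
            continue
        if n >= HC_MIN:
            cls = "HC"
        elif MC_RANGE[0] <= n <= MC_RANGE[1]:
            cls = "MC"
        else:
            cls = "LC"
        a, b = sorted(pair)
        rows.append({"family_a": a, "family_b": b, "count": n, "class": cls})
    return pd.DataFrame(rows, columns=["family_a", "family_b", "count", "class"])


def run_operon_support(
    run: GeneRun,
    operon_pairs: set,
    threshold: float = RUN_SUPPORT_THRESHOLD,
) -> tuple[bool, float]:
    """A run is supported if >= 60% of its internal gene pairs are operonic."""
    fams = run.families
    internal = [frozenset(p) for p in zip(fams, fams[1:])]
    if not internal:
        return False, 0.0
    frac = sum(1 for p in internal if p in operon_pairs) / len(internal)
    return frac >= threshold, frac


def read_operon_pairs(path) -> dict[str, set]:
    """Operon gene-pair TSV: genome_id, family_a, family_b."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out: dict[str, set] = {}
    for _, row in df.iterrows():
        out.setdefault(row["genome_id"], set()).add(
            frozenset((row["family_a"], row["family_b"]))
        )
    return out


# ---------------------------------------------------------------------------
# consensus annotation

def consensus_annotation(
    per_gene_annotations: Sequence[str],
) -> tuple[str, int, int]:
    """Modal annotation among family members, as (label, k, n).

    Empty annotations are ignored; with none at all the family is
    reported as not annotated.  Ties break by canonical label.
    """
    labels = [a for a in per_gene_annotations if a]
    n = len(per_gene_annotations)
    if not labels:
        return "not annotated", 0, n
    counts = Counter(labels)
    best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return best[0], best[1], n


# ---------------------------------------------------------------------------
# leave-one-out stability

@dataclass
class RecoveryTable:
    """Per-run recovery status under the 1- and 2-fragment rules."""

    runs: list = field(default_factory=list)  # (run, recovered_1frag, recovered_2frag)
    n_replicates: int = 0

    def summary(self) -> dict:
        total = len(self.runs)
        rec1 = sum(1 for _, a, _ in self.runs if a)
        rec2 = sum(1 for _, _, b in self.runs if b)
        return {
            "total": total,
            "recovered_1frag": rec1,
            "recovered_2frag": rec2,
            "pct_1frag": 100.0 * rec1 / total if total else 0.0,
            "pct_2frag": 100.0 * rec2 / total if total else 0.0,
        }


def _run_recovered(
    original: GeneRun, replicate_runs: Sequence[GeneRun], share: float = LOO_SHARE
) -> tuple[bool, bool]:
    """(1-fragment, 2-fragment) recovery of one run in one replicate."""
    fams = set(original.families)
    need = share * len(fams)
    overlaps = sorted(
        (len(fams & set(r.families)) for r in replicate_runs), reverse=True
    )
    one = bool(overlaps) and overlaps[0] >= need
    two = sum(overlaps[:2]) >= need if overlaps else False
    return one, two


def leave_one_out(
    genomes: GenomeSet,
    tree: SpeciesTree,
    config,
    target_leaves: Sequence[str] | None = None,
    min_run_length: int = 4,
    recovery_fraction: float = LOO_RECOVERY_FRACTION,
) -> RecoveryTable:
    """Leave-one-out stability of the reconstructed runs of one ancestor.

    The full reconstruction's runs (length >= ``min_run_length``) at the
    LCA of ``target_leaves`` are checked against every reconstruction
    with one genome left out; a run counts as globally recovered if at
    least ``ceil(recovery_fraction * n_replicates)`` replicates contain
    a similar enough run (80% gene sharing; 1- and 2-fragment rules).
    """
    from paleogen.pipeline import reconstruct  # local import to avoid a cycle

    leaves = tree.leaf_ids()
    target_leaves = list(target_leaves or leaves)
    target = tree.lca(target_leaves).id
    full = reconstruct(genomes, tree, config)
    selected = [r for r in full.runs[target].runs if len(r) >= min_run_length]

    replicate_runs: list[list[GeneRun]] = []
    for left_out in leaves:
        pruned_tree = tree.prune_leaf(left_out)
        pruned_genomes = GenomeSet(
            genomes[g] for g in genomes.ids() if g != left_out
        )
        kept = [l for l in target_leaves if l != left_out]
        node = pruned_tree.lca(kept).id
        rec = reconstruct(pruned_genomes, pruned_tree, config)
        replicate_runs.append(rec.runs[node].runs)

    n_rep = len(replicate_runs)
    need = math.ceil(recovery_fraction * n_rep)
    table = RecoveryTable(n_replicates=n_rep)
    for run in selected:
        hits = [_run_recovered(run, reps) for reps in replicate_runs]
        rec1 = sum(1 for a, _ in hits if a) >= need
        rec2 = sum(1 for _, b in hits if b) >= need
        table.runs.append((run, rec1, rec2))
    return table
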