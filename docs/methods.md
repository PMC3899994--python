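# Methods

`paleogen` reconstructs ancestral bacterial genomes on a rooted
bifurcating species tree at three levels — gene content, contiguous
gene order (gene runs), and replicon architecture — and infers the
evolutionary events implied along every branch.  This note describes
the models and procedures, the parameters that matter, the companion
simulator, and the numerical and design choices that were genuinely
open.

## Input model

Each extant genome is reduced to a set of *replicons* (chromosomes and
plasmids), each an ordered, stranded string over an alphabet Σ of
orthologous-family identifiers.  Genes with no homolog in any other
genome are *singletons*, written `*`; they occupy positions (and thus
break adjacencies) but are not characters.  The input contract forbids
paralogs: no non-`*` family may occur twice in one genome — mixed
families must be refined upstream.  Replicon strings are linear by
default; a `circular` flag adds the wrap-around adjacency.  A *core*
family is one present in every input genome.

## Characters: families and neighboring gene pairs

Every gene is represented by its two ends (5′ head, 3′ tail).  A
neighboring gene pair (NGP) — two genes physically adjacent on one
replicon — is stored as the unordered pair of the two facing ends,
e.g. `fam5:t~fam9:h`.  This two-node encoding makes the key invariant
to the replicon's reading direction while preserving relative
orientation, so strandedness of reconstructed runs comes for free.
Gene families and NGPs each yield a binary presence matrix
(character × genome).

## Ancestral states

Two engines reconstruct presence/absence at internal nodes:

* **Maximum parsimony** — Fitch's algorithm, vectorized across
  characters.  The up-pass prefers the parent's resolved state within
  an ambiguity set; root ambiguity resolves to *absence*, the
  conservative choice consistent with the stringent probability
  cutoffs used elsewhere.

* **Maximum likelihood** — a two-state continuous-time Markov chain
  with gain rate `q01` and loss rate `q10` per unit branch length,
  transition probabilities in closed form, Felsenstein pruning with
  per-node scaling, and marginal posteriors from the standard
  below-partial / above-contribution two-pass.  The root prior is the
  chain's stationary distribution (a uniform prior is available).
  Rates are fitted by bounded (1e-6 … 1e3) multi-start L-BFGS-B on
  pattern-compressed data, one shared model per character class (one
  for gene characters, one for NGP characters): single-character ML is
  ill-posed for rare characters.  Per-character fitting is available
  behind a flag.  Zero or missing branch lengths are replaced by
  1e-6.

Presence is called with inclusive (≥) thresholds: `gene_pair_cutoff`
and `gene_occurrence_cutoff`, both 0.9 by default.  An NGP survives
calling only if both member families are called present at the node.

## Gene-run assembly

For one node, called families contribute their two ends as graph nodes
joined by an intra-gene edge of weight 1; each called NGP contributes
an inter-gene edge weighted by the reciprocal of its posterior (1
under parsimony).  Kruskal's algorithm with a deterministic tie-break
(weight, then canonical edge key) yields a minimum spanning forest.
Runs are then peeled off each fragment as the best *legitimate* path:
edges strictly alternate intra/inter and both terminal edges are
intra-gene, so each reported gene is wholly included and oriented
(head→tail traversal = `+`).  Selection is by most genes, then lowest
total weight, then canonical key; because path weights on a tree are
unique sums of edge weights, a linear dynamic program replaces
explicit all-pairs shortest-path computation.  Selected paths are
removed, fragments re-split, and the process repeats; fragments
reduced to one gene, or admitting no legitimate path of at least
`min_run_genes` (default 2) genes, surrender their families to a
leftover pool.  A literal `lowest-score` selection rule (which, with
all weights ≥ 1, always yields the two genes around the cheapest
inter-gene edge) is retained for comparison.

## Replicon architecture

Architecture is rebuilt bottom-up.  At a node, families present on a
replicon in *both* children are partitioned into co-inheritance groups
by their (replicon-in-child-1, replicon-in-child-2) pattern; families
absent from one or both children carry no joint signal and are set
aside as *unplaced*.  Groups form a graph with edges where two
patterns share a replicon in the same child.  An outgroup — the
sibling node's groups, or for the root the designated outgroup
genome(s) — supplies the ancestral linkage signal: a target group
links to an outgroup group when they share at least
`max(min(3, smaller), ceil(0.2 · smaller))` families, where `smaller`
is the smaller group's size.  The relative part stops a large group
from anchoring through a few stray translocated genes; capping the
absolute demand at the smaller group's size lets short, fully
contained translocated segments find an anchor instead of stranding
as tiny replicons.

Two adjacent target groups merge into one ancestral replicon when
their *dominant* anchors (the outgroup group each shares the most
genes with) coincide.  This is deliberately stricter than merging
everything connected within an outgroup component: transitive merging
lets a single small translocated group chain the chromosome and
plasmid into one replicon, and over-merging — unlike over-splitting —
cannot be corrected downstream.  Groups without anchors, or never
merged, become their own replicons.  Unplaced families attach to the
replicon holding the majority of their gene-run companions, else to
the largest replicon, preserving the partition property.

Scheduling: a node can be assembled once its sibling's children are
leaves or already assembled; rounds over the tree converge by
induction on subtree size.  The root uses the designated outgroup
genomes; when none are available (e.g. after pruning an outgroup leaf
in the leave-one-out protocol) root groups are left unmerged.

**Merge correction.**  Because assembly over-splits in practice, gene
runs of at least `merge_min_run_length` (default 4) genes whose
members map to two or more replicons generate merge proposals: the
relative signal is N2/(N1+N2) — N1 genes on the run's modal replicon,
N2 on the challenger — with proposals below a 0.1 floor dropped, and
the absolute signal is the run length, summed per (node, replicon
pair).  Proposals pooled over all nodes are z-scored and split by
2-means clustering (fixed seed); the cluster whose centroid has the
larger summed standardized coordinates is accepted and its pairs
merged transitively.  With fewer than two distinct proposals no
separation exists: a lone proposal is accepted iff relative ≥ 0.25 and
absolute ≥ 8 (both configurable); identical proposals are rejected.

**Chromosome restoration.**  The replicon with the most core genes
becomes the main chromosome (ties by total gene count, then ID); any
other replicon holding at least 5% of all core genes (inclusive) is a
secondary chromosome; the rest are plasmids.  Chromids are
deliberately not modeled.

## Event inference

Along each branch, gene gains and losses are set differences of called
family sets.  Replicons are mapped bipartitely by shared families
(correspondence requires `max(3, 20%·smaller)` shared genes); a parent
mapping to ≥ 2 children is a split, ≥ 2 parents onto one child a
merge, and unmapped replicons are losses/gains.  Parent runs are
traced into the child: a run is conserved (one child run shares ≥ 80%
of its genes), extended (conserved and longer), fragmented(k) (k ≥ 2
child runs jointly reach 80%), or lost.  A reversal is a maximal
shared run segment inverted in both order and strand, after orienting
the child run to maximize same-order agreement (so a wholesale
reversed copy is recognized as the same run).  Horizontal transfer and
time calibration are out of scope: without a time axis,
contemporaneity of ancestors is undefined.

## Simulator

The simulator supplies ground truth.  It draws a random rooted binary
topology (uniform recursive splitting; optionally an outgroup clade of
the last `n_outgroup` labels attached at the root), i.i.d. exponential
branch lengths, and evolves a root genome (default: 1,000-family
chromosome plus 200-family plasmid) down each branch under Poisson
event counts: gene gain, loss, duplication, reversal, translocation,
transposition; replicon gain, merge, split, loss.  Default rates per
unit branch length — gain 40, loss 40, duplication 5, reversal 20,
transposition 8, translocation 2, replicon events 0.4–0.6 — with
branch mean 0.05 give a few percent gene flux per branch and rarer
inter-replicon movement, i.e. moderately diverged genomes of the kind
the method targets.  Segment lengths are 1 + Geometric(p = 0.2).  The
main chromosome is immune to replicon loss, so a genome always keeps
one replicon.  Every event is logged with fully concrete operands;
replaying the log from the root reproduces every node genome exactly,
and a fixed seed reproduces the whole result bit for bit.

Two conversions align simulator output with the reconstruction input
contract: duplicated copies are emitted as singletons (`*`) so the
no-paralog invariant holds (a flag emits true same-family copies for
studying upstream refinement), and families observed in exactly one
leaf genome are emitted as singletons, as an ortholog-identification
pipeline would report them.

What the simulator does **not** emulate: annotation error and missing
genes, ortholog mis-assignment and family-refinement mistakes,
horizontal transfer, rate heterogeneity across lineages or genes, and
compositional biases of real replicons.  Simulated leaf genomes are
therefore cleaner than real data; reconstruction metrics on them
(pair precision ≈ 1, run coverage ≈ 100%) are upper bounds, and
passing tests demonstrate correctness of the machinery, not expected
real-data accuracy.

## Evaluation protocols

* Gene-pair precision/recall against the true ancestral NGP sets,
  pooled over internal nodes.
* Run coverage per node: number of runs, longest run, genes on runs,
  and their percentage of called genes.
* Operon support: operon gene pairs classified by occurrence count
  (highly conserved ≥ 10 genomes, moderately 6–9, lowly 2–5; single
  occurrences dropped); a run is supported if ≥ 60% of its internal
  pairs are operonic.
* Leave-one-out stability: for each input genome, reconstruction is
  repeated without it; a run of ≥ 4 genes from the full reconstruction
  is recovered in a replicate if one run shares ≥ 80% of its genes
  (1-fragment rule) or its two largest fragments jointly do
  (2-fragment rule), and globally recovered if ≥ ceil(0.818 · n)
  replicates recover it — the fraction generalizes an 18-of-22 rule to
  any genome count.
* Consensus annotation: a family's annotation is the mode over its
  members, reported as k/n, ties by canonical label, `not annotated`
  when empty.

## Numerical and reproducibility notes

All stochastic steps flow from explicit seeds (`numpy` Generators, a
fixed `random_state` for 2-means); set iterations that affect output
are sorted, so identical seeds give bit-identical report directories.
Monotonicity checks of the cutoff sweep treat differences within 1e-6
as ties, since pooled precision saturates within ~1e-5 of 1 on clean
simulated data and denominator shrinkage can move it by ~1e-8 per
step.  The oracle tests hold the pruning marginals to 1e-8 against
exhaustive enumeration and the Fitch change counts and spanning-forest
weights to exact agreement with brute force.

## Problem sizes used in the shipped studies

The acceptance computations run 200 random ≤ 7-leaf trees for the
likelihood and parsimony oracles, 100 random ≤ 10-node graphs for the
spanning-forest oracle, an identity reconstruction at the full
1,200-gene / two-replicon scale, a 10-dataset cutoff sweep and a
10-dataset replicon-recovery study at the default scale (21 leaves,
two outgroups, 1,200-gene root), and a scripted-split experiment.
These sizes exercise every code path at the study scale while keeping
a complete run within a few minutes on one CPU.

## Known limitations

* No paralogs: duplicate resolution is delegated upstream.
* Replicon identity of unplaced families relies on run companions;
  isolated families default to the largest replicon.
* Event calling uses fixed correspondence thresholds; branches with
  several overlapping replicon events may be summarized ambiguously.
* The two-state ML model ignores rate heterogeneity across characters
  beyond the gene/NGP class split.
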