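"""Binary presence characters: gene families and neighboring gene pairs.

Each gene is represented by its two ends (5' head, 3' tail), so that a
neighboring gene pair (NGP) — two genes physically adjacent on one
replicon — encodes both adjacency and relative orientation.  An NGP is
stored as the unordered pair of the two facing gene ends, which makes
the key invariant to the reading direction of the replicon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from paleogen.genome_io import GeneRecord, GenomeSet, Replicon

HEAD = "h"  # 5' end
TAIL = "t"  # 3' end


class CharacterError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GeneEnd:
    family: str
    end: str  # HEAD or TAIL

    def __str__(self) -> str:
        return f"{self.family}:{self.end}"


@dataclass(frozen=True, order=True)
class NGP:
    """Canonical unordered pair of gene ends from two distinct families."""

    a: GeneEnd
    b: GeneEnd

    @property
    def key(self) -> str:
        return f"{self.a}~{self.b}"

    @property
    def families(self) -> tuple[str, str]:
        return (self.a.family, self.b.family)

    @classmethod
    def from_key(cls, key: str) -> "NGP":
        left, right = key.split("~")

        def parse(text: str) -> GeneEnd:
            fam, end = text.rsplit(":", 1)
            return GeneEnd(fam, end)

        return cls(parse(left), parse(right))


def oriented_ends(gene: GeneRecord) -> tuple[GeneEnd, GeneEnd]:
    """Left and right ends of a gene as laid out on the replicon.

    On the forward strand the head (5') comes first; on the reverse
    strand the tail (3') does.
    """
    if gene.is_singleton:
        raise CharacterError(f"singleton gene {gene.gene_id!r} has no usable ends")
    head, tail = GeneEnd(gene.family, HEAD), GeneEnd(gene.family, TAIL)
    return (head, tail) if gene.strand == "+" else (tail, head)


def canonical_ngp(a: GeneEnd, b: GeneEnd) -> NGP:
    """Order-insensitive, reading-direction-insensitive adjacency key."""
    if a.family == b.family:
        raise CharacterError(
            f"self-adjacency of family {a.family!r} (impossible without paralogs)"
        )
    lo, hi = sorted((a, b))
    return NGP(lo, hi)


def replicon_ngps(replicon: Replicon, skip_singletons: bool = False) -> list[NGP]:
    """NGPs along one replicon; the circular flag adds the wrap-around pair.

    With ``skip_singletons`` (off by default) runs of ``*`` genes between
    two family-bearing genes are treated as transparent rather than as
    adjacency breaks.
    """
    ngps: list[NGP] = []
    if skip_singletons:
        genes = [g for g in replicon.genes if not g.is_singleton]
        for g1, g2 in zip(genes, genes[1:]):
            ngps.append(canonical_ngp(oriented_ends(g1)[1], oriented_ends(g2)[0]))
        if replicon.circular and len(genes) >= 2:
            ngps.append(canonical_ngp(oriented_ends(genes[-1])[1], oriented_ends(genes[0])[0]))
        return ngps

    genes = replicon.genes
    pairs = list(zip(genes, genes[1:]))
    if replicon.circular and len(genes) >= 2:
        pairs.append((genes[-1], genes[0]))
    for g1, g2 in pairs:
        if g1.is_singleton or g2.is_singleton or g1.family == g2.family:
            continue
        ngps.append(canonical_ngp(oriented_ends(g1)[1], oriented_ends(g2)[0]))
    return ngps


def genome_ngps(genome, skip_singletons: bool = False) -> set[NGP]:
    out: set[NGP] = set()
    for rep in genome.replicons.values():
        out.update(replicon_ngps(rep, skip_singletons))
    return out


def extract_gene_content(genomes: GenomeSet) -> pd.DataFrame:
    """Binary family-by-genome presence matrix (singletons excluded)."""
    families = sorted(genomes.alphabet())
    ids = genomes.ids()
    data = np.zeros((len(families), len(ids)), dtype=np.int8)
    index = {f: i for i, f in enumerate(families)}
    for j, gid in enumerate(ids):
        for fam in genomes[gid].family_set():
            data[index[fam], j] = 1
    return pd.DataFrame(data, index=families, columns=ids)


def extract_ngp_matrix(genomes: GenomeSet, skip_singletons: bool = False) -> pd.DataFrame:
    """Binary NGP-by-genome presence matrix over all observed canonical NGPs."""
    per_genome = {gid: genome_ngps(genomes[gid], skip_singletons) for gid in genomes.ids()}
    keys = sorted({n.key for s in per_genome.values() for n in s})
    index = {k: i for i, k in enumerate(keys)}
    ids = genomes.ids()
    data = np.zeros((len(keys), len(ids)), dtype=np.int8)
    for j, gid in enumerate(ids):
        for ngp in per_genome[gid]:
            data[index[ngp.key], j] = 1
    return pd.DataFrame(data, index=keys, columns=ids)


def matrix_to_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="character")
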