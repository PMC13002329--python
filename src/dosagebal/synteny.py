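"""Collinearity-block chaining, duplication-origin classification, and
synteny networks.

Anchors (homologous gene pairs placed by gene-order rank on their
chromosomes) are chained per chromosome pair by sparse dynamic programming,
allowing same- and opposite-orientation chains with a bounded rank gap, in
the spirit of MCScanX.  Family genes are then classified into duplication
origins — WGD/segmental (block anchor), tandem (rank-adjacent family member),
proximal (nearby family member), dispersed, or singleton — in that priority
order.  Cross-genome blocks assemble into a synteny network whose connected
components define the family's collinearity communities.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class Anchor:
    """A homologous gene pair with gene-order ranks on its two chromosomes."""

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    score: float = 1.0


@dataclass
class SyntenyBlock:
    """A chained set of anchors, monotone in rank on both genomes."""

    anchors: list[Anchor]
    orientation: str  # "same" | "inverted"
    chrom_a: str
    chrom_b: str

    @property
    def size(self) -> int:
        return len(self.anchors)


def _best_chain(
    anchors: list[Anchor], orientation: str, max_gap: int, score_mode: str
) -> list[Anchor]:
    """Highest-scoring monotone chain by O(n²) dynamic programming."""
    if not anchors:
        return []
    anc = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
    n = len(anc)
    weight = [a.score if score_mode == "bits" else 1.0 for a in anc]
    best = list(weight)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if not (0 < anc[i].rank_a - anc[j].rank_a <= max_gap):
                continue
            if orientation == "same":
                ok = 0 < anc[i].rank_b - anc[j].rank_b <= max_gap
            else:
                ok = 0 < anc[j].rank_b - anc[i].rank_b <= max_gap
            if ok and best[j] + weight[i] > best[i]:
                best[i] = best[j] + weight[i]
                prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(anc[end])
        end = prev[end]
    return chain[::-1]


def chain_collinear_blocks(
    anchors: list[Anchor],
    min_size: int = 5,
    max_gap: int = 25,
    score_mode: str = "count",
) -> list[SyntenyBlock]:
    """Chain anchors into collinear blocks per chromosome pair.

    Blocks are peeled greedily: the best remaining chain (same or inverted
    orientation) is reported and its anchors removed, until no chain reaches
    `min_size` anchors.  Rank gaps between consecutive anchors are bounded by
    `max_gap` in both genomes; ranks are strictly monotone, so tandem arrays
    (tied ranks) never inflate a block.
    """
    if score_mode not in ("count", "bits"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    by_pair: dict[tuple[str, str], list[Anchor]] = defaultdict(list)
    for a in anchors:
        by_pair[(a.chrom_a, a.chrom_b)].append(a)

    blocks: list[SyntenyBlock] = []
    for (chrom_a, chrom_b) in sorted(by_pair):
        remaining = list(by_pair[(chrom_a, chrom_b)])
        while True:
            candidates = [
                (_best_chain(remaining, orient, max_gap, score_mode), orient)
                for orient in ("same", "inverted")
            ]
            chain, orient = max(candidates, key=lambda c: len(c[0]))
            if len(chain) < min_size:
                break
            blocks.append(SyntenyBlock(chain, orient, chrom_a, chrom_b))
            used = set(id(a) for a in chain)
            remaining = [a for a in remaining if id(a) not in used]
    return blocks


def classify_duplicates(
    family_genes: list[str],
    blocks: list[SyntenyBlock],
    gene_order: dict[str, tuple[str, int]],
    proximal_max: int = 10,
    species_of_gene: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Duplication-origin label per family gene, plus class shares.

    Priority: wgd_segmental (the gene anchors a collinear block) > tandem
    (another family member at an adjacent rank on the same chromosome) >
    proximal (within `proximal_max` ranks) > dispersed (any other family
    member in the same genome) > singleton.  `gene_order` maps gene ->
    (chromosome, rank) and must cover every family gene.
    """
    missing = [g for g in family_genes if g not in gene_order]
    if missing:
        raise KeyError(f"genes missing from gene order: {missing[:5]}")
    species_of_gene = species_of_gene or {g: "genome" for g in family_genes}

    anchored = set()
    for block in blocks:
        for a in block.anchors:
            anchored.update((a.gene_a, a.gene_b))

    family = set(family_genes)
    by_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for g in family_genes:
        chrom, rank = gene_order[g]
        by_chrom[chrom].append((rank, g))

    rows = []
    for g in family_genes:
        chrom, rank = gene_order[g]
        neighbors = [r for r, other in by_chrom[chrom] if other != g]
        same_genome = [
            other
            for other in family
            if other != g and species_of_gene.get(other) == species_of_gene.get(g)
        ]
        if g in anchored:
            label = "wgd_segmental"
        elif any(abs(r - rank) == 1 for r in neighbors):
            label = "tandem"
        elif any(2 <= abs(r - rank) <= proximal_max for r in neighbors):
            label = "proximal"
        elif same_genome:
            label = "dispersed"
        else:
            label = "singleton"
        rows.append({"gene": g, "duplication_class": label})
    df = pd.DataFrame(rows)
    shares = (
        df["duplication_class"].value_counts(normalize=True).mul(100.0).rename("share_pct")
    )
    df.attrs["class_shares_pct"] = shares.to_dict()
    return df


def build_synteny_network(
    blocks: list[SyntenyBlock], family_members: set[str] | None = None
) -> tuple[nx.Graph, list[set[str]]]:
    """Graph of anchored family-gene pairs plus its connected components.

    Nodes are family genes (all anchored genes when `family_members` is
    None); one edge per distinct anchored pair.  Communities are the
    connected components, largest first.
    """
    graph = nx.Graph()
    for block in blocks:
        for a in block.anchors:
            if family_members is not None and (
                a.gene_a not in family_members or a.gene_b not in family_members
            ):
                continue
            graph.add_edge(a.gene_a, a.gene_b)
    communities = sorted(nx.connected_components(graph), key=len, reverse=True)
    return graph, communities
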