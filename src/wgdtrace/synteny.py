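"""Collinear synteny-block chaining and the cross-genome locus network.

Homolog anchor pairs (already significance-filtered upstream) are chained
into blocks by dynamic programming per orientation: a block is a run of
anchors whose gene ranks increase strictly along both segments (or increase
along one and decrease along the other, for an inverted block), with
consecutive anchors at most ``max_gap_ranks`` gene ranks apart and a score
of summed anchor similarities minus a per-rank gap penalty. The best chain
is extracted, its anchors removed, and chaining repeats — the greedy
iterated scheme used by MCScan-family tools.

Blocks containing a focal gene yield its "syntelogs" (syntenic homologs),
the paralog pairs that carry the Ks dating signal; blocks between focal
loci define the weighted collinearity network (edge weight = log-transformed
block score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Iterable, Sequence

import networkx as nx

from .formats_io import GeneLocus

__all__ = [
    "AnchorPair",
    "SyntenyBlock",
    "LocusNetwork",
    "ChainParams",
    "chain_anchors",
    "chain_anchors_grouped",
    "extract_flanking_syntelogs",
    "build_locus_network",
    "locus_degree",
]


@dataclass(frozen=True)
class AnchorPair:
    """One significant homolog pair with resolvable loci."""

    locus_a: GeneLocus
    locus_b: GeneLocus
    similarity: float  # e.g. -log10 E-value; must be >= 0

    def __post_init__(self) -> None:
        if self.similarity < 0:
            raise ValueError("anchor similarity must be >= 0")

    @property
    def gene_a(self) -> str:
        return self.locus_a.gene_id

    @property
    def gene_b(self) -> str:
        return self.locus_b.gene_id

    @property
    def ranks(self) -> tuple[int, int]:
        return self.locus_a.rank, self.locus_b.rank


@dataclass
class SyntenyBlock:
    """A chained, order-consistent anchor run between two segments."""

    block_id: str
    anchors: list[AnchorPair]
    orientation: str  # "same" | "inverted"
    score: float

    @property
    def chromosomes(self) -> tuple[str, str]:
        a = self.anchors[0]
        return a.locus_a.chromosome, a.locus_b.chromosome

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for a in self.anchors:
            out.add(a.gene_a)
            out.add(a.gene_b)
        return out

    def validate(self) -> None:
        ra = [a.locus_a.rank for a in self.anchors]
        rb = [a.locus_b.rank for a in self.anchors]
        if any(y <= x for x, y in zip(ra, ra[1:])):
            raise ValueError(f"{self.block_id}: ranks not increasing on segment A")
        ok = (
            all(y > x for x, y in zip(rb, rb[1:]))
            if self.orientation == "same"
            else all(y < x for x, y in zip(rb, rb[1:]))
        )
        if not ok:
            raise ValueError(f"{self.block_id}: ranks not monotone on segment B")


@dataclass(frozen=True)
class ChainParams:
    max_gap_ranks: int = 25
    min_anchors: int = 5
    gap_penalty: float = 1.0


def _best_chain(anchors: list[AnchorPair], params: ChainParams,
                orientation: str) -> tuple[float, list[int]]:
    """DP over anchors sorted by (rank_a, rank_b): best-scoring chain with
    strict monotonicity and the rank-gap constraint in both genomes."""
    sign = 1 if orientation == "same" else -1
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i].ranks[0], sign * anchors[i].ranks[1]))
    best = [anchors[i].similarity for i in order]
    prev = [-1] * len(order)
    for j in range(len(order)):
        aj = anchors[order[j]]
        for i in range(j):
            ai = anchors[order[i]]
            da = aj.ranks[0] - ai.ranks[0]
            db = sign * (aj.ranks[1] - ai.ranks[1])
            if da <= 0 or db <= 0:
                continue
            if da > params.max_gap_ranks or db > params.max_gap_ranks:
                continue
            cand = best[i] + aj.similarity - params.gap_penalty * ((da - 1) + (db - 1))
            if cand > best[j] + 1e-12:
                best[j] = cand
                prev[j] = i
    end = max(range(len(order)), key=lambda j: best[j], default=-1)
    if end < 0:
        return float("-inf"), []
    chain = []
    j = end
    while j >= 0:
        chain.append(order[j])
        j = prev[j]
    chain.reverse()
    return best[end], chain


def chain_anchors(anchors: Sequence[AnchorPair],
                  params: ChainParams | None = None) -> list[SyntenyBlock]:
    """Greedy iterated DP chaining of anchors sharing one chromosome pair.

    Repeatedly extracts the maximal-scoring chain over both orientations,
    removing its anchors, until no chain reaches ``min_anchors``.
    """
    params = params or ChainParams()
    pool = list(anchors)
    pairs = {(a.locus_a.chromosome, a.locus_b.chromosome) for a in pool}
    if len(pairs) > 1:
        raise ValueError(
            f"anchors span multiple chromosome pairs {sorted(pairs)}; partition first"
        )
    blocks: list[SyntenyBlock] = []
    counter = 0
    while pool:
        candidates = []
        for orientation in ("same", "inverted"):
            score, idx = _best_chain(pool, params, orientation)
            candidates.append((score, orientation, idx))
        score, orientation, idx = max(candidates, key=lambda t: (t[0], t[1] == "same"))
        if len(idx) < params.min_anchors:
            break
        chosen = [pool[i] for i in idx]
        chrom_a, chrom_b = chosen[0].locus_a.chromosome, chosen[0].locus_b.chromosome
        counter += 1
        block = SyntenyBlock(
            block_id=f"{chrom_a}__{chrom_b}__{counter}",
            anchors=chosen, orientation=orientation, score=score,
        )
        block.validate()
        blocks.append(block)
        used = set(idx)
        pool = [a for i, a in enumerate(pool) if i not in used]
    return blocks


def chain_anchors_grouped(anchors: Iterable[AnchorPair],
                          params: ChainParams | None = None) -> list[SyntenyBlock]:
    """Partition anchors by chromosome pair and chain each partition."""
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        groups.setdefault((a.locus_a.chromosome, a.locus_b.chromosome), []).append(a)
    blocks = []
    for key in sorted(groups):
        blocks.extend(chain_anchors(groups[key], params))
    return blocks


def extract_flanking_syntelogs(blocks: Sequence[SyntenyBlock],
                               focal_gene: str) -> list[tuple[str, str]]:
    """Anchor pairs of every block that contains ``focal_gene``, deduplicated
    across overlapping blocks (the focal pair itself included)."""
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for block in blocks:
        if focal_gene not in block.genes:
            continue
        for a in block.anchors:
            pair = (a.gene_a, a.gene_b) if a.gene_a <= a.gene_b else (a.gene_b, a.gene_a)
            if pair not in seen:
                seen.add(pair)
                out.append(pair)
    return out


class LocusNetwork:
    """Undirected weighted network over focal loci; weight = ln(1 + block
    score), max-weight edge kept when parallel blocks link the same pair."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_node(self, locus: str) -> None:
        self.graph.add_node(locus)

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            return  # self-loops excluded by construction
        if weight <= 0:
            raise ValueError("edge weights must be positive")
        if self.graph.has_edge(u, v):
            weight = max(weight, self.graph[u][v]["weight"])
        self.graph.add_edge(u, v, weight=weight)

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


def build_locus_network(blocks: Sequence[SyntenyBlock],
                        focal_loci: Iterable[str]) -> LocusNetwork:
    """Connect two focal loci whenever they sit on the opposite segments of
    some block; parallel blocks keep the strongest edge."""
    focal = set(focal_loci)
    net = LocusNetwork()
    for locus in sorted(focal):
        net.add_node(locus)
    for block in blocks:
        side_a = {a.gene_a for a in block.anchors} & focal
        side_b = {a.gene_b for a in block.anchors} & focal
        if block.score <= -1:
            continue  # ln(1+score) undefined; degenerate chain
        w = log(1.0 + max(block.score, 0.0))
        if w <= 0:
            continue
        for u in side_a:
            for v in side_b:
                if u != v:
                    net.add_edge(u, v, w)
    return net


def locus_degree(network: LocusNetwork, locus: str) -> int:
    """Number of syntenic relationships a focal locus participates in."""
    if locus not in network.graph:
        raise KeyError(f"locus {locus!r} not in network")
    return int(network.graph.degree[locus])
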