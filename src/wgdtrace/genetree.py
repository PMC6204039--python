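"""Gene-tree construction and support-based duplication detection.

The synthetic path builds neighbour-joining trees from pairwise NG86 Ks
distances and attaches bootstrap supports by codon-column resampling.
Duplication events are then called with the three-focal-support test: a
node whose two child clades share at least one species is a candidate
duplication; BS-1 is the support of the node itself and BS-2 / BS-3 the
supports of its two child clades, and the call is "supported" only when
all three reach the threshold (default 90 for bootstrap, 0.95 for
posterior). Duplications whose child clades share two or more species are
classified as shared (ancestral, WGD-compatible); a single shared species
marks a species-specific duplication.

Taxon-exclusion series rerun the test after pruning chosen taxa — the
manoeuvre that turns an ambiguous deep duplication into a fully supported
one when early-diverging lineages attach inside one subgenome clade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import ks_engine

__all__ = [
    "DistanceMatrix",
    "DuplicationCall",
    "NomenclatureMap",
    "nj_tree",
    "bootstrap_supports",
    "root_by_outgroup",
    "detect_duplications",
    "run_exclusion_series",
    "assign_subfamily_names",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with taxon labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(m)):
            raise ValueError("distance matrix must be finite")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        self.matrix = m


# ---------------------------------------------------------------------------
# neighbour joining


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Neighbour-joining agglomeration, deterministic under ties.

    Ties in the Q criterion break on the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest member leaf).
    Negative branch lengths are clamped to zero. The result is unrooted
    (three children at the seed node) and consistent on additive matrices.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace(d.labels)
    nodes: dict[str, dendropy.Node] = {}
    for lab in d.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes[lab] = node
    # active clusters keyed by their smallest leaf label
    dist: dict[frozenset[str], float] = {}
    active = sorted(d.labels)
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((d.labels[i], d.labels[j]))] = float(d.matrix[i, j])

    def dd(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(dd(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                q = (r - 2) * dd(a, b) - row_sum[a] - row_sum[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = dd(a, b)
        la = dab / 2.0 + (row_sum[a] - row_sum[b]) / (2.0 * (r - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = dendropy.Node()
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        new_label = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_label, c))] = (dd(a, c) + dd(b, c) - dab) / 2.0
        active = sorted((set(active) - {a, b}) | {new_label})
        nodes[new_label] = parent
    # final three-way join (three-point formulas)
    a, b, c = active
    center = dendropy.Node()
    nodes[a].edge.length = max((dd(a, b) + dd(a, c) - dd(b, c)) / 2.0, 0.0)
    nodes[b].edge.length = max((dd(a, b) + dd(b, c) - dd(a, c)) / 2.0, 0.0)
    nodes[c].edge.length = max((dd(a, c) + dd(b, c) - dd(a, b)) / 2.0, 0.0)
    for lab in (a, b, c):
        center.add_child(nodes[lab])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    tree.support_units = "bootstrap"
    return tree


# ---------------------------------------------------------------------------
# bootstrap


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _internal_splits(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Non-trivial splits of an (un)rooted tree, keyed by the canonical side
    (the lexicographically smaller of the two leaf sets)."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: tuple(sorted(s)))
        out[key] = node
    return out


def bootstrap_supports(sequences: Mapping[str, str], replicates: int = 100,
                       seed: int = 0) -> dendropy.Tree:
    """NJ tree with bootstrap supports from one gapless codon alignment.

    ``sequences`` maps gene ids to aligned in-frame CDS strings of equal
    length. Codon columns are resampled with replacement per replicate, NG86
    Ks distances recomputed, the NJ tree rebuilt, and each internal split of
    the original tree scored as the percentage of replicates containing it.
    """
    if len(sequences) < 4:
        raise ValueError("bootstrap supports undefined for < 4 leaves")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal lengths)")
    (length,) = lengths
    if length % 3 != 0:
        raise ValueError("aligned length must be a codon multiple")
    n_cols = length // 3
    encoded = {g: ks_engine.encode_codons(s) for g, s in sequences.items()}
    labels, mat = ks_engine.ng86_distance_matrix(encoded)
    tree = nj_tree(DistanceMatrix(labels=labels, matrix=mat))
    splits = _internal_splits(tree)
    counts = {key: 0 for key in splits}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        _, bmat = ks_engine.ng86_distance_matrix(encoded, columns=cols)
        btree = nj_tree(DistanceMatrix(labels=labels, matrix=bmat))
        for key in _internal_splits(btree):
            if key in counts:
                counts[key] += 1
    for node in tree.preorder_node_iter():
        node.support = None
    for key, node in splits.items():
        node.support = 100.0 * counts[key] / replicates
        node.label = f"{node.support:g}"
    tree.support_units = "bootstrap"
    return tree


# ---------------------------------------------------------------------------
# rooting


def root_by_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the midpoint of the outgroup's pendant edge, re-attaching
    supports to the clades they subtend."""
    tree = tree.clone(depth=1)
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == outgroup:
            leaf = lf
            break
    if leaf is None:
        raise KeyError(f"outgroup {outgroup!r} not a leaf of the tree")
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    # a support labels the split between a clade and its complement; prefer
    # the side it was written on when both sides occur as rooted clades
    direct: dict[frozenset[str], float] = {}
    complement: dict[frozenset[str], float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or getattr(node, "support", None) is None:
            continue
        side = _leafset(node)
        direct.setdefault(side, node.support)
        complement.setdefault(all_leaves - side, node.support)
    half = (leaf.edge.length or 0.0) / 2.0
    tree.reroot_at_edge(leaf.edge, update_bipartitions=False,
                        length1=half, length2=half)
    tree.suppress_unifurcations()
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = _leafset(node)
        node.support = direct.get(side, complement.get(side))
        node.label = None if node.support is None else f"{node.support:g}"
    tree.support_units = getattr(tree, "support_units", "bootstrap")
    return tree


# ---------------------------------------------------------------------------
# duplication detection


@dataclass
class DuplicationCall:
    """One candidate duplication node with its three focal supports."""

    node_id: str
    bs1: float                      # support of the parent (duplication) node
    bs2: float                      # support of the first child clade
    bs3: float                      # support of the second child clade
    species_left: frozenset[str]
    species_right: frozenset[str]
    classification: str             # "shared" | "species_specific"
    supported: bool
    fully_supported: bool
    at_root: bool = False           # BS-1 read from the outgroup-adjacent split

    @property
    def shared_species(self) -> frozenset[str]:
        return self.species_left & self.species_right


def _clade_support(node: dendropy.Node, full: float) -> float:
    if node.is_leaf():
        return full  # a leaf is not an estimated clade
    s = getattr(node, "support", None)
    return full if s is None else s


def detect_duplications(tree: dendropy.Tree,
                        species_of: Mapping[str, str] | Callable[[str], str],
                        threshold: float | None = None) -> list[DuplicationCall]:
    """Call duplications on a rooted, support-annotated gene tree.

    Every internal node whose two child clades share >= 1 species yields a
    call; ``supported`` requires min(BS-1, BS-2, BS-3) >= threshold. The
    default threshold is 90 (bootstrap units) or 0.95 (posterior).
    """
    if not tree.is_rooted:
        raise ValueError("tree must be rooted (use root_by_outgroup)")
    units = getattr(tree, "support_units", "bootstrap")
    full = 100.0 if units == "bootstrap" else 1.0
    if threshold is None:
        threshold = 90.0 if units == "bootstrap" else 0.95
    if callable(species_of):
        sp = species_of
    else:
        mapping = dict(species_of)

        def sp(gene: str) -> str:
            if gene not in mapping:
                raise KeyError(f"no species mapping for leaf {gene!r}")
            return mapping[gene]

    calls: list[DuplicationCall] = []
    for idx, node in enumerate(tree.preorder_node_iter()):
        children = node.child_nodes()
        if len(children) != 2:
            continue
        left, right = children
        sp_left = frozenset(sp(lf.taxon.label) for lf in left.leaf_iter())
        sp_right = frozenset(sp(lf.taxon.label) for lf in right.leaf_iter())
        inter = sp_left & sp_right
        if not inter:
            continue
        at_root = node is tree.seed_node
        bs1 = getattr(node, "support", None)
        if bs1 is None:
            if at_root:
                # root support is not estimable; read the outgroup-adjacent
                # bipartition, i.e. the better-supported child clade
                bs1 = max(_clade_support(left, full), _clade_support(right, full))
            else:
                bs1 = full
        bs2 = _clade_support(left, full)
        bs3 = _clade_support(right, full)
        calls.append(DuplicationCall(
            node_id=f"node{idx}",
            bs1=bs1, bs2=bs2, bs3=bs3,
            species_left=sp_left, species_right=sp_right,
            classification="shared" if len(inter) >= 2 else "species_specific",
            supported=min(bs1, bs2, bs3) >= threshold,
            fully_supported=min(bs1, bs2, bs3) >= full,
            at_root=at_root,
        ))
    return calls


def run_exclusion_series(
    sequences: Mapping[str, str],
    exclusion_sets: Sequence[tuple[str, set[str]]],
    outgroup: str,
    species_of: Mapping[str, str],
    threshold: float = 90.0,
    replicates: int = 100,
    seed: int = 0,
) -> tuple[dict[str, list[DuplicationCall]], pd.DataFrame]:
    """Re-run tree building + duplication detection under taxon exclusions.

    Each entry of ``exclusion_sets`` is (analysis name, set of species to
    prune). The outgroup must survive every exclusion. Returns per-analysis
    calls plus a comparison table of supported shared duplications.
    """
    out_species = species_of[outgroup]
    results: dict[str, list[DuplicationCall]] = {}
    rows = []
    for name, excluded in exclusion_sets:
        if out_species in excluded:
            raise ValueError(f"analysis {name!r}: exclusion removes the outgroup")
        present = {species_of[g] for g in sequences}
        for taxon in excluded - present:
            warnings.warn(f"analysis {name!r}: taxon {taxon!r} absent; ignored")
        keep = {g: s for g, s in sequences.items() if species_of[g] not in excluded}
        if len(keep) < 4:
            raise ValueError(f"analysis {name!r}: fewer than 4 leaves remain")
        tree = bootstrap_supports(keep, replicates=replicates, seed=seed)
        rooted = root_by_outgroup(tree, outgroup)
        calls = detect_duplications(rooted, species_of, threshold=threshold)
        results[name] = calls
        for call in calls:
            rows.append({
                "analysis": name, "node": call.node_id,
                "bs1": call.bs1, "bs2": call.bs2, "bs3": call.bs3,
                "classification": call.classification,
                "supported": call.supported,
                "shared_species": ",".join(sorted(call.shared_species)),
            })
    table = pd.DataFrame(
        rows, columns=["analysis", "node", "bs1", "bs2", "bs3",
                       "classification", "supported", "shared_species"],
    )
    return results, table


# ---------------------------------------------------------------------------
# nomenclature


@dataclass
class NomenclatureMap:
    """gene_id -> assigned family name, plus genes no anchor clade covers."""

    names: dict[str, str]
    unclassified: frozenset[str]


def assign_subfamily_names(
    tree: dendropy.Tree,
    anchors: Mapping[str, int],
    family_prefix: str,
    species_of: Mapping[str, str] | None = None,
) -> NomenclatureMap:
    """Assign subfamily names from anchor genes of known subfamily.

    ``anchors`` maps anchor gene ids to their subfamily number (1, 2, ...).
    Every gene takes the subfamily of the smallest clade containing it and
    an anchor; genes whose smallest anchor-bearing clade mixes subfamilies
    stay unclassified. Within a species and subfamily, suffix letters follow
    the tree's leaf order: subfamily 1 uses A, C, E, ...; subfamily 2 uses
    B, D, F, ... A species with exactly one family member in the whole tree
    gets the bare ``<species>_<prefix>`` name.
    """
    if species_of is None:
        species_of = {}

    def sp(gene: str) -> str:
        return species_of.get(gene, gene.split("_", 1)[0])

    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = set(anchors) - set(leaves)
    if missing:
        raise KeyError(f"anchor genes not in tree: {sorted(missing)}")

    # subfamily of each gene = subfamily of the smallest anchor-bearing clade
    subfamily: dict[str, int | None] = {}
    for lf in tree.leaf_node_iter():
        gene = lf.taxon.label
        node = lf
        assigned: int | None = None
        while node is not None:
            here = {anchors[g] for g in
                    (x.taxon.label for x in node.leaf_iter()) if g in anchors}
            if here:
                assigned = here.pop() if len(here) == 1 else None
                break
            node = node.parent_node
        subfamily[gene] = assigned

    species_counts: dict[str, int] = {}
    for gene in leaves:
        species_counts[sp(gene)] = species_counts.get(sp(gene), 0) + 1

    names: dict[str, str] = {}
    unclassified: set[str] = set()
    letter_pos: dict[tuple[str, int], int] = {}
    for gene in leaves:  # leaf order = in-order traversal of the rooted tree
        species = sp(gene)
        if species_counts[species] == 1:
            names[gene] = f"{species}_{family_prefix}"
            continue
        fam = subfamily[gene]
        if fam is None:
            unclassified.add(gene)
            continue
        i = letter_pos.get((species, fam), 0)
        letter_pos[(species, fam)] = i + 1
        letter = chr(ord("A") + (fam - 1) + 2 * i)
        names[gene] = f"{species}_{family_prefix}{fam}{letter}"
    if len(set(names.values())) != len(names):
        raise ValueError("nomenclature produced duplicate names")
    return NomenclatureMap(names=names, unclassified=frozenset(unclassified))
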