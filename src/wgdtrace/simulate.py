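"""Ground-truthed synthetic WGD datasets.

The generator plants whole-genome duplications on chosen branches of a
species tree whose branch lengths are expected synonymous substitutions per
synonymous site. An ancestral genome of ``n_genes`` ordered gene families
evolves down the tree; at each WGD every chromosome is copied wholesale and
each duplicated gene is independently retained with the event's retention
probability (fractionation), so collinear duplicated gene orders with gaps
emerge exactly as post-polyploid genomes show them. Every divergence — WGD
or speciation — is recorded in per-family gene trees whose branch lengths
are true synonymous distances, giving exact expectations for every
downstream estimate.

Codon sequences use a stylised code built for an analytic link to NG86:
ancestral codons are drawn from the four NCN families (Ala, Thr, Pro, Ser),
whose third positions are strictly fourfold-degenerate and whose first
positions change amino acid on every substitution. Third positions then
evolve under Jukes-Cantor at the branch's synonymous rate and first
positions at ``omega`` times that rate, the second position staying fixed,
so the expected NG86 Ks of a pair equals its true synonymous path length
and no stop codon can ever arise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import dendropy
import numpy as np

from .formats_io import CdsRecord, GeneLocus

__all__ = [
    "WgdSpec",
    "SimConfig",
    "GNode",
    "SimTruth",
    "simulate_history",
    "simulate_sequences",
    "emit_dataset",
]

NUCS = "ACGT"


def two_wgd_benchmark(seed: int = 0, n_genes: int = 200,
                      codons_per_gene: int = 300) -> "SimConfig":
    """The standard two-WGD recovery scenario.

    Two species A and B share an ancient WGD at true pairwise synonymous
    distance 1.0 and a recent one at 0.3 (both with retention 0.8), mirroring
    the gamma -> salicoid series; their ortholog divergence (0.05) is small
    against the younger WGD, and O is a pre-WGD single-copy outgroup.
    """
    return SimConfig(
        species_tree="((A:0.025,B:0.025)AB:0.575,O:0.6)ROOT;",
        wgd_events=(
            WgdSpec(branch="AB", position=0.1 / 0.575, retention=0.8,
                    label="ancient"),
            WgdSpec(branch="AB", position=0.45 / 0.575, retention=0.8,
                    label="recent"),
        ),
        n_genes=n_genes, codons_per_gene=codons_per_gene, omega=0.2, seed=seed,
    )


def wgd_free_control(seed: int = 0, n_genes: int = 100,
                     codons_per_gene: int = 300) -> "SimConfig":
    """No polyploidy: every family stays single-copy per species (four
    species so trees are still estimable), so any supported shared
    duplication call is a false positive."""
    return SimConfig(
        species_tree="(((A:0.025,B:0.025)AB:0.275,C:0.3)ABC:0.3,O:0.6)ROOT;",
        wgd_events=(),
        n_genes=n_genes, codons_per_gene=codons_per_gene, omega=0.2, seed=seed,
    )


def basal_lineage_scenario(seed: int = 0, n_genes: int = 30,
                           codons_per_gene: int = 300) -> "SimConfig":
    """An early-diverging single-copy lineage C outside a shared WGD.

    C's lone gene sits on a long branch near the duplication stem and tends
    to attach inside one subgenome clade of the estimated tree, depressing
    the child-clade supports — the configuration the taxon-exclusion series
    is built to resolve.
    """
    return SimConfig(
        species_tree="(((A:0.05,B:0.05)AB:0.55,C:0.6)IN:0.15,O:0.75)ROOT;",
        wgd_events=(
            WgdSpec(branch="AB", position=0.1 / 0.55, retention=0.9,
                    label="ancient"),
        ),
        n_genes=n_genes, codons_per_gene=codons_per_gene, omega=0.2, seed=seed,
    )


@dataclass(frozen=True)
class WgdSpec:
    """One planted WGD: on the branch subtending ``branch`` (a node label of
    the species tree), at relative ``position`` along it, with per-duplicate
    ``retention`` probability."""

    branch: str
    position: float
    retention: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.position <= 1.0:
            raise ValueError(f"{self.label}: position must be in [0, 1]")
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError(f"{self.label}: retention must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    species_tree: str                       # newick; labelled internal nodes
    wgd_events: tuple[WgdSpec, ...] = ()
    n_genes: int = 200
    codons_per_gene: int = 300
    omega: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.codons_per_gene < 1:
            raise ValueError("codons_per_gene must be >= 1")


class GNode:
    """Gene-tree node; ``length`` is the synonymous distance to the parent."""

    __slots__ = ("length", "children", "event", "gene_id")

    def __init__(self, length: float = 0.0) -> None:
        self.length = length
        self.children: list[GNode] = []
        self.event: str | None = None   # WGD label or "spec:<node>" at splits
        self.gene_id: str | None = None  # set on extant tips

    def leaves(self) -> Iterator["GNode"]:
        if not self.children:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def newick(self, supports: float | None = None) -> str:
        if not self.children:
            return f"{self.gene_id}:{self.length:.6f}"
        inner = ",".join(c.newick(supports) for c in self.children)
        lab = "" if supports is None else f"{supports:g}"
        return f"({inner}){lab}:{self.length:.6f}"


@dataclass
class _Copy:
    family: int
    node: GNode


@dataclass
class SimTruth:
    """Complete ground truth of one simulated history."""

    config: SimConfig
    genomes: dict[str, dict[str, list[str]]]          # species -> chrom -> gene ids
    gene_trees: dict[int, GNode]                      # family -> root
    event_log: list[dict]                             # one row per duplicate decision
    true_pairs: list[dict]                            # gene_a, gene_b, distance, event

    def paralog_pairs(self, species: str | None = None) -> list[dict]:
        out = []
        for p in self.true_pairs:
            if not p["event"].startswith("spec:"):
                if species is None or (
                    p["gene_a"].split("_", 1)[0] == species
                    and p["gene_b"].split("_", 1)[0] == species
                ):
                    out.append(p)
        return out


def _label_species_tree(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.sim_label = node.taxon.label
        elif node.label:
            node.sim_label = node.label
        else:
            i += 1
            node.sim_label = f"n{i}"


def simulate_history(cfg: SimConfig) -> SimTruth:
    """Run the retention/fractionation model and return full ground truth."""
    tree = dendropy.Tree.get(data=cfg.species_tree, schema="newick",
                             suppress_internal_node_taxa=True)
    _label_species_tree(tree)
    labels = {n.sim_label for n in tree.preorder_node_iter()}
    by_branch: dict[str, list[WgdSpec]] = {}
    for ev in cfg.wgd_events:
        if ev.branch not in labels:
            raise ValueError(f"WGD {ev.label!r} on unknown branch {ev.branch!r}")
        by_branch.setdefault(ev.branch, []).append(ev)
    for evs in by_branch.values():
        evs.sort(key=lambda e: e.position)
    rng = np.random.default_rng(cfg.seed)

    gene_trees = {f: GNode() for f in range(cfg.n_genes)}
    event_log: list[dict] = []
    genomes: dict[str, dict[str, list[str]]] = {}
    tip_gene_nodes: dict[str, GNode] = {}
    copy_counters: dict[tuple[str, int], int] = {}

    def split_genome(genome: list[list[_Copy]], node, n_children: int):
        """Speciation: every open lineage forks once, each child species
        continuing on its own branch."""
        child_genomes: list[list[list[_Copy]]] = [[] for _ in range(n_children)]
        for chrom in genome:
            per_child: list[list[_Copy]] = [[] for _ in range(n_children)]
            for cp in chrom:
                kids = [GNode() for _ in range(n_children)]
                cp.node.children = kids
                cp.node.event = f"spec:{node.sim_label}"
                for k, kid in enumerate(kids):
                    per_child[k].append(_Copy(cp.family, kid))
            for k in range(n_children):
                child_genomes[k].append(per_child[k])
        return child_genomes

    def apply_wgd(genome: list[list[_Copy]], ev: WgdSpec, branch_label: str) -> None:
        new_chroms: list[list[_Copy]] = []
        for ci, chrom in enumerate(genome):
            dup_chrom: list[_Copy] = []
            for cp in chrom:
                retained = bool(rng.random() < ev.retention)
                event_log.append({
                    "wgd": ev.label, "branch": branch_label,
                    "family": cp.family, "chromosome_index": ci,
                    "retained": retained,
                })
                if retained:
                    orig, dup = GNode(), GNode()
                    cp.node.children = [orig, dup]
                    cp.node.event = ev.label
                    cp.node = orig
                    dup_chrom.append(_Copy(cp.family, dup))
            new_chroms.append(dup_chrom)
        genome.extend(new_chroms)

    def run_branch(node, genome: list[list[_Copy]]) -> None:
        length = node.edge.length or 0.0
        events = by_branch.get(node.sim_label, [])
        pos = 0.0
        for ev in events:
            seg = (ev.position - pos) * length
            for chrom in genome:
                for cp in chrom:
                    cp.node.length += seg
            apply_wgd(genome, ev, node.sim_label)
            pos = ev.position
        seg = (1.0 - pos) * length
        for chrom in genome:
            for cp in chrom:
                cp.node.length += seg
        if node.is_leaf():
            species = node.sim_label
            genomes[species] = {}
            for ci, chrom in enumerate(genome):
                chrom_name = f"{species}_chr{ci + 1}"
                ids = []
                for cp in chrom:
                    k = copy_counters.get((species, cp.family), 0)
                    copy_counters[(species, cp.family)] = k + 1
                    gid = f"{species}_f{cp.family:04d}{chr(ord('a') + k)}"
                    cp.node.gene_id = gid
                    tip_gene_nodes[gid] = cp.node
                    ids.append(gid)
                if ids:
                    genomes[species][chrom_name] = ids
        else:
            children = node.child_nodes()
            for child, child_genome in zip(children,
                                           split_genome(genome, node, len(children))):
                run_branch(child, child_genome)

    root = tree.seed_node
    root_genome: list[list[_Copy]] = [
        [_Copy(f, gene_trees[f]) for f in range(cfg.n_genes)]
    ]
    root_children = root.child_nodes()
    if not root_children:
        raise ValueError("species tree must have at least two tips")
    for child, child_genome in zip(root_children,
                                   split_genome(root_genome, root, len(root_children))):
        run_branch(child, child_genome)

    true_pairs = _collect_true_pairs(gene_trees)
    return SimTruth(config=cfg, genomes=genomes, gene_trees=gene_trees,
                    event_log=event_log, true_pairs=true_pairs)


def _collect_true_pairs(gene_trees: dict[int, GNode]) -> list[dict]:
    """All extant within-family pairs with true synonymous path distances and
    the event at their divergence node."""
    pairs: list[dict] = []

    def walk(node: GNode) -> list[tuple[str, float]]:
        if not node.children:
            return [(node.gene_id, node.length)]
        below: list[list[tuple[str, float]]] = [walk(c) for c in node.children]
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for ga, da in below[i]:
                    for gb, db in below[j]:
                        a, b = (ga, gb) if ga <= gb else (gb, ga)
                        pairs.append({
                            "gene_a": a, "gene_b": b,
                            "distance": da + db,
                            "event": node.event or "unknown",
                        })
        merged = [(g, d + node.length) for sub in below for g, d in sub]
        return merged

    for fam in sorted(gene_trees):
        walk(gene_trees[fam])
    return pairs


def pick_focal_family(event_log: list[dict], n_genes: int,
                      prefer: int | None = None) -> int:
    """Choose a focal family that retained its duplicate at every WGD.

    Mirrors how a focal family is chosen on real data: the study anchor is
    a family whose duplicated syntenic copies survived fractionation at each
    event. Prefers ``prefer`` (or the middle of the gene order) and otherwise
    takes the nearest fully retained family; with no WGDs the preferred
    family is returned unchanged.
    """
    events = {e["wgd"] for e in event_log}
    if prefer is None:
        prefer = n_genes // 2
    if not events:
        return prefer
    retained: dict[int, set[str]] = {}
    for e in event_log:
        if e["retained"]:
            retained.setdefault(e["family"], set()).add(e["wgd"])
    full = [f for f, evs in retained.items() if evs == events]
    if not full:
        raise ValueError("no family retained duplicates at every WGD")
    return min(full, key=lambda f: (abs(f - prefer), f))


def truth_loci(truth: SimTruth, gene_span: int = 900,
               spacing: int = 1000) -> dict[str, GeneLocus]:
    """Gene loci (with ranks) straight from the simulated gene orders."""
    loci: dict[str, GeneLocus] = {}
    for species in sorted(truth.genomes):
        for chrom in sorted(truth.genomes[species]):
            for i, gid in enumerate(truth.genomes[species][chrom]):
                loci[gid] = GeneLocus(
                    gene_id=gid, species=species, chromosome=chrom,
                    start=i * spacing, end=i * spacing + gene_span, rank=i,
                )
    return loci


# ---------------------------------------------------------------------------
# sequence evolution


def _jc_substitute(states: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor branch over 4 states: each site differs from its
    parent with probability 3/4 (1 - exp(-4t/3)), landing uniformly on one
    of the other three nucleotides."""
    if t <= 0:
        return states.copy()
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    out = states.copy()
    hit = rng.random(states.size) < p_diff
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate_sequences(truth: SimTruth, cfg: SimConfig | None = None) -> dict[str, CdsRecord]:
    """Evolve codon sequences along the true gene trees (see module docs for
    the NCN-code construction that ties NG86 Ks to the true distances)."""
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1)  # independent stream from history
    n = cfg.codons_per_gene
    records: dict[str, CdsRecord] = {}

    def evolve(node: GNode, pos1: np.ndarray, pos3: np.ndarray) -> None:
        p1 = _jc_substitute(pos1, node.length * cfg.omega, rng)
        p3 = _jc_substitute(pos3, node.length, rng)
        if not node.children:
            codons = [NUCS[a] + "C" + NUCS[b] for a, b in zip(p1, p3)]
            seq = "".join(codons)
            gid = node.gene_id
            records[gid] = CdsRecord(
                gene_id=gid, species=gid.split("_", 1)[0], sequence=seq
            )
        else:
            for child in node.children:
                evolve(child, p1, p3)

    for fam in sorted(truth.gene_trees):
        anc1 = rng.integers(0, 4, size=n)
        anc3 = rng.integers(0, 4, size=n)
        evolve(truth.gene_trees[fam], anc1, anc3)
    return records


# ---------------------------------------------------------------------------
# dataset emission


def emit_dataset(truth: SimTruth, seqs: dict[str, CdsRecord],
                 outdir: str | Path) -> dict:
    """Write the five dataset artifacts (CDS FASTA, BED gene orders, anchor
    TSV, true gene trees, truth JSON) plus a checksummed manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_len = 3 * truth.config.codons_per_gene

    fasta = outdir / "cds.fasta"
    with open(fasta, "w") as fh:
        for gid in sorted(seqs):
            fh.write(f">{gid}\n{seqs[gid].sequence}\n")

    bed = outdir / "genes.bed"
    with open(bed, "w") as fh:
        for species in sorted(truth.genomes):
            for chrom in sorted(truth.genomes[species]):
                for i, gid in enumerate(truth.genomes[species][chrom]):
                    start = i * 1000
                    fh.write(f"{chrom}\t{start}\t{start + gene_len}\t{gid}\t0\t+\n")

    anchors = outdir / "anchors.tsv"
    with open(anchors, "w") as fh:
        fh.write("gene_a\tgene_b\tsimilarity\n")
        for p in truth.true_pairs:
            sim = max(1.0, 50.0 - p["distance"])
            fh.write(f"{p['gene_a']}\t{p['gene_b']}\t{sim:.4f}\n")

    trees = outdir / "gene_trees.nwk"
    with open(trees, "w") as fh:
        for fam in sorted(truth.gene_trees):
            fh.write(truth.gene_trees[fam].newick(supports=100) + ";\n")

    truth_json = outdir / "truth.json"
    with open(truth_json, "w") as fh:
        json.dump({
            "config": {
                "species_tree": truth.config.species_tree,
                "wgd_events": [vars(e) if not hasattr(e, "__dataclass_fields__")
                               else {k: getattr(e, k) for k in
                                     ("branch", "position", "retention", "label")}
                               for e in truth.config.wgd_events],
                "n_genes": truth.config.n_genes,
                "codons_per_gene": truth.config.codons_per_gene,
                "omega": truth.config.omega,
                "seed": truth.config.seed,
            },
            "genomes": truth.genomes,
            "event_log": truth.event_log,
            "true_pairs": truth.true_pairs,
        }, fh, indent=0, sort_keys=True)

    files = [fasta, bed, anchors, trees, truth_json]
    manifest = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
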