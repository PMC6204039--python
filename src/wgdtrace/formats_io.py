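"""Readers, writers and gene-structure utilities.

All external representations touched by the pipeline come through this
module: in-frame CDS FASTA, gene models (GFF3 / BED), Newick gene trees
with support labels, and TSV/SIF edge lists for the synteny network.
Coordinates are normalised to an internal 0-based half-open convention at
the I/O boundary; GFF3 is 1-based inclusive, BED already 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "CdsRecord",
    "GeneLocus",
    "GeneModel",
    "FrameError",
    "CdsValidationError",
    "FormatError",
    "read_cds_fasta",
    "read_gene_models",
    "read_tree_newick",
    "compute_intron_phases",
    "write_edge_list",
    "isoform_stem",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


class FrameError(ValueError):
    """CDS length is not a multiple of three."""


class CdsValidationError(ValueError):
    """CDS contains an internal stop codon or invalid characters."""


class FormatError(ValueError):
    """Malformed or empty input file."""


@dataclass(frozen=True)
class CdsRecord:
    """One in-frame coding sequence, species-prefixed (e.g. ``Vitvi_VOZ1A``)."""

    gene_id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0:
            raise FrameError(
                f"{self.gene_id}: CDS length {len(self.sequence)} is not divisible by 3"
            )
        if not set(self.sequence) <= set("ACGT"):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise CdsValidationError(f"{self.gene_id}: non-ACGT characters {bad}")
        for i in range(0, len(self.sequence) - 3, 3):
            if self.sequence[i : i + 3] in STOP_CODONS:
                raise CdsValidationError(
                    f"{self.gene_id}: internal stop codon at nt {i}"
                )

    @property
    def codons(self) -> list[str]:
        return [self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)]

    @property
    def protein(self) -> str:
        return str(Seq(self.sequence).translate())


@dataclass
class GeneLocus:
    """Chromosomal placement of one gene (0-based half-open, internal units)."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1  # order index along the chromosome; assigned after loading

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: require 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass
class GeneModel:
    """A gene locus plus its coding-exon structure (5'->3' transcript order).

    ``exon_spans`` keeps the genomic (start, end) of each CDS segment in
    ascending genomic order, so GFF3 round trips are exact; it is optional for
    models built programmatically.
    """

    locus: GeneLocus
    exon_cds_lengths: list[int]
    exon_spans: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.exon_cds_lengths:
            raise ValueError(f"{self.locus.gene_id}: gene model needs >= 1 exon")
        if any(x <= 0 for x in self.exon_cds_lengths):
            raise ValueError(f"{self.locus.gene_id}: exon CDS lengths must be positive")


def _species_of(gene_id: str) -> str:
    return gene_id.split("_", 1)[0] if "_" in gene_id else gene_id


def isoform_stem(gene_id: str) -> str:
    """Isoform grouping key: the id up to the last '.'-separated suffix.

    Phytozome-style names (``Potri.004G050900.1``, ``.2`` ...) collapse to the
    locus stem; ids without a dot are their own stem.
    """
    if "." in gene_id:
        stem, suffix = gene_id.rsplit(".", 1)
        if suffix.isdigit():
            return stem
    return gene_id


def read_cds_fasta(path: str | Path, isoform_policy: str = "longest") -> list[CdsRecord]:
    """Read and validate in-frame CDS records from FASTA.

    Terminal stop codons are stripped; internal stops are rejected. With
    ``isoform_policy='longest'`` only the longest sequence per isoform stem is
    kept (mirroring primary-transcript selection); ``'all'`` keeps every record.
    """
    if isoform_policy not in ("longest", "all"):
        raise ValueError(f"unknown isoform_policy {isoform_policy!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    out: list[CdsRecord] = []
    seen: set[str] = set()
    for rec in records:
        seq = str(rec.seq).upper()
        if len(seq) % 3 != 0:
            raise FrameError(f"{rec.id}: CDS length {len(seq)} is not divisible by 3")
        if seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        if rec.id in seen:
            raise CdsValidationError(f"duplicate gene_id {rec.id}")
        seen.add(rec.id)
        out.append(CdsRecord(gene_id=rec.id, species=_species_of(rec.id), sequence=seq))
    if isoform_policy == "longest":
        best: dict[str, CdsRecord] = {}
        for r in out:
            stem = isoform_stem(r.gene_id)
            if stem not in best or len(r.sequence) > len(best[stem].sequence):
                best[stem] = r
        # preserve input encounter order of the winning records
        keep = {id(v) for v in best.values()}
        out = [r for r in out if id(r) in keep]
    return out


def _assign_ranks(models: list[GeneModel]) -> None:
    by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault((m.locus.species, m.locus.chromosome), []).append(m)
    for group in by_chrom.values():
        for rank, m in enumerate(sorted(group, key=lambda g: (g.locus.start, g.locus.gene_id))):
            m.locus.rank = rank


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def read_gene_models(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 (CDS features, grouped by Parent/ID) or BED.

    BED6 yields single-exon models; BED12 block fields give the exon structure.
    Coordinates come back 0-based half-open with exon CDS lengths in transcript
    (5'->3') order and per-chromosome ranks assigned by start position.
    """
    if format == "gff3":
        models = _read_gff3(Path(path))
    elif format == "bed":
        models = _read_bed(Path(path))
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    _assign_ranks(models)
    return models


def _read_gff3(path: Path) -> list[GeneModel]:
    # (chrom, strand, gene) -> list of (start0, end0) CDS segments
    segs: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    order: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}: GFF3 line with {len(parts)} columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
            if ftype != "CDS":
                continue
            a = dict(_GFF_ATTR.findall(attrs))
            gid = a.get("Parent") or a.get("ID")
            if gid is None:
                raise FormatError(f"{path}: CDS feature without Parent/ID")
            key = (chrom, strand, gid)
            if key not in segs:
                segs[key] = []
                order.append(key)
            segs[key].append((int(start) - 1, int(end)))  # GFF3 1-based inclusive
    models = []
    for chrom, strand, gid in order:
        spans = sorted(segs[(chrom, strand, gid)])
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise CdsValidationError(f"{gid}: overlapping CDS segments")
        lengths = [e - s for s, e in spans]
        if strand == "-":
            lengths = lengths[::-1]
        locus = GeneLocus(
            gene_id=gid, species=_species_of(gid), chromosome=chrom,
            start=spans[0][0], end=spans[-1][1], strand=strand,
        )
        models.append(GeneModel(locus=locus, exon_cds_lengths=lengths, exon_spans=spans))
    return models


def _read_bed(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: BED line with {len(parts)} columns")
            chrom, start, end, gid = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) >= 6 else "+"
            if len(parts) >= 12:  # BED12 blocks
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                lengths = sizes[::-1] if strand == "-" else sizes
            else:
                lengths = [end - start]
            locus = GeneLocus(
                gene_id=gid, species=_species_of(gid), chromosome=chrom,
                start=start, end=end, strand=strand,
            )
            models.append(GeneModel(locus=locus, exon_cds_lengths=lengths))
    return models


def write_gene_models_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Inverse of :func:`read_gene_models` for format='gff3' (round-trip exact)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            loc = m.locus
            if m.exon_spans is not None:
                spans = m.exon_spans
            else:
                lengths = (
                    m.exon_cds_lengths[::-1] if loc.strand == "-" else m.exon_cds_lengths
                )
                spans, pos = [], loc.start
                for ln in lengths:
                    spans.append((pos, pos + ln))
                    pos += ln
            for s, e in spans:
                fh.write(
                    f"{loc.chromosome}\twgdtrace\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{loc.strand}\t.\tParent={loc.gene_id}\n"
                )


def compute_intron_phases(model: GeneModel) -> list[int]:
    """Intron phases: cumulative coding length of the preceding exons, mod 3.

    A four-exon gene with coding lengths [99, 150, 100, 200] has phases
    [0, 0, 1] — the conserved pattern of the focal family.
    """
    phases = []
    total = 0
    for ln in model.exon_cds_lengths[:-1]:
        total += ln
        phases.append(total % 3)
    return phases


def read_tree_newick(path: str | Path, support_units: str = "bootstrap") -> dendropy.Tree:
    """Parse a Newick gene tree whose internal-node labels are support values.

    The tree comes back with ``node.support`` (float or None) on internal nodes
    and ``tree.support_units`` set to ``'bootstrap'`` (range 0-100) or
    ``'posterior'`` (range 0-1). Missing branch lengths default to 0.
    """
    if support_units not in ("bootstrap", "posterior"):
        raise ValueError(f"unknown support_units {support_units!r}")
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: Newick parse error: {exc}") from exc
    hi = 100.0 if support_units == "bootstrap" else 1.0
    for node in tree.preorder_node_iter():
        if node.edge.length is None:
            node.edge.length = 0.0
        node.support = None
        if not node.is_leaf() and node.label is not None:
            try:
                val = float(node.label)
            except ValueError:
                continue
            if not (0.0 <= val <= hi):
                raise CdsValidationError(
                    f"support {val} outside [0, {hi}] for {support_units} units"
                )
            node.support = val
    tree.support_units = support_units
    return tree


def write_edge_list(network, path: str | Path, format: str = "tsv") -> None:
    """Export a locus network as a deterministic (lexicographically sorted)
    TSV or SIF edge list for external renderers."""
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {format!r}")
    rows = sorted(
        (min(u, v), max(u, v), w) for u, v, w in network.edges()
    )
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write("node_a\tnode_b\tweight\n")
            for u, v, w in rows:
                fh.write(f"{u}\t{v}\t{w:.6f}\n")
        else:
            for u, v, w in rows:
                fh.write(f"{u}\tsyntenic\t{v}\n")
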