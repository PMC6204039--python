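"""Pairwise Ka/Ks estimation: protein-guided codon alignment and the
Nei-Gojobori (1986) counting method with Jukes-Cantor correction.

NG86 counts synonymous (S) and nonsynonymous (N) sites per codon by
enumerating the three single-nucleotide neighbours at each position
(mutations creating stop codons are excluded from the denominator), and
scores codon pairs differing at several positions by averaging synonymous /
nonsynonymous differences over all substitution pathways that avoid stop
codons. Proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits
with d = -3/4 ln(1 - 4/3 p), which saturates at p >= 3/4.

Site and pathway counts for all 61 x 61 sense-codon pairs are precomputed
once, so scoring an alignment is a table lookup per column; this is what
makes bootstrap tree building over NG86 distances affordable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .formats_io import CdsRecord, STOP_CODONS

__all__ = [
    "ProteinAlignment",
    "CodonAlignment",
    "NgCounts",
    "KsEstimate",
    "SATURATED",
    "align_proteins_global",
    "back_translate",
    "ng86_counts",
    "ks_estimate",
    "ks_pair",
    "filter_ks_pairs",
    "gc3",
    "ng86_distance_matrix",
]

SATURATED = float("inf")

NUCS = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}

_TRANSLATE = {c: str(Seq(c).translate()) for c in ALL_CODONS}


# ---------------------------------------------------------------------------
# precomputed NG86 tables


def _syn_site_fraction(codon: str) -> float:
    """Synonymous-site count of one codon: sum over positions of the fraction
    of non-stop single-nucleotide neighbours that are synonymous."""
    aa = _TRANSLATE[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for n in NUCS:
            if n == codon[pos]:
                continue
            nb = codon[:pos] + n + codon[pos + 1 :]
            if nb in STOP_CODONS:
                continue
            valid += 1
            if _TRANSLATE[nb] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


def _pathway_diffs(a: str, b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two sense
    codons over all substitution orderings that avoid stop codons."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    sd_sum = nd_sum = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _TRANSLATE[cur] == _TRANSLATE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            sd_sum += sd
            nd_sum += nd
            n_paths += 1
    if n_paths == 0:
        return math.nan, math.nan  # no stop-free pathway; column is skipped
    return sd_sum / n_paths, nd_sum / n_paths


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    syn_sites = np.full(64, np.nan)
    for c in SENSE_CODONS:
        syn_sites[CODON_INDEX[c]] = _syn_site_fraction(c)
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    valid = np.zeros((64, 64), dtype=bool)
    for a in SENSE_CODONS:
        ia = CODON_INDEX[a]
        for b in SENSE_CODONS:
            ib = CODON_INDEX[b]
            s, n = _pathway_diffs(a, b)
            sd[ia, ib] = s
            nd[ia, ib] = n
            valid[ia, ib] = not math.isnan(s)
    return syn_sites, sd, nd, valid


SYN_SITES, SD_TABLE, ND_TABLE, PAIR_VALID = _build_tables()


def encode_codons(sequence: str) -> np.ndarray:
    """Encode a CDS into codon indices 0..63; -1 marks gaps / ambiguity /
    stop codons (columns carrying -1 are skipped by the counters)."""
    n = len(sequence) // 3
    out = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        codon = sequence[3 * i : 3 * i + 3]
        idx = CODON_INDEX.get(codon, -1)
        if idx >= 0 and codon not in STOP_CODONS:
            out[i] = idx
    return out


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class ProteinAlignment:
    """A global pairwise amino-acid alignment (gapped strings, equal length)."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in length")


@dataclass(frozen=True)
class CodonAlignment:
    """Aligned codon columns; '---' marks a gap cell."""

    gene_a: str
    gene_b: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.codons_a)


@lru_cache(maxsize=1)
def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_proteins_global(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> ProteinAlignment:
    """Optimal global alignment (BLOSUM62, affine gaps) of two protein
    sequences; the first alignment of Biopython's deterministic enumeration
    is taken, so ties break reproducibly."""
    if not a or not b:
        raise ValueError("empty protein sequence")
    alphabet = set("ACDEFGHIKLMNPQRSTVWY")
    for name, s in (("a", a), ("b", b)):
        bad = set(s) - alphabet
        if bad:
            raise ValueError(f"sequence {name}: invalid residues {sorted(bad)}")
    aln = (aligner or _default_aligner()).align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ProteinAlignment(seq_a=ga, seq_b=gb)


def back_translate(aln: ProteinAlignment, cds_a: CdsRecord, cds_b: CdsRecord) -> CodonAlignment:
    """Replace each aligned residue by its source codon ('---' at gaps).

    Each CDS must translate exactly to the ungapped protein it aligns as;
    a mismatch raises naming the offending column.
    """
    cols_a, cols_b = [], []
    ia = ib = 0
    codons_a, codons_b = cds_a.codons, cds_b.codons
    for col, (ra, rb) in enumerate(zip(aln.seq_a, aln.seq_b)):
        if ra == "-":
            cols_a.append("---")
        else:
            if ia >= len(codons_a) or _TRANSLATE.get(codons_a[ia], "?") != ra:
                raise ValueError(
                    f"{cds_a.gene_id}: translation mismatch at alignment column {col}"
                )
            cols_a.append(codons_a[ia])
            ia += 1
        if rb == "-":
            cols_b.append("---")
        else:
            if ib >= len(codons_b) or _TRANSLATE.get(codons_b[ib], "?") != rb:
                raise ValueError(
                    f"{cds_b.gene_id}: translation mismatch at alignment column {col}"
                )
            cols_b.append(codons_b[ib])
            ib += 1
    if ia != len(codons_a) or ib != len(codons_b):
        raise ValueError("codon alignment did not consume both CDS sequences")
    return CodonAlignment(
        gene_a=cds_a.gene_id, gene_b=cds_b.gene_id,
        codons_a=tuple(cols_a), codons_b=tuple(cols_b),
    )


# ---------------------------------------------------------------------------
# counting and correction


@dataclass(frozen=True)
class NgCounts:
    S: float      # synonymous sites (averaged over the two sequences)
    N: float      # nonsynonymous sites
    Sd: float     # synonymous differences
    Nd: float     # nonsynonymous differences
    L: int        # compared codon columns


def _counts_from_indices(ca: np.ndarray, cb: np.ndarray) -> NgCounts:
    mask = (ca >= 0) & (cb >= 0)
    ca, cb = ca[mask], cb[mask]
    if ca.size:
        mask2 = PAIR_VALID[ca, cb]
        ca, cb = ca[mask2], cb[mask2]
    if ca.size == 0:
        raise ValueError("no comparable codon columns (all gapped/stop/ambiguous)")
    s = float((SYN_SITES[ca].sum() + SYN_SITES[cb].sum()) / 2.0)
    n = float(3.0 * ca.size - s)
    sd = float(SD_TABLE[ca, cb].sum())
    nd = float(ND_TABLE[ca, cb].sum())
    return NgCounts(S=s, N=n, Sd=sd, Nd=nd, L=int(ca.size))


def ng86_counts(aln: CodonAlignment) -> NgCounts:
    """NG86 site and difference counts for one codon alignment. Columns with
    a gap, stop or ambiguous codon on either side are skipped whole."""
    ca = encode_codons("".join(c if len(c) == 3 else "NNN" for c in aln.codons_a))
    cb = encode_codons("".join(c if len(c) == 3 else "NNN" for c in aln.codons_b))
    return _counts_from_indices(ca, cb)


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; saturates (returns inf) at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return SATURATED
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def gc3(sequence: str) -> float:
    """G+C fraction at codon third positions of an ungapped CDS."""
    third = sequence[2::3]
    if not third:
        return 0.0
    return (third.count("G") + third.count("C")) / len(third)


@dataclass(frozen=True)
class KsEstimate:
    gene_a: str
    gene_b: str
    ks: float          # JC-corrected synonymous distance; inf when saturated
    ka: float
    p_s: float
    p_n: float
    gc3: float         # mean third-position GC of the two full CDS
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def saturated(self) -> bool:
        return "SATURATED" in self.flags


def ks_estimate(counts: NgCounts, cds_a: CdsRecord, cds_b: CdsRecord,
                max_ks: float = 2.0, gc3_cutoff: float = 0.75) -> KsEstimate:
    """Correct NG86 proportions to Ka/Ks and attach QC flags.

    Flags: SATURATED (pS >= 3/4, correction undefined), KS_GT_MAX
    (ks > max_ks), GC3_HIGH (mean full-CDS third-position GC > cutoff —
    only acted on for configured taxa at the filtering stage).
    """
    if counts.S <= 0 or counts.N <= 0:
        raise ValueError("degenerate comparison: S or N is zero")
    p_s = counts.Sd / counts.S
    p_n = counts.Nd / counts.N
    ks = jukes_cantor(p_s)
    ka = jukes_cantor(p_n)
    g = (gc3(cds_a.sequence) + gc3(cds_b.sequence)) / 2.0
    flags = set()
    if ks == SATURATED:
        flags.add("SATURATED")
    elif ks > max_ks:
        flags.add("KS_GT_MAX")
    if g > gc3_cutoff:
        flags.add("GC3_HIGH")
    return KsEstimate(
        gene_a=cds_a.gene_id, gene_b=cds_b.gene_id,
        ks=ks, ka=ka, p_s=p_s, p_n=p_n, gc3=g, flags=frozenset(flags),
    )


def ks_pair(cds_a: CdsRecord, cds_b: CdsRecord, **kwargs) -> KsEstimate:
    """Full per-pair route: protein alignment -> back-translation -> NG86 ->
    JC correction."""
    aln = align_proteins_global(cds_a.protein, cds_b.protein)
    codon_aln = back_translate(aln, cds_a, cds_b)
    return ks_estimate(ng86_counts(codon_aln), cds_a, cds_b, **kwargs)


def filter_ks_pairs(
    estimates: list[KsEstimate],
    max_ks: float = 2.0,
    gc3_cutoff: float = 0.75,
    gc3_taxa: set[str] | frozenset[str] = frozenset(),
) -> tuple[list[KsEstimate], list[tuple[KsEstimate, str]]]:
    """Apply the saturation and GC3 reliability filters.

    Pairs with ks > max_ks (or saturated pS) are dropped; pairs with mean
    GC3 above the cutoff are dropped only when *both* genes belong to
    ``gc3_taxa`` (the grass-genome rule). Returns (retained, rejections),
    each rejection tagged with its reason.
    """
    kept: list[KsEstimate] = []
    rejected: list[tuple[KsEstimate, str]] = []
    for est in estimates:
        if est.saturated or est.ks > max_ks:
            rejected.append((est, "KS_GT_MAX" if not est.saturated else "SATURATED"))
            continue
        sp_a = est.gene_a.split("_", 1)[0]
        sp_b = est.gene_b.split("_", 1)[0]
        if est.gc3 > gc3_cutoff and sp_a in gc3_taxa and sp_b in gc3_taxa:
            rejected.append((est, "GC3_HIGH"))
            continue
        kept.append(est)
    return kept, rejected


def ng86_distance_matrix(encoded: dict[str, np.ndarray],
                         columns: np.ndarray | None = None,
                         saturation_cap: float = 4.0) -> tuple[list[str], np.ndarray]:
    """Pairwise NG86 Ks distance matrix over pre-encoded codon sequences.

    ``columns`` optionally selects (bootstrap-resampled) codon columns.
    Saturated or degenerate pairs get ``saturation_cap`` so NJ stays finite.
    Labels come back sorted for deterministic downstream tie-breaking.
    """
    labels = sorted(encoded)
    n = len(labels)
    mat = np.zeros((n, n))
    arrs = [encoded[l] if columns is None else encoded[l][columns] for l in labels]
    for i in range(n):
        for j in range(i + 1, n):
            try:
                c = _counts_from_indices(arrs[i], arrs[j])
                d = jukes_cantor(c.Sd / c.S) if c.S > 0 else SATURATED
            except ValueError:
                d = SATURATED
            if not math.isfinite(d):
                d = saturation_cap
            mat[i, j] = mat[j, i] = d
    return labels, mat
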