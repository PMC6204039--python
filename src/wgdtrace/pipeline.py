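"""End-to-end orchestration: synteny -> syntelog extraction -> Ks filtering
-> dating (CI, KDE peaks, WGD matching), with optional gene-tree duplication
calls. Every stage persists plain TSV/JSON so externally computed anchors or
trees can be substituted at any cut point, and the run report records every
parameter and every filter rejection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import dating, formats_io, genetree, ks_engine, simulate, synteny

logger = logging.getLogger("wgdtrace")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "load_anchor_pairs",
    "ks_peak_study",
    "duplication_recovery_study",
]


@dataclass
class PipelineConfig:
    cds_path: str
    gene_models_path: str
    anchors_path: str
    focal_genes: tuple[str, ...]
    outdir: str
    gene_models_format: str = "bed"
    reference_table: str | None = None     # packaged literature table if None
    scope: str | None = None               # lineage filter for WGD matching
    max_ks: float = 2.0
    gc3_cutoff: float = 0.75
    gc3_taxa: tuple[str, ...] = ()
    chain: synteny.ChainParams = field(default_factory=synteny.ChainParams)
    tree_path: str | None = None
    species_map: Mapping[str, str] | None = None
    outgroup: str | None = None
    support_threshold: float = 90.0
    rate: float | None = None              # synonymous subs/site/year for dating
    seed: int = 0

    def validate(self) -> None:
        for name in ("cds_path", "gene_models_path", "anchors_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if not self.focal_genes:
            raise ValueError("at least one focal gene is required")


def load_anchor_pairs(path: str | Path,
                      loci: Mapping[str, formats_io.GeneLocus]) -> list[synteny.AnchorPair]:
    """Read an anchor TSV (gene_a, gene_b, similarity) against known loci;
    rows naming unknown genes are skipped with a log entry."""
    df = pd.read_csv(path, sep="\t")
    anchors = []
    skipped = 0
    for row in df.itertuples(index=False):
        la, lb = loci.get(row.gene_a), loci.get(row.gene_b)
        if la is None or lb is None:
            skipped += 1
            continue
        anchors.append(synteny.AnchorPair(locus_a=la, locus_b=lb,
                                          similarity=float(row.similarity)))
    if skipped:
        logger.info("anchors: skipped %d rows with unresolvable loci", skipped)
    return anchors


def ks_peak_study(truth, seqs, focal_family: int | None = None,
                  species: str = "A",
                  refs: Sequence[dating.WgdReference] | None = None,
                  chain: synteny.ChainParams | None = None) -> dict:
    """Syntelog Ks dating on one simulated genome, in memory.

    Chains the species' true paralog anchors into blocks, extracts syntelogs
    around the focal family's copies, estimates and filters Ks, and locates /
    matches the density peaks. The focal family defaults to one whose
    duplicates survived every planted WGD (how a study family is chosen on
    real data). Returns the retained sample, peaks and assignments.
    """
    if focal_family is None:
        focal_family = simulate.pick_focal_family(
            truth.event_log, truth.config.n_genes)
    loci = simulate.truth_loci(truth)
    anchors = [
        synteny.AnchorPair(locus_a=loci[p["gene_a"]], locus_b=loci[p["gene_b"]],
                           similarity=max(1.0, 50.0 - p["distance"]))
        for p in truth.paralog_pairs(species)
    ]
    blocks = synteny.chain_anchors_grouped(anchors, chain)
    focal = sorted(g for g in loci
                   if g.startswith(f"{species}_f{focal_family:04d}"))
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for f in focal:
        for pr in synteny.extract_flanking_syntelogs(blocks, f):
            if pr not in seen:
                seen.add(pr)
                pairs.append(pr)
    estimates = [ks_engine.ks_pair(seqs[a], seqs[b]) for a, b in pairs]
    kept, rejected = ks_engine.filter_ks_pairs(estimates)
    peaks: list[dating.KsPeak] = []
    assignments: list[dating.PeakAssignment] = []
    ci = None
    if len(kept) >= 2:
        sample = dating.KsSample(values=tuple(e.ks for e in kept),
                                 source=f"{species} syntelogs")
        ci = dating.mean_ci(sample)
        peaks = dating.kde_peaks(sample)
        if refs is not None:
            assignments = dating.match_wgd(None, peaks, refs)
    return {"blocks": blocks, "pairs": pairs, "kept": kept,
            "rejected": rejected, "ci": ci, "peaks": peaks,
            "assignments": assignments}


def duplication_recovery_study(truth, seqs, outgroup_species: str = "O",
                               shared_species: tuple[str, str] = ("A", "B"),
                               threshold: float = 90.0, replicates: int = 100,
                               seed: int = 0) -> dict:
    """Per-family NJ + bootstrap + support-based duplication calling.

    For every planted WGD, counts the families whose retained duplicates
    (inherited by the shared species) yield a supported shared duplication
    call, and counts supported shared calls overall (the false-positive
    measure on WGD-free simulations).
    """
    retained: dict[str, set[int]] = {}
    for e in truth.event_log:
        if e["retained"]:
            retained.setdefault(e["wgd"], set()).add(e["family"])
    by_family: dict[str, dict[str, str]] = {}
    for gid in seqs:
        fam = gid.split("_", 1)[1][1:5]
        by_family.setdefault(fam, {})[gid] = seqs[gid].sequence
    eligible = {w: 0 for w in retained}
    hits = {w: 0 for w in retained}
    total_supported_shared = 0
    families_scored = 0
    for fam_key in sorted(by_family):
        fam = int(fam_key)
        sub = by_family[fam_key]
        if len(sub) < 4:
            continue
        families_scored += 1
        tree = genetree.bootstrap_supports(sub, replicates=replicates,
                                           seed=seed + fam)
        out_gene = sorted(g for g in sub
                          if g.startswith(f"{outgroup_species}_"))[0]
        rooted = genetree.root_by_outgroup(tree, out_gene)
        calls = genetree.detect_duplications(
            rooted, {g: g.split("_", 1)[0] for g in sub}, threshold=threshold)
        ok = [c for c in calls
              if c.supported and c.classification == "shared"]
        total_supported_shared += len(ok)
        for w, fams in retained.items():
            if fam in fams:
                eligible[w] += 1
                if any(set(shared_species) <= c.shared_species for c in ok):
                    hits[w] += 1
    return {"eligible": eligible, "hits": hits,
            "recovery": {w: (hits[w] / eligible[w] if eligible[w] else None)
                         for w in retained},
            "supported_shared_calls": total_supported_shared,
            "families_scored": families_scored}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full inference and return the JSON-serialisable report.

    Artifacts written under ``cfg.outdir``: blocks.tsv, syntelogs.tsv,
    ks.tsv (with rejection reasons), peaks.tsv, network_edges.tsv,
    duplications.tsv (when a tree is supplied) and report.json.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {
        "max_ks": cfg.max_ks, "gc3_cutoff": cfg.gc3_cutoff,
        "gc3_taxa": list(cfg.gc3_taxa),
        "chain": vars(cfg.chain), "seed": cfg.seed,
        "support_threshold": cfg.support_threshold,
        "scope": cfg.scope, "rate": cfg.rate,
    }}

    stage = "io"
    try:
        cds = {r.gene_id: r for r in formats_io.read_cds_fasta(cfg.cds_path)}
        models = formats_io.read_gene_models(cfg.gene_models_path,
                                             format=cfg.gene_models_format)
        loci = {m.locus.gene_id: m.locus for m in models}
        anchors = load_anchor_pairs(cfg.anchors_path, loci)
        report["io"] = {"n_cds": len(cds), "n_loci": len(loci),
                        "n_anchors": len(anchors)}

        stage = "synteny"
        blocks = synteny.chain_anchors_grouped(anchors, cfg.chain)
        pd.DataFrame([{
            "block_id": b.block_id, "chrom_a": b.chromosomes[0],
            "chrom_b": b.chromosomes[1], "orientation": b.orientation,
            "n_anchors": b.n_anchors, "score": b.score,
            "anchors": ";".join(f"{a.gene_a}|{a.gene_b}" for a in b.anchors),
        } for b in blocks]).to_csv(outdir / "blocks.tsv", sep="\t", index=False)
        report["synteny"] = {"n_blocks": len(blocks)}

        stage = "syntelogs"
        pairs: list[tuple[str, str]] = []
        seen = set()
        for focal in cfg.focal_genes:
            for pair in synteny.extract_flanking_syntelogs(blocks, focal):
                if pair not in seen:
                    seen.add(pair)
                    pairs.append(pair)
        pd.DataFrame(pairs, columns=["gene_a", "gene_b"]).to_csv(
            outdir / "syntelogs.tsv", sep="\t", index=False)
        report["syntelogs"] = {"n_pairs": len(pairs)}

        stage = "ks"
        estimates = []
        for ga, gb in pairs:
            if ga not in cds or gb not in cds:
                logger.info("ks: missing CDS for pair %s / %s", ga, gb)
                continue
            estimates.append(ks_engine.ks_pair(cds[ga], cds[gb],
                                               max_ks=cfg.max_ks,
                                               gc3_cutoff=cfg.gc3_cutoff))
        kept, rejected = ks_engine.filter_ks_pairs(
            estimates, max_ks=cfg.max_ks, gc3_cutoff=cfg.gc3_cutoff,
            gc3_taxa=set(cfg.gc3_taxa))
        rows = []
        for est in kept:
            rows.append({"gene_a": est.gene_a, "gene_b": est.gene_b,
                         "ks": est.ks, "ka": est.ka, "p_s": est.p_s,
                         "p_n": est.p_n, "gc3": est.gc3, "status": "retained"})
        for est, reason in rejected:
            rows.append({"gene_a": est.gene_a, "gene_b": est.gene_b,
                         "ks": est.ks, "ka": est.ka, "p_s": est.p_s,
                         "p_n": est.p_n, "gc3": est.gc3, "status": reason})
        pd.DataFrame(rows).to_csv(outdir / "ks.tsv", sep="\t", index=False)
        report["ks"] = {"pairs_in": len(estimates), "retained": len(kept),
                        "rejected": len(rejected),
                        "rejections": [{"gene_a": e.gene_a, "gene_b": e.gene_b,
                                        "reason": r} for e, r in rejected]}

        stage = "dating"
        if kept:
            sample = dating.KsSample(values=tuple(e.ks for e in kept),
                                     source="syntelogs")
            ci = dating.mean_ci(sample)
            peaks = (dating.kde_peaks(sample) if len(kept) >= 2
                     else [dating.KsPeak(mode=kept[0].ks, density_at_mode=1.0,
                                         bandwidth=0.0)])
            refs = dating.load_reference_table(cfg.reference_table)
            assignments = dating.match_wgd(ci, peaks, refs, scope=cfg.scope)
            pd.DataFrame([{
                "mode": a.peak.mode, "density": a.peak.density_at_mode,
                "bandwidth": a.peak.bandwidth,
                "event": a.event or "novel",
                "candidates": ";".join(c.event for c in a.candidates),
            } for a in assignments]).to_csv(outdir / "peaks.tsv", sep="\t",
                                            index=False)
            report["dating"] = {
                "ci": {"mean": ci.mean, "lower": ci.lower, "upper": ci.upper,
                       "n": ci.n},
                "peaks": [{"mode": a.peak.mode, "event": a.event or "novel"}
                          for a in assignments],
            }
            if cfg.rate:
                t = dating.ks_to_time(ci, cfg.rate)
                report["dating"]["time_mya"] = t.mya
                report["dating"]["time_mya_ci"] = list(t.mya_ci)
        else:
            report["dating"] = {"ci": None, "peaks": []}

        stage = "network"
        net = synteny.build_locus_network(blocks, cfg.focal_genes)
        formats_io.write_edge_list(net, outdir / "network_edges.tsv")
        report["network"] = {"n_nodes": len(net.nodes()),
                             "n_edges": len(net.edges())}

        if cfg.tree_path is not None:
            stage = "genetree"
            if cfg.species_map is None or cfg.outgroup is None:
                raise ValueError("tree analysis needs species_map and outgroup")
            tree = formats_io.read_tree_newick(cfg.tree_path)
            rooted = genetree.root_by_outgroup(tree, cfg.outgroup)
            calls = genetree.detect_duplications(rooted, cfg.species_map,
                                                 threshold=cfg.support_threshold)
            pd.DataFrame([{
                "node": c.node_id, "bs1": c.bs1, "bs2": c.bs2, "bs3": c.bs3,
                "species_left": ",".join(sorted(c.species_left)),
                "species_right": ",".join(sorted(c.species_right)),
                "classification": c.classification, "supported": c.supported,
            } for c in calls]).to_csv(outdir / "duplications.tsv", sep="\t",
                                      index=False)
            report["duplications"] = {
                "n_calls": len(calls),
                "n_supported_shared": sum(
                    1 for c in calls
                    if c.supported and c.classification == "shared"),
            }
    except Exception:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
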