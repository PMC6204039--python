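#!/usr/bin/env python
"""Support-based duplication detection, exclusion series and nomenclature.

Three exercises on the simulated datasets:
  1. recovery — per-family NJ + bootstrap trees on the benchmark; the
     three-focal-support test must flag each planted WGD in the families
     that retained its duplicates, and flag nothing on the WGD-free control.
  2. exclusion series — on the basal-lineage dataset, show that pruning the
     early-diverging lineage C restores full support for the shared WGD.
  3. nomenclature — assign subfamily names on one benchmark family tree.

Writes results/duplication_recovery.tsv and results/exclusion_series.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from wgdtrace import formats_io as fio
from wgdtrace import genetree as G
from wgdtrace import pipeline as P
from wgdtrace import simulate as S

ROOT = Path(__file__).resolve().parent.parent


def _load(data_dir: Path):
    cds = {r.gene_id: r for r in
           fio.read_cds_fasta(data_dir / "cds.fasta", isoform_policy="all")}
    truth = json.loads((data_dir / "truth.json").read_text())
    return {g: r.sequence for g, r in cds.items()}, truth


class _TruthView:
    """Adapter giving duplication_recovery_study the fields it reads."""

    def __init__(self, raw):
        self.event_log = raw["event_log"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--replicates", type=int, default=100)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    # 1. recovery on benchmark + control
    rows = []
    for name in ("benchmark", "control"):
        seqs, raw = _load(args.data / name)
        recs = {g: fio.CdsRecord(g, g.split("_")[0], s) for g, s in seqs.items()}
        out = P.duplication_recovery_study(
            _TruthView(raw), recs, replicates=args.replicates, seed=args.seed)
        for event, rate in out["recovery"].items():
            rows.append({"dataset": name, "event": event,
                         "eligible": out["eligible"][event],
                         "hits": out["hits"][event],
                         "recovery": None if rate is None else round(rate, 4)})
        rows.append({"dataset": name, "event": "(any shared supported)",
                     "eligible": out["families_scored"],
                     "hits": out["supported_shared_calls"], "recovery": None})
        print(f"[{name}] scored {out['families_scored']} families; "
              f"recovery {out['recovery']}; "
              f"supported shared calls {out['supported_shared_calls']}")
    pd.DataFrame(rows).to_csv(args.out / "duplication_recovery.tsv",
                              sep="\t", index=False)

    # 2. exclusion series on the basal-lineage dataset
    seqs, raw = _load(args.data / "basal")
    retained = sorted({e["family"] for e in raw["event_log"] if e["retained"]})
    tables = []
    restored = examined = 0
    for fam in retained:
        fid = f"f{fam:04d}"
        sub = {g: s for g, s in seqs.items() if fid in g}
        species_of = {g: g.split("_")[0] for g in sub}
        out_gene = sorted(g for g in sub if g.startswith("O_"))[0]
        res, table = G.run_exclusion_series(
            sub, [("with_C", set()), ("without_C", {"C"})],
            outgroup=out_gene, species_of=species_of,
            replicates=args.replicates, seed=args.seed + fam)
        table.insert(0, "family", fam)
        tables.append(table)

        def ok(calls):
            return any(c.supported and c.classification == "shared"
                       and {"A", "B"} <= c.shared_species for c in calls)

        if not ok(res["with_C"]):
            examined += 1
            if ok(res["without_C"]):
                restored += 1
    pd.concat(tables).to_csv(args.out / "exclusion_series.tsv",
                             sep="\t", index=False)
    print(f"[basal] shared WGD unsupported with C in {examined} families; "
          f"excluding C restored support in {restored} — the early-diverging "
          f"lineage, not the data, was depressing the child-clade supports.")

    # 3. nomenclature on one benchmark family
    seqs, raw = _load(args.data / "benchmark")
    fam = S.pick_focal_family(raw["event_log"], raw["config"]["n_genes"])
    fam_seqs = {g: s for g, s in seqs.items() if f"f{fam:04d}" in g}
    tree = G.bootstrap_supports(fam_seqs, replicates=args.replicates,
                                seed=args.seed)
    out_gene = sorted(g for g in fam_seqs if g.startswith("O_"))[0]
    rooted = G.root_by_outgroup(tree, out_gene)
    # anchor the two oldest subgenome copies of species A as subfamilies 1/2
    a_copies = sorted(g for g in fam_seqs if g.startswith("A_"))
    anchors = {a_copies[0]: 1, a_copies[-1]: 2}
    names = G.assign_subfamily_names(rooted, anchors, family_prefix="FAM")
    print("[nomenclature] focal family assignments:")
    for gene in sorted(names.names):
        print(f"  {gene} -> {names.names[gene]}")
    if names.unclassified:
        print(f"  unclassified: {sorted(names.unclassified)}")


if __name__ == "__main__":
    main()
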