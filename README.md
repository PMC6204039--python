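# wgdtrace

Reconstructing whole-genome-duplication (WGD) histories from a focal gene
family. Plant genomes carry layers of ancient polyploidy (the core-eudicot
γ triplication, the salicoid, τ, ρ and T events, ...) that erode by
fractionation until only scattered duplicate pairs and collinear chromosome
segments remain. `wgdtrace` implements the integrated inference used to
read those layers from a single well-conserved gene family and its genomic
neighbourhood:

1. **Codon-level Ks estimation** — protein-guided global alignment,
   back-translation to codons, and Nei–Gojobori (1986) counting of
   synonymous/nonsynonymous sites and differences with Jukes–Cantor
   correction, `Ks = −¾ ln(1 − 4/3 pS)`. Pairs with `Ks > 2` (saturated)
   are excluded, as are high-GC3 pairs in configured lineages.
2. **Synteny-block chaining** — dynamic-programming chaining of homolog
   anchor pairs into collinear blocks (both orientations, rank-gap
   penalties), extraction of the "syntelog" paralog pairs flanking the
   focal loci, and a cross-genome locus network weighted by
   `ln(1 + block score)`.
3. **Ks-peak dating** — 95% Student-t confidence interval of the mean,
   Gaussian-KDE peak location, matching of peaks against a packaged table
   of literature Ks ranges per named WGD event, and the per-lineage clock
   `T = Ks / (2r)` with `r` in synonymous substitutions/site/year.
4. **Support-based duplication detection** — on a rooted gene tree, every
   node whose two child clades share species is a candidate duplication;
   it is accepted when BS-1 (the node), BS-2 and BS-3 (the child clades)
   all reach the support threshold (default 90). Taxon-exclusion series
   rerun the test after pruning destabilising lineages, and a nomenclature
   routine assigns subfamily names (1A/1C/…, 2B/2D/…) from anchor genes.
5. **A ground-truthed simulator** — plants WGDs on a species tree with
   synonymous branch lengths, duplicates whole gene orders, fractionates
   duplicates i.i.d., and evolves codon sequences whose expected NG86 Ks
   equals the true synonymous path length, so every stage is testable
   without external genome data.

The intended user is a molecular evolutionist who has a curated gene
family (CDS FASTA, gene models, anchor pairs from a collinearity tool,
and optionally externally inferred trees) and wants reproducible Ks
dating and duplication calls; the simulator makes the whole procedure
verifiable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (seeded; outputs land in `results/`):

```bash
python analysis/01_simulate_dataset.py     # emit ground-truthed datasets
python analysis/02_synteny_blocks.py       # chain anchors into blocks
python analysis/03_ks_dating.py            # syntelog Ks -> KDE peaks -> events
python analysis/04_duplication_calls.py    # NJ+bootstrap duplication recovery
```

`03_ks_dating.py` prints, for the benchmark scenario (two WGDs planted at
true pairwise Ks 1.0 and 0.3, retention 0.8, 200 families × 300 codons):

```
818 syntelog pairs -> 818 retained, 0 rejected by filters
Ks mean 0.757, 95% CI [0.733, 0.781] (n=818; bimodal, so the CI spans both components)
  peak at Ks 0.99 -> ancient
  peak at Ks 0.30 -> recent
```

The two KDE modes sit within 0.01–0.01 of the planted distances and both
are matched to their events' reference ranges. The clock arithmetic block
reproduces the published calibrations, e.g. `Ks 1.975 at 192 My ->
r = 5.14e-09 /site/yr` and `Ks 0.87 at 6.03e-9 -> 72.1 Mya`.
`04_duplication_calls.py` reports the support-based test recovering the
planted duplications in ~98% (ancient) and ~91% (recent) of eligible
families, zero supported shared calls on the WGD-free control, and the
exclusion series restoring full support once the early-diverging lineage
is pruned.

Library use mirrors the scripts:

```python
from wgdtrace import ks_engine, dating

est = ks_engine.ks_pair(cds_a, cds_b)          # CdsRecord pair -> KsEstimate
ci = dating.mean_ci(dating.KsSample(values=(0.8, 0.9, 1.0, 1.1, 1.2)))
print(ci.mean, ci.lower, ci.upper)             # 1.0 0.804 1.196
```

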