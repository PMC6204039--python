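# Methods

## Ks estimation (ks_engine)

Pairs of in-frame CDS are aligned at the protein level (Needleman–Wunsch
via Biopython's `PairwiseAligner`, BLOSUM62, gap open −10 / extend −0.5,
ties broken by the aligner's deterministic enumeration order) and
back-translated to codon columns. Any consistent global aligner serves
here, since downstream counting only consumes codon columns; externally
aligned proteins can be substituted.

Nei–Gojobori (1986) counting: each codon's synonymous-site content is the
sum over its three positions of the fraction of non-stop single-nucleotide
neighbours that are synonymous (mutations to stops are excluded from the
denominator — the convention of the PAML implementation); S and N are
averaged over the two sequences. Codon pairs differing at k positions are
scored by averaging synonymous/nonsynonymous differences over all k!
substitution orderings, discarding orderings that pass through a stop
codon; if no stop-free pathway exists the column is skipped. Columns with
a gap, a stop or a non-ACGT character are skipped whole — fractional
column scoring is not defined by the method. All 61×61 sense-codon pair
counts are precomputed once, making per-alignment counting a table lookup
(this is what keeps bootstrap tree building affordable); the test suite
verifies the tables against an independent brute-force enumerator on 1000
random alignments.

Proportions convert to distances by the one-parameter correction
`d = −¾ ln(1 − 4/3 p)`, undefined (reported as a SATURATED sentinel) at
`p ≥ 3/4`. GC3 is computed on the full ungapped CDS rather than alignment
columns, so it is stable under alignment choice. Filtering removes pairs
with `Ks > 2.0` (saturation regime) always, and pairs with mean GC3 above
0.75 only when **both** genes belong to a configurable taxon set — the
rule is a grass-genome artefact control and is not meaningful for
low-GC3 lineages. Every rejection is logged with its reason.

## Synteny (synteny)

Anchor pairs (significance filtering is upstream) are chained per
chromosome pair by dynamic programming: a chain must be strictly
monotone in gene rank on both segments (increasing/increasing for "same"
orientation, increasing/decreasing for "inverted"), consecutive anchors
at most `max_gap_ranks` (default 25) ranks apart in either genome, and
its score is Σ similarity − `gap_penalty` (default 1.0) per skipped rank.
Gaps are measured in gene ranks, not base pairs, which is robust to
intergenic-length variation. The best chain is extracted, its anchors
removed, and chaining repeats until no chain reaches `min_anchors`
(default 5) — the greedy iterated scheme of the MCScan family, with the
defaults those tools typically use. A brute-force subset enumerator
validates the DP on all small instances. Because the literature only uses
block scores log-transformed, the absolute score scale is fixed here for
determinism rather than to match any external tool.

Syntelogs of a focal gene are the anchor pairs of every block containing
it, deduplicated across overlapping blocks. The locus network connects
focal loci that occupy opposite segments of a block, with weight
`ln(1 + score)` and the max-weight edge kept across parallel blocks.

## Gene trees and duplication detection (genetree)

The synthetic path builds neighbour-joining trees from pairwise NG86 Ks
distances (saturated pairs capped at 4.0 so the agglomeration stays
finite). NJ is written here rather than borrowed so that tie-breaking
(lexicographically smallest cluster-label pair) and negative-branch
clamping are explicit and runs are byte-reproducible; dendropy's NJ is
the cross-check oracle in the tests. Bootstrap supports resample codon
columns (the resampling unit is the codon), rebuild the NJ tree, and
score each internal split of the original tree as the percentage of
replicates containing it. The default is 100 replicates — a desk-scale
setting, exposed as a parameter, in place of the 1000 typically used on
real data.

Rooting places the root at the midpoint of the outgroup's pendant edge.
Supports are indexed by the split they label before rerooting and
re-attached to the clades subtending them afterwards, preferring the side
a support was originally written on when both sides occur as clades.

Duplication detection: every internal node whose two child clades share
at least one species is a candidate; BS-1 is the node's own support and
BS-2/BS-3 the child-clade supports, with leaf children given full support
by convention (a leaf is not an estimated clade). When the candidate is
the root (or its split is the outgroup-adjacent pendant split, which
bootstrap cannot score), BS-1 falls back to the outgroup-adjacent
bipartition and the call is flagged `at_root`. A call is *supported* when
min(BS-1, BS-2, BS-3) ≥ threshold — 90 for bootstrap units, 0.95 for
posterior — and classified *shared* when the child clades share ≥ 2
species, *species-specific* when they share exactly one. The shared rule
is a formalisation of what is usually judged visually; two species is the
minimum evidence that the duplication predates a speciation.

Exclusion series prune chosen taxa, rebuild, re-root and re-call,
emitting a comparison table. Nomenclature assigns each gene the subfamily
of the smallest clade containing it and an anchor gene (genes whose
smallest anchor-bearing clade mixes subfamilies stay unclassified), and
letters follow the rooted tree's leaf order: subfamily 1 → A, C, E…,
subfamily 2 → B, D, F…; a species with a single family member gets the
bare family name. Leaf-order lettering is a fixed convention; published
names do not state whether letters encode tree order or discovery order.

## Dating (dating)

The confidence interval is Student-t on the mean (normal-approximation
and bootstrap variants were considered; t is the default because sample
sizes per block can be small). KDE uses a Gaussian kernel with
Silverman's rule-of-thumb bandwidth (`0.9·min(sd, IQR/1.34)·n^{−1/5}`,
as in R's `density()` default) evaluated on a 0.01 grid over
[0, max + 3h]; peaks are local maxima with density ≥ 25% of the global
maximum (a configurable floor that suppresses noise shoulders). A peak is
assigned to a reference event when its mode falls in the event's
literature Ks range or the sample CI overlaps it; ambiguous overlaps are
reported ranked by mode-to-midpoint distance, and unmatched peaks as
novel.

The packaged reference table carries literature Ks ranges per lineage and
event with citation tags. Rows whose sources print a range are shipped
verbatim; rows whose sources print only a point mode (τ ≈ 1.13, P ≈ 0.36,
the Vitis γ median 1.22) are shipped as a window around that mode wide
enough to cover the reported block CIs. Users can substitute their own
CSV.

Time conversion is the per-lineage strict clock `T = Ks/(2r)`;
`rate_from_calibration` is its exact algebraic inverse, and CI endpoints
map through the same formula (so the reported age interval is a linear
image of the Ks interval, with no extra error propagation).

## Simulator (simulate)

The generator models exactly the processes the inference exploits. An
ancestral genome of `n_genes` ordered families descends a species tree
whose branch lengths are expected synonymous substitutions per synonymous
site. At each planted WGD the entire gene order is duplicated onto new
chromosomes and each duplicated gene is retained independently with the
event's retention probability; originals persist, so fractionation
punches gaps into otherwise collinear duplicated orders. Every divergence
(WGD or speciation) becomes a node in per-family gene trees whose branch
lengths are true synonymous distances; a WGD pair's true distance is
twice the synonymous length from the WGD point to the tips.

Sequences use a deliberately stylised code chosen for an analytic link to
the estimator: ancestral codons are drawn uniformly from the four NCN
families (Ala GCN, Thr ACN, Pro CCN, Ser TCN). Their third positions are
strictly fourfold-degenerate and evolve under per-site Jukes–Cantor at
the branch's synonymous rate; their first positions change amino acid on
every substitution and evolve at ω (default 0.2) times that rate; second
positions are fixed. No stop codon can arise, and the expected NG86 Ks of
any pair equals its true synonymous path length exactly — which is the
property the recovery tests need. The cost is realism elsewhere: no
twofold-degenerate sites, no codon-usage or GC bias, no indels, no gene
conversion, no small-scale rearrangement by default, uniform retention
across the genome. Passing tests therefore demonstrate correctness of the
estimators and the detection logic under the model's assumptions, not
robustness to alignment error or rate heterogeneity in real data.

### Study scenarios

* `two_wgd_benchmark` — species A and B (ortholog divergence Ks 0.05)
  share an ancient WGD at true pairwise Ks 1.0 and a recent one at 0.3,
  both with retention 0.8; O is a pre-WGD single-copy outgroup (divergence
  Ks 1.2); 200 families × 300 codons. The WGD distances, retention and
  problem size are the stated recovery conditions; the ortholog divergence
  is set well below the younger WGD (as in the poplar–willow/salicoid
  configuration) so that the recovery statistic measures the detection
  method rather than gene-tree estimation error, and the outgroup depth
  keeps its placement on the central edge of the duplication split.
* `wgd_free_control` — four single-copy species, no WGD: any supported
  shared call is a false positive.
* `basal_lineage_scenario` — one shared WGD plus an early-diverging
  single-copy lineage C whose long unbroken branch tends to attach inside
  one subgenome clade of the estimated tree, depressing BS-2/BS-3; the
  exclusion series demonstrates that pruning C restores full support —
  the same manoeuvre used on basal eudicots in real analyses.

Problem sizes throughout (families, codons, bootstrap replicates) are
desk-scale choices that keep the full study in the order of a minute on
one CPU; all are parameters.

## Pipeline (cli interface)

`pipeline.run_pipeline` executes synteny → syntelog extraction → Ks
filtering → dating (and, when a tree is supplied, duplication calls) over
files, persisting each stage as plain TSV/JSON so externally computed
anchors or trees can be substituted at any cut point; the report records
the full effective parameter set and every filter rejection, and a failed
stage leaves a `FAILED` marker naming it. The numbered scripts under
`analysis/` are the command-line surface of the package; `ks_peak_study`
and `duplication_recovery_study` are the in-memory equivalents used by
the tests and the acceptance script.

## Known limitations

* NG86 with Jukes–Cantor saturates near Ks ≈ 2–3; distances there are
  reported but filtered from dating, and NJ caps them. No maximum-
  likelihood codon models, gamma rate variation or codon-usage correction.
* KDE peak matching reports candidate events; it does not deconvolve
  overlapping peaks (no mixture modelling).
* The duplication test is the published support-based procedure, not a
  gene-tree/species-tree reconciliation; paralog loss patterns that mimic
  speciation topologies are outside its reach.
* The strict per-lineage clock `T = Ks/2r` inherits all rate-variation
  caveats; different calibrations give materially different ages, which
  is why rates are explicit parameters everywhere.
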