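# fbfsubnet

Analysis pipeline for **gender-dependent FBF binding subnetworks** in the
*C. elegans* germline, from iCLIP reads to called binding peaks, motif
content, differential binding, clustered RNA "blocks" and cross-species PUF
target overlap.

FBF (*fem-3* Binding Factor; the PUF paralogs FBF-1/FBF-2) maintains
germline stem cells and directs the sperm-to-oocyte decision by binding the
FBF binding element (FBE, UGUNNNAU) in target 3′UTRs. Comparing iCLIP from
spermatogenic versus oocyte-producing germlines asks which FBF targets are
gamete-independent — candidates for the stem-cell subnetwork — and which
are gamete-specific. This package implements that computational route as a
tested, reusable library plus CLI, together with a ground-truth synthetic
iCLIP generator so every stage can be verified end to end without the
original sequencing data.

**Who it is for:** computational biologists analysing CLIP-type data for
RNA-binding-protein targets, and anyone who wants a desk-scale, fully
seeded reference implementation of this analysis design.

## The statistics at the core

* **Peak calling:** reads in the 500-bp window around a candidate summit
  are placed in ten 50-bp bins; the no-antibody control's bin heights (RPM
  scale) fit a Gaussian N(μ, σ), and the peak p-value is
  P(X ≥ height_rpm). p-values are Benjamini–Hochberg corrected (FDR 1%),
  then two reads-in-peak cutoffs apply: RPM height ≥ 2× control and raw
  height ≥ 10× control.
* **Differential binding:** per-gene negative-binomial Wald test of
  reads-per-gene (median-of-ratios size factors, trend-moderated
  method-of-moments dispersion), restricted to gamete-program genes with
  ≥ 20 mean reads; calls need adjusted p < 0.01 and ≥ 2-fold change.
* **Blocks:** target RNAs are clustered on control-subtracted log₂ RPM by
  average-linkage Euclidean clustering; the four blocks are numbered I–IV
  by spermatogenic-to-oogenic binding ratio, and PCA of the same matrix
  separates RNAs by overall binding (PC1) and gender ratio (PC2).
* **Orthology:** worm–mammal ortholog groups are connected components of
  the bipartite orthology graph after ≤ 10-ortholog degree caps; target
  overlap is counted per group.

See `docs/methods.md` for the full model descriptions and design choices.

## Worked example

Scan the wild-type *fem-3* 3′UTR fragment for FBEs:

```bash
$ fbfsubnet scanfbe CGCTTCTTGTGTCAT
[
  {
    "start": 7,
    "octamer": "UGUGUCAU",
    "is_canonical": true,
    "is_relaxed_optimal": true,
    "is_strict_optimal": false,
    "minus1C": false,
    "minus2C": true
  }
]
```

One canonical FBE at 0-based offset 7 with an affinity-enhancing cytosine
two bases upstream — the element next to the classic *fem-3(gf)* mutation
site.

Run the whole pipeline on seeded synthetic data (150 genes, 30k-read
libraries, three replicates per gender, planted 4-fold gender blocks):

```bash
$ printf 'seed: 1\nsynthetic:\n  n_genes: 150\n  library_size: 30000\n' > small.yaml
$ fbfsubnet run --config small.yaml --outdir run1
{
  "stages": ["simulate", "dedup", "count", "correlate", "callpeaks",
             "scanfbe", "diff", "blocks", "ortho_overlap"],
  "outdir": "run1"
}
```

Numbers this run printed into `run1/` and what they mean:

* `correlations.json` — replicate Spearman ρ within gender 0.990–0.992
  versus 0.939 between genders, two-tailed t-test p = 1.9×10⁻¹³: FBF's
  binding landscape differs reproducibly between genders.
* `peaks_*.bed`, `fbe_fractions.json` — 45 peaks called in the
  spermatogenic and 42 in the oocyte condition, 100% containing a
  canonical FBE (every planted site in this fixture carries one; none were
  called off-target).
* `differential.tsv` — 124 testable genes; 10 called differentially bound
  (7 sperm-enriched, 3 oocyte-enriched). Planted block-I genes report
  log2 fold changes near 2, the planted 4-fold.
* `overlap.json` — 60% of FBF-targeted ortholog groups shared with the
  synthetic mammalian PUM target list (43 targeted groups, 26 shared).

Each stage is also callable on its own (`fbfsubnet simulate | preprocess |
dedup | count | correlate | callpeaks | scanfbe | diff | blocks |
ortho-overlap`) and from Python via `fbfsubnet.<module>`.

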