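# Methods

This note documents the models, statistics and numerical choices behind
`fbfsubnet`, and what its synthetic-data tests do and do not demonstrate
about real iCLIP data.

## The analysis in one paragraph

FBF (the near-identical *C. elegans* PUF paralogs FBF-1/FBF-2) binds target
mRNAs through the FBF binding element (FBE), the octamer UGUNNNAU, mostly in
3′UTRs. iCLIP libraries from spermatogenic and oocyte-producing germlines,
plus a no-antibody control, yield reads whose per-gene counts — after UMI
deduplication and reads-per-million (RPM) scaling — estimate the frequency
of FBF–RNA complex formation. The pipeline calls binding peaks against a
Gaussian null fit to the control, scans peaks for FBEs, tests reads-per-gene
for gender-differential binding with a negative-binomial model, clusters
target RNAs into blocks by their binding profiles, and measures how FBF
targets overlap mammalian PUM targets through transitively merged ortholog
groups.

## Peak calling

**Candidates.** Read coverage per (chromosome, strand) is thresholded at
`min_height_raw` (default 5 deduplicated reads); each maximal run above
threshold contributes one summit at its coverage argmax (leftmost on ties),
and summits closer than 50 bp merge, keeping the higher one. This candidate
step is deliberately simple: the statistical machinery downstream is the
part with testable guarantees.

**Null model.** For each candidate, the 500-bp window around the summit is
tiled into ten 50-bp bins. Control bin heights — reads *starting* in the
bin, scaled to per-million by each control replicate's own library size and
pooled across replicates — fit a Gaussian (sample mean μ, sample SD σ with
n−1). The peak's p-value is the upper-tail probability of the FBF summit-bin
height under Normal(μ, max(σ, σ_floor)). σ_floor defaults to one read per
million of the smallest control library, so an all-zero control window still
yields finite p-values. The null is fit per window by default; a pooled
genome-wide variant is available (`PeakConfig.pooled_null`).

**Window anchoring.** The tiling is anchored so that the summit bin is
*centred* on the summit (window = [summit−225, summit+275) at defaults).
Because bin heights count read 5′ starts while the summit is a coverage
argmax, starts sit roughly half a read length upstream of the summit; a
boundary-anchored bin would systematically miss most of them. Windows are
clipped at chromosome edges; truncated bins keep their shorter span and
`n_bins` records the pooled count.

**Correction and cutoffs.** p-values are Benjamini–Hochberg corrected
across all candidates of a dataset and filtered at FDR 1%. Two
reads-in-peak cutoffs then apply: per-million height ≥ 2× control and raw
height ≥ 10× control, each against the matched summit bin of the pooled
control with a one-read-equivalent pseudocount so zero-control peaks remain
testable. The matched-bin choice keeps the numerator and denominator in the
same units; cutoff values are configurable because appropriate values vary
between datasets. Surviving peaks are gene-assigned with ncRNA priority
(a peak overlapping exons of one ncRNA and any mRNAs goes to the ncRNA),
FBE-annotated on the sense strand over both the 500-bp window and the
summit ± 25 nt region, and ranked by descending per-million height with
coordinate tie-breaks.

## FBE scanning

The canonical FBE is UGUNNNAU (T/U equivalent, overlapping matches all
reported, sense strand only). Two "optimal" refinements coexist as
independent flags rather than being reconciled: relaxed UGUDHHAU
(D∈{A,U,G}, H∈{A,U,C}) and the strict nonamer UGURCCAUR (R∈{A,G}) with a
required cytosine immediately upstream. −1C/−2C flags mark
affinity-enhancing cytosines one or two bases 5′ of the octamer.

## Read-to-gene assignment and counting

A read is assigned to a gene iff it shares ≥ 1 base with an exon of that
gene on the same strand (iCLIP is stranded). In counting mode, reads
touching exons of two or more genes are discarded as ambiguous; the
peak-assignment mode applies ncRNA priority first. Library size is the
per-sample total of assigned reads; RPM = count × 10⁶ / library size.
Combined two-paralog replicates are built by summing paired columns — the
canonical pairings are (1,3),(2,2),(3,1) for the oogenic set and
(2,1),(1,2),(3,3) for the spermatogenic set — with library sizes adding.

## UMI deduplication

Aligned reads group by (chromosome, strand, start); within a group, UMIs
cluster by the directional rule with edges u→v when Hamming(u,v) = 1,
count(u) ≥ 2·count(v) − 1 **and** count(u) > count(v). The strict-majority
condition is this package's refinement: without it, two distinct molecules
observed once each with adjacent UMIs would merge, and collapsing would not
be idempotent. One representative per cluster survives (highest count,
lexicographically smallest UMI on ties); output order is canonical
(position, then UMI). Limitation: the group key uses the leftmost alignment
coordinate; for minus-strand reads the biological 5′ end is the right edge,
which matters only when duplicates differ in trimmed length.

## Differential binding

A negative-binomial Wald test stands in for dedicated
differential-expression packages; the comparison design — program
restriction, read filter, fold and FDR thresholds — is the substance being
reproduced, not any particular GLM implementation.

* **Filter:** genes in a gamete program (spermatogenic, oogenic or both)
  with mean raw count ≥ 20 over the designated samples.
* **Normalization:** median-of-ratios size factors over genes nonzero in
  every sample, rescaled to geometric mean 1.
* **Dispersion:** per-gene method-of-moments α pooled within gender
  (floor 10⁻⁸), then moderated by a fitted a₁/μ + a₀ trend using
  max(gene, trend). With three replicates the per-gene estimate often
  collapses to the floor; taking the maximum against the trend keeps the
  test calibrated (≤ 2% of null genes at adjusted p < 0.01 in simulation)
  at a modest, conservative cost in power that the 4-fold recovery
  simulations still pass with sensitivity ≈ 1.
* **Statistic:** log2FC = log2((m_s + δ)/(m_o + δ)) with pseudocount
  δ = 0.5 normalized counts; Var(mean) = (μ + αμ²)/n per gender;
  z = lfc/se against a standard normal, two-sided; BH across tested genes.
* **Calls:** enriched if adjusted p < 0.01 and |log2FC| ≥ 1 (a strict `>`
  variant is a flag, since "twofold or higher" and "> 2 fold" both appear
  in the field's usage).

## Blocks (clustering) and PCA

Target RNAs (≥ 1 significant peak) are represented as
log2(max(RPM − control_mean, 0) + 1) per FBF sample; the clamp-then-add-one
transform keeps "no binding above control" at exactly zero while preserving
monotonicity. All-zero rows are dropped and reported (peaks can be assigned
to an ncRNA whose reads were all ambiguous when counting, leaving no
reads-per-gene). Rows are clustered by unweighted average linkage on
Euclidean distances and cut to k flat clusters (default k = 5). The largest
cluster is the residual ("none"); the rest are labeled I–IV by decreasing
mean (sperm − oocyte) profile, so block I is sperm-enriched, II/III
gender-neutral and IV oocyte-enriched. k and manual per-RNA overrides (with
provenance recorded) are analyst-facing — the number of meaningful blocks
is a judgment the tool does not automate. PCA is column-centred SVD with
each component flipped so its loading sum is ≥ 0; on planted matrices PC1
tracks overall binding frequency (|ρ| ≥ 0.9) and PC2 the gender ratio
(|ρ| ≥ 0.8). The block-I paring rule keeps RNAs whose highest peak reaches
25 RPM and contains a canonical FBE.

## Ortholog groups and overlap

Orthology edges form a bipartite worm–mammal graph. Worm genes with more
than ten mammalian partners are removed first, then mammalian genes with
more than ten worm partners (degrees re-evaluated after the first pass; an
iterated variant is a flag). Groups are the connected components of the
filtered graph — the transitive-orthology rule on both sides at once. A
group is worm-targeted if any worm member is an FBF target and shared if
additionally any mammal member is a PUM target; the headline fraction is
shared / worm-targeted. The all-genes baseline uses the same code path with
the full worm universe as targets. Degree caps are applied before merging
by default; the post-merge order is available behind the `iterate` flag.

## The synthetic data generator

The generator emulates the statistical regime the analysis assumes, at desk
scale (hundreds of genes rather than the ~12,000 expressed in the
germline):

* **Gene models:** 1–2 exons, transcripts ~0.8–2.3 kb, 3′UTRs 160–400 nt,
  both strands, six chromosomes; a configurable ncRNA fraction (default
  5%).
* **Abundance:** log-normal with shape σ = 1 — a long-tailed regime in
  which the highest-frequency targets are also abundant RNAs.
* **Binding:** blocks I–IV are planted in proportions (5%, 25%, 1.5%, 2%)
  of mRNA genes, echoing the relative sizes of the four observed blocks.
  Target genes get an expected RPM drawn log-uniformly from (2000, 20000);
  block III draws from the top of that range. Gender-specific blocks are
  scaled by `sperm_oocyte_fold` (default 4). Background mass is spread over
  non-target genes by abundance so each library's expectations total 10⁶
  RPM.
* **Reads:** unique molecules are Poisson; FBF reads on targets place
  their centres as a discretized Gaussian (SD 10 nt) around the planted
  FBE — producing single-bin-dominant peaks under 50-bp binning — while
  control and non-target reads are uniform over exons. Reads are
  single-end, 35 nt (configurable), on the transcript's strand. The true
  spatial read distribution around binding sites is not known; the
  Gaussian is a stand-in, not an inference.
* **Controls:** no-antibody libraries track abundance only and are 10% of
  the FBF library size by default, reflecting the low yield of a
  no-antibody immunoprecipitation. This ratio is what makes the raw
  tenfold cutoff meaningful at desk scale.
* **UMIs and duplicates:** each molecule gets a random UMI (default 7 nt);
  PCR duplicates (extra copies Poisson with mean d/(1−d), d = 0.5) re-emit
  the molecule's UMI with per-base error 1%.
* **Sequence truth:** planted canonical FBEs are written into 3′UTRs (half
  with a −1/−2 cytosine by default); all other canonical FBEs — on either
  genome strand and across splice junctions in transcript space — are
  scrubbed by point mutation, so a motif scan finds planted sites and
  nothing else. Every dataset ships with a truth table (block labels,
  expected RPM per condition, planted positions) so downstream stages are
  scored for recovery.

**What passing these tests does not show:** the generator has no
crosslink-induced truncations or deletions, no splicing isoforms, no
mappability or sequence-composition bias, no overdispersion beyond Poisson
in molecule counts within a replicate, and genes never overlap (real
ambiguous-read rates are higher). Recovery rates on this fixture are upper
bounds on real-data performance; the calibration properties (FDR control
of the peak caller and the differential test) are the transferable claims.

## Problem sizes and determinism

Tests and the acceptance script run the pipeline at reduced sizes chosen to
exercise every code path with comfortable statistical margins: 60–250
genes, libraries of 10⁴–10⁵ reads, 2,000-row clustering matrices, 2,000-gene
differential simulations. All randomness flows from a single root seed
through named `numpy` SeedSequence spawns; seeded runs are bit-reproducible,
and the pipeline manifest records a SHA-256 for every output so rerun
identity is checkable.
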