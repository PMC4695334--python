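# Methods

`epismad` implements a two-condition integrative analysis of transcription
factor (TF) binding, chromatin state and transcriptional response. The
motivating biology is a signaling pathway (TGF-β acting through SMAD3)
whose downstream effects differ radically between two cell contexts even
though the TF's genomic binding is largely similar: the analysis asks, gene
by gene, whether context-specific regulation is explained by differential
TF binding, by a permissive difference in the local epigenome, by both, or
by neither. Everything below is stated for two generic conditions A and B.

## Coordinate model and windows

Coordinates are 0-based half-open (BED convention) everywhere. Each gene is
a single collapsed transcript span with a strand; the transcription start
site (TSS) is `start` on the plus strand and `end − 1` on the minus strand.
Two windows are derived per gene:

* **gene-proximal** — from 1,500 bp upstream of the TSS to the end of the
  gene body (`[start − 1500, end)` on plus, `[start, end + 1500)` on
  minus), clipped to the chromosome. This is the unit within which TF
  peaks are considered associated with a gene, and the quantification
  window for every chromatin factor except DNA methylation.
* **TSS-proximal** — a symmetric 3,000 bp window containing the TSS base:
  `[tss − 1500, tss + 1500)` on plus and `[tss − 1499, tss + 1501)` on
  minus. The two formulas are exact mirror images under coordinate
  reflection (base `x ↦ L − 1 − x`), which the property tests exercise.
  Used only for promoter DNA-methylation quantification.

Annotations with multiple isoforms must be collapsed to one span per gene
before entering the package; isoform-aware analysis is out of scope.

## Peak matching across conditions

The same factor's peak sets from the two conditions are reconciled into
*shared* and *condition-unique* binding events. A candidate pair is
shareable when **the summit of either peak lies inside the other peak's
interval** (symmetric closure). Candidates are ranked by summit distance
(ties broken lexicographically by peak id, making the result deterministic)
and accepted greedily under a one-to-one constraint. Missing summits
default to interval midpoints. The criterion is deliberately robust to the
width mismatch between point-source callers (MACS-like) and broad-domain
callers (SICER-like); a plain ≥ 1 bp interval-overlap criterion is
available as a config switch. The matcher is validated against an O(n·m)
all-pairs brute-force oracle on random instances.

Occupancy matrices (binary query-peak coverage over a 5 kb window centered
on each reference summit, rows ordered shared-first) provide the standard
side-by-side heatmap input.

## Binding modes and occupancy categories

A reconciled event is assigned to a gene when its interval (the union of
the matched peaks) overlaps the gene-proximal window by ≥ 1 bp; an event
spanning two windows is assigned to both; full containment is a stricter
config alternative. Each gene's event counts
(`n_unique_A`, `n_unique_B`, `n_shared`) determine its **mode**: bound in A
only (1), in B only (2), in both (3), in neither (4), where "bound in A"
means at least one A-unique or shared event. Mode 3 genes are refined by
**occupancy category**: *identical* (only shared events), *mixed* (shared
plus unique), *mutually exclusive* (unique events on both sides, no shared
site). Note a gene with unique events on both sides but no shared site is
mode 3 — common binding does not require common sites.

Enrichment of binding among responsive genes, and of each mode within a
gene set, is tested against the treatment-independent background with a
2×2 Pearson chi-square (df = 1, two-sided, **no continuity correction**);
any expected cell < 5 sets a warning flag on the result rather than
failing, and Fisher's exact test is available as a config alternative.
Fold enrichment is the ratio of in-set to in-background fractions.
Benjamini–Hochberg correction is applied across the four modes of one
table; the paper trail for that choice is that no correction is obviously
canonical for a four-cell lookup and BH is the mildest standard option.

## Responsive-gene calling

Treated and control replicates are compared per gene, per condition, per
time point (1, 3, 6, 24 h) on the log2 scale, with BH adjustment across
genes and a responsiveness threshold of **FDR < 0.1**. The default test is
a **moderated-variance t**: per-gene pooled variances are shrunk toward a
common prior fitted across genes by moment-matching a scaled-F model on
log s² (Smyth-style empirical Bayes), and the t statistic gains the prior
degrees of freedom. With three replicates per group the per-gene variance
estimate is the binding constraint on power, and borrowing strength across
genes is the standard remedy for expression arrays; plain Welch's t is
retained under `method="welch"` and is also the automatic fallback inside
the replicate-count differential test. Degenerate zero-variance genes get
p = 1 when group means agree (and p = 0 when they differ, the noise-free
limit). Externally computed responsive-gene lists can be ingested directly
(`sets_from_lists`), bypassing the test.

Per time point the calls partition the universe into A-unique, B-unique,
shared and independent sets (A-unique at t ⇔ responsive in A and not in B
at t). The **background** ("treatment-independent") set is global:
responsive at *no* time point in *either* condition — the conservative
reading, since a per-time-point background would let late responders
contaminate early backgrounds.

## Differential chromatin and the epigenome gene sets

Six factors are quantified per gene window: the TF itself, three open
marks (H3K4me3, H3K27ac, Pol II), the repressive mark H3K27me3, and DNA
methylation (TSS-proximal window; everything else gene-proximal). Without
replicates the test is the classic **exact binomial two-library
comparison**: conditional on the window total, the A count is
Binomial(n, lib_A/(lib_A+lib_B)) under the null; log2 fold changes are
library-normalized with a 0.5 pseudocount. With ≥ 2 columns per side a
Welch t on log2 CPM is used instead. A call requires both FDR < 0.05 and
|log2FC| ≥ 1 (the effect floor emulates restricting attention to the most
pronounced signal differences; both thresholds are parameters).

Three set families follow per condition X: `smad3_high(X)` (TF
significantly higher in X), `open_chromatin_high(X)` (union of higher-in-X
calls over the three open marks), and `hypo_methylation(X)` (methylation
significantly *lower* in X, i.e. the higher-in-the-other-condition calls
inverted). Over-representation of any differential set within a context
set is a one-sided hypergeometric test, reported separately per direction
to reproduce the bi-symmetrical presentation; the hypergeometric choice
(set overlap rather than a ranked-list statistic) is the package's own.

## Context classification

Each context-specific responsive gene (by default the A-unique and
B-unique sets at 24 h) is labeled from its own condition's memberships:

| smad3_high | open ∨ hypo-meth | label |
|---|---|---|
| yes | yes | epigenome_assisted |
| no | yes | epigenome_directed |
| yes | no | smad3_only |
| no | no | unexplained |

The labels partition each context set. The two archetypes: identical TF
binding in both conditions with promoter methylation only in the
non-responsive condition → directed; condition-unique TF binding plus a
methylation difference → assisted. "Unexplained" genes are reported
without interpretation.

## Synthetic data generator

The generator plants all layers consistently and records them in a truth
table. Defaults (the conditions every recovery figure refers to):

* 1,000 genes on 4 chromosomes, lengths uniform on [2, 8] kb, 8 kb
  intergenic gaps so derived windows never overlap;
* class fractions 0.15 / 0.15 / 0.10 A-unique / B-unique / shared
  (60% independent); onset times drawn 0.10/0.20/0.30/0.40 over
  1/3/6/24 h, responses persistent from onset (a transient-response switch
  exists for timing-structure studies);
* expression: planted |log2FC| = 2 (70% up), Gaussian noise σ = 0.5,
  3 replicates per group, baselines uniform on [5, 10] log2 units;
* TF peaks: widths ~ N(300, 50²) bp (floor 150), shared events written at
  identical coordinates with the B copy shifted uniformly within ±50 bp,
  per-gene/per-condition false-positive and per-peak false-negative rates
  of 0.01 emulating peak-calling error;
* window counts: negative binomial with means 200 (high state) vs 50 (low
  state) — the 4-fold state difference — and dispersion 0.01 (biological
  coefficient of variation 0.1, typical of cell-line replicates); library
  size 10⁶ per sample; dispersion 0 switches to deterministic counts at
  the mean for the noise-free limit;
* context labels: assisted 0.30 / directed 0.50 / unexplained 0.20
  (directed most common, mirroring the asymmetry such studies report);
  assisted genes always carry an open-chromatin difference (and a
  methylation difference half the time), directed genes carry at least one
  permissive difference; the TF count state is tied to planted binding
  presence, so the truth's SMAD3-high set is exactly the
  bound-in-one-condition genes.

One RNG stream (PCG64, seeded `[seed, stream-id]`) per output family —
layout, classes, modes, states, peaks, errors, expression, one per count
factor — so adding a factor never perturbs another family's draws; a fixed
seed reproduces byte-identical files.

What the generator does **not** emulate: read-level data, fragment-size and
GC effects, CG-content bias of methylation enrichment, overlapping genes
and alternative promoters, distal/enhancer binding, correlated noise
across time points, and probe-level array artifacts. Passing recovery
tests therefore demonstrate the correctness and calibration of the
analysis logic under the stated noise model, not performance on real
sequencing data.

## Numerical choices and problem sizes

BH via statsmodels (validated against a hand step-up oracle), chi-square
via scipy (validated against the N(ad−bc)²/… shortcut formula to 1e−9),
hypergeometric via scipy (validated against exact enumeration on all
universes ≤ 25), exact binomial via scipy's minimum-likelihood two-sided
method (validated against a hand tail sum). Matching ties are broken by
peak id; profile tables order categories canonically (identical, mixed,
mutually_exclusive, A_only, B_only, unbound). Degenerate 2×2 margins give
p = 1. The trigamma inversion inside the variance-prior fit runs Newton
iterations to 1e−10 relative tolerance; an observed log-variance spread at
or below the chi-square sampling floor yields an infinite prior (normal
reference distribution).

Validation problem sizes were chosen to keep the full suite and the
acceptance script each under a minute of compute: 100 random instances for
the brute-force equivalences, 1,000 resampling replicates for the
chi-square calibration (type-I rate required within 0.05 ± 0.015), 1,000
null genes for p-value uniformity (KS at α = 0.01), and the 1,000-gene
default configuration for end-to-end recovery (responsive class and mode
≥ 95%, category ≥ 90%, set sensitivity ≥ 0.90 and precision ≥ 0.95,
context label ≥ 85%, noise-free recovery exact).

## Known limitations

Responsive-class errors are dominated by the FDR < 0.1 threshold itself
(~5–10% of calls at a time point where many genes respond are expected
false discoveries); the context-label accuracy inherits those flips. The
replicate-free binomial test assumes Poisson sampling and is
anticonservative under strong overdispersion — the |log2FC| ≥ 1 floor is
what keeps the false-positive rate low, and count replicates (switching to
the Welch path) are preferable when available. The greedy nearest-summit
matching is order-independent but not globally optimal for pathological
many-to-many overlap configurations. Two conditions only; >2-condition
comparisons and signal-level (bigWig) occupancy are out of scope.
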