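# epismad

Two-condition integration of transcription-factor binding, chromatin state
and transcriptional response.

## The problem

A signaling pathway such as TGF-β acts through a single effector TF
(SMAD3) yet produces opposite programs in different cell contexts — for
example promoting tumor-initiating cells in one breast-cancer line while
suppressing them in another. The classical explanation is that the TF is
simply guided to different genes in different cells; genome-wide data
often contradict this, showing largely similar binding between contexts.
`epismad` implements the analysis that resolves the discrepancy gene by
gene: it asks whether each context-specific responsive gene is explained
by **differential TF binding**, by a **permissive difference in the local
epigenome** (open-chromatin marks or promoter DNA methylation), by both,
or by neither.

For two conditions A and B the pipeline:

1. calls treatment-responsive genes per time point (treated vs control
   replicates on the log2 scale, moderated-variance t, BH FDR < 0.1) and
   partitions each time point into A-unique / B-unique / shared /
   independent sets;
2. reconciles the TF's peak sets into *shared* events (a summit of either
   peak inside the other peak's interval; greedy one-to-one,
   nearest-summit) and *condition-unique* events, and builds 5-kb
   summit-centered occupancy matrices;
3. assigns events to genes over the **gene-proximal window** (1,500 bp
   upstream of the TSS to the gene-body end) and classifies every gene
   into four binding modes — bound in A only (1), B only (2), both (3),
   neither (4) — refining mode 3 by occupancy category (identical / mixed
   / mutually exclusive sites), with 2×2 chi-square enrichment of binding
   and of each mode against the treatment-independent background;
4. tests each chromatin factor (TF, H3K4me3, H3K27ac, Pol II, H3K27me3,
   DNA methylation over the ±1,500 bp TSS window) for differential signal
   between conditions (exact binomial two-library test without replicates,
   Welch on log2 CPM with them; FDR < 0.05 and |log2FC| ≥ 1), deriving the
   SMAD3-high, open-chromatin-high and hypo-methylation gene sets per
   condition, with hypergeometric set enrichment;
5. labels each context-specific responsive gene
   **epigenome_assisted** (differential binding + permissive epigenetic
   difference), **epigenome_directed** (equal binding, epigenetic
   difference only), **smad3_only**, or **unexplained**.

A seeded synthetic-data generator plants all of these layers consistently
(responsive classes, binding modes with coordinate-level shared peaks,
negative-binomial window counts encoding 4-fold chromatin-state
differences, context labels) and writes a ground-truth table, so the whole
pipeline is validated end to end against known truth.

## Worked example

```sh
python examples/05_context_classification.py
```

runs the full pipeline on a 400-gene simulated dataset (seed 42) and
prints:

```
context-specific responders at 24 h, by label:
context              label  n_genes
      A epigenome_assisted       21
      A epigenome_directed       28
      A         smad3_only        1
      A        unexplained       16
      B epigenome_assisted       19
      B epigenome_directed       31
      B         smad3_only        0
      B        unexplained       12

recovery vs planted truth:
        class_24: 0.955
            mode: 0.985
        category: 0.960
   context_label: 0.958
  smad3_high(A) sensitivity 1.00, precision 1.00
```

Reading the output: of condition A's 66 unique responders at 24 h, 28 are
*epigenome-directed* — their TF binding is equivalent in both conditions
and their context-specificity tracks an open-chromatin or
promoter-methylation difference — while 21 are *epigenome-assisted*
(differential binding coupled with a permissive epigenetic difference).
The recovery block compares every recovered label against the generator's
planted truth: 95.5% of genes get the right responsive class at 24 h
(errors are dominated by the FDR < 0.1 threshold itself), 98.5% the right
binding mode, and 95.8% of context genes the right label.

The other examples (`examples/01…04`) exercise each stage on its own.
Equivalent shell usage:

```sh
epismad simulate --seed 42 --out data/
epismad run-all --config config.yaml --out results/
```

where `config.yaml` either requests simulation (`simulate: {...}`) or
points at real inputs (BED6/GTF genes, chromosome sizes, narrowPeak/BED
peak files, count and expression TSVs). Individual stages are available
as `de`, `match`, `modes`, `diffchrom`, `classify` and `report`.

## Layout

```
src/epismad/     genome, io, stats, peaks, expression, binding,
                 chromatin, classify, simulate, pipeline, cli
tests/           unit + property tests, end-to-end acceptance suite
examples/        one narrative script per capability
docs/methods.md  model, assumptions, defaults, limitations
```
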