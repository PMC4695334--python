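"""Epigenome-assisted vs epigenome-directed classification.

Each context-specific responsive gene is labeled from its memberships in
its own condition's differential sets:

* **epigenome_assisted** — differentially higher TF binding *and* a
  permissive epigenetic difference (open-chromatin-high or TSS
  hypo-methylation): the epigenome acts in synergy with differential
  binding.
* **epigenome_directed** — no differential TF binding, but a permissive
  epigenetic difference: specificity tracks the epigenome alone (the
  promoter-methylation archetype).
* **smad3_only** — differential TF binding with no epigenetic difference.
* **unexplained** — none of the above.

The four labels partition each context gene set.
"""

from __future__ import annotations

import pandas as pd

from .chromatin import EpigenomeGeneSets

LABELS = ("epigenome_assisted", "epigenome_directed", "smad3_only", "unexplained")


def classify_gene(in_smad3_high: bool, in_open_high: bool, in_hypo_meth: bool) -> str:
    epigenetic = in_open_high or in_hypo_meth
    if in_smad3_high and epigenetic:
        return "epigenome_assisted"
    if not in_smad3_high and epigenetic:
        return "epigenome_directed"
    if in_smad3_high:
        return "smad3_only"
    return "unexplained"


def classify_context_genes(
    context_sets: dict[str, set[str]],
    epigenome_sets: EpigenomeGeneSets,
) -> pd.DataFrame:
    """Label every context-specific responsive gene.

    ``context_sets`` maps condition -> that condition's unique responsive
    genes (e.g. the A-unique and B-unique sets at one time point).  A gene
    appearing in both contexts violates the upstream partition and is a
    hard error.
    """
    conditions = sorted(context_sets)
    for i, c1 in enumerate(conditions):
        for c2 in conditions[i + 1:]:
            both = context_sets[c1] & context_sets[c2]
            if both:
                raise ValueError(f"genes in both contexts {c1} and {c2}: {sorted(both)[:3]}")
    rows = []
    for condition in conditions:
        smad3 = epigenome_sets.smad3_high.get(condition, set())
        open_high = epigenome_sets.open_chromatin_high.get(condition, set())
        hypo = epigenome_sets.hypo_methylation.get(condition, set())
        for gene in sorted(context_sets[condition]):
            s, o, h = gene in smad3, gene in open_high, gene in hypo
            rows.append((gene, condition, s, o, h, classify_gene(s, o, h)))
    return pd.DataFrame(rows, columns=["gene_id", "context", "in_smad3_high",
                                       "in_open_chromatin_high", "in_hypo_methylation", "label"])


def label_summary(classification: pd.DataFrame) -> pd.DataFrame:
    """Label counts per context, all four labels always present."""
    rows = []
    for context, sub in classification.groupby("context"):
        counts = sub["label"].value_counts()
        for label in LABELS:
            rows.append((context, label, int(counts.get(label, 0))))
    return pd.DataFrame(rows, columns=["context", "label", "n_genes"])


def set_overlap_report(
    context_set: set[str],
    smad3_high: set[str],
    open_high: set[str],
    hypo_meth: set[str],
) -> pd.DataFrame:
    """Counts of the 7 intersection regions of the three differential sets
    within a context set, plus the outside-all region; counts sum to the
    context-set size."""
    rows = []
    for in_s in (True, False):
        for in_o in (True, False):
            for in_h in (True, False):
                n = sum(
                    1 for g in context_set
                    if (g in smad3_high) == in_s and (g in open_high) == in_o and (g in hypo_meth) == in_h
                )
                rows.append((in_s, in_o, in_h, n))
    return pd.DataFrame(rows, columns=["smad3_high", "open_chromatin_high", "hypo_methylation", "n_genes"])
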