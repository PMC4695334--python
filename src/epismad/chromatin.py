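"""Differential chromatin signal over gene windows and the derived gene sets.

Per-window counts for each factor (the TF itself, H3K4me3, H3K27ac, Pol II,
H3K27me3, and DNA methylation) are compared between the two conditions.
Without replicates the classic exact-binomial two-library test is used:
conditional on the window total, the condition-A count is binomial with
success probability given by the library-size ratio.  With replicates a
Welch t on log2 CPM is used instead.  Direction calls require both FDR < α
and |log2FC| >= a floor (default 1), emulating a stringent "most pronounced
differences" analysis.

From the per-factor calls three gene-set families are built per condition X:

* ``smad3_high(X)`` — genes with significantly higher TF signal in X;
* ``open_chromatin_high(X)`` — union of higher-in-X calls over the open
  marks (H3K4me3, H3K27ac, Pol II);
* ``hypo_methylation(X)`` — genes whose TSS methylation is significantly
  *lower* in X, i.e. higher in the opposing condition.

Methylation is quantified over TSS-proximal windows, every other factor
over gene-proximal windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountTable
from .stats import bh_adjust, binomial_two_library, log2_ratio, welch_ttest

TF_FACTOR = "smad3"
OPEN_MARKS = ("h3k4me3", "h3k27ac", "polii")
REPRESSIVE_MARKS = ("h3k27me3", "methylation")
ALL_FACTORS = (TF_FACTOR,) + OPEN_MARKS + REPRESSIVE_MARKS

HIGHER_A, HIGHER_B, NS = "higher_A", "higher_B", "ns"


def quantify_window_counts(window_ids: list[str], table: CountTable) -> CountTable:
    """Validate an externally supplied count table against the window set.

    Every requested window must be present; extra rows are dropped so the
    table is keyed exactly by the analysis windows, in window order.
    """
    missing = [w for w in window_ids if w not in table.counts.index]
    if missing:
        raise ValueError(f"windows missing from the count table: {missing[:5]}")
    return CountTable(table.counts.loc[window_ids], table.library_sizes)


def differential_test(
    table: CountTable,
    condition_a: str = "A",
    condition_b: str = "B",
    alpha: float = 0.05,
    min_lfc: float = 1.0,
    factor: str = "",
) -> pd.DataFrame:
    """Per-window differential call between two conditions.

    Returns a frame with window_id, factor, log2fc (A vs B, library-size
    normalized), pvalue, fdr (BH across windows) and direction in
    {higher_A, higher_B, ns}.  Swapping the conditions flips every
    direction and negates log2fc exactly.
    """
    cols_a = table.columns_for(condition_a)
    cols_b = table.columns_for(condition_b)
    counts = table.counts
    libs = table.library_sizes
    if len(cols_a) >= 2 and len(cols_b) >= 2:
        # replicate path: Welch on log2 CPM
        cpm_a = np.log2((counts[cols_a].to_numpy(float) + 0.5) / libs[cols_a].to_numpy() * 1e6)
        cpm_b = np.log2((counts[cols_b].to_numpy(float) + 0.5) / libs[cols_b].to_numpy() * 1e6)
        lfc, _, p = welch_ttest(cpm_a, cpm_b)
    else:
        # replicate-free path: exact binomial conditional test, summed columns
        ca = counts[cols_a].to_numpy(float).sum(axis=1)
        cb = counts[cols_b].to_numpy(float).sum(axis=1)
        la = float(libs[cols_a].sum())
        lb = float(libs[cols_b].sum())
        p = np.array([binomial_two_library(int(a), int(b), la, lb) for a, b in zip(ca, cb)])
        lfc = np.array([log2_ratio(a, b, la, lb) for a, b in zip(ca, cb)])
    q = bh_adjust(p)
    direction = np.where((q < alpha) & (lfc >= min_lfc), HIGHER_A,
                         np.where((q < alpha) & (lfc <= -min_lfc), HIGHER_B, NS))
    return pd.DataFrame({
        "window_id": counts.index,
        "factor": factor,
        "log2fc": lfc,
        "pvalue": p,
        "fdr": q,
        "direction": direction,
    }).reset_index(drop=True)


@dataclass
class EpigenomeGeneSets:
    """Differential gene sets per condition, derived from the calls alone."""

    smad3_high: dict[str, set[str]] = field(default_factory=dict)
    open_chromatin_high: dict[str, set[str]] = field(default_factory=dict)
    hypo_methylation: dict[str, set[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for family, sets in (("smad3_high", self.smad3_high),
                             ("open_chromatin_high", self.open_chromatin_high),
                             ("hypo_methylation", self.hypo_methylation)):
            for condition in sorted(sets):
                for gene in sorted(sets[condition]):
                    rows.append((family, condition, gene))
        return pd.DataFrame(rows, columns=["set", "condition", "gene_id"])


def _direction_set(calls: pd.DataFrame, direction: str) -> set[str]:
    return set(calls.loc[calls["direction"] == direction, "window_id"])


def build_epigenome_sets(
    calls_by_factor: dict[str, pd.DataFrame],
    condition_a: str = "A",
    condition_b: str = "B",
) -> EpigenomeGeneSets:
    """Assemble the three per-condition set families from per-factor calls.

    ``hypo_methylation(X)`` inverts the methylation calls: lower methylation
    in X means the methylation signal was higher in the opposing condition.
    """
    missing = [f for f in ALL_FACTORS if f not in calls_by_factor]
    if missing:
        raise ValueError(f"differential calls missing for factors: {missing}")
    sets = EpigenomeGeneSets()
    tf = calls_by_factor[TF_FACTOR]
    sets.smad3_high[condition_a] = _direction_set(tf, HIGHER_A)
    sets.smad3_high[condition_b] = _direction_set(tf, HIGHER_B)
    open_a: set[str] = set()
    open_b: set[str] = set()
    for mark in OPEN_MARKS:
        open_a |= _direction_set(calls_by_factor[mark], HIGHER_A)
        open_b |= _direction_set(calls_by_factor[mark], HIGHER_B)
    sets.open_chromatin_high[condition_a] = open_a
    sets.open_chromatin_high[condition_b] = open_b
    meth = calls_by_factor["methylation"]
    sets.hypo_methylation[condition_a] = _direction_set(meth, HIGHER_B)
    sets.hypo_methylation[condition_b] = _direction_set(meth, HIGHER_A)
    return sets


def gene_set_enrichment(differential_set: set[str], context_set: set[str], universe: set[str]) -> dict:
    """One-sided hypergeometric over-representation of a differential set
    within a context set; reported per direction by the caller to mirror a
    bi-symmetrical presentation."""
    if not universe:
        raise ValueError("empty universe")
    if not differential_set <= universe or not context_set <= universe:
        raise ValueError("sets must be subsets of the universe")
    from .stats import hypergeom_over

    overlap = len(differential_set & context_set)
    p = hypergeom_over(len(universe), len(differential_set), len(context_set), overlap)
    # odds ratio of the 2x2 membership table (0.5 haldane correction)
    a = overlap
    b = len(context_set) - overlap
    c = len(differential_set) - overlap
    d = len(universe) - a - b - c
    odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return {"overlap": overlap, "n_differential": len(differential_set),
            "n_context": len(context_set), "n_universe": len(universe),
            "pvalue": p, "odds_ratio": odds}
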