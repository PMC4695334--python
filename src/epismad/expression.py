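"""Treatment-responsive gene calling and context-set partitioning.

For each condition and time point, treated replicates are compared with
control replicates gene-by-gene on the log2 scale; Benjamini–Hochberg
adjustment is applied across all tested genes and a gene is *responsive*
when its FDR falls below 0.1.  Per time point the two conditions' calls are
then partitioned into condition-A-unique, condition-B-unique, shared and
independent sets.  The global background ("treatment-independent") set
contains the genes responsive at no time point in either condition.

The default test is the moderated-variance t (variance pooled across genes
with empirical-Bayes shrinkage): with a handful of replicates per group the
per-gene variance estimate is the limiting factor, and borrowing strength
across genes is standard practice for expression arrays.  Plain Welch's t
is available via ``method="welch"``.  Externally computed responsive-gene
lists can bypass the test entirely (``sets_from_lists``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import TIME_POINTS, ExpressionMatrix
from .stats import bh_adjust, moderated_ttest, welch_ttest

RESPONSIVE_FDR = 0.1
CLASSES = ("A_unique", "B_unique", "shared", "independent")


def call_responsive(
    expr: ExpressionMatrix,
    condition: str,
    time: int,
    method: str = "moderated",
    fdr: float = RESPONSIVE_FDR,
) -> pd.DataFrame:
    """Per-gene treated-vs-control calls at one (condition, time point).

    Returns a frame with gene_id, condition, time, log2fc (treated - control),
    pvalue, fdr (BH across all tested genes) and the responsive flag.
    Zero-variance genes with equal group means get p = 1.
    """
    treated = expr.group(condition, "treated", time)
    control = expr.group(condition, "control", time)
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError(f"condition {condition!r} time {time}: need >= 2 replicates per group")
    test = {"moderated": moderated_ttest, "welch": welch_ttest}[method]
    lfc, _, p = test(treated, control)
    q = bh_adjust(p)
    return pd.DataFrame({
        "gene_id": expr.gene_ids,
        "condition": condition,
        "time": time,
        "log2fc": lfc,
        "pvalue": p,
        "fdr": q,
        "responsive": q < fdr,
    })


def call_all_times(
    expr: ExpressionMatrix, condition: str, method: str = "moderated", fdr: float = RESPONSIVE_FDR
) -> pd.DataFrame:
    frames = [call_responsive(expr, condition, t, method, fdr) for t in TIME_POINTS]
    return pd.concat(frames, ignore_index=True)


@dataclass
class ContextGeneSets:
    """Per-time-point four-way partition of the gene universe plus the
    global treatment-independent background."""

    universe: set[str]
    condition_a: str
    condition_b: str
    per_time: dict[int, dict[str, set[str]]] = field(default_factory=dict)
    background: set[str] = field(default_factory=set)

    def at(self, time: int, which: str) -> set[str]:
        return self.per_time[time][which]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for time in sorted(self.per_time):
            for cls in CLASSES:
                for gene in sorted(self.per_time[time][cls]):
                    rows.append((gene, time, cls, gene in self.background))
        return pd.DataFrame(rows, columns=["gene_id", "time", "class", "in_background"])


def _responsive_sets(calls: pd.DataFrame) -> dict[int, set[str]]:
    out: dict[int, set[str]] = {}
    for time, sub in calls.groupby("time"):
        out[int(time)] = set(sub.loc[sub["responsive"], "gene_id"])
    return out


def partition_context_sets(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> ContextGeneSets:
    """Partition each time point's universe into the four context classes.

    A gene is A_unique at a time point iff responsive in A and not in B at
    that time point (symmetrically for B_unique); shared iff responsive in
    both; independent otherwise.  The background set is global: responsive
    at no tested time point in either condition.
    """
    universe_a = set(calls_a["gene_id"])
    universe_b = set(calls_b["gene_id"])
    if universe_a != universe_b:
        raise ValueError("the two conditions were tested on different gene universes")
    cond_a = calls_a["condition"].iloc[0]
    cond_b = calls_b["condition"].iloc[0]
    resp_a = _responsive_sets(calls_a)
    resp_b = _responsive_sets(calls_b)
    if set(resp_a) != set(resp_b):
        raise ValueError("the two conditions were tested at different time points")
    sets = ContextGeneSets(universe_a, cond_a, cond_b)
    ever = set()
    for time in sorted(resp_a):
        a, b = resp_a[time], resp_b[time]
        ever |= a | b
        sets.per_time[time] = {
            "A_unique": a - b,
            "B_unique": b - a,
            "shared": a & b,
            "independent": universe_a - a - b,
        }
    sets.background = universe_a - ever
    return sets


def sets_from_lists(
    universe: set[str],
    responsive_a: dict[int, set[str]],
    responsive_b: dict[int, set[str]],
    condition_a: str = "A",
    condition_b: str = "B",
) -> ContextGeneSets:
    """Build context sets from externally computed responsive-gene lists
    (e.g. a limma/array pipeline), one set per condition per time point."""
    def as_calls(resp: dict[int, set[str]], condition: str) -> pd.DataFrame:
        rows = []
        for time, ids in resp.items():
            missing = ids - universe
            if missing:
                raise ValueError(f"responsive genes outside the universe: {sorted(missing)[:3]}")
            for gene in sorted(universe):
                rows.append((gene, condition, time, gene in ids))
        return pd.DataFrame(rows, columns=["gene_id", "condition", "time", "responsive"])

    return partition_context_sets(as_calls(responsive_a, condition_a), as_calls(responsive_b, condition_b))
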