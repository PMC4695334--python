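"""Gene-level TF binding modes and their enrichment statistics.

Reconciled binding events (shared / condition-unique, from
:mod:`epismad.peaks`) are assigned to genes whenever their interval
overlaps the gene-proximal window by at least one base (an event spanning
two genes' windows is assigned to both; full containment is available as a
stricter alternative).  Each gene is then classified into one of four
binding modes —

1. bound in condition A only,
2. bound in condition B only,
3. bound in both conditions,
4. bound in neither —

where "bound in A" means the gene carries an A-unique or a shared event.
Mode 3 is refined into an occupancy category from the gene's composite
profile: *identical* (only shared events), *mixed* (shared plus unique),
or *mutually_exclusive* (unique events on both sides, no shared site).

Enrichment of binding among responsive genes, and of each mode within a
gene set, is measured against the treatment-independent background with a
2x2 chi-square (df=1, no continuity correction; Fisher's exact available
for small cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .genome import ProximalWindow
from .peaks import SHARED, UNIQUE_A, UNIQUE_B, PeakMatch
from .stats import Chi2Result, bh_adjust, chi2_2x2, fisher_2x2

MODES = (1, 2, 3, 4)
CATEGORIES = ("identical", "mixed", "mutually_exclusive", "A_only", "B_only", "unbound")


def assign_proximal_peaks(
    windows: dict[str, ProximalWindow],
    matches: list[PeakMatch],
    rule: str = "overlap",
) -> dict[str, list[int]]:
    """Map gene id -> indices of matches assigned to its gene-proximal window.

    ``rule="overlap"``: >= 1 bp overlap of the match's representative
    interval (union of the matched peaks) with the window;
    ``rule="containment"``: the interval must lie entirely inside it.
    """
    if rule not in ("overlap", "containment"):
        raise ValueError(f"unknown assignment rule {rule!r}")
    trees: dict[str, IntervalTree] = {}
    for gene_id, w in windows.items():
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, gene_id)
    assigned: dict[str, list[int]] = {gene_id: [] for gene_id in windows}
    for idx, m in enumerate(matches):
        for iv in trees.get(m.chrom, IntervalTree()).overlap(m.start, m.end):
            if rule == "containment" and not (m.start >= iv.begin and m.end <= iv.end):
                continue
            assigned[iv.data].append(idx)
    return assigned


@dataclass(frozen=True)
class GeneBindingProfile:
    gene_id: str
    n_unique_a: int
    n_unique_b: int
    n_shared: int
    mode: int
    category: str


def classify_mode(gene_id: str, n_unique_a: int, n_unique_b: int, n_shared: int) -> GeneBindingProfile:
    """Mode and occupancy category from a gene's composite event counts."""
    present_a = n_unique_a > 0 or n_shared > 0
    present_b = n_unique_b > 0 or n_shared > 0
    if present_a and present_b:
        mode = 3
        if n_shared > 0 and n_unique_a == 0 and n_unique_b == 0:
            category = "identical"
        elif n_shared > 0:
            category = "mixed"
        else:
            category = "mutually_exclusive"
    elif present_a:
        mode, category = 1, "A_only"
    elif present_b:
        mode, category = 2, "B_only"
    else:
        mode, category = 4, "unbound"
    return GeneBindingProfile(gene_id, n_unique_a, n_unique_b, n_shared, mode, category)


def build_profiles(
    windows: dict[str, ProximalWindow],
    matches: list[PeakMatch],
    rule: str = "overlap",
) -> pd.DataFrame:
    """Per-gene binding profile frame: event counts, mode, category."""
    assigned = assign_proximal_peaks(windows, matches, rule)
    rows = []
    for gene_id in windows:
        counts = {SHARED: 0, UNIQUE_A: 0, UNIQUE_B: 0}
        for idx in assigned[gene_id]:
            counts[matches[idx].status] += 1
        prof = classify_mode(gene_id, counts[UNIQUE_A], counts[UNIQUE_B], counts[SHARED])
        rows.append((prof.gene_id, prof.n_unique_a, prof.n_unique_b, prof.n_shared, prof.mode, prof.category))
    return pd.DataFrame(rows, columns=["gene_id", "n_unique_A", "n_unique_B", "n_shared", "mode", "category"])


def _mode_lookup(profiles: pd.DataFrame) -> pd.Series:
    return profiles.set_index("gene_id")["mode"]


def bound_fraction_enrichment(
    responsive: set[str],
    background: set[str],
    profiles: pd.DataFrame,
    condition: str = "A",
    test: str = "chi2",
) -> dict:
    """Enrichment of genes bound in ``condition`` among responsive genes.

    2x2 table (bound/unbound x responsive/background) against the
    treatment-independent background; the two sets must be disjoint.
    """
    if responsive & background:
        raise ValueError("responsive and background sets must be disjoint")
    modes = _mode_lookup(profiles)
    bound_modes = {"A": {1, 3}, "B": {2, 3}}[condition]

    def split(ids: set[str]) -> tuple[int, int]:
        m = modes.reindex(sorted(ids))
        if m.isna().any():
            raise ValueError("gene set contains genes without a binding profile")
        bound = int(m.isin(bound_modes).sum())
        return bound, len(ids) - bound

    rb, ru = split(responsive)
    bb, bu = split(background)
    result = _run_test([[rb, ru], [bb, bu]], test)
    frac_resp = rb / len(responsive) if responsive else 0.0
    frac_back = bb / len(background) if background else 0.0
    fold = frac_resp / frac_back if frac_back > 0 else float("inf") if frac_resp > 0 else 1.0
    return {
        "condition": condition,
        "bound_responsive": rb, "unbound_responsive": ru,
        "bound_background": bb, "unbound_background": bu,
        "bound_fraction_responsive": frac_resp, "bound_fraction_background": frac_back,
        "fold": fold, "chi2": result.statistic, "pvalue": result.pvalue,
        "low_expected": result.low_expected,
    }


def _run_test(table, test: str) -> Chi2Result:
    if test == "chi2":
        return chi2_2x2(table)
    if test == "fisher":
        return fisher_2x2(table)
    raise ValueError(f"unknown enrichment test {test!r}")


def mode_enrichment(
    gene_set: set[str],
    background: set[str],
    profiles: pd.DataFrame,
    label: str = "",
    test: str = "chi2",
) -> pd.DataFrame:
    """Per-mode enrichment of ``gene_set`` over the background distribution.

    For each mode a 2x2 chi-square (in-mode / not-in-mode x set /
    background); fold = set fraction / background fraction; BH across the
    four modes.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    if not background:
        raise ValueError("empty background set")
    modes = _mode_lookup(profiles)
    m_set = modes.reindex(sorted(gene_set))
    m_back = modes.reindex(sorted(background))
    if m_set.isna().any() or m_back.isna().any():
        raise ValueError("gene set contains genes without a binding profile")
    rows = []
    for mode in MODES:
        a = int((m_set == mode).sum())
        b = len(gene_set) - a
        c = int((m_back == mode).sum())
        d = len(background) - c
        frac_set = a / len(gene_set)
        frac_back = c / len(background)
        fold = frac_set / frac_back if frac_back > 0 else float("inf") if frac_set > 0 else 1.0
        result = _run_test([[a, b], [c, d]], test)
        rows.append((label, mode, a, c, frac_set, frac_back, fold,
                     result.statistic, result.pvalue, result.low_expected))
    frame = pd.DataFrame(rows, columns=["set", "mode", "n_set", "n_background", "frac_set",
                                        "frac_background", "fold", "chi2", "pvalue", "low_expected"])
    frame["fdr"] = bh_adjust(frame["pvalue"].to_numpy())
    return frame


def composite_profile_table(gene_ids: set[str], profiles: pd.DataFrame) -> pd.DataFrame:
    """Genes of a set grouped by occupancy category, in canonical order,
    with per-category counts — the tabular form of the composite-profile
    display."""
    sub = profiles[profiles["gene_id"].isin(gene_ids)].copy()
    if len(sub) != len(gene_ids):
        missing = gene_ids - set(sub["gene_id"])
        raise ValueError(f"genes without a binding profile: {sorted(missing)[:3]}")
    sub["category"] = pd.Categorical(sub["category"], categories=list(CATEGORIES), ordered=True)
    sub = sub.sort_values(["category", "n_shared", "gene_id"], ascending=[True, False, True])
    counts = sub.groupby("category", observed=False).size()
    sub["category_count"] = sub["category"].map(counts).astype(int)
    sub["category"] = sub["category"].astype(str)
    return sub.reset_index(drop=True)
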