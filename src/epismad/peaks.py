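"""Cross-condition peak comparison.

Two peak sets for the same factor, one per condition, are reconciled into
*shared* binding events (the same site called in both conditions) and
*condition-unique* events.  Sharedness is declared when the summit of either
peak falls inside the other peak's interval (symmetric closure); this is
robust to width differences between point-source (MACS-like) and broad
(SICER-like) calls.  Multi-overlaps are resolved greedily, one-to-one, by
smallest summit distance.  A plain >= 1 bp interval-overlap criterion is
available as an alternative.

The occupancy matrix is the binary presence of the query peak set in a
fixed window (default 5 kb) centered on each reference peak summit — the
classic side-by-side occupancy heatmap input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import PeakRecord

SHARED, UNIQUE_A, UNIQUE_B = "shared", "unique_A", "unique_B"


@dataclass(frozen=True)
class PeakMatch:
    """A reconciled binding event: one peak per condition when shared,
    otherwise the single condition-unique peak.  ``start``/``end`` span the
    union of the matched intervals; ``summit`` is the A-side summit when
    present, else the B-side."""

    id_a: str | None
    id_b: str | None
    status: str
    chrom: str
    start: int
    end: int
    summit: int

    def __post_init__(self) -> None:
        expected = {SHARED: (True, True), UNIQUE_A: (True, False), UNIQUE_B: (False, True)}[self.status]
        if ((self.id_a is not None), (self.id_b is not None)) != expected:
            raise ValueError(f"match ids inconsistent with status {self.status}")


def _check_unique_ids(peaks: list[PeakRecord], label: str) -> None:
    names = [p.name for p in peaks]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise ValueError(f"duplicate peak id {dup!r} in condition {label}")


def _is_shared_pair(pa: PeakRecord, pb: PeakRecord, criterion: str) -> bool:
    if pa.chrom != pb.chrom:
        return False
    if criterion == "summit_in_interval":
        return (pb.start <= pa.summit < pb.end) or (pa.start <= pb.summit < pa.end)
    if criterion == "overlap":
        return pa.start < pb.end and pb.start < pa.end
    raise ValueError(f"unknown sharedness criterion {criterion!r}")


def match_peaks(
    peaks_a: list[PeakRecord], peaks_b: list[PeakRecord], criterion: str = "summit_in_interval"
) -> list[PeakMatch]:
    """Classify all peaks of two conditions into shared / unique_A / unique_B.

    Candidate shared pairs are ranked by summit distance (ties broken by
    peak ids, keeping the result deterministic) and accepted greedily while
    both peaks are still unmatched, so each peak joins at most one match.
    Symmetric: swapping the inputs swaps roles but yields the same pairs.
    """
    _check_unique_ids(peaks_a, "A")
    _check_unique_ids(peaks_b, "B")

    trees_b: dict[str, IntervalTree] = {}
    summits_b: dict[str, list[tuple[int, int]]] = {}
    for j, pb in enumerate(peaks_b):
        trees_b.setdefault(pb.chrom, IntervalTree()).addi(pb.start, pb.end, j)
        summits_b.setdefault(pb.chrom, []).append((pb.summit, j))
    trees_a: dict[str, IntervalTree] = {}
    for i, pa in enumerate(peaks_a):
        trees_a.setdefault(pa.chrom, IntervalTree()).addi(pa.start, pa.end, i)

    candidates: set[tuple[int, int]] = set()
    for i, pa in enumerate(peaks_a):
        for iv in trees_b.get(pa.chrom, IntervalTree()).at(pa.summit):
            candidates.add((i, iv.data))
    for j, pb in enumerate(peaks_b):
        for iv in trees_a.get(pb.chrom, IntervalTree()).at(pb.summit):
            candidates.add((iv.data, j))
    if criterion == "overlap":
        candidates = set()
        for i, pa in enumerate(peaks_a):
            for iv in trees_b.get(pa.chrom, IntervalTree()).overlap(pa.start, pa.end):
                candidates.add((i, iv.data))

    ranked = sorted(
        candidates,
        key=lambda ij: (abs(peaks_a[ij[0]].summit - peaks_b[ij[1]].summit),
                        peaks_a[ij[0]].name, peaks_b[ij[1]].name),
    )
    matched_a: dict[int, int] = {}
    matched_b: dict[int, int] = {}
    for i, j in ranked:
        if i in matched_a or j in matched_b:
            continue
        matched_a[i] = j
        matched_b[j] = i

    matches: list[PeakMatch] = []
    for i, pa in enumerate(peaks_a):
        if i in matched_a:
            pb = peaks_b[matched_a[i]]
            matches.append(PeakMatch(pa.name, pb.name, SHARED, pa.chrom,
                                     min(pa.start, pb.start), max(pa.end, pb.end), pa.summit))
        else:
            matches.append(PeakMatch(pa.name, None, UNIQUE_A, pa.chrom, pa.start, pa.end, pa.summit))
    for j, pb in enumerate(peaks_b):
        if j not in matched_b:
            matches.append(PeakMatch(None, pb.name, UNIQUE_B, pb.chrom, pb.start, pb.end, pb.summit))
    return matches


_STATUS_ORDER = {SHARED: 0, UNIQUE_A: 1, UNIQUE_B: 2}


def occupancy_matrix(
    reference: list[PeakRecord],
    query: list[PeakRecord],
    window: int = 5000,
    statuses: dict[str, str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Binary query occupancy around each reference summit.

    Entry (i, j) is 1 iff any query peak covers position
    ``summit_i + (j - window // 2)``.  Rows are ordered shared-first (when
    ``statuses`` maps reference peak name -> status) then by chromosome and
    summit.  Returns (matrix int8, row annotation frame).
    """
    if window <= 0 or window % 2:
        raise ValueError("window must be even and positive")
    trees: dict[str, IntervalTree] = {}
    for q in query:
        trees.setdefault(q.chrom, IntervalTree()).addi(q.start, q.end)

    def row_key(p: PeakRecord):
        status = statuses.get(p.name, UNIQUE_A) if statuses else SHARED
        return (_STATUS_ORDER.get(status, 3), p.chrom, p.summit, p.name)

    ordered = sorted(reference, key=row_key)
    half = window // 2
    mat = np.zeros((len(ordered), window), dtype=np.int8)
    for i, p in enumerate(ordered):
        lo, hi = p.summit - half, p.summit + half
        for iv in trees.get(p.chrom, IntervalTree()).overlap(lo, hi):
            a = max(iv.begin, lo) - lo
            b = min(iv.end, hi) - lo
            mat[i, a:b] = 1
    rows = pd.DataFrame({
        "peak_id": [p.name for p in ordered],
        "status": [statuses.get(p.name, "") if statuses else "" for p in ordered],
        "chrom": [p.chrom for p in ordered],
        "summit": [p.summit for p in ordered],
    })
    return mat, rows


def matches_to_frame(matches: list[PeakMatch]) -> pd.DataFrame:
    """Flat TSV-ready view of a match list."""
    return pd.DataFrame({
        "id_a": [m.id_a or "" for m in matches],
        "id_b": [m.id_b or "" for m in matches],
        "status": [m.status for m in matches],
        "chrom": [m.chrom for m in matches],
        "start": [m.start for m in matches],
        "end": [m.end for m in matches],
        "summit": [m.summit for m in matches],
    })
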