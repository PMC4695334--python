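"""Readers and writers for the external formats the pipeline touches.

Dialects: ENCODE narrowPeak (canonical peak format; column 10 is the summit
offset from the interval start, -1 meaning absent), broadPeak, BED6, BED6
gene annotations, GTF restricted to ``gene`` features, two-column chromosome
sizes, and TSV tables for counts, expression and every result.

All readers validate and reject rather than coerce; parse errors carry the
1-based line number.  Writers are byte-stable: fixed column order, tab
separation, floats at 6 significant digits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeLayout

FLOAT_FORMAT = "%.6g"
TIME_POINTS = (1, 3, 6, 24)
TREATMENTS = ("control", "treated")


class ParseError(ValueError):
    """A line of an input file failed to parse under the declared dialect."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = path, lineno


@dataclass(frozen=True)
class PeakRecord:
    """One called peak.  ``summit_offset`` is bases from ``start`` (None if
    the caller reported none); the working summit falls back to the interval
    midpoint."""

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "."
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"peak {self.name}: require 0 <= start < end, got [{self.start}, {self.end})")
        if self.summit_offset is not None and not (0 <= self.summit_offset < self.end - self.start):
            raise ValueError(f"peak {self.name}: summit offset {self.summit_offset} outside interval")

    @property
    def summit(self) -> int:
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2


def _parse_int(token: str, path, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {token!r}") from None


def _parse_float(token: str, path, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric {what}: {token!r}") from None


_DIALECT_MIN_COLS = {"narrowPeak": 10, "broadPeak": 9, "bed6": 4}


def read_peaks(path, dialect: str = "narrowPeak") -> list[PeakRecord]:
    """Read a peak file under the named dialect.

    narrowPeak: 10 columns, column 10 = summit offset (-1 -> absent).
    broadPeak: 9 columns, no summit.  bed6: 4-6 columns, score optional.
    """
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    path = Path(path)
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < _DIALECT_MIN_COLS[dialect]:
                raise ParseError(path, lineno, f"expected >= {_DIALECT_MIN_COLS[dialect]} columns for {dialect}, got {len(cols)}")
            chrom = cols[0]
            start = _parse_int(cols[1], path, lineno, "start")
            end = _parse_int(cols[2], path, lineno, "end")
            if end <= start:
                raise ParseError(path, lineno, f"end {end} <= start {start}")
            name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else f"peak_{lineno}"
            score = _parse_float(cols[4], path, lineno, "score") if len(cols) > 4 and cols[4] != "." else 0.0
            strand = cols[5] if len(cols) > 5 else "."
            summit: int | None = None
            if dialect == "narrowPeak":
                raw = _parse_int(cols[9], path, lineno, "summit offset")
                if raw != -1:
                    if not (0 <= raw < end - start):
                        raise ParseError(path, lineno, f"summit offset {raw} outside interval of width {end - start}")
                    summit = raw
            try:
                records.append(PeakRecord(chrom, start, end, name, score, strand, summit))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise ValueError(f"{path}: duplicate peak id {dup!r}")
    return records


def write_peaks(records: list[PeakRecord], path, dialect: str = "narrowPeak") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for r in records:
            base = [r.chrom, str(r.start), str(r.end), r.name, FLOAT_FORMAT % r.score, r.strand]
            if dialect == "narrowPeak":
                summit = -1 if r.summit_offset is None else r.summit_offset
                fh.write("\t".join(base + ["0", "-1", "-1", str(summit)]) + "\n")
            elif dialect == "broadPeak":
                fh.write("\t".join(base + ["0", "-1", "-1"]) + "\n")
            else:
                fh.write("\t".join(base) + "\n")


def read_chrom_sizes(path) -> GenomeLayout:
    """Two-column TSV: chromosome name, length."""
    path = Path(path)
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(path, lineno, "expected two columns: name, length")
            name = cols[0]
            if name in lengths:
                raise ParseError(path, lineno, f"duplicate chromosome {name!r}")
            lengths[name] = _parse_int(cols[1], path, lineno, "chromosome length")
    return GenomeLayout(lengths)


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.lengths.items():
            fh.write(f"{name}\t{length}\n")


def read_genes_bed6(path) -> list[GeneModel]:
    """One BED6 record per gene (multi-isoform annotations must be collapsed
    to a single span upstream)."""
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ParseError(path, lineno, f"expected 6 columns, got {len(cols)}")
            gene_id = cols[3]
            if gene_id in seen:
                raise ParseError(path, lineno, f"duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            try:
                genes.append(GeneModel(gene_id, cols[0], _parse_int(cols[1], path, lineno, "start"),
                                       _parse_int(cols[2], path, lineno, "end"), cols[5]))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return genes


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_genes_gtf(path) -> list[GeneModel]:
    """GTF restricted to ``gene`` features; 1-based closed coordinates are
    converted to 0-based half-open."""
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(path, lineno, f"expected 9 GTF columns, got {len(cols)}")
            if cols[2] != "gene":
                continue
            m = _GTF_GENE_ID.search(cols[8])
            if m is None:
                raise ParseError(path, lineno, "gene feature without gene_id attribute")
            gene_id = m.group(1)
            if gene_id in seen:
                raise ParseError(path, lineno, f"duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            start = _parse_int(cols[3], path, lineno, "start") - 1
            end = _parse_int(cols[4], path, lineno, "end")
            try:
                genes.append(GeneModel(gene_id, cols[0], start, end, cols[6]))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return genes


def read_genes(path) -> list[GeneModel]:
    """Dispatch on extension: .gtf/.gff -> GTF gene features, else BED6."""
    suffix = Path(path).suffix.lower()
    return read_genes_gtf(path) if suffix in (".gtf", ".gff") else read_genes_bed6(path)


def write_gene_table(frame: pd.DataFrame, path) -> None:
    """Write a result table as TSV: header mandatory, tab-separated, floats
    at 6 significant digits, no quoting.  Byte-stable for a given frame."""
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gene_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", header=0)
    if frame.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate column names")
    return frame


@dataclass(frozen=True)
class SampleAnnotation:
    condition: str
    treatment: str
    time: int
    replicate: int

    @property
    def token(self) -> str:
        return f"{self.condition}.{self.treatment}.{self.time}.{self.replicate}"


@dataclass
class ExpressionMatrix:
    """log2 expression values, genes x samples, with parsed sample annotation.

    Column tokens encode ``condition.treatment.time.replicate`` with
    treatment in {control, treated} and time in {1, 3, 6, 24} (hours).
    """

    values: pd.DataFrame
    samples: list[SampleAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.samples) != self.values.shape[1]:
            raise ValueError("sample annotation does not match column count")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return sorted({s.condition for s in self.samples})

    def group(self, condition: str, treatment: str, time: int) -> np.ndarray:
        """Values (genes x replicates) for one (condition, treatment, time) cell."""
        cols = [i for i, s in enumerate(self.samples)
                if s.condition == condition and s.treatment == treatment and s.time == time]
        return self.values.iloc[:, cols].to_numpy(dtype=float)


def _parse_sample_token(token: str, path, what="sample") -> SampleAnnotation:
    parts = token.split(".")
    if len(parts) != 4:
        raise ValueError(f"{path}: {what} token {token!r} is not condition.treatment.time.rep")
    condition, treatment, time_s, rep_s = parts
    if treatment not in TREATMENTS:
        raise ValueError(f"{path}: unknown treatment {treatment!r} in {token!r}")
    try:
        time = int(time_s)
        rep = int(rep_s)
    except ValueError:
        raise ValueError(f"{path}: non-integer time/replicate in {token!r}") from None
    if time not in TIME_POINTS:
        raise ValueError(f"{path}: unknown time point {time} in {token!r} (allowed: {TIME_POINTS})")
    return SampleAnnotation(condition, treatment, time, rep)


def read_expression(path, min_replicates: int = 2) -> ExpressionMatrix:
    """Read an expression TSV whose header encodes the sample annotation."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=0, index_col=0)
    samples = [_parse_sample_token(c, path) for c in frame.columns]
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    for col in frame.columns:
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            gene = frame.index[vals.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
        frame[col] = vals.astype(float)
    counts: dict[tuple, int] = {}
    for s in samples:
        counts[(s.condition, s.treatment, s.time)] = counts.get((s.condition, s.treatment, s.time), 0) + 1
    for key, n in counts.items():
        if n < min_replicates:
            raise ValueError(f"{path}: group {key} has {n} replicate(s); need >= {min_replicates}")
    return ExpressionMatrix(frame, samples)


def write_expression(expr: ExpressionMatrix, path) -> None:
    frame = expr.values.copy()
    frame.columns = [s.token for s in expr.samples]
    frame.to_csv(path, sep="\t", index=True, index_label="gene_id", float_format=FLOAT_FORMAT)


@dataclass
class CountTable:
    """Non-negative integer window counts plus per-column genome-wide
    library sizes (a library size need not bound its column sum)."""

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if list(self.library_sizes.index) != list(self.counts.columns):
            raise ValueError("library sizes must cover exactly the count columns")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        arr = self.counts.to_numpy()
        if np.isnan(arr.astype(float)).any():
            raise ValueError("count table has missing cells")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate window id {dup!r}")

    def columns_for(self, condition: str) -> list[str]:
        cols = [c for c in self.counts.columns if c.split(".")[0] == condition]
        if not cols:
            raise ValueError(f"no columns for condition {condition!r}")
        return cols


def read_counts(path, library_path) -> CountTable:
    """Counts TSV (window id x sample columns) + two-column library-size TSV."""
    counts = pd.read_csv(path, sep="\t", header=0, index_col=0)
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            row = counts.index[vals.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: non-numeric count at window {row!r}, column {col!r}")
        counts[col] = vals.astype(int)
    libs = pd.read_csv(library_path, sep="\t", header=0, index_col=0).iloc[:, 0]
    libs = libs.reindex(counts.columns)
    if libs.isna().any():
        missing = libs.index[libs.isna()][0]
        raise ValueError(f"{library_path}: no library size for column {missing!r}")
    return CountTable(counts, libs.astype(float))


def write_counts(table: CountTable, path, library_path) -> None:
    table.counts.to_csv(path, sep="\t", index=True, index_label="window_id")
    libs = table.library_sizes.to_frame("library_size")
    libs.to_csv(library_path, sep="\t", index=True, index_label="sample", float_format=FLOAT_FORMAT)
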