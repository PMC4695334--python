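"""Core genomic coordinate types and the proximal-window definitions.

Every downstream stage shares two windows derived per gene:

* the **gene-proximal** window, running from 1,500 bp upstream of the
  transcription start site (TSS) to the end of the gene body — the unit
  within which TF peaks are considered associated with a gene;
* the **TSS-proximal** window, a symmetric 3,000 bp window around the TSS
  (±1,500 bp) — used for promoter DNA-methylation quantification.

Coordinates are 0-based half-open (BED convention) throughout.  For a
minus-strand gene the TSS is the base ``end - 1``.  The TSS-proximal window
is, on the plus strand, ``[tss - 1500, tss + 1500)`` and, on the minus
strand, ``[tss - 1499, tss + 1501)`` — both are 3,000 bp windows containing
the TSS base, and the two formulas are exact mirror images of each other
under reflection of the chromosome (base ``x`` maps to ``L - 1 - x``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

GENE_PROXIMAL_UPSTREAM = 1500
TSS_FLANK = 1500


class AnnotationError(ValueError):
    """A gene annotation is inconsistent with the genome layout."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (bp)."""

    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if not isinstance(length, int) or length < 1:
                raise ValueError(f"chromosome {name!r}: length must be a positive integer, got {length!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise AnnotationError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class GeneModel:
    """A gene collapsed to a single transcript span.

    ``start < end``; the TSS is ``start`` on the plus strand and ``end - 1``
    on the minus strand, so it always lies inside ``[start, end)``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class ProximalWindow:
    """A derived per-gene window, clipped to chromosome bounds."""

    gene_id: str
    kind: str  # "gene_proximal" | "tss_proximal"
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"window for {self.gene_id}: empty after clipping [{self.start}, {self.end})")

    def overlaps(self, start: int, end: int) -> bool:
        return start < self.end and end > self.start

    def contains(self, start: int, end: int) -> bool:
        return start >= self.start and end <= self.end


def _check_gene(gene: GeneModel, layout: GenomeLayout) -> int:
    chrom_len = layout.length(gene.chrom)
    if gene.end > chrom_len:
        raise AnnotationError(
            f"gene {gene.gene_id} [{gene.start}, {gene.end}) exceeds {gene.chrom} length {chrom_len}"
        )
    return chrom_len


def derive_gene_proximal(gene: GeneModel, layout: GenomeLayout, upstream: int = GENE_PROXIMAL_UPSTREAM) -> ProximalWindow:
    """Window from ``upstream`` bp upstream of the TSS to the gene-body end.

    Plus strand: ``[start - upstream, end)``; minus strand:
    ``[start, end + upstream)``; clipped to ``[0, chromosome length)``.
    The window always contains the full gene body.
    """
    chrom_len = _check_gene(gene, layout)
    if gene.strand == "+":
        start, end = gene.start - upstream, gene.end
    else:
        start, end = gene.start, gene.end + upstream
    return ProximalWindow(gene.gene_id, "gene_proximal", gene.chrom, max(0, start), min(chrom_len, end))


def derive_tss_proximal(gene: GeneModel, layout: GenomeLayout, flank: int = TSS_FLANK) -> ProximalWindow:
    """Symmetric ``2 * flank`` bp window around the TSS base.

    Plus strand: ``[tss - flank, tss + flank)``; minus strand:
    ``[tss - flank + 1, tss + flank + 1)``.  Both contain the TSS base and
    map onto each other exactly under strand reflection.
    """
    chrom_len = _check_gene(gene, layout)
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - flank, tss + flank
    else:
        start, end = tss - flank + 1, tss + flank + 1
    return ProximalWindow(gene.gene_id, "tss_proximal", gene.chrom, max(0, start), min(chrom_len, end))


def derive_windows(
    genes: list[GeneModel], layout: GenomeLayout, kind: str = "gene_proximal"
) -> dict[str, ProximalWindow]:
    """Derive one window per gene; ``kind`` selects the definition."""
    derive = {"gene_proximal": derive_gene_proximal, "tss_proximal": derive_tss_proximal}[kind]
    seen: set[str] = set()
    out: dict[str, ProximalWindow] = {}
    for gene in genes:
        if gene.gene_id in seen:
            raise AnnotationError(f"duplicate gene id {gene.gene_id!r}")
        seen.add(gene.gene_id)
        out[gene.gene_id] = derive(gene, layout)
    return out
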