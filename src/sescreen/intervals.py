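"""Genomic interval and gene-annotation primitives.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``.  Intervals sort
lexicographically by chromosome name, then numerically by (start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GenomicInterval", "GeneAnnotation", "DETableRow"]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be non-empty.
    start, end : int
        0-based half-open coordinates with ``0 <= start < end``.
    name : str, optional
        Feature label.  When omitted, :attr:`label` falls back to the
        ``chrom:start-end`` locus string.
    strand : str
        One of ``+``, ``-``, ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return self.name if self.name is not None else f"{self.chrom}:{self.start}-{self.end}"

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies fully within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its body interval, strand-derived TSS and TF flag.

    The transcription start site is the first transcribed base:
    ``body.start`` on the + strand, ``body.end - 1`` on the - strand.
    """

    gene_id: str
    body: GenomicInterval
    strand: str
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")

    @property
    def chrom(self) -> str:
        return self.body.chrom

    @property
    def tss(self) -> int:
        """0-based TSS position derived from the strand."""
        return self.body.start if self.strand == "+" else self.body.end - 1


@dataclass(frozen=True)
class DETableRow:
    """One row of a differential-expression table.

    ``direction`` is derived: ``up`` iff log2fc > 0 else ``down``.
    """

    gene_id: str
    log2fc: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"gene {self.gene_id}: fdr {self.fdr} outside [0, 1]")

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


def sort_intervals(intervals) -> list[GenomicInterval]:
    """Return intervals sorted by (chrom, start, end); stable for ties."""
    return sorted(intervals, key=GenomicInterval.sort_key)
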