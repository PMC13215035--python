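"""Gene-centric downstream summaries of a ChIP-seq peak set.

Two analyses: (1) classify each gene by whether peaks fall in its genomic
region and/or its strand-aware proximal promoter, then summarize those
fractions by differential-expression direction; (2) overlap
direction-split DE genes (fold change > 2, FDR < 0.05) with named disease
gene lists for circle-plot-style output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import DETableRow, GeneAnnotation, GenomicInterval

__all__ = [
    "PeakGeneAnnotation",
    "classify_gene_peaks",
    "summarize_peak_fractions",
    "filter_de_table",
    "overlap_gene_sets",
]

logger = logging.getLogger("sescreen")

#: default proximal-promoter window: (upstream bp, downstream bp) of the TSS
DEFAULT_PROMOTER_WINDOW = (2000, 2000)


@dataclass(frozen=True)
class PeakGeneAnnotation:
    """Peak presence flags for one gene.

    ``has_peak`` and ``has_promoter_peak`` are computed independently: the
    promoter window may extend beyond the gene body, so neither implies
    the other.
    """

    gene_id: str
    has_peak: bool
    has_promoter_peak: bool
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW


def promoter_interval(gene: GeneAnnotation, window: tuple[int, int]) -> GenomicInterval:
    """Strand-aware proximal-promoter interval around the TSS.

    For a + strand gene with TSS t: ``[t - up, t + down)``.  For a - strand
    gene the window is mirrored so that "upstream" extends toward larger
    coordinates: ``[t + 1 - down, t + 1 + up)``.
    """
    up, down = window
    t = gene.tss
    if gene.strand == "+":
        lo, hi = t - up, t + down
    else:
        lo, hi = t + 1 - down, t + 1 + up
    lo = max(0, lo)
    if hi <= lo:
        hi = lo + 1
    return GenomicInterval(gene.chrom, lo, hi, name=f"{gene.gene_id}_promoter")


def classify_gene_peaks(
    gene: GeneAnnotation,
    peaks: Sequence[GenomicInterval],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> PeakGeneAnnotation:
    """Flag whether any peak overlaps the gene body / proximal promoter."""
    promoter = promoter_interval(gene, promoter_window)
    has_peak = any(p.overlaps(gene.body) for p in peaks)
    has_promoter_peak = any(p.overlaps(promoter) for p in peaks)
    return PeakGeneAnnotation(gene.gene_id, has_peak, has_promoter_peak, promoter_window)


def summarize_peak_fractions(
    de_rows: Sequence[DETableRow],
    annotations: Mapping[str, PeakGeneAnnotation],
) -> pd.DataFrame:
    """Fractions of up/down DE genes carrying gene-body and promoter peaks.

    One row per direction with numerators and denominators.  DE genes with
    no annotation are excluded with a warning and counted in
    ``n_missing``.  An empty direction class yields NA fractions with
    count 0.
    """
    rows = []
    for direction in ("up", "down"):
        class_genes = [r.gene_id for r in de_rows if r.direction == direction]
        present = [g for g in class_genes if g in annotations]
        missing = len(class_genes) - len(present)
        if missing:
            logger.warning(
                "%d %s-regulated DE genes missing from peak annotation; excluded",
                missing, direction,
            )
        n = len(present)
        n_peak = sum(1 for g in present if annotations[g].has_peak)
        n_prom = sum(1 for g in present if annotations[g].has_promoter_peak)
        rows.append(
            {
                "direction": direction,
                "n_genes": n,
                "n_missing": missing,
                "n_with_peak": n_peak,
                "frac_with_peak": n_peak / n if n else float("nan"),
                "n_with_promoter_peak": n_prom,
                "frac_with_promoter_peak": n_prom / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def filter_de_table(
    de_rows: Iterable[DETableRow],
    min_abs_log2fc: float = 1.0,
    max_fdr: float = 0.05,
) -> list[DETableRow]:
    """Keep rows with |log2fc| > min_abs_log2fc and fdr < max_fdr.

    The default threshold |log2fc| > 1 is the fold-change > 2 rule on the
    log2 scale.
    """
    return [r for r in de_rows if abs(r.log2fc) > min_abs_log2fc and r.fdr < max_fdr]


def overlap_gene_sets(
    de_rows: Sequence[DETableRow],
    disease_lists: Mapping[str, set[str]],
    min_abs_log2fc: float = 1.0,
    max_fdr: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int], int]:
    """Overlap filtered DE genes with named disease gene lists.

    Returns ``(records, per_list_counts, union_count)`` where records has
    one row per (DE gene, list) membership carrying direction and log2fc
    (circle-plot radial value), per_list_counts maps list name to its hit
    count, and union_count is the number of distinct DE genes hitting at
    least one list.  Gene matching is case-insensitive.
    """
    filtered = filter_de_table(de_rows, min_abs_log2fc, max_fdr)
    records = []
    union: set[str] = set()
    counts = {name: 0 for name in disease_lists}
    for row in filtered:
        key = row.gene_id.upper()
        for name in sorted(disease_lists):
            if key in disease_lists[name]:
                records.append(
                    {
                        "gene_id": row.gene_id,
                        "list_name": name,
                        "direction": row.direction,
                        "log2fc": row.log2fc,
                    }
                )
                counts[name] += 1
                union.add(key)
    df = pd.DataFrame(records, columns=["gene_id", "list_name", "direction", "log2fc"])
    return df, counts, len(union)
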