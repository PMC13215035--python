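"""Readers and writers for the plain-text formats the pipeline touches.

Formats: BED3/4/6 (peaks, stitched regions, SEs), 4-column bedGraph
(signal density), TSV with header (gene annotation, DE table, disease gene
lists), and one-symbol-per-line text (TF catalogue).  All coordinates are
0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .intervals import DETableRow, GeneAnnotation, GenomicInterval, sort_intervals
from .signal import SignalTrack

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_tf_list",
    "read_de_table",
    "read_disease_lists",
]

logger = logging.getLogger("sescreen")


class ParseError(ValueError):
    """Raised for malformed input files; message names file and line."""


def _data_lines(path: Path):
    """Yield (1-based line number, stripped line), skipping blanks and
    track/browser/# header lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            stripped = line.lstrip()
            if stripped.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/4/6 file into sorted :class:`GenomicInterval` records.

    Output is sorted by (chrom, start, end).  The name comes from column 4
    when present, otherwise ``chrom:start-end``; strand from column 6 when
    present, else ``.``.

    Raises
    ------
    ParseError
        On fewer than 3 columns, non-integer coordinates, or start >= end;
        the message names the offending line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if start < 0 or start >= end:
            raise ParseError(f"{path}:{lineno}: invalid coordinates start={start} end={end}")
        name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else None
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        if name is None:
            name = f"{chrom}:{start}-{end}"
        intervals.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
    return sort_intervals(intervals)


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    scores: Iterable[float] | None = None,
) -> None:
    """Write intervals as BED6 (score column 0 unless *scores* given)."""
    intervals = list(intervals)
    score_list = list(scores) if scores is not None else [0.0] * len(intervals)
    with open(path, "w") as fh:
        for iv, score in zip(intervals, score_list):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{score:g}\t{iv.strand}\n"
            )


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Overlapping segments on a chromosome are rejected (ValueError);
    malformed lines raise :class:`ParseError` with the line number.
    """
    path = Path(path)
    segments = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns (bedGraph)")
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed bedGraph fields") from None
        if start < 0 or start >= end:
            raise ParseError(f"{path}:{lineno}: invalid coordinates start={start} end={end}")
        segments.append((fields[0], start, end, value))
    return SignalTrack.from_segments(segments)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.segments():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def read_tf_list(path: str | Path) -> set[str]:
    """One gene symbol per line; upper-cased for case-insensitive matching."""
    symbols = set()
    with open(path) as fh:
        for raw in fh:
            sym = raw.strip()
            if sym and not sym.startswith("#"):
                symbols.add(sym.upper())
    return symbols


def read_gene_annotation(
    path: str | Path, tf_list_path: str | Path | None = None
) -> list[GeneAnnotation]:
    """Read a gene annotation (BED6 or header TSV) with optional TF flags.

    Accepted layouts:

    * BED6: chrom, start, end, gene_id, score, strand (no header);
    * TSV with a header containing gene_id/chrom/start/end/strand columns.

    ``is_tf`` is true iff the gene symbol appears in the TF list
    (case-insensitive).  TF-list symbols absent from the annotation are
    logged as warnings.  Duplicate gene_ids are an error.
    """
    path = Path(path)
    tf_symbols = read_tf_list(tf_list_path) if tf_list_path is not None else set()

    with open(path) as fh:
        first = fh.readline()
    is_tsv = "gene_id" in first.split()

    rows: list[tuple[str, str, int, int, str]] = []  # gene_id, chrom, start, end, strand
    if is_tsv:
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for r in df.itertuples(index=False):
            rows.append((str(r.gene_id), str(r.chrom), int(r.start), int(r.end), str(r.strand)))
    else:
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 gene annotation needs 6 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            rows.append((fields[3], fields[0], start, end, fields[5]))

    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for gene_id, chrom, start, end, strand in rows:
        if gene_id in seen:
            raise ParseError(f"{path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                body=GenomicInterval(chrom, start, end, name=gene_id, strand=strand),
                strand=strand,
                is_tf=gene_id.upper() in tf_symbols,
            )
        )

    unmatched = tf_symbols - {g.gene_id.upper() for g in genes}
    for sym in sorted(unmatched):
        logger.warning("TF list symbol %s not found in gene annotation", sym)
    return genes


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tis_tf\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.body.start}\t{g.body.end}\t{g.strand}\t"
                f"{int(g.is_tf)}\n"
            )


def read_de_table(path: str | Path) -> list[DETableRow]:
    """TSV with header columns gene_id (or gene), log2fc, fdr."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene_id") or cols.get("gene")
    fc_col = cols.get("log2fc") or cols.get("log2foldchange")
    fdr_col = cols.get("fdr") or cols.get("padj")
    if gene_col is None or fc_col is None or fdr_col is None:
        raise ParseError(f"{path}: need gene_id/log2fc/fdr columns, got {list(df.columns)}")
    return [
        DETableRow(str(r[gene_col]), float(r[fc_col]), float(r[fdr_col]))
        for _, r in df.iterrows()
    ]


def read_disease_lists(path: str | Path) -> dict[str, set[str]]:
    """TSV with header columns list_name, gene_id -> {list_name: symbols}."""
    df = pd.read_csv(path, sep="\t")
    if not {"list_name", "gene_id"} <= set(df.columns):
        raise ParseError(f"{path}: need columns list_name, gene_id")
    lists: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        lists.setdefault(str(r.list_name), set()).add(str(r.gene_id).upper())
    return lists
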