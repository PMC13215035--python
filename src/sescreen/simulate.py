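"""Synthetic multi-sample H3K27ac-like cohort with planted super-enhancers.

The generator emulates a cohort of N samples, each with a peak set (BED)
and a matching signal track (bedGraph): background enhancer peaks with
right-skewed (gamma) signal areas at random loci, plus planted SE loci —
clusters of >= 3 peaks within the stitching distance whose aggregate
signal is a configurable multiple of the background median — shared across
an explicit subset of samples, optionally anchored at a TF gene.  Every
source of randomness flows from a single seed; identical configs produce
byte-identical files.

The ground truth (locus, sharing pattern, anchored gene) is emitted as a
TSV so recovery of the planted SEs by the full pipeline can be scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusSE
from .intervals import GeneAnnotation, GenomicInterval
from .io import write_bed, write_bedgraph, write_gene_annotation
from .signal import SignalTrack

__all__ = [
    "PlantedSE",
    "SimConfig",
    "CohortFiles",
    "RecoveryScore",
    "default_planted_ses",
    "simulate_cohort",
    "read_truth",
    "score_recovery",
]

logger = logging.getLogger("sescreen")


@dataclass(frozen=True)
class PlantedSE:
    """A ground-truth super-enhancer locus planted into the cohort.

    fold : aggregate constituent signal as a multiple of the median
        background peak signal (20x by default — strong enough to sit on
        the steep tail of the rank-signal curve).
    present_in : indices (0-based) of the samples carrying this SE.
    at_gene / gene_is_tf : optional gene anchored near the locus (TSS
        placed 3 kb past the locus end so promoter exclusion cannot remove
        planted constituents) and whether it is in the TF catalogue.
    """

    se_id: str
    chrom: str
    start: int
    end: int
    n_constituents: int = 4
    fold: float = 20.0
    present_in: tuple[int, ...] = tuple(range(9))
    at_gene: str | None = None
    gene_is_tf: bool = False

    def __post_init__(self) -> None:
        if self.n_constituents < 3:
            raise ValueError(f"{self.se_id}: planted SEs need >= 3 constituents")
        if self.fold <= 0:
            raise ValueError(f"{self.se_id}: fold must be > 0")
        if not self.present_in:
            raise ValueError(f"{self.se_id}: present_in must be non-empty")

    @property
    def locus(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.se_id)


def default_planted_ses(n_samples: int = 9) -> tuple[PlantedSE, ...]:
    """The default planted layout: three SEs on a 2 x 10 Mb genome.

    One locus with the largest fold (30x) present in every sample and
    anchored at a TF gene — the discovery analogue whose consensus priority
    should be 1; one 20x locus in 7 samples at a second TF gene; one 20x
    locus in 6 samples at a non-TF gene.
    """
    if n_samples < 6:
        raise ValueError("default planted layout needs >= 6 samples")
    return (
        PlantedSE(
            "planted_tf_strong", "chr1", 1_000_000, 1_030_000,
            n_constituents=4, fold=30.0,
            present_in=tuple(range(n_samples)),
            at_gene="SETF01", gene_is_tf=True,
        ),
        PlantedSE(
            "planted_tf_mid", "chr1", 5_000_000, 5_025_000,
            n_constituents=4, fold=20.0,
            present_in=tuple(range(min(7, n_samples))),
            at_gene="SETF02", gene_is_tf=True,
        ),
        PlantedSE(
            "planted_non_tf", "chr2", 2_000_000, 2_020_000,
            n_constituents=3, fold=20.0,
            present_in=tuple(range(min(6, n_samples))),
            at_gene="SEGENE03", gene_is_tf=False,
        ),
    )


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic cohort.

    Defaults emulate the study conditions: 9 samples, ~500 background
    enhancer peaks per sample with gamma(1.5) right-skewed signal areas,
    log-normal (sd 0.2) per-sample depth jitter, and the planted layout of
    :func:`default_planted_ses`.
    """

    seed: int = 0
    n_samples: int = 9
    genome: tuple[tuple[str, int], ...] = (("chr1", 10_000_000), ("chr2", 10_000_000))
    n_genes: int = 200
    tf_fraction: float = 0.25
    n_background_peaks: int = 500
    background_shape: float = 1.5
    background_scale: float = 100.0
    peak_width: tuple[int, int] = (500, 2000)
    noise_sd: float = 0.2
    stitch_distance: int = 12500
    planted_ses: tuple[PlantedSE, ...] | None = None

    def resolved_planted(self) -> tuple[PlantedSE, ...]:
        if self.planted_ses is not None:
            return self.planted_ses
        return default_planted_ses(self.n_samples)

    def validate(self) -> None:
        sizes = dict(self.genome)
        planted = self.resolved_planted()
        for p in planted:
            if p.chrom not in sizes or p.end > sizes[p.chrom]:
                raise ValueError(f"planted SE {p.se_id} does not fit the genome")
            if max(p.present_in) >= self.n_samples:
                raise ValueError(f"planted SE {p.se_id}: present_in exceeds n_samples")
        for i, a in enumerate(planted):
            for b in planted[i + 1:]:
                if a.locus.overlaps(b.locus):
                    raise ValueError(f"planted loci {a.se_id} and {b.se_id} overlap")


@dataclass
class CohortFiles:
    """Paths of everything one simulation wrote."""

    outdir: Path
    sample_ids: list[str]
    peak_beds: dict[str, Path]
    signal_bedgraphs: dict[str, Path]
    genes_tsv: Path
    tf_list: Path
    truth_tsv: Path


def _planted_constituents(p: PlantedSE) -> list[GenomicInterval]:
    """Evenly spaced constituent peaks spanning the locus.

    Constituent width is 1/(2k-1) of the locus so gaps equal widths; the
    locus sizes in the default layout keep every gap well under the
    stitching distance.
    """
    k = p.n_constituents
    width = (p.end - p.start) // (2 * k - 1)
    if width < 50:
        raise ValueError(f"{p.se_id}: locus too small for {k} constituents")
    out = []
    for j in range(k):
        s = p.start + j * 2 * width
        out.append(GenomicInterval(p.chrom, s, s + width, name=f"{p.se_id}_c{j + 1}"))
    gap = out[1].start - out[0].end
    if gap > 12500:
        raise ValueError(f"{p.se_id}: constituent gap {gap} exceeds stitch distance")
    return out


def _sample_background(
    rng: np.random.Generator,
    config: SimConfig,
    forbidden: list[GenomicInterval],
) -> list[GenomicInterval]:
    """Disjoint background peaks avoiding planted loci (+ stitch margin)."""
    chroms = [c for c, _ in config.genome]
    sizes = dict(config.genome)
    margin = config.stitch_distance
    peaks: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for f in forbidden:
        occupied[f.chrom].append((f.start - margin, f.end + margin))
    attempts = 0
    max_attempts = config.n_background_peaks * 20
    while len(peaks) < config.n_background_peaks and attempts < max_attempts:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(config.peak_width[0], config.peak_width[1] + 1))
        start = int(rng.integers(0, sizes[chrom] - width))
        end = start + width
        # keep peaks pairwise disjoint and clear of planted territory
        if any(start < e and s < end for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        peaks.append(GenomicInterval(chrom, start, end))
    # rename by final sorted order for stable labels
    peaks.sort(key=GenomicInterval.sort_key)
    return [
        GenomicInterval(p.chrom, p.start, p.end, name=f"bg_{i + 1:04d}")
        for i, p in enumerate(peaks)
    ]


def _place_genes(
    rng: np.random.Generator,
    config: SimConfig,
    planted: Sequence[PlantedSE],
) -> list[GeneAnnotation]:
    """Shared gene annotation: planted anchor genes + random background genes.

    Anchor genes get their TSS 3 kb past the locus end on the + strand.
    Background gene TSSs are rejection-sampled to stay >= 60 kb from any
    planted locus so gene assignment of planted SEs is unambiguous.
    """
    sizes = dict(config.genome)
    genes: list[GeneAnnotation] = []
    for p in planted:
        if p.at_gene is None:
            continue
        tss = p.end + 3000
        body_end = min(tss + 20_000, sizes[p.chrom])
        genes.append(
            GeneAnnotation(
                gene_id=p.at_gene,
                body=GenomicInterval(p.chrom, tss, body_end, name=p.at_gene, strand="+"),
                strand="+",
                is_tf=p.gene_is_tf,
            )
        )
    chroms = [c for c, _ in config.genome]
    n_background = max(0, config.n_genes - len(genes))
    n_tf = int(round(n_background * config.tf_fraction))
    placed = 0
    attempts = 0
    while placed < n_background and attempts < n_background * 50:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        body_len = int(rng.integers(5_000, 50_000))
        start = int(rng.integers(0, sizes[chrom] - body_len))
        end = start + body_len
        near_planted = any(
            p.chrom == chrom and start - 60_000 < p.end and p.start < end + 60_000
            for p in planted
        )
        if near_planted:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        is_tf = placed < n_tf
        gene_id = (f"TF{placed + 1:03d}" if is_tf else f"GENE{placed + 1:03d}")
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                body=GenomicInterval(chrom, start, end, name=gene_id, strand=strand),
                strand=strand,
                is_tf=is_tf,
            )
        )
        placed += 1
    genes.sort(key=lambda g: g.gene_id)
    return genes


def simulate_cohort(config: SimConfig, outdir: str | Path) -> CohortFiles:
    """Write the full synthetic cohort to *outdir* and return its paths.

    Per sample: ``<sample>.peaks.bed`` and ``<sample>.signal.bedgraph``.
    Shared: ``genes.tsv`` (with TF flags), ``tf_list.txt``, ``truth.tsv``.
    Identical configs (including seed) produce byte-identical files.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    planted = config.resolved_planted()
    sample_ids = [f"sample_{i + 1:02d}" for i in range(config.n_samples)]

    planted_constituents = {p.se_id: _planted_constituents(p) for p in planted}
    all_planted_loci = [p.locus for p in planted]
    genes = _place_genes(rng, config, planted)

    peak_beds: dict[str, Path] = {}
    signal_bedgraphs: dict[str, Path] = {}
    for i, sample_id in enumerate(sample_ids):
        background = _sample_background(rng, config, all_planted_loci)
        bg_areas = rng.gamma(config.background_shape, config.background_scale, len(background))
        median_area = float(np.median(bg_areas))
        depth_factor = float(rng.lognormal(mean=0.0, sigma=config.noise_sd))

        peaks: list[GenomicInterval] = list(background)
        segments: list[tuple[str, int, int, float]] = [
            (p.chrom, p.start, p.end, depth_factor * a / p.length)
            for p, a in zip(background, bg_areas)
        ]
        for p in planted:
            if i not in p.present_in:
                continue
            constituents = planted_constituents[p.se_id]
            total_area = p.fold * median_area
            per_constituent = total_area / len(constituents)
            for c in constituents:
                peaks.append(c)
                segments.append((c.chrom, c.start, c.end, depth_factor * per_constituent / c.length))

        peaks.sort(key=GenomicInterval.sort_key)
        bed_path = outdir / f"{sample_id}.peaks.bed"
        bg_path = outdir / f"{sample_id}.signal.bedgraph"
        write_bed(peaks, bed_path)
        write_bedgraph(SignalTrack.from_segments(segments), bg_path)
        peak_beds[sample_id] = bed_path
        signal_bedgraphs[sample_id] = bg_path

    genes_tsv = outdir / "genes.tsv"
    write_gene_annotation(genes, genes_tsv)
    tf_list = outdir / "tf_list.txt"
    with open(tf_list, "w") as fh:
        for g in genes:
            if g.is_tf:
                fh.write(g.gene_id + "\n")

    truth_tsv = outdir / "truth.tsv"
    with open(truth_tsv, "w") as fh:
        fh.write("se_id\tchrom\tstart\tend\tn_constituents\tfold\tpresent_in\tat_gene\tgene_is_tf\n")
        for p in planted:
            present = ",".join(sample_ids[j] for j in sorted(p.present_in))
            fh.write(
                f"{p.se_id}\t{p.chrom}\t{p.start}\t{p.end}\t{p.n_constituents}\t"
                f"{p.fold:g}\t{present}\t{p.at_gene or '.'}\t{int(p.gene_is_tf)}\n"
            )

    return CohortFiles(
        outdir=outdir,
        sample_ids=sample_ids,
        peak_beds=peak_beds,
        signal_bedgraphs=signal_bedgraphs,
        genes_tsv=genes_tsv,
        tf_list=tf_list,
        truth_tsv=truth_tsv,
    )


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read truth.tsv back into a DataFrame (round-trip of the planted set)."""
    return pd.read_csv(path, sep="\t")


@dataclass(frozen=True)
class RecoveryScore:
    """Recovery of the planted SEs by the consensus output.

    sensitivity : recovered / eligible planted SEs (eligible = shared by at
        least min_presence samples); None when no planted SE is eligible.
    precision : kept consensus SEs overlapping any planted locus / all kept.
    rank_of_planted_tf : priority of the consensus SE recovering the
        planted TF locus with the largest fold; None if not recovered.
    """

    sensitivity: float | None
    precision: float | None
    rank_of_planted_tf: int | None
    n_eligible: int
    n_recovered: int
    n_kept: int


def score_recovery(
    truth: pd.DataFrame,
    consensus: Sequence[ConsensusSE],
    min_presence: int,
    min_locus_overlap: float = 0.5,
) -> RecoveryScore:
    """Score the consensus output against the planted ground truth.

    A planted SE is recovered iff some kept consensus SE overlaps its locus
    by >= ``min_locus_overlap`` of the locus length.  Precision counts kept
    consensus SEs overlapping any planted locus (by >= 1 bp).
    """
    loci = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.se_id)
        for r in truth.itertuples(index=False)
    ]
    presence = {
        r.se_id: len(str(r.present_in).split(","))
        for r in truth.itertuples(index=False)
    }
    eligible = [iv for iv in loci if presence[iv.name] >= min_presence]

    recovered: set[str] = set()
    recovering_cluster: dict[str, ConsensusSE] = {}
    for iv in eligible:
        need = min_locus_overlap * iv.length
        for c in consensus:
            if c.interval.overlap_length(iv) >= need:
                recovered.add(iv.name)
                prev = recovering_cluster.get(iv.name)
                if prev is None or (c.priority or 0) < (prev.priority or 0):
                    recovering_cluster[iv.name] = c
                break

    n_kept = len(consensus)
    n_true_positive = sum(
        1 for c in consensus if any(c.interval.overlap_length(iv) > 0 for iv in loci)
    )
    sensitivity = len(recovered) / len(eligible) if eligible else None
    precision = n_true_positive / n_kept if n_kept else None

    # strongest planted TF locus = TF-anchored row with the largest fold
    tf_rows = truth[truth["gene_is_tf"] == 1]
    rank_of_planted_tf = None
    if not tf_rows.empty:
        best = tf_rows.loc[tf_rows["fold"].idxmax()]
        c = recovering_cluster.get(str(best.se_id))
        if c is not None:
            rank_of_planted_tf = c.priority
    return RecoveryScore(
        sensitivity=sensitivity,
        precision=precision,
        rank_of_planted_tf=rank_of_planted_tf,
        n_eligible=len(eligible),
        n_recovered=len(recovered),
        n_kept=n_kept,
    )
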