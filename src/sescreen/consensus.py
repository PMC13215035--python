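"""Cross-sample consensus super-enhancers and the TF screen.

Per-sample SE calls are merged by single-linkage overlap clustering
(>= 1 bp by default), filtered on a presence threshold (the reliability
rule: an SE must be called in enough samples to count), aggregated by
average per-sample rank and depth-normalized intensity, prioritized, and
intersected with a transcription-factor catalogue to nominate SE-regulated
TFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calling import SampleSECalls
from .intervals import GeneAnnotation, GenomicInterval

__all__ = [
    "ScreenConfig",
    "ConsensusMember",
    "GeneAssignment",
    "ConsensusSE",
    "normalize_intensity",
    "build_consensus",
    "filter_presence",
    "aggregate_and_prioritize",
    "assign_genes",
    "screen_tfs",
]

logger = logging.getLogger("sescreen")


@dataclass(frozen=True)
class ScreenConfig:
    """Consensus-screen parameters.

    min_presence : minimum number of distinct samples an SE cluster must be
        called in to be kept (default 6, i.e. "more than 5" of a 9-sample
        cohort).
    gene_window : bp flank around a consensus SE within which a gene TSS is
        assigned to it (default 50 kb).
    min_overlap_frac : optional minimum overlap, as a fraction of the
        shorter interval, for two SEs to be linked (0 = any >=1 bp overlap).
    """

    min_presence: int = 6
    gene_window: int = 50_000
    min_overlap_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.min_presence < 1:
            raise ValueError("min_presence must be >= 1")
        if self.gene_window < 0:
            raise ValueError("gene_window must be >= 0")
        if not (0.0 <= self.min_overlap_frac <= 1.0):
            raise ValueError("min_overlap_frac must be in [0, 1]")


@dataclass(frozen=True)
class ConsensusMember:
    """One sample's SE contributing to a consensus cluster."""

    sample_id: str
    interval: GenomicInterval
    rank: int
    intensity: float


@dataclass(frozen=True)
class GeneAssignment:
    gene_id: str
    distance: int  # signed bp from nearest SE edge; 0 if TSS inside the SE
    is_nearest: bool
    is_tf: bool


@dataclass
class ConsensusSE:
    """A cross-sample SE cluster.

    ``presence`` counts distinct samples; a sample contributing two SEs to
    one cluster counts once for presence but both enter ``members``.
    """

    interval: GenomicInterval
    members: list[ConsensusMember]
    avg_rank: float | None = None
    avg_intensity: float | None = None
    priority: int | None = None
    genes: list[GeneAssignment] = field(default_factory=list)

    @property
    def presence(self) -> int:
        return len({m.sample_id for m in self.members})

    @property
    def is_tf_se(self) -> bool:
        return any(g.is_tf for g in self.genes)


def normalize_intensity(calls: SampleSECalls) -> dict[int, float]:
    """Per-region intensity in (0, 1]: signal / max signal in the sample.

    The divisor is the maximum over ALL of the sample's stitched regions
    (SE and TE alike), which cancels per-sample depth/efficiency scale so
    intensities are comparable across samples.  Keys are indices into
    ``calls.regions``.

    Raises
    ------
    ValueError
        If the sample has no regions or its maximum signal is 0.
    """
    if not calls.regions:
        raise ValueError(f"sample {calls.sample_id}: no regions")
    max_signal = max(r.signal for r in calls.regions)
    if max_signal <= 0:
        raise ValueError(f"sample {calls.sample_id}: degenerate sample, max signal is 0")
    return {i: r.signal / max_signal for i, r in enumerate(calls.regions)}


def build_consensus(
    all_calls: Sequence[SampleSECalls],
    min_overlap_frac: float = 0.0,
) -> list[ConsensusSE]:
    """Single-linkage clustering of per-sample SEs across the cohort.

    Only regions flagged ``is_super`` participate.  Two SEs are linked when
    their half-open intervals overlap by >= 1 bp (or by
    ``min_overlap_frac`` of the shorter of the incoming interval and the
    growing cluster span, if set).  The cluster interval is the union span
    of its members.  Output is sorted by (chrom, start) and independent of
    the order samples are supplied in.
    """
    if not all_calls:
        raise ValueError("need at least one sample")
    entries: list[ConsensusMember] = []
    for calls in all_calls:
        intensities = normalize_intensity(calls)
        for i, region in enumerate(calls.regions):
            if region.is_super:
                entries.append(
                    ConsensusMember(
                        sample_id=calls.sample_id,
                        interval=region.interval,
                        rank=region.rank,
                        intensity=intensities[i],
                    )
                )
    entries.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.interval.end, m.sample_id))

    clusters: list[ConsensusSE] = []
    cur: list[ConsensusMember] = []
    cur_chrom, cur_start, cur_end = None, 0, -1
    for m in entries:
        iv = m.interval
        if cur and iv.chrom == cur_chrom:
            overlap = cur_end - iv.start
            if min_overlap_frac > 0.0:
                need = min_overlap_frac * min(iv.length, cur_end - cur_start)
                linked = overlap >= need and overlap >= 1
            else:
                linked = overlap >= 1
        else:
            linked = False
        if linked:
            cur.append(m)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                clusters.append(_finish_cluster(cur, cur_chrom, cur_start, cur_end))
            cur = [m]
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur:
        clusters.append(_finish_cluster(cur, cur_chrom, cur_start, cur_end))
    return clusters


def _finish_cluster(members, chrom, start, end) -> ConsensusSE:
    return ConsensusSE(
        interval=GenomicInterval(chrom, start, end),
        members=sorted(members, key=lambda m: (m.sample_id, m.interval.start, m.interval.end)),
    )


def filter_presence(clusters: Iterable[ConsensusSE], config: ScreenConfig) -> list[ConsensusSE]:
    """Keep clusters present in at least ``config.min_presence`` samples."""
    kept: list[ConsensusSE] = []
    for c in clusters:
        if c.presence >= config.min_presence:
            kept.append(c)
        else:
            logger.debug(
                "dropping consensus SE %s: presence %d < %d",
                c.interval, c.presence, config.min_presence,
            )
    return kept


def aggregate_and_prioritize(clusters: Iterable[ConsensusSE]) -> list[ConsensusSE]:
    """Average member ranks/intensities and assign 1-based priorities.

    Sort key is (avg_rank ascending, avg_intensity descending, chrom,
    start): the paper-style combination of average ranking number and
    signal intensity, realized lexicographically rather than as an invented
    composite score.
    """
    out = list(clusters)
    for c in out:
        if not c.members:
            raise ValueError(f"cluster {c.interval} has no members")
        c.avg_rank = float(np.mean([m.rank for m in c.members]))
        c.avg_intensity = float(np.mean([m.intensity for m in c.members]))
    out.sort(key=lambda c: (c.avg_rank, -c.avg_intensity, c.interval.chrom, c.interval.start))
    for i, c in enumerate(out, start=1):
        c.priority = i
    return out


def assign_genes(
    cluster: ConsensusSE,
    genes: Sequence[GeneAnnotation],
    window: int,
) -> list[GeneAssignment]:
    """Assign every gene whose TSS lies within window bp of the SE span.

    A gene is assigned iff its TSS falls in
    ``[interval.start - window, interval.end + window)``.  Distance is 0
    when the TSS is inside the SE span, otherwise the signed offset from
    the nearest SE edge (negative upstream of the span start).  The
    closest gene (smallest |distance|, ties by gene_id) is flagged nearest.
    Assignments are stored on the cluster and returned.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    iv = cluster.interval
    assignments: list[GeneAssignment] = []
    for g in genes:
        if g.chrom != iv.chrom:
            continue
        tss = g.tss
        if not (iv.start - window <= tss < iv.end + window):
            continue
        if iv.start <= tss < iv.end:
            distance = 0
        elif tss < iv.start:
            distance = tss - iv.start  # negative: upstream of the span
        else:
            distance = tss - iv.end
        assignments.append(GeneAssignment(g.gene_id, distance, False, g.is_tf))
    if assignments:
        best = min(abs(a.distance) for a in assignments)
        nearest_id = min(a.gene_id for a in assignments if abs(a.distance) == best)
        assignments = [
            GeneAssignment(a.gene_id, a.distance, a.gene_id == nearest_id, a.is_tf)
            for a in assignments
        ]
    assignments.sort(key=lambda a: (abs(a.distance), a.gene_id))
    cluster.genes = assignments
    return assignments


def screen_tfs(
    clusters: Sequence[ConsensusSE],
    genes: Sequence[GeneAnnotation],
) -> pd.DataFrame:
    """Intersect prioritized consensus SEs with the TF catalogue.

    One row per TF gene assigned to at least one kept cluster, carrying the
    best (lowest) avg_rank among its clusters and that cluster's
    avg_intensity, priority and span; ordered by avg_rank ascending.
    Returns an empty table (with a warning) when no TF is assigned.
    """
    tf_ids = {g.gene_id for g in genes if g.is_tf}
    best: dict[str, ConsensusSE] = {}
    n_hits: dict[str, int] = {}
    for c in clusters:
        if c.avg_rank is None:
            raise ValueError("clusters must be aggregated before screening")
        for a in c.genes:
            if a.gene_id not in tf_ids:
                continue
            n_hits[a.gene_id] = n_hits.get(a.gene_id, 0) + 1
            if a.gene_id not in best or c.avg_rank < best[a.gene_id].avg_rank:
                best[a.gene_id] = c
    rows = []
    for gene_id, c in best.items():
        rows.append(
            {
                "gene_id": gene_id,
                "avg_rank": c.avg_rank,
                "avg_intensity": c.avg_intensity,
                "priority": c.priority,
                "se_chrom": c.interval.chrom,
                "se_start": c.interval.start,
                "se_end": c.interval.end,
                "presence": c.presence,
                "n_clusters": n_hits[gene_id],
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "avg_rank", "avg_intensity", "priority",
            "se_chrom", "se_start", "se_end", "presence", "n_clusters",
        ],
    )
    if df.empty:
        logger.warning("no TF gene assigned to any kept consensus SE")
        return df
    return df.sort_values(["avg_rank", "gene_id"], kind="mergesort").reset_index(drop=True)
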