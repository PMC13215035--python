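"""Per-sample super-enhancer calling (ROSE-style).

The procedure: drop peaks fully contained in a TSS-exclusion window, stitch
the remaining peaks transitively when their gaps are at most the stitching
distance (~12.5 kb for H3K27ac enhancer clusters), quantify net signal
(ChIP minus optional input control) over each stitched region, and separate
super-enhancers from typical enhancers with the tangent-line cutoff on the
ascending rank-signal ("hockey stick") curve.

Cutoff geometry.  Sort the n region signals ascending into v(1..n) and set
the global slope s = (max(v) - min(v)) / n, the slope of the diagonal of the
rank-signal plot.  For each candidate index x, f(x) counts the points lying
on or below the line of slope s through (x, v(x)).  The cutoff index x* is
the argmin of f (ties to the smallest x, for determinism); regions with
signal strictly greater than v(x*) are super-enhancers.  At the tangent
point of a convex "hockey stick" curve this line touches the curve from
below, so f is minimized exactly where the curve's local slope reaches s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .intervals import GeneAnnotation, GenomicInterval, sort_intervals
from .signal import SignalTrack

__all__ = [
    "StitchParams",
    "StitchedRegion",
    "SampleSECalls",
    "SECallError",
    "exclude_tss_proximal",
    "stitch",
    "quantify_signal",
    "compute_cutoff",
    "call_sample",
]


class SECallError(ValueError):
    """Raised when SE calling cannot proceed (e.g. no regions to rank)."""


@dataclass(frozen=True)
class StitchParams:
    """Tunable parameters of the per-sample caller.

    stitch_distance : maximum gap (bp) between peaks merged into one region.
    tss_exclusion_window : half-width (bp) of the promoter-exclusion zone;
        peaks fully inside [TSS - w, TSS + w] are removed before stitching.
    quantify_mode : ``constituents`` integrates signal over the union of
        constituent peaks (gaps count as background); ``full_region``
        integrates over the whole stitched span.
    clamp_negative : clamp net (ChIP - control) region signal at 0.
    """

    stitch_distance: int = 12500
    tss_exclusion_window: int = 2500
    quantify_mode: str = "constituents"
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.stitch_distance < 0 or self.tss_exclusion_window < 0:
            raise ValueError("distances must be >= 0")
        if self.quantify_mode not in ("constituents", "full_region"):
            raise ValueError(f"unknown quantify_mode {self.quantify_mode!r}")


@dataclass
class StitchedRegion:
    """A stitched enhancer region with its constituent peaks.

    ``signal``, ``rank`` and ``is_super`` are filled in by
    :func:`call_sample`; rank 1 is the strongest region.
    """

    interval: GenomicInterval
    constituents: list[GenomicInterval]
    signal: float | None = None
    rank: int | None = None
    is_super: bool | None = None

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


@dataclass
class SampleSECalls:
    """One sample's ranked stitched regions with the SE/TE partition.

    ``cutoff_index`` is the 1-based index x* into the ascending-sorted
    signal vector; regions with signal strictly above ``cutoff_value`` are
    super-enhancers.
    """

    sample_id: str
    regions: list[StitchedRegion]
    cutoff_index: int
    cutoff_value: float

    @property
    def n_se(self) -> int:
        return sum(1 for r in self.regions if r.is_super)

    def super_enhancers(self) -> list[StitchedRegion]:
        return [r for r in self.regions if r.is_super]

    def typical_enhancers(self) -> list[StitchedRegion]:
        return [r for r in self.regions if not r.is_super]


def exclude_tss_proximal(
    peaks: Iterable[GenomicInterval],
    genes: Sequence[GeneAnnotation],
    window: int,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Split peaks into (kept, excluded) by TSS proximity.

    A peak is excluded iff it is FULLY contained within the half-open zone
    ``[tss - window, tss + window)`` of any gene; peaks that merely overlap
    a zone are kept.  With window=0 the zone is empty and the call is the
    identity.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    peaks = list(peaks)
    if not peaks or not genes or window == 0:
        return peaks, []
    # Per-chromosome sorted TSS zone starts, for binary search.
    zones: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        lo = max(0, g.tss - window)
        hi = g.tss + window
        by_chrom.setdefault(g.chrom, []).append((lo, hi))
    for chrom, zs in by_chrom.items():
        zs.sort()
        starts = np.array([z[0] for z in zs], dtype=np.int64)
        # running max of ends lets containment be checked against any zone
        # starting at or before the peak start
        ends = np.maximum.accumulate(np.array([z[1] for z in zs], dtype=np.int64))
        zones[chrom] = (starts, ends)

    kept: list[GenomicInterval] = []
    excluded: list[GenomicInterval] = []
    for peak in peaks:
        contained = False
        if peak.chrom in zones:
            starts, cum_ends = zones[peak.chrom]
            i = int(np.searchsorted(starts, peak.start, side="right")) - 1
            if i >= 0 and peak.end <= cum_ends[i]:
                # some zone with start <= peak.start reaches past peak.end:
                # running-max end guarantees a single zone contains the peak
                # only if zone ends are monotone under the running max; the
                # containment test is exact because zones are intervals and
                # the running max is attained by one actual zone end whose
                # start is <= peak.start.
                contained = True
        (excluded if contained else kept).append(peak)
    return kept, excluded


def stitch(peaks: Iterable[GenomicInterval], distance: int) -> list[StitchedRegion]:
    """Merge peaks transitively when the gap between them is <= distance.

    Peaks on different chromosomes never merge.  The region interval spans
    from the first constituent's start to the last constituent's end.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    peaks = sort_intervals(peaks)
    regions: list[StitchedRegion] = []
    current: list[GenomicInterval] = []
    cur_end = -1
    for peak in peaks:
        if current and peak.chrom == current[0].chrom and peak.start - cur_end <= distance:
            current.append(peak)
            cur_end = max(cur_end, peak.end)
        else:
            if current:
                regions.append(_make_region(current))
            current = [peak]
            cur_end = peak.end
    if current:
        regions.append(_make_region(current))
    return regions


def _make_region(constituents: list[GenomicInterval]) -> StitchedRegion:
    chrom = constituents[0].chrom
    start = min(c.start for c in constituents)
    end = max(c.end for c in constituents)
    return StitchedRegion(
        interval=GenomicInterval(chrom, start, end, name=f"{chrom}:{start}-{end}"),
        constituents=list(constituents),
    )


def quantify_signal(
    region: StitchedRegion,
    chip: SignalTrack,
    control: SignalTrack | None = None,
    params: StitchParams = StitchParams(),
) -> float:
    """Net signal (density x bp) of a region: sum of chip - control density.

    The integration domain is the union of constituent peaks
    (``constituents`` mode, gaps are background) or the whole stitched span
    (``full_region`` mode).  Negative net signal clamps to 0 when
    ``params.clamp_negative``.
    """
    if params.quantify_mode == "full_region":
        domains = [region.interval]
    else:
        domains = region.constituents
    total = 0.0
    for iv in domains:
        total += chip.integrate(iv.chrom, iv.start, iv.end)
        if control is not None:
            total -= control.integrate(iv.chrom, iv.start, iv.end)
    if params.clamp_negative:
        total = max(total, 0.0)
    return total


def compute_cutoff(signals: Sequence[float] | np.ndarray) -> tuple[int, float]:
    """Tangent-line SE cutoff on the ascending-sorted signal vector.

    Returns ``(x_star, cutoff_value)`` where ``x_star`` is the 1-based index
    into the sorted vector minimizing f(x) = #{i : v(i) <= v(x) + s (i - x)}
    with s = (max(v) - min(v)) / n, ties broken toward the smallest x, and
    ``cutoff_value = v(x_star)``.  Regions are super-enhancers iff their
    signal is strictly greater than the cutoff value.  Negative inputs are
    clamped to 0 before sorting.

    Raises
    ------
    SECallError
        If fewer than 2 signals are supplied.
    """
    v = np.sort(np.clip(np.asarray(signals, dtype=np.float64), 0.0, None))
    n = v.size
    if n < 2:
        raise SECallError(f"need >= 2 regions to place a cutoff, got {n}")
    s = (v[-1] - v[0]) / n
    idx = np.arange(1, n + 1, dtype=np.float64)
    # f[x] = row-wise count of points on/below the slope-s line through x
    line = v[:, None] + s * (idx[None, :] - idx[:, None])
    f = np.count_nonzero(v[None, :] <= line, axis=1)
    x_star = int(np.argmin(f)) + 1  # argmin takes the first (smallest x) tie
    return x_star, float(v[x_star - 1])


def call_sample(
    sample_id: str,
    peaks: Iterable[GenomicInterval],
    chip: SignalTrack,
    control: SignalTrack | None = None,
    genes: Sequence[GeneAnnotation] = (),
    params: StitchParams = StitchParams(),
) -> SampleSECalls:
    """Full per-sample SE call: exclude, stitch, quantify, cutoff, rank.

    Ranks are 1-based with rank 1 = highest signal; ties in signal are
    broken by (chrom, start) so output is deterministic.
    """
    kept, _excluded = exclude_tss_proximal(peaks, genes, params.tss_exclusion_window)
    regions = stitch(kept, params.stitch_distance)
    if not regions:
        raise SECallError(f"sample {sample_id}: no regions to rank after TSS exclusion")
    for region in regions:
        region.signal = quantify_signal(region, chip, control, params)
    x_star, cutoff_value = compute_cutoff([r.signal for r in regions])
    order = sorted(
        range(len(regions)),
        key=lambda i: (-regions[i].signal, regions[i].interval.chrom, regions[i].interval.start),
    )
    for rank, i in enumerate(order, start=1):
        regions[i].rank = rank
        regions[i].is_super = regions[i].signal > cutoff_value
    # emit regions in rank order (strongest first)
    ranked = [regions[i] for i in order]
    return SampleSECalls(
        sample_id=sample_id,
        regions=ranked,
        cutoff_index=x_star,
        cutoff_value=cutoff_value,
    )
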