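"""Piecewise-constant per-base signal over a genome (bedGraph semantics).

A :class:`SignalTrack` holds, per chromosome, sorted non-overlapping
``[start, end)`` segments each with a constant per-base density.  Bases not
covered by any segment have density 0.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

__all__ = ["SignalTrack"]


class SignalTrack:
    """Sparse piecewise-constant signal density, one value per segment.

    Construct from an iterable of ``(chrom, start, end, density)`` tuples via
    :meth:`from_segments`.  Segments on a chromosome must not overlap;
    construction validates and sorts them.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # data: chrom -> (starts, ends, values), already sorted & disjoint
        self._data = data

    @classmethod
    def from_segments(cls, segments: Iterable[tuple[str, int, int, float]]) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            if start < 0 or start >= end:
                raise ValueError(f"invalid segment {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        data = {}
        for chrom, segs in by_chrom.items():
            segs.sort()
            starts = np.array([s[0] for s in segs], dtype=np.int64)
            ends = np.array([s[1] for s in segs], dtype=np.int64)
            values = np.array([s[2] for s in segs], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            data[chrom] = (starts, ends, values)
        return cls(data)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def segments(self) -> Iterator[tuple[str, int, int, float]]:
        """Yield (chrom, start, end, density) in sorted order."""
        for chrom in self.chroms:
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def density_at(self, chrom: str, pos: int) -> float:
        """Density at a single base; 0 outside all segments."""
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def integrate(self, chrom: str, start: int, end: int) -> float:
        """Sum of density x overlap length over ``[start, end)``."""
        if end <= start or chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(values[lo:hi] * ov))

    def total_area(self) -> float:
        """Sum of density x length over all segments."""
        return float(
            sum(np.sum(v * (e - s)) for s, e, v in self._data.values())
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        return list(self.segments()) == list(other.segments())
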