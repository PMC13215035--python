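import numpy as np
import pytest

from sescreen import GeneAnnotation, GenomicInterval, SignalTrack


@pytest.fixture
def flat_track():
    """Density 2.0 over chr1:[0, 100)."""
    return SignalTrack.from_segments([("chr1", 0, 100, 2.0)])


@pytest.fixture
def plus_gene():
    return GeneAnnotation(
        "GENEA", GenomicInterval("chr1", 1000, 9000, name="GENEA", strand="+"), "+"
    )


def brute_force_cutoff(signals):
    """O(n^2) pure-Python reference for the tangent-line cutoff.

    Independent of the vectorized implementation: explicit loops, Python
    floats.  Returns (1-based index, cutoff value).
    """
    v = sorted(max(0.0, float(x)) for x in signals)
    n = len(v)
    assert n >= 2
    s = (v[-1] - v[0]) / n
    best_x, best_f = None, None
    for x in range(1, n + 1):
        f = sum(1 for i in range(1, n + 1) if v[i - 1] <= v[x - 1] + s * (i - x))
        if best_f is None or f < best_f:
            best_f, best_x = f, x
    return best_x, v[best_x - 1]


def brute_force_cutoff_semivec(signals):
    """O(n^2) brute force with a per-candidate numpy inner loop.

    Same minimization as :func:`brute_force_cutoff` but fast enough for
    n up to a few thousand; still a candidate-by-candidate search, not the
    broadcast matrix the implementation uses.
    """
    v = np.sort(np.clip(np.asarray(signals, dtype=float), 0.0, None))
    n = v.size
    s = (v[-1] - v[0]) / n
    i = np.arange(1, n + 1, dtype=float)
    best_x, best_f = None, None
    for x in range(1, n + 1):
        f = int(np.count_nonzero(v <= v[x - 1] + s * (i - x)))
        if best_f is None or f < best_f:
            best_f, best_x = f, x
    return best_x, float(v[best_x - 1])


def random_signal_vector(rng, n):
    """A mixed-law signal vector: heavy-tailed, duplicated, zero-inflated."""
    law = rng.integers(6)
    if law == 0:
        v = rng.uniform(0, 1000, n)
    elif law == 1:
        v = rng.gamma(1.5, 100.0, n)
    elif law == 2:
        v = rng.lognormal(3.0, 1.5, n)
    elif law == 3:
        v = rng.integers(0, 10, n).astype(float)  # heavy duplication
    elif law == 4:
        v = np.full(n, float(rng.integers(0, 100)))  # constant
    else:
        v = rng.gamma(1.5, 100.0, n)
        v[rng.random(n) < 0.3] = 0.0  # zero-inflated
    if rng.random() < 0.2:
        v = v - np.median(v)  # include negatives (clamped by the cutoff)
    return v
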