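"""The candidate-histogram ensemble, its Hamiltonian, and a brute-force oracle.

The set of candidate gapped histograms on ``n`` sorted points is a two-layer
Ising ensemble: one spin per spacing (same bin / new bin) plus one hidden
spin (gap / no gap) per down-spin, ``3^(n-1)`` configurations in total.  The
energy of a configuration with bins ``{[a_j, b_j]}`` is

    H = sum_j DESS(bin_j) + L0 * (B - 1),

the total decoding error plus ``L0`` per interior boundary.  Gap spins carry
no energy; gaps are decided after the fact by the gap tests.  The exhaustive
minimiser here exists purely as a correctness oracle for the tree-guided
search at small ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .core import SortedSample, dess

__all__ = [
    "EnergyDecomposition",
    "ensemble_size",
    "ensemble_size_binomial_sum",
    "hamiltonian",
    "brute_force_min",
]


@dataclass(frozen=True)
class EnergyDecomposition:
    total_dess: float
    boundary_count: int  # number of bins B
    L0: float

    @property
    def hamiltonian(self) -> float:
        return self.total_dess + self.L0 * (self.boundary_count - 1)


def ensemble_size(n: int) -> int:
    """Number of two-layer spin configurations on n points: 3^(n-1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 3 ** (n - 1)


def ensemble_size_binomial_sum(n: int) -> int:
    """The same count via sum_k C(n-1, k) 2^k (k = number of boundaries)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sum(comb(n - 1, k) * 2**k for k in range(n))


def _as_sorted_values(sample) -> np.ndarray:
    if isinstance(sample, SortedSample):
        return sample.values
    return SortedSample.from_values(sample).values


def _segments_from_partition(n: int, partition) -> list[tuple[int, int]]:
    """Validate a partition into contiguous runs of sorted indices.

    ``partition`` is a sequence of (lo, hi) half-open index pairs, or a
    sequence of index arrays.  Returns the (lo, hi) list in order.
    """
    segs = []
    for part in partition:
        part = np.asarray(part)
        if part.ndim == 0:
            raise ValueError("each cell must be a pair or index array")
        if part.size == 2 and part.dtype.kind in "iu" and np.all(np.diff(part) >= 1):
            # ambiguous: treat len-2 arrays as explicit index lists
            pass
        idx = np.sort(part.astype(int))
        if np.any(np.diff(idx) != 1):
            raise ValueError("partition cell is not contiguous")
        segs.append((int(idx[0]), int(idx[-1]) + 1))
    segs.sort()
    pos = 0
    for lo, hi in segs:
        if lo != pos:
            raise ValueError("partition does not cover the sample contiguously")
        pos = hi
    if pos != n:
        raise ValueError("partition does not cover the sample")
    return segs


def hamiltonian(sample, partition, L0: float) -> EnergyDecomposition:
    """Energy of a contiguous partition: total DESS + L0 per interior boundary.

    ``partition`` lists the bins as index arrays (or (lo, hi) runs produced
    by :func:`brute_force_min`) into the *sorted* sample.  Each bin's DESS
    uses its empirical min/max as boundaries.
    """
    x = _as_sorted_values(sample)
    if partition and all(
        isinstance(p, tuple) and len(p) == 2 and isinstance(p[0], int) for p in partition
    ):
        segs = sorted(partition)
        pos = 0
        for lo, hi in segs:
            if lo != pos or hi <= lo:
                raise ValueError("partition does not cover the sample contiguously")
            pos = hi
        if pos != x.size:
            raise ValueError("partition does not cover the sample")
    else:
        segs = _segments_from_partition(x.size, partition)
    total = 0.0
    for lo, hi in segs:
        seg = x[lo:hi]
        total += dess(seg, seg[0], seg[-1])
    return EnergyDecomposition(total_dess=total, boundary_count=len(segs), L0=L0)


def brute_force_min(sample, L0: float, max_n: int = 20):
    """Exhaustive minimum-energy contiguous partition (oracle, n <= 20).

    Enumerates all ``2^(n-1)`` layer-1 spin states.  Ties are broken toward
    fewer bins, then toward the lexicographically earliest boundary set.

    Returns ``(partition, EnergyDecomposition)`` where ``partition`` is a
    list of (lo, hi) half-open index runs into the sorted sample.
    """
    x = _as_sorted_values(sample)
    n = x.size
    if n > max_n:
        raise ValueError(
            f"brute-force enumeration refused for n={n} > {max_n} "
            f"(2^(n-1) contiguous partitions)"
        )
    # precompute DESS of every contiguous segment
    seg_dess = np.zeros((n, n + 1))
    for lo in range(n):
        for hi in range(lo + 1, n + 1):
            seg = x[lo:hi]
            seg_dess[lo, hi] = dess(seg, seg[0], seg[-1])

    best = None  # (H, B, cuts, segs)
    for mask in range(1 << max(n - 1, 0)):
        cuts = tuple(i + 1 for i in range(n - 1) if mask >> i & 1)
        bounds = (0,) + cuts + (n,)
        total = sum(seg_dess[bounds[j], bounds[j + 1]] for j in range(len(bounds) - 1))
        B = len(bounds) - 1
        H = total + L0 * (B - 1)
        key = (H, B, cuts)
        if best is None or key < best[0]:
            segs = [(bounds[j], bounds[j + 1]) for j in range(B)]
            best = (key, EnergyDecomposition(total_dess=total, boundary_count=B, L0=L0), segs)
    return best[2], best[1]
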