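"""Order statistics of the uniform distribution and the decoding-error criterion.

A histogram bin is modelled as a uniform part ``U_p[a, b]``: conditional on
falling in the bin, observations are uniform on ``[a, b]``.  Decoding a bin
means replacing its ``m`` sorted members by the expected order statistics
``a + (b - a) k/(m + 1)``.  The decoding error sum of squares (DESS) is the
expected squared reconstruction error

    DESS = m (b - a)^2 / (6 (m + 1)) + sum_k [x_(k) - (a + (b - a) k/(m+1))]^2,

whose mean under true uniformity is ``(b - a)^2 m / (3 (m + 1))`` — close to
``(b - a)^2 / 3`` for any moderately large ``m`` and independent of sample
size.  That scale-free constant is what makes DESS usable as a uniformity
criterion: a bin whose DESS is much larger than ``(b - a)^2 / 3`` is not a
single uniform part and should be subdivided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SortedSample",
    "UniformPartMoments",
    "order_stat_moments",
    "dess",
    "dess_expectation",
    "uniformity_check",
    "UniformityResult",
]


@dataclass(frozen=True)
class SortedSample:
    """A one-dimensional sample kept in ascending order.

    Parameters
    ----------
    values : ndarray
        Sorted (non-decreasing) observations.
    labels : ndarray or None
        Optional treatment label per observation, aligned with ``values``.
    """

    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("sample must be a non-empty 1-D array")
        if np.any(np.isnan(values)):
            raise ValueError("sample contains NaN")
        if np.any(np.diff(values) < 0):
            raise ValueError("values must be sorted ascending")
        object.__setattr__(self, "values", values)
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != values.shape:
                raise ValueError("labels must align 1:1 with values")
            object.__setattr__(self, "labels", labels)

    @classmethod
    def from_values(cls, values, labels=None) -> "SortedSample":
        """Sort ``values`` (stably), carrying ``labels`` along."""
        values = np.asarray(values, dtype=float)
        order = np.argsort(values, kind="stable")
        return cls(
            values[order],
            None if labels is None else np.asarray(labels)[order],
        )

    @property
    def n(self) -> int:
        return self.values.size

    def standardized(self) -> "SortedSample":
        """Zero mean, unit standard deviation (n-1 divisor)."""
        v = self.values
        s = v.std(ddof=1)
        if s == 0:
            raise ValueError("cannot standardize a constant sample")
        return SortedSample((v - v.mean()) / s, self.labels)


@dataclass(frozen=True)
class UniformPartMoments:
    """Mean and variance of the k-th order statistic of m i.i.d. U(0,1)."""

    k: int
    m: int
    mean: float
    variance: float


def order_stat_moments(k: int, m: int) -> UniformPartMoments:
    """Moments of the k-th of m uniform order statistics.

    ``E[X_(k)] = k/(m+1)`` and
    ``Var[X_(k)] = k (m - k + 1) / ((m+1)^2 (m+2))``.
    """
    if not (1 <= k <= m):
        raise ValueError(f"rank k={k} out of range for sample size m={m}")
    mean = k / (m + 1)
    variance = k * (m - k + 1) / ((m + 1) ** 2 * (m + 2))
    return UniformPartMoments(k=k, m=m, mean=mean, variance=variance)


def dess(values, a: float, b: float) -> float:
    """Decoding error sum of squares of a bin on boundaries ``[a, b]``.

    ``values`` must be sorted and lie inside ``[a, b]``.  Degenerate bins
    (``a == b``, only possible when all members tie) have DESS 0 by
    definition: they cannot be subdivided.
    """
    x = np.asarray(values, dtype=float)
    m = x.size
    if m < 1:
        raise ValueError("empty bin")
    if a == b:
        if x[0] != a or x[-1] != a:
            raise ValueError("zero-width boundaries require all-tied data")
        return 0.0
    if a > b:
        raise ValueError("left boundary exceeds right boundary")
    if x[0] < a or x[-1] > b:
        raise ValueError("data outside [a, b]")
    k = np.arange(1, m + 1)
    decoded = a + (b - a) * k / (m + 1)
    return m * (b - a) ** 2 / (6 * (m + 1)) + float(np.sum((x - decoded) ** 2))


def dess_expectation(m: int, a: float, b: float) -> float:
    """Exact mean of DESS for m i.i.d. U(a, b): ``(b-a)^2 m / (3 (m+1))``."""
    return (b - a) ** 2 * m / (3 * (m + 1))


@dataclass(frozen=True)
class UniformityResult:
    satisfied: bool
    dess: float
    expected: float
    tolerance: float


def uniformity_check(values, a: float, b: float, tau: float = 0.25) -> UniformityResult:
    """One-sided DESS uniformity criterion.

    The bin is accepted as one uniform part iff
    ``DESS <= (1 + tau) * expected`` where ``expected`` is the exact
    finite-m mean ``(b-a)^2 m/(3(m+1))``.  The check is one-sided because a
    too-small DESS never motivates a split; ``tau`` is a multiplicative
    slack on the "about (b-a)^2/3" reference.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = np.asarray(values, dtype=float)
    d = dess(x, a, b)
    expected = dess_expectation(x.size, a, b)
    return UniformityResult(
        satisfied=bool(d <= (1 + tau) * expected),
        dess=d,
        expected=expected,
        tolerance=tau,
    )
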