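"""Possibly gapped histograms from a hierarchical-clustering tree.

The tree-guided search replaces the exhaustive minimum-energy hunt over the
``3^(n-1)`` candidate ensemble: an agglomerative tree (complete, average or
ward linkage — single linkage is excluded because it lacks the subdividing
tendency) on the sorted 1-D sample is walked from the root downward in
decreasing merge height.  A node is STOP-marked — its data segment becomes a
bin — as soon as its DESS falls below the boundary-cost index ``L0`` or the
segment passes the DESS uniformity criterion; otherwise its two children
become active.  The STOP-marked segments partition the sample into ordered
uniform parts.  Each adjacent pair is then tested for an existential gap,
either by non-crossing of the theoretically extended boundaries

    a_hat = x_(1) - (x_(m) - x_(1))/(m + 1),   b_hat = x_(m) + (x_(m) - x_(1))/(m + 1)

(the expected overshoot of uniform extremes), or by re-checking uniformity
after forcing both bins to share the mid-point of the facing extremes.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage

from .core import SortedSample, dess, dess_expectation, uniformity_check

__all__ = [
    "TreeNode",
    "HistogramBin",
    "GappedHistogram",
    "hc_tree_1d",
    "extended_boundaries",
    "build",
    "gap_check",
    "refine",
]

_ALLOWED_LINKAGE = ("complete", "average", "ward")


@dataclass
class TreeNode:
    """A node of the 1-D agglomerative tree over a contiguous index run."""

    lo: int  # inclusive start in the sorted sample
    hi: int  # exclusive end
    height: float
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def size(self) -> int:
        return self.hi - self.lo


def hc_tree_1d(sample, linkage: str = "complete") -> TreeNode:
    """Agglomerative tree on a sorted 1-D sample under |x - y| dissimilarity.

    Every inter-node's leaf set is verified to be a contiguous run of the
    sorted sample (guaranteed for the admissible linkages in one dimension).
    Single linkage is rejected: it chains through any spacing and never
    isolates uniform parts.
    """
    if linkage == "single":
        raise ValueError(
            "single linkage is excluded: it lacks the subdividing tendency "
            "needed to isolate uniform parts"
        )
    if linkage not in _ALLOWED_LINKAGE:
        raise ValueError(f"linkage must be one of {_ALLOWED_LINKAGE}")
    x = sample.values if isinstance(sample, SortedSample) else np.asarray(sample, float)
    if np.any(np.diff(x) < 0):
        raise ValueError("sample must be sorted")
    n = x.size
    if n < 2:
        raise ValueError("need n >= 2 to build a tree")
    Z = _scipy_linkage(x[:, None], method=linkage)
    nodes: dict[int, TreeNode] = {
        i: TreeNode(lo=i, hi=i + 1, height=0.0) for i in range(n)
    }
    for row, (ia, ib, h, _) in enumerate(Z):
        a, b = nodes.pop(int(ia)), nodes.pop(int(ib))
        if a.lo > b.lo:
            a, b = b, a
        if a.hi != b.lo:
            raise AssertionError(
                "non-contiguous merge in 1-D tree; linkage violates ordering"
            )
        nodes[n + row] = TreeNode(lo=a.lo, hi=b.hi, height=float(h), left=a, right=b)
    (root,) = nodes.values()
    return root


def extended_boundaries(members) -> tuple[float, float]:
    """Extended bin boundaries from the extreme order-statistic overshoot.

    For m >= 2: ``(x_(1) - r/(m+1), x_(m) + r/(m+1))`` with ``r`` the
    empirical range.  Singletons extend to themselves.
    """
    x = np.asarray(members, dtype=float)
    m = x.size
    if m < 2:
        return float(x[0]), float(x[0])
    ext = (x[-1] - x[0]) / (m + 1)
    return float(x[0] - ext), float(x[-1] + ext)


@dataclass
class HistogramBin:
    """One uniform part: members, empirical and extended boundaries, DESS."""

    lo: int
    hi: int
    members: np.ndarray
    dess: float
    node: TreeNode | None = None

    @property
    def m(self) -> int:
        return self.members.size

    @property
    def a(self) -> float:
        return float(self.members[0])

    @property
    def b(self) -> float:
        return float(self.members[-1])

    @property
    def a_hat(self) -> float:
        return extended_boundaries(self.members)[0]

    @property
    def b_hat(self) -> float:
        return extended_boundaries(self.members)[1]

    @property
    def dess_threshold(self) -> float:
        """The uniformity reference (b-a)^2 m / (3(m+1)) on this bin."""
        return dess_expectation(self.m, self.a, self.b)


@dataclass
class GappedHistogram:
    bins: list[HistogramBin]
    gap_flags: list[bool]
    L0: float
    linkage: str
    tau: float
    gap_method: str
    sample: SortedSample
    tree: TreeNode | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def total_dess(self) -> float:
        return float(sum(b.dess for b in self.bins))

    @property
    def hamiltonian(self) -> float:
        return self.total_dess + self.L0 * (self.n_bins - 1)

    def bin_labels(self, k: int) -> np.ndarray:
        """Treatment labels of the members of bin k (requires labels)."""
        if self.sample.labels is None:
            raise ValueError("sample carries no labels")
        b = self.bins[k]
        return self.sample.labels[b.lo : b.hi]

    def _check_partition(self) -> None:
        pos = 0
        for b in self.bins:
            if b.lo != pos:
                raise AssertionError("bins are not a contiguous partition")
            pos = b.hi
        if pos != self.sample.n:
            raise AssertionError("bins do not cover the sample")


def _resolve_l0(l0, l0_frac, root_height: float) -> float:
    if l0 is not None and l0_frac is not None:
        raise ValueError("give either an absolute L0 or a fraction, not both")
    if l0 is not None:
        return float(l0)
    frac = 0.1 if l0_frac is None else float(l0_frac)
    return frac * root_height


def _make_bin(x: np.ndarray, lo: int, hi: int, node: TreeNode | None) -> HistogramBin:
    seg = x[lo:hi]
    return HistogramBin(lo=lo, hi=hi, members=seg, dess=dess(seg, seg[0], seg[-1]), node=node)


def gap_check(left_bin: HistogramBin, right_bin: HistogramBin,
              method: str = "extension", tau: float = 0.25) -> bool:
    """True iff the space between two consecutive bins is an existential gap.

    "extension": gap iff the extended boundaries do not cross,
    ``b_hat(left) < a_hat(right)``.  "midpoint": substitute the shared
    mid-point of the facing extremes for each bin's facing boundary and
    re-check uniformity; no gap iff both bins still pass.
    """
    if left_bin.b >= right_bin.a:
        raise ValueError("bins overlap; gap test requires left.b < right.a")
    if method == "extension":
        return left_bin.b_hat < right_bin.a_hat
    if method == "midpoint":
        c = (left_bin.b + right_bin.a) / 2
        left_ok = uniformity_check(left_bin.members, left_bin.a, c, tau).satisfied
        right_ok = uniformity_check(right_bin.members, c, right_bin.b, tau).satisfied
        return not (left_ok and right_ok)
    raise ValueError("gap method must be 'extension' or 'midpoint'")


def build(sample, l0: float | None = None, l0_frac: float | None = None,
          linkage: str = "complete", tau: float = 0.25,
          gap_method: str = "extension", standardize: bool = False) -> GappedHistogram:
    """Tree-guided search for a possibly gapped histogram.

    Active inter-nodes are visited in strictly decreasing merge height (ties
    broken by leftmost segment).  A node whose segment has DESS below ``L0``
    or passes the uniformity criterion is STOP-marked and becomes a bin;
    otherwise its children become active.  ``L0`` defaults to
    ``0.1 x (root merge height)``; pass ``l0`` for an absolute value.
    """
    if not isinstance(sample, SortedSample):
        sample = SortedSample.from_values(sample)
    if standardize:
        sample = sample.standardized()
    x = sample.values
    n = x.size

    if n == 1:
        bins = [_make_bin(x, 0, 1, None)]
        return GappedHistogram(bins=bins, gap_flags=[], L0=0.0 if l0 is None else float(l0),
                               linkage=linkage, tau=tau, gap_method=gap_method,
                               sample=sample, tree=None)

    tree = hc_tree_1d(sample, linkage=linkage)
    L0 = _resolve_l0(l0, l0_frac, tree.height)

    heap: list[tuple[float, int, TreeNode]] = []

    def push(node: TreeNode) -> None:
        heapq.heappush(heap, (-node.height, node.lo, node))

    push(tree)
    stopped: list[TreeNode] = []
    while heap:
        _, _, node = heapq.heappop(heap)
        seg = x[node.lo : node.hi]
        d = dess(seg, seg[0], seg[-1])
        if node.is_leaf or d < L0 or uniformity_check(seg, seg[0], seg[-1], tau).satisfied:
            stopped.append(node)
        else:
            push(node.left)
            push(node.right)

    stopped.sort(key=lambda nd: nd.lo)
    bins = [_make_bin(x, nd.lo, nd.hi, nd) for nd in stopped]
    hist = GappedHistogram(bins=bins, gap_flags=[], L0=L0, linkage=linkage, tau=tau,
                           gap_method=gap_method, sample=sample, tree=tree)
    hist._check_partition()
    hist.gap_flags = [
        gap_check(bins[k], bins[k + 1], method=gap_method, tau=tau)
        for k in range(len(bins) - 1)
    ]
    return hist


def refine(histogram: GappedHistogram, l0: float | None = None) -> GappedHistogram:
    """Bifurcate every bin with DESS > L0 along the stored tree branches.

    Descends recursively until each segment has DESS <= L0 or is a
    singleton.  Total DESS never increases; the bin count never decreases.
    """
    L0 = histogram.L0 if l0 is None else float(l0)
    x = histogram.sample.values

    def expand(node: TreeNode | None, lo: int, hi: int) -> list[tuple[int, int, TreeNode | None]]:
        seg = x[lo:hi]
        d = dess(seg, seg[0], seg[-1])
        if d <= L0 or node is None or node.is_leaf:
            return [(lo, hi, node)]
        return expand(node.left, node.left.lo, node.left.hi) + expand(
            node.right, node.right.lo, node.right.hi
        )

    pieces: list[tuple[int, int, TreeNode | None]] = []
    for b in histogram.bins:
        pieces.extend(expand(b.node, b.lo, b.hi))
    bins = [_make_bin(x, lo, hi, node) for lo, hi, node in pieces]
    out = GappedHistogram(bins=bins, gap_flags=[], L0=histogram.L0,
                          linkage=histogram.linkage, tau=histogram.tau,
                          gap_method=histogram.gap_method,
                          sample=histogram.sample, tree=histogram.tree)
    out._check_partition()
    out.gap_flags = [
        gap_check(bins[k], bins[k + 1], method=histogram.gap_method, tau=histogram.tau)
        for k in range(len(bins) - 1)
    ]
    return out
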