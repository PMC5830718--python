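"""Phase-1 ANOHT: entropy-coded bin composition across treatments.

Build one possibly gapped histogram on the pooled sample, colour each bin by
treatment membership, and measure how far each bin's colour composition is
from the pooled treatment proportions: a bin's Shannon entropy ``H_k``
(natural log) relative to the entropy ``H_0`` of the treatment sample sizes
is a local index of segregation — 0 when one treatment owns the bin, 1 when
the bin mirrors the pool.  Significance comes from simple random sampling
without replacement (per bin) or full label permutation (overall weighted
entropy), one-sided toward small entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histogram import GappedHistogram

__all__ = [
    "BinComposition",
    "entropy",
    "bin_entropy_index",
    "bin_pvalue",
    "overall_test",
    "phase1_report",
]


def entropy(counts) -> float:
    """Shannon entropy (nats) of a count vector, 0 log 0 = 0."""
    c = np.asarray(counts, dtype=float)
    tot = c.sum()
    if tot <= 0:
        raise ValueError("entropy of an empty count vector")
    q = c[c > 0] / tot
    return float(-(q * np.log(q)).sum())


def bin_entropy_index(counts, global_sizes) -> tuple[float, float]:
    """Bin entropy ``H_k`` and its ratio to the pooled-size entropy ``H_0``."""
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(global_sizes, dtype=float)
    if counts.sum() < 1:
        raise ValueError("bin is empty")
    if np.any(sizes < 1):
        raise ValueError("every treatment must have at least one observation")
    if sizes.size < 2:
        raise ValueError("entropy ratio undefined for a single treatment")
    h_k = entropy(counts)
    h_0 = entropy(sizes)
    if h_0 == 0:
        raise ValueError("pooled-size entropy is zero")
    return h_k, h_k / h_0


def _encode(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    return uniq, codes


def _entropy_rows(count_rows: np.ndarray) -> np.ndarray:
    """Row-wise entropy of an (M, J) count matrix."""
    tot = count_rows.sum(axis=1, keepdims=True)
    q = count_rows / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log(q), 0.0)
    return -terms.sum(axis=1)


@dataclass(frozen=True)
class BinComposition:
    counts: np.ndarray
    m: int
    entropy: float
    entropy_ratio: float
    p_value: float
    p_value_add_one: float


def bin_pvalue(bin_labels, pooled_labels, reps: int = 1000, seed: int = 0) -> tuple[float, float]:
    """One-sided permutation p-value for one bin's composition.

    Draws ``reps`` label subsets of the bin's size without replacement from
    the pooled label multiset; p is the proportion with entropy
    ``H* <= H_k`` (small entropy = segregation).  Returns the raw proportion
    (zeros allowed) and the add-one estimate ``(#{<=} + 1)/(reps + 1)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    pool_uniq, pool_codes = _encode(pooled_labels)
    bin_labels = np.asarray(bin_labels)
    m = bin_labels.size
    if m > pool_codes.size:
        raise ValueError("bin larger than the pooled sample")
    J = pool_uniq.size
    obs_counts = np.array([(bin_labels == u).sum() for u in pool_uniq])
    h_obs = entropy(obs_counts)

    keys = rng.random((reps, pool_codes.size))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    draws = pool_codes[idx]  # (reps, m)
    counts = np.stack([(draws == j).sum(axis=1) for j in range(J)], axis=1)
    h_star = _entropy_rows(counts)
    hits = int((h_star <= h_obs + 1e-12).sum())
    return hits / reps, (hits + 1) / (reps + 1)


def _bin_slices(histogram: GappedHistogram) -> list[tuple[int, int]]:
    return [(b.lo, b.hi) for b in histogram.bins]


def overall_test(histogram: GappedHistogram, labels=None, reps: int = 1000,
                 seed: int = 0) -> dict:
    """Permutation test of the bin-size-weighted entropy across all bins.

    Statistic ``sum_k (m_k/n) H_k``; p-value is the proportion of full label
    permutations with a statistic at most the observed one (one-sided, small
    entropy = treatments segregate across bins).
    """
    if labels is None:
        labels = histogram.sample.labels
    if labels is None:
        raise ValueError("no treatment labels available")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    uniq, codes = _encode(labels)
    n = codes.size
    J = uniq.size
    slices = _bin_slices(histogram)
    weights = np.array([hi - lo for lo, hi in slices]) / n

    def weighted_entropy(code_matrix: np.ndarray) -> np.ndarray:
        # code_matrix: (M, n) label codes; returns (M,) weighted entropies
        out = np.zeros(code_matrix.shape[0])
        for w, (lo, hi) in zip(weights, slices):
            seg = code_matrix[:, lo:hi]
            counts = np.stack([(seg == j).sum(axis=1) for j in range(J)], axis=1)
            out += w * _entropy_rows(counts)
        return out

    observed = float(weighted_entropy(codes[None, :])[0])
    keys = rng.random((reps, n))
    perms = codes[np.argsort(keys, axis=1)]
    stats = weighted_entropy(perms)
    hits = int((stats <= observed + 1e-12).sum())
    return {
        "weighted_entropy": observed,
        "p": hits / reps,
        "p_add_one": (hits + 1) / (reps + 1),
        "reps": reps,
    }


def phase1_report(histogram: GappedHistogram, reps: int = 1000, seed: int = 0) -> dict:
    """Per-bin compositions (counts, entropy, ratio, p) plus the overall test."""
    labels = histogram.sample.labels
    if labels is None:
        raise ValueError("phase 1 requires a labelled sample")
    rng = np.random.default_rng(seed)
    uniq, _ = _encode(labels)
    sizes = np.array([(labels == u).sum() for u in uniq])
    rows = []
    for k, b in enumerate(histogram.bins):
        lab = labels[b.lo : b.hi]
        counts = np.array([(lab == u).sum() for u in uniq])
        h_k, ratio = bin_entropy_index(counts, sizes)
        p, p1 = bin_pvalue(lab, labels, reps=reps, seed=rng)
        rows.append(
            BinComposition(counts=counts, m=b.m, entropy=h_k,
                           entropy_ratio=ratio, p_value=p, p_value_add_one=p1)
        )
    overall = overall_test(histogram, labels, reps=reps, seed=rng)
    return {"treatments": list(uniq), "bins": rows, "overall": overall}
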