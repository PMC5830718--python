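"""Phase-2 ANOHT: treatment tree and branch authenticity by mimicking.

The pooled histogram's bins turn the J treatments into rows of a J x K count
matrix T; row frequencies P_jk = T_jk / n_j are empirical bin probabilities.
A reference tree is built on the rows (Euclidean distance, complete linkage
by default) and each of its J-1 inter-nodes gets a rank-digit, the ascending
rank of its merge height.  Authenticity of a branch asks whether its member
set re-forms in trees built on mimicked rows, where each row is perturbed by
the exact Gaussian limit of its bin-frequency increments: the Brownian-bridge
increment covariance

    Sigma* = diag(p) - p p^T,

scaled by 1/n_j.  Draws from N(0, Sigma*) use the constructive identity
W = G - p (sum_k G_k) with independent G_k ~ N(0, p_k), so every mimicked row
sums to one exactly and no factorisation of the singular matrix is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist

from .core import SortedSample
from .histogram import GappedHistogram

__all__ = [
    "TreatmentBinTable",
    "IncrementCovariance",
    "Branch",
    "AuthenticityTree",
    "treatment_bin_table",
    "sigma_star",
    "mimic_row",
    "rank_digits",
    "authenticity",
    "authenticity_from_rows",
]


@dataclass(frozen=True)
class TreatmentBinTable:
    """J x K counts T, row totals n_j and row frequencies P."""

    labels: list
    T: np.ndarray
    boundaries: np.ndarray | None = None

    def __post_init__(self):
        T = np.asarray(self.T, dtype=float)
        if T.ndim != 2:
            raise ValueError("T must be a J x K matrix")
        if np.any(T < 0) or np.any(T != np.round(T)):
            raise ValueError("T must hold non-negative integer counts")
        if np.any(T.sum(axis=1) == 0):
            raise ValueError("every treatment needs at least one observation")
        object.__setattr__(self, "T", T)

    @property
    def n_j(self) -> np.ndarray:
        return self.T.sum(axis=1)

    @property
    def P(self) -> np.ndarray:
        return self.T / self.n_j[:, None]


def treatment_bin_table(sample: SortedSample, histogram: GappedHistogram) -> TreatmentBinTable:
    """Tabulate treatment x bin counts from a labelled histogram."""
    labels = sample.labels if sample.labels is not None else histogram.sample.labels
    if labels is None:
        raise ValueError("sample carries no treatment labels")
    values = histogram.sample.values
    uniq = list(np.unique(np.asarray(labels)))
    K = histogram.n_bins
    T = np.zeros((len(uniq), K))
    for k, b in enumerate(histogram.bins):
        lab = labels[b.lo : b.hi]
        for j, u in enumerate(uniq):
            T[j, k] = (lab == u).sum()
    boundaries = np.array([histogram.bins[0].a] + [b.b for b in histogram.bins])
    covered = int(T.sum())
    if covered != values.size:
        raise ValueError(f"{values.size - covered} values fall outside all bins")
    return TreatmentBinTable(labels=uniq, T=T, boundaries=boundaries)


@dataclass(frozen=True)
class IncrementCovariance:
    """Covariance diag(p) - p p^T of bin-probability increments."""

    p: np.ndarray
    matrix: np.ndarray


def sigma_star(p) -> IncrementCovariance:
    """Brownian-bridge increment covariance ``diag(p) - p p^T``."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must be a probability vector")
    return IncrementCovariance(p=p, matrix=np.diag(p) - np.outer(p, p))


def mimic_row(p, n_j: float, seed=0, size: int | None = None) -> np.ndarray:
    """Mimicked frequency row(s) ``p + W / sqrt(n_j)``, W ~ N(0, Sigma*).

    Uses W = G - p (sum G) with independent G_k ~ N(0, p_k): the law is
    exactly N(0, diag(p) - p p^T), every draw sums to one exactly, and a
    zero cell stays exactly zero.  Components may go negative; they are kept
    (Euclidean distances remain well defined and the Gaussian law exact).
    """
    p = np.asarray(p, dtype=float)
    if n_j < 1:
        raise ValueError("n_j must be >= 1")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    m = 1 if size is None else size
    G = rng.standard_normal((m, p.size)) * np.sqrt(p)
    W = G - np.outer(G.sum(axis=1), p)
    rows = p + W / np.sqrt(n_j)
    return rows[0] if size is None else rows


def _merge_sets(Z: np.ndarray, J: int) -> list[frozenset]:
    """Leaf set of each internal node, in merge order."""
    sets: dict[int, frozenset] = {i: frozenset([i]) for i in range(J)}
    out = []
    for row, (ia, ib, _, _) in enumerate(Z):
        s = sets[int(ia)] | sets[int(ib)]
        sets[J + row] = s
        out.append(s)
    return out


def rank_digits(Z: np.ndarray) -> np.ndarray:
    """Ascending-height ranks (1..J-1) of the merges of a linkage matrix.

    Ties are broken by merge order; since agglomerative heights are
    non-decreasing in merge order, the digit of merge i is i + 1.
    """
    heights = np.asarray(Z)[:, 2]
    order = np.argsort(heights, kind="stable")
    ranks = np.empty(heights.size, dtype=int)
    ranks[order] = np.arange(1, heights.size + 1)
    return ranks


@dataclass(frozen=True)
class Branch:
    leaves: frozenset
    height: float
    rank_digit: int
    authenticity: float
    clade_recovery: float


@dataclass(frozen=True)
class AuthenticityTree:
    labels: list
    linkage_matrix: np.ndarray
    branches: list[Branch]
    mimics: int

    def branch_by_leaves(self, names) -> Branch:
        idx = frozenset(self.labels.index(n) for n in names)
        for br in self.branches:
            if br.leaves == idx:
                return br
        raise KeyError(f"no branch with leaves {set(names)}")

    def to_newick(self) -> str:
        """Newick string with authenticity indices as internal-node labels."""
        J = len(self.labels)
        Z = self.linkage_matrix
        auth = {br.leaves: br.authenticity for br in self.branches}
        sets = _merge_sets(Z, J)

        def render(i: int) -> str:
            if i < J:
                return str(self.labels[i]).replace(" ", "_")
            row = i - J
            ia, ib, h, _ = Z[row]
            inner = f"({render(int(ia))},{render(int(ib))})"
            return f"{inner}{auth[sets[row]]:.4f}"

        return render(J + Z.shape[0] - 1) + ";"


def _linkage_rows(rows: np.ndarray, method: str) -> np.ndarray:
    d = pdist(rows, metric="euclidean")
    return _scipy_linkage(d, method=method)


def authenticity_from_rows(rows: np.ndarray, mimic_draws, labels=None,
                           linkage: str = "complete", mimics: int = 10000) -> AuthenticityTree:
    """Shared authenticity engine over arbitrary row vectors.

    ``mimic_draws(i)`` must return the i-th mimicked (J, K) row matrix.  For
    each reference branch with leaf set S and rank digit r the index is the
    proportion of mimicked trees in which the smallest branch containing S
    has rank digit <= r; the plain clade-recovery proportion (S re-appears
    exactly) is reported alongside.
    """
    rows = np.asarray(rows, dtype=float)
    J = rows.shape[0]
    if J < 2:
        raise ValueError("need at least two treatments")
    if labels is None:
        labels = list(range(J))
    Z = _linkage_rows(rows, linkage)
    if np.allclose(Z[:, 2], 0):
        warnings.warn("degenerate table: identical rows, tree heights are zero")
    digits = rank_digits(Z)
    ref_sets = _merge_sets(Z, J)

    together = np.zeros(J - 1)
    exact = np.zeros(J - 1)
    for i in range(mimics):
        Zm = _linkage_rows(mimic_draws(i), linkage)
        mim_sets = _merge_sets(Zm, J)
        mim_digits = rank_digits(Zm)
        for b, S in enumerate(ref_sets):
            contain = min(
                (mim_digits[t] for t, ms in enumerate(mim_sets) if S <= ms),
            )
            if contain <= digits[b]:
                together[b] += 1
            if S in mim_sets:
                exact[b] += 1

    branches = [
        Branch(leaves=ref_sets[b], height=float(Z[b, 2]), rank_digit=int(digits[b]),
               authenticity=together[b] / mimics, clade_recovery=exact[b] / mimics)
        for b in range(J - 1)
    ]
    return AuthenticityTree(labels=list(labels), linkage_matrix=Z,
                            branches=branches, mimics=mimics)


def authenticity(table: TreatmentBinTable, linkage: str = "complete",
                 mimics: int = 10000, seed: int = 0) -> AuthenticityTree:
    """Authenticity tree of a treatment x bin table (Algorithm of phase 2).

    The reference tree is built on the row frequencies P; each mimic
    perturbs row j by N(0, Sigma*_j / n_j).  Mimicked count matrices
    M = n_j P-hat renormalise back to P-hat row-wise, so distances are
    computed on the frequency scale for reference and mimics alike.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    P = table.P
    n_j = table.n_j
    J = P.shape[0]
    all_draws = np.stack(
        [mimic_row(P[j], n_j[j], seed=rng, size=mimics) for j in range(J)],
        axis=1,
    )  # (mimics, J, K)
    return authenticity_from_rows(
        P, lambda i: all_draws[i], labels=table.labels, linkage=linkage, mimics=mimics
    )
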