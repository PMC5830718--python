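"""Right-censored extension: KM/NA estimators and censored-data ANOHT.

With right censoring, observed pairs are ``(X_i, delta_i)`` where
``X_i = T_i ^ C_i`` and ``delta_i = 1{T_i <= C_i}``.  The Kaplan-Meier
product-limit estimate jumps only at uncensored times; its jump masses are
the redistribution-to-the-right weights, so a censored-data histogram is
built on event times only and re-weighted by those masses.  Phase-2
mimicking rests on the Gaussian limits of the KM and Nelson-Aalen processes,
whose covariances plug in the variance integral

    int dF_u / (1 - H)^2  ~  n * sum delta_(i) / ((n - i)(n - i + 1))

over ordered observations: Sigma# (KM, Brownian-bridge-like, increments
correlated through the survival prefactors) and Sigma** (NA, Brownian-motion
-like, independent increments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SortedSample
from .histogram import GappedHistogram, build
from .phase2 import AuthenticityTree, authenticity_from_rows

__all__ = [
    "CensoredSample",
    "SurvivalCurve",
    "kaplan_meier",
    "nelson_aalen",
    "variance_integral",
    "sigma_k_plugin",
    "sigma_hash",
    "sigma_doublestar",
    "censored_histogram",
    "censored_authenticity",
]


@dataclass(frozen=True)
class CensoredSample:
    """Ordered right-censored pairs; at ties, events precede censorings."""

    times: np.ndarray
    status: np.ndarray
    label: str | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.status, dtype=int)
        if t.ndim != 1 or t.size < 1 or t.shape != s.shape:
            raise ValueError("times and status must be matching 1-D arrays")
        if np.any(t < 0):
            raise ValueError("negative times")
        if not set(np.unique(s)) <= {0, 1}:
            raise ValueError("status must be 0 (censored) or 1 (event)")
        order = np.lexsort((-s, t))  # time ascending, events before censorings
        object.__setattr__(self, "times", t[order])
        object.__setattr__(self, "status", s[order])

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def event_times(self) -> np.ndarray:
        return self.times[self.status == 1]


@dataclass(frozen=True)
class SurvivalCurve:
    """Step function (KM survival or NA cumulative hazard) with KM weights.

    ``values[i]`` is the estimate just after ``times[i]``; ``weights`` are
    the per-observation jump masses (zero at censorings for KM), and
    ``residual_mass`` the mass left beyond the last observation.
    """

    times: np.ndarray
    values: np.ndarray
    weights: np.ndarray
    kind: str  # "survival" or "hazard"

    @property
    def residual_mass(self) -> float:
        return float(self.values[-1]) if self.kind == "survival" else float("nan")

    def evaluate(self, t) -> np.ndarray:
        """Right-continuous step evaluation; baseline before the first time."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        base = 1.0 if self.kind == "survival" else 0.0
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], base)
        return out if out.ndim else float(out)


def kaplan_meier(sample: CensoredSample) -> SurvivalCurve:
    """Product-limit survival estimate with redistribution weights.

    ``S(t) = prod_{X_(i) <= t} (1 - delta_(i)/(n - i + 1))``; the jump at an
    event is ``S(X_(i)-) * delta_(i)/(n - i + 1)``, the mass the censored
    observations to its left redistribute onto it.
    """
    n = sample.n
    i = np.arange(1, n + 1)
    factors = 1.0 - sample.status / (n - i + 1)
    values = np.cumprod(factors)
    prev = np.concatenate([[1.0], values[:-1]])
    weights = prev * sample.status / (n - i + 1)
    return SurvivalCurve(times=sample.times, values=values, weights=weights, kind="survival")


def nelson_aalen(sample: CensoredSample) -> SurvivalCurve:
    """Cumulative-hazard estimate ``Lambda(t) = sum_{X_(i) <= t} delta_(i)/(n-i+1)``."""
    n = sample.n
    i = np.arange(1, n + 1)
    increments = sample.status / (n - i + 1)
    km_w = kaplan_meier(sample).weights
    return SurvivalCurve(times=sample.times, values=np.cumsum(increments),
                         weights=km_w, kind="hazard")


def variance_integral(sample: CensoredSample, t_lo: float, t_hi: float) -> float:
    """Plug-in ``int_(t_lo, t_hi] dF_u / (1 - H)^2``.

    ``n * sum delta_(i) / ((n - i)(n - i + 1))`` over ordered observations in
    ``(t_lo, t_hi]``; the ``i = n`` term (``n - i = 0``) is dropped, the
    standard Greenwood-type guard.
    """
    if t_lo >= t_hi:
        raise ValueError("t_lo must be < t_hi")
    n = sample.n
    i = np.arange(1, n + 1)
    in_window = (sample.times > t_lo) & (sample.times <= t_hi) & (i < n)
    terms = sample.status[in_window] / ((n - i[in_window]) * (n - i[in_window] + 1))
    return float(n * terms.sum())


def _check_boundaries(sample: CensoredSample, boundaries: np.ndarray) -> None:
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    last_event = sample.event_times.max() if sample.event_times.size else -np.inf
    if boundaries[-1] > last_event:
        warnings.warn(
            "boundary beyond the last event time: the survival tail is not "
            "identifiable there; the last value is carried forward"
        )


def sigma_k_plugin(F_at_boundaries) -> np.ndarray:
    """Complete-data Brownian-bridge covariance ``F(t_min)(1 - F(t_max))``."""
    F = np.asarray(F_at_boundaries, dtype=float)
    lo = np.minimum.outer(F, F)
    hi = np.maximum.outer(F, F)
    return lo * (1.0 - hi)


def _tri_ones(K: int) -> np.ndarray:
    return np.tril(np.ones((K, K)))


def sigma_hash(sample: CensoredSample, boundaries) -> tuple[np.ndarray, np.ndarray]:
    """KM covariance ``Sigma# = D_S A diag(v) A^T D_S`` and its increment form.

    ``boundaries`` are the K bin edges t_1 < ... < t_K; ``v_k`` is the
    variance integral over ``(t_{k-1}, t_k]`` with t_0 below all data.
    Returns ``(Sigma#, A^-1 Sigma# A^-T)``; the latter drives the mimicking
    of KM bin increments.
    """
    t = np.asarray(boundaries, dtype=float)
    _check_boundaries(sample, t)
    K = t.size
    km = kaplan_meier(sample)
    S = km.evaluate(t)
    edges = np.concatenate([[min(-1.0, t[0] - 1.0)], t])
    v = np.array([variance_integral(sample, edges[k], edges[k + 1]) for k in range(K)])
    A = _tri_ones(K)
    sig = np.diag(S) @ A @ np.diag(v) @ A.T @ np.diag(S)
    Ainv = np.linalg.inv(A)
    return sig, Ainv @ sig @ Ainv.T


def sigma_doublestar(sample: CensoredSample, boundaries) -> np.ndarray:
    """NA increment covariance: diagonal of per-bin variance integrals."""
    t = np.asarray(boundaries, dtype=float)
    _check_boundaries(sample, t)
    edges = np.concatenate([[min(-1.0, t[0] - 1.0)], t])
    v = [variance_integral(sample, edges[k], edges[k + 1]) for k in range(t.size)]
    return np.diag(v)


def censored_histogram(sample: CensoredSample, l0: float | None = None,
                       l0_frac: float | None = None, tau: float = 0.25,
                       linkage: str = "complete") -> tuple[GappedHistogram, np.ndarray, float]:
    """Two-step censored-data histogram: bins on events, KM masses as weights.

    Returns ``(histogram, bin_masses, residual_tail_mass)``; the masses plus
    the tail (survival beyond the last observation) sum to one.
    """
    events = sample.event_times
    if events.size < 2:
        raise ValueError("need at least two uncensored observations")
    hist = build(events, l0=l0, l0_frac=l0_frac, tau=tau, linkage=linkage)
    km = kaplan_meier(sample)
    ev_weights = km.weights[sample.status == 1]
    ev_times = sample.times[sample.status == 1]
    masses = np.array(
        [ev_weights[(ev_times >= b.a) & (ev_times <= b.b)].sum() for b in hist.bins]
    )
    return hist, masses, km.residual_mass


def _mvn_sampler(cov: np.ndarray, rng: np.random.Generator):
    """Exact N(0, cov) sampler via eigen-decomposition, clipping tiny negatives."""
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)

    def draw(size: int) -> np.ndarray:
        return rng.standard_normal((size, cov.shape[0])) @ L.T

    return draw


def censored_authenticity(samples: dict[str, CensoredSample], boundaries,
                          basis: str = "na", mimics: int = 10000, seed: int = 0,
                          linkage: str = "complete") -> AuthenticityTree:
    """Branch authenticity of a treatment tree from right-censored data.

    ``boundaries`` are bin edges t_0 < t_1 < ... < t_K.  Rows are per-bin KM
    survival decrements (basis "km") or NA hazard increments (basis "na"),
    kept as raw increments.  Mimicking perturbs row j by N(0, Cov_j / n_j)
    with Cov = A^-1 Sigma# A^-T (KM) or Sigma** (NA, sampled as independent
    normals).
    """
    if len(samples) < 2:
        raise ValueError("need at least two treatments")
    t = np.asarray(boundaries, dtype=float)
    if t.size < 3:
        raise ValueError("need at least two bins (three boundary points)")
    inner = t[1:]
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    labels = list(samples)
    rows, draws = [], []
    for name in labels:
        s = samples[name]
        if basis == "km":
            curve = kaplan_meier(s)
            vals = np.concatenate([[curve.evaluate(t[0])], curve.evaluate(inner)])
            row = vals[:-1] - vals[1:]  # survival decrements, non-negative
            _, cov = sigma_hash(s, inner)
        elif basis == "na":
            curve = nelson_aalen(s)
            vals = np.concatenate([[curve.evaluate(t[0])], curve.evaluate(inner)])
            row = vals[1:] - vals[:-1]
            cov = sigma_doublestar(s, inner)
        else:
            raise ValueError("basis must be 'km' or 'na'")
        sampler = _mvn_sampler(cov / s.n, rng)
        rows.append(row)
        draws.append(row + sampler(mimics))
    rows = np.asarray(rows)
    draws = np.stack(draws, axis=1)  # (mimics, J, K)
    return authenticity_from_rows(rows, lambda i: draws[i], labels=labels,
                                  linkage=linkage, mimics=mimics)
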