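"""Seeded synthetic generators and the bundled Iris fixture.

Everything the method assumes can be emulated here: mixtures of uniform
parts separated by true gaps (the generative model behind a possibly gapped
histogram), multi-treatment samples with controlled bin-composition
structure, and right-censored samples with a controlled censoring rate.
All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import SortedSample
from .censored import CensoredSample

__all__ = [
    "MixtureSpec",
    "gen_gapped_mixture",
    "gen_multitreatment",
    "gen_censored",
    "iris_fixture",
    "iris_frame",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Uniform-part mixture: ordered (a_j, b_j, weight_j) triples."""

    parts: tuple
    n: int

    def __post_init__(self):
        parts = tuple((float(a), float(b), float(w)) for a, b, w in self.parts)
        if not parts:
            raise ValueError("at least one uniform part required")
        weights = np.array([w for _, _, w in parts])
        if np.any(weights <= 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be positive and sum to 1")
        for a, b, _ in parts:
            if a > b:
                raise ValueError("part with a > b")
        for (_, b0, _), (a1, _, _) in zip(parts, parts[1:]):
            if a1 < b0:
                raise ValueError("parts must be ordered and non-overlapping")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        object.__setattr__(self, "parts", parts)


def gen_gapped_mixture(spec: MixtureSpec, seed: int = 0) -> SortedSample:
    """Draw n i.i.d. values from the uniform mixture; labels = true part index."""
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    weights = np.array([w for _, _, w in spec.parts])
    which = rng.choice(len(spec.parts), size=spec.n, p=weights)
    lo = np.array([a for a, _, _ in spec.parts])[which]
    hi = np.array([b for _, b, _ in spec.parts])[which]
    values = rng.uniform(lo, hi)
    return SortedSample.from_values(values, labels=which)


def gen_multitreatment(specs: dict[str, MixtureSpec], seed: int = 0) -> SortedSample:
    """Pooled labelled sample with known per-treatment mixture laws."""
    if len(specs) < 2:
        raise ValueError("need at least two treatments")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    values, labels = [], []
    for name, spec in specs.items():
        s = gen_gapped_mixture(spec, seed=rng)
        values.append(s.values)
        labels.append(np.full(spec.n, name, dtype=object))
    return SortedSample.from_values(np.concatenate(values), np.concatenate(labels))


def gen_censored(event_rate: float = 1.0, censor_rate: float | None = 1.0,
                 n: int = 100, seed: int = 0, label: str | None = None,
                 event_sampler=None, censor_sampler=None) -> CensoredSample:
    """Right-censored sample ``(X, delta)`` with X = T ^ C, delta = 1{T <= C}.

    Defaults to independent exponentials; with rates ``lam_T`` and ``lam_C``
    the censoring probability is ``lam_C / (lam_T + lam_C)`` (e.g. a target
    rate of 2/3 needs ``censor_rate = 2 * event_rate``).  Pass
    ``censor_rate=None`` for no censoring, or custom ``*_sampler(rng, n)``
    callables for other laws.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    T = event_sampler(rng, n) if event_sampler else rng.exponential(1.0 / event_rate, n)
    if censor_sampler is not None:
        C = censor_sampler(rng, n)
    elif censor_rate is None:
        C = np.full(n, np.inf)
    else:
        C = rng.exponential(1.0 / censor_rate, n)
    X = np.minimum(T, C)
    delta = (T <= C).astype(int)
    return CensoredSample(times=X, status=delta, label=label)


def iris_frame() -> pd.DataFrame:
    """The bundled 150-flower Iris table (public domain, in-repo CSV)."""
    with resources.files("anoht").joinpath("data/iris.csv").open() as fh:
        return pd.read_csv(fh)


def iris_fixture(standardize: bool = False) -> dict[str, SortedSample]:
    """One labelled SortedSample per Iris feature, optionally standardized."""
    df = iris_frame()
    out = {}
    for col in ("sepal_length", "sepal_width", "petal_length", "petal_width"):
        s = SortedSample.from_values(df[col].to_numpy(), df["species"].to_numpy())
        out[col] = s.standardized() if standardize else s
    return out
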