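"""CSV/JSON readers and writers and the run configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SortedSample
from .censored import CensoredSample, SurvivalCurve
from .histogram import GappedHistogram
from .phase2 import AuthenticityTree

log = logging.getLogger("anoht")

__all__ = [
    "RunConfig",
    "read_values_csv",
    "read_censored_csv",
    "histogram_report",
    "tree_report",
    "curves_frame",
    "write_report",
    "bins_to_bed",
]


@dataclass
class RunConfig:
    """User-facing knobs shared by the CLI commands."""

    l0: float | None = None          # absolute exchange rate; overrides l0_frac
    l0_frac: float = 0.1             # fraction of the root merge height
    linkage: str = "complete"
    tau: float = 0.25                # DESS criterion slack
    gap_method: str = "extension"
    standardize: bool = False
    reps: int = 1000                 # permutation count (phase 1)
    mimics: int = 10000              # mimic count (phase 2 / censored)
    seed: int = 0
    basis: str = "na"                # censored phase-2 basis: "km" or "na"

    def __post_init__(self):
        if self.linkage == "single":
            raise ValueError("single linkage is excluded")
        for name in ("l0_frac", "tau", "reps", "mimics"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_values_csv(path) -> SortedSample:
    """Read a single-column or (value, label) CSV into a sorted sample.

    A header is expected; the numeric column may be named anything if it is
    the only column, otherwise it must be called ``value`` with an optional
    ``label`` column.  Missing rows are rejected with their count reported.
    """
    df = pd.read_csv(path)
    if df.shape[1] == 1:
        value_col, label_col = df.columns[0], None
    elif "value" in df.columns:
        value_col = "value"
        label_col = "label" if "label" in df.columns else None
    else:
        raise ValueError("expected a single column or columns named value[,label]")
    raw = df[value_col]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna()
    if bad.any():
        rows = list(df.index[bad][:10])
        raise ValueError(f"{int(bad.sum())} non-numeric/missing rows (e.g. {rows})")
    if len(df) == 0:
        raise ValueError("empty input file")
    labels = df[label_col].to_numpy() if label_col else None
    log.info("read %d rows from %s", len(df), path)
    return SortedSample.from_values(values.to_numpy(), labels)


def read_censored_csv(path) -> dict[str, CensoredSample] | CensoredSample:
    """Read a (time, status[, label]) CSV; returns per-label samples if labelled."""
    df = pd.read_csv(path)
    for col in ("time", "status"):
        if col not in df.columns:
            raise ValueError("censored input needs columns time,status[,label]")
    if df.isna().any().any():
        raise ValueError(f"{int(df.isna().any(axis=1).sum())} rows with missing values")
    if "label" in df.columns:
        return {
            str(name): CensoredSample(g["time"].to_numpy(), g["status"].to_numpy(),
                                      label=str(name))
            for name, g in df.groupby("label")
        }
    return CensoredSample(df["time"].to_numpy(), df["status"].to_numpy())


def histogram_report(hist: GappedHistogram, masses=None) -> dict:
    """JSON-ready report of a gapped histogram (bins, gaps, config)."""
    bins = []
    for k, b in enumerate(hist.bins):
        row = {
            "a": b.a, "b": b.b, "a_hat": b.a_hat, "b_hat": b.b_hat,
            "m": b.m, "dess": b.dess, "threshold": b.dess_threshold,
        }
        if masses is not None:
            row["mass"] = float(masses[k])
        bins.append(row)
    gaps = [
        {"after_bin": k, "open_interval": [hist.bins[k].b_hat, hist.bins[k + 1].a_hat]}
        for k, flag in enumerate(hist.gap_flags) if flag
    ]
    return {
        "n": hist.sample.n,
        "L0": hist.L0,
        "linkage": hist.linkage,
        "tau": hist.tau,
        "gap_method": hist.gap_method,
        "bins": bins,
        "gap_flags": list(map(bool, hist.gap_flags)),
        "gaps": gaps,
        "total_dess": hist.total_dess,
        "hamiltonian": hist.hamiltonian,
    }


def tree_report(tree: AuthenticityTree) -> dict:
    return {
        "labels": [str(x) for x in tree.labels],
        "mimics": tree.mimics,
        "merges": tree.linkage_matrix[:, :3].tolist(),
        "branches": [
            {
                "leaves": sorted(str(tree.labels[i]) for i in br.leaves),
                "height": br.height,
                "rank_digit": br.rank_digit,
                "authenticity": br.authenticity,
                "clade_recovery": br.clade_recovery,
            }
            for br in tree.branches
        ],
        "newick": tree.to_newick(),
    }


def curves_frame(km: SurvivalCurve, na: SurvivalCurve) -> pd.DataFrame:
    """Tidy (time, S_hat, Lambda_hat, weight) table of the two estimates."""
    return pd.DataFrame(
        {"time": km.times, "S_hat": km.values, "Lambda_hat": na.values,
         "weight": km.weights}
    )


def write_report(obj: dict, path) -> None:
    """Write a JSON report with sorted keys (round-trip stable)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def bins_to_bed(hist: GappedHistogram, path) -> None:
    """BED-like 3-column interval file of the bins (name, a, b)."""
    lines = [f"bin{k}\t{b.a:.10g}\t{b.b:.10g}" for k, b in enumerate(hist.bins)]
    Path(path).write_text("\n".join(lines) + "\n")
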