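"""Replicate- and run-level QC for qPCR telomere (T/S ratio) assays.

Each sample is assayed in duplicate wells on three days (nominally six T/S
values).  QC proceeds in two stages:

* **Run level** — an assay run is excluded outright when it has ≥8 invalid
  control wells, or when more than 4 of its control DNA values fall outside
  2.5 standard deviations of the across-run control mean.
* **Replicate level** — within a sample, the largest and smallest T/S values
  are marked as *potential* outliers; the mean ``m`` of the remaining values
  is computed, and a potential outlier ``v`` is excluded iff
  ``|log(m / v)| > threshold`` (default 0.4, natural log).  Potential
  outliers that pass the test are restored, and the reported mean/SD covers
  all retained values.  At most two values can ever be excluded per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "InsufficientReplicatesError",
    "ReplicateSet",
    "RunControls",
    "ReplicateQCResult",
    "flag_runs",
    "qc_replicates",
    "summarize_replicates",
    "ReplicateQC",
]


class InsufficientReplicatesError(ValueError):
    """Fewer than 3 replicate values: the outlier rule is undefined."""


@dataclass
class ReplicateSet:
    """T/S ratio values from repeated wells for one sample."""

    sample_id: str
    values: list[float]
    run_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values):
            raise ValueError(f"T/S ratios must be positive (sample {self.sample_id})")

    def drop_runs(self, excluded: set[str]) -> "ReplicateSet":
        if not self.run_ids:
            return self
        kept = [
            (v, r) for v, r in zip(self.values, self.run_ids) if r not in excluded
        ]
        return ReplicateSet(
            sample_id=self.sample_id,
            values=[v for v, _ in kept],
            run_ids=[r for _, r in kept],
        )


@dataclass
class RunControls:
    """Control-well summary for one assay run."""

    run_id: str
    n_invalid_wells: int
    control_values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_invalid_wells < 0:
            raise ValueError("invalid-well count must be >= 0")


@dataclass
class ReplicateQCResult:
    sample_id: str
    mean: float
    sd: float
    n_retained: int
    excluded: list[float]


def flag_runs(
    runs: Iterable[RunControls],
    all_run_mean: float,
    all_run_sd: float,
    max_invalid_wells: int = 8,
    max_out_of_range: int = 4,
    sd_multiplier: float = 2.5,
) -> set[str]:
    """Run ids failing either run-level rule.

    A run is excluded when ``n_invalid_wells >= max_invalid_wells`` or when
    *more than* ``max_out_of_range`` control values lie outside
    ``all_run_mean ± sd_multiplier * all_run_sd`` (exactly 4 is retained).
    """
    if all_run_sd <= 0:
        raise ValueError("all_run_sd must be positive")
    lo = all_run_mean - sd_multiplier * all_run_sd
    hi = all_run_mean + sd_multiplier * all_run_sd
    excluded = set()
    for run in runs:
        if run.n_invalid_wells >= max_invalid_wells:
            excluded.add(run.run_id)
            continue
        n_out = sum(1 for v in run.control_values if v < lo or v > hi)
        if n_out > max_out_of_range:
            excluded.add(run.run_id)
    return excluded


def qc_replicates(
    values: Sequence[float],
    threshold: float = 0.4,
    log_base: float | None = None,
    restore_passing: bool = True,
) -> ReplicateQCResult:
    """Outlier-screened mean and SD of one sample's replicate T/S values.

    ``log_base=None`` uses the natural logarithm for the ratio criterion;
    pass e.g. 10 for a base-10 reading.  ``restore_passing=False`` keeps
    the final mean restricted to the interior values even when a potential
    outlier passes the test (the stricter alternative reading).

    The result carries the retained mean and SD (n−1 denominator; 0 for a
    single retained value) plus the excluded values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InsufficientReplicatesError(
            f"need >= 3 replicate values, got {v.size}"
        )
    if (v <= 0).any() or not np.isfinite(v).all():
        raise ValueError("T/S ratios must be positive and finite")

    log = math.log if log_base is None else (lambda x: math.log(x, log_base))

    i_min = int(np.argmin(v))
    i_max = int(np.argmax(v))
    if v[i_min] == v[i_max]:
        # all values identical: no outlier candidates
        retained = v
        excluded: list[float] = []
    else:
        candidates = [i_min, i_max]
        interior = np.delete(v, candidates)
        m = float(interior.mean())
        excluded_idx = [i for i in candidates if abs(log(m / v[i])) > threshold]
        excluded = [float(v[i]) for i in excluded_idx]
        # default reading restores a potential outlier that passes the test;
        # the strict alternative keeps the interior mean either way
        retained = np.delete(v, excluded_idx) if restore_passing else interior
    mean = float(retained.mean())
    sd = float(retained.std(ddof=1)) if retained.size > 1 else 0.0
    return ReplicateQCResult(
        sample_id="", mean=mean, sd=sd, n_retained=int(retained.size),
        excluded=excluded,
    )


def summarize_replicates(
    long: pd.DataFrame,
    threshold: float = 0.4,
    log_base: float | None = None,
    excluded_runs: set[str] | None = None,
) -> pd.DataFrame:
    """Per-sample QC summary from a long table (sample_id, run_id, ts).

    Rows from ``excluded_runs`` are dropped first; samples left with fewer
    than 3 values get NaN summaries and ``qc_pass=False``.
    """
    df = long
    if excluded_runs and "run_id" in df.columns:
        df = df[~df["run_id"].isin(excluded_runs)]
    rows = []
    for sid, grp in df.groupby("sample_id", sort=True):
        vals = grp["ts"].to_numpy(dtype=float)
        try:
            res = qc_replicates(vals, threshold=threshold, log_base=log_base)
            rows.append(
                {
                    "sample_id": sid,
                    "ts_mean": res.mean,
                    "ts_sd": res.sd,
                    "n_retained": res.n_retained,
                    "n_excluded": len(res.excluded),
                    "qc_pass": True,
                }
            )
        except InsufficientReplicatesError:
            rows.append(
                {
                    "sample_id": sid,
                    "ts_mean": np.nan,
                    "ts_sd": np.nan,
                    "n_retained": len(vals),
                    "n_excluded": 0,
                    "qc_pass": False,
                }
            )
    return pd.DataFrame(rows)


class ReplicateQC(BaseEstimator, TransformerMixin):
    """Transformer facade: long replicate table → per-sample QC summary."""

    def __init__(
        self,
        threshold: float = 0.4,
        log_base: float | None = None,
        excluded_runs: set[str] | None = None,
    ):
        self.threshold = threshold
        self.log_base = log_base
        self.excluded_runs = excluded_runs

    def fit(self, X: pd.DataFrame, y=None) -> "ReplicateQC":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return summarize_replicates(
            X,
            threshold=self.threshold,
            log_base=self.log_base,
            excluded_runs=self.excluded_runs,
        )
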