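"""Virus removal-rate arithmetic and the accompanying statistical tests.

Bottle incubations are sampled by flow cytometry as counts per ml of
virus-like particles (and bacteria) in biological triplicate.  Removal is
summarised as the percent reduction relative to each replicate's own
time-zero count, averaged across replicates (mean +- SD); dividing a
reduction by the elapsed days gives a linear daily removal rate, and
treatments are compared as percent rate increases over a reference
(typically the cell-free, abiotic bottles).

Two tests are provided: Welch's unequal-variance t-test for comparing
abundances between treatments at a time point, and the Wilcoxon
signed-rank test (exact null distribution for n <= 25) for paired
comparisons of isotope labelling over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceSeries",
    "RemovalSummary",
    "percent_reduction",
    "daily_removal_rate",
    "rate_increase",
    "round_half_away",
    "welch_t_test",
    "wilcoxon_signed_rank",
    "read_abundance_csv",
    "write_abundance_csv",
    "removal_summary_table",
]


@dataclass(frozen=True)
class AbundanceSeries:
    """One replicate's count time series for one treatment and target."""

    treatment: str
    replicate: str
    times: np.ndarray  # days
    counts: np.ndarray  # particles per ml
    target: str = "virus"  # virus | bacteria

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if times.shape != counts.shape or times.ndim != 1:
            raise ValueError("times and counts must be 1-D arrays of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if 0.0 not in times:
            raise ValueError("time 0 must be present")
        if np.any(counts[np.isfinite(counts)] < 0):
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)

    def count_at(self, t: float) -> float:
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise KeyError(f"time {t} not sampled for {self.treatment}/{self.replicate}")
        return float(self.counts[idx[0]])


@dataclass(frozen=True)
class RemovalSummary:
    """Across-replicate removal summary for one treatment at one time."""

    treatment: str
    time: float
    reduction_mean: float  # %
    reduction_sd: float | None  # % (None when n < 2)
    daily_rate: float  # % per day, unrounded
    n_replicates: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one usable replicate")


def percent_reduction(
    series: Iterable[AbundanceSeries], time: float
) -> RemovalSummary:
    """Mean +- SD percent reduction at ``time`` relative to each replicate's t=0.

    Each replicate is normalised to its own starting count
    (r_i = 100*(1 - count_i(t)/count_i(0))); replicates with a zero
    starting count are excluded and counted in ``n_excluded``.
    """
    series = list(series)
    if not series:
        raise ValueError("no series given")
    treatments = {s.treatment for s in series}
    if len(treatments) != 1:
        raise ValueError(f"series mix treatments {sorted(treatments)}")
    reductions = []
    excluded = 0
    for s in series:
        c0 = s.count_at(0.0)
        ct = s.count_at(time)
        if c0 <= 0 or not np.isfinite(c0) or not np.isfinite(ct):
            excluded += 1
            continue
        reductions.append(100.0 * (1.0 - ct / c0))
    if not reductions:
        raise ValueError("all replicates excluded (zero or missing counts at t=0)")
    arr = np.array(reductions)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return RemovalSummary(
        treatment=series[0].treatment,
        time=time,
        reduction_mean=mean,
        reduction_sd=sd,
        daily_rate=daily_removal_rate(mean, time),
        n_replicates=arr.size,
        n_excluded=excluded,
    )


def daily_removal_rate(reduction_percent: float, elapsed_days: float) -> float:
    """Linear daily removal rate (% per day): reduction / elapsed.

    Returns the unrounded value; apply :func:`round_half_away` with one
    decimal for reporting.
    """
    if elapsed_days <= 0:
        raise ValueError("elapsed_days must be positive")
    return reduction_percent / elapsed_days


def rate_increase(rate_treatment: float, rate_reference: float) -> float:
    """Percent increase of a treatment's daily rate over a reference rate.

    Inputs should be unrounded rates; round the result to the nearest
    integer for reporting.
    """
    if rate_reference <= 0:
        raise ValueError("reference rate must be positive")
    return 100.0 * (rate_treatment - rate_reference) / rate_reference


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (reporting convention for rates)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def welch_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's two-sample unequal-variance t-test (two-sided).

    Returns (t, Welch-Satterthwaite df, p).  Requires n >= 2 per sample
    and a nonzero variance in at least one.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both samples have zero variance")
    sa2n, sb2n = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sa2n + sb2n)
    df = (sa2n + sb2n) ** 2 / (
        sa2n**2 / (a.size - 1) + sb2n**2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _exact_wilcoxon_p(w: float, ranks: np.ndarray) -> float:
    """Two-sided exact p by dynamic programming over the 2^n sign assignments.

    Ranks are mid-ranks (multiples of 0.5); doubling makes them integers,
    so the null distribution of 2W is a polynomial convolution.
    """
    scaled = np.rint(2 * ranks).astype(int)
    total = int(scaled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w))
    mean2 = total / 2.0
    # two-sided: fold around the symmetric mean of 2W
    dev = abs(w2 - mean2)
    lo = mean2 - dev
    hi = mean2 + dev
    idx = np.arange(dist.size)
    p = dist[(idx <= lo + 1e-9) | (idx >= hi - 1e-9)].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(
    differences: Sequence[float], exact_max_n: int = 25
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences (two-sided).

    Zero differences are dropped; ties get mid-ranks.  The statistic W is
    the sum of ranks of positive differences.  The p-value uses the exact
    null distribution for n <= ``exact_max_n`` and a normal approximation
    with continuity and tie correction above.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_wilcoxon_p(w, ranks)
    else:
        mean = n * (n + 1) / 4.0
        # variance with tie correction
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        dev = abs(w - mean) - 0.5  # continuity correction
        z = max(dev, 0.0) / math.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    return w, p


# ---------------------------------------------------------------------------
# tabular I/O


_CSV_COLUMNS = ["treatment", "replicate", "time_days", "target", "count_per_ml"]


def write_abundance_csv(series: Iterable[AbundanceSeries], path) -> None:
    rows = []
    for s in series:
        for t, c in zip(s.times, s.counts):
            rows.append(
                {
                    "treatment": s.treatment,
                    "replicate": s.replicate,
                    "time_days": t,
                    "target": s.target,
                    "count_per_ml": c,
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_abundance_csv(path) -> list[AbundanceSeries]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"abundance CSV missing columns {sorted(missing)}")
    out = []
    for (treatment, replicate, target), grp in df.groupby(
        ["treatment", "replicate", "target"], sort=True
    ):
        grp = grp.sort_values("time_days")
        out.append(
            AbundanceSeries(
                treatment=str(treatment),
                replicate=str(replicate),
                times=grp["time_days"].to_numpy(),
                counts=grp["count_per_ml"].to_numpy(),
                target=str(target),
            )
        )
    return out


def removal_summary_table(
    series: Iterable[AbundanceSeries], times: Sequence[float], target: str = "virus"
) -> pd.DataFrame:
    """Removal summaries for every treatment at each requested time."""
    series = [s for s in series if s.target == target]
    rows = []
    for treatment in sorted({s.treatment for s in series}):
        group = [s for s in series if s.treatment == treatment]
        for t in times:
            if t == 0:
                continue
            summ = percent_reduction(group, t)
            rows.append(
                {
                    "treatment": summ.treatment,
                    "time_days": summ.time,
                    "reduction_mean_pct": summ.reduction_mean,
                    "reduction_sd_pct": summ.reduction_sd,
                    "daily_rate_pct_per_day": summ.daily_rate,
                    "daily_rate_reported": round_half_away(summ.daily_rate, 1),
                    "n_replicates": summ.n_replicates,
                    "n_excluded": summ.n_excluded,
                }
            )
    return pd.DataFrame(rows)
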