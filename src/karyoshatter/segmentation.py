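"""Changepoint segmentation of probe-level log2 ratios.

The profile of each chromosome is partitioned into contiguous segments by
minimizing the penalized residual sum of squares

    sum_over_segments [ sum_{i in seg} (x_i - mean(seg))^2 ]  +  beta * (#segments)

with a minimum segment length (``min_probes``).  The optimizer is PELT
(pruned exact linear time): identical optimum to exhaustive dynamic
programming, with candidate pruning for speed.  Pruning is delayed by one
minimum segment length so that the minimum-length constraint can never
exclude the dominating candidate — the result is exactly the DP optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class ProfileError(ValueError):
    """Raised for malformed probe input (unsorted, non-finite, ...)."""


@dataclass(frozen=True)
class Segment:
    """A piecewise-constant stretch of the copy-number profile.

    ``start``/``end`` are 0-based half-open bp coordinates spanning the
    member probes (start = first probe position - 1, end = last probe
    position), so that a segment's interval is exactly the span it is
    evidenced by.
    """

    chromosome: str
    start: int
    end: int
    mean_log2: float
    n_probes: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end {self.end} <= start {self.start}")

    @property
    def size_bp(self) -> int:
        return self.end - self.start


def pelt_breakpoints(values: np.ndarray, penalty: float, min_size: int = 1) -> list[int]:
    """Optimal changepoints of a 1-D signal under an RSS + penalty objective.

    Returns segment end indices (exclusive), the last being ``len(values)``.
    The solution minimizes ``sum RSS(segment) + penalty * n_segments`` over
    all partitions into segments of at least ``min_size`` points, and equals
    the exhaustive dynamic-programming optimum.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        return []
    if n < min_size:
        return [n]
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    never = np.iinfo(np.int64).max
    dead_at = np.full(n + 1, never, dtype=np.int64)  # first time c may be dropped
    cands = np.empty(n + 1, dtype=np.int64)
    cands[0] = 0
    m = 1
    for t in range(min_size, n + 1):
        active = cands[:m]
        eligible = active[(t - active >= min_size) & (dead_at[active] > t)]
        if eligible.size == 0:
            continue
        costs = (cs2[t] - cs2[eligible]) - (cs[t] - cs[eligible]) ** 2 / (t - eligible)
        totals = F[eligible] + costs
        best = int(np.argmin(totals))
        F[t] = totals[best] + penalty
        prev[t] = eligible[best]
        # c dominated by t for every u >= t + min_size (RSS cost is
        # superadditive under merging); schedule removal then.
        kill = eligible[totals > F[t]]
        dead_at[kill] = np.minimum(dead_at[kill], t + min_size)
        keep = dead_at[active] > t + 1
        if not np.all(keep):
            kept = active[keep]
            m = kept.size
            cands[:m] = kept
        cands[m] = t
        m += 1
    if not np.isfinite(F[n]):
        return [n]  # no feasible split; single segment
    ends = []
    t = n
    while t > 0:
        ends.append(t)
        t = prev[t]
    return ends[::-1]


def segment_values(values: np.ndarray, penalty: float, min_size: int = 1
                   ) -> list[tuple[int, int, float]]:
    """Segment a raw value array; returns (start_idx, end_idx, mean) triples."""
    ends = pelt_breakpoints(values, penalty, min_size)
    out = []
    s = 0
    for e in ends:
        out.append((s, e, float(np.mean(values[s:e]))))
        s = e
    return out


def segment_profile(probes: pd.DataFrame, config) -> list[Segment]:
    """Segment a probe table (columns chrom, pos, log2ratio) per chromosome.

    Probes must be sorted by (chromosome block, position).  Chromosomes with
    fewer than ``config.min_probes`` probes are skipped with a warning.
    """
    required = {"chrom", "pos", "log2ratio"}
    if not required.issubset(probes.columns):
        raise ProfileError(f"probe table needs columns {sorted(required)}")
    if not np.all(np.isfinite(probes["log2ratio"].to_numpy(dtype=float))):
        raise ProfileError("non-finite log2 ratio in probe table")

    segments: list[Segment] = []
    for chrom, grp in probes.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise ProfileError(f"probe positions not sorted/unique on {chrom}")
        if len(pos) < config.min_probes:
            warnings.warn(
                f"chromosome {chrom} has {len(pos)} < {config.min_probes} probes; skipped",
                stacklevel=2)
            continue
        vals = grp["log2ratio"].to_numpy(dtype=float)
        for s, e, mean in segment_values(vals, config.segmentation_penalty,
                                         config.min_probes):
            segments.append(Segment(
                chromosome=str(chrom),
                start=int(pos[s]) - 1,
                end=int(pos[e - 1]),
                mean_log2=mean,
                n_probes=e - s,
            ))
    return segments
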