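import numpy as np
import pytest

from karyoshatter.calling import CallingConfig
from karyoshatter.genome import build_genome_model


def dp_changepoint_oracle(x, penalty, min_size=1):
    """Exhaustive optimal-partitioning dynamic program (no pruning).

    Independent oracle for the penalized least-squares changepoint problem:
    O(n^2) over all admissible split points.  Returns (segment end indices,
    optimal objective value).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for t in range(min_size, n + 1):
        starts = np.arange(0, t - min_size + 1)
        starts = starts[np.isfinite(F[starts])]
        if starts.size == 0:
            continue
        cost = (cs2[t] - cs2[starts]) - (cs[t] - cs[starts]) ** 2 / (t - starts)
        totals = F[starts] + cost + penalty
        i = int(np.argmin(totals))
        F[t] = totals[i]
        prev[t] = starts[i]
    ends = []
    t = n
    while t > 0:
        ends.append(t)
        t = prev[t]
    # F[0] = -penalty makes F[n] = RSS + (k-1)*penalty; report RSS + k*penalty
    return ends[::-1], float(F[n] + penalty)


def partition_objective(x, ends, penalty):
    """Penalized RSS of a given partition (independent of both solvers)."""
    x = np.asarray(x, dtype=float)
    total, s = 0.0, 0
    for e in ends:
        seg = x[s:e]
        total += float(np.sum((seg - seg.mean()) ** 2)) + penalty
        s = e
    return total


@pytest.fixture(scope="session")
def tiny_genome():
    """Two equal chromosomes, 200 probes, no gene annotation."""
    return build_genome_model(
        probe_count=200,
        chromosomes={"chrA": 100_000_000, "chrB": 100_000_000},
        with_genes=False,
    )


@pytest.fixture(scope="session")
def default_genome():
    """Full 24-chromosome synthetic genome at reduced probe density."""
    return build_genome_model(probe_count=24_000)


@pytest.fixture(scope="session")
def calling_config():
    return CallingConfig()
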