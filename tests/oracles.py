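"""Independent brute-force oracles used by the test suite.

Deliberately written with plain Python loops and the standard library
(statistics, math, itertools) so they share no code path with the
implementations they check.
"""

from __future__ import annotations

import itertools
import math
import statistics


def oracle_d(row: list[float | None], s0: float) -> float:
    vals = [v for v in row if v is not None]
    mean = statistics.fmean(vals)
    se = statistics.stdev(vals) / math.sqrt(len(vals))
    return mean / (se + s0)


def oracle_sam(
    rows: dict[str, list[float | None]], s0: float
) -> tuple[dict[str, float], dict[str, float]]:
    """Exhaustive sign-flip one-class SAM: per-gene d and q (percent).

    Enumerates every sign pattern over the replicate slots, computes the
    modified t for each gene under each pattern, and derives q-values by
    direct counting with the median-null / observed-count ratio, capped
    at 100 and monotonized along decreasing |d|.
    """
    genes = list(rows)
    n_rep = len(next(iter(rows.values())))
    d_obs = {g: oracle_d(rows[g], s0) for g in genes}

    patterns = list(itertools.product([1.0, -1.0], repeat=n_rep))
    null_abs: list[list[float]] = []
    for pattern in patterns:
        flipped_abs = []
        for g in genes:
            row = [
                None if v is None else v * s
                for v, s in zip(rows[g], pattern)
            ]
            flipped_abs.append(abs(oracle_d(row, s0)))
        null_abs.append(flipped_abs)

    q_raw = {}
    for g in genes:
        threshold = abs(d_obs[g])
        observed = sum(1 for h in genes if abs(d_obs[h]) >= threshold)
        counts = [
            sum(1 for value in pattern_abs if value >= threshold)
            for pattern_abs in null_abs
        ]
        q_raw[g] = min(100.0 * statistics.median(counts) / observed, 100.0)

    ordered = sorted(genes, key=lambda g: (-abs(d_obs[g]), g))
    q = {}
    running = math.inf
    for g in reversed(ordered):
        running = min(running, q_raw[g])
        q[g] = running
    return d_obs, q


def oracle_hypergeom_over(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact integer enumeration."""
    numer = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
    )
    return numer / math.comb(N, n)


def oracle_hypergeom_under(k: int, K: int, n: int, N: int) -> float:
    """P(X <= k) by exact integer enumeration."""
    numer = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(max(0, n - (N - K)), k + 1)
    )
    return numer / math.comb(N, n)


def oracle_window_means(scores: list[float], window: int) -> list[float]:
    return [
        sum(scores[i : i + window]) / window
        for i in range(len(scores) - window + 1)
    ]


def oracle_stretches_linear(
    values: list[float], threshold: float, min_length: int
) -> list[tuple[int, int]]:
    """Single-pass run finder (cheap enough for thousands of profiles)."""
    runs = []
    start = None
    for i, v in enumerate(list(values) + [threshold]):  # sentinel closes runs
        if v > threshold:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_length:
                runs.append((start + 1, i))
            start = None
    return runs


def oracle_stretches(
    values: list[float], threshold: float, min_length: int
) -> list[tuple[int, int]]:
    """Maximal (start, end) runs (1-based, inclusive) with value > threshold,
    found by testing every candidate interval for maximality."""
    n = len(values)
    runs = []
    for start in range(n):
        for end in range(start, n):
            if all(values[i] > threshold for i in range(start, end + 1)):
                left_ok = start == 0 or values[start - 1] <= threshold
                right_ok = end == n - 1 or values[end + 1] <= threshold
                if left_ok and right_ok and end - start + 1 >= min_length:
                    runs.append((start + 1, end + 1))
    return sorted(set(runs))
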