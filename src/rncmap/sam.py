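"""One-class SAM permutation test on replicated log2(IP/reference) ratios.

The caller asks, per gene, whether its replicate log-ratios are
reproducibly shifted away from zero.  The statistic is the moderated
one-class t

    d_i = mean_i / (s_i + s0)

where ``mean_i`` and ``s_i`` are the mean and standard error over the
gene's non-missing replicates and ``s0`` is a small positive
"exchangeability" offset that stops genes with tiny scatter from
dominating the ranking.  The null distribution is generated by flipping
replicate signs: one sign pattern per permutation, shared by every gene,
which preserves gene-gene correlation.  When all ``2^R`` patterns fit in
the permutation budget they are enumerated exactly.

q-values (percent scale): for each gene, the median over permutations of
the number of null |d| values at or above its observed |d|, divided by
the observed count of genes at or above that |d|, times 100; capped at
100 and made monotone non-increasing in |d|.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .containers import FormatError, InsufficientDataError, RatioMatrix, SamResult, TargetSet

QUALITY_COLUMNS = ("regression_correlation", "signal_over_background")

#: strict lower bounds a measurement must exceed to be kept
MIN_REGRESSION_CORRELATION = 0.6
MIN_SIGNAL_OVER_BACKGROUND = 2.5


class InsufficientReplicatesError(InsufficientDataError):
    """Fewer than two usable replicates for the one-class test."""


def spot_quality_filter(measurements: pd.DataFrame, condition: str = "") -> RatioMatrix:
    """Build a RatioMatrix from per-measurement rows, masking low-quality spots.

    ``measurements`` needs columns ``gene_id``, ``sample_id``, ``value``,
    ``regression_correlation`` and ``signal_over_background``.  A
    measurement survives iff regression_correlation > 0.6 AND
    signal_over_background > 2.5 (both strict); failing measurements
    become missing cells.
    """
    required = {"gene_id", "sample_id", "value", *QUALITY_COLUMNS}
    missing_cols = required - set(measurements.columns)
    if missing_cols:
        raise FormatError(f"missing quality columns: {sorted(missing_cols)}")
    keep = (
        (measurements["regression_correlation"] > MIN_REGRESSION_CORRELATION)
        & (measurements["signal_over_background"] > MIN_SIGNAL_OVER_BACKGROUND)
    )
    cleaned = measurements.assign(value=measurements["value"].where(keep))
    wide = cleaned.pivot(index="gene_id", columns="sample_id", values="value")
    # preserve first-appearance order of genes and samples
    wide = wide.reindex(
        index=measurements["gene_id"].drop_duplicates(),
        columns=measurements["sample_id"].drop_duplicates(),
    )
    wide.index.name = None
    wide.columns.name = None
    return RatioMatrix(wide, condition=condition)


def filter_features(matrix: RatioMatrix, max_missing: int = 1) -> RatioMatrix:
    """Drop gene rows with more than ``max_missing`` missing replicate values.

    The default keeps genes missing at most one value, i.e. removes
    features missing two or more.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    n_missing = matrix.data.isna().sum(axis=1)
    return RatioMatrix(matrix.data.loc[n_missing <= max_missing], matrix.condition)


def median_center(matrix: RatioMatrix) -> RatioMatrix:
    """Subtract each array column's median (global per-array centering)."""
    centered = matrix.data - matrix.data.median(axis=0, skipna=True)
    return RatioMatrix(centered, matrix.condition)


def knn_impute(matrix: RatioMatrix, k: int = 10) -> RatioMatrix:
    """Fill missing cells from the k nearest complete gene rows.

    Distance is Euclidean over the incomplete gene's observed columns,
    normalised per column count; the imputed value is the neighbour
    mean in the missing column.  Run after :func:`filter_features` so
    at most one cell per row needs filling.  Sign-flip permutations
    only generate a proper null for a gene when every replicate can be
    flipped, so the permutation test should see a complete matrix.
    Falls back to the row mean when no complete donor rows exist.
    """
    values = matrix.values.copy()
    complete = ~np.isnan(values).any(axis=1)
    donors = values[complete]
    for i in np.flatnonzero(~complete):
        row = values[i]
        obs = ~np.isnan(row)
        if not obs.any():
            continue
        if len(donors) == 0:
            values[i, ~obs] = np.nanmean(row)
            continue
        dist = np.sqrt(((donors[:, obs] - row[obs]) ** 2).mean(axis=1))
        nearest = donors[np.argsort(dist, kind="stable")[: min(k, len(donors))]]
        values[i, ~obs] = nearest[:, ~obs].mean(axis=0)
    return RatioMatrix(
        pd.DataFrame(values, index=matrix.gene_ids, columns=matrix.sample_ids),
        matrix.condition,
    )


def _row_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row mean and standard error over non-missing entries."""
    n = np.sum(~np.isnan(values), axis=1)
    mean = np.nanmean(values, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(values, axis=1, ddof=1)
    se = sd / np.sqrt(n)
    return mean, se


def _d_stat(mean: np.ndarray, se: np.ndarray, s0: float) -> np.ndarray:
    denom = se + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = mean / denom
    # zero scatter and zero s0: define d = 0 for zero means (null data),
    # +-inf otherwise so the gene still ranks above everything finite
    degenerate = denom == 0
    with np.errstate(invalid="ignore"):
        d[degenerate] = np.where(
            mean[degenerate] == 0, 0.0, np.sign(mean[degenerate]) * np.inf
        )
    return d


def select_s0(mean: np.ndarray, s: np.ndarray, n_bins: int = 10) -> float:
    """Pick s0 among the 0th-100th percentiles (step 5) of the s distribution.

    The chosen s0 minimises the coefficient of variation of the median
    |d| across s-quantile bins, i.e. makes the statistic's scale roughly
    independent of the per-gene scatter (the standard SAM recipe).
    """
    candidates = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    bins = [b for b in bins if len(b)]
    best_s0, best_cv = float(candidates[0]), np.inf
    for s0 in candidates:
        d = np.abs(_d_stat(mean.copy(), s, float(s0)))
        medians = np.array([np.median(d[b]) for b in bins])
        center = medians.mean()
        if not np.isfinite(center) or center == 0:
            continue
        cv = medians.std() / center
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _sign_patterns(n_replicates: int, n_permutations: int, seed: int) -> np.ndarray:
    """Sign-flip patterns, exhaustively enumerated when 2^R fits the budget."""
    if 2**n_replicates <= n_permutations:
        return np.array(
            list(itertools.product((1.0, -1.0), repeat=n_replicates))
        )
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2, size=(n_permutations, n_replicates)) * 2.0 - 1.0


def sam_one_class(
    matrix: RatioMatrix,
    n_permutations: int = 800,
    seed: int = 0,
    s0: float | None = None,
) -> SamResult:
    """One-class SAM: moderated t statistics and permutation q-values.

    Parameters
    ----------
    matrix
        Feature-filtered ratio matrix; every gene needs >= 2 non-missing
        replicates.
    n_permutations
        Permutation budget.  All ``2^R`` sign patterns are enumerated
        exactly whenever that is within budget; otherwise
        ``n_permutations`` random patterns are drawn with ``seed``.
    s0
        Exchangeability offset; estimated from the data by
        :func:`select_s0` when None (pass 0.0 for the plain t ratio).
    """
    if matrix.n_replicates < 2:
        raise InsufficientReplicatesError("need >= 2 replicate columns")
    values = matrix.values
    n_obs = np.sum(~np.isnan(values), axis=1)
    if np.any(n_obs < 2):
        raise InsufficientReplicatesError(
            "every gene needs >= 2 non-missing replicates; run filter_features first"
        )

    mean, se = _row_stats(values)
    if s0 is None:
        s0 = select_s0(mean, se)
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    d = _d_stat(mean, se, s0)

    abs_d = np.abs(d)
    n_genes = len(abs_d)
    sorted_abs = np.sort(abs_d)
    # observed count of |d| >= |d_i|
    observed_ge = n_genes - np.searchsorted(sorted_abs, abs_d, side="left")

    patterns = _sign_patterns(matrix.n_replicates, n_permutations, seed)
    null_counts = np.empty((len(patterns), n_genes))
    for b, pattern in enumerate(patterns):
        null_mean, null_se = _row_stats(values * pattern)
        null_abs = np.sort(np.abs(_d_stat(null_mean, null_se, s0)))
        null_counts[b] = n_genes - np.searchsorted(null_abs, abs_d, side="left")
    median_null = np.median(null_counts, axis=0)

    q = np.minimum(100.0 * median_null / observed_ge, 100.0)

    # monotonize: sort by |d| descending (ties by gene_id) and take the
    # running minimum from the least significant gene upward
    gene_ids = np.array(matrix.gene_ids)
    order = np.lexsort((gene_ids, -abs_d))
    q_sorted = q[order]
    q_mono = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_out = np.empty_like(q)
    q_out[order] = q_mono

    return SamResult(
        gene_ids=list(matrix.gene_ids),
        d=d,
        s=se,
        q=q_out,
        s0=float(s0),
        n_permutations=len(patterns),
        condition=matrix.condition,
    )


def call_targets(
    result: SamResult, q_threshold: float = 1.0, sign: str = "positive"
) -> TargetSet:
    """Genes with q <= threshold (percent), restricted to d > 0 by default."""
    if sign not in ("positive", "both"):
        raise ValueError("sign must be 'positive' or 'both'")
    keep = result.q <= q_threshold
    if sign == "positive":
        keep &= result.d > 0
    genes = frozenset(np.array(result.gene_ids)[keep])
    return TargetSet(condition=result.condition, q_threshold=q_threshold, genes=genes)
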