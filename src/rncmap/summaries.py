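"""Descriptive statistics: correlation maps, hierarchical clustering,
cumulative-fraction curves and box-plot summaries.

Replicate agreement and bait-bait relationships are summarised by
pairwise Pearson correlation (pairwise-complete over missing cells) and
average-linkage agglomerative clustering on the dissimilarity 1 - r.
The clustering is implemented directly (rather than through a library
call) because reproducible output requires a stated tie-break: among
equidistant candidate merges, the pair whose sorted representative-id
tuple is lexicographically smallest merges first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import InsufficientDataError, RatioMatrix


class EmptyGroupError(ValueError):
    """A grouping used for per-group curves contains an empty group."""


@dataclass
class CorrelationMatrix:
    ids: list[str]
    r: np.ndarray  # symmetric, unit diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.ids, columns=self.ids)


@dataclass(frozen=True)
class BoxStats:
    """Median/quartile/whisker summary of one distribution.

    Whiskers sit at the most extreme data points within 1.5 IQR of the
    quartiles (Tukey convention); quartiles interpolate linearly between
    order statistics.
    """

    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    n: int


def _pairwise_pearson(x: np.ndarray, y: np.ndarray, min_overlap: int = 3) -> float:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < min_overlap:
        raise InsufficientDataError(
            f"only {int(ok.sum())} pairwise-complete observations (need {min_overlap})"
        )
    xv, yv = x[ok], y[ok]
    xc, yc = xv - xv.mean(), yv - yv.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise InsufficientDataError("zero variance in pairwise-complete overlap")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def pearson_matrix(matrix: RatioMatrix, axis: str = "samples") -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between samples or genes."""
    if axis == "samples":
        vectors = matrix.values.T
        ids = matrix.sample_ids
    elif axis == "genes":
        vectors = matrix.values
        ids = matrix.gene_ids
    else:
        raise ValueError("axis must be 'samples' or 'genes'")
    m = len(ids)
    if m < 2:
        raise InsufficientDataError("need >= 2 vectors to correlate")
    r = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            r[i, j] = r[j, i] = _pairwise_pearson(vectors[i], vectors[j])
    return CorrelationMatrix(ids=list(ids), r=r)


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` rows are (left, right, height, size) with cluster indices
    in scipy convention: 0..n-1 are leaves (in ``labels`` order), merge
    k creates cluster n+k.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the tree."""
        n = len(self.labels)

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            left, right, _, _ = self.merges[node - n]
            return walk(left) + walk(right)

        return [self.labels[i] for i in walk(n + len(self.merges) - 1)]

    def to_newick(self) -> str:
        n = len(self.labels)

        def render(node: int, parent_height: float) -> str:
            if node < n:
                return f"{self.labels[node]}:{parent_height:.6g}"
            left, right, height, _ = self.merges[node - n]
            inner = ",".join(render(c, height) for c in (left, right))
            return f"({inner}):{max(parent_height - height, 0.0):.6g}"

        root = n + len(self.merges) - 1
        root_height = self.merges[-1][2] if self.merges else 0.0
        return render(root, root_height).rsplit(":", 1)[0] + ";"


def hcluster(
    matrix: RatioMatrix,
    axis: str = "samples",
    linkage: str = "average",
    tie_tol: float = 1e-12,
) -> Dendrogram:
    """Agglomerative clustering on the dissimilarity 1 - Pearson r.

    Items are canonicalised to id order before clustering, so the tree
    is invariant to input column/row permutations; equidistant merges
    are broken by the lexicographically smallest pair of cluster
    representative ids.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError("linkage must be average, complete or single")
    corr = pearson_matrix(matrix, axis=axis)
    order = np.argsort(corr.ids, kind="stable")
    labels = [corr.ids[i] for i in order]
    dist = 1.0 - corr.r[np.ix_(order, order)]

    n = len(labels)
    # active cluster id -> (representative id, member count, scipy index)
    active: dict[int, tuple[str, int]] = {i: (labels[i], 1) for i in range(n)}
    index = {i: i for i in range(n)}
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best_pair, best_dist, best_key = None, np.inf, None
        for pair, dij in d.items():
            i, j = sorted(pair)
            key = tuple(sorted((active[i][0], active[j][0])))
            if dij < best_dist - tie_tol or (
                abs(dij - best_dist) <= tie_tol
                and (best_key is None or key < best_key)
            ):
                best_pair, best_dist, best_key = (i, j), dij, key
        i, j = best_pair
        rep = min(active[i][0], active[j][0])
        size = active[i][1] + active[j][1]
        left, right = sorted((index[i], index[j]))
        merges.append((left, right, float(best_dist), size))
        for k in active:
            if k in (i, j):
                continue
            dik, djk = d[frozenset((i, k))], d[frozenset((j, k))]
            if linkage == "average":
                new = (active[i][1] * dik + active[j][1] * djk) / size
            elif linkage == "complete":
                new = max(dik, djk)
            else:
                new = min(dik, djk)
            d[frozenset((i, k))] = new
            del d[frozenset((j, k))]
        del d[frozenset((i, j))]
        del active[j]
        active[i] = (rep, size)
        index[i] = next_id
        next_id += 1
    return Dendrogram(labels=labels, merges=merges)


def cumulative_fraction(
    scores: pd.Series, groups: dict[str, str]
) -> dict[str, pd.DataFrame]:
    """Per-group ECDF of a per-gene score.

    Returns, per group, a frame of (score, fraction) pairs where
    fraction is the proportion of the group's genes with score <= that
    score; the final fraction is 1.
    """
    by_group: dict[str, list[float]] = {}
    for gene, group in groups.items():
        if gene in scores.index and not np.isnan(scores[gene]):
            by_group.setdefault(group, []).append(float(scores[gene]))
    out = {}
    for group in sorted(set(groups.values())):
        values = sorted(by_group.get(group, []))
        if not values:
            raise EmptyGroupError(f"group {group!r} has no scored genes")
        arr = np.array(values)
        uniq = np.unique(arr)
        frac = np.searchsorted(arr, uniq, side="right") / len(arr)
        out[group] = pd.DataFrame({"score": uniq, "fraction": frac})
    return out


def fraction_enriched(
    scores: pd.Series, groups: dict[str, str], cutoff: float = 0.0
) -> dict[str, float]:
    """Per-group fraction of genes with score strictly above ``cutoff``
    (the "percent enriched" readout of a cumulative-fraction plot)."""
    ecdfs = cumulative_fraction(scores, groups)
    out = {}
    for group, table in ecdfs.items():
        below = table[table["score"] <= cutoff]
        out[group] = float(1.0 - (below["fraction"].iloc[-1] if len(below) else 0.0))
    return out


def boxplot_stats(values) -> BoxStats:
    """Median, quartiles (linear interpolation) and Tukey whiskers."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise InsufficientDataError("boxplot_stats needs >= 1 value")
    q25, med, q75 = np.quantile(arr, [0.25, 0.5, 0.75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return BoxStats(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n=int(arr.size),
    )
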