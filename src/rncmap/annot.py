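"""Hypergeometric over/under-representation of annotation terms.

For a target set of size n drawn from a background of size N, a term
annotated on K background genes and k target genes is scored by the
hypergeometric tail: P(X >= k) for over-representation, P(X <= k) for
under-representation, with X ~ Hypergeometric(N, K, n).  Fold
enrichment is (k/n)/(K/N).  Raw p-values against a fixed alpha are the
default; Bonferroni and Benjamini-Hochberg adjustments are available as
clearly separate options.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import InvalidConfigError
from .setops import ConsistencyError


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # annotated in target
    n: int  # target size
    K: int  # annotated in background
    N: int  # background size
    p: float
    fold: float
    direction: str  # "over" | "under"
    significant: bool = False


def _check_bounds(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise InvalidConfigError(
            f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}"
        )


def hypergeom_pvalue(k: int, K: int, n: int, N: int, direction: str = "over") -> float:
    """Exact hypergeometric tail probability.

    over: P(X >= k); under: P(X <= k).  Computed in log space via the
    survival/distribution functions so small tails stay accurate.
    """
    _check_bounds(k, K, n, N)
    if direction == "over":
        # P(X >= k) = sf(k - 1)
        return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))
    if direction == "under":
        return float(min(stats.hypergeom.cdf(k, N, K, n), 1.0))
    raise ValueError("direction must be 'over' or 'under'")


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): representation in targets over the background rate."""
    if n <= 0 or K <= 0 or N <= 0:
        raise InvalidConfigError("n, K and N must be positive")
    return (k / n) / (K / N)


def enrich_terms(
    targets,
    background: set[str],
    annotations: dict[str, set[str]],
    alpha: float = 0.01,
    direction: str = "over",
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """Test every annotation term for over/under-representation.

    ``annotations`` maps gene_id -> set of terms (only background genes
    are counted).  One result per term with K >= 1, sorted by ascending
    p (ties by term name); results with adjusted/raw p < alpha are
    flagged significant.  ``correction``: None (raw p, default),
    "bonferroni" or "bh".
    """
    target_genes = set(targets.genes)
    if not target_genes <= background:
        raise ConsistencyError("targets must be a subset of the background")
    if correction not in (None, "bonferroni", "bh"):
        raise ValueError("correction must be None, 'bonferroni' or 'bh'")

    term_bg: dict[str, int] = {}
    term_tg: dict[str, int] = {}
    for gene in background:
        for term in annotations.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in target_genes:
                term_tg[term] = term_tg.get(term, 0) + 1

    n, N = len(target_genes), len(background)
    results = []
    for term in sorted(term_bg):
        K = term_bg[term]
        k = term_tg.get(term, 0)
        p = hypergeom_pvalue(k, K, n, N, direction=direction)
        fold = fold_enrichment(k, n, K, N) if n > 0 else 0.0
        results.append(
            EnrichmentResult(
                term=term, k=k, n=n, K=K, N=N, p=p, fold=fold, direction=direction
            )
        )
    results.sort(key=lambda r: (r.p, r.term))

    m = len(results)
    if m:
        if correction == "bonferroni":
            adjusted = [min(r.p * m, 1.0) for r in results]
        elif correction == "bh":
            adjusted = np.minimum.accumulate(
                [r.p * m / (i + 1) for i, r in enumerate(results)][::-1]
            )[::-1]
            adjusted = np.minimum(adjusted, 1.0).tolist()
        else:
            adjusted = [r.p for r in results]
        results = [
            EnrichmentResult(
                term=r.term, k=r.k, n=r.n, K=r.K, N=r.N, p=r.p, fold=r.fold,
                direction=r.direction, significant=bool(a < alpha),
            )
            for r, a in zip(results, adjusted)
        ]
    return results
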