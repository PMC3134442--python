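"""Target-set algebra over called interactomes.

Joint classifications of genes by membership in target sets: the
SRP/membrane quadrants (co- vs post-translational ER targeting routes),
NAC-dependence classes of SRP targets (wild type vs NAC-deleted
strains), NAC dimer substrate assignment from the three subunit target
sets, SS/TM composition of a target set, and category/percentage tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .containers import InvalidConfigError, TargetSet
from .summaries import BoxStats, boxplot_stats

QUADRANTS = ("SRP+/Mem+", "SRP+/Mem-", "SRP-/Mem+", "SRP-/Mem-")
NAC_CLASSES = ("NAC-independent", "NAC-dependent", "Off-target", "none")
DIMERS = (
    "Egd1/Egd2",
    "Btt1/Egd2",
    "Egd2-homodimer",
    "Btt1-homodimer",
    "Egd1-only",
    "unassigned",
)


class ConsistencyError(ValueError):
    """A target set contains genes outside the declared universe."""


class MissingAnnotationError(KeyError):
    """A target gene lacks a required annotation row."""


class EmptyClassError(ValueError):
    """A feature class that must be non-empty is empty."""


def _check_universe(ts: TargetSet, universe: frozenset[str] | set[str]) -> None:
    stray = ts.genes - set(universe)
    if stray:
        raise ConsistencyError(
            f"{len(stray)} genes in {ts.condition!r} outside universe, "
            f"e.g. {sorted(stray)[:3]}"
        )


def quadrant_classify(
    srp: TargetSet, mem: TargetSet, universe: set[str]
) -> pd.Series:
    """SRP+/- x Mem+/- label per universe gene (partition of the universe)."""
    _check_universe(srp, universe)
    _check_universe(mem, universe)
    labels = {}
    for gene in universe:
        s = "+" if gene in srp else "-"
        m = "+" if gene in mem else "-"
        labels[gene] = f"SRP{s}/Mem{m}"
    return pd.Series(labels, name="quadrant").sort_index()


def nac_dependence(
    srp_wt: TargetSet, srp_dnac: TargetSet, universe: set[str]
) -> pd.Series:
    """NAC-dependence class per universe gene.

    In both strains -> NAC-independent; wild type only -> NAC-dependent;
    NAC-deleted only -> Off-target; neither -> none.
    """
    _check_universe(srp_wt, universe)
    _check_universe(srp_dnac, universe)
    labels = {}
    for gene in universe:
        in_wt, in_d = gene in srp_wt, gene in srp_dnac
        if in_wt and in_d:
            labels[gene] = "NAC-independent"
        elif in_wt:
            labels[gene] = "NAC-dependent"
        elif in_d:
            labels[gene] = "Off-target"
        else:
            labels[gene] = "none"
    return pd.Series(labels, name="nac_class").sort_index()


def dimer_assign(
    egd1: TargetSet, egd2: TargetSet, btt1: TargetSet
) -> pd.Series:
    """Assign NAC targets to the dimer they most plausibly report on.

    Targets shared by a beta subunit and the alpha subunit Egd2 are
    heterodimer substrates; targets unique to Egd2 or Btt1 are homodimer
    substrates.  Genes in all three sets go to Egd1/Egd2 (the dominant
    heterodimer in vivo).
    """
    labels = {}
    for gene in egd1.genes | egd2.genes | btt1.genes:
        in1, in2, inb = gene in egd1, gene in egd2, gene in btt1
        if in1 and in2:
            labels[gene] = "Egd1/Egd2"
        elif in2 and inb:
            labels[gene] = "Btt1/Egd2"
        elif in2:
            labels[gene] = "Egd2-homodimer"
        elif in1 and inb:
            # two beta subunits, no alpha: no dimer is defined
            labels[gene] = "unassigned"
        elif inb:
            labels[gene] = "Btt1-homodimer"
        else:
            labels[gene] = "Egd1-only"
    return pd.Series(labels, name="dimer", dtype=object).sort_index()


def sstm_fraction(
    targets: TargetSet, annotations: pd.DataFrame
) -> dict[str, float]:
    """SS/TM composition of a target set.

    Returns fractions (summing to 1) of targets whose protein has only a
    signal sequence, only transmembrane segments, both, or neither.
    ``annotations`` is the gene table with boolean ``has_ss``/``has_tm``
    columns indexed by gene_id.
    """
    missing = targets.genes - set(annotations.index)
    if missing:
        raise MissingAnnotationError(
            f"unannotated target genes, e.g. {sorted(missing)[:3]}"
        )
    if not targets.genes:
        return {"ss_only": 0.0, "tm_only": 0.0, "both": 0.0, "neither": 0.0}
    sub = annotations.loc[sorted(targets.genes)]
    ss = sub["has_ss"].to_numpy(bool)
    tm = sub["has_tm"].to_numpy(bool)
    n = len(sub)
    return {
        "ss_only": float((ss & ~tm).sum()) / n,
        "tm_only": float((~ss & tm).sum()) / n,
        "both": float((ss & tm).sum()) / n,
        "neither": float((~ss & ~tm).sum()) / n,
    }


def round_percent(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (table convention)."""
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CategoryTable:
    """Per-category counts and percentages of a target set.

    Genes can belong to several categories, so counts may sum to more
    than ``total``; percentages use the stated total, not the row sum.
    """

    rows: pd.DataFrame  # columns: category, count, percent, genes
    total: int


def category_table(
    targets: TargetSet,
    category_map: dict[str, set[str]],
    total: int | None = None,
) -> CategoryTable:
    """Count target genes per annotation category, with percentages.

    ``category_map`` maps gene_id -> set of category names (multi-
    membership counts once per category).  ``total`` defaults to the
    target-set size and is the denominator for percentages.
    """
    if total is None:
        total = len(targets.genes)
    if total < 1:
        raise InvalidConfigError("total must be >= 1")
    per_category: dict[str, list[str]] = {}
    for gene in sorted(targets.genes):
        for cat in category_map.get(gene, ()):
            per_category.setdefault(cat, []).append(gene)
    rows = pd.DataFrame(
        {
            "category": list(per_category),
            "count": [len(v) for v in per_category.values()],
            "genes": [sorted(v) for v in per_category.values()],
        }
    )
    rows["percent"] = [round_percent(c, total) for c in rows["count"]]
    rows = rows.sort_values(
        ["count", "category"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)[["category", "count", "percent", "genes"]]
    return CategoryTable(rows=rows, total=total)


def category_table_from_counts(
    counts: dict[str, int], total: int
) -> CategoryTable:
    """CategoryTable straight from per-category gene counts (no gene lists)."""
    if total < 1:
        raise InvalidConfigError("total must be >= 1")
    rows = pd.DataFrame(
        {
            "category": list(counts),
            "count": list(counts.values()),
            "genes": [[] for _ in counts],
        }
    )
    rows["percent"] = [round_percent(c, total) for c in rows["count"]]
    rows = rows.sort_values(
        ["count", "category"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)[["category", "count", "percent", "genes"]]
    return CategoryTable(rows=rows, total=total)


def enrichment_distribution(
    classes: dict[str, set[str]], scores: pd.Series
) -> dict[str, BoxStats]:
    """Box-plot summary of a per-gene score within each feature class.

    Typical use: distribution of the SAM d score among targets with a
    predicted SS, a TM, or neither.
    """
    out = {}
    for name, members in classes.items():
        values = scores.reindex(sorted(members)).dropna().to_numpy()
        if len(values) == 0:
            raise EmptyClassError(f"class {name!r} has no scored members")
        out[name] = boxplot_stats(values)
    return out
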