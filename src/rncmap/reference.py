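"""Published category-count tables shipped as worked-example inputs.

Two interactome category tables from the original yeast study are
bundled as plain counts: GO-component categories of (i) the 213 SRP
targets lacking a predicted signal sequence or transmembrane region and
(ii) the 541 membrane-associated mRNAs not enriched with SRP
(Mem+/SRP-).  :func:`load_reference_table` recomputes the percentage
column from the counts and the printed totals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .setops import CategoryTable, category_table_from_counts

#: table name -> (resource file, total set size)
REFERENCE_TABLES = {
    "srp_no_sstm": ("srp_no_sstm_categories.tsv", 213),
    "mem_only": ("mem_only_categories.tsv", 541),
}


def load_reference_counts(name: str) -> tuple[dict[str, int], int]:
    """Per-category gene counts and the total set size."""
    try:
        filename, total = REFERENCE_TABLES[name]
    except KeyError:
        raise KeyError(
            f"unknown reference table {name!r}; choose from {sorted(REFERENCE_TABLES)}"
        ) from None
    with resources.files("rncmap.data").joinpath(filename).open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    return dict(zip(frame["category"], frame["count"])), total


def load_reference_table(name: str) -> CategoryTable:
    """CategoryTable with percentages recomputed from the stored counts."""
    counts, total = load_reference_counts(name)
    return category_table_from_counts(counts, total)
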