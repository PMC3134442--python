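#!/usr/bin/env python
"""Annotation-term enrichment of the called interactomes.

Hypergeometric over-representation of localization terms in each
bait's target set against the translatome background (the ribosomal-
bait universe), reported with fold enrichment.  Secretory terms should
dominate the SRP interactome; mitochondrial terms the Btt1 set.

Run after 02_call_targets.py.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from rncmap import io as rio
from rncmap.annot import enrich_terms
from rncmap.containers import TargetSet

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = ROOT / "results" / "study"
    targets_dir = ROOT / "results" / "targets"
    if not targets_dir.exists():
        raise SystemExit("run analysis/02_call_targets.py first")
    out = ROOT / "results" / "enrichment"
    out.mkdir(exist_ok=True)

    annotations = rio.read_annotations(study / "annotations.tsv")
    background = set(rio.read_target_set(study / "translatome.txt").genes)
    term_map = {
        g: {annotations.loc[g, "localization"]} for g in background
    }

    for bait in ("Srp54", "Btt1", "Mem"):
        ts = rio.read_target_set(targets_dir / f"{bait}.txt")
        clipped = TargetSet(ts.condition, ts.q_threshold,
                            frozenset(ts.genes & background))
        results = enrich_terms(clipped, background, term_map, alpha=0.01)
        frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
        frame.to_csv(out / f"{bait}_localization.tsv", sep="\t", index=False)
        top = [r for r in results if r.significant and r.fold > 1][:3]
        summary = ", ".join(
            f"{r.term} ({r.fold:.1f}x, p={r.p:.2g})" for r in top
        ) or "none"
        print(f"{bait}: over-represented terms vs translatome: {summary}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
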