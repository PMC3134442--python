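#!/usr/bin/env python
"""Interactome set algebra: quadrants, NAC dependence, dimer substrates.

Combines the per-bait target sets into the joint classifications the
study design supports: SRP x membrane quadrants (co- vs
post-translational ER routes), NAC-dependence of SRP binding (wild type
vs deletion strain), NAC dimer substrate assignment, and the SS/TM
composition of each SRP interactome.  Scores every classification
against the planted truth.

Run after 02_call_targets.py.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from rncmap import io as rio
from rncmap.containers import TargetSet
from rncmap.setops import (
    dimer_assign,
    nac_dependence,
    quadrant_classify,
    sstm_fraction,
)
from rncmap.synth import StudyConfig, simulate_study

ROOT = Path(__file__).resolve().parents[1]


def clip(ts, universe):
    return TargetSet(ts.condition, ts.q_threshold, frozenset(ts.genes & universe))


def balanced_accuracy(predicted: pd.Series, truth: pd.Series) -> float:
    recalls = [
        (predicted[truth[truth == c].index] == c).mean()
        for c in sorted(truth.unique())
    ]
    return float(np.mean(recalls))


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    study = ROOT / "results" / "study"
    targets_dir = ROOT / "results" / "targets"
    if not targets_dir.exists():
        raise SystemExit("run analysis/02_call_targets.py first")
    out = ROOT / "results" / "classes"
    out.mkdir(exist_ok=True)

    targets = {
        p.stem: rio.read_target_set(p)
        for p in targets_dir.glob("*.txt")
    }
    annotations = rio.read_annotations(study / "annotations.tsv")
    universe = set(rio.read_target_set(study / "translatome.txt").genes)

    quad = quadrant_classify(
        clip(targets["Srp54"], universe), clip(targets["Mem"], universe), universe
    )
    nac = nac_dependence(
        clip(targets["Srp54"], universe),
        clip(targets["Srp54-dNAC"], universe),
        universe,
    )
    dimers = dimer_assign(targets["Egd1"], targets["Egd2"], targets["Btt1"])
    labels = pd.DataFrame({"quadrant": quad, "nac_class": nac})
    labels["dimer"] = dimers.reindex(labels.index)
    labels.index.name = "gene_id"
    labels.to_csv(out / "labels.tsv", sep="\t")

    # score against the planted truth (regenerated from the same seed)
    bundle = simulate_study(StudyConfig(), seed=args.seed)
    q_acc = balanced_accuracy(quad, bundle.planted_quadrants())
    n_acc = balanced_accuracy(nac, bundle.planted_nac_classes())

    print("quadrant counts:", quad.value_counts().to_dict())
    print("NAC-dependence counts:", nac.value_counts().to_dict())
    print("dimer counts:", dimers.value_counts().to_dict())
    print(f"balanced accuracy vs planted truth: quadrants {q_acc:.1%}, "
          f"NAC classes {n_acc:.1%}")
    for bait in ("Srp54", "Srp54-dNAC"):
        frac = sstm_fraction(targets[bait], annotations)
        print(f"{bait}: SS/TM-bearing fraction "
              f"{1 - frac['neither']:.1%} (ss_only {frac['ss_only']:.1%}, "
              f"tm_only {frac['tm_only']:.1%}, both {frac['both']:.1%})")
    print(f"wrote {out / 'labels.tsv'}")


if __name__ == "__main__":
    main()
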