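#!/usr/bin/env python
"""Sequence features of the called SRP interactome.

Computes Kyte-Doolittle hydropathy features (whole-protein mean,
N-terminal window-11 mean over the first 50 residues, hydrophobic
stretches) for every synthetic protein and contrasts SRP targets with
the rest of the translatome: SRP targets should be markedly more
hydrophobic at the N terminus and almost always carry a stretch.

Run after 02_call_targets.py.
"""

from pathlib import Path

import pandas as pd

from rncmap import io as rio
from rncmap.hydropathy import (
    find_stretches,
    first_stretch_length,
    hydropathy_profile,
    mean_hydrophobicity,
    nterm_hydrophobicity,
)
from rncmap.summaries import boxplot_stats

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = ROOT / "results" / "study"
    targets_dir = ROOT / "results" / "targets"
    if not targets_dir.exists():
        raise SystemExit("run analysis/02_call_targets.py first")
    out = ROOT / "results" / "features"
    out.mkdir(exist_ok=True)

    sequences = rio.read_fasta(study / "proteome.fasta")
    srp = rio.read_target_set(targets_dir / "Srp54.txt").genes
    translatome = rio.read_target_set(study / "translatome.txt").genes

    rows = []
    for gene, seq in sequences.items():
        profile = hydropathy_profile(seq, sequence_id=gene)
        stretches = find_stretches(profile)
        rows.append(
            {
                "gene_id": gene,
                "length": len(seq),
                "mean_hydrophobicity": mean_hydrophobicity(seq),
                "nterm_hydrophobicity": nterm_hydrophobicity(seq),
                "n_stretches": len(stretches),
                "first_stretch_length": first_stretch_length(seq),
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    table.to_csv(out / "protein_features.tsv", sep="\t")

    groups = {
        "SRP targets": table.loc[sorted(srp & set(table.index))],
        "translatome, non-SRP": table.loc[sorted(translatome - srp)],
    }
    print(f"{'group':<22} {'n':>5} {'nterm KD median':>16} {'with stretch':>13}")
    for name, sub in groups.items():
        box = boxplot_stats(sub["nterm_hydrophobicity"])
        with_stretch = (sub["n_stretches"] > 0).mean()
        print(f"{name:<22} {len(sub):>5} {box.median:>16.2f} {with_stretch:>12.1%}")
    lengths = groups["SRP targets"]["first_stretch_length"].dropna()
    print(f"first-stretch length among SRP targets: "
          f"median {lengths.median():.0f} (n={len(lengths)})")
    print(f"wrote {out / 'protein_features.tsv'}")


if __name__ == "__main__":
    main()
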