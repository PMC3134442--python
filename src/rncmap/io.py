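"""Readers and writers for every file the pipeline touches.

Everything is plain text: tab-separated tables (empty cell = missing),
FASTA for protein sequences, JSON for planted truth and manifests.
Writers emit provenance headers (``# key: value`` comment lines) where
the format tolerates them, so any output can be traced to the seed and
thresholds that produced it.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import FormatError, GeneRecord, RatioMatrix, SyntheticTruth, TargetSet

FASTA_WRAP = 60


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences by id; lowercase residues are uppercased with a warning."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA id {record.id!r}")
        seq = str(record.seq)
        if not seq:
            raise FormatError(f"empty FASTA record {record.id!r}")
        if not seq.isupper():
            warnings.warn(f"uppercasing residues in {record.id!r}", stacklevel=2)
            seq = seq.upper()
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return sequences


def write_matrix(matrix: RatioMatrix, path: str | Path) -> None:
    """RatioMatrix TSV: first column gene_id, header row sample ids,
    empty cell = missing."""
    out = matrix.data.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_matrix(path: str | Path, condition: str = "") -> RatioMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if frame.columns[0] != "gene_id":
        raise FormatError("first matrix column must be 'gene_id'")
    if frame["gene_id"].duplicated().any():
        raise FormatError("duplicate gene ids in matrix file")
    frame = frame.set_index("gene_id")
    frame.index.name = None
    return RatioMatrix(frame, condition=condition)


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene_id", "localization", "has_ss", "has_tm", "abundance", "translation_rate"]
    annotations[cols].to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str}, true_values=["True"], false_values=["False"]
    )
    required = {"gene_id", "localization", "has_ss", "has_tm"}
    if not required <= set(frame.columns):
        raise FormatError(f"annotation file missing columns {sorted(required - set(frame.columns))}")
    if frame["gene_id"].duplicated().any():
        raise FormatError("duplicate gene ids in annotation file")
    return frame.set_index("gene_id", drop=False)


def write_sam_result(result, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# condition: {result.condition}\n")
        fh.write(f"# s0: {result.s0!r}\n")
        fh.write(f"# n_permutations: {result.n_permutations}\n")
        result.to_frame().to_csv(fh, sep="\t", index=False)


def write_target_set(ts: TargetSet, path: str | Path, **provenance) -> None:
    """One gene per line, with a header comment recording condition and
    threshold (plus any extra provenance keys)."""
    with open(path, "w") as fh:
        fh.write(f"# condition: {ts.condition}\n")
        fh.write(f"# q_threshold: {ts.q_threshold}\n")
        for key, value in provenance.items():
            fh.write(f"# {key}: {value}\n")
        for gene in sorted(ts.genes):
            fh.write(f"{gene}\n")


def read_target_set(path: str | Path) -> TargetSet:
    condition, q_threshold = "", 0.0
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            key = key.strip()
            if key == "condition":
                condition = value.strip()
            elif key == "q_threshold":
                q_threshold = float(value)
            continue
        genes.append(line)
    if len(genes) != len(set(genes)):
        raise FormatError("duplicate genes in target-set file")
    return TargetSet(condition=condition, q_threshold=q_threshold, genes=frozenset(genes))


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "bait_id": truth.bait_id,
        "planted_targets": sorted(truth.planted_targets),
        "effect_size": truth.effect_size,
        "noise_sd": truth.noise_sd,
        "missing_rate": truth.missing_rate,
        "n_replicates": truth.n_replicates,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    payload["planted_targets"] = frozenset(payload["planted_targets"])
    return SyntheticTruth(**payload)


def read_category_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, category/term) -> gene_id -> set of terms."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise FormatError("category map needs two columns (gene_id, category)")
    gene_col, cat_col = frame.columns[:2]
    out: dict[str, set[str]] = {}
    for gene, cat in zip(frame[gene_col], frame[cat_col]):
        out.setdefault(gene, set()).add(cat)
    return out


def write_category_map(mapping: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        {"gene_id": gene, "category": cat}
        for gene in sorted(mapping)
        for cat in sorted(mapping[gene])
    ]
    pd.DataFrame(rows, columns=["gene_id", "category"]).to_csv(path, sep="\t", index=False)
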