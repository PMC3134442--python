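"""Core data containers shared across the pipeline.

The pipeline moves three kinds of objects around: gene-level annotation
records, replicated log2(IP/reference) ratio matrices, and the derived
per-gene statistics / target sets.  Matrices are thin wrappers around a
pandas DataFrame (rows = genes, columns = replicate samples, NaN =
missing measurement) so that standard pandas operations remain available
while the wrapper enforces the invariants the statistics rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOCALIZATIONS = (
    "ER",
    "Golgi",
    "plasma-membrane",
    "mitochondrion",
    "nucleus",
    "cytosol",
    "vacuole",
    "unknown",
)

#: localization classes treated as secretory-pathway for annotation purposes
SECRETORY_LOCALIZATIONS = frozenset({"ER", "Golgi", "plasma-membrane", "vacuole"})


class InvalidConfigError(ValueError):
    """A generator or pipeline configuration violates its preconditions."""


class FormatError(ValueError):
    """An input file or table does not match the expected layout."""


class InsufficientDataError(ValueError):
    """Not enough observations to compute the requested statistic."""


@dataclass(frozen=True)
class GeneRecord:
    """Annotation for one gene: where its protein lives and how it is made.

    ``has_ss`` / ``has_tm`` are the binary signal-sequence / transmembrane
    predictions consumed as annotations; ``abundance`` (mRNA copies) and
    ``translation_rate`` are arbitrary-unit positive covariates.
    """

    gene_id: str
    localization: str
    has_ss: bool
    has_tm: bool
    abundance: float
    translation_rate: float
    sequence_id: str

    def __post_init__(self) -> None:
        if self.localization not in LOCALIZATIONS:
            raise InvalidConfigError(
                f"unknown localization {self.localization!r} for {self.gene_id}"
            )
        if not self.abundance > 0:
            raise InvalidConfigError(f"abundance must be > 0 for {self.gene_id}")
        if not self.translation_rate > 0:
            raise InvalidConfigError(
                f"translation_rate must be > 0 for {self.gene_id}"
            )


def genome_to_frame(genome: list[GeneRecord]) -> pd.DataFrame:
    """Annotation table (one row per gene, indexed by gene_id)."""
    frame = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genome],
            "localization": [g.localization for g in genome],
            "has_ss": [g.has_ss for g in genome],
            "has_tm": [g.has_tm for g in genome],
            "abundance": [g.abundance for g in genome],
            "translation_rate": [g.translation_rate for g in genome],
            "sequence_id": [g.sequence_id for g in genome],
        }
    )
    return frame.set_index("gene_id", drop=False)


class RatioMatrix:
    """Gene x replicate matrix of log2(IP/reference) ratios.

    NaN entries mark missing measurements.  ``condition`` names the bait
    or fraction the replicates belong to (e.g. ``"Srp54"``).
    """

    def __init__(self, data: pd.DataFrame, condition: str = "") -> None:
        if data.index.has_duplicates:
            raise FormatError("duplicate gene ids in ratio matrix")
        if data.columns.has_duplicates:
            raise FormatError("duplicate sample ids in ratio matrix")
        self.data = data.astype(float)
        self.condition = condition

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "RatioMatrix":
        return RatioMatrix(self.data.copy(), self.condition)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"RatioMatrix(condition={self.condition!r}, "
            f"genes={self.n_genes}, replicates={self.n_replicates})"
        )


@dataclass
class SamResult:
    """Per-gene moderated one-class t statistics and q-values (percent).

    ``d = mean / (se + s0)`` with the per-gene mean and standard error
    computed over non-missing replicates; ``q`` is on the 0-100 percent
    scale used for FDR thresholds.
    """

    gene_ids: list[str]
    d: np.ndarray
    s: np.ndarray
    q: np.ndarray
    s0: float
    n_permutations: int
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "d": self.d, "s": self.s, "q": self.q}
        ).set_index("gene_id", drop=False)


@dataclass
class TargetSet:
    """Genes called enriched for one bait/condition at a q threshold."""

    condition: str
    q_threshold: float
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.q_threshold < 0:
            raise InvalidConfigError("q_threshold must be >= 0")
        self.genes = frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one simulated immunopurification."""

    bait_id: str
    planted_targets: frozenset[str]
    effect_size: float
    noise_sd: float
    missing_rate: float
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise InvalidConfigError("effect_size must be >= 0")
        if not self.noise_sd > 0:
            raise InvalidConfigError("noise_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if self.n_replicates < 2:
            raise InvalidConfigError("n_replicates must be >= 2")
        object.__setattr__(self, "planted_targets", frozenset(self.planted_targets))
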