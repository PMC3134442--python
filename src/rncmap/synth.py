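"""Synthetic study generator with known planted ground truth.

Generates a small yeast-like genome (localization, SS/TM flags,
abundance, translation rate, protein sequences) and replicated
log2(IP/reference) ratio matrices for a roster of baits that mirrors
the study design: two ribosomal baits capturing the translatome, SRP in
wild-type and NAC-deleted cells, the three NAC subunits, and a membrane
fraction.  Each bait has a planted target set whose entries receive a
positive mean log-ratio shift on top of Gaussian replicate noise with
missing-completely-at-random dropouts, so every downstream stage can be
scored against known truth.

Determinism: one global integer seed; each bait's random stream is
seeded by the low 31 bits of SHA-256("<seed>/<purpose>/<bait>"), so
adding or removing a bait never perturbs the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    GeneRecord,
    InvalidConfigError,
    RatioMatrix,
    SECRETORY_LOCALIZATIONS,
    SyntheticTruth,
    genome_to_frame,
)

#: background residues (all Kyte-Doolittle <= -0.4) guarantee that no
#: accidental window-7 mean ever exceeds the stretch threshold of 1
BACKGROUND_ALPHABET = "STNQGPDEKR"
STRETCH_RESIDUES = "IVL"

#: genome composition: fractions of each localization class
DEFAULT_COMPOSITION = {
    "cytosol": 0.40,
    "nucleus": 0.15,
    "mitochondrion": 0.15,
    "ER": 0.10,
    "plasma-membrane": 0.07,
    "Golgi": 0.03,
    "vacuole": 0.03,
    "unknown": 0.07,
}

BAITS = ("Rpl16", "Rpl17", "Egd2", "Egd1", "Btt1", "Srp54", "Srp54-dNAC", "Mem")


def derive_seed(seed: int, *keys: str) -> int:
    """Stable per-purpose child seed (low 31 bits of a SHA-256 digest)."""
    tag = "/".join([str(seed), *keys]).encode()
    return int.from_bytes(hashlib.sha256(tag).digest()[:4], "little") & 0x7FFFFFFF


def generate_protein(
    length: int,
    stretch_spec: list[tuple[int, int, str]] | None = None,
    seed: int = 0,
) -> str:
    """Amino-acid string with planted hydrophobic stretches.

    ``stretch_spec`` entries are (start, length, residue) with 1-based
    inclusive starts; planted positions carry the given high-hydropathy
    residue, everything else is drawn from the low-hydropathy background
    alphabet so no spurious stretch can arise.
    """
    if length < 1:
        raise InvalidConfigError("protein length must be >= 1")
    stretch_spec = stretch_spec or []
    occupied = np.zeros(length, dtype=bool)
    for start, slen, residue in stretch_spec:
        if slen < 1 or start < 1 or start + slen - 1 > length:
            raise InvalidConfigError(
                f"stretch ({start}, {slen}) outside [1, {length}]"
            )
        span = slice(start - 1, start - 1 + slen)
        if occupied[span].any():
            raise InvalidConfigError("overlapping planted stretches")
        occupied[span] = True
    rng = np.random.default_rng(seed)
    residues = rng.choice(list(BACKGROUND_ALPHABET), size=length)
    for start, slen, residue in stretch_spec:
        residues[start - 1 : start - 1 + slen] = residue
    return "".join(residues)


@dataclass(frozen=True)
class GenomeParams:
    """Knobs for the genome generator (probabilities and log-normal scales)."""

    ss_prob: float = 0.45  # P(has_ss) for secretory-localized genes
    tm_prob: float = 0.65  # P(has_tm) for secretory-localized genes
    background_sstm_prob: float = 0.02  # P(has_ss or has_tm) elsewhere
    abundance_mu: float = 3.0  # log-normal location, arbitrary mRNA copies
    abundance_sigma: float = 1.2
    translation_mu: float = 0.0  # log-normal location, arbitrary units
    translation_sigma: float = 0.8
    min_protein_length: int = 120
    max_protein_length: int = 600
    stretch_min: int = 12  # planted residue-run lengths for SS/TM genes
    stretch_max: int = 21


def generate_genome(
    n_genes: int,
    composition: dict[str, float] | None = None,
    seed: int = 0,
    params: GenomeParams = GenomeParams(),
) -> tuple[list[GeneRecord], dict[str, str]]:
    """Gene table plus protein sequences for a synthetic genome.

    Localizations are a multinomial draw from ``composition``;
    secretory-class genes receive SS/TM flags with the configured
    probabilities, and every SS/TM-flagged gene's protein carries at
    least one planted N-terminal hydrophobic stretch.  Abundance and
    translation rate are log-normal.
    """
    if n_genes < 1:
        raise InvalidConfigError("n_genes must be >= 1")
    composition = dict(composition or DEFAULT_COMPOSITION)
    unknown = set(composition) - set(DEFAULT_COMPOSITION)
    if unknown:
        raise InvalidConfigError(f"unknown localization classes: {sorted(unknown)}")
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9:
        raise InvalidConfigError(f"composition fractions sum to {total}, not 1")

    rng = np.random.default_rng(seed)
    classes = sorted(composition)
    probs = np.array([composition[c] for c in classes])
    localizations = rng.choice(classes, size=n_genes, p=probs)
    width = max(4, len(str(n_genes)))

    genome: list[GeneRecord] = []
    sequences: dict[str, str] = {}
    for i in range(n_genes):
        gene_id = f"G{i + 1:0{width}d}"
        loc = str(localizations[i])
        if loc in SECRETORY_LOCALIZATIONS:
            has_ss = bool(rng.random() < params.ss_prob)
            has_tm = bool(rng.random() < params.tm_prob)
        else:
            has_ss = bool(rng.random() < params.background_sstm_prob)
            has_tm = bool(rng.random() < params.background_sstm_prob)
        abundance = float(rng.lognormal(params.abundance_mu, params.abundance_sigma))
        rate = float(rng.lognormal(params.translation_mu, params.translation_sigma))
        length = int(rng.integers(params.min_protein_length, params.max_protein_length + 1))
        spec = []
        if has_ss or has_tm:
            slen = int(rng.integers(params.stretch_min, params.stretch_max + 1))
            start = int(rng.integers(3, 12))
            residue = str(rng.choice(list(STRETCH_RESIDUES)))
            spec.append((start, slen, residue))
            if has_tm and length > start + slen + 80:
                # internal TM-like second stretch
                slen2 = int(rng.integers(params.stretch_min, params.stretch_max + 1))
                start2 = int(rng.integers(start + slen + 20, length - slen2))
                spec.append((start2, slen2, str(rng.choice(list(STRETCH_RESIDUES)))))
        sequences[gene_id] = generate_protein(
            length, spec, seed=derive_seed(seed, "protein", gene_id)
        )
        genome.append(
            GeneRecord(
                gene_id=gene_id,
                localization=loc,
                has_ss=has_ss,
                has_tm=has_tm,
                abundance=abundance,
                translation_rate=rate,
                sequence_id=gene_id,
            )
        )
    return genome, sequences


def simulate_ip(genome: list[GeneRecord], truth: SyntheticTruth) -> RatioMatrix:
    """Replicated log-ratio matrix for one immunopurification.

    Entry (g, r) = effect_size * 1[g planted] + N(0, noise_sd^2); each
    entry is independently missing with probability missing_rate.
    """
    gene_ids = [g.gene_id for g in genome]
    stray = truth.planted_targets - set(gene_ids)
    if stray:
        raise InvalidConfigError(
            f"planted targets outside genome, e.g. {sorted(stray)[:3]}"
        )
    rng = np.random.default_rng(truth.seed)
    n, r = len(gene_ids), truth.n_replicates
    shift = np.array([g.gene_id in truth.planted_targets for g in genome], float)
    values = truth.effect_size * shift[:, None] + rng.normal(0.0, truth.noise_sd, (n, r))
    if truth.missing_rate > 0:
        values[rng.random((n, r)) < truth.missing_rate] = np.nan
    data = pd.DataFrame(
        values,
        index=gene_ids,
        columns=[f"{truth.bait_id}_r{i + 1}" for i in range(r)],
    )
    return RatioMatrix(data, condition=truth.bait_id)


@dataclass(frozen=True)
class StudyConfig:
    """Study-level simulation settings.

    Defaults are the conditions the downstream calibration tests run
    under: 1000 genes, 4 replicates per bait, planted shift 2.0 against
    replicate noise 0.5 (signal-to-noise 4), 5% random dropout.
    """

    n_genes: int = 1000
    baits: tuple[str, ...] = BAITS
    effect_size: float = 2.0
    noise_sd: float = 0.5
    missing_rate: float = 0.05
    n_replicates: int = 4
    composition: dict[str, float] | None = None
    genome_params: GenomeParams = GenomeParams()
    translatome_quantile: float = 0.40  # translation-rate cutoff quantile
    #: non-canonical SRP targets (no SS/TM) as a fraction of the SS/TM
    #: target count; 0.43 leaves ~70% of SRP-WT targets SS/TM-bearing
    noncanonical_srp_frac: float = 0.43
    nac_dependent_frac: float = 0.30  # low-abundance share of SRP-WT lost in dNAC
    #: cytosolic off-target gain in the NAC deletion, relative to |SRP-WT|;
    #: 0.40 drives the SS/TM share of the deletion-strain interactome to ~45%
    off_target_frac: float = 0.40
    egd2_frac: float = 0.90  # share of translatome bound by Egd2
    egd1_of_egd2: float = 0.85  # Egd1 overlap with Egd2
    btt1_extra_frac: float = 0.20  # non-mitochondrial share of Btt1 targets
    mem_mito_prob: float = 0.70  # P(mitochondrial translatome gene in Mem)
    effect_overrides: tuple[tuple[str, float], ...] = ()

    def effect_for(self, bait: str) -> float:
        return dict(self.effect_overrides).get(bait, self.effect_size)


@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    genome: list[GeneRecord]
    sequences: dict[str, str]
    annotations: pd.DataFrame
    matrices: dict[str, RatioMatrix]
    truths: dict[str, SyntheticTruth]
    translatome: frozenset[str] = field(default_factory=frozenset)

    def planted_nac_classes(self) -> pd.Series:
        """Ground-truth NAC-dependence class per translatome gene."""
        wt = self.truths["Srp54"].planted_targets
        dn = self.truths["Srp54-dNAC"].planted_targets
        labels = {}
        for gene in sorted(self.translatome):
            if gene in wt and gene in dn:
                labels[gene] = "NAC-independent"
            elif gene in wt:
                labels[gene] = "NAC-dependent"
            elif gene in dn:
                labels[gene] = "Off-target"
            else:
                labels[gene] = "none"
        return pd.Series(labels, name="nac_class")

    def planted_quadrants(self) -> pd.Series:
        """Ground-truth SRP/Mem quadrant per translatome gene."""
        srp = self.truths["Srp54"].planted_targets
        mem = self.truths["Mem"].planted_targets
        labels = {}
        for gene in sorted(self.translatome):
            s = "+" if gene in srp else "-"
            m = "+" if gene in mem else "-"
            labels[gene] = f"SRP{s}/Mem{m}"
        return pd.Series(labels, name="quadrant")


def _pick(rng: np.random.Generator, pool: list[str], k: int) -> set[str]:
    k = min(k, len(pool))
    if k <= 0:
        return set()
    return set(rng.choice(sorted(pool), size=k, replace=False))


def plant_target_sets(
    annotations: pd.DataFrame, config: StudyConfig, seed: int
) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    """Planted target sets per bait, plus the planted translatome.

    Structure: the ribosomal baits capture the translatome (genes above
    the translation-rate quantile).  SRP-WT targets are the SS/TM-
    bearing translatome genes plus a small non-canonical remainder.
    SRP in the NAC-deleted strain loses a low-abundance "NAC-dependent"
    subset of the WT set and gains a high-abundance cytosolic
    "off-target" subset.  The membrane fraction holds the secretory
    genes plus most mitochondrial genes.  NAC subunit sets overlap as
    Egd1 ~ Egd2 >> Btt1, with Egd2 covering nearly the whole translatome
    and Btt1 biased to mitochondrial genes.
    """
    rng = np.random.default_rng(derive_seed(seed, "plant"))
    ann = annotations
    rate_cut = ann["translation_rate"].quantile(config.translatome_quantile)
    translatome = set(ann.index[ann["translation_rate"] > rate_cut])

    sstm = set(ann.index[(ann["has_ss"] | ann["has_tm"])]) & translatome
    non_sstm = sorted(translatome - sstm)
    srp_wt = sstm | _pick(rng, non_sstm, round(config.noncanonical_srp_frac * len(sstm)))

    by_abundance = ann.loc[sorted(srp_wt)].sort_values("abundance")
    n_dep = round(config.nac_dependent_frac * len(srp_wt))
    nac_dependent = set(by_abundance.index[:n_dep])
    cytosolic = ann.index[(ann["localization"] == "cytosol")]
    cyto_pool = (
        ann.loc[sorted(set(cytosolic) & translatome - srp_wt)]
        .sort_values("abundance", ascending=False)
    )
    n_off = round(config.off_target_frac * len(srp_wt))
    off_target = set(cyto_pool.index[: 2 * n_off])
    off_target = _pick(rng, sorted(off_target), n_off)
    srp_dnac = (srp_wt - nac_dependent) | off_target

    secretory = set(
        ann.index[ann["localization"].isin(sorted(SECRETORY_LOCALIZATIONS))]
    )
    mito = set(ann.index[ann["localization"] == "mitochondrion"]) & translatome
    mem = (secretory & translatome) | sstm
    mem |= {g for g in sorted(mito) if rng.random() < config.mem_mito_prob}

    egd2 = _pick(rng, sorted(translatome), round(config.egd2_frac * len(translatome)))
    egd1 = _pick(rng, sorted(egd2), round(config.egd1_of_egd2 * len(egd2)))
    btt1 = mito | _pick(
        rng, sorted(translatome - mito), round(config.btt1_extra_frac * len(mito))
    )

    planted = {
        "Rpl16": frozenset(translatome),
        "Rpl17": frozenset(translatome),
        "Egd2": frozenset(egd2),
        "Egd1": frozenset(egd1),
        "Btt1": frozenset(btt1),
        "Srp54": frozenset(srp_wt),
        "Srp54-dNAC": frozenset(srp_dnac),
        "Mem": frozenset(mem),
    }
    return planted, frozenset(translatome)


def simulate_study(config: StudyConfig = StudyConfig(), seed: int = 0) -> StudyBundle:
    """Simulate the full multi-bait study with known planted truth."""
    if not config.baits:
        raise InvalidConfigError("config names no baits")
    unknown = set(config.baits) - set(BAITS)
    if unknown:
        raise InvalidConfigError(f"unknown baits: {sorted(unknown)}")

    genome, sequences = generate_genome(
        config.n_genes,
        composition=config.composition,
        seed=derive_seed(seed, "genome"),
        params=config.genome_params,
    )
    annotations = genome_to_frame(genome)
    planted, translatome = plant_target_sets(annotations, config, seed)

    matrices, truths = {}, {}
    for bait in config.baits:
        truth = SyntheticTruth(
            bait_id=bait,
            planted_targets=planted[bait],
            effect_size=config.effect_for(bait),
            noise_sd=config.noise_sd,
            missing_rate=config.missing_rate,
            n_replicates=config.n_replicates,
            seed=derive_seed(seed, "ip", bait),
        )
        truths[bait] = truth
        matrices[bait] = simulate_ip(genome, truth)
    return StudyBundle(
        genome=genome,
        sequences=sequences,
        annotations=annotations,
        matrices=matrices,
        truths=truths,
        translatome=translatome,
    )
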