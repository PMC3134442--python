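# Methods

This note documents the statistical procedures, the synthetic-data
model, the parameter defaults, and the numerical choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Enrichment calling (one-class SAM)

Input is a gene × replicate matrix of log2(IP/reference) ratios for one
bait, with missing cells allowed.

**Filtering.** Two stages. Spot-level: a measurement survives only if
its regression correlation exceeds 0.6 *and* its signal-over-background
exceeds 2.5 (both strict); failures become missing cells
(`spot_quality_filter`). Gene-level: rows missing two or more replicate
values are dropped (`filter_features`, `max_missing = 1`).

**Imputation.** Sign-flip permutations only produce a proper null for a
gene when every one of its replicates can actually be flipped: a
pattern whose flipped replicates coincide with a gene's missing cells
leaves that gene's null |d| identical to its observed |d|. With
missingness at a few percent and target sets of O(100) genes, those
self-copies inflate the median null exceedance count enough to floor
q-values near `100 × missing_rate` for true targets. The pipeline
therefore KNN-imputes the (at most one per row after filtering)
surviving missing cells before testing: the imputed value is the
column mean of the `k = 10` nearest complete rows by Euclidean distance
over the gene's observed columns. This mirrors the imputation step that
has always accompanied SAM in practice. `sam_one_class` itself does not
impute — its per-gene statistics use non-missing entries only, so a
gene's d is invariant to where its missing cells sit.

**Statistic.** `d_i = mean_i / (se_i + s0)` with `mean_i` and `se_i`
the mean and standard error (sd/√n, ddof = 1) over non-missing
replicates. `s0 ≥ 0` is the exchangeability offset that prevents genes
with accidentally tiny scatter from dominating: it is chosen among the
0th–100th percentiles (step 5) of the per-gene `se` distribution as the
value minimizing the coefficient of variation of the median |d| across
ten `se`-quantile bins. `s0` can be pinned (`s0=0` gives the plain t
ratio, used by the exact-oracle tests).

**Permutation null.** One sign pattern in {±1}^R per permutation,
shared by all genes (preserving gene–gene correlation); the flipped
matrix is re-scored exactly like the observed one. When `2^R ≤ 800`
(always true at the study's 3–4 replicates) all patterns are enumerated
exactly; otherwise 800 patterns are drawn from the given seed.

**q-values** (percent scale). For gene i with threshold `t = |d_i|`:
`q_i = 100 × median_b #{j : |d_jb| ≥ t} / #{j : |d_j| ≥ t}`, capped at
100, then monotonized by a running minimum from the least significant
gene upward along the |d|-descending order (ties broken by gene id).
Targets: `q ≤ 1` and `d > 0` ("enriched"; `sign="both"` is available).

**Null-data behaviour.** With exhaustive enumeration the `2^(R-1)`
distinct |d| pattern datasets are exchangeable on pure-null data, so
the single most extreme gene obtains a median null count of zero — and
hence q = 0 — with probability ≈ 3/8 per matrix (≈ 3/16 after the
positive-sign restriction). A single spurious call on a null matrix is
therefore an inherent, occasional outcome of this estimator, not a bug;
what the method does guarantee, and what the calibration tests measure,
is that the *median* false-positive count across repeated null studies
is zero, i.e. at most 1% of calls.

**Normalization.** Global per-column median-centering is available
(`center` flag, `--center`) as a stand-in for upstream array
normalization, but is off by default: the generator emits already-
normalized ratios, and for baits where a majority of genes is genuinely
enriched (the ribosomal baits) global centering would subtract the
signal itself.

## Sequence features

Kyte–Doolittle per-residue scores, sliding-window mean with no terminal
padding: a length-L protein yields `L − w + 1` profile values at window
`w` (default 7). Per-protein hydrophobicity is the whole-profile mean;
N-terminal hydrophobicity is the window-11 profile mean over the first
50 residues (40 values). Hydrophobic stretches are maximal runs of
profile values **strictly** greater than 1 with run length ≥ 5,
reported in profile coordinates (window-start positions);
`stretch_residue_span` maps a stretch to residues
`[start, end + w − 1]`. Residue `X` scores 0 with a warning; any other
non-standard letter is an error; sequences shorter than the window are
an error (full-length ORFs never trigger this). An optional
`max_hydrophobicity_in_region` scores an annotated SS/TM region by its
profile peak instead of the whole-protein mean.

## Set classification

Quadrants and NAC classes are pure set algebra over called target sets
restricted to a universe, by default the translatome (the ribosomal-
bait target set), overridable to the genome. Dimer assignment:
Egd1∩Egd2 → Egd1/Egd2 (genes in all three sets included — the
dominant heterodimer takes priority); Egd2∩Btt1 (not Egd1) → Btt1/Egd2;
unique to Egd2 or Btt1 → the respective homodimer; unique to Egd1 →
Egd1-only; Egd1∩Btt1 without Egd2 has no α subunit and is labelled
`unassigned`. Category tables count a gene once per category
(multi-membership), so counts may exceed the total; percentages are
`100·count/total` rounded **half-up** to one decimal, matching the
published tables reproduced in `rncmap.reference`. The classification
q threshold is a parameter (default 1.0 percent).

## Annotation enrichment

Exact hypergeometric tails via scipy's log-space survival/distribution
functions: over-representation `P(X ≥ k)`, under `P(X ≤ k)`, with
X ~ Hypergeometric(N, K, n). Fold enrichment `(k/n)/(K/N)`. Raw
p-values against α = 0.01 are the default (no multiple-testing
correction), with Bonferroni and Benjamini–Hochberg available as
clearly labelled options. Backgrounds: whole genome or the translatome.
Terms are a flat gene→term table; no ontology-graph propagation.

## Summaries

Pearson correlation uses pairwise-complete observations (≥ 3 shared
non-missing values per pair, else an error). Hierarchical clustering is
agglomerative on `1 − r` with average linkage (complete/single
selectable), implemented directly so the tie-break is deterministic:
items are canonicalized to id order, and among equidistant candidate
merges (tolerance 1e-12) the pair with the lexicographically smallest
sorted representative-id tuple merges first — making the tree invariant
to input order. Quantiles interpolate linearly between order statistics
(the "type 7" rule); box-plot whiskers sit at the most extreme points
within 1.5 IQR of the quartiles. ECDF tables report, per group, the
fraction of genes at or below each distinct score.

## Synthetic study generator

The generator emulates the study design: baits Rpl16, Rpl17 (ribosomal,
capturing the translatome), Egd2/Egd1/Btt1 (NAC subunits), Srp54 in
wild-type and ΔNAC backgrounds, and a membrane fraction, each with 4
replicates by default.

**Genome.** Localizations are a multinomial draw (defaults: cytosol
0.40, nucleus 0.15, mitochondrion 0.15, ER 0.10, plasma membrane 0.07,
Golgi 0.03, vacuole 0.03, unknown 0.07). Secretory-class genes get
`has_ss` with probability 0.45 and `has_tm` with 0.65 (background rate
0.02 elsewhere). Abundance and translation rate are log-normal
(location 3.0 / 0.0, scale 1.2 / 0.8, arbitrary units). Proteins are
120–600 residues from a background alphabet {S,T,N,Q,G,P,D,E,K,R} whose
Kyte–Doolittle scores are all ≤ −0.4, so no accidental stretch can
arise at threshold 1; SS/TM genes carry one planted N-terminal run of
12–21 I/V/L residues (TM genes may get a second, internal run), long
enough that the window-7 profile is guaranteed to contain a qualifying
stretch.

**Planted sets.** The translatome is the top 60% of genes by
translation rate. SRP-WT = SS/TM-bearing translatome genes plus a
non-canonical remainder sized at 0.43 of the SS/TM count, leaving ≈ 70%
of SRP-WT targets SS/TM-bearing — the wild-type composition the study
reports. The ΔNAC set removes the 30% lowest-abundance SRP-WT genes
("NAC-dependent") and adds high-abundance cytosolic off-targets sized
at 0.40·|SRP-WT|, driving the SS/TM share of the deletion interactome
to ≈ 45%. The membrane set holds secretory-localized and SS/TM
translatome genes plus mitochondrial genes with probability 0.7. NAC
subunits: Egd2 covers 90% of the translatome, Egd1 is 85% of Egd2
(high overlap), Btt1 is the mitochondrial translatome plus a 20%
remainder — giving the Egd1≈Egd2≫Btt1 overlap structure.

**Signal model.** Entry (g, r) = `effect·1[g planted] + N(0, σ²)` with
defaults effect 2.0 and σ 0.5 (signal-to-noise 4, the regime the
calibration checks run in), plus 5%
missing-completely-at-random dropout. Replicates are independent; no
replicate-to-replicate correlation, probe-level effects, or dye bias
are modelled. Passing tests therefore demonstrate correctness of the
statistical machinery under idealized noise, not robustness to array
artefacts.

**Determinism.** One global seed; every stream (genome, planting, each
bait's matrix, each protein) is seeded by the low 31 bits of
SHA-256("seed/purpose/key"), so adding or removing a bait never
perturbs the others, and identical configurations are bit-identical.

## Problem sizes

The default study is 1000 genes × 8 baits × 4 replicates — large enough
that class proportions and the SS/TM shift are stable to a point or
two across seeds, small enough that the full pipeline runs in about a
second. Calibration checks use 20–24 null studies of 300 genes and 10
spike-in studies of 1000 genes with 50 planted targets.

## Known limitations

- The permutation budget at 3–4 replicates is the exhaustive 8–16
  patterns; q-value granularity is correspondingly coarse, and the
  occasional q = 0 top gene on null data (above) is inherent.
- KNN imputation assumes the missing mechanism is ignorable (the
  generator's dropout is MCAR by construction).
- The hypergeometric tests treat terms independently; no ontology
  structure or term correlation is modelled.
- Average-linkage heights are not guaranteed monotone in general; they
  are checked empirically against an independent implementation rather
  than asserted as a theorem.
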