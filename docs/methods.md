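# Methods

## Scope and data model

clockscape analyzes a fixed gene panel (default: the nine core circadian
transcriptional–translational feedback loop genes) across independent
cancer-type cohorts. All assays share one container, a features × samples
matrix with typed validation: methylation beta values must lie in [0, 1],
CNV calls in {−2, −1, 0, +1, +2} (heterozygous vs homozygous
deletion/amplification). Matrices are TSV with feature IDs in the first
column and sample IDs in the header; `NA`, `NaN` and empty cells parse as
missing, and missingness survives write/read round trips. Orientation is
never guessed: a transposed file simply fails ID matching.

Missing data are handled pairwise-complete for correlations; samples
missing an assay drop out of that stage only.

## Pathway activity (RPPA)

Each protein row is centered and scaled to unit sample SD (ddof = 1);
zero-variance proteins carry no relative signal and are dropped with a
warning. The pathway activity score of a sample is

PAS(p, s) = Σ_{positive regulators} x̃ − Σ_{negative regulators} x̃,

with missing member values omitted from the sums. The ten hallmark
pathways (TSC/mTOR, RTK, RAS/MAPK, PI3K/AKT, Hormone ER, Hormone AR, EMT,
DNA Damage Response, Cell Cycle, Apoptosis) ship as an editable
`data/pathways.tsv` modeled on published RPPA pathway annotations;
membership and signs are a curation choice, not a result of this package.

A gene's effect on a pathway is called by splitting samples at the gene's
median expression (ties to the low group — deterministic), comparing the
two groups' PAS with a two-sided Mann–Whitney U test (rank-based,
robust to RPPA outliers; Welch's t is available via `test="welch"`), and
BH-adjusting across all gene × pathway tests. "activate" requires
fdr ≤ threshold and a higher mean PAS in the high-expression group;
"inhibit" the reverse. `pct_influenced` is the absolute rank-biserial
effect size |2U/(n₁n₂) − 1| clipped to [0, 1]; it is an explicit stand-in
for a per-patient influence fraction and should not be read as a
percentage of patients.

## Epigenomics

Tumor-vs-normal methylation difference per gene: effect = mean beta
difference, p from the Wilcoxon rank-sum test (betas are bounded and
non-normal), BH FDR across the panel, significance at fdr < 0.05.
Gene-level betas are assumed pre-aggregated (e.g. promoter means);
probe→gene mapping is an upstream preprocessing contract.

Methylation→expression coupling uses Spearman ρ across tumors, because
methylation-driven silencing is a monotone, not linear, claim.

CNV frequencies count the fraction of non-missing samples per category;
a gene is `displayed` when its largest category frequency is strictly
greater than the display fraction (default 5%).

## Survival

The Kaplan–Meier estimator and the two-group log-rank test are
implemented from first principles (product-limit over distinct event
times; observed-minus-expected with hypergeometric variance; χ² on 1 df)
and are cross-checked in the test suite both against `lifelines` and
against an exhaustive brute-force risk-set enumeration over all
event/censor patterns and group splits of up to six subjects. Patients
are split at each gene's median expression (ties to the low group).
Per-gene log-rank p-values are reported without multiplicity correction,
mirroring the per-gene presentation convention of median-split survival
screens; the combined report therefore shows no FDR column for this
stage. `direction` compares the restricted mean survival of the two KM
curves up to the shorter arm's last follow-up, and only when p ≤ 0.05.

Differential expression uses effect = log2((mean_a + ε)/(mean_b + ε))
with ε = 10⁻³ expression units, Wilcoxon rank-sum p, BH FDR, and the
joint filter |log2FC| > 1 AND fdr ≤ 0.05. A fold-change threshold of
"|FC| > 1" is read on the log2 scale — a raw fold change of 1 is no
change, so the literal reading would be vacuous. Both thresholds are
configurable.

## Drug sensitivity

For each panel gene and drug, Pearson r between log2(expression + 1) and
AUC across shared cell lines (log scale is the standard choice for
transcript–drug-response association), Fisher-stabilized z = atanh(r),
z-score = z·√(n − 3), two-sided p from the standard normal (the exact
Pearson t p is available via `p_method="exact"`; the two agree within
~10% relative for n ≥ 50). BH runs within each gene's drug family —
each gene's drug profile is treated as one screen. Because higher AUC
means more resistant, a significant positive correlation is labeled
"resistance" and a negative one "sensitivity". |r| = 1 (within 10⁻¹² —
exactly affine pairs land there after rounding) is reported as a signed
infinite z with p = 0 and a warning.

## Immune infiltration

The shipped signature is a marker-mean z-score: per cell type (B, CD4+ T,
CD8+ T, neutrophil, macrophage, dendritic; markers in
`data/immune_markers.tsv`), the score is the mean over observed markers
of per-gene z-scored log2(x + 1). This is a deliberately simple stand-in
for purity-adjusted deconvolution; any externally computed infiltration
matrix can be passed through `immune_scores.tsv` instead. Panel genes are
then correlated with each score by Spearman ρ with BH FDR across
gene × cell-type pairs.

## Rhythmicity (cosinor)

Single-component cosinor at a fixed period (default 24 h):
y = M + β_c·cos(ωt) + β_s·sin(ωt), ω = 2π/period, fitted by least
squares. Amplitude = √(β_c² + β_s²); acrophase = (period/2π)·atan2(β_s,
β_c) mod period (the peak time of the fitted cosine). Rhythmicity is the
F-test of the two rhythm coefficients against the intercept-only model on
(2, n − 3) df. Requirements: n ≥ 4 and ≥ 3 distinct time points modulo
the period (otherwise "degenerate sampling"). A constant series is
reported as amplitude 0, p = 1, using a scale-aware zero test on the
total sum of squares. Timestamps are assumed known; estimating phase from
unordered samples is out of scope, as are multi-harmonic fits and
permutation-based rhythm detectors.

## Multiple testing

The FDR procedure is Benjamini–Hochberg throughout (the step-up
procedure; delegated to statsmodels, with NaN p-values excluded from the
family and propagated). Families are formed within a cohort and analysis
type — gene × pathway calls, the methylation panel, each gene's drug
profile, gene × cell-type immune pairs, the rhythm panel — and never
pooled across cancer types.

## Synthetic cohorts

The generator emulates, at desk scale, the assay set of a TCGA-style
cohort with matched normals, a cell-line drug screen, and a time-stamped
normal-tissue series. Defaults: 200 tumors, 50 normals, 100 cell lines,
8 drugs, 24 time points over 48 h, 20 extra null genes.

* **Methylation**: logit-normal background (center ~ N(−0.8, 0.4) on the
  logit scale, logit SD 0.5); silenced genes add Δβ (default 0.2) to
  tumor betas, clipped to [0, 1].
* **Expression**: log-normal, log-mean ~ N(3, 1), log SD 0.6 (0.3 for
  cell lines); silenced genes' tumor log-expression drops by 0.7 (~2×).
* **Correlation planting** is rank-preserving via a Gaussian copula: to
  hit a target Spearman ρ_s, latent normals are correlated at
  r = 2·sin(πρ_s/6), so the target survives any monotone marginal.
  Immune targets are planted on marker genes jointly: with m markers and
  drivers j, per-marker weights w_j = ρ_j/√(m(1 − Σρ²) + Σρ²) make the
  m-marker mean score correlate with each driver at exactly ρ_j (for
  independent driver latents).
* **RPPA**: standard-normal proteins; for a planted (gene, pathway,
  effect) the pathway's positive regulators shift by `effect_sd` in
  samples with above-median driver expression; negative `effect_sd`
  plants inhibition.
* **Survival**: exponential event times with baseline median 365 d and
  hazard multiplied by HR^{1[expression > median]} per prognostic gene;
  independent uniform censoring on [0, 4.6 × median event time], which
  gives ≈30% censoring for exponential event times.
* **Time series**: mesor ~ N(5, 1) plus A·cos(2π(t − φ)/24) for rhythmic
  genes and Gaussian noise (SD 0.5).

All randomness flows from one seeded generator; the same seed yields a
byte-identical serialized cohort. The generator does **not** mimic real
TCGA batch structure, tumor purity, platform noise, probe-level
methylation, or dose–response curve shape — passing recovery tests shows
the estimators work under the stated model, not that real-data effect
sizes will match.

## Validation harness

`clockscape.validation` measures, at the simulation sizes quoted below
(chosen to keep the whole harness within a few minutes on one CPU):
PAS vs a brute-force loop oracle (100 random instances, tolerance
10⁻¹²); activation-call recovery for a planted 0.8 SD effect and the
null call rate (100 seeds, n = 200); methylation null calibration (2000
null genes) and Δβ = 0.2 detection (100 seeds); KM/log-rank exactness
against exhaustive enumeration (≤ 6 subjects); median-split log-rank
power at HR = 2 (500 seeds, 100+100) and type-I error (2000 seeds);
cosinor noiseless exactness, noisy recovery (A = 1, σ = 0.5, n = 24, 200
seeds) and time-shift equivariance; Fisher-Z round trip and drug-label
recovery at ρ = 0.4, n = 100 (100 seeds); the 10-gene differential
expression fixture; and a determinism + wall-time check of the full
three-cohort simulate + run. `scripts/acceptance.py` reports all of these
as JSON; `tests/test_acceptance.py` asserts them.

## Known limitations

* Pathway memberships and immune marker lists are curated defaults, not
  discoveries; edit the data files for other annotations.
* The immune score is marker-based and purity-unaware; CD8A-family
  markers are expressed on other cell types, an ambiguity the score does
  not resolve.
* Survival analysis is univariate (no Cox adjustment, no subtype labels).
* SNV analysis and probe-level methylation are out of scope.
* The per-gene raw-p convention for survival inflates family-wise error
  across a panel; the combined report keeps it explicit by omitting an
  FDR column for that stage.
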