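# Methods

## The measurement model

A screen well holds one tumor line in one culture condition (monoculture or
coculture with a single fibroblast), one drug at one dose, in one replicate.
Its mitochondrial-dye fluorescence is read before drug addition (`F₀`, time 0)
and every 8 h afterwards. Loss of signal reports loss of mitochondrial
membrane integrity, i.e. apoptotic death; alamethicin-permeabilized wells give
the fully-dead background floor. The canonical in-memory representation is a
tidy table (one row per well × timepoint) wrapped by `ScreenTensor`; the two
controls are reserved drug tokens (`vehicle`, `alamethicin`, dose 0) so they
flow through counting and normalization like any treatment.

Normalization is strictly per-well: `v(t) = (F(t) − B)/(F₀ − B)` with
`B` either 0 (`background="none"`) or the mean post-drug alamethicin signal of
the same (line, condition) culture. Per-well baselines absorb plating-density
and labeling variation; plate-level drift correction is intentionally out of
scope. Negative values are floored at 0 (dead cannot be deader) and floor
events are counted in the run manifest. Tables whose normalization state is
unknown (external exports) default to `background="none"` to avoid
double-correction.

## Fibroblast influence and hit calling

Influence is the replicate-matched log2 ratio `r = log2(v_co / v_mono)`;
replicate i of a coculture is paired with replicate i of the matching
monoculture, so the two replicate ratios are independent draws. Ratios are
masked (with a reason, and excluded from all downstream statistics) when
either viability is 0.

The noise scale σ is a **single pooled estimate**: the SD over all conditions
of the replicate half-difference `(r₁ − r₂)/2`. For two independent
replicates this is exactly the SD of the replicate mean `r̄`, so the hit rule
`|r̄| > 3σ` has the textbook two-sided normal tail ≈ 2·Φ(−3) ≈ 0.27 % under
the null — the property the null-screen test checks. Per-condition SDs at
n = 2 are unusable, hence pooling. Two alternative conventions are exposed as
flags and reported side by side in every run manifest, because published hit
counts rarely state the convention: `paired_sqrt2` (`(r₁ − r₂)/√2`, the
single-replicate SD, ≈ √2 larger) and `pooled_replicate_sd` (root mean
per-condition replicate variance, numerically close to `paired_sqrt2`).

Hit enrichment per design factor (time, dose, drug class) uses two-sided
Fisher exact tests on (hit/non-hit) × (level/other) tables, without
multiple-testing correction — the enrichment p-values are reported raw, as
screen-level descriptions rather than confirmatory tests.

## Subtype PCA

The decomposition runs on the z-scored coculture **response** matrix: one row
per culture pair (line × condition), one column per (drug, dose, time),
column-wise mean 0 / variance 1, zero-variance columns dropped and missing
cells (≤ 20 %) mean-imputed, both counted in the manifest. The response
matrix — not the influence-ratio matrix — is the default because a
subtype-specific sensitivity difference shifts mono- and coculture alike and
therefore largely cancels in the ratio; the ratio unfold remains available
(`pca_value="influence"`) for questions about fibroblast structure.

PCA is a full SVD with a deterministic sign convention (the
largest-magnitude loading of each component is made positive), explained
fractions over the complete eigenvalue spectrum (they sum to 1), and a
truncation warning when more components than the matrix rank are requested.
PC–subtype association splits each component's scores at the median
(strictly above vs at-or-below — parameter-free, invariant to monotone
transformations of the scores) and tests the 2 × 2 table against BL/ML
membership with Fisher's exact test. Loading enrichment ranks features by
loading (descending, ascending, or by magnitude per the `tail` flag), takes
the top quartile (configurable), and Fisher-tests each drug class, features
inheriting class from their drug.

UPGMA clustering (scipy average linkage, Euclidean distance) of line × drug
sensitivity summaries rounds out the monoculture overview; trees are
serialized as Newick strings with branch lengths derived from merge heights.

## Tissue divergence

Each fibroblast's influence profile is its vector of mean ratios over
(line, drug, dose, time). All pairwise Pearson correlations are split into
within-tissue and between-tissue samples and compared with a two-sample KS
test — exact enumeration when either sample has fewer than 10 pairs,
asymptotic otherwise. Pairs sharing < 50 % of profile entries are masked;
zero-variance profiles correlate 1 with an equal profile and are otherwise
masked. Identical samples short-circuit to D = 0, p = 1.

A power caveat that the repeated-seed tests make visible: correlations are
scale-invariant, so two tissues with same-sign priming effects of different
magnitude produce mutually correlated profiles and become indistinguishable
by this statistic. Under the default generator conditions (tissue effects
drawn uniformly on [−1.5, 1.5]) a nontrivial fraction of random panels draws
predominantly same-sign tissue effects, and the KS test then has little to
detect; the divergence test is informative about *divergently signed* tissue
structure, which is the phenomenon of interest.

## Mechanism statistics

**Priming score.** A BH3 profile is % cytochrome c retention across the BIM
peptide dose series (100, 33, 10, 3.3, 1, 0.33 μM). The score integrates the
*release* fraction (1 − retention/100) over log10 dose by trapezoid and
divides by the log10 span, giving a dimensionless value in [0, 1] where
larger = more primed; Δpriming is coculture minus monoculture. Integrating
release rather than retention makes the score and the priming shift point the
same way.

**Correlations.** Priming–sensitivity association is a plain Pearson r with
t-distribution p. The γ-H2AX–sensitivity association instead uses a
permutation null (default 10,000 permutations of y, seeded;
`p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1)`), switching automatically to
exhaustive enumeration when n! ≤ 50,000 — at the typical panel sizes of a
follow-up experiment the sampled p-value's resolution matters.

**Bliss.** Fractional *effect* (1 − fractional viability) is the working
scale, so the independence expectation `A + B − A·B` is dimensionally
consistent, and `CI = observed effect / expected effect` with CI > 1 =
synergy. CI maps read the monotherapy effects off the grid's dose-0 margins,
as an experimentalist would; cells with expectation 0 (both monotherapies
inert) are flagged undefined rather than raising.

## The synthetic-data generator

The generator exists so that every statistic above can be exercised against a
known truth. It emulates:

- the full-factorial design (defaults: 3 BL + 3 ML lines, 16 fibroblasts
  across 8 tissues, 42 drugs in 10 classes — 24 cytotoxic, 18 targeted,
  including an inert anti-estrogen class for receptor-negative lines — at
  doses 0.1/1/3.2/10 μM, 8-h reads to 72 h, duplicate wells, vehicle and
  alamethicin controls), which yields 312,120 post-drug measurements;
- fibroblast influence through a single latent **priming shift**
  `p = μ_tissue + ε_fibroblast (+ pair noise)`, with
  `logit(Emax_eff) = logit(Emax) + p` and `ln EC50_eff = ln EC50 − p`
  (coupling fixed at 1) — the mechanism the screen's follow-up assays probe.
  A hook for per-(fibroblast, drug) shifts exists for the rare drug-specific
  interaction;
- death kinetics `D(t) = Emax_eff · dose^h/(dose^h + EC50_eff^h) ·
  max(0, 1 − e^{−κ(t−τ)})` — a delayed-exponential commitment model chosen
  because two interpretable parameters (delay τ ~ 4–16 h, rate κ ~
  0.05–0.2 h⁻¹) reproduce sigmoidal kinetic death traces;
- signal `F = F₀ · [(1 − D)(1 − bg) + bg] · (1 + CV·z)` with bg = 0.05 and
  CV = 0.05 — multiplicative noise because plate-reader error scales with
  intensity;
- a BL-only Emax boost (+0.8 logit) restricted to conventional-chemo classes,
  the structure the subtype PCA is meant to find;
- BH3 profiles as descending logistics in log BIM dose whose midpoint falls
  with p; γ-H2AX nucleus tables with drug/time-dependent lognormal
  intensities *independent* of p by default (a coupling knob exists for power
  analysis), nucleus counts ~758 per condition (range 93–1,632); combination
  grids that are exactly Bliss-independent or exceed/undershoot the
  expectation by a configurable margin when both drugs are present;
  exponential growth curves with per-pair rate modifiers defaulting to 0.

Defaults that the underlying experimental description does not pin down were
fixed once at values a screener would call realistic and are not revisited:
the four-dose grid (0.1–10 μM half-ish-log), Emax ~ U(0.3, 0.95) with inert
Emax 0.02, EC50 ~ 10^U(−1,1) μM, Hill slope U(0.8, 2.5), tissue effects
U(−1.5, 1.5), fibroblast SD 0.3, pair noise 0.2, baseline 1000 AU.

All randomness flows from one seed through fixed-order streams (screen, BH3,
γ-H2AX, combination, growth), so ledgers and outputs are bit-reproducible.
The `GroundTruth` ledger stores tissue effects, per-fibroblast and per-pair
priming shifts, per-(line, drug) pharmacology, effective parameters and the
noise-free dead-fraction trajectories.

What the generator deliberately does **not** emulate — and what passing tests
therefore do not establish about real screens: spatial/edge-well plate
artifacts, fibroblast death or overgrowth contaminating the dye signal,
drug-specific stromal metabolism (beyond the hook), non-multiplicative reader
noise, batch effects between plates, and any transcriptional detail behind
the subtype labels.

## Numerical choices

- Hill fits: bounded least squares over (Emax, log10 EC50, h) with a fixed
  multi-start grid (observed log10 doses × slopes {0.5, 1, 2, 4}), ties
  broken by lowest residual then lowest EC50 — deterministic without
  randomness. Curves with < 5 % decline return the observed decline with an
  `undetermined` EC50 flag; EC50 outside [min dose/10, max dose·10] is
  flagged `extrapolated`.
- Dose equality is exact (doses are design constants); time grids likewise.
- AUCs (growth, priming) are trapezoidal.
- Fisher/KS/Pearson come from scipy.stats; tests cross-check them against
  exhaustive enumeration oracles on instances small enough to enumerate.
- Degenerate inputs have defined behavior throughout: F₀ ≤ B raises a
  degenerate-well error listing wells; v = 0 masks ratios with reasons;
  all-identical correlation samples give D = 0, p = 1; CI with expectation 0
  is NaN-flagged.

## Problem sizes in the test suite

Unit tests run on a miniature but structurally complete design (2 lines, 4
fibroblasts/2 tissues, 10 drugs, 3 post-drug timepoints). The acceptance
suite runs the full default design once end to end, a 16,128-condition
single-timepoint null screen for the 3σ false-positive rate, and 50 replicate
full-size screens for the tissue sign-recovery and KS-detection rates; the
whole suite completes in a few minutes on one CPU.

## Known limitations

- The hit rule assumes approximately Gaussian log-ratio noise; heavy-tailed
  reader artifacts would inflate σ rather than the hit list.
- The pooled σ ignores any dose- or time-dependence of measurement noise.
- Influence ratios are undefined where monoculture viability reaches 0; very
  potent drugs therefore contribute fewer evaluable conditions at late times.
- The divergence statistic is blind to same-sign tissue differences (see
  above).
- The Bliss CI uses the division convention on effects; a flag inverts the
  viability/effect reading but no Loewe/ZIP-style surface models are fitted.
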