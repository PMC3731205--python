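# Methods

## Quantification model

A SILAC experiment mixes two metabolically labeled strains before lysis, so
each tryptic peptide carries a light and a heavy ion intensity. The peptide
ratio is r = I_heavy / I_light. When one channel is undetected, the missing
intensity is imputed at the noise floor (default 10³, the minimal ion
intensity used when no noise peaks are detected in the expected m/z range);
peptides empty in both channels carry no information and are dropped with a
warning. Imputation is recorded per peptide and summarized per protein as
`imputed_fraction`.

A protein is quantified from its unique peptide sequences (charge states
collapse to one sequence; duplicates are merged by their median ratio before
counting). The protein ratio is the median of the peptide ratios, with the
arithmetic mean reported alongside; proteins with fewer than
`min_unique_peptides` (default 3) are flagged under-quantified and excluded
from substrate calling and profiles. **Median convention:** for even peptide
counts the median is the *geometric* midpoint of the central pair, i.e. the
ordinary median on the log scale. Ratios are multiplicative quantities, and
this convention makes the median equivariant under taking reciprocals —
median(1/x) = 1/median(x) — which in turn makes label-swapped replicates and
direct mutant-vs-mutant comparisons aggregate consistently; the arithmetic
midpoint breaks the ratio-of-ratios identity for floor-imputed proteins by up
to ~0.2 log2 even on noiseless data. Odd counts return the middle ratio
unchanged.

Raw ratios are heavy/light; `orient_to_reference` re-expresses every protein
ratio with the non-reference strain in the numerator (reciprocal when the
reference strain was grown heavy), so oriented ratios are always tagged/mock
or mutant/WT. Downstream reporting is log2.

## Target calling

Tagged-vs-mock purifications are run as two replicates with the isotope
assignment swapped to control for label-specific artifacts. A protein is
called a SUMO target when it is quantified (≥ 3 unique peptides) in both
replicates with an oriented median ratio of at least `fold_cutoff` (default
10, inclusive) in each. Because contaminants enter the purification from both
arms equally, they sit near ratio 1 and fail the cutoff. The
minimum-peptides rule is applied per replicate by default; a `combined` mode
(sum of unique peptides across replicates) is available because the
interaction of the two rules is not uniquely determined by the calling
description.

## Specificity profiles and ratio of ratios

For each called target, the per-genotype log2 change vector is filled from
oriented mutant-vs-WT experiments over the declared genotype set (siz1Δ,
siz2Δ, siz1Δ siz2Δ, mms21-11, esc2Δ, slx5Δ, slx5Δ siz1Δ, slx5Δ siz2Δ).
Genotypes where a target was not quantified are NA; NA propagates through all
profile arithmetic and nothing is imputed at the profile level.

The indirect mutant-vs-mutant comparison is
log2(A/B) = log2(A/WT) − log2(B/WT). `validate_derived_vs_direct` compares it
with a direct A-vs-B experiment and reports per-protein |Δlog2| and the
fraction within a tolerance (default 1.0 log2, i.e. the two-fold resolution
the multi-peptide quantification supports). On noiseless synthetic data the
identity is exact up to IEEE double rounding (observed residual ~1e-15 log2);
under the default noise it holds within 1 log2 for essentially all targets.

## Dependency classification

The classifier consumes the four core genotypes (siz1Δ, siz2Δ, siz1Δ siz2Δ,
mms21-11) and applies, in order: insufficient_data (≥ 2 core values NA);
siz1_specific (siz1Δ ≤ strong_loss and mms21-11 inside the unaffected band);
mms21_preferred (mms21-11 ≤ strong_loss, double deletion not);
siz1_siz2_redundant (only the double deletion ≤ strong_loss, mms21-11
intact); up_in_mutant (some value ≥ gain, none ≤ strong_loss); unaffected
(all inside the band); otherwise mixed. The thresholds (strong_loss = −2,
band = ±0.5, gain = +1, all log2) are package choices — the underlying
biology is described only qualitatively — and are therefore config-exposed
and echoed into the classification output header. Comparisons against NA are
false, so a single missing genotype can only demote a call, never create
one. esc2Δ and slx5Δ profiles are reported but deliberately do not enter the
category rule; they are analyzed through their own comparisons (esc2Δ vs
mms21-11 similarity, slx5Δ accumulation of Mms21-dependent targets).

## GCR rate estimation and table arithmetic

Fluctuation assays yield mutant-colony counts over parallel cultures of N_t
cells. The default estimator is the Lea–Coulson method of the median: solve
r̃/m − ln m = 1.24 for the expected mutations per culture m (bisection via
Brent's method on m ∈ [10⁻⁶, 10⁶], xtol 10⁻⁹) and report rate = m/N_t. When
the median count is zero the zero-class estimator m = −ln f₀ is used instead;
when no culture has any mutant only an upper bound
−ln(1 − 1/(n+1))/N_t exists and a below-detection error carries it. The
estimator family is the standard choice for this assay and is recorded in
every result.

Fold increases (rate over the wild-type single-copy reference) and assay
ratios (duplication-assay rate over single-copy rate) are rounded
half-away-from-zero at per-cell significant figures, because the published
table mixes precisions (46.7 beside 82); precision is therefore an input,
inferred per cell from the printed numeral when checking the packaged
fixture. Three printed ratio cells are internally inconsistent with their own
rates under any rounding (369 vs 369.57, 128 vs 128.57, 86 vs 84.85) and are
flagged, not forced.

Interaction calls use fold triplets: synergistic when
fold_ab ≥ κ·(fold_a + fold_b − 1) (the additive expectation of independent
pathways), epistatic when fold_ab ≤ κ·max(fold_a, fold_b) (the double
resembles the stronger single). Both conditions can hold when one single
dominates, so synergy is tested first only when the double exceeds both
singles. κ = 1.5 separates the labeled synergistic (siz1Δ siz2Δ) and
epistatic (esc2Δ mms21-11) reference cases using only the published folds.

## Synthetic-data generator

The generator emulates the statistical structure the analysis relies on, not
mass spectra. A proteome of `n_proteins` splits into SUMO targets
(`target_fraction`, default 0.50), contaminants (`contaminant_fraction`,
default 0.35, true ratio lognormal around 1 clipped to [0.5, 2]) and weakly
enriched bystanders (ratio 2–8). Target enrichment is lognormal(ln 50, 0.6)
floored at 12; peptide counts are 2 + Poisson(4) (median ≈ 6, matching the
observation that most substrates are identified from fewer than 10
peptides); peptide ionization factors are lognormal(0, 0.5) per peptide and
protein baselines lognormal(`intensity_log_mean` = 11.5,
`intensity_log_sd` = 1.0).

Each target's sumoylation level under a genotype is
S = w₁·a₁ + w₂·a₂ + w_r·max(a₁, a₂) + w_m·a_m·(1 − c·(1 − a_esc2)), with the
Mms21 term multiplied by `slx5_gain` (≥ 1) when Slx5 is inactive; the aᵢ are
0/1 activity indicators, the weights sum to 1 so S(WT) = 1, c is the Esc2
coupling of the Mms21 component, and the max() term encodes Siz1/Siz2
redundancy (either paralog suffices). This is the simplest structure that
reproduces the observed qualitative classes — a few strictly Siz1-dependent
substrates, a redundant Siz1/Siz2 majority, an Mms21-preferred subset whose
sumoylation needs Esc2 and accumulates without Slx5, and no Siz2-exclusive
class. The default class mix is 10% Siz1-only, 55% redundant, 15% Mms21,
20% mixed (Dirichlet weights).

Peptide ratios are true_ratio · exp(ε), ε ~ N(0, σ²) with σ = 0.2 on the
natural-log scale by default (the ratio-noise magnitude is not an observable
of the study design and is a package choice). A level of 0 (fully lost
modification) renders that channel undetected; independently, with
`missing_channel_prob` (default 0.05) the lower-intensity channel of a
peptide is dropped. Both exercise the noise-floor imputation path.
Per-protein streams (sequences, ionization factors) are keyed by
(seed, protein) and per-experiment streams (noise, dropouts) by
(seed, experiment_id) and drawn independently of the channel assignment, so
a label swap of the same experiment permutes the intensity columns and
nothing else — orientation must undo it exactly — while distinct experiments
get independent noise.

The fluctuation sampler draws mutation events per culture as Poisson(m),
m = rate·N_t, and clone sizes from the Lea–Coulson law P(s = k) = 1/(k(k+1))
by inversion (s = ⌊1/U⌋), truncated at N_t. This gives desk-scale exactness
without simulating 10⁹ divisions; rate = 0 degenerates to all-zero counts
and m > 10⁴ is rejected as outside the countable-colony regime.

What the generator does not emulate: spectrum-level identification, decoys,
retention time and charge states, fractionation, inter-experiment protein
abundance changes (a profile change is modification change by construction),
plating efficiency or phenotypic lag. Passing tests therefore demonstrate
correctness of the quantification, calling, profiling and rate arithmetic
under the stated noise model — not robustness to identification errors or
abundance confounds in real data.

## Numerical choices and edge cases

* Noise-floor imputation applies to exactly one channel; both-empty peptides
  are dropped (no signal, no ratio).
* Estimated log2 losses for fully lost modifications are large negative but
  finite (floor over a real intensity), typically −6 to −7 at default
  intensities; they are not clamped.
* Problem sizes in tests and the acceptance script (200–1000 proteins,
  24–48 cultures, 100 estimator repeats) are chosen as the smallest sizes at
  which the measured operating characteristics are stable to re-seeding.
* TSVs are written with `%.17g` floats and read back with round-trip float
  parsing, so write∘read is the identity and identically configured runs are
  byte-identical; "NA" is the missing marker throughout.
* `round_sig` uses decimal arithmetic (half away from zero) to avoid binary
  rounding artifacts at the printed precision, with an explicit decade
  rollover (9.96 → 10 at two significant figures).

## Known limitations

* Quantification accuracy is bounded by the median's sampling noise: with
  five peptides and σ = 0.2 the protein log2 estimate has SD ≈ 0.155, so
  ~80% of proteins land within ±0.2 log2 and ~98% within ±0.35 log2 of
  truth. Two-fold changes are comfortably resolved; ±15% changes are not.
* The dependency classifier is a hard-threshold rule; targets with genuine
  partial dependencies near a threshold flip categories with noise.
* The Lea–Coulson median estimator assumes equal N_t across cultures and no
  plating-efficiency or phenotypic-lag corrections; confidence intervals are
  out of scope.
* The published peptide-level source tables exist only as journal
  supplements, so the published 176-target and 306-overlap counts can only
  be re-derived when those tables are supplied as TSVs
  (`tests/data/external/enrichment_rep{1,2}.tsv`); all other results are
  self-contained.
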