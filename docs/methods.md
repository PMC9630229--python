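# Methods

This note documents the models, conventions and design choices behind
`diabsub`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Synthetic cohort model

The generator emulates a three-subgroup cohort of recent-onset type 2
diabetes (n = 687; subgroup sizes 307 / 130 / 250 for MOD / SIRD-RII /
MARD-II by default, or multinomial from the mixture weights).

Per subgroup, each variable is drawn independently from the family in which
its published summary is reported:

- **Gaussian(mean, SD)** for symmetric variables: onset age, index age, BMI
  (kg/m²), HbA1c (%), eGFR (ml/min/1.73 m²), HDL-cholesterol (mmol/l).
- **Log-normal** for right-skewed variables: HOMA2-B (%), HOMA2-IR,
  triacylglycerol (mmol/l), TG/HDL ratio. Parameters come from the reported
  median (IQR) by `mu = ln(median)`, `sigma = (ln q3 − ln q1) / (2 z₀.₇₅)`
  with `z₀.₇₅ ≈ 0.6745`. This anchors the median exactly and reproduces the
  IQR *width* (q3/q1 ratio) exactly; the individual quartiles also coincide
  when (and only when) the reported IQR is log-symmetric about the median —
  a two-parameter family cannot absorb quartile asymmetry, and we prefer an
  exact median to a compromise fit because the median is the calibration
  target checked downstream.

Samples are clipped to physiological ranges (HbA1c to (3, 20)%, positive
floors for ratio variables) — at the calibrated parameters clipping is a
sub-0.1% event. Sex and ethnicity are categorical draws at the per-subgroup
reported fractions.

**What this generator does *not* model.** Within-subgroup correlations
(published summaries carry none; an optional correlation matrix can be added
for stress tests), missingness, measurement error in HOMA2 indices, and the
fact that the published subgroup summaries describe clusters from a *hard*
k-means partition. The last point matters: a hard partition tiles classifier
space with non-overlapping cells, while independent parametric mixtures
overlap at the boundaries. Tests passing on these cohorts therefore
demonstrate pipeline correctness and planted-truth recovery, not that real
data would yield identical cluster geometry — see §3 on the optimal-k vote.

## 2. Subtyping stage

**Standardisation.** Classifiers are reduced to mean 0, SD 1 after log
transforms on HOMA2-B and HOMA2-IR. Sample SD (ddof = 1) is the default
convention; population SD is available via `ddof=0`. Fitted `ScalingParams`
can be applied to new data (reference-cohort scaling) and inverted exactly.

**k-means.** Lloyd iterations with k-means++ seeding, best of `restarts`
(default 25) by WSS, via scikit-learn. Labels are renumbered canonically by
descending cluster size (ties by first row occurrence) so outputs are
deterministic across label permutations. Empty clusters during iteration are
handled by scikit-learn's relocation rule; restart selection absorbs the
difference from other conventions.

**Optimal k.** Twelve internal validity indices vote; the modal k wins, ties
to the smallest k. Directions: maximise Calinski–Harabasz, silhouette, Dunn,
point-biserial, Ratkowsky–Lance, Krzanowski–Lai; minimise Davies–Bouldin,
C-index, McClain–Rao, Xie–Beni. Ball–Hall uses the successive-difference
rule and Hartigan the ≤10 rule-of-thumb (falling back to the largest
successive drop when no k satisfies it); difference-based rules only compare
k values inside the candidate range, so the smallest candidate cannot win by
differencing against a fit outside it. An index undefined at some k abstains
there (logged). Graphical-inspection indices (Hubert, D-index) are excluded
from the electorate because they do not emit a vote.

**Stability.** Nonparametric bootstrap over rows; for each replicate k-means
is refitted with the same k and every original cluster — restricted to the
resampled rows, membership counted over distinct original rows — is matched
greedily to the bootstrap cluster maximising the Jaccard index. Per-cluster
means over B replicates are reported; B = 500 is the package default (the
statistic is stable well below that; larger B changes the third decimal).

**Phenotype naming.** With k = 3: SIRD-RII = highest standardised HbA1c
centroid; of the rest, MARD-II = higher onset-age centroid; remainder = MOD.
The rule is overridable, and degenerate centroid configurations fall back to
generic names with a warning.

**Reference assignment.** New cohorts are assigned by minimal Euclidean
distance to per-cluster raw means of a chosen variable set (BMI, onset age,
HbA1c, TG/HDL ratio for cohorts lacking HOMA indices). By default both
centroids and rows are standardised with the reference cohort's scaling —
otherwise BMI and onset-age units dominate the distance; a raw-scale mode
exists for strict replication of unit-weighted distance.

**Sex sensitivity.** Classifiers can be replaced by OLS residuals on a sex
indicator; concordance between partitions is reported as agreement fraction
and Cohen's kappa after Hungarian alignment of the confusion matrix.

## 3. Known behaviour of the optimal-k vote on synthetic cohorts

On the calibrated 687-row cohort the electorate splits nearly evenly between
k = 2 and k = 3 (k = 3 wins in roughly two-thirds of seeds). This is the
boundary-overlap effect of §1: with independent within-subgroup sampling the
MOD and MARD-II components overlap enough that silhouette, Davies–Bouldin,
Dunn, point-biserial and Xie–Beni prefer the coarser split by thin margins,
while Calinski–Harabasz, Ratkowsky–Lance, Hartigan and Ball–Hall prefer
k = 3; C-index and McClain–Rao drift toward the top of the range (their
documented bias on weakly separated continuous data). The same vote recovers
the planted k essentially always for well-separated mixtures (property
tests), so the behaviour reflects the synthetic geometry, not the
implementation.

## 4. Polygenic scores

Scores are weighted sums of risk-allele dosages in [0, 2]. Dosage files
counting the other allele are flipped (`d → 2 − d`) via an explicit
counted-allele map; a simultaneous allele/weight flip changes scores only by
an additive constant, leaving associations untouched. Missing dosages are
mean-imputed per variant by default (strict mode raises). The three packaged
panels (beta-cell dysfunction 35 SNPs, insulin resistance 20 SNPs, type 1
diabetes 9 SNPs) are synthetic stand-ins with invented identifiers,
frequencies in (0.3, 0.7) and weights of realistic effect-size magnitude;
the pipeline treats any panel purely as data. Genotype principal components
are accepted as numeric covariates (their computation is out of scope; the
generator emits Gaussian placeholders). Association is OLS of the score on
subgroup indicators (MOD reference) plus covariates, with Wald 95% CIs.
The top-percentile flag uses the nearest-rank-above quantile, so at least
one score always flags and ties at the threshold are kept.

The genotype generator plants a subgroup score shift Δ by moving risk-allele
frequencies additively, `δ_v = Δ w_v / (2 Σ w²)`, which yields the requested
mean shift in expectation and errors out if any frequency leaves (0, 1).

## 5. Lipidomic screen

Concentrations are strictly positive species × sample tables with per-species
class and signal-to-noise annotations and per-sample subgroup and batch
labels. Conventions:

- SNR filter removes species with SNR strictly below 3 (SNR = 3 is kept).
- Batch correction centres each species' log-concentrations on the batch
  median and re-centres to the global median — robust, invertible, and
  exactly removes additive log-scale offsets; a passthrough mode exists
  since the reference method is unspecified upstream.
- The Kruskal–Wallis statistic uses tie-corrected H with the chi-square
  approximation (df = 2); all-tied species get H = 0, p = 1. The screen is
  vectorised over species (rank once per row), which makes 500-replicate
  null-calibration experiments cheap; scipy's scalar implementation serves
  as the independent oracle in tests.
- The Bonferroni denominator is the post-filter species count (315 at the
  full panel → threshold 1.59 × 10⁻⁴).
- Replication tests only discovery hits, two-sided at nominal 0.05,
  direction-agnostic (the upstream report does not state a one-sided
  check); `pass_validation ⊆ pass_discovery` holds structurally.
- Pairwise contrasts are per-species OLS of log concentration on subgroup
  indicators; coefficients are log fold-differences versus MOD.

With 75 large-effect species planted among 315 and 45 re-planted in
validation, the expected replicated count slightly exceeds 45: each of the
30 discovery-true species left null in validation replicates falsely with
probability 0.05 (≈1.5 expected). The acceptance check's ±2 band absorbs the
typical case.

## 6. Outcomes

**Progressive CKD rule.** Event at the *first* measurement at or below 60%
of baseline eGFR that is confirmed by any later measurement ≥0.25 years
after it that is also at or below threshold; otherwise censored at the last
measurement. The event time is the qualifying measurement, not the
confirmation ("3 months" is interpreted as ≥0.25 years on the continuous
axis); both choices are documented here because the clinical definition
leaves them open, and the qualifying-time convention is switch-ready. The
rule is monotone: appending a later confirming value can create an event but
never remove one.

**Incidence.** Rate = 1000·k/T per 1000 person-years with the exact Garwood
interval, `[χ²(α/2, 2k)/2T, χ²(1−α/2, 2k+2)/2T]`, lower bound 0 at k = 0.

**Survival.** Kaplan–Meier, k-sample logrank and Cox proportional hazards
are provided by lifelines behind this module's interface. Cox uses Efron's
tie correction (the standard of the survival ecosystem); categorical
covariates are indicator-coded with the largest level as reference unless
overridden (subgroup reference forced to MOD in the study configuration);
the progressive-CKD model additionally adjusts baseline eGFR. The
proportional-hazards assumption is tested per covariate by the
Grambsch–Therneau correlation of scaled Schoenfeld residuals with event-time
rank. Restricting the CKD analysis to baseline eGFR > 60 is available as a
cohort filter rather than hard-wired, since the upstream restriction is
ambiguous between the plotted and modelled analyses.

**Event-time generator.** Constant baseline hazard (Weibull shape exposed,
default 1 — Cox HR recovery is shape-agnostic) scaled by
`exp(subgroup log-HR + 0.05·(age − 55) + 0.3·[male])`; administrative
censoring per participant uniform on (6.3, 8.3) years, targeting a 7.3-year
median follow-up, with optional random exponential censoring. Baseline rates
(events/person-year at the covariate reference) are 0.0068 for progressive
CKD, 0.0064 for heart failure, 0.009 for MACE and 0.010 for mortality —
chosen to match the reference subgroup's published crude-incidence scale.

## 7. Orchestration and reproducibility

A single master seed fans out per stage via
`SeedSequence([master, crc32(stage_name)])`, masked to 31 bits; stages are
therefore individually re-runnable and the full report is bit-for-bit
reproducible for a fixed config (config identity is tracked by a SHA-256
hash of the serialised settings). Problem sizes used by the packaged
checks — 10-seed ensembles for cluster proportions, 20 seeds for the
optimal-k vote and Cox recovery, B = 500 bootstrap replicates, n = 5000
event-time cohorts, 200-replicate null calibrations — were chosen as the
points where the measured statistics stabilise while a full run stays
interactive on a single CPU.

## 8. Limitations

- Calibration fidelity is bounded by what published summary tables report:
  no correlations, no tails beyond the parametric families, hard-partition
  geometry replaced by overlapping mixtures (§1, §3).
- The lipid generator plants log-scale location shifts only; dispersion or
  shape differences between subgroups are not modelled.
- No competing risks, time-varying covariates, or informative censoring in
  the survival stage; MACE and heart-failure events arrive as coded inputs.
- The PRS stage performs no LD handling or PC computation; panels are data.
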