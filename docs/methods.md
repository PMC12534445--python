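# Methods

## Data model

The unit of observation is the bout: one episode of interaction between an
immature individual and a single object, coded into a closed seven-category
ethogram (tool, doll, aggression, game, locomotion aid, physical
stimulation, play nest) and as typical (matching established adult forms)
or atypical, with atypical bouts subdivided into omission (attempted adult
form missing key elements) and commission (novel, modified or
recontextualized use). Unknown categories are rejected rather than coerced:
the ethogram is closed by design, and silent coercion would hide coding
errors. Ages are stored as decimal years with no rounding on ingest;
whole-year binning (for age diversity and the young/old comparison) happens
downstream. Files are comma-separated UTF-8 with a header row; optional
fields serialize as empty cells, and floats are written in repr form so
read∘write is the exact identity.

## Exploration Index

Five per-individual metrics: total bouts; category diversity (1–7);
atypical proportion; object-use rate (bouts per observation hour); age
diversity, the number of distinct whole-year age points (0, 1, 2, … yrs,
realized as floor(age)) at which bouts occurred. Each is z-transformed
across individuals with the sample SD (n−1), the default of the mainstream
statistics stacks, and the index is the sum of the five z-scores. Two
conventions worth noting:

- A zero-variance metric contributes zeros for everyone instead of
  erroring, which keeps the composite defined on degenerate (e.g. tiny
  simulated) datasets.
- The fourth metric has two published phrasings — raw observation hours
  vs. bouts per hour. The rate is the operational definition and the
  default; `metric4="hours"` switches to raw hours for sensitivity checks.
  (The index is invariant to affine rescaling of any raw metric, so the
  choice of units never matters; the choice of *rate vs. hours* does.)

All profiled individuals enter every z-transform; individuals with zero
bouts are excluded upstream, mirroring a study design in which only
object-using subjects are scored. Whether a 0.5-year-old's bout counts as
age point 0 follows from floor(); exact integer ages fall in the bin they
name.

## Explorer classes

Because the index is scalar, the k-means objective is minimized by a
partition contiguous in sorted order. We therefore compute the *global*
optimum by dynamic programming over cut positions (O(k n²) with prefix
sums) instead of Lloyd's algorithm: no seeds, no restarts, and the
partition — the headline descriptive result — is perfectly reproducible.
k is selected over k = 1…6 (36 individuals cannot support more) by the
elbow method, formalized as the k in 2…k_max−1 maximizing the discrete
second difference wcss(k−1) − 2·wcss(k) + wcss(k+1), ties toward smaller
k; a constant input returns k = 1.

A consequence used in the tests: an optimal 2-partition is a threshold
rule, so every high-cluster value exceeds every low-cluster value and the
Mann–Whitney U between the clusters is forced to n₁·n₂ in the
high-orientation and 0 in the other. Both printed orientations of the
same comparison are reported (`u_statistic`, `u_min`).

## Inferential machinery

All estimators are written from scratch on numpy/scipy; statsmodels and
scikit-learn appear only as independent cross-checks in the tests.

**OLS.** Least-squares via `lstsq`, classical covariance
σ̂²(XᵀX)⁻¹ with σ̂² = RSS/(n−p). Normal-based p-values and CIs, matching
the z-value convention used throughout.

**Huber robust regression.** IRLS on the Huber ψ with tuning constant
c = 1.345 (95% Gaussian efficiency); residual scale = median(|r|)/Φ⁻¹(3/4)
(the MAD about zero, ×1.4826) recomputed every iteration; convergence when
the maximum coefficient change is below 1e-8, cap 50 iterations
(non-convergence returns `converged=False` with the iterate trace rather
than raising). Standard errors use the sandwich form with Huber's
degrees-of-freedom correction — the "H1" covariance of the mainstream
stack — so the full coefficient table (estimates, SEs, scale) agrees with
that stack to numerical precision on well-behaved data, which the suite
asserts at 1e-7. Zero MAD (a majority of exactly-fit residuals) falls back
to the OLS scale with a warning. Treatment contrasts use female and
primiparous as reference levels.

**Logistic regression.** Newton–Raphson on the log-likelihood with step
halving (the log-likelihood is non-decreasing across iterations by
construction), SEs from the observed information. Perfect separation by a
single covariate is detected up front from non-overlapping class supports
and raised with the covariate's name; divergence (|β| > 1e4) is flagged as
quasi-separation. The atypicality model is fit at the bout level —
atypical(1)/typical(0) on age at bout — because the published comparisons
are phrased in percentages *of bouts*; an individual-level aggregation is
available as a sensitivity alternative. No cluster-robust adjustment is
applied, matching the simple published model.

**Mann–Whitney U.** Midranks for ties; both orientations reported
(u_statistic + u_min = n₁n₂). The two-sided p-value is exact — computed
from the full rank-sum null distribution via dynamic programming — when
n₁+n₂ ≤ 20 and there are no ties (the enumeration is cheap there);
otherwise the normal approximation with tie and continuity corrections.
The exact path matches full enumeration over all C(N, n₁) labelings and
scipy's exact method to 1e-12 in the tests.

**Variance components / ICC.** One-way random-intercept model
y_ij = μ + b_i + e_ij, fit by REML profiled down to a one-dimensional
optimization over λ = σ²_b/σ²_w (grid bracketing + bounded refinement,
λ = 0 boundary checked explicitly), exact for unbalanced group sizes; the
ANOVA method-of-moments estimator is the independent cross-check and
agrees with REML to 1e-6 on balanced designs, as theory requires. Negative
component estimates truncate at zero, so ICC ∈ [0, 1]. REML (not ML) is
the default because it is the default of the stack the analysis mirrors;
the ANOVA estimator is available via `method="anova"`.

## In-study fixture

`table1_fixture()` reconstructs the published bout accounting exactly:
67 bouts by 36 individuals; category and subcategory counts (tool 28 with
leaf-clipping 1 / leaf-grooming 8 / leaf napkin 1 / sponge 12 / stick
tools 6, game 11, play nest 9, physical stimulation 8, aggression 7, doll
2, locomotion aid 2); 34 typical vs. 33 atypical with 2 omission and 31
commission; 56 bouts at ages ≤ 4 years of which 30 atypical and 11 above
4 years of which 3 atypical; per-individual bout counts 1–5 with 16
multi-bout individuals and four individuals active at more than one
whole-year age; 7 maternal sibling pairs; observation hours in
[2.72, 37.24] summing to 569.58. Per-individual attributes the published
tables do not print — exact ages, each subject's hours, which individuals
pair as siblings, parity of singleton mothers — are synthesized
deterministically and marked as such in the source; only the aggregate
constraints above are guaranteed. Consequently the fixture's regression,
ICC and clustering outputs are illustrative, not reproductions: the
published coefficient table depends on the deposited per-individual data,
which the package accepts at `data/deposited/` when available.

Two printed figures are knowingly inconsistent in the source tables
(typical share 50.8% vs. 34/67 = 50.7%; mean contact hours 14.99 vs.
569.58/36 = 15.82); the fixture and tests follow the integer counts and
totals, which are self-consistent.

## Synthetic-data generator

`simulate_dataset` emulates the study design: n = 36 subjects (sex
Bernoulli 1/2; maternal parity Bernoulli 1/2 with pair-mothers forced
multiparous), 7 sibling pairs sharing maternal ID and a maternal random
effect, observation hours uniform on the reported [2.72, 37.24] h, subject
ages uniform on [0.5, 13] yr. Bout counts are zero-truncated Poisson with
log-rate

log r_i = log(r₀) + [female]·log(2.2) + [multiparous]·log(2.6)
          − 0.16·(age_i − mean age) + m_(mother) + ε_i,

with r₀ = 67/569.58 bouts/h (the study's overall rate, read as the
reference-class rate: male, primiparous offspring at the mean age with
zero latent effect), ε ~ N(0, 0.5²) a latent exploration propensity, and
the maternal SD set from the target intraclass correlation by the
closed-form identity τ² = ICC/(1−ICC)·σ²_ε (default ICC 0.10). Bout ages
fall within ±1 yr of the subject's age; categories are multinomial in the
observed 7-category mix (tool 28/67, …); typicality is Bernoulli with
logit 0.5 − 0.2·age + 0.3·(m+ε); atypical bouts are commission with the
observed 31:2 odds. All draws flow through one `default_rng(seed)` stream
in fixed order, so a seed pins the dataset bit for bit across platforms.

Effect magnitudes (2.2× female, 2.6× multiparous, −0.16/yr) are the
package's own design choice where the source reports only directions: they
were set, in a design study run before the test expectations were frozen,
so that the *realized* coefficients of the downstream robust regression
match the reported effect sizes on the index scale (median ≈ −2.2 for sex,
≈ +2.5 for parity over replicates) and all three signs are recoverable in
well over 95% of replicates at n = 36.

What the generator does *not* emulate: because the effects multiply the
reference rate upward, generated datasets are considerably denser (≈10
bouts per subject) than the field data (1.86); bout counts are
conditionally Poisson (no behavioral bursts or observation-process biases
such as focal vs. ad libitum sampling); ages are uniform rather than
concentrated at 1–3 years; and the index's distributional family in real
data is unknown — the generator's Gaussian latent structure and the
bimodal helper (`simulate_bimodal_explorers`) are stand-ins. Passing
recovery tests therefore demonstrates correctness of the estimators under
a clearly detectable signal, not that a 67-bout field sample has that
power.

## Pipeline

`run_pipeline` executes validate → typicality → metrics → clustering →
logistic → OLS/Huber regression → ICC, logging stage timings to stderr and
never interleaving logs with report content. Degenerate inputs mark
sections skipped with a reason instead of failing: clustering needs ≥ 4
profiled individuals, the regressions ≥ 6 (four parameters), the ICC ≥ 2
mothers with at least one of them contributing ≥ 2 offspring, the logistic
≥ 2 bouts in each outcome class. JSON output is schema-stable and sorted,
with no timestamps, so identical inputs and configuration reproduce
byte-identical reports; provenance carries SHA-256 hashes of the input
files, the full configuration and the package version.

## Problem sizes used in the tests

Oracle-equivalence tests run at the sizes where exhaustive enumeration is
exact and fast: all 2- and 3-partitions at n ≤ 12 for k-means, all
C(N, n₁) labelings at N ≤ 10 for the exact U null, 12–20-point toys for
the grid-search regression oracles. Recovery tests use 200 replicates of
the n = 36 generator for the robust-regression signs, 200 groups × 5 for
ICC recovery at 0.10 ± 0.03, and ≈2000 bouts for the logistic age slope
(±0.05). The full suite completes in well under a minute on one core.

## Known limitations

- The published coefficient table cannot be recomputed without the study's
  deposited per-individual data; the dedicated test documents this and
  reports the values the aggregate-faithful reconstruction gives instead.
- The elbow rule needs wcss at k−1 and k+1, so it can only select
  k ∈ {2, …, k_max−1}; genuinely unimodal data still yield k = 2 unless
  the input is constant (the published method shares this property).
- The exact-U path is limited to untied samples with n₁+n₂ ≤ 20;
  beyond that the tie/continuity-corrected normal approximation is used.
- The REML optimizer searches λ ∈ [0, 10⁴] (ICC ≤ 0.9999); an exactly
  zero within-group variance is special-cased to ICC = 1.
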