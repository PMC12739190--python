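# Methods

## The score

The Dental Diet Risk Score is the affine composite

DDRS = w_S·S + w_A·A + w_K·(100 − K) + w_Q·(100 − Q),
(w_S, w_A, w_K, w_Q) = (0.40, 0.20, 0.25, 0.15),

over four 0–100 dietary components: free-sugar exposure S and
acidic-beverage exposure A (risk direction), protective-food intake K and
overall diet quality Q (protective direction, entered inverted). With
non-negative weights summing to one, the score is exactly bounded in
[0, 100], strictly increasing in S and A, strictly decreasing in K and Q,
and linear in the weight vector at a fixed profile. The score is kept
unrounded internally; integer rounding is presentation-only.

## Synthetic cohort model

No real cohort jointly observes the four components and the three indices
(MEDAS, DPI, HEI), so the study is simulation-based. Each profile draws a
latent diet-quality factor H ~ Beta(a_H, b_H) on [0, 1] and four
independent noise variables U_i ~ Beta(α_i, β_i) with α ∈ [2, 5],
β ∈ [3, 6] — right-skewed, bounded shapes of the kind seen in NHANES-style
intake distributions. Components are convex mixtures

S = 100·[(1−λ_S)·U_S + λ_S·(1−H)]    (A analogous),
K = 100·[(1−λ_K)·U_K + λ_K·H]        (Q analogous),

so they respect [0, 100] by construction with no clamping. The indices
share the same factor: DPI = clamp(K + ε, 0, 100) with ε ~ N(0, σ_dpi),
HEI likewise from Q, and MEDAS_raw ~ Binomial(14, p) with
p = clamp((1−λ_M)/2 + λ_M·H, 0.02, 0.98). MEDAS is modelled as a binomial
total rather than 14 item-level indicators because only the rescaled total
enters any analysis. Only DPI/HEI are clamped; the clamped fraction is
reported as a diagnostic (≈1–2 % at the calibrated noise scales).

A single shared factor with per-component loadings is the smallest
structure that can induce the full pattern of inverse DDRS–index
correlations; it was preferred over copulas because the convex mixture
keeps components in range without distorting tails.

### Calibration

The loadings and index noise scales are free parameters with no direct
empirical anchor. They are fixed once by `calibrate_generator`: a grid
search (built by `build_calibration_grid` around an analytic
moment-matching solution) minimizing the summed squared deviation of the
three correlations (native scale) and four variance shares (÷100) from
their target values, each candidate evaluated on an n = 10,000 cohort with
the fixed calibration seed 7. Calibration fails loudly — reporting the
best deviations achieved — unless every correlation lands within 0.05 and
every share within 5 points. The winner is frozen as a versioned fixture
(`src/ddrs/data/calibrated_generator.yaml`): H ~ Beta(2, 2), noise
Beta(2, 3) for all components, λ = (0.66, 0.57, 0.73, 0.50), λ_M = 0.49,
σ_dpi = 16.8, σ_hei = 15.8. Runtime always loads the fixture and never
re-calibrates silently. Production runs default to seed 42; all CLI
commands expose `--seed`.

### Scenario presets

The healthy / unhealthy / mixed cohorts are generated from frozen preset
configurations (`scenario_presets.yaml`) rather than filtered from the
pooled sample: under the calibrated generator, profiles with all three
indices simultaneously ≥ 70 are rare (≈2 % of the pooled cohort), so
filtering yields small, truncation-biased groups. Presets re-shape the
latent factor (healthy: Beta(7, 1); unhealthy: Beta(1.5, 17)) and adjust
noise shapes within their admissible ranges; the mixed preset additionally
decouples protective-food intake from the latent factor (λ_K = 0 with a
low-mean Beta(2, 6) noise), since moderate MEDAS/HEI with low DPI cannot
arise from a one-factor shift. Threshold-based classification of arbitrary
cohorts (healthy iff all indices ≥ 70, unhealthy iff all ≤ 30, else mixed —
a complete partition) remains available and is what `DDRSModel.fit()`
applies to its own cohort.

## Statistics

* **Correlations.** Sample Pearson r; 95 % CI by Fisher z
  (atanh(r) ± 1.96/√(n−3), back-transformed); two-sided p from the
  t-distribution with n − 2 df. At n = 10,000 the Fisher interval half-width
  is ≈0.012 — narrower than the roughly ±0.03 intervals often quoted for
  these headline correlations; the package reports the Fisher interval and
  makes no attempt to reproduce wider CIs whose method is unspecified.
* **Variance decomposition.** share_i = 100·Cov(term_i, DDRS)/Var(DDRS)
  over the four weighted terms. Covariance shares are exact under
  arbitrary correlation between terms and sum to 100 identically
  (bilinearity), which the suite asserts at 1e−9; under independence they
  reduce to w_i²σ_i²/Σ w_j²σ_j², the closed form used as the test oracle.
  Order-dependent LMG-style attribution was not used: for a fixed linear
  composite the covariance share is unique and order-free.
* **Contrasts.** Welch's t-test (no equal-variance assumption) and
  Cohen's d with the pooled-SD (n₁+n₂−2) denominator.
* **Quantiles.** Medians/IQRs use linear interpolation between order
  statistics.

## Weight sensitivity

`perturb_weights` multiplies one weight by a factor and rescales the other
three by a common multiplier so the four again sum to one (exact, property
tested); it raises an infeasible-perturbation error when the scaled weight
would reach 1.

The tornado analysis and the 0.30 → 0.50 sugar-weight experiment default to
**one-at-a-time perturbation without renormalization**. The two semantics
answer different questions. Without renormalization the change in mean
score is (Δw_i)·mean(term_i)/w_i — the lever arm of that weight — giving
the classical tornado reading and, for near-equal term means, a
0.20/0.90 ≈ 22 % rise in mean DDRS when w_S moves from 0.30 to 0.50.
Under proportional renormalization the mean change reduces to the
difference between one component's mean and the weighted mean of the
others, which is near zero for any cohort with comparable component levels
(≈−2 % on the calibrated cohort) and makes all tornado bars vanish for
i.i.d. equal-mean components. Both are available via `renormalize=`; the
sensitivity effect size is the change in the cohort *mean* DDRS (median- or
ratio-based definitions would differ slightly and are not used).

## Convergence

`convergence_check` draws one master cohort at the largest grid size from a
dedicated substream and recomputes the three correlations and four shares
on nested prefixes at each grid n. Nested prefixes isolate the pure
sample-size effect: with independent cohorts per n the successive delta of
r near n ≈ 9,000 has standard deviation ≈0.009, the same order as the 0.01
stabilization tolerance, so a perfectly converged generator would still
"fail" stochastically. The stabilization size is the smallest grid point
after which every successive change stays below tolerance (0.01 for r,
1 point for shares); on the calibrated generator with the default
1,000–12,000 grid this is reached well below 10,000, consistent with a
Monte Carlo SE of r of ≈0.006 at n = 8,000.

## Orchestration and determinism

`run_study` spawns independent substreams from the master seed
(main cohort, three scenario cohorts, convergence) via `SeedSequence`, so
changing one stage's configuration does not perturb the others. All CSV
artifacts are written with fixed six-decimal formatting and `\n` line
endings; reruns under the same config are byte-identical, and the run
manifest (config + hash + package version) suffices to re-execute a run.
Default problem sizes are those of the study design — 10,000 main profiles,
2,000 per scenario cohort, convergence grid 1,000–12,000 — and the whole
pipeline runs in a few seconds on one CPU; tests use smaller smoke sizes
(100–800) where the statistic under test does not depend on n.

## What the simulation does and does not show

The generator reproduces the *statistical skeleton* the analysis assumes:
bounded skewed marginals, a common latent quality factor, index noise, and
the headline correlation/variance structure. It does not model real dietary
behaviour — no food-level items, no energy intake, no measurement error
structure, no demographic covariates — so passing tests demonstrate
internal consistency and reproducibility of the scoring and analysis
machinery, not clinical validity of the score. Validation against real
oral-health outcomes (DMFT, plaque, periodontal indices) is explicitly out
of scope.

## Known limitations

* The calibrated parameters are one consistent solution, not a unique one;
  other loading/noise combinations could match the same seven targets.
* MEDAS's binomial model caps its normalized mean at 25–75 for λ_M = 0.5
  unless H is extreme (the p-clamp at 0.02/0.98 binds only at the tails).
* Fisher CIs understate the width of intervals produced by other CI
  methods (e.g. bootstrap on non-Gaussian data) at this n.
* The variance decomposition attributes shared (latent-factor) variance to
  each term through its covariance with the total; it is not a causal
  attribution.
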