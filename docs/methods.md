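# Methods

## Model

The analysis models each retained first-response RT through the
shifted-lognormal transform `y = log(RT − s)` with shift `s = 0.2` s.
The standard model is a linear mixed model on `y`:

    y_n = μ + b[superblock_n] + θ·x_n + u_i(n) + t_i(n)·x_n + ε_n

- `x = 1` on incongruent trials, 0 on congruent, so `θ` is directly the
  log-scale conflict effect. Because the model is additive on the log
  scale, a constant `θ` means the *ratio* of incongruent to congruent
  (RT − 0.2) is constant: the seconds-scale conflict effect shrinks
  proportionally as practice speeds responding.
- `b` holds one additive practice offset per 48-trial superblock (four
  12-trial blocks), constrained to sum to zero. Practice is categorical
  rather than a linear trend because empirical speeding is typically
  non-linear (fast early gains). Fits to a single superblock (the
  48-trial aggregation level) drop the practice term.
- `u_i ~ N(0, σ_I²)` subject intercepts, `t_i ~ N(0, σ_T²)` subject
  conflict slopes, `ε ~ N(0, σ_N²)` trial noise. Intercepts and slopes
  are independent: conventional mixed-model defaults for this design
  assume no intercept–slope correlation, and the data sizes involved
  identify such a correlation poorly.

Comparison variants: `no_practice` removes `b`; `interaction` adds
sum-to-zero superblock × conflict offsets.

Trait precision is `η = σ_T / σ_N`, computed draw-wise from the
posterior. Reliability and planning quantities follow the three-equation
system in the README. Note the deliberate notational asymmetry: the
planning equation treats `r` as the observed–true *correlation*, whose
square is the variance-ratio form of reliability. The package implements
the planning equation verbatim because only that form reproduces the
conventional planning numbers (≈420 total trials at η = 0.13 for
r = 0.8; trait SD ≈ 1.35 and ≈2 standard errors at r = 0.8 and 0.9);
the consistency `ratio-form(L(η, r)) = r²` holds exactly and is enforced
by a property test rather than "fixed".

## Priors and sampling

- Effect coefficients (conflict, practice, interaction): independent
  N(0, 0.5²). The response is on the natural-log scale where conflict
  effects are ~0.1, so 0.5 is weakly informative. Intercept: N(0, 10²).
- Standard deviations σ_I, σ_T, σ_N: half-Cauchy with scale 1.0
  (random effects) and 1.0 (residual), implemented through the
  Huang–Wand inverse-gamma mixture so every conditional stays conjugate.
  Degenerate fits (σ_T → 0) are handled by the posterior piling up mass
  near zero; σ draws remain strictly positive.
- Sampler: blocked Gibbs — the fixed-effect vector jointly from its
  multivariate-normal conditional, subject intercepts and slopes in
  vectorized per-subject updates, then variances and auxiliaries. Two
  exact generalized-Gibbs translation moves (shifting mass between μ and
  the mean of `u`, and between θ and the mean of `t`) are interleaved;
  the likelihood is invariant along these directions, so the move has a
  closed-form Gaussian conditional, and it removes the random-walk
  coupling that otherwise cripples mixing of the fixed effects.
- Defaults: 4 chains × (1000 warmup + 2500 draws); convergence gated at
  R-hat ≤ 1.01 and bulk ESS ≥ 400 (arviz). A failed gate attaches a
  warning and flags the result — never silently.
- Exact equality with any particular R toolchain's default Bayes-factor
  implementation is a non-goal; Bayes factors are validated by direction,
  order of magnitude, and cross-method agreement.

## Bayes factors

BF1 = p(y | standard) / p(y | no practice); BF2 = p(y | standard) /
p(y | interaction). Two estimators:

- **Bridge sampling** (default for `marginal_likelihood`): subject
  random effects are integrated out analytically (Woodbury identities on
  the per-subject 2×2 blocks), leaving a low-dimensional posterior over
  (β, log σ). A moment-matched Gaussian proposal and the iterative
  optimal-bridge estimator give each log marginal likelihood; the SE is
  a batch standard error over four disjoint draw batches.
- **Savage–Dickey** (pipeline default, faster): both comparisons are
  nested (practice block = 0; interaction block = 0), so the BF is the
  prior-to-posterior density ratio at the zero block. The posterior
  density at zero is Rao-Blackwellised: each Gibbs iteration evaluates
  the exact Gaussian conditional density of the tested block at zero,
  and these are averaged. The SE is the spread of per-chain estimates.

Comparing a model with itself reuses the same marginal-likelihood
estimate, so the self-BF is exactly 1. Estimates whose log-scale SE
exceeds 0.5 are flagged.

## Synthetic data

The generator is the exact inverse of the standard model plus
contamination, organised as 12-trial blocks with congruency balanced per
subject (within one trial of the target split, randomly intermixed) and
double-shot flags on a random third of trials (first responses only are
simulated; second responses never enter the analysis). Contamination:

- anticipatory presses, probability 0.02, RT ~ Uniform(0.05, 0.245) s —
  deliberately below the 0.25 s filter so preprocessing is exercised;
- lapses, probability 0.01, recorded as missing RT and incorrect;
- errors, Bernoulli per condition (defaults 3% congruent / 7%
  incongruent). Error rates are free parameters of the generator, not
  estimates from any dataset.

Default generative truth: μ = −0.7 (≈0.7 s mean RT), θ = 0.10,
σ_I = 0.30, σ_T = 0.06, σ_N = 0.35 (η ≈ 0.17, in the range observed for
conflict tasks), practice declining linearly by 0.1 log units across 9
superblocks (≈10% total speedup, sum-to-zero).

What the generator does *not* emulate: speed–accuracy trade-offs,
sequential (post-error / congruency-sequence) effects, fatigue-driven
drift in the variance components, RT–accuracy coupling, and second
(double-shot) responses. Passing tests therefore demonstrate that the
pipeline recovers the model's own data-generating process and that its
planning algebra is exact; they do not certify the shifted-lognormal
model against real data, which must be checked per dataset (e.g. via the
practice-effect Bayes factors and fit summaries).

## Preprocessing rules

Participants are excluded (whole-subject) for overall accuracy < 60%,
for > 10% anticipatory trials (RT < 0.1 s), or for > 10% non-responses
(missing or slower than 4 s) — strict inequalities exactly as stated, so
accuracy of exactly 0.60 is retained. Trials are removed when RT < 0.25 s
(anticipatory), missing, or (by default) incorrect; `correct_only=False`
keeps error RTs, since either convention appears in the literature.
Cumulative aggregation levels (48, 96, …, 432 trials) are defined by
*scheduled* block membership: trial filtering may leave fewer retained
rows per level, which mirrors how sessions accumulate in practice.

## Numerical choices

- Quantiles (credible intervals, medians) use linear interpolation.
- Seconds-scale equivalents: the conflict effect is
  `exp(μ)(exp(θ) − 1)` per draw (mean practice offset is zero under the
  sum-to-zero constraint); trait and noise SDs have no closed seconds
  form here, so each posterior draw is transformed by Monte Carlo with
  10⁴ shared standard-normal auxiliaries (common random numbers across
  draws).
- Trials-required curves apply the planning equation to each posterior η
  draw; credible bands are draw-wise quantiles. The identity-line
  crossing is linearly interpolated between adjacent aggregation levels
  on the median curve (and likewise on the band edges). An alternative —
  transforming the η interval endpoints instead of the draws — gives
  nearly identical bands because the transform is monotone; draw-wise is
  used throughout. A curve that stays above the identity line reports
  "not reached within measured range"; one already below it at the first
  level reports that level.
- One global pipeline seed spawns per-stage seeds via
  `numpy.random.SeedSequence`, so partial reruns and full reruns agree;
  outputs are bit-reproducible given config + seed (manifest checksums
  are compared in tests).

## Problem sizes

Package defaults target study scale (30–200 subjects × 432 trials,
4 × 2500 draws; roughly a minute per full cumulative analysis). The test
suite runs the same code at reduced scale — typically 2 chains ×
(300 warmup + 400 draws), 8–100 subjects, with the convergence gate
relaxed to match (R-hat 1.05, ESS 50) — sizes chosen to keep the suite
quick while leaving Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

- Reliability here corresponds to split-half-style (within-session)
  reliability; test–retest stability over days or weeks will be lower
  and needs two-session data and a model with session effects (out of
  scope).
- No intercept–slope correlation; no heavy-tailed or skewed residuals
  beyond what the log transform absorbs.
- The Savage–Dickey estimator degrades when the posterior of the tested
  block sits far from zero (BF1 with a huge practice effect); the
  reported SE and the bridge-sampling cross-check expose this.
- Accuracy-based conflict measures and evidence-accumulation modelling
  are out of scope.
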