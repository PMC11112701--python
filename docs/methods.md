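# Methods

This note records the models implemented in `srtsim`, the defaults chosen
where the emulated study protocol leaves freedom, and what the simulation
can and cannot establish about real child listeners.

## The listener model

A simulated child is defined entirely by a word-level logistic psychometric
function per familiarity condition:

    p(snr) = 1 / (1 + exp(−(snr − SRT_c)/β)),

SRT_c in dB SNR, β in dB. Guess and lapse rates are fixed at zero
(asymptotes at 0 and 100%), which makes the 50% point identical to the
logistic midpoint — the defining property the fitting stage relies on.

Keywords within a sentence are conditionally independent given SNR by
default (`keyword_rho = 0`). Real keyword errors within a sentence
correlate (shared glimpses, attention lapses); an exchangeable Gaussian
copula with correlation `keyword_rho` is available, but no empirical basis
exists for a default other than 0, so 0 it is. Under independence the
sentence-level success probabilities have closed forms — P(≥1 of k) =
1 − (1−p)^k and binomial tails for stricter criteria — which serve as exact
oracles for the staircase equilibria.

The psychometric slope β defaults to 2.0 dB, a typical value for sentence
material in speech maskers. It is *uncalibrated*: the emulated study
reports only fit r², not slopes, so this default is a field-plausible
choice, configurable in `CohortConfig.slope_db`.

## Cohort generation

True SRTs follow

    SRT(i,c) = β₀ + β_age·(log₁₀ age_i − mean log₁₀ age) + β_c + b_i + ε_ic

with b_i ~ N(0, σ_subject²) and ε_ic ~ N(0, σ_resid²). Defaults (dB):
β₀ = −2.75, β_age = −16.21 per log₁₀(year), β_familiar-target = −3.36,
β_familiar-masker = −0.20, baseline condition coefficient 0. Ages are
uniform on [8.5, 13.1] years and log₁₀ age is centered at the generated
cohort's own sample mean, the same convention the analysis model uses.
Interaction terms are absent from the generator (the study-level structure
puts them at ≈ 0), while the analysis model estimates them.

σ_subject = 3.4 and σ_resid = 2.2 are calibrated so the *marginal*
per-condition SD reproduces the ~4.1 dB observed between children:

    var = σ_subject² + σ_resid² + β_age²·var(clog₁₀ age)
        = 11.56 + 4.84 + 262.8·0.0029 ≈ 17.2  →  SD ≈ 4.15 dB.

The split between subject and residual variance is not identified by a
marginal SD alone; 3.4/2.2 apportions roughly 70% of the non-age variance
to the stable subject component, consistent with the strong between-subject
correlation across conditions such designs show. Both are configurable.

## Corpus and sentence bookkeeping

Lists of 16 sentences with keyword counts in {3,4} summing to 50 admit
exactly one composition (fourteen 3s, two 4s); the generator randomises
only the positions of the 4-keyword sentences. Sentence durations are
truncated-normal (mean 1.8 s, SD 0.3 s, floor 1.0 s) — purely nominal,
chosen so the 24-sentence masker streams land near their ~45 s target
duration. Masker inter-sentence gaps are exponential (mean 0.15 s) capped
at 0.2 s, mirroring the manual pause-editing step. Level normalisation is
represented symbolically (all tokens at equal nominal level); no signal
processing is performed anywhere.

Per simulated child, a random starting list in 1–18 is drawn and sentences
are consumed in numerical list order across practice (16 sentences) and the
three 40-sentence condition blocks, wrapping at list 18 and never reusing a
sentence within a child.

## Adaptive procedure

Two one-down/one-up staircases per condition, interleaved, sharing the
sentence queue: lax (sentence correct iff ≥ 1 keyword) and strict (≥ 3).
Start +7 dB SNR (practice +10), 20 trials each, step 4 dB before the first
reversal and 2 dB after. Implementation choices where the protocol
description leaves room:

- **Reversal** = change of direction between consecutive *movements*; the
  first movement sets a direction without counting. The reversal caused by
  a movement is registered *before* choosing that movement's step, so the
  movement on which the first reversal occurs already uses 2 dB.
- **Interleaving** is a seeded uniform choice among unfinished tracks
  (strict alternation available via `schedule="alternate"`); analysis-level
  results are insensitive to this choice.
- **No SNR bounds** by default — measured tracks can in principle climb to
  +40 dB SNR and beyond, which the outlier stage handles; optional clamps
  exist in `TrackConfig`.
- The practice block is simulated (the listener model is stateless, so it
  cannot affect later blocks) and excluded from analysis.

A one-down/one-up rule converges on the 50% point of the *sentence-level*
function under its criterion, so the lax track equilibrates below the
word-level SRT and the strict track above it; the pooled keyword data
bracket the word-level function from both sides, which is what makes the
two-criterion design efficient for estimating both midpoint and slope.

## Psychometric fitting

Every keyword is one Bernoulli observation at its sentence's SNR; both
tracks' keywords are pooled and the two-parameter logit is fitted by
maximum likelihood (equivalent to a logit GLM with the slope constrained
positive). The likelihood objective is chosen because the data are
keyword-level Bernoulli outcomes; a least-squares fit to per-SNR
proportions is the main alternative recipe and yields nearly identical
SRTs on this design, but is not the default. Optimisation: L-BFGS-B on
(α, log β), analytic gradient, deviance tolerance 1e-8, three starting
points, log β bounded in [log 1e-3, log 1e3]. Complete separation (every
correct keyword at or above every incorrect one) has no finite-slope ML
solution; such fits are flagged `converged=False` and emit no SRT.

Fit quality r² is the squared Pearson correlation between observed and
fitted proportion-correct over unique SNRs, keyword-count-weighted
(unweighted also reported); with fewer than three unique SNRs it is
undefined (NaN). Standard errors come from the observed Fisher information.

## Cohort analysis

- **Outliers:** a subject is excluded when any condition SRT lies more than
  4 SDs from that condition's mean computed over the *other* subjects
  (leave-one-out). Including the candidate inflates the SD and shrinks its
  own z-score: a +31 dB extreme in a 24-subject cohort with SD ≈ 4 dB is
  flagged robustly under LOO but only marginally otherwise.
- **Model:** `srt ~ clog10_age * condition + (1 | subject)`, REML, via
  statsmodels MixedLM; baseline = unfamiliar target/unfamiliar masker.
  When lbfgs ends on a singular Hessian the fit silently retries with
  bfgs/cg/powell; near-zero subject variance is flagged `singular`.
- **Degrees of freedom** use the containment convention: within-subject
  terms (condition, interaction) get n_obs − n_subjects − p_within
  (= 40 for 22×3), the between-subject age slope gets n_subjects − 2
  (= 20). The intercept is assigned to the within stratum. Exact df
  replication of every published mixed-model table is not promised — df
  conventions differ across software — but the (2, 40) and (1, 20) F-test
  df pairs of the canonical design are reproduced.
- The coefficient table reports two-sided p and additionally one-tailed
  p (= half), since directional hypotheses are conventional for the
  familiarity contrasts.
- **Main-effect F tests** are reported both from the full interaction model
  (Wald) and from an additive refit, since main effects are conventionally
  judged without the interaction present.
- **Contrasts:** LS-mean condition differences at the mean centered age
  (where interaction terms vanish), with one-tailed t oriented toward the
  planned direction (familiar target better), plus two-sided and Tukey
  studentized-range adjusted values (q = |t|·√2, k = 3 means).

The mixed-model fixed effects, SEs and variance components are verified in
the test suite against an independent R/nlme REML fit to 1e-3.

## F0 analysis

Semitone separation is 12·log₂(F0_target/F0_masker). Synthetic mother F0s
are truncated-normal N(200, 15²) on [160, 250] Hz — a realistic adult-female
range under which >3-semitone target/masker separations are rare, matching
the emulated talker pool. The age-controlled correlation residualises both
SRT and |semitones| on centered log₁₀ age (the same age scale as the mixed
model; the choice of scale is a design decision, absolute rather than
signed separation likewise) and reports Pearson r of the residuals with a
two-tailed t on n − 3 df. Zero-variance residuals (e.g. a variable
collinear with age) return NaN rather than a spurious value. F0 and SRT
are linked *only* through this correlational analysis: the listener
response model deliberately contains no F0 term.

## Problem sizes and numerics

The parameter-recovery experiment uses 200 replicate cohorts of 22 subjects
(three 40-trial condition blocks plus practice each), the size at which the
study-level fixed-effect structure was fitted; it completes in about two
minutes single-threaded. The Monte-Carlo SE of the 200-replicate mean age
coefficient is ≈ 1.2 dB — the age slope is intrinsically noisy at n = 22
because log₁₀ age spans only ~0.19 across 8.5–13.1 years. Staircase
equilibrium checks use 10⁴-trial tracks with a 200-trial burn-in. All
randomness flows from a single seed through `numpy.random.SeedSequence`
spawning, so every pipeline output is bit-reproducible given its seed.

## What passing tests do and do not show

The simulated listener is an idealisation: stationary, lapse-free, with a
shared slope and independent keywords. Recovery of the generating
coefficients through the full pipeline therefore demonstrates that the
*measurement and inference machinery* is unbiased and correctly
implemented — not that real children behave logistically, nor that human
fit-quality statistics (e.g. the observed r² range) will match: human r²
reflects attention drift and inter-trial dependence that this generator
deliberately omits. Simulated r² values run higher than human ones for
exactly that reason, and the test suite records rather than asserts them
against human figures.
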