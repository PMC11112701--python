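# srtsim

Simulated speech-reception-threshold (SRT) measurement and analysis for
child speech-in-speech experiments.

`srtsim` re-creates, end to end and without human subjects or audio, the
measurement machinery of a talker-familiarity study in school-age children:
open-set sentence recognition in a two-talker masker, measured adaptively
with two interleaved staircases and analysed with mixed-effects models.
It is intended for psychoacousticians and methodologists who want to study
the statistical behaviour of this class of adaptive protocol — bias and
variance of staircase SRT estimates, power of the cohort-level analysis,
sensitivity to scoring criteria — on simulated listeners whose ground truth
is known.

## What it implements

**Corpus.** A symbolic BKB-like sentence corpus: 21 lists × 16 sentences,
3–4 keywords each, exactly 50 keywords per list. Lists 1–18 are target
material; lists 19–21 form the two masker streams (list 19 + first half of
list 20, and second half of list 20 + list 21), with inter-sentence gaps
capped at 200 ms.

**Listeners.** A simulated child is a word-level logistic psychometric
function per familiarity condition,

```
p(snr) = 1 / (1 + exp(−(snr − SRT)/β)),
```

with asymptotes at 0 and 100%, so the word-level SRT is the 50% point.
Cohort ground truth follows a mixed-effects structure on centered log₁₀ age:

```
SRT(i, c) = β₀ + β_age·clog₁₀(age_i) + β_c + b_i + ε_ic,
b_i ~ N(0, σ_subject²),   ε_ic ~ N(0, σ_resid²),
```

with default fixed effects β₀ = −2.75 dB, β_age = −16.21 dB/log₁₀(yr),
β_familiar-target = −3.36 dB, β_familiar-masker = −0.20 dB (baseline:
unfamiliar target / unfamiliar masker), and σ defaults calibrated to a
4.1 dB marginal per-condition SD.

**Measurement.** Per condition, two interleaved one-down/one-up staircases
on target SNR (masker fixed at 70 dB SPL): a *lax* track (sentence correct
if ≥ 1 keyword correct) and a *strict* track (≥ 3 keywords). Each track runs
20 sentences starting at +7 dB SNR, stepping 4 dB until its first reversal
and 2 dB thereafter. Keyword data from both tracks are pooled and fitted by
maximum likelihood with the logit above; the measured SRT is the fitted 50%
point, with a per-SNR r² as fit quality.

**Analysis.** Subjects with an SRT beyond 4 leave-one-out SDs of any
condition mean are excluded; the rest enter a REML linear mixed model
`srt ~ clog10_age * condition + (1 | subject)` (statsmodels MixedLM) with
containment degrees of freedom, Wald F tests, and pairwise LS-mean condition
contrasts (one-tailed t and Tukey studentized-range adjusted p). An
exploratory module relates target/masker F0 separation in semitones
(12·log₂(F0a/F0b)) to SRTs via age-partialled correlation.

The package is organised statsmodels-style: `PsychometricModel(...).fit()`
returns a `PsychometricResults` (midpoint, slope, SRT, r², SEs, `summary()`,
`plot()`), and `SRTMixedModel(df).fit()` returns an `SRTMixedResults`
(coefficient table, F tests, variance components, contrasts, `summary()`,
`plot()`).

## Worked example

```python
from srtsim import RunConfig, run_experiment
from srtsim.pipeline import report

cfg = RunConfig(seed=42)          # 22 subjects, study-default protocol
run_experiment(cfg, "demo_run")
print(report("demo_run"))
```

prints (abridged):

```
Fixed-effect estimates (srt_db ~ clog_age * condition + (1|subject)):

                               term      beta        se        df         t         p  p_one_tailed
                          Intercept   -2.4141    0.7720   40.0000   -3.1270    0.0033        0.0016
                           clog_age  -23.9900   14.8292   20.0000   -1.6178    0.1214        0.0607
         condition[familiar_masker]   -1.4571    0.6758   40.0000   -2.1562    0.0371        0.0186
         condition[familiar_target]   -3.6212    0.6758   40.0000   -5.3586    0.0000        0.0000
...

Condition means:
      condition  n  mean_srt_db  sd_srt_db
familiar_masker 22       -3.871      4.400
familiar_target 22       -6.035      3.009
     unfamiliar 22       -2.414      3.667

seed = 42, subjects = 22 (0 excluded), sigma_subject = 2.84, sigma_resid = 2.24
```

Reading it: this simulated 22-child cohort shows the familiar-target
advantage (−3.6 dB vs baseline, the generating truth being −3.36 dB), a
negative age slope in dB per log₁₀(year) (noisy at n = 22 — its SE is
~15 dB), and no reliable familiar-masker effect. `trials.csv` holds every
staircase trial; `subjects.csv` the per-condition fitted SRTs and r².

The same pipeline is scriptable from the shell:

```
srtsim simulate --config cfg.yaml --seed 42 --out demo_run
srtsim analyze --in demo_run/subjects.csv --out demo_run/results
srtsim recover --seed 0 -r 200 --out recovery
srtsim report demo_run
```

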