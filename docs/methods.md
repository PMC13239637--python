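# Methods

This note documents the models, defaults and numerical choices behind
`fearcon`, and what the synthetic data can and cannot establish.

## Paradigm generation

The generator reproduces the two-day design exactly: habituation 3 CS+ / 3
CS−, acquisition 10 paired CS+/US + 6 CS+ + 16 CS− (62.5 % reinforcement),
extinction 16 + 16, recall 12 + 12; 8 s CS, US at CS onset + 7.9 s,
inter-trial intervals i.i.d. uniform on [14.3, 17.9] s (the distribution is
our minimal assumption; only the range is part of the design). Ordering
constraints: acquisition trials 1, 2 and 32 are reinforced, and each trial
kind is split equally between phase halves. The 3+3 habituation phase cannot
split 3 same-kind trials exactly; we allow a ±1 imbalance there, and the
validator checks exact equality wherever counts are even.

The day-1 ordering is fixed by an internal canonical seed so it is identical
for every participant, as is each of the two recall orderings (one per
counterbalance arm: recall opens with CS+ in arm A, CS− in arm B). A user
seed therefore only drives the inter-trial-interval draws; exactly two
distinct trial sequences exist (L = 2), which is what the fitting weights
w_l refer to. A 120 s pre-extinction fixation period (stimulation ramp-in)
is carried as design metadata and does not shift within-phase clocks.

## Synthetic skin conductance

Each phase is simulated as one continuous recording at 100 Hz (scoring is
sampling-rate independent well above the 10 Hz filter band; the original
hardware rate of 2 kHz would only cost runtime). A trial's phasic response is
a unit-peak biexponential kernel (rise 0.75 s, decay 2.5 s — canonical
sudomotor shape) scaled by

```
amp_t = Bernoulli(1 − p_nonresponse) ·
        (gain_orienting · habituation_rate^t + gain_expectancy · E_t + |N(0, σ_amp)|)
```

with response latency fixed at 1.5 s after CS onset (inside the 1–8.5 s
scoring window), an unconditioned response of gain 1.2 μS at US onset +
1.5 s on reinforced trials, and white measurement noise (σ = 0.02 μS).

The latent US expectancy E_t is a simple delta-rule (Rescorla–Wagner-style)
update per CS — deliberately *not* the replay model — so that fitting the
replay model to these data is a genuine recovery exercise rather than a
self-fit. Defaults: learning rate 0.35 during acquisition, 0.18 during
extinction/recall (slower unlearning), E = 0 throughout habituation.
Spontaneous recovery is planted directly: the sham group receives a
`recovery_boost` of 0.5 on its first six recall CS+ presentations with a
linearly fading profile; the verum group receives none. Amplitude scales are
calibrated to directionality only — no published expectancy-to-μS mapping
exists — so absolute simulated amplitudes are arbitrary but fixed.

What the generator does **not** emulate: tonic drifts and movement
artifacts, MR gradient noise, inter-individual kernel-shape variability, and
non-responders beyond the simple per-trial Bernoulli. Passing tests
therefore show that the pipeline's logic is correct under the stated
statistical structure, not that it is robust to every artifact of real
electrodermal recordings.

## SCR scoring

Traces are zero-phase low-pass filtered (4th-order Butterworth, 10 Hz,
mirroring the study hardware filter; applied once upstream of detection and
measurement). A response is the largest trough-to-peak amplitude whose
*onset* (the trough, a local minimum) falls inside the scoring window — the
peak may fall later. A (trough, peak) pair qualifies if the trough is the
minimum and the peak the maximum of the enclosed segment, no intervening
counter-movement falls by the minimum amplitude (0.01 μS) or more — a drop
that large marks the boundary of a separate response — the amplitude is at
least 0.01 μS, and the rise time (trough to peak, uncapped) is at least
500 ms. Peak ties resolve to the earliest attainment. Trials without a
qualifying pair score zero and remain in all analyses.

Raw amplitudes are averaged into blocks first and log-transformed second
(LN(1 + mean SCR)), matching the stated processing order; habituation forms
one 3-trial block per CS, acquisition/extinction early/late blocks of 8,
recall early/late blocks of 6. SCR_diff subtracts the CS− block mean from
the CS+ block mean on the log scale.

## Replay model

The value function is a fully connected network, two hidden ReLU layers of
64 units and a sigmoid output; v_t is read out *before* any update on trial
t, then (s_t, r_t, δ_t) is appended to unbounded memory (94 experiences at
most) and *i* batches of size *b* are trained by plain SGD on mean-squared
error toward the stored reinforcements. Loss, optimizer, learning rate
(0.01) and scaled-Gaussian initialization are fixed configuration constants:
none are part of the scientific claim, and all conclusions rest on
qualitative/penalty-region behaviour rather than exact v values. Stimuli are
two fixed orthogonal 8-bit binary codes of equal norm.

Replay priorities use the recency weight λ^τ with τ counted in trials since
storage, recomputed at every sampling call; with the RPE flag the stored
|δ| multiplies the weight (the experience tuple holds δ from storage time),
falling back to recency-only if all weighted priorities vanish. Batches are
sampled with replacement. Habituation trials are stored (r = 0) like any
other experience. Sleep replay runs exactly 100 batches of 64 with softmax
probabilities over r; an instrumented counter exposes the update count.
Trials continue to train during recall, which produces the within-recall
decay of the recovered response.

## Fitting

Target curves Ȳ_l stack per-presentation group means of log-transformed
CS-window scores, CS+ ordinals (1..47) before CS− ordinals. Model curves V̄_l
average v per ordinal across ensemble agents. SCR (log-μS) and prediction
(probability) scales are reconciled by min–max normalizing each whole
2N-entry curve to [0, 1] before the L1 comparison (epsilon-guarded for
constant curves); the norm is configurable to L2. Penalties are computed on
the *unnormalized* prediction scale, where the thresholds 0.1 and 0.15 are
defined (boundary inclusive on the penalized side), from the ensemble curves
averaged across sequences — the day-1 ordering is identical for both
sequences, so their acquisition/extinction ordinals coincide. The printed
fit formula is maximized with the penalties subtracted, which is the stated
intent of penalizing failed safety/extinction learning.

Grid-search ties break lexicographically on (b, λ, i, β, RPE). The
desk-scale default grid (b ∈ {16, 64}, λ ∈ {0.5, 0.8, 1}, i ∈ {2, 6, 12},
β ∈ {1, 3, 5}, RPE ∈ {yes, no}, 5 agents per configuration) keeps a full
run in minutes; the full 7200-configuration grid with 25 agents is a
documented long-running mode. Per-configuration seeds derive from the master
seed and the configuration identity, so the surface is independent of grid
ordering and resumable by construction.

## Parametric modulators

For each phase, CS events (onsets at CS onset) are weighted by the
ensemble-mean prediction and US/no-US events (onsets at CS onset + 7.9 s,
the omission time on unreinforced trials) by the ensemble-mean absolute
prediction error, grouped irrespective of CS type. Weights are mean-centered
per regressor — the standard convention for parametric modulators — and
written as whitespace-delimited FSL 3-column files (onset, duration 0,
weight; 6-decimal fixed format, byte-stable round trip).

## Rank statistics

The ANOVA-type statistic uses the standard midrank construction: all N·d
observations are jointly midranked; per-cell relative effects q and a
block-diagonal covariance estimate V (independent groups; within-group
subject resampling covariance) feed A = N·q'Mq/tr(MV) for each effect's
projection M, referred to F(f̂, ∞) with f̂ = tr(MV)²/tr((MV)²) — evaluated
as a scaled chi-square. Infinite denominator degrees of freedom are used
throughout; the finite-df variant inflates type-I error in small samples.
Degenerate inputs (constant data) return statistic 0 and p = 1. The RTE of a
cell is (mean cell midrank − 0.5)/N_obs — the probability that a random
observation from the cell exceeds a random observation from the pooled
reference distribution (the conventional reference) — with confidence
intervals from a seeded 1000-replicate subject-level bootstrap. Post hoc
cell contrasts are standardized differences of relative effects with
Tukey–Kramer (studentized-range, infinite df) family-wise adjustment.

Calibration is verified by simulation: the null rejection rate of the ATS at
α = 0.05 over 2000 synthetic null datasets (20 subjects per group) lies
within [0.03, 0.07], and on large balanced Gaussian data the ATS flags the
same effects as a parametric mixed ANOVA.

## Problem sizes and determinism

Tests and the pipeline default to scaled-down problem sizes chosen for
desk-scale runtime: 100 Hz traces, 5-agent ensembles and the reduced grid in
fitting, a 3-seed coarse-grid parameter-recovery check, and a 2000-replicate
null calibration. Every stochastic component draws from
`numpy.random.SeedSequence` children of a single master seed; reruns of any
stage, the pipeline, or the acceptance script are bit-reproducible.

## Known limitations

- The generator's expectancy-to-amplitude mapping is directional, not
  calibrated to real μS effect sizes; absolute fitted F values are not
  comparable to fits on empirical data.
- The scorer's counter-movement rule resolves overlapping responses by
  boundary-marking drops of ≥ 0.01 μS; heavily overlapping responses within
  a window are scored as their largest single excursion, not deconvolved.
- The ATS implementation targets the infinite-denominator-df statistic only;
  finite-df variants and covariance-structured mixed models are out of scope.
- Exact training dynamics (loss, optimizer, learning rate) of the value
  network are explicit package choices; analyses relying on exact v values
  rather than the documented qualitative behaviour would need sensitivity
  checks across these settings.
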