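# fearcon

Computational analysis of a two-day differential fear-conditioning and
extinction experiment, exercised end to end on synthetic data. The package is
aimed at researchers modelling fear learning from skin-conductance readouts:
it generates the trial paradigm, simulates and scores electrodermal traces,
fits a replay-based reinforcement-learning model to the group-level response
curves, exports model-derived parametric modulators for fMRI designs, and
runs rank-based nonparametric repeated-measures statistics.

## The experiment and the model

Two conditioned stimuli (CS+ and CS−) are presented over two days:
habituation (3+3 trials), acquisition training (10 paired CS+/US, 6 CS+
only, 16 CS−; a 62.5 % reinforcement rate), extinction training (16+16) on
day 1, and recall (12+12) on day 2. Each 8 s CS is followed after 7.9 s by
the aversive US on reinforced trials; inter-trial intervals are drawn from
[14.3, 17.9] s. The first two and the last acquisition trials are always
reinforced, trial kinds are balanced across phase halves, and the recall
phase opens with CS+ in one counterbalance arm and CS− in the other.

The learning model is an artificial agent whose value network (two hidden
layers of 64 units, sigmoid output) predicts the US probability
*v<sub>t</sub>* for the current stimulus *s<sub>t</sub>* and incurs a
prediction error δ<sub>t</sub> = r<sub>t</sub> − v<sub>t</sub>. Experiences
(s, r, δ) are stored in memory and replayed in *i* batches of size *b* per
trial, sampled with probability P(e<sub>k</sub>) = p<sub>k</sub>/Σp
proportional to a priority p = λ<sup>τ</sup> (recency) or p = |δ|λ<sup>τ</sup>
(RPE-weighted). Between days, a sleep-replay phase — 100 batches of 64
sampled with softmax probability e<sup>βr</sup>/Σe<sup>βr</sup> over the
stored reinforcements — preferentially reactivates reinforced experiences
and thereby restores part of the extinguished association: the model's
mechanism for spontaneous recovery at recall.

Hyper-parameters (b, λ, i, β, RPE) are fitted by grid search against
per-presentation group-mean SCR curves Ȳ<sub>l</sub> with goodness of fit

```
F(b, λ, i, β, RPE) = − Σ_l  w_l ‖Ȳ_l − V̄_l‖₁  −  P_Saf  −  P_Ext
```

where V̄<sub>l</sub> are ensemble-averaged model predictions, w<sub>l</sub>
counts participants per trial sequence, and the penalties (10 each) fire if
the model fails to learn CS− safety (mean v over the last 4 acquisition CS−
presentations ≥ 0.1) or fails to extinguish (mean v over the last 4
extinction CS+ presentations ≥ 0.15).

SCRs are scored trough-to-peak (minimum amplitude 0.01 μS, minimum rise time
500 ms) inside the CS window (1–8.5 s after CS onset) and the
unconditioned-response window (8.5–13 s), zero-scored when no deflection
qualifies, block-averaged and LN(1+SCR)-transformed. Group comparisons use
the rank-based ANOVA-type statistic (ATS) with infinite denominator degrees
of freedom and relative treatment effects (RTE) as effect sizes.

## Worked example

Simulate a small labelled cohort (the synthetic generator plants CS+ > CS−
differentiation during acquisition, extinction decay, and spontaneous
recovery in the sham group only), score it, and inspect early/late recall
blocks:

```python
from fearcon import scr_synth, scr_scoring, Phase

members = scr_synth.simulate_cohort(n_sham=6, n_verum=6,
                                    params=scr_synth.SCRGenParams(), seed=3)
scores = scr_scoring.score_cohort(members)
blocks = scr_scoring.block_average(scores, Phase.RECALL)
groups = scores.groupby("participant")["group"].first()
blocks = blocks.merge(groups, left_on="participant", right_index=True)
print(blocks.groupby(["group", "block", "cs_type"])["mean_log_scr"]
      .mean().unstack("cs_type").round(3))
```

```
cs_type        CS+    CS-
group block
sham  early  0.223  0.022
      late   0.024  0.030
verum early  0.069  0.033
      late   0.031  0.032
```

The sham group shows a clear early-recall CS+/CS− differential (spontaneous
recovery of the conditioned response, LN(1+μS) scale) that is gone by late
recall; the verum group shows no such recovery — the pattern the statistics
module then formalizes with ATS and Tukey–Kramer-adjusted rank contrasts.

The full study pipeline (cohort → scoring → model fitting → modulator export
→ statistics → markdown report) runs with:

```bash
fearcon run --seed 1 --out run_out        # study-sized, several minutes
```

## Layout

- `fearcon.paradigm` — trial sequences, timings, counterbalancing, validation
- `fearcon.scr_synth` — synthetic SCR traces with ground truth
- `fearcon.scr_scoring` — trough-to-peak scoring, blocks, SCR_diff
- `fearcon.rl_agent` — value network, prioritized replay, sleep replay
- `fearcon.fitting` — target curves, penalties, grid search
- `fearcon.modulators` — FSL 3-column parametric-modulator export
- `fearcon.npstats` — RTE, ANOVA-type statistic, post hoc contrasts
- `fearcon.pipeline` — end-to-end orchestration and reporting

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical choices.
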