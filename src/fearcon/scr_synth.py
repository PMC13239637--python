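"""Synthetic skin-conductance data with ground truth.

Generates phasic electrodermal traces whose event-related response amplitudes
scale with a latent US expectancy, so that the downstream scoring and
statistics see the qualitative structure observed in differential fear
conditioning: CS+ > CS- differentiation during acquisition, decay across
extinction, and — only in the sham group — spontaneous recovery of the CS+
response in early recall. The latent expectancy trajectory is a simple
associative (delta-rule) update, deliberately NOT the replay-based learning
model in :mod:`fearcon.rl_agent`, so that hyper-parameter fitting against
these data is a genuine recovery exercise rather than a self-fit.

Amplitude scales are calibrated only to directionality (the study reports no
expectancy-to-microsiemens mapping); absolute values are arbitrary but fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .paradigm import CSType, ExperimentDesign, Phase, TrialEvent

__all__ = [
    "SCRGenParams",
    "GroundTruth",
    "SCRTrace",
    "scr_kernel",
    "single_deflection_trace",
    "latent_expectancy",
    "simulate_participant",
    "simulate_cohort",
]

# Latency from CS onset to sudomotor response onset (s). Inside the 1-8.5 s
# scoring window.
RESPONSE_LATENCY_S = 1.5
TRACE_TAIL_S = 13.0
BASELINE_US = 2.0


@dataclass(frozen=True)
class SCRGenParams:
    """Generator settings.

    ``fs`` defaults to 100 Hz (the study hardware sampled at 2 kHz; scoring is
    rate-independent well below that). ``recovery_boost`` is the extra CS+
    expectancy injected at the start of recall, applied only to the sham
    group — it is what makes spontaneous recovery group-specific.
    """

    fs: float = 100.0
    kernel_rise: float = 0.75
    kernel_decay: float = 2.5
    gain_expectancy: float = 0.8       # uS per unit expectancy
    gain_orienting: float = 0.35       # uS, novelty response to any CS
    habituation_rate: float = 0.95     # per-trial decay of the orienting term
    ur_gain: float = 1.2               # uS, response to a delivered US
    noise_sd: float = 0.02             # uS, per-sample measurement noise
    amp_noise_sd: float = 0.10         # uS, half-normal trial amplitude noise
    nonresponse_prob: float = 0.10
    group: str = "sham"                # "sham" | "verum"
    recovery_boost: float = 0.5        # extra CS+ expectancy, early recall
    learning_rate: float = 0.35        # delta-rule rate for the latent E_t
    extinction_rate: float = 0.18      # slower unlearning during extinction

    def __post_init__(self) -> None:
        if self.group not in ("sham", "verum"):
            raise ValueError("group must be 'sham' or 'verum'")
        for name in ("gain_expectancy", "gain_orienting", "ur_gain",
                     "noise_sd", "amp_noise_sd", "recovery_boost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.nonresponse_prob <= 1.0):
            raise ValueError("nonresponse_prob must be in [0, 1]")
        if not (0.0 <= self.habituation_rate <= 1.0):
            raise ValueError("habituation_rate must be in [0, 1]")
        if self.fs <= 2.0 / self.kernel_rise:
            raise ValueError("fs too low to resolve the response rise")


@dataclass(frozen=True)
class GroundTruth:
    """Latent per-trial quantities the generator used."""

    expectancy: np.ndarray     # E_t in [0, 1], one per trial
    amplitude: np.ndarray      # emitted CS-response amplitude, uS
    group: str


@dataclass(frozen=True)
class SCRTrace:
    """A sampled conductance series with its event table and ground truth."""

    fs: float
    samples: np.ndarray
    design: ExperimentDesign
    truth: GroundTruth
    participant_id: str = "p0"

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "conductance_uS": self.samples})


def scr_kernel(
    t: np.ndarray | float, rise: float = 0.75, decay: float = 2.5
) -> np.ndarray:
    """Unit-peak biexponential sudomotor response shape.

    ``k(t) = (e^{-t/decay} - e^{-t/rise}) / k(t*)`` for t > 0, zero otherwise;
    the peak time is ``t* = rise*decay/(decay-rise) * ln(decay/rise)``.
    """
    if rise >= decay:
        raise ValueError("kernel rise must be < decay")
    t = np.asarray(t, dtype=float)
    tp = np.where(t > 0, t, np.inf)  # avoid exp overflow for t << 0
    out = np.exp(-tp / decay) - np.exp(-tp / rise)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return out / peak


def single_deflection_trace(
    fs: float,
    duration: float,
    onset: float,
    amplitude: float,
    rise_time: float,
    decay: float = 3.0,
    baseline: float = BASELINE_US,
) -> np.ndarray:
    """A noise-free trace with one trough-to-peak deflection of known geometry.

    The trough sits exactly on the sample nearest ``onset``; the peak sits
    ``floor(rise_time * fs)`` samples later, so the discrete rise time is the
    largest sampled time not exceeding ``rise_time``. Used for scorer
    threshold probing and round-trip oracles.
    """
    n = int(round(duration * fs))
    y = np.full(n, baseline, dtype=float)
    i0 = int(round(onset * fs))
    n_rise = int(np.floor(rise_time * fs))
    i_peak = i0 + n_rise
    if i_peak >= n:
        raise ValueError("deflection does not fit in the trace")
    ramp = np.linspace(0.0, amplitude, n_rise + 1)
    y[i0 : i_peak + 1] += ramp
    tail = np.arange(n - i_peak) / fs
    y[i_peak:] += amplitude * np.exp(-tail / decay)
    y[i_peak] = baseline + amplitude  # exact peak (ramp end, decay start overlap)
    return y


# ---------------------------------------------------------------------------
# Latent expectancy
# ---------------------------------------------------------------------------

def latent_expectancy(
    design: ExperimentDesign,
    params: SCRGenParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-trial latent US expectancy E_t in [0, 1].

    Delta-rule update per CS: zero through habituation, rising for CS+ during
    acquisition, decaying (more slowly) across extinction, and — for the sham
    group only — boosted on the first six recall CS+ presentations with a
    linearly fading boost.
    """
    e = {CSType.CSP: 0.0, CSType.CSM: 0.0}
    out = np.empty(len(design.trials), dtype=float)
    recall_csp_seen = 0
    for i, trial in enumerate(design.trials):
        val = e[trial.cs_type]
        if trial.phase is Phase.HABITUATION:
            val = 0.0
        if (
            trial.phase is Phase.RECALL
            and trial.cs_type is CSType.CSP
            and params.group == "sham"
            and recall_csp_seen < 6
        ):
            fade = 1.0 - recall_csp_seen / 6.0
            val = min(1.0, val + params.recovery_boost * fade)
        if trial.phase is Phase.RECALL and trial.cs_type is CSType.CSP:
            recall_csp_seen += 1
        out[i] = val
        # update after readout
        if trial.phase is not Phase.HABITUATION:
            r = 1.0 if trial.reinforced else 0.0
            rate = (
                params.extinction_rate
                if trial.phase in (Phase.EXTINCTION, Phase.RECALL)
                else params.learning_rate
            )
            e[trial.cs_type] = float(np.clip(e[trial.cs_type] + rate * (r - e[trial.cs_type]), 0.0, 1.0))
    return out


# ---------------------------------------------------------------------------
# Trace simulation
# ---------------------------------------------------------------------------

def _phase_trace(
    trials: Sequence[TrialEvent],
    expectancy: np.ndarray,
    trial_offset: int,
    params: SCRGenParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one continuous recording (one phase = one session)."""
    if not trials:
        return np.zeros(0), np.zeros(0)
    dur = trials[-1].cs_onset + trials[-1].cs_duration + TRACE_TAIL_S
    n = int(round(dur * params.fs))
    t_axis = np.arange(n) / params.fs
    y = np.full(n, BASELINE_US, dtype=float)
    amps = np.empty(len(trials), dtype=float)
    for j, trial in enumerate(trials):
        k = trial_offset + j
        responds = rng.random() >= params.nonresponse_prob
        amp = 0.0
        if responds:
            amp = (
                params.gain_orienting * params.habituation_rate**k
                + params.gain_expectancy * expectancy[k]
                + abs(rng.normal(0.0, params.amp_noise_sd))
            )
        amps[j] = amp
        if amp > 0:
            y += amp * scr_kernel(
                t_axis - trial.cs_onset - RESPONSE_LATENCY_S,
                params.kernel_rise, params.kernel_decay,
            )
        if trial.reinforced and params.ur_gain > 0:
            ur_amp = params.ur_gain * (1.0 + abs(rng.normal(0.0, 0.1)))
            y += ur_amp * scr_kernel(
                t_axis - trial.us_onset - RESPONSE_LATENCY_S,
                params.kernel_rise, params.kernel_decay,
            )
    if params.noise_sd > 0:
        y += rng.normal(0.0, params.noise_sd, size=n)
    return y, amps


def simulate_participant(
    design: ExperimentDesign,
    params: SCRGenParams,
    seed: int | np.random.SeedSequence,
    participant_id: str = "p0",
) -> dict[Phase, SCRTrace]:
    """Simulate one participant: one trace per phase (each phase is its own
    recording session, with phase-relative clocks matching the design).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    expectancy = latent_expectancy(design, params, rng)

    traces: dict[Phase, SCRTrace] = {}
    offset = 0
    all_amps: list[np.ndarray] = []
    phase_slices: dict[Phase, tuple[int, int]] = {}
    for phase in (Phase.HABITUATION, Phase.ACQUISITION, Phase.EXTINCTION, Phase.RECALL):
        trials = design.phase_trials(phase)
        y, amps = _phase_trace(trials, expectancy, offset, params, rng)
        phase_slices[phase] = (offset, offset + len(trials))
        offset += len(trials)
        all_amps.append(amps)
        traces[phase] = SCRTrace(
            fs=params.fs,
            samples=y,
            design=design,
            truth=GroundTruth(
                expectancy=expectancy[slice(*phase_slices[phase])],
                amplitude=amps,
                group=params.group,
            ),
            participant_id=participant_id,
        )
    return traces


@dataclass(frozen=True)
class CohortMember:
    participant_id: str
    group: str
    counterbalance_id: str
    design: ExperimentDesign
    traces: dict[Phase, SCRTrace]


def simulate_cohort(
    n_sham: int,
    n_verum: int,
    params: SCRGenParams,
    seed: int,
) -> list[CohortMember]:
    """Simulate a labelled cohort (study analyzed 18 sham / 22 verum).

    Per-participant seeds are spawned deterministically from the master seed;
    counterbalance arms alternate within each group so both trial sequences
    are represented.
    """
    if n_sham < 1 or n_verum < 1:
        raise ValueError("need at least one participant per group")
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_sham + n_verum)
    members: list[CohortMember] = []
    idx = 0
    for group, n in (("sham", n_sham), ("verum", n_verum)):
        gp = replace(params, group=group)
        for j in range(n):
            cb = "A" if j % 2 == 0 else "B"
            design = build_design_cached(cb, children[idx])
            pid = f"{group}{j:02d}"
            traces = simulate_participant(design, gp, children[idx], pid)
            members.append(CohortMember(pid, group, cb, design, traces))
            idx += 1
    return members


_design_cache: dict[tuple[str, int], ExperimentDesign] = {}


def build_design_cached(
    counterbalance_id: str, seed: int | np.random.SeedSequence
) -> ExperimentDesign:
    """Build a design whose ordering is canonical per counterbalance; ITIs are
    drawn from the participant seed."""
    from .paradigm import build_experiment

    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed.spawn(1)[0])
    else:
        rng = np.random.default_rng(seed)
    return build_experiment(counterbalance_id, rng)
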