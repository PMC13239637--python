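"""Event-related SCR quantification.

Responses are scored trough-to-peak on the low-pass-filtered conductance
trace: within a scoring window, the score is the largest peak-minus-trough
difference over all (local trough, later local peak) pairs whose amplitude is
at least 0.01 uS and whose trough-to-peak rise time is at least 500 ms, where
the response onset (trough) falls inside the window. Trials with no
qualifying deflection score zero and stay in the analysis.

Two windows per trial: the CS response window 1-8.5 s after CS onset, and the
unconditioned-response window 8.5-13 s after CS onset (8.5 s being the
presumed onset of the response to the aversive stimulus). Raw scores are
averaged into blocks and normalized as LN(1 + mean SCR); differential
responses (SCR_diff) subtract the CS- block mean from the CS+ block mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .paradigm import CSType, ExperimentDesign, Phase
from .scr_synth import SCRTrace

__all__ = [
    "ScoringParams",
    "lowpass_filter",
    "score_window",
    "score_experiment",
    "score_cohort",
    "block_average",
    "BLOCK_SIZES",
]

# Trials per (CS, block) cell when block-averaging each phase.
BLOCK_SIZES: dict[Phase, int] = {
    Phase.HABITUATION: 3,
    Phase.ACQUISITION: 8,
    Phase.EXTINCTION: 8,
    Phase.RECALL: 6,
}


@dataclass(frozen=True)
class ScoringParams:
    min_amplitude: float = 0.01        # uS
    min_rise_time: float = 0.5         # s, trough to peak
    cs_window: tuple[float, float] = (1.0, 8.5)    # s after CS onset
    ur_window: tuple[float, float] = (8.5, 13.0)   # s after CS onset
    lowpass_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.min_amplitude <= 0 or self.min_rise_time <= 0:
            raise ValueError("minimum criteria must be positive")
        if not (self.cs_window[0] < self.cs_window[1] <= self.ur_window[0] < self.ur_window[1]):
            raise ValueError("windows must be ordered and non-overlapping")


def lowpass_filter(samples: np.ndarray, fs: float, cutoff: float = 10.0) -> np.ndarray:
    """Zero-phase 10 Hz low-pass, mirroring the study's hardware filter."""
    if cutoff >= fs / 2:
        return np.asarray(samples, dtype=float)
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, samples)


def _local_extrema(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local minima (troughs) and maxima (peaks), plateau-aware.

    A trough is the last sample of a non-increasing run followed by a strict
    rise (so a deflection starting from a flat baseline has its trough at the
    foot of the rise, not at the trace start); a peak is the first sample of
    a non-increasing run preceded by a strict rise. Trace edges count.
    """
    n = y.size
    if n < 2:
        return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
    rising = y[:-1] < y[1:]            # strict rise from i to i+1
    not_rising = y[:-1] >= y[1:]
    trough = np.concatenate(([True], not_rising)) & np.concatenate((rising, [False]))
    peak = np.concatenate(([True], rising)) & np.concatenate((not_rising, [True]))
    return np.flatnonzero(trough), np.flatnonzero(peak)


def score_window(
    trace_samples: np.ndarray,
    fs: float,
    window_start: float,
    window_end: float,
    params: ScoringParams = ScoringParams(),
    *,
    prefiltered: bool = False,
) -> float:
    """Maximum qualifying trough-to-peak amplitude with onset in the window.

    A valid (trough, peak) pair is a local-minimum sample ``i`` inside
    ``[window_start, window_end)`` (trace clock, seconds) and a later
    local-maximum sample ``j`` — possibly past the window end — such that

    * ``y[i]`` is the minimum and ``y[j]`` the maximum of ``y[i..j]`` (the
      deflection is a single excursion rising from its onset), and
    * no counter-movement inside ``y[i..j]`` falls by ``min_amplitude`` or
      more (a drop that large marks the boundary of a separate response), and
    * amplitude ``y[j] - y[i] >= min_amplitude`` with rise time
      ``(j - i)/fs >= min_rise_time``.

    Returns the largest qualifying amplitude, or 0.0 if none qualifies.
    """
    y = np.asarray(trace_samples, dtype=float)
    n = y.size
    i0 = int(np.ceil(window_start * fs - 1e-9))
    i1 = int(np.floor(window_end * fs + 1e-9))
    if i0 < 0 or i0 >= n or window_end * fs > n:
        raise ValueError("scoring window outside trace")
    if not prefiltered:
        y = lowpass_filter(y, fs, params.lowpass_hz)

    troughs, _ = _local_extrema(y)
    troughs = troughs[(troughs >= i0) & (troughs < i1)]
    min_gap = int(np.ceil(params.min_rise_time * fs - 1e-9))
    # excursions cannot usefully extend far past the window: cap the scan
    end_cap = min(n, i1 + int(np.ceil(13.0 * fs)))
    best = 0.0
    for ti in troughs:
        seg = y[ti + 1 : end_cap]
        if seg.size == 0:
            continue
        run_max = np.maximum.accumulate(seg)
        prev_max = np.concatenate(([y[ti]], run_max[:-1]))
        stop = (seg < y[ti]) | (run_max - seg >= params.min_amplitude)
        idx_stop = int(np.argmax(stop)) if stop.any() else seg.size
        k = np.arange(seg.size)
        valid = (seg > prev_max) & (k >= min_gap - 1) & (k < idx_stop)
        if not valid.any():
            continue
        amp = float(seg[valid].max() - y[ti])
        if amp >= params.min_amplitude - 1e-12 and amp > best:
            best = amp
    return best


def amplitude_threshold(
    params: ScoringParams = ScoringParams(),
    fs: float = 1000.0,
    tol: float = 1e-4,
) -> float:
    """Smallest deflection amplitude (uS) the scorer accepts, by bisection.

    Probes the scorer with noise-free single-deflection traces (1.5 s rise,
    onset inside the window) of varying amplitude and bisects the 0-to-nonzero
    transition to within ``tol``.
    """
    from .scr_synth import single_deflection_trace

    def accepted(amp: float) -> bool:
        y = single_deflection_trace(fs, 30.0, onset=10.0, amplitude=amp,
                                    rise_time=1.5)
        return score_window(y, fs, 9.0, 16.5, params, prefiltered=True) > 0

    lo, hi = 1e-6, 1.0
    assert not accepted(lo) and accepted(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lo, hi = (lo, mid) if accepted(mid) else (mid, hi)
    return 0.5 * (lo + hi)


def rise_time_threshold(
    params: ScoringParams = ScoringParams(),
    fs: float = 1000.0,
    tol: float = 1e-3,
) -> float:
    """Smallest trough-to-peak rise time (s) the scorer accepts, by bisection.

    Probes with noise-free deflections of fixed 0.5 uS amplitude and varying
    rise time; bisects the rejection/acceptance transition to within ``tol``
    seconds.
    """
    from .scr_synth import single_deflection_trace

    def accepted(rise: float) -> bool:
        y = single_deflection_trace(fs, 30.0, onset=10.0, amplitude=0.5,
                                    rise_time=rise)
        return score_window(y, fs, 9.0, 16.5, params, prefiltered=True) > 0

    lo, hi = 2.0 / fs, 3.0
    assert not accepted(lo) and accepted(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lo, hi = (lo, mid) if accepted(mid) else (mid, hi)
    return 0.5 * (lo + hi)


def score_experiment(
    trace: SCRTrace,
    phase: Phase,
    params: ScoringParams = ScoringParams(),
) -> pd.DataFrame:
    """Score every trial of a phase in both windows.

    Returns a tidy frame with one row per (trial, window). UR-window rows are
    additionally labelled by stimulus class: ``CS+/US`` for reinforced trials,
    ``CS+/no-US`` for unreinforced CS+ trials, ``CS-`` otherwise.
    """
    trials = trace.design.phase_trials(phase)
    if not trials:
        raise ValueError(f"design has no trials for phase {phase.value!r}")
    y = lowpass_filter(trace.samples, trace.fs, params.lowpass_hz)
    n = y.size
    missing = [
        t.index_in_phase
        for t in trials
        if (t.cs_onset + params.ur_window[1]) * trace.fs > n
    ]
    if missing:
        raise ValueError(f"trace does not cover trials {missing} of {phase.value}")

    rows = []
    for t in trials:
        for window_name, (w0, w1) in (("CS", params.cs_window), ("UR", params.ur_window)):
            amp = score_window(
                y, trace.fs, t.cs_onset + w0, t.cs_onset + w1, params, prefiltered=True
            )
            if window_name == "CS":
                stim_class = t.cs_type.value
            else:
                stim_class = (
                    "CS+/US" if t.reinforced
                    else ("CS+/no-US" if t.cs_type is CSType.CSP else "CS-")
                )
            rows.append({
                "participant": trace.participant_id,
                "phase": phase.value,
                "index_in_phase": t.index_in_phase,
                "cs_type": t.cs_type.value,
                "reinforced": t.reinforced,
                "window": window_name,
                "stim_class": stim_class,
                "amplitude": amp,
            })
    return pd.DataFrame(rows)


def score_cohort(members, params: ScoringParams = ScoringParams()) -> pd.DataFrame:
    """Score every phase of every cohort member into one long table."""
    frames = []
    for m in members:
        for phase, trace in m.traces.items():
            df = score_experiment(trace, phase, params)
            df["group"] = m.group
            df["counterbalance"] = m.counterbalance_id
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def block_average(scores: pd.DataFrame, phase: Phase) -> pd.DataFrame:
    """Average CS-window trial scores into blocks; LN(1+mean) normalize.

    Habituation forms a single block per CS (3 trials). Acquisition and
    extinction use the first and last eight trials of each CS as early/late
    blocks; recall uses the first and last six. Returns one row per
    (participant, cs_type, block) plus the per-block differential response
    ``scr_diff`` = mean_log(CS+) - mean_log(CS-).
    """
    df = scores[(scores["phase"] == phase.value) & (scores["window"] == "CS")]
    size = BLOCK_SIZES[phase]
    rows = []
    for (pid, cs), sub in df.groupby(["participant", "cs_type"], sort=True):
        sub = sub.sort_values("index_in_phase")
        amps = sub["amplitude"].to_numpy()
        if phase is Phase.HABITUATION:
            if amps.size != size:
                raise ValueError(
                    f"{pid}: expected {size} {cs} habituation trials, got {amps.size}"
                )
            blocks = {"habituation": amps}
        else:
            if amps.size != 2 * size:
                raise ValueError(
                    f"{pid}: expected {2 * size} {cs} trials in {phase.value}, got {amps.size}"
                )
            blocks = {"early": amps[:size], "late": amps[-size:]}
        for block, vals in blocks.items():
            rows.append({
                "participant": pid,
                "phase": phase.value,
                "block": block,
                "cs_type": cs,
                "mean_raw_scr": float(np.mean(vals)),
                "mean_log_scr": float(np.log1p(np.mean(vals))),
            })
    out = pd.DataFrame(rows)
    wide = out.pivot_table(
        index=["participant", "phase", "block"], columns="cs_type",
        values="mean_log_scr", aggfunc="first",
    )
    if {"CS+", "CS-"} <= set(wide.columns):
        diff = (wide["CS+"] - wide["CS-"]).rename("scr_diff").reset_index()
        out = out.merge(diff, on=["participant", "phase", "block"], how="left")
    else:
        out["scr_diff"] = np.nan
    return out
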