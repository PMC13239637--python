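"""Trial-by-trial parametric modulators in FSL 3-column EV format.

For each experimental phase two modulated event sets are built from the
fitted ensemble: CS events (at CS onset), weighted by the ensemble-mean US
prediction, and US/no-US events (at CS onset + 7.9 s, the delivery time or
the corresponding omission time), weighted by the ensemble-mean absolute
prediction error. Events are grouped irrespective of CS trial type within a
phase, all durations are 0 s, and weights are mean-centered per set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .paradigm import ExperimentDesign, Phase

__all__ = ["EVEvent", "build_modulators", "write_fsl_ev3", "read_fsl_ev3"]


@dataclass(frozen=True)
class EVEvent:
    onset: float
    duration: float     # always 0 in this design
    weight: float


def build_modulators(
    ensemble: pd.DataFrame,
    design: ExperimentDesign,
    phase: Phase,
    *,
    demean: bool = True,
) -> dict[str, list[EVEvent]]:
    """EV sets for one phase: ``{"cs": [...], "us": [...]}``.

    ``ensemble`` is a ``run_ensemble`` table; onsets come from the design
    (phase-relative session clock).
    """
    trials = design.phase_trials(phase)
    if not trials:
        raise ValueError(f"design has no {phase.value} trials")
    sub = ensemble[ensemble["phase"] == phase.value].sort_values("index_in_phase")
    if len(sub) != len(trials):
        raise ValueError(
            f"ensemble covers {len(sub)} {phase.value} trials, design has {len(trials)}"
        )
    v = sub["v_mean"].to_numpy(dtype=float)
    absd = sub["abs_delta_mean"].to_numpy(dtype=float)
    if demean:
        v = v - v.mean()
        absd = absd - absd.mean()
    cs_events = [
        EVEvent(onset=t.cs_onset, duration=0.0, weight=float(w))
        for t, w in zip(trials, v)
    ]
    us_events = [
        EVEvent(onset=t.us_onset, duration=0.0, weight=float(w))
        for t, w in zip(trials, absd)
    ]
    return {"cs": cs_events, "us": us_events}


def write_fsl_ev3(events: list[EVEvent], path: str | Path) -> Path:
    """Write a whitespace-delimited 3-column EV file (6-decimal fixed)."""
    path = Path(path)
    lines = [f"{e.onset:.6f} {e.duration:.6f} {e.weight:.6f}" for e in events]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_fsl_ev3(path: str | Path) -> list[EVEvent]:
    events = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        onset, duration, weight = (float(x) for x in line.split())
        events.append(EVEvent(onset=onset, duration=duration, weight=weight))
    return events
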