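"""Two-day differential fear-conditioning paradigm: trial sequences and timelines.

The experiment runs over two consecutive days. Day 1 comprises habituation
(3 CS+ only, 3 CS- only), acquisition training (10 paired CS+/US, 6 CS+ only,
16 CS- only; a 62.5% reinforcement rate) and extinction training (16 CS+ only,
16 CS- only). Day 2 is the recall phase (12 CS+ only, 12 CS- only). Each trial
presents the CS for 8 s; on reinforced trials the aversive US arrives 7.9 s
after CS onset and co-terminates with it. Inter-trial intervals are randomized
between 14.3 and 17.9 s.

Ordering constraints: the first two and the last acquisition trials are paired
CS+/US trials, and within each phase the number of events of each kind is kept
(as) equal (as possible) in the first and second halves. The day-1 ordering is
identical for every participant; during recall the initial event is
counterbalanced between CS+ and CS-, yielding exactly two distinct trial
sequences.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "CSType",
    "PhaseSpec",
    "TrialEvent",
    "ExperimentDesign",
    "ConstraintError",
    "CANONICAL_PHASE_SPECS",
    "CS_DURATION_S",
    "US_DELAY_S",
    "ITI_RANGE_S",
    "build_phase_sequence",
    "build_experiment",
    "validate_design",
    "design_to_frame",
    "design_from_frame",
]

# Fixed trial timing (seconds)
CS_DURATION_S = 8.0
US_DELAY_S = 7.9          # US onset relative to CS onset; also the no-US marker
ITI_RANGE_S = (14.3, 17.9)

# Pre-extinction fixation (ctACS ramp-in) recorded as metadata only; it does
# not shift within-phase trial clocks.
PRE_EXTINCTION_FIXATION_S = 120.0

# Internal seeds fixing the day-1 ordering (identical for all participants)
# and the two canonical recall orderings (one per counterbalance).
_CANONICAL_DAY1_SEED = 20240117
_CANONICAL_RECALL_SEED = 20240218


class Phase(str, enum.Enum):
    HABITUATION = "habituation"
    ACQUISITION = "acquisition"
    EXTINCTION = "extinction"
    RECALL = "recall"


class CSType(str, enum.Enum):
    CSP = "CS+"
    CSM = "CS-"


class ConstraintError(ValueError):
    """A requested sequence cannot satisfy the paradigm's ordering constraints."""


@dataclass(frozen=True)
class PhaseSpec:
    """Trial composition of one experimental phase."""

    name: Phase
    n_paired_csplus: int
    n_unpaired_csplus: int
    n_csminus: int

    def __post_init__(self) -> None:
        if min(self.n_paired_csplus, self.n_unpaired_csplus, self.n_csminus) < 0:
            raise ConstraintError("trial counts must be non-negative")
        if self.name is not Phase.ACQUISITION and self.n_paired_csplus != 0:
            raise ConstraintError(
                f"phase {self.name.value!r} must not contain paired CS+/US trials"
            )

    @property
    def n_trials(self) -> int:
        return self.n_paired_csplus + self.n_unpaired_csplus + self.n_csminus


CANONICAL_PHASE_SPECS: dict[Phase, PhaseSpec] = {
    Phase.HABITUATION: PhaseSpec(Phase.HABITUATION, 0, 3, 3),
    Phase.ACQUISITION: PhaseSpec(Phase.ACQUISITION, 10, 6, 16),
    Phase.EXTINCTION: PhaseSpec(Phase.EXTINCTION, 0, 16, 16),
    Phase.RECALL: PhaseSpec(Phase.RECALL, 0, 12, 12),
}


@dataclass(frozen=True)
class TrialEvent:
    """One CS presentation with its reinforcement flag and timings.

    Onsets are phase-relative seconds with 0 at the first CS onset of the
    phase. ``us_onset`` marks the US arrival on reinforced trials and the
    corresponding no-US time point on unreinforced trials.
    """

    phase: Phase
    index_in_phase: int          # 1-based
    cs_type: CSType
    reinforced: bool
    cs_onset: float
    cs_duration: float
    us_onset: float
    iti: float

    def __post_init__(self) -> None:
        if self.reinforced and self.cs_type is not CSType.CSP:
            raise ConstraintError("only CS+ trials may be reinforced")
        if abs((self.us_onset - self.cs_onset) - US_DELAY_S) > 1e-9:
            raise ConstraintError("us_onset must be cs_onset + 7.9 s")
        lo, hi = ITI_RANGE_S
        if not (lo <= self.iti <= hi):
            raise ConstraintError(f"iti {self.iti} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class ExperimentDesign:
    """Full two-day design for one participant / one trial sequence.

    ``sequence_label`` identifies which of the two distinct orderings this is
    (the orderings differ only in the recall phase; L = 2).
    """

    counterbalance_id: str       # "A" (recall opens with CS+) or "B" (CS-)
    day1: tuple[TrialEvent, ...]
    day2: tuple[TrialEvent, ...]
    pre_extinction_fixation_s: float = PRE_EXTINCTION_FIXATION_S

    @property
    def sequence_label(self) -> str:
        return self.counterbalance_id

    @property
    def trials(self) -> tuple[TrialEvent, ...]:
        return self.day1 + self.day2

    def phase_trials(self, phase: Phase) -> tuple[TrialEvent, ...]:
        return tuple(t for t in self.trials if t.phase is phase)


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------

_PAIRED, _CSP_ONLY, _CSM_ONLY = "paired", "cs+only", "cs-only"


def _split_half_counts(n: int, rng: np.random.Generator) -> tuple[int, int]:
    """Split a kind count across halves; exact for even n, off by one for odd."""
    lo = n // 2
    if n % 2 == 0:
        return lo, lo
    extra_first = bool(rng.integers(2))
    return (lo + 1, lo) if extra_first else (lo, lo + 1)


def _order_kinds(
    spec: PhaseSpec, rng: np.random.Generator, first_cs: CSType | None
) -> list[str]:
    """Pseudorandom trial-kind order honouring the phase constraints."""
    counts = {
        _PAIRED: spec.n_paired_csplus,
        _CSP_ONLY: spec.n_unpaired_csplus,
        _CSM_ONLY: spec.n_csminus,
    }
    is_acq = spec.name is Phase.ACQUISITION
    if is_acq and spec.n_paired_csplus < 3:
        raise ConstraintError(
            "acquisition needs >= 3 paired CS+/US trials (first two and last)"
        )

    halves: list[list[str]] = [[], []]
    for kind, n in counts.items():
        a, b = _split_half_counts(n, rng)
        halves[0] += [kind] * a
        halves[1] += [kind] * b
    # balance a possible one-trial mismatch in overall half sizes
    n_trials = spec.n_trials
    if len(halves[0]) != n_trials - n_trials // 2:
        # move one trial of an odd-count kind between halves
        donor, receiver = (0, 1) if len(halves[0]) > len(halves[1]) else (1, 0)
        for kind, n in counts.items():
            if n % 2 == 1 and kind in halves[donor]:
                halves[donor].remove(kind)
                halves[receiver].append(kind)
                if len(halves[0]) == n_trials - n_trials // 2:
                    break

    for attempt in range(1000):
        first = list(halves[0])
        second = list(halves[1])
        rng.shuffle(first)
        rng.shuffle(second)
        if is_acq:
            # first two and the very last trial must be paired CS+/US
            if first.count(_PAIRED) < 2 or second.count(_PAIRED) < 1:
                raise ConstraintError(
                    "equal-halves split leaves too few paired trials to pin "
                    "the first two and last acquisition trials"
                )
            for _ in range(2):
                first.remove(_PAIRED)
            second.remove(_PAIRED)
            rng.shuffle(first)
            rng.shuffle(second)
            order = [_PAIRED, _PAIRED] + first + second + [_PAIRED]
        else:
            order = first + second
        if first_cs is not None:
            want = _CSM_ONLY if first_cs is CSType.CSM else None
            got_csm = order[0] == _CSM_ONLY
            if (want is None) != (not got_csm):
                continue
        return order
    raise ConstraintError("could not satisfy first-trial constraint")


def _kind_to_event(kind: str) -> tuple[CSType, bool]:
    if kind == _PAIRED:
        return CSType.CSP, True
    if kind == _CSP_ONLY:
        return CSType.CSP, False
    return CSType.CSM, False


def build_phase_sequence(
    spec: PhaseSpec,
    seed: int | np.random.Generator,
    *,
    first_cs: CSType | None = None,
    iti_rng: np.random.Generator | None = None,
) -> tuple[TrialEvent, ...]:
    """Generate the ordered trial events of one phase.

    Parameters
    ----------
    spec
        Phase composition (trial counts per kind).
    seed
        Seed (or Generator) driving the pseudorandom ordering.
    first_cs
        Optionally constrain the CS type of the first trial (used for the
        recall counterbalancing).
    iti_rng
        Separate generator for the inter-trial-interval draws; defaults to
        the ordering generator. Keeping them separate lets the day-1 ordering
        stay fixed across participants while ITIs vary.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if iti_rng is None:
        iti_rng = rng
    order = _order_kinds(spec, rng, first_cs)

    events: list[TrialEvent] = []
    t = 0.0
    lo, hi = ITI_RANGE_S
    for idx, kind in enumerate(order, start=1):
        cs_type, reinforced = _kind_to_event(kind)
        iti = float(iti_rng.uniform(lo, hi))
        events.append(
            TrialEvent(
                phase=spec.name,
                index_in_phase=idx,
                cs_type=cs_type,
                reinforced=reinforced,
                cs_onset=t,
                cs_duration=CS_DURATION_S,
                us_onset=t + US_DELAY_S,
                iti=iti,
            )
        )
        t += CS_DURATION_S + iti
    return tuple(events)


def build_experiment(
    counterbalance_id: str, seed: int | np.random.Generator
) -> ExperimentDesign:
    """Assemble the full two-day design for one counterbalance arm.

    The day-1 ordering (habituation, acquisition, extinction) and the recall
    ordering for each counterbalance are fixed by canonical internal seeds, so
    every participant experiences one of exactly two sequences. The user seed
    only drives the ITI draws.
    """
    if counterbalance_id not in ("A", "B"):
        raise ValueError("counterbalance_id must be 'A' or 'B'")
    iti_rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )

    day1: list[TrialEvent] = []
    for phase in (Phase.HABITUATION, Phase.ACQUISITION, Phase.EXTINCTION):
        order_rng = np.random.default_rng(_CANONICAL_DAY1_SEED + hash(phase.value) % 1000)
        day1 += build_phase_sequence(
            CANONICAL_PHASE_SPECS[phase], order_rng, iti_rng=iti_rng
        )

    first = CSType.CSP if counterbalance_id == "A" else CSType.CSM
    recall_rng = np.random.default_rng(_CANONICAL_RECALL_SEED)
    day2 = build_phase_sequence(
        CANONICAL_PHASE_SPECS[Phase.RECALL], recall_rng, first_cs=first, iti_rng=iti_rng
    )
    return ExperimentDesign(counterbalance_id=counterbalance_id,
                            day1=tuple(day1), day2=tuple(day2))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _phase_groups(trials: Iterable[TrialEvent]) -> dict[Phase, list[TrialEvent]]:
    groups: dict[Phase, list[TrialEvent]] = {}
    for t in trials:
        groups.setdefault(t.phase, []).append(t)
    return groups


def validate_design(design: ExperimentDesign) -> pd.DataFrame:
    """Check every paradigm constraint; returns a report, never raises.

    The report has one row per named constraint with a boolean ``passed``
    column and a human-readable detail string.
    """
    rows: list[dict] = []

    def check(name: str, passed: bool, detail: str = "") -> None:
        rows.append({"constraint": name, "passed": bool(passed), "detail": detail})

    groups = _phase_groups(design.trials)
    for phase, spec in CANONICAL_PHASE_SPECS.items():
        trials = groups.get(phase, [])
        n_paired = sum(t.reinforced for t in trials)
        n_cspo = sum((t.cs_type is CSType.CSP) and not t.reinforced for t in trials)
        n_csm = sum(t.cs_type is CSType.CSM for t in trials)
        check(
            f"{phase.value}-composition",
            (n_paired, n_cspo, n_csm)
            == (spec.n_paired_csplus, spec.n_unpaired_csplus, spec.n_csminus),
            f"paired={n_paired} cs+only={n_cspo} cs-={n_csm}",
        )
        # equal halves per kind (exact for even counts, +/-1 otherwise)
        half = len(trials) - len(trials) // 2
        ok = True
        detail = []
        for kind_name, pred in (
            ("paired", lambda t: t.reinforced),
            ("cs+only", lambda t: t.cs_type is CSType.CSP and not t.reinforced),
            ("cs-", lambda t: t.cs_type is CSType.CSM),
        ):
            a = sum(pred(t) for t in trials[:half])
            b = sum(pred(t) for t in trials[half:])
            total = a + b
            if total % 2 == 0:
                ok &= a == b
            else:
                ok &= abs(a - b) <= 1
            detail.append(f"{kind_name}:{a}/{b}")
        check(f"{phase.value}-equal-halves", ok, " ".join(detail))

    acq = groups.get(Phase.ACQUISITION, [])
    check(
        "acquisition-first-two-paired",
        len(acq) >= 2 and acq[0].reinforced and acq[1].reinforced,
    )
    check("acquisition-last-paired", bool(acq) and acq[-1].reinforced)

    rate_ok = False
    if acq:
        n_csp = sum(t.cs_type is CSType.CSP for t in acq)
        n_reinf = sum(t.reinforced for t in acq)
        rate_ok = n_csp > 0 and abs(n_reinf / n_csp - 0.625) < 1e-12
    check("acquisition-62.5%-reinforcement", rate_ok)

    for label, trials in (("day1", design.day1), ("day2", design.day2)):
        onsets_ok = True
        prev_phase, prev_onset = None, -np.inf
        for t in trials:
            if t.phase is prev_phase and t.cs_onset <= prev_onset:
                onsets_ok = False
            prev_phase, prev_onset = t.phase, t.cs_onset
        check(f"{label}-onsets-increasing", onsets_ok)

    timing_ok = all(
        abs(t.us_onset - t.cs_onset - US_DELAY_S) < 1e-9
        and ITI_RANGE_S[0] <= t.iti <= ITI_RANGE_S[1]
        and (not t.reinforced or t.cs_type is CSType.CSP)
        for t in design.trials
    )
    check("trial-timing-and-reinforcement-flags", timing_ok)

    recall = groups.get(Phase.RECALL, [])
    want = CSType.CSP if design.counterbalance_id == "A" else CSType.CSM
    check(
        "recall-counterbalanced-first-event",
        bool(recall) and recall[0].cs_type is want,
        f"first={recall[0].cs_type.value if recall else 'n/a'} expected={want.value}",
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def design_to_frame(design: ExperimentDesign) -> pd.DataFrame:
    """One row per trial: phase, index, cs_type, reinforced, timings."""
    rows = []
    for day, trials in ((1, design.day1), (2, design.day2)):
        for t in trials:
            d = asdict(t)
            d["phase"] = t.phase.value
            d["cs_type"] = t.cs_type.value
            d["day"] = day
            rows.append(d)
    df = pd.DataFrame(rows)
    cols = ["day", "phase", "index_in_phase", "cs_type", "reinforced",
            "cs_onset", "cs_duration", "us_onset", "iti"]
    return df[cols]


def design_from_frame(df: pd.DataFrame, counterbalance_id: str) -> ExperimentDesign:
    days: dict[int, list[TrialEvent]] = {1: [], 2: []}
    for _, row in df.iterrows():
        days[int(row["day"])].append(
            TrialEvent(
                phase=Phase(row["phase"]),
                index_in_phase=int(row["index_in_phase"]),
                cs_type=CSType(row["cs_type"]),
                reinforced=bool(row["reinforced"]),
                cs_onset=float(row["cs_onset"]),
                cs_duration=float(row["cs_duration"]),
                us_onset=float(row["us_onset"]),
                iti=float(row["iti"]),
            )
        )
    return ExperimentDesign(counterbalance_id=counterbalance_id,
                            day1=tuple(days[1]), day2=tuple(days[2]))
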