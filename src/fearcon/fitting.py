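"""Penalized hyper-parameter fitting of the replay model to group SCR curves.

For each of the two trial sequences l the scored CS-window SCRs are averaged
per presentation ordinal across participants, giving target curves
``Y_l = (y+_1..y+_N, y-_1..y-_N)``; the model's ensemble-averaged US
predictions form the matching ``V_l``. The goodness of fit of a
hyper-parameter configuration is

    F(b, lam, i, beta, RPE) = - sum_l w_l * ||Y_l - V_l||_1 - P_Saf - P_Ext

where ``w_l`` counts participants who experienced sequence l, and the
penalties (each 0 or 10) fire when the model fails to learn safety
(mean v over the last 4 acquisition CS- presentations >= 0.1) or fails to
extinguish (mean v over the last 4 extinction CS+ presentations >= 0.15).
Larger F is better; the grid-search maximum is the fitted configuration.

SCR amplitudes (log-microsiemens) and US-probability predictions live on
different scales; both curves are min-max normalized to [0, 1] over the whole
2N-entry curve before comparison (epsilon-guarded for constant curves).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paradigm import CSType, ExperimentDesign, Phase
from .rl_agent import HyperParams, run_ensemble

__all__ = [
    "AveragedCurves",
    "FitResult",
    "PENALTY_VALUE",
    "SAFETY_THRESHOLD",
    "EXTINCTION_THRESHOLD",
    "average_scr_curves",
    "ensemble_curves",
    "penalty_saf",
    "penalty_ext",
    "goodness_of_fit",
    "grid_search",
    "DESK_GRID",
]

PENALTY_VALUE = 10.0
SAFETY_THRESHOLD = 0.10      # on v over last 4 acquisition CS- presentations
EXTINCTION_THRESHOLD = 0.15  # on v over last 4 extinction CS+ presentations
_N_END = 4

# Reduced grid for desk-scale runs; the full Table-1-sized grid
# (rl_agent.TABLE1_GRID, 7200 configurations x 25 agents) is a documented
# long-running mode.
DESK_GRID: dict[str, list] = {
    "b": [16, 64],
    "lam": [0.5, 0.8, 1.0],
    "i": [2, 6, 12],
    "beta": [1, 3, 5],
    "rpe": [True, False],
}

_PHASE_ORDER = [Phase.HABITUATION, Phase.ACQUISITION, Phase.EXTINCTION, Phase.RECALL]


@dataclass(frozen=True)
class AveragedCurves:
    """Per-ordinal group-mean curve for one trial sequence."""

    y: np.ndarray          # length 2N: CS+ ordinals then CS- ordinals
    w: int                 # participants contributing
    label: str             # sequence label l

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("w must be >= 1")


def _minmax(y: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    lo, hi = y.min(), y.max()
    if hi - lo < eps:
        return np.zeros_like(y)
    return (y - lo) / (hi - lo)


def _add_ordinals(scores: pd.DataFrame) -> pd.DataFrame:
    df = scores.copy()
    order = {p.value: k for k, p in enumerate(_PHASE_ORDER)}
    df["_phase_order"] = df["phase"].map(order)
    df = df.sort_values(["participant", "_phase_order", "index_in_phase"])
    df["ordinal"] = df.groupby(["participant", "cs_type"]).cumcount() + 1
    return df.drop(columns="_phase_order")


def average_scr_curves(
    scores: pd.DataFrame, label: str, *, normalize: bool = True
) -> AveragedCurves:
    """Group-mean per-ordinal curve from CS-window trial scores.

    ``scores`` is the long trial-score table (one sequence's participants,
    CS window only or mixed — the CS window is selected here). Scores are
    log-transformed per trial (LN(1 + amplitude)) before averaging, the scale
    the analysis uses throughout.
    """
    df = scores[scores["window"] == "CS"]
    if df.empty:
        raise ValueError("no CS-window scores supplied")
    df = _add_ordinals(df)
    df = df.assign(log_amp=np.log1p(df["amplitude"]))
    cell = df.groupby(["cs_type", "ordinal"])["log_amp"]
    counts = df.groupby(["cs_type", "ordinal"])["participant"].nunique()
    if counts.nunique() != 1:
        raise ValueError("participants contribute unequal trial counts")
    mean = cell.mean()
    parts = []
    for cs in (CSType.CSP.value, CSType.CSM.value):
        parts.append(mean.loc[cs].sort_index().to_numpy())
    y = np.concatenate(parts)
    if normalize:
        y = _minmax(y)
    return AveragedCurves(y=y, w=int(counts.iloc[0]), label=label)


def ensemble_curves(ens: pd.DataFrame, label: str, *, normalize: bool = True) -> AveragedCurves:
    """V-bar curve (CS+ ordinals then CS-) from a ``run_ensemble`` table."""
    parts = []
    for cs in (CSType.CSP.value, CSType.CSM.value):
        sub = ens[ens["cs_type"] == cs].sort_values("ordinal")
        parts.append(sub["v_mean"].to_numpy())
    y = np.concatenate(parts)
    if normalize:
        y = _minmax(y)
    return AveragedCurves(y=y, w=1, label=label)


def _end_mean(ens: pd.DataFrame, phase: Phase, cs: CSType) -> float:
    sub = ens[(ens["phase"] == phase.value) & (ens["cs_type"] == cs.value)]
    v = sub.sort_values("index_in_phase")["v_mean"].to_numpy()
    if v.size < _N_END:
        raise ValueError(f"fewer than {_N_END} {cs.value} presentations in {phase.value}")
    return float(v[-_N_END:].mean())


def penalty_saf(ens: pd.DataFrame | float) -> float:
    """0 if the model learned CS- safety, 10 otherwise (boundary penalized)."""
    v_end = ens if np.isscalar(ens) else _end_mean(ens, Phase.ACQUISITION, CSType.CSM)
    return 0.0 if v_end < SAFETY_THRESHOLD else PENALTY_VALUE


def penalty_ext(ens: pd.DataFrame | float) -> float:
    """0 if the model extinguished the CS+ response, 10 otherwise."""
    v_end = ens if np.isscalar(ens) else _end_mean(ens, Phase.EXTINCTION, CSType.CSP)
    return 0.0 if v_end < EXTINCTION_THRESHOLD else PENALTY_VALUE


def goodness_of_fit(
    targets: list[AveragedCurves],
    model: list[AveragedCurves],
    p_saf: float = 0.0,
    p_ext: float = 0.0,
    *,
    norm: str = "l1",
) -> float:
    """Weighted negative curve mismatch minus penalties; larger is better."""
    if len(targets) != len(model):
        raise ValueError("sequence counts differ")
    total = 0.0
    for yl, vl in zip(targets, model):
        if yl.y.shape != vl.y.shape:
            raise ValueError(f"curve length mismatch for sequence {yl.label!r}")
        d = yl.y - vl.y
        dist = np.abs(d).sum() if norm == "l1" else float(np.linalg.norm(d))
        total -= yl.w * dist
    return total - p_saf - p_ext


@dataclass(frozen=True)
class FitResult:
    surface: pd.DataFrame       # one row per configuration
    best: HyperParams
    best_ensembles: dict[str, pd.DataFrame]   # label -> run_ensemble table


def grid_search(
    grid: dict[str, list],
    targets: dict[str, AveragedCurves],
    designs: dict[str, ExperimentDesign],
    n_agents: int,
    seed: int,
    *,
    norm: str = "l1",
) -> FitResult:
    """Exhaustive search of the hyper-parameter grid.

    ``targets`` and ``designs`` are keyed by sequence label l. Every
    configuration trains ``n_agents`` fresh agents per sequence from seeds
    derived deterministically from ``seed``; ties in F break lexicographically
    on (b, lam, i, beta, RPE).
    """
    keys = ("b", "lam", "i", "beta", "rpe")
    for k in keys:
        if k not in grid or not grid[k]:
            raise ValueError(f"empty grid for {k!r}")
    labels = sorted(targets)
    if sorted(designs) != labels:
        raise ValueError("targets and designs must cover the same sequences")

    master = np.random.SeedSequence(seed)
    rows = []
    results: dict[tuple, dict[str, pd.DataFrame]] = {}
    for combo in itertools.product(*(grid[k] for k in keys)):
        hp = HyperParams(**dict(zip(keys, combo)))
        # seed per configuration: independent of grid ordering
        cfg_ss = np.random.SeedSequence(
            entropy=master.entropy,
            spawn_key=(hash(hp.key()) & 0x7FFFFFFF,),
        )
        child = cfg_ss.spawn(len(labels))
        ens_by_label: dict[str, pd.DataFrame] = {}
        vcurves = []
        saf_ends, ext_ends = [], []
        for lab, ss in zip(labels, child):
            ens = run_ensemble(designs[lab], hp, n_agents=n_agents, seed=ss)
            ens_by_label[lab] = ens
            vcurves.append(ensemble_curves(ens, lab))
            saf_ends.append(_end_mean(ens, Phase.ACQUISITION, CSType.CSM))
            ext_ends.append(_end_mean(ens, Phase.EXTINCTION, CSType.CSP))
        # day-1 ordering is shared across sequences: penalize on the mean
        p_saf = penalty_saf(float(np.mean(saf_ends)))
        p_ext = penalty_ext(float(np.mean(ext_ends)))
        f = goodness_of_fit([targets[l] for l in labels], vcurves,
                            p_saf, p_ext, norm=norm)
        rows.append({
            "b": hp.b, "lam": hp.lam, "i": hp.i, "beta": hp.beta,
            "rpe": hp.rpe, "F": f, "p_saf": p_saf, "p_ext": p_ext,
            "v_acq_end": float(np.mean(saf_ends)),
            "v_ext_end": float(np.mean(ext_ends)),
        })
        results[hp.key()] = ens_by_label

    surface = pd.DataFrame(rows)
    ranked = surface.sort_values(
        ["F", "b", "lam", "i", "beta", "rpe"],
        ascending=[False, True, True, True, True, True],
    )
    top = ranked.iloc[0]
    best = HyperParams(b=int(top["b"]), lam=float(top["lam"]), i=int(top["i"]),
                       beta=float(top["beta"]), rpe=bool(top["rpe"]))
    return FitResult(surface=surface, best=best,
                     best_ensembles=results[best.key()])
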