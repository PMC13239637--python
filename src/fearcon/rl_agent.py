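"""Replay-based reinforcement-learning model of fear acquisition, extinction
and spontaneous recovery.

An artificial agent learns to predict the probability of the aversive US from
the visual stimulus. On each trial it emits a prediction ``v_t`` in [0, 1]
and a prediction error ``delta_t = r_t - v_t`` (reinforcement ``r_t`` coded 1
for paired, 0 for unpaired trials), stores the experience tuple
``(s_t, r_t, delta_t)`` in memory, and then trains on ``i`` batches of size
``b`` sampled from memory with probability proportional to a priority score:
recency ``lambda^tau`` alone, or optionally ``|delta| * lambda^tau`` when the
RPE flag is set.

Because extinction in an unchanged context would simply overwrite the
acquired association, the model includes a sleep-replay phase between day 1
and day 2: 100 batches of size 64 sampled with softmax probability
``exp(beta * r_k) / sum_i exp(beta * r_i)``, which preferentially reactivates
reinforced experiences and thereby restores part of the original fear
association — the mechanism behind spontaneous recovery at recall.

The value function is a fully connected network with two hidden layers of 64
units and a sigmoid output. Loss, optimizer and initialization are not part
of the scientific claim and are fixed here: mean-squared error against r,
plain SGD, seeded scaled-Gaussian initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .paradigm import CSType, ExperimentDesign, Phase

__all__ = [
    "STIMULUS_CODES",
    "Experience",
    "HyperParams",
    "ValueNet",
    "Agent",
    "AgentTrace",
    "prediction_error",
    "replay_probabilities",
    "sleep_probabilities",
    "train_on_trial",
    "sleep_replay",
    "run_agent",
    "run_ensemble",
    "TABLE1_GRID",
    "DEFAULT_ENSEMBLE_SIZE",
]

# Two orthogonal, equal-norm 8-bit codes standing in for the square/diamond
# figures. Any fixed distinct encoding works; this one is a config constant.
STIMULUS_CODES: dict[CSType, np.ndarray] = {
    CSType.CSP: np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float),
    CSType.CSM: np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float),
}

DEFAULT_ENSEMBLE_SIZE = 25
SLEEP_N_BATCHES = 100
SLEEP_BATCH_SIZE = 64

# Full grid the study searched over.
TABLE1_GRID: dict[str, list] = {
    "b": [1, 16, 32, 64, 96, 128],
    "lam": [0.05, 0.4, 0.5, 0.6, 0.7, 0.8, 0.825, 0.85, 0.895, 1.0],
    "i": list(range(1, 13)),
    "beta": [1, 2, 3, 4, 5],
    "rpe": [True, False],
}


@dataclass(frozen=True)
class HyperParams:
    """Searchable hyper-parameters plus fixed training settings."""

    b: int = 16                 # replay batch size
    lam: float = 0.8            # recency decay factor
    i: int = 6                  # replays (batch updates) per trial
    beta: float = 3.0           # sleep-replay inverse temperature
    rpe: bool = False           # priorities also scale with |delta|
    learning_rate: float = 0.01  # fixed SGD step
    sleep_n_batches: int = SLEEP_N_BATCHES
    sleep_batch_size: int = SLEEP_BATCH_SIZE

    def __post_init__(self) -> None:
        if self.b < 1 or self.i < 0:
            raise ValueError("b >= 1 and i >= 0 required")
        if not (0.0 < self.lam <= 1.0):
            raise ValueError("lam must be in (0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def key(self) -> tuple:
        """Deterministic (lexicographic) identity for tie-breaking."""
        return (self.b, self.lam, self.i, self.beta, self.rpe)


@dataclass(frozen=True)
class Experience:
    """Stored tuple (s, r, delta) plus its storage trial index."""

    s: np.ndarray
    r: float
    delta: float
    t_stored: int

    def __post_init__(self) -> None:
        if self.r not in (0.0, 1.0):
            raise ValueError("reinforcement must be 0 or 1")


def prediction_error(r: float, v: float) -> float:
    """Signed US prediction error delta = r - v."""
    return float(r) - float(v)


def replay_probabilities(
    memory: list[Experience], t_now: int, lam: float, rpe: bool
) -> np.ndarray:
    """Waking-replay sampling distribution over the memory buffer.

    Priority p_k = lam^tau_k, optionally multiplied by |delta_k| (the
    prediction error stored with the experience). If the RPE-weighted
    priorities all vanish, falls back to recency-only priorities.
    """
    if not memory:
        raise ValueError("memory is empty")
    tau = np.array([t_now - e.t_stored for e in memory], dtype=float)
    if np.any(tau < 0):
        raise ValueError("experience stored in the future")
    p = lam ** tau
    if rpe:
        weighted = np.abs([e.delta for e in memory]) * p
        if weighted.sum() > 0:
            p = weighted
    total = p.sum()
    if total <= 0:  # lam**tau underflow for ancient memories at tiny lam
        p = np.where(tau == tau.min(), 1.0, 0.0)
        total = p.sum()
    return p / total


def sleep_probabilities(memory: list[Experience], beta: float) -> np.ndarray:
    """Sleep-replay softmax over stored reinforcements r_k."""
    if not memory:
        raise ValueError("memory is empty")
    r = np.array([e.r for e in memory], dtype=float)
    z = np.exp(beta * (r - r.max()))
    return z / z.sum()


class ValueNet:
    """Two hidden fully connected layers (64 units, ReLU) + sigmoid output."""

    HIDDEN = 64

    def __init__(self, n_inputs: int, rng: np.random.Generator):
        h = self.HIDDEN
        def init(n_in, n_out):
            return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.w1 = init(n_inputs, h)
        self.b1 = np.zeros(h)
        self.w2 = init(h, h)
        self.b2 = np.zeros(h)
        self.w3 = init(h, 1)
        self.b3 = np.zeros(1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """US probability for a batch of stimulus codes (rows)."""
        x = np.atleast_2d(x)
        a1 = np.maximum(x @ self.w1 + self.b1, 0.0)
        a2 = np.maximum(a1 @ self.w2 + self.b2, 0.0)
        z = a2 @ self.w3 + self.b3
        return 1.0 / (1.0 + np.exp(-z[:, 0]))

    def sgd_step(self, x: np.ndarray, target: np.ndarray, lr: float) -> None:
        """One backpropagation step on MSE loss toward the r targets."""
        x = np.atleast_2d(x)
        target = np.asarray(target, dtype=float)
        m = x.shape[0]
        a1 = np.maximum(x @ self.w1 + self.b1, 0.0)
        a2 = np.maximum(a1 @ self.w2 + self.b2, 0.0)
        z = a2 @ self.w3 + self.b3
        v = 1.0 / (1.0 + np.exp(-z[:, 0]))
        # dL/dz for L = mean((v - r)^2)
        dz = (2.0 / m) * (v - target) * v * (1.0 - v)
        dz = dz[:, None]
        gw3 = a2.T @ dz
        gb3 = dz.sum(0)
        da2 = dz @ self.w3.T
        da2[a2 <= 0] = 0.0
        gw2 = a1.T @ da2
        gb2 = da2.sum(0)
        da1 = da2 @ self.w2.T
        da1[a1 <= 0] = 0.0
        gw1 = x.T @ da1
        gb1 = da1.sum(0)
        self.w1 -= lr * gw1; self.b1 -= lr * gb1
        self.w2 -= lr * gw2; self.b2 -= lr * gb2
        self.w3 -= lr * gw3; self.b3 -= lr * gb3


@dataclass
class Agent:
    net: ValueNet
    hp: HyperParams
    rng: np.random.Generator
    memory: list[Experience] = field(default_factory=list)
    t: int = 0                      # trials experienced so far
    sleep_updates_done: int = 0

    @classmethod
    def fresh(cls, hp: HyperParams, seed: int | np.random.SeedSequence) -> "Agent":
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        rng = np.random.default_rng(ss)
        n_inputs = len(next(iter(STIMULUS_CODES.values())))
        return cls(net=ValueNet(n_inputs, rng), hp=hp, rng=rng)

    def predict(self, cs_type: CSType) -> float:
        return float(self.net.forward(STIMULUS_CODES[cs_type])[0])


def _replay_batches(agent: Agent, n_batches: int, batch_size: int,
                    probs_fn) -> None:
    xs = np.stack([e.s for e in agent.memory])
    rs = np.array([e.r for e in agent.memory])
    for _ in range(n_batches):
        probs = probs_fn()
        idx = agent.rng.choice(len(agent.memory), size=batch_size,
                               replace=True, p=probs)
        agent.net.sgd_step(xs[idx], rs[idx], agent.hp.learning_rate)


def train_on_trial(agent: Agent, cs_type: CSType, reinforced: bool) -> tuple[float, float]:
    """Experience one trial: predict, store, replay. Returns (v_t, delta_t).

    ``v_t`` is read out before any weight update for this trial; the stored
    experience carries the delta computed from that prediction.
    """
    r = 1.0 if reinforced else 0.0
    v = agent.predict(cs_type)
    delta = prediction_error(r, v)
    agent.memory.append(
        Experience(s=STIMULUS_CODES[cs_type].copy(), r=r, delta=delta,
                   t_stored=agent.t)
    )
    agent.t += 1
    if agent.hp.i > 0:
        _replay_batches(
            agent, agent.hp.i, agent.hp.b,
            lambda: replay_probabilities(agent.memory, agent.t, agent.hp.lam,
                                         agent.hp.rpe),
        )
    return v, delta


def sleep_replay(agent: Agent) -> Agent:
    """Between-day consolidation: 100 batches of 64, softmax over r."""
    if not agent.memory:
        raise ValueError("cannot sleep on an empty memory")
    probs = sleep_probabilities(agent.memory, agent.hp.beta)
    _replay_batches(agent, agent.hp.sleep_n_batches, agent.hp.sleep_batch_size,
                    lambda: probs)
    agent.sleep_updates_done += agent.hp.sleep_n_batches
    return agent


@dataclass(frozen=True)
class AgentTrace:
    """Per-trial record of the agent's behaviour over the full experiment."""

    table: pd.DataFrame   # trial, phase, index_in_phase, cs_type, v, delta
    sleep_updates: int

    def v_series(self, phase: Phase, cs_type: CSType) -> np.ndarray:
        t = self.table
        sel = (t["phase"] == phase.value) & (t["cs_type"] == cs_type.value)
        return t.loc[sel].sort_values("index_in_phase")["v"].to_numpy()


def run_agent(
    design: ExperimentDesign,
    hp: HyperParams,
    seed: int | np.random.SeedSequence,
    *,
    sleep: bool = True,
) -> AgentTrace:
    """Train one agent through the two-day design.

    Day 1 (habituation, acquisition, extinction) is experienced trial by
    trial, then the sleep-replay phase runs (unless disabled for ablation),
    then the day-2 recall trials are experienced the same way.
    """
    agent = Agent.fresh(hp, seed)
    rows = []
    for trial_no, trial in enumerate(design.day1):
        v, delta = train_on_trial(agent, trial.cs_type, trial.reinforced)
        rows.append((trial_no, trial.phase.value, trial.index_in_phase,
                     trial.cs_type.value, trial.reinforced, v, delta))
    if sleep:
        sleep_replay(agent)
    for trial_no, trial in enumerate(design.day2, start=len(design.day1)):
        v, delta = train_on_trial(agent, trial.cs_type, trial.reinforced)
        rows.append((trial_no, trial.phase.value, trial.index_in_phase,
                     trial.cs_type.value, trial.reinforced, v, delta))
    table = pd.DataFrame(
        rows, columns=["trial", "phase", "index_in_phase", "cs_type",
                       "reinforced", "v", "delta"],
    )
    return AgentTrace(table=table, sleep_updates=agent.sleep_updates_done)


def run_ensemble(
    design: ExperimentDesign,
    hp: HyperParams,
    n_agents: int = DEFAULT_ENSEMBLE_SIZE,
    seed: int | np.random.SeedSequence = 0,
    *,
    sleep: bool = True,
) -> pd.DataFrame:
    """Average per-presentation-ordinal predictions across random agents.

    Returns one row per trial of the design with ensemble-mean ``v`` and
    mean ``|delta|`` (plus per-CS presentation ordinals), i.e. the V-bar
    curves used for fitting and the modulator weights used for export.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_agents)
    v_acc = None
    absd_acc = None
    base = None
    for child in children:
        trace = run_agent(design, hp, child, sleep=sleep)
        if base is None:
            base = trace.table.drop(columns=["v", "delta"])
            v_acc = trace.table["v"].to_numpy().copy()
            absd_acc = np.abs(trace.table["delta"].to_numpy())
        else:
            v_acc += trace.table["v"].to_numpy()
            absd_acc += np.abs(trace.table["delta"].to_numpy())
    out = base.copy()
    out["v_mean"] = v_acc / n_agents
    out["abs_delta_mean"] = absd_acc / n_agents
    # per-CS presentation ordinal within the whole experiment and per phase
    out["ordinal"] = out.groupby("cs_type").cumcount() + 1
    return out
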