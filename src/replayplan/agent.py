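"""Temporal-difference learner with prioritized offline replay.

The agent maintains tabular state-action values updated by the SARSA-style
rule

    delta = r + gamma * Q(s', a') - Q(s, a)
    Q(s, a) <- Q(s, a) + alpha * delta

with gamma fixed at 1 (the task horizon is a single step) and the successor
term dropped at terminal states. Choices are softmax in the values, with an
optional uniform lapse.

Offline replay follows the Dyna / prioritized-sweeping recipe: every
experienced transition is kept in a buffer tagged with the unsigned
prediction error |delta| it last produced (scaled by a per-agent
``pe_sensitivity`` gain), and tagging a state also raises the priority of
buffered predecessors of that state, so that surprise at a stage-II outcome
marks the root transition leading there for replay. At each rest period the
agent draws ``replay_budget_k`` replay events; under the prioritized mode
each draw picks a transition with probability proportional to its current
priority, competing against a constant ``background_replay_mass`` of
off-task memory (draws landing there replay nothing task-related). Replayed
root transitions bootstrap from the greedy successor value, which is the
integration step that lets second-stage reward changes propagate to the
root policy without any root-state visit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .task import ACTIONS, STAGE1, STATES

__all__ = [
    "AgentParams",
    "QTable",
    "ReplayItem",
    "ReplayBuffer",
    "ReplayEvent",
    "TDAgent",
    "td_update",
    "softmax_choose",
    "softmax_probabilities",
    "tag_experience",
    "offline_replay",
    "fit_learning_rate",
    "FitResult",
    "ContractError",
    "EstimationError",
]

REPLAY_MODES = ("prioritized", "uniform", "none")


class ContractError(ValueError):
    """An operation was called with arguments violating its contract."""


class EstimationError(RuntimeError):
    """Likelihood-based estimation is impossible on the supplied data."""


@dataclass(frozen=True)
class AgentParams:
    """Learner parameters.

    alpha : learning rate in (0, 1].
    gamma : discount; 1 for this one-step-horizon task.
    beta : softmax inverse temperature (currency^-1); 0 gives random choice.
    lapse : probability of a uniform random choice regardless of values.
    replay_budget_k : replay draws per rest period.
    replay_mode : 'prioritized', 'uniform', or 'none'.
    pe_sensitivity : gain applied to |delta| when tagging replay priorities;
        models across-participant variation in neural PE sensitivity.
    background_replay_mass : constant priority mass of competing off-task
        memories in the prioritized draw (same units as priorities).
    """

    alpha: float = 0.7
    gamma: float = 1.0
    beta: float = 3.0
    lapse: float = 0.05
    replay_budget_k: int = 20
    replay_mode: str = "prioritized"
    pe_sensitivity: float = 1.0
    background_replay_mass: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ContractError("alpha must lie in (0, 1]")
        if self.beta < 0:
            raise ContractError("beta must be nonnegative")
        if not 0.0 <= self.lapse <= 1.0:
            raise ContractError("lapse must lie in [0, 1]")
        if self.replay_mode not in REPLAY_MODES:
            raise ContractError(f"unknown replay mode {self.replay_mode!r}")
        if self.replay_budget_k < 0:
            raise ContractError("replay_budget_k must be nonnegative")
        if self.pe_sensitivity < 0 or self.background_replay_mass < 0:
            raise ContractError("gains and masses must be nonnegative")


class QTable:
    """State-action values, zero-initialized, in currency units."""

    def __init__(self, values: dict | None = None):
        self._q = {(s, a): 0.0 for s in STATES for a in ACTIONS[s]}
        if values:
            self._q.update(values)

    def __getitem__(self, key):
        return self._q[key]

    def __setitem__(self, key, value):
        if key not in self._q:
            raise KeyError(key)
        self._q[key] = value

    def __eq__(self, other):
        return isinstance(other, QTable) and self._q == other._q

    def copy(self) -> "QTable":
        return QTable(dict(self._q))

    def as_dict(self) -> dict:
        return dict(self._q)

    def values_at(self, s: str) -> np.ndarray:
        return np.array([self._q[(s, a)] for a in ACTIONS[s]])

    def greedy(self, s: str) -> str:
        # deterministic tie-break toward the first-listed action
        values = self.values_at(s)
        return ACTIONS[s][int(np.argmax(values))]

    def max_value(self, s: str) -> float:
        return float(self.values_at(s).max())


def td_update(q: QTable, s, a, r, s_next, a_next, params: AgentParams) -> float:
    """Apply the TD update in place and return the signed prediction error."""
    if s_next is not None and a_next is None:
        raise ContractError("nonterminal successor requires a_next")
    successor = 0.0 if s_next is None else q[(s_next, a_next)]
    delta = r + params.gamma * successor - q[(s, a)]
    q[(s, a)] = q[(s, a)] + params.alpha * delta
    return delta


def softmax_probabilities(values: np.ndarray, beta: float, lapse: float = 0.0) -> np.ndarray:
    z = beta * np.asarray(values, dtype=float)
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    if lapse:
        p = (1.0 - lapse) * p + lapse / len(p)
    return p


def softmax_choose(q: QTable, s: str, beta: float, rng: np.random.Generator,
                   lapse: float = 0.0) -> str:
    if beta < 0:
        raise ContractError("beta must be nonnegative")
    p = softmax_probabilities(q.values_at(s), beta, lapse)
    return ACTIONS[s][int(rng.choice(len(p), p=p))]


@dataclass
class ReplayItem:
    """A stored transition with its replay priority (unsigned PE at tag time)."""

    s: str
    a: str
    r: float | None  # None for root transitions (replayed with r = 0)
    s_next: str | None
    priority: float
    tag_time: int


class ReplayBuffer:
    """One item per (state, action); re-tagging replaces the stored priority."""

    def __init__(self):
        self._items: dict = {}

    def __len__(self):
        return len(self._items)

    def items(self) -> list:
        return list(self._items.values())

    def get(self, s, a) -> ReplayItem | None:
        return self._items.get((s, a))

    def tag(self, s, a, r, s_next, delta, tag_time=0, *,
            pe_sensitivity: float = 1.0, propagate: bool = True) -> None:
        priority = pe_sensitivity * abs(delta)
        item = self._items.get((s, a))
        if item is None:
            self._items[(s, a)] = ReplayItem(s, a, r, s_next, priority, tag_time)
        else:
            item.r, item.s_next = r, s_next
            item.priority, item.tag_time = priority, tag_time
        if propagate:
            # prioritized-sweeping backup: surprise at s marks buffered
            # predecessors of s for replay
            for other in self._items.values():
                if other.s_next == s:
                    other.priority = max(other.priority, priority)


def tag_experience(buffer: ReplayBuffer, transition, delta, tag_time=0, *,
                   pe_sensitivity: float = 1.0, propagate: bool = True) -> ReplayBuffer:
    """Tag ``transition = (s, a, r, s_next)`` with priority |delta|."""
    s, a, r, s_next = transition
    buffer.tag(s, a, r, s_next, delta, tag_time,
               pe_sensitivity=pe_sensitivity, propagate=propagate)
    return buffer


@dataclass(frozen=True)
class ReplayEvent:
    """One replay draw; ``s`` is ``'off-task'`` for background draws."""

    step: int
    s: str
    a: str | None
    priority: float
    delta: float


OFF_TASK = "off-task"


def offline_replay(q: QTable, buffer: ReplayBuffer, params: AgentParams,
                   rng: np.random.Generator):
    """Run one rest period of replay; returns ``(q, replay_log)``.

    Each replayed transition is re-updated against the current values:
    terminal (stage-II) items replay their stored reward; root items replay
    r = 0 while bootstrapping from the greedy successor action (no
    behavioral next action exists offline). Priorities are refreshed to the
    new |delta| after each replay, and predecessor priorities are raised in
    turn, as during online tagging.
    """
    log: list = []
    if params.replay_mode == "none" or params.replay_budget_k == 0:
        return q, log
    items = buffer.items()
    if not items:
        return q, log
    for step in range(params.replay_budget_k):
        if params.replay_mode == "prioritized":
            weights = np.array([it.priority for it in items])
            total = weights.sum() + params.background_replay_mass
            if total <= 0.0:
                break
            u = rng.uniform(0.0, total)
            cum = np.cumsum(weights)
            idx = int(np.searchsorted(cum, u, side="right"))
            if idx >= len(items):  # background draw: nothing task-related
                log.append(ReplayEvent(step, OFF_TASK, None, 0.0, 0.0))
                continue
            item = items[idx]
        elif params.replay_mode == "uniform":
            item = items[int(rng.integers(len(items)))]
        else:  # pragma: no cover - guarded above
            raise ContractError(params.replay_mode)
        sampled_priority = item.priority
        if item.s_next is None:
            delta = td_update(q, item.s, item.a, item.r, None, None, params)
        else:
            a_greedy = q.greedy(item.s_next)
            delta = td_update(q, item.s, item.a, 0.0, item.s_next, a_greedy, params)
        buffer.tag(item.s, item.a, item.r, item.s_next, delta, item.tag_time,
                   pe_sensitivity=params.pe_sensitivity)
        log.append(ReplayEvent(step, item.s, item.a, sampled_priority, delta))
    return q, log


class TDAgent:
    """Bundles values, parameters, and the replay buffer behind the hooks
    that :func:`replayplan.task.run_block` drives."""

    def __init__(self, params: AgentParams | None = None):
        self.params = params or AgentParams()
        self.q = QTable()
        self.buffer = ReplayBuffer()
        self._time = 0

    def choose(self, s: str, rng: np.random.Generator) -> str:
        return softmax_choose(self.q, s, self.params.beta, rng, self.params.lapse)

    def update(self, s, a, r, s_next, a_next) -> float:
        delta = td_update(self.q, s, a, r, s_next, a_next, self.params)
        stored_r = None if s == STAGE1 else r
        tag_experience(
            self.buffer, (s, a, stored_r, s_next), delta, self._time,
            pe_sensitivity=self.params.pe_sensitivity)
        self._time += 1
        return delta

    def rest_replay(self, rng: np.random.Generator) -> list:
        self.q, log = offline_replay(self.q, self.buffer, self.params, rng)
        return log


@dataclass
class FitResult:
    """Pooled maximum-likelihood learning-rate estimate.

    ``alpha`` is the reported estimate (smallest grid value whose
    log-likelihood is within ``tie_tol`` of the maximum); ``alpha_argmax``
    is the raw grid argmax.
    """

    alpha: float
    alpha_argmax: float
    log_likelihood: float
    identifiable: bool
    grid: np.ndarray
    grid_log_likelihood: np.ndarray
    n_choices: int


def _block_steps(log) -> list:
    """Normalize a block's learning + relearning records into flat steps.

    Accepts a BlockResult, a pandas DataFrame with the phase-log columns, or
    an iterable of EpisodeRecord. Test-phase records are ignored (no
    feedback, no learning).
    """
    if hasattr(log, "learning"):
        records = list(log.learning.records) + list(log.relearning.records)
        return [(r.phase, r.trial_index, r.s, r.a,
                 0.0 if r.s == STAGE1 else r.r, r.s_next, r.a_next, r.forced)
                for r in records]
    if hasattr(log, "itertuples"):
        steps = []
        for row in log.itertuples(index=False):
            if row.phase == "test":
                continue
            s_next = row.s_next if isinstance(row.s_next, str) and row.s_next else None
            a_next = row.a_next if isinstance(row.a_next, str) and row.a_next else None
            r = 0.0 if row.s == STAGE1 else float(row.r)
            steps.append((row.phase, int(row.trial), row.s, row.a, r,
                          s_next, a_next, bool(row.forced)))
        return steps
    return [(r.phase, r.trial_index, r.s, r.a,
             0.0 if r.s == STAGE1 else r.r, r.s_next, r.a_next, r.forced)
            for r in log if r.phase != "test"]


def fit_learning_rate(
    logs: Sequence,
    beta: float,
    *,
    lapse: float = 0.0,
    grid: np.ndarray | None = None,
    tie_tol: float = 1.0,
) -> FitResult:
    """Pooled MLE of the learning rate from choice logs of many blocks.

    For each candidate alpha on a 0.01-step grid, every block's value
    trajectory is reconstructed by replaying its logged transitions through
    the TD update, and the log-likelihood of the *free* (non-forced)
    choices is accumulated under a softmax(beta * Q) rule (with the fixed,
    known ``lapse`` mixed in).

    Ties break toward the smaller alpha. Because near-deterministic choice
    (large beta times large value gaps) leaves the likelihood essentially
    flat *above* the true learning rate while dropping sharply below it,
    "tie" is read as any log-likelihood within ``tie_tol`` (default 1 nat)
    of the maximum: the reported estimate is the lower edge of that
    near-maximal plateau, which is the quantity the data identify. A fully
    flat likelihood (e.g. beta = 0) is flagged as non-identifiable.
    """
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 2)
    blocks = [_block_steps(log) for log in logs]
    n_free = sum(1 for steps in blocks for st in steps if not st[7])
    if n_free == 0:
        raise EstimationError("no free choices in the supplied logs")

    lls = np.empty(len(grid))
    for gi, alpha in enumerate(grid):
        total = 0.0
        for steps in blocks:
            q = {(s, a): 0.0 for s in STATES for a in ACTIONS[s]}
            i = 0
            while i < len(steps):
                phase, trial, s, a, r, s_next, a_next, forced = steps[i]
                if phase == "learning":
                    # the two steps of one trial: both choices precede both updates
                    p2 = steps[i + 1]
                    for st in (steps[i], p2):
                        if not st[7]:
                            total += _choice_logp(q, st[2], st[3], beta, lapse)
                    # root update bootstraps from the greedy successor action
                    # under the candidate trajectory, matching the generative
                    # rule (the root learns state worth, not pressed keys)
                    a_boot = max(ACTIONS[s_next], key=lambda b: q[(s_next, b)])
                    d1 = r + q[(s_next, a_boot)] - q[(s, a)]
                    q[(s, a)] += alpha * d1
                    d2 = p2[4] - q[(p2[2], p2[3])]
                    q[(p2[2], p2[3])] += alpha * d2
                    i += 2
                else:  # relearning: single terminal step
                    if not forced:
                        total += _choice_logp(q, s, a, beta, lapse)
                    q[(s, a)] += alpha * (r - q[(s, a)])
                    i += 1
        lls[gi] = total

    best = int(np.argmax(lls))  # first max -> smallest alpha on exact ties
    edge = int(np.argmax(lls >= lls.max() - tie_tol))
    identifiable = bool(lls.max() - lls.min() > 1e-9)
    if not identifiable:
        edge = 0  # flat likelihood: grid minimum, flagged
    return FitResult(float(grid[edge]), float(grid[best]), float(lls[edge]),
                     identifiable, grid, lls, n_free)


def _choice_logp(q: dict, s: str, a: str, beta: float, lapse: float) -> float:
    actions = ACTIONS[s]
    z = [beta * q[(s, b)] for b in actions]
    m = max(z)
    exps = [math.exp(v - m) for v in z]
    denom = sum(exps)
    p = exps[actions.index(a)] / denom
    if lapse:
        p = (1.0 - lapse) * p + lapse / len(actions)
    return math.log(p)
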