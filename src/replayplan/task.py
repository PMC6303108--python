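"""Two-stage reward-revaluation decision task.

The environment is a deterministic three-state Markov decision process: a
root state ``S1`` whose two actions lead to one of two second-stage states
(``left`` -> ``S2``, ``right`` -> ``S3``), each of which offers a ``top`` /
``bottom`` choice paying a monetary reward in [1, 50]. A block runs through
three phases:

* **Learning** -- ~70 full episodes (root choice, second-stage choice,
  reward), with forced-choice balancing so every (state, action) pair is
  adequately sampled.
* **Relearning** -- second-stage-only episodes. In *revaluation* blocks the
  second-stage reward means change here so that the optimal root action
  flips; in *control* blocks they do not. After every ``episodes_per_rest``
  episodes a rest period occurs, at which the agent's offline-replay hook
  is invoked.
* **Test** -- root-state choices with no feedback and no value update,
  probing whether the agent replanned.

Crossed with the revaluation factor, a *noise* factor decides whether
rewards are drawn from a normal distribution around the state-action mean
(then clipped to [1, 50]) or delivered deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

STAGE1 = "S1"
STAGE2_STATES = ("S2", "S3")
STATES = (STAGE1,) + STAGE2_STATES
STAGE1_ACTIONS = ("left", "right")
STAGE2_ACTIONS = ("top", "bottom")
#: Deterministic root transition: the action label fixes the successor state.
TRANSITION = {"left": "S2", "right": "S3"}
ACTIONS = {
    STAGE1: STAGE1_ACTIONS,
    "S2": STAGE2_ACTIONS,
    "S3": STAGE2_ACTIONS,
}
STAGE2_PAIRS = tuple((s, a) for s in STAGE2_STATES for a in STAGE2_ACTIONS)
ALL_PAIRS = tuple((STAGE1, a) for a in STAGE1_ACTIONS) + STAGE2_PAIRS

REWARD_MIN = 1.0
REWARD_MAX = 50.0

CONDITIONS = ("revaluation", "control")
NOISE_LEVELS = ("noisy", "noiseless")
CATEGORIES_S1 = ("face", "scene")

PHASES = ("learning", "relearning", "test")


class ConfigurationError(ValueError):
    """Invalid block configuration (bad enum, inconsistent schedule...)."""


class ProtocolError(RuntimeError):
    """A phase protocol was violated (e.g. a root-state visit during relearning)."""


class InterfaceError(TypeError):
    """The supplied agent does not expose the required hooks."""


@dataclass(frozen=True)
class BlockConfig:
    """Condition, reward structure, and schedule for one task block."""

    block_id: str
    condition: str
    noise: str
    stage1_category: str
    reward_mean: dict
    reward_sd: float
    reval_reward_mean: dict
    n_learning_trials: int = 70
    n_relearning_episodes: int = 18
    episodes_per_rest: int = 6
    n_rest_periods: int = 3
    n_test_trials: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.noise not in NOISE_LEVELS:
            raise ConfigurationError(f"unknown noise level {self.noise!r}")
        if self.stage1_category not in CATEGORIES_S1:
            raise ConfigurationError(
                f"unknown root-state category {self.stage1_category!r}")
        if self.n_relearning_episodes != self.episodes_per_rest * self.n_rest_periods:
            raise ConfigurationError(
                "n_relearning_episodes must equal episodes_per_rest * n_rest_periods")
        for means in (self.reward_mean, self.reval_reward_mean):
            if set(means) != set(STAGE2_PAIRS):
                raise ConfigurationError("reward means must cover all stage-II pairs")
            for value in means.values():
                if not REWARD_MIN <= value <= REWARD_MAX:
                    raise ConfigurationError(
                        f"reward mean {value} outside [{REWARD_MIN}, {REWARD_MAX}]")
        if self.noise == "noiseless" and self.reward_sd != 0.0:
            raise ConfigurationError("noiseless blocks must have reward_sd == 0")
        if self.reward_sd < 0:
            raise ConfigurationError("reward_sd must be nonnegative")
        if self.condition == "control" and self.reval_reward_mean != self.reward_mean:
            raise ConfigurationError("control blocks must not change reward means")
        if self.condition == "revaluation":
            pre = best_stage2_state(self.reward_mean)
            post = best_stage2_state(self.reval_reward_mean)
            if pre == post:
                raise ConfigurationError(
                    "revaluation blocks must flip the dominant stage-II state")

    @property
    def stage2_category(self) -> str:
        return "scene" if self.stage1_category == "face" else "face"

    def means_for_phase(self, phase: str) -> dict:
        """Learning uses the original means; relearning and test the post-change ones."""
        if phase not in PHASES:
            raise ConfigurationError(f"unknown phase {phase!r}")
        return self.reward_mean if phase == "learning" else self.reval_reward_mean

    def optimal_stage1_action(self, phase: str) -> str:
        """Root action leading to the stage-II state with the best attainable mean."""
        best = best_stage2_state(self.means_for_phase(phase))
        for action, state in TRANSITION.items():
            if state == best:
                return action
        raise AssertionError("unreachable")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reward_mean"] = {f"{s}:{a}": v for (s, a), v in self.reward_mean.items()}
        d["reval_reward_mean"] = {
            f"{s}:{a}": v for (s, a), v in self.reval_reward_mean.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BlockConfig":
        d = dict(d)
        for key in ("reward_mean", "reval_reward_mean"):
            d[key] = {tuple(k.split(":")): v for k, v in d[key].items()}
        return cls(**d)


def best_stage2_state(means: dict) -> str:
    """Stage-II state holding the maximal best-action mean."""
    return max(
        STAGE2_STATES,
        key=lambda s: max(means[(s, a)] for a in STAGE2_ACTIONS),
    )


@dataclass
class EpisodeRecord:
    """One state-action step of one trial; ``r``/``delta`` are NaN where absent."""

    phase: str
    trial_index: int
    s: str
    a: str
    r: float
    s_next: str | None
    a_next: str | None
    delta: float
    forced: bool


@dataclass
class PhaseLog:
    records: list = field(default_factory=list)
    #: episode indices after which a rest period occurred (relearning only)
    rest_boundaries: list = field(default_factory=list)

    def to_frame(self, block_id: str = "") -> pd.DataFrame:
        rows = [
            {
                "block_id": block_id,
                "phase": r.phase,
                "trial": r.trial_index,
                "s": r.s,
                "a": r.a,
                "r": r.r,
                "s_next": r.s_next if r.s_next is not None else "",
                "a_next": r.a_next if r.a_next is not None else "",
                "delta": r.delta,
                "forced": r.forced,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


@dataclass
class BlockResult:
    """Everything one block produces for the downstream stages."""

    config: BlockConfig
    learning: PhaseLog
    relearning: PhaseLog
    test: PhaseLog
    replay_logs: list  # one replay log (list of ReplayEvent) per rest period

    @property
    def rest_schedule(self) -> list:
        return list(self.relearning.rest_boundaries)

    def stage1_replay_counts(self) -> list:
        """Number of replayed root-state transitions per rest period."""
        return [sum(1 for ev in log if ev.s == STAGE1) for log in self.replay_logs]

    def to_frame(self) -> pd.DataFrame:
        frames = [
            log.to_frame(self.config.block_id)
            for log in (self.learning, self.relearning, self.test)
        ]
        return pd.concat(frames, ignore_index=True)


def make_block_config(
    condition: str,
    noise: str,
    stage1_category: str,
    seed: int,
    *,
    block_id: str | None = None,
    best_mean: float = 45.0,
    mid_mean: float = 20.0,
    low_mean: float = 5.0,
    reward_sd: float = 2.0,
    **schedule,
) -> BlockConfig:
    """Build a block configuration for one cell of the 2 x 2 design.

    One stage-II state strictly dominates before revaluation (its best action
    pays ``best_mean`` on average vs. the other state's ``mid_mean``); in
    revaluation blocks the post-change means swap those two best-action
    payouts so the optimal root action flips. Which state is initially rich,
    and which action slot pays best within each state, are drawn from
    ``seed`` so blocks differ superficially while keeping the same margins.
    """
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown condition {condition!r}")
    if noise not in NOISE_LEVELS:
        raise ConfigurationError(f"unknown noise level {noise!r}")
    if not (REWARD_MIN <= low_mean < mid_mean < best_mean <= REWARD_MAX):
        raise ConfigurationError("means must satisfy 1 <= low < mid < best <= 50")
    rng = np.random.default_rng(seed)
    rich_state = STAGE2_STATES[int(rng.integers(2))]
    poor_state = "S3" if rich_state == "S2" else "S2"
    best_action = {s: STAGE2_ACTIONS[int(rng.integers(2))] for s in STAGE2_STATES}

    def means(rich: str) -> dict:
        poor = "S3" if rich == "S2" else "S2"
        out = {}
        out[(rich, best_action[rich])] = best_mean
        out[(rich, other_action(best_action[rich]))] = low_mean
        out[(poor, best_action[poor])] = mid_mean
        out[(poor, other_action(best_action[poor]))] = low_mean
        return out

    reward_mean = means(rich_state)
    if condition == "revaluation":
        reval_reward_mean = means(poor_state)
    else:
        reval_reward_mean = dict(reward_mean)
    return BlockConfig(
        block_id=block_id or f"{condition}-{noise}-{stage1_category}-{seed}",
        condition=condition,
        noise=noise,
        stage1_category=stage1_category,
        reward_mean=reward_mean,
        reward_sd=reward_sd if noise == "noisy" else 0.0,
        reval_reward_mean=reval_reward_mean,
        rng_seed=int(seed),
        **schedule,
    )


def other_action(action: str) -> str:
    if action in STAGE1_ACTIONS:
        return STAGE1_ACTIONS[1 - STAGE1_ACTIONS.index(action)]
    return STAGE2_ACTIONS[1 - STAGE2_ACTIONS.index(action)]


def env_step(
    config: BlockConfig,
    phase: str,
    s: str,
    a: str,
    rng: np.random.Generator,
):
    """One environment transition: ``(s_next, reward, done)``.

    Root-state steps are deterministic, unrewarded and only legal outside
    the relearning phase; stage-II steps terminate the episode with a
    reward drawn from the phase-appropriate mean (clipped to [1, 50]).
    """
    if phase not in PHASES:
        raise ConfigurationError(f"unknown phase {phase!r}")
    if s == STAGE1:
        if phase == "relearning":
            raise ProtocolError("the root state is never visited during relearning")
        if a not in STAGE1_ACTIONS:
            raise ConfigurationError(f"invalid root action {a!r}")
        return TRANSITION[a], 0.0, False
    if s not in STAGE2_STATES or a not in STAGE2_ACTIONS:
        raise ConfigurationError(f"invalid state-action ({s!r}, {a!r})")
    mean = config.means_for_phase(phase)[(s, a)]
    if config.reward_sd == 0.0:
        r = mean
    else:
        r = float(np.clip(rng.normal(mean, config.reward_sd), REWARD_MIN, REWARD_MAX))
    return None, r, True


def run_block(config: BlockConfig, agent, rng: np.random.Generator | None = None) -> BlockResult:
    """Run an agent through one block, logging every step.

    The agent must expose ``choose(state, rng)``, ``update(s, a, r, s_next,
    a_next) -> delta`` and ``rest_replay(rng) -> replay_log``. Test-phase
    choices use ``choose`` but never ``update``, so the agent's values are
    untouched by the test.
    """
    for hook in ("choose", "update", "rest_replay"):
        if not callable(getattr(agent, hook, None)):
            raise InterfaceError(f"agent lacks required hook {hook!r}")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    learning = PhaseLog()
    last_seen = {pair: -(10 ** 9) for pair in ALL_PAIRS}
    for t in range(config.n_learning_trials):
        # Forced-choice balancing: any pair not experienced in the last 10
        # trials is presented as a forced choice (stalest pair first).
        stale = [p for p in ALL_PAIRS if last_seen[p] < t - 10]
        target = min(stale, key=lambda p: (last_seen[p], ALL_PAIRS.index(p))) if stale else None
        forced1 = forced2 = False
        if target is not None and target[0] == STAGE1:
            a1, forced1 = target[1], True
        elif target is not None:
            # reaching a stale stage-II pair constrains the root choice too
            a1 = next(a for a, s in TRANSITION.items() if s == target[0])
            forced1 = True
        else:
            a1 = agent.choose(STAGE1, rng)
        s2, _, _ = env_step(config, "learning", STAGE1, a1, rng)
        if target is not None and target[0] == s2:
            a2, forced2 = target[1], True
        else:
            a2 = agent.choose(s2, rng)
        _, r, done = env_step(config, "learning", s2, a2, rng)
        assert done
        # both choices are made before either value update (the second-stage
        # stimulus is evaluated with pre-trial values); the root update
        # bootstraps from the greedy successor action under the pre-update
        # values -- the root learns what the successor state is *worth*, not
        # which key was pressed there (forced or lapsed presses would
        # otherwise corrupt the root preference)
        a2_boot = agent.q.greedy(s2) if hasattr(agent, "q") else a2
        d1 = agent.update(STAGE1, a1, 0.0, s2, a2_boot)
        d2 = agent.update(s2, a2, r, None, None)
        learning.records.append(EpisodeRecord(
            "learning", t, STAGE1, a1, math.nan, s2, a2_boot, d1, forced1))
        learning.records.append(EpisodeRecord(
            "learning", t, s2, a2, r, None, None, d2, forced2))
        last_seen[(STAGE1, a1)] = t
        last_seen[(s2, a2)] = t

    relearning = PhaseLog()
    replay_logs = []
    for i in range(config.n_relearning_episodes):
        s = STAGE2_STATES[i % 2]
        a = agent.choose(s, rng)
        _, r, _ = env_step(config, "relearning", s, a, rng)
        d = agent.update(s, a, r, None, None)
        relearning.records.append(EpisodeRecord(
            "relearning", i, s, a, r, None, None, d, False))
        if (i + 1) % config.episodes_per_rest == 0:
            relearning.rest_boundaries.append(i + 1)
            replay_logs.append(agent.rest_replay(rng))

    test = PhaseLog()
    for t in range(config.n_test_trials):
        a = agent.choose(STAGE1, rng)
        test.records.append(EpisodeRecord(
            "test", t, STAGE1, a, math.nan, None, None, math.nan, False))

    return BlockResult(config, learning, relearning, test, replay_logs)
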