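"""Synthetic voxel time series with category-selective populations.

The generator emulates the measurement side of the study: a blocked
face/scene/object localizer run and 30-s rest periods sampled at
TR = 2.08 s, over a voxel set split into three equally sized
category-selective populations plus a nonselective background. Category
stimulation adds a constant selectivity amplitude to the matching
population; all voxels carry i.i.d. Gaussian noise (no drift, spatial or
temporal autocorrelation -- see docs/methods.md for what this does and does
not emulate). Rest periods receive (a) an exponentially decaying spillover
of the pre-rest stimulus category starting at TR 0, and (b) one discrete
root-state-category reactivation event per replayed root transition,
injected at a uniformly random TR >= 5 so that ground truth lies inside the
analysis window (TRs 5-14). A block's three rest periods are thereby
coupled to the agent's offline-replay log, and a participant cohort couples
replay propensity to both behavior and neural evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agent import AgentParams, TDAgent
from .behavior import score_block
from .task import BlockConfig, BlockResult, make_block_config, run_block, STAGE1

__all__ = [
    "CATEGORIES",
    "TR_SECONDS",
    "REST_TRS",
    "SPILLOVER_SKIP_TRS",
    "VoxelTimeSeries",
    "NeuroGenParams",
    "CouplingSpec",
    "BlockData",
    "ParticipantData",
    "Cohort",
    "generate_localizer",
    "generate_rest_period",
    "generate_cohort",
    "save_voxel_tsv",
    "load_voxel_tsv",
]

CATEGORIES = ("face", "scene", "object")
TR_SECONDS = 2.08
#: 30 s / 2.08 s = 14.4 TRs, rounded up so the omitted first 5 TRs and the
#: analyzed last 10 TRs exactly tile the rest period.
REST_TRS = 15
SPILLOVER_SKIP_TRS = 5
#: 12-s localizer blocks at TR 2.08 s ~ 6 TRs.
LOCALIZER_BLOCK_TRS = 6
LOCALIZER_CYCLES = 4


@dataclass
class VoxelTimeSeries:
    """TR x voxel matrix with per-TR labels and a ground-truth event ledger."""

    data: np.ndarray
    labels: list
    events: list = field(default_factory=list)  # (tr_index, category, amplitude)
    tr_seconds: float = TR_SECONDS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be TR x voxel")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal the TR count")
        if np.isnan(self.data).any():
            raise ValueError("data must not contain missing values")

    @property
    def n_trs(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class NeuroGenParams:
    """Generator knobs, all in arbitrary signal units unless noted."""

    n_voxels_per_population: int = 50
    selectivity_amplitude: float = 1.0
    noise_sd: float = 1.0
    spillover_amplitude: float = 2.0
    spillover_decay_tr: float = 2.0  # e-folding time, in TRs
    coupling_gain: float = 2.0  # reactivation events per replayed root state
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_voxels_per_population < 1:
            raise ValueError("need at least one voxel per population")
        for name in ("selectivity_amplitude", "noise_sd", "spillover_amplitude",
                     "spillover_decay_tr", "coupling_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_voxels(self) -> int:
        return 4 * self.n_voxels_per_population

    def population(self, category: str) -> slice:
        """Column slice of a selective population ('background' for the rest)."""
        order = CATEGORIES + ("background",)
        i = order.index(category)
        n = self.n_voxels_per_population
        return slice(i * n, (i + 1) * n)


def generate_localizer(params: NeuroGenParams,
                       rng: np.random.Generator | None = None) -> VoxelTimeSeries:
    """Blocked localizer: 4 cycles x 3 categories, 6-TR blocks with 6-TR rests.

    Block order is shuffled within each cycle. Each category block adds
    ``selectivity_amplitude`` to its selective population on every block TR;
    i.i.d. Gaussian noise is added everywhere.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    labels: list = ["rest"] * LOCALIZER_BLOCK_TRS  # lead-in rest
    for _ in range(LOCALIZER_CYCLES):
        order = [CATEGORIES[i] for i in rng.permutation(len(CATEGORIES))]
        for cat in order:
            labels += [cat] * LOCALIZER_BLOCK_TRS
            labels += ["rest"] * LOCALIZER_BLOCK_TRS
    n_trs = len(labels)
    data = params.noise_sd * rng.standard_normal((n_trs, params.n_voxels))
    events = []
    for tr, lab in enumerate(labels):
        if lab in CATEGORIES:
            data[tr, params.population(lab)] += params.selectivity_amplitude
            events.append((tr, lab, params.selectivity_amplitude))
    return VoxelTimeSeries(data, labels, events)


def generate_rest_period(
    params: NeuroGenParams,
    stage1_category: str,
    pre_rest_category: str,
    n_replay_events: int,
    rng: np.random.Generator,
    *,
    allow_early_events: bool = False,
) -> VoxelTimeSeries:
    """One 15-TR rest period with spillover and replay-coupled reactivations.

    Spillover adds ``spillover_amplitude * exp(-t / spillover_decay_tr)`` of
    the pre-rest stimulus category to its population from TR 0. Each of the
    ``coupling_gain * n_replay_events`` (rounded) reactivation events adds
    ``selectivity_amplitude`` to the root-state category's population at a
    uniformly random TR >= 5 (the analysis window); ``allow_early_events``
    is a stress mode that lets events fall anywhere, to quantify what the
    window omission loses.
    """
    if stage1_category not in CATEGORIES or pre_rest_category not in CATEGORIES:
        raise ValueError("categories must be one of face/scene/object")
    if n_replay_events < 0:
        raise ValueError("replay event count must be nonnegative")
    data = params.noise_sd * rng.standard_normal((REST_TRS, params.n_voxels))
    events = []
    if params.spillover_amplitude > 0:
        t = np.arange(REST_TRS)
        decay = params.spillover_amplitude * np.exp(-t / params.spillover_decay_tr)
        data[:, params.population(pre_rest_category)] += decay[:, None]
    n_events = int(round(params.coupling_gain * n_replay_events))
    lo = 0 if allow_early_events else SPILLOVER_SKIP_TRS
    for _ in range(n_events):
        tr = int(rng.integers(lo, REST_TRS))
        data[tr, params.population(stage1_category)] += params.selectivity_amplitude
        events.append((tr, stage1_category, params.selectivity_amplitude))
    return VoxelTimeSeries(data, ["rest"] * REST_TRS, events)


@dataclass(frozen=True)
class CouplingSpec:
    """Across-participant distribution of replay propensity.

    Each participant i receives a propensity u_i evenly spaced on
    [u_min, u_max] (shuffled across participants), which jointly sets the
    replay budget k_i = round(k_max * u_i), the PE-sensitivity gain of
    tagging (priority = u_i * |delta|), and the gain of the participant's
    simulated PE-sensitive region signal. One latent propensity driving all
    three is the generative version of the hypothesis that neural PE
    sensitivity begets replay, which begets replanning.
    """

    k_max: int = 40
    u_min: float = 0.0
    u_max: float = 1.0
    #: tagging gain per unit propensity: pe_sensitivity_i = pe_scale * u_i.
    #: Sub-unity by default so that, against the agent's fixed background
    #: replay mass, task replay (and with it the policy flip) accrues
    #: gradually across the propensity range instead of saturating at once.
    pe_scale: float = 0.1
    pe_signal_noise_sd: float = 1.0

    def propensities(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = np.linspace(self.u_min, self.u_max, n)
        rng.shuffle(u)
        return u


@dataclass
class BlockData:
    """One block's behavior, neural data, and ground truth."""

    config: BlockConfig
    result: BlockResult
    score: float
    stage1_replay_counts: list
    rests: list  # 3 VoxelTimeSeries
    pe_regressor_onsets: np.ndarray
    pe_regressor_modulator: np.ndarray  # |delta| at reward onsets
    pe_signal: np.ndarray  # simulated PE-sensitive region time series


@dataclass
class ParticipantData:
    pid: int
    propensity: float
    replay_budget_k: int
    pe_sensitivity: float
    localizer: VoxelTimeSeries
    blocks: list


@dataclass
class Cohort:
    participants: list
    neuro_params: NeuroGenParams
    coupling: CouplingSpec
    agent_params: AgentParams
    seed: int

    def scores_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant": p.pid,
                "block_id": b.config.block_id,
                "condition": b.config.condition,
                "noise": b.config.noise,
                "score": b.score,
            }
            for p in self.participants for b in p.blocks
        ]
        return pd.DataFrame(rows)


def _block_cells(rng: np.random.Generator) -> list:
    """The 2 x 2 cells with root categories balanced 2 face / 2 scene."""
    cells = [(c, n) for c in ("revaluation", "control")
             for n in ("noisy", "noiseless")]
    cats = ["face", "face", "scene", "scene"]
    order = rng.permutation(4)
    cat_order = rng.permutation(4)
    return [(cells[i], cats[j]) for i, j in zip(order, cat_order)]


def _pe_signal(deltas: np.ndarray, gain: float, noise_sd: float,
               rng: np.random.Generator):
    """Simulated time series of a PE-sensitive region during learning.

    Two samples per reward receipt (onset + baseline); the onset sample
    carries a unit mean response plus ``gain`` times the unsigned PE.
    """
    n = len(deltas)
    onsets = np.arange(0, 2 * n, 2)
    signal = noise_sd * rng.standard_normal(2 * n)
    signal[onsets] += 1.0 + gain * np.abs(deltas)
    return signal, onsets, np.abs(deltas)


def generate_cohort(
    n_participants: int = 24,
    seed: int = 0,
    coupling: CouplingSpec | None = None,
    neuro: NeuroGenParams | None = None,
    agent_params: AgentParams | None = None,
) -> Cohort:
    """Simulate a full cohort: behavior, localizers, and replay-coupled rests.

    Each participant completes 4 blocks (revaluation/control x
    noisy/noiseless, order randomized, root categories balanced). The
    participant's latent replay propensity sets their replay budget, their
    PE-sensitivity tagging gain, and the gain of their simulated
    PE-sensitive region signal. Bit-identical under a fixed seed.
    """
    coupling = coupling or CouplingSpec()
    neuro = neuro or NeuroGenParams()
    base_agent = agent_params or AgentParams()
    root = np.random.default_rng([seed, 0x5EED])
    u = coupling.propensities(n_participants, root)

    participants = []
    for pid in range(n_participants):
        prng = np.random.default_rng([seed, 1000 + pid])
        k = int(round(coupling.k_max * u[pid]))
        pe_gain = float(u[pid])
        params_i = replace(base_agent, replay_budget_k=k,
                           pe_sensitivity=coupling.pe_scale * float(u[pid]))
        localizer = generate_localizer(neuro, prng)
        blocks = []
        for bi, ((condition, noise), cat) in enumerate(_block_cells(prng)):
            config = make_block_config(
                condition, noise, cat,
                seed=int(prng.integers(2 ** 31)),
                block_id=f"p{pid:02d}-b{bi}-{condition}-{noise}",
            )
            agent = TDAgent(params_i)
            result = run_block(config, agent, prng)
            counts = result.stage1_replay_counts()
            rests = [
                generate_rest_period(neuro, config.stage1_category,
                                     config.stage2_category, c, prng)
                for c in counts
            ]
            deltas = np.array([
                r.delta for r in result.learning.records if r.s != STAGE1
            ])
            signal, onsets, modulator = _pe_signal(
                deltas, pe_gain, coupling.pe_signal_noise_sd, prng)
            blocks.append(BlockData(
                config=config,
                result=result,
                score=score_block(result).value,
                stage1_replay_counts=counts,
                rests=rests,
                pe_regressor_onsets=onsets,
                pe_regressor_modulator=modulator,
                pe_signal=signal,
            ))
        participants.append(ParticipantData(
            pid, float(u[pid]), k, pe_gain, localizer, blocks))
    return Cohort(participants, neuro, coupling, base_agent, seed)


def save_voxel_tsv(ts: VoxelTimeSeries, path) -> None:
    """Write a voxel matrix as TSV with a JSON header line (``#`` prefixed)."""
    header = {
        "tr_seconds": ts.tr_seconds,
        "labels": list(ts.labels),
        "events": [list(e) for e in ts.events],
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        np.savetxt(fh, ts.data, delimiter="\t", fmt="%.8g")


def load_voxel_tsv(path) -> VoxelTimeSeries:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("missing JSON header line")
        header = json.loads(first[1:])
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return VoxelTimeSeries(
        data, header["labels"],
        [tuple(e) for e in header["events"]],
        header["tr_seconds"])
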