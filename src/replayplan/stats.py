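"""Brain-behavior inference: rank correlations, participant bootstrap,
rest-period dynamics, Fisher-z comparison, and the unsigned-PE
parametric-modulation regression.

All resampling routines are driven by an explicit seed or Generator and
reproduce bit-identically under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "CorrStats",
    "StatResult",
    "BootstrapResult",
    "PERegressor",
    "spearman_corr",
    "bootstrap_corr_diff",
    "rest_dynamics",
    "fisher_z_compare",
    "parametric_modulation_glm",
    "BoundaryError",
    "RankDeficiencyError",
]


class BoundaryError(ValueError):
    """A correlation/size argument lies on or outside its admissible range."""


class RankDeficiencyError(ValueError):
    """The regression design is rank-deficient (e.g. constant modulator)."""


@dataclass(frozen=True)
class CorrStats:
    rho: float
    p: float
    n: int
    note: str | None = None


@dataclass(frozen=True)
class StatResult:
    name: str
    value: float
    dof: object = None
    p: float = float("nan")
    note: str | None = None


@dataclass(frozen=True)
class BootstrapResult:
    observed_diff: float
    p: float
    n_boot: int
    mean: float
    ci_low: float
    ci_high: float
    alternative: str
    n_degenerate: int = 0


def spearman_corr(x, y, *, method: str = "t", n_perm: int = 10_000,
                  seed: int | np.random.Generator = 0) -> CorrStats:
    """Tie-corrected (average-rank) Spearman rho.

    ``method='t'`` (default) uses the t approximation for the two-sided p;
    ``method='permutation'`` shuffles one variable ``n_perm`` times and
    reports the two-sided permutation p, a robustness option for small
    samples with heavy ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrStats(float("nan"), float("nan"), len(x),
                         note="undefined: constant input")
    rho, p = scipy.stats.spearmanr(x, y)
    if method == "permutation":
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        null = np.empty(n_perm)
        yy = y.copy()
        for b in range(n_perm):
            rng.shuffle(yy)
            null[b] = scipy.stats.spearmanr(x, yy).statistic
        p = float((1 + np.sum(np.abs(null) >= abs(rho))) / (1 + n_perm))
    elif method != "t":
        raise ValueError("method must be 't' or 'permutation'")
    return CorrStats(float(rho), float(p), len(x))


def _resample_rho(x, y) -> float:
    """Spearman rho treating degenerate (constant) resamples as 0."""
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    return float(scipy.stats.spearmanr(x, y).statistic)


def bootstrap_corr_diff(
    x_reval, y_reval, x_control, y_control,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    alternative: str = "greater",
) -> BootstrapResult:
    """Participant bootstrap of the correlation difference between conditions.

    Participants are resampled with replacement jointly -- one resample
    index vector is applied to both conditions, so a participant's
    revaluation and control data travel together. For each of ``n_boot``
    resamples the difference rho_reval - rho_control is recomputed;
    ``alternative='greater'`` (the directional hypothesis that the
    revaluation correlation is larger) reports the proportion of resampled
    differences <= 0. Resamples where a correlation is undefined (constant
    input) contribute a 0 coefficient and are counted in ``n_degenerate``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    arrays = [np.asarray(a, dtype=float)
              for a in (x_reval, y_reval, x_control, y_control)]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all inputs must be indexed by the same participants")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = _resample_rho(arrays[0], arrays[1]) - _resample_rho(arrays[2], arrays[3])
    diffs = np.empty(n_boot)
    n_degenerate = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xr, yr, xc, yc = (a[idx] for a in arrays)
        degenerate = any(np.all(v == v[0]) for v in (xr, yr, xc, yc))
        n_degenerate += int(degenerate)
        diffs[b] = _resample_rho(xr, yr) - _resample_rho(xc, yc)
    # mid-p tie handling: exact zeros count half, so the symmetric null
    # (identical conditions) yields p = 0.5 rather than 1
    p_le = float(np.mean(diffs < 0.0) + 0.5 * np.mean(diffs == 0.0))
    if alternative == "greater":
        p = p_le
    else:
        p_ge = 1.0 - p_le
        p = min(1.0, 2.0 * min(p_le, p_ge))
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapResult(observed, p, n_boot, float(diffs.mean()),
                           float(lo), float(hi), alternative, n_degenerate)


def rest_dynamics(evidence: pd.DataFrame) -> dict:
    """Within-block rest-period dynamics of replay evidence.

    ``evidence`` needs columns ``participant``, ``block_id``, ``condition``,
    ``rest_index`` (1..3), ``evidence``, and ``score`` (the block's
    replanning magnitude, repeated across its rests). Evidence is
    mean-centered within block across the three rests; the returned dict
    holds, per condition, the paired t test of centered Rest 1 vs Rest 3
    (on participant means), the paired t of uncentered Rest 1 evidence
    between revaluation and control, per-rest Spearman correlations of
    evidence with replanning in the revaluation condition, and the
    ``centered`` long table. Blocks with missing rests are excluded (their
    ids under ``excluded_blocks``).
    """
    required = {"participant", "block_id", "condition", "rest_index",
                "evidence", "score"}
    if not required.issubset(evidence.columns):
        raise ValueError(f"evidence table needs columns {sorted(required)}")
    counts = evidence.groupby("block_id")["rest_index"].nunique()
    complete = counts[counts == 3].index
    excluded = sorted(set(counts.index) - set(complete))
    ev = evidence[evidence["block_id"].isin(complete)].copy()
    ev["centered"] = ev["evidence"] - ev.groupby("block_id")["evidence"].transform("mean")

    out: dict = {"centered": ev, "excluded_blocks": excluded}
    for cond, sub in ev.groupby("condition"):
        wide = (sub.groupby(["participant", "rest_index"])["centered"]
                .mean().unstack("rest_index"))
        d = (wide[1] - wide[3]).to_numpy()
        if np.var(d, ddof=1) == 0:
            out[f"rest1_vs_rest3_{cond}"] = StatResult(
                f"t({len(d) - 1})", float("nan"), len(d) - 1, float("nan"),
                note="degenerate: zero variance")
        else:
            t, p = scipy.stats.ttest_1samp(d, 0.0)
            out[f"rest1_vs_rest3_{cond}"] = StatResult(
                f"t({len(d) - 1})", float(t), len(d) - 1, float(p))

    raw1 = (ev[ev["rest_index"] == 1]
            .groupby(["participant", "condition"])["evidence"].mean()
            .unstack("condition"))
    if {"revaluation", "control"}.issubset(raw1.columns):
        d = (raw1["revaluation"] - raw1["control"]).dropna().to_numpy()
        if len(d) >= 2 and np.var(d, ddof=1) > 0:
            t, p = scipy.stats.ttest_1samp(d, 0.0)
            out["rest1_revaluation_vs_control"] = StatResult(
                f"t({len(d) - 1})", float(t), len(d) - 1, float(p))
        else:
            out["rest1_revaluation_vs_control"] = StatResult(
                "t", float("nan"), None, float("nan"), note="degenerate")

    reval = ev[ev["condition"] == "revaluation"]
    for rest in (1, 2, 3):
        sub = reval[reval["rest_index"] == rest]
        agg = sub.groupby("participant")[["evidence", "score"]].mean()
        if len(agg) >= 4:
            out[f"replay_behavior_rest{rest}"] = spearman_corr(
                agg["evidence"].to_numpy(), agg["score"].to_numpy())
    return out


def fisher_z_compare(rho1: float, n1: int, rho2: float, n2: int) -> StatResult:
    """Compare two independent correlation coefficients via the atanh transform."""
    if n1 < 4 or n2 < 4:
        raise BoundaryError("both samples must have n >= 4")
    if abs(rho1) >= 1 or abs(rho2) >= 1:
        raise BoundaryError("|rho| must be < 1")
    z = (math.atanh(rho1) - math.atanh(rho2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return StatResult("z", float(z), (n1, n2), float(p))


@dataclass
class PERegressor:
    """Reward-onset regressor parametrically modulated by unsigned PE.

    ``onsets`` are sample indices of reward receipt; ``modulator`` holds the
    corresponding |delta| values, mean-centered before entering the design.
    """

    onsets: np.ndarray
    modulator: np.ndarray

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.modulator = np.asarray(self.modulator, dtype=float)
        if self.onsets.shape != self.modulator.shape or self.onsets.ndim != 1:
            raise ValueError("onsets and modulator must be equal-length 1-d arrays")

    def centered_modulator(self) -> np.ndarray:
        return self.modulator - self.modulator.mean()


def parametric_modulation_glm(signal, regressor: PERegressor) -> StatResult:
    """OLS of a signal on [intercept, onset indicator, centered |PE|].

    Returns the modulation beta with its t statistic and two-sided p. The
    onset indicator absorbs the mean response to reward receipt, so the
    modulation beta measures variance around that mean tracking unsigned
    prediction error.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-d")
    if regressor.onsets.min(initial=0) < 0 or (len(regressor.onsets) and
                                               regressor.onsets.max() >= len(signal)):
        raise ValueError("onsets must index into the signal")
    if len(np.unique(regressor.modulator)) < 2:
        raise RankDeficiencyError("modulator must take at least 2 distinct values")
    indicator = np.zeros(len(signal))
    indicator[regressor.onsets] = 1.0
    mod = np.zeros(len(signal))
    mod[regressor.onsets] = regressor.centered_modulator()
    X = np.column_stack([np.ones(len(signal)), indicator, mod])
    fit = sm.OLS(signal, X).fit()
    return StatResult("beta", float(fit.params[2]), float(fit.df_resid),
                      float(fit.pvalues[2]))
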