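"""Replanning-magnitude statistic and group-level behavioral tests.

The replanning (revaluation) magnitude of a block is

    ns_test / n_test - ns_learning / n_learning

where ``ns_test`` counts test-phase choices of the action that is optimal
*at test* (out of ``n_test`` valid test choices) and ``ns_learning`` counts
choices of that same action among the last 10 valid root-state choices of
the learning phase. The score lies in [-1, 1]; in revaluation blocks it
measures successful reversal of an initially correct preference, while in
control blocks (where the optimal action never changes) a large score flags
an unwarranted reversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .task import STAGE1, BlockResult
from .stats import StatResult

__all__ = [
    "ChoiceCounts",
    "ReplanningScore",
    "UndefinedScoreError",
    "replanning_magnitude",
    "counts_from_block",
    "score_block",
    "group_behavior_tests",
]


class UndefinedScoreError(ValueError):
    """No valid responses in a phase: the block's score is undefined."""


@dataclass(frozen=True)
class ChoiceCounts:
    """Counts entering the replanning-magnitude ratio."""

    ns_test: int
    n_test: int
    ns_learning: int
    n_learning: int

    def __post_init__(self):
        if not (0 <= self.ns_test <= self.n_test):
            raise ValueError("ns_test must lie in [0, n_test]")
        if not (0 <= self.ns_learning <= self.n_learning):
            raise ValueError("ns_learning must lie in [0, n_learning]")


@dataclass(frozen=True)
class ReplanningScore:
    block_id: str
    condition: str
    noise: str
    value: float


def replanning_magnitude(counts: ChoiceCounts) -> float:
    """Difference of the two choice proportions; in [-1, 1]."""
    if counts.n_test < 1 or counts.n_learning < 1:
        raise UndefinedScoreError(
            "replanning magnitude undefined without valid responses in both phases")
    return counts.ns_test / counts.n_test - counts.ns_learning / counts.n_learning


def counts_from_block(result: BlockResult, last_n_learning: int = 10) -> ChoiceCounts:
    """Extract choice counts from a block log.

    The reference action is the root action that is optimal at test (i.e.
    under the post-revaluation means). Simulated agents always respond, so
    the denominators are simply the numbers of logged choices; records with
    a missing action (if any) are excluded from both counts. Forced root
    choices are excluded too -- they reflect the sampling schedule, not the
    participant's preference, and would bias the learning-phase proportion.
    """
    optimal = result.config.optimal_stage1_action("test")
    test_choices = [r.a for r in result.test.records if r.a is not None]
    learning_choices = [
        r.a for r in result.learning.records
        if r.s == STAGE1 and r.a is not None and not r.forced
    ][-last_n_learning:]
    return ChoiceCounts(
        ns_test=sum(a == optimal for a in test_choices),
        n_test=len(test_choices),
        ns_learning=sum(a == optimal for a in learning_choices),
        n_learning=len(learning_choices),
    )


def score_block(result: BlockResult) -> ReplanningScore:
    cfg = result.config
    return ReplanningScore(
        cfg.block_id, cfg.condition, cfg.noise,
        replanning_magnitude(counts_from_block(result)))


def group_behavior_tests(scores: pd.DataFrame) -> dict:
    """Group-level behavioral comparisons on participant-level means.

    ``scores`` needs columns ``participant``, ``condition``, ``noise``,
    ``score``. Scores are averaged within participant x condition before
    testing. Returns one-sample t tests per condition (vs 0), the paired t
    test revaluation - control, and a 2 x 2 condition x noise ANOVA (type-II
    sums of squares on participant x cell means; the design is balanced so
    the SS type is immaterial). Degenerate (zero-variance) inputs are
    flagged in the result rather than raising.
    """
    required = {"participant", "condition", "noise", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(required)}")
    by_cond = (scores.groupby(["participant", "condition"])["score"]
               .mean().unstack("condition"))
    if by_cond.shape[0] < 2:
        raise ValueError("need at least two participants")

    out: dict = {}
    for cond in by_cond.columns:
        x = by_cond[cond].to_numpy()
        out[f"one_sample_t_{cond}"] = _one_sample_t(x, f"t({len(x) - 1})")
    if {"revaluation", "control"}.issubset(by_cond.columns):
        d = (by_cond["revaluation"] - by_cond["control"]).to_numpy()
        out["paired_t_revaluation_vs_control"] = _one_sample_t(
            d, f"t({len(d) - 1})")

    cell = (scores.groupby(["participant", "condition", "noise"])["score"]
            .mean().reset_index())
    if cell["score"].var() == 0:
        out["anova_condition"] = StatResult("F", float("nan"), None, float("nan"),
                                            note="degenerate: zero variance")
        out["anova_noise"] = StatResult("F", float("nan"), None, float("nan"),
                                        note="degenerate: zero variance")
        out["anova_interaction"] = StatResult("F", float("nan"), None, float("nan"),
                                              note="degenerate: zero variance")
    else:
        model = smf.ols("score ~ C(condition) * C(noise)", data=cell).fit()
        table = sm.stats.anova_lm(model, typ=2)
        for key, row in (("anova_condition", "C(condition)"),
                         ("anova_noise", "C(noise)"),
                         ("anova_interaction", "C(condition):C(noise)")):
            out[key] = StatResult(
                "F", float(table.loc[row, "F"]),
                (float(table.loc[row, "df"]), float(table.loc["Residual", "df"])),
                float(table.loc[row, "PR(>F)"]))
    return out


def _one_sample_t(x: np.ndarray, name: str) -> StatResult:
    if np.var(x, ddof=1) == 0:
        # all differences equal: t undefined unless the mean is 0 too
        if np.allclose(x, 0):
            return StatResult(name, 0.0, len(x) - 1, 1.0,
                              note="degenerate: all values zero")
        return StatResult(name, float("nan"), len(x) - 1, float("nan"),
                          note="degenerate: zero variance")
    t, p = scipy.stats.ttest_1samp(x, 0.0)
    return StatResult(name, float(t), len(x) - 1, float(p))
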