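"""End-to-end pipeline: cohort simulation -> MVPA -> brain-behavior statistics.

``run_pipeline`` chains every stage, writes delimited-text tables, a plain
text report, and a manifest with content hashes, and returns the analysis
results as objects. Every stochastic stage derives its seed
deterministically from the master seed and a stage tag, so re-running with
the same configuration reproduces byte-identical outputs and individual
stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agent import AgentParams, fit_learning_rate
from .behavior import group_behavior_tests
from .mvpa import replay_evidence, select_rois, train_category_classifier
from .neurogen import Cohort, CouplingSpec, NeuroGenParams, generate_cohort
from .stats import (PERegressor, bootstrap_corr_diff, fisher_z_compare,
                    parametric_modulation_glm, rest_dynamics, spearman_corr)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "analyze_cohort",
           "stage_rng", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""


def stage_rng(master_seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-stage generator from the master seed and a stage tag."""
    return np.random.default_rng([master_seed, zlib.crc32(tag.encode()) & 0x7FFFFFFF])


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    n_participants: int = 24
    seed: int = 0
    n_boot: int = 1000
    replay_mode: str = "prioritized"
    fit_alpha: bool = True
    out_dir: str | Path | None = None
    agent: AgentParams = field(default_factory=AgentParams)
    neuro: NeuroGenParams = field(default_factory=NeuroGenParams)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)

    def agent_params(self) -> AgentParams:
        return dataclasses.replace(self.agent, replay_mode=self.replay_mode)


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: Cohort
    scores: pd.DataFrame
    evidence: pd.DataFrame
    participant_summary: pd.DataFrame
    behavior_tests: dict
    brain_behavior: dict
    dynamics: dict
    alpha_fit: object | None
    manifest: dict | None


def _evidence_tables(cohort: Cohort):
    """Run the MVPA stack over every participant and block.

    Returns a long evidence table (one row per block x rest, for both the
    root-state category and the stage-II category) plus cross-correlation
    diagnostics per participant.
    """
    rows = []
    xcorr = []
    for p in cohort.participants:
        face_roi, scene_roi = select_rois(p.localizer)
        classifiers = {
            "face": train_category_classifier(p.localizer, face_roi, "face"),
            "scene": train_category_classifier(p.localizer, scene_roi, "scene"),
        }
        all_rests = [r for b in p.blocks for r in b.rests]
        from .mvpa import evidence_cross_correlation
        xc = evidence_cross_correlation(classifiers["face"], classifiers["scene"],
                                        all_rests)
        xcorr.append({"participant": p.pid, "rest_face_scene_r": xc.value})
        for b in p.blocks:
            s1 = replay_evidence(classifiers[b.config.stage1_category], b.rests,
                                 b.config.block_id)
            s2 = replay_evidence(classifiers[b.config.stage2_category], b.rests,
                                 b.config.block_id)
            for rest_index in range(3):
                rows.append({
                    "participant": p.pid,
                    "block_id": b.config.block_id,
                    "condition": b.config.condition,
                    "noise": b.config.noise,
                    "rest_index": rest_index + 1,
                    "evidence": s1.per_rest[rest_index],
                    "stage2_evidence": s2.per_rest[rest_index],
                    "block_mean": s1.block_mean,
                    "stage2_block_mean": s2.block_mean,
                    "score": b.score,
                })
    return pd.DataFrame(rows), pd.DataFrame(xcorr)


def _participant_summary(evidence: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Participant x condition means of replay evidence and replanning."""
    agg = (evidence.groupby(["participant", "condition"])
           .agg(evidence=("block_mean", "mean"),
                stage2_evidence=("stage2_block_mean", "mean"),
                score=("score", "mean"))
           .reset_index())
    betas = []
    for p in cohort.participants:
        vals = []
        for b in p.blocks:
            if b.config.condition != "revaluation":
                continue
            reg = PERegressor(b.pe_regressor_onsets, b.pe_regressor_modulator)
            vals.append(parametric_modulation_glm(b.pe_signal, reg).value)
        betas.append({"participant": p.pid,
                      "pe_modulation_beta": float(np.mean(vals))})
    return agg.merge(pd.DataFrame(betas), on="participant")


def analyze_cohort(cohort: Cohort, n_boot: int = 1000, seed: int = 0) -> dict:
    """All brain-behavior statistics for a simulated cohort.

    Computes the per-condition Spearman correlations between mean replay
    evidence and replanning magnitude, the participant bootstrap of their
    difference, the Fisher-z comparison, the stage-II-category specificity
    check, rest-period dynamics, and the PE-sensitivity (modulation beta)
    correlations with replay and replanning.
    """
    evidence, xcorr = _evidence_tables(cohort)
    summary = _participant_summary(evidence, cohort)
    wide = summary.pivot(index="participant", columns="condition",
                         values=["evidence", "stage2_evidence", "score"])
    ev_r = wide[("evidence", "revaluation")].to_numpy()
    sc_r = wide[("score", "revaluation")].to_numpy()
    ev_c = wide[("evidence", "control")].to_numpy()
    sc_c = wide[("score", "control")].to_numpy()
    n = len(ev_r)

    corr_reval = spearman_corr(ev_r, sc_r)
    corr_control = spearman_corr(ev_c, sc_c)
    boot = bootstrap_corr_diff(ev_r, sc_r, ev_c, sc_c, n_boot=n_boot,
                               seed=stage_rng(seed, "bootstrap"))
    corr_stage2_reval = spearman_corr(
        wide[("stage2_evidence", "revaluation")].to_numpy(), sc_r)
    corr_stage2_control = spearman_corr(
        wide[("stage2_evidence", "control")].to_numpy(), sc_c)
    betas = summary.drop_duplicates("participant").set_index("participant")
    corr_pe_replay = spearman_corr(
        betas["pe_modulation_beta"].to_numpy(),
        wide[("evidence", "revaluation")].reindex(betas.index).to_numpy())
    corr_pe_replan = spearman_corr(
        betas["pe_modulation_beta"].reindex(wide.index).to_numpy(), sc_r)
    fz = None
    if abs(corr_reval.rho) < 1 and abs(corr_control.rho) < 1:
        fz = fisher_z_compare(corr_reval.rho, n, corr_control.rho, n)
    dynamics = rest_dynamics(evidence)
    fz_rests = None
    r1 = dynamics.get("replay_behavior_rest1")
    r3 = dynamics.get("replay_behavior_rest3")
    if (r1 is not None and r3 is not None
            and abs(r1.rho) < 1 and abs(r3.rho) < 1):
        fz_rests = fisher_z_compare(r1.rho, r1.n, r3.rho, r3.n)

    return {
        "evidence": evidence,
        "cross_correlation": xcorr,
        "participant_summary": summary,
        "corr_reval": corr_reval,
        "corr_control": corr_control,
        "bootstrap": boot,
        "fisher_z_conditions": fz,
        "fisher_z_rest1_vs_rest3": fz_rests,
        "corr_stage2_reval": corr_stage2_reval,
        "corr_stage2_control": corr_stage2_control,
        "corr_pe_replay": corr_pe_replay,
        "corr_pe_replanning": corr_pe_replan,
        "dynamics": dynamics,
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and (optionally) write the report bundle."""
    try:
        cohort = generate_cohort(
            n_participants=config.n_participants,
            seed=config.seed,
            coupling=config.coupling,
            neuro=config.neuro,
            agent_params=config.agent_params(),
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"simulate: {exc}") from exc

    scores = cohort.scores_frame()
    try:
        behavior_tests = group_behavior_tests(scores)
        analysis = analyze_cohort(cohort, n_boot=config.n_boot, seed=config.seed)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"analyze: {exc}") from exc

    alpha_fit = None
    if config.fit_alpha:
        logs = [b.result for p in cohort.participants for b in p.blocks]
        alpha_fit = fit_learning_rate(logs, beta=config.agent.beta,
                                      lapse=config.agent.lapse)

    manifest = None
    if config.out_dir is not None:
        manifest = _write_outputs(config, cohort, scores, behavior_tests,
                                  analysis, alpha_fit)
    return PipelineResult(
        config=config,
        cohort=cohort,
        scores=scores,
        evidence=analysis["evidence"],
        participant_summary=analysis["participant_summary"],
        behavior_tests=behavior_tests,
        brain_behavior=analysis,
        dynamics=analysis["dynamics"],
        alpha_fit=alpha_fit,
        manifest=manifest,
    )


def _stat_rows(named: dict) -> list:
    rows = []
    for key, res in named.items():
        if res is None or isinstance(res, (pd.DataFrame, list)):
            continue
        if hasattr(res, "rho"):
            rows.append({"name": key, "statistic": "spearman_rho",
                         "value": res.rho, "p": res.p, "n": res.n})
        elif hasattr(res, "observed_diff"):
            rows.append({"name": key, "statistic": "bootstrap_diff",
                         "value": res.observed_diff, "p": res.p, "n": res.n_boot})
        elif hasattr(res, "value"):
            rows.append({"name": key, "statistic": res.name,
                         "value": res.value, "p": res.p, "n": ""})
    return rows


def _write_outputs(config, cohort, scores, behavior_tests, analysis, alpha_fit):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    def write_csv(name, df):
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        files[name] = path

    write_csv("behavior_scores.csv", scores)
    write_csv("evidence.csv", analysis["evidence"])
    write_csv("participant_summary.csv", analysis["participant_summary"])
    write_csv("cross_correlation.csv", analysis["cross_correlation"])

    trial_frames = [b.result.to_frame().assign(participant=p.pid)
                    for p in cohort.participants for b in p.blocks]
    write_csv("trials.csv", pd.concat(trial_frames, ignore_index=True))

    replay_rows = [
        {"participant": p.pid, "block_id": b.config.block_id,
         "rest_index": ri + 1, "step": ev.step, "replayed_state": ev.s,
         "action": ev.a or "", "priority": ev.priority}
        for p in cohort.participants for b in p.blocks
        for ri, log in enumerate(b.result.replay_logs) for ev in log
    ]
    write_csv("replay_log.csv", pd.DataFrame(
        replay_rows, columns=["participant", "block_id", "rest_index",
                              "step", "replayed_state", "action", "priority"]))

    events_rows = [
        {"participant": p.pid, "block_id": b.config.block_id,
         "rest_index": ri + 1, "tr": tr, "category": cat, "amplitude": amp}
        for p in cohort.participants for b in p.blocks
        for ri, rest in enumerate(b.rests) for (tr, cat, amp) in rest.events
    ]
    write_csv("ground_truth_events.csv", pd.DataFrame(
        events_rows, columns=["participant", "block_id", "rest_index",
                              "tr", "category", "amplitude"]))

    stat_rows = _stat_rows(behavior_tests)
    stat_rows += _stat_rows({k: v for k, v in analysis.items()
                             if k not in ("evidence", "participant_summary",
                                          "cross_correlation", "dynamics")})
    stat_rows += _stat_rows({k: v for k, v in analysis["dynamics"].items()
                             if k not in ("centered", "excluded_blocks")})
    if alpha_fit is not None:
        stat_rows.append({"name": "alpha_hat", "statistic": "mle",
                          "value": alpha_fit.alpha, "p": "", "n": alpha_fit.n_choices})
    write_csv("statistics.csv", pd.DataFrame(stat_rows))

    report = _format_report(config, scores, behavior_tests, analysis, alpha_fit)
    report_path = out / "report.txt"
    report_path.write_text(report)
    files["report.txt"] = report_path

    manifest = {
        "package_version": __version__,
        "config": {
            "n_participants": config.n_participants,
            "seed": config.seed,
            "n_boot": config.n_boot,
            "replay_mode": config.replay_mode,
            "agent": dataclasses.asdict(config.agent),
            "neuro": dataclasses.asdict(config.neuro),
            "coupling": dataclasses.asdict(config.coupling),
        },
        "files": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _format_report(config, scores, behavior_tests, analysis, alpha_fit) -> str:
    by_cond = scores.groupby("condition")["score"].mean()
    lines = [
        "replayplan pipeline report",
        "==========================",
        f"participants: {config.n_participants}  seed: {config.seed}  "
        f"replay mode: {config.replay_mode}",
        "",
        "Replanning behavior (mean replanning magnitude per condition):",
    ]
    for cond in ("revaluation", "control"):
        if cond in by_cond.index:
            res = behavior_tests.get(f"one_sample_t_{cond}")
            lines.append(f"  {cond:12s} mean = {by_cond[cond]:+.3f}   "
                         f"{res.name} = {res.value:.2f}, p = {res.p:.3g}")
    paired = behavior_tests.get("paired_t_revaluation_vs_control")
    if paired is not None:
        lines.append(f"  revaluation - control: {paired.name} = "
                     f"{paired.value:.2f}, p = {paired.p:.3g}")
    for key in ("anova_condition", "anova_noise", "anova_interaction"):
        res = behavior_tests.get(key)
        if res is not None and res.dof is not None:
            lines.append(f"  {key}: F = {res.value:.2f}, p = {res.p:.3g}")

    cr, cc = analysis["corr_reval"], analysis["corr_control"]
    boot = analysis["bootstrap"]
    lines += [
        "",
        "Replay evidence vs replanning (Spearman, participant means):",
        f"  revaluation: rho = {cr.rho:.3f}, p = {cr.p:.4g} (n = {cr.n})",
        f"  control:     rho = {cc.rho:.3f}, p = {cc.p:.4g} (n = {cc.n})",
        f"  bootstrap difference (reval - control): diff = "
        f"{boot.observed_diff:.3f}, one-sided p = {boot.p:.4g} "
        f"({boot.n_boot} resamples)",
    ]
    s2r = analysis["corr_stage2_reval"]
    lines.append(f"  stage-II-category control: rho = {s2r.rho:.3f}, "
                 f"p = {s2r.p:.3g} (revaluation)")
    if analysis["fisher_z_conditions"] is not None:
        fz = analysis["fisher_z_conditions"]
        lines.append(f"  condition comparison: Fisher z = "
                     f"{fz.value:.2f}, p = {fz.p:.3g}")
    if analysis["fisher_z_rest1_vs_rest3"] is not None:
        fzr = analysis["fisher_z_rest1_vs_rest3"]
        lines.append(f"  rest 1 vs rest 3 correlation comparison: Fisher z = "
                     f"{fzr.value:.2f}, p = {fzr.p:.3g}")
    pe_replay = analysis["corr_pe_replay"]
    pe_replan = analysis["corr_pe_replanning"]
    lines += [
        "",
        "PE sensitivity (modulation beta) couplings:",
        f"  with replay evidence: rho = {pe_replay.rho:.3f}, p = {pe_replay.p:.3g}",
        f"  with replanning:      rho = {pe_replan.rho:.3f}, p = {pe_replan.p:.3g}",
    ]
    dyn = analysis["dynamics"]
    lines.append("")
    lines.append("Rest-period dynamics (centered evidence):")
    for cond in ("revaluation", "control"):
        res = dyn.get(f"rest1_vs_rest3_{cond}")
        if res is not None:
            lines.append(f"  rest 1 vs rest 3, {cond}: {res.name} = "
                         f"{res.value:.2f}, p = {res.p:.3g}")
    r1 = dyn.get("rest1_revaluation_vs_control")
    if r1 is not None:
        lines.append(f"  rest 1, revaluation vs control: {r1.name} = "
                     f"{r1.value:.2f}, p = {r1.p:.3g}")
    if alpha_fit is not None:
        lines += ["", f"Pooled MLE learning rate: alpha_hat = "
                      f"{alpha_fit.alpha:.2f} ({alpha_fit.n_choices} free choices)"]
    lines.append("")
    return "\n".join(lines)
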