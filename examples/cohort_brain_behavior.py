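"""Run a full simulated cohort and the brain-behavior statistics.

Generates a cohort whose latent replay propensity couples the replay
budget, the PE-sensitivity of memory tagging, and the neural PE response;
then runs the complete MVPA + inference chain: per-condition Spearman
correlations between rest-period replay evidence and replanning, the
participant bootstrap of their difference, and the rest-period dynamics.

A smaller cohort than the default (12 participants, 300 bootstrap
resamples) keeps this example fast; `replayplan run --seed 0 --out ...`
runs the full default and writes the complete report bundle.
"""

from replayplan import RunConfig, run_pipeline

result = run_pipeline(RunConfig(n_participants=12, seed=0, n_boot=300))

scores = result.scores.groupby("condition")["score"].mean()
bb = result.brain_behavior
print(f"mean replanning: revaluation {scores['revaluation']:+.2f}, "
      f"control {scores['control']:+.2f}")
print(f"replay evidence vs replanning (Spearman):")
print(f"  revaluation rho = {bb['corr_reval'].rho:.2f} (p = {bb['corr_reval'].p:.4f})")
print(f"  control     rho = {bb['corr_control'].rho:.2f} (p = {bb['corr_control'].p:.2f})")
print(f"  bootstrap difference: one-sided p = {bb['bootstrap'].p:.3f}")
print(f"  stage-II-category check: rho = {bb['corr_stage2_reval'].rho:.2f} "
      f"(p = {bb['corr_stage2_reval'].p:.2f})")
d = result.dynamics
print(f"rest dynamics (revaluation): rest1 vs rest3 t = "
      f"{d['rest1_vs_rest3_revaluation'].value:.2f} "
      f"(p = {d['rest1_vs_rest3_revaluation'].p:.3f})")
print("\nReplay evidence predicts replanning in revaluation blocks only, the")
print("stage-II category shows no coupling, and evidence declines from rest 1")
print("to rest 3 as PEs shrink. The bootstrap difference is borderline at this")
print("reduced cohort size; the default 24-participant run rejects it cleanly.")
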