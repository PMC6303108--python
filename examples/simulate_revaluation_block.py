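"""Simulate one revaluation block and watch replay flip the root policy.

A TD agent learns the two-stage task, experiences the second-stage reward
swap during relearning, and replays prioritized (high-|PE|) transitions at
each rest period. The replanning magnitude compares its test-phase root
choices with its late-learning preference: ~1 means it integrated the swap
offline, ~0 means it kept its old policy.
"""

import numpy as np

from replayplan import AgentParams, TDAgent, make_block_config, run_block, score_block

config = make_block_config("revaluation", "noiseless", "face", seed=7)
print(f"pre-change means:  {config.reward_mean}")
print(f"post-change means: {config.reval_reward_mean}")
print(f"optimal root action during learning: {config.optimal_stage1_action('learning')}"
      f" -> at test: {config.optimal_stage1_action('test')}\n")

for mode, k in (("prioritized", 20), ("none", 0)):
    agent = TDAgent(AgentParams(replay_mode=mode, replay_budget_k=k))
    result = run_block(config, agent, np.random.default_rng(7))
    counts = result.stage1_replay_counts()
    score = score_block(result).value
    q = agent.q
    print(f"replay={mode:11s} k={k:2d}: root replays per rest {counts}, "
          f"Q(S1,left)={q[('S1', 'left')]:5.1f} Q(S1,right)={q[('S1', 'right')]:5.1f}, "
          f"replanning magnitude {score:+.2f}")

print("\nWith prioritized replay the root values integrate the new second-stage")
print("rewards and the test choices reverse; without replay the root state was")
print("never revisited, so the old policy survives (any small positive score is")
print("a stray lapse choice among the four test trials).")
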