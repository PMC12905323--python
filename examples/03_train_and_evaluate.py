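"""Train a small dueling double DQN on the benchmark scene and evaluate it.

A short CPU run (3000 steps here; use scaled_train_config's 20000 for the full
desk-scale study) followed by a greedy evaluation against a random baseline.
Success means covering 95% of the target within 80 steps.
"""

import numpy as np

import ribscan as rs
from ribscan.agent import scaled_net_config, scaled_train_config
from ribscan.phantom import benchmark_scene

scene = benchmark_scene()
env = rs.IntercostalScanEnv(scene, seed=0)
cfg = scaled_train_config(seed=1, total_steps=3000)
trainer = rs.DQNTrainer(env, cfg, scaled_net_config())
trainer.train()
print(f"trained {trainer.step_i} steps over {len(trainer.episode_returns)} episodes")
print(f"mean episode return, first third: {np.mean(trainer.episode_returns[:12]):.1f}")
print(f"mean episode return, last third:  {np.mean(trainer.episode_returns[-12:]):.1f}")

for name, policy in [
    ("random", rs.random_policy(np.random.default_rng(7))),
    ("greedy", rs.greedy_policy(trainer.net)),
]:
    ev = rs.IntercostalScanEnv(scene, seed=0)
    table, _ = rs.evaluate_policy(policy, ev, n_episodes=20, seed=123)
    row = table[(table.size_class == "all") & (table.episodes == "all")].iloc[0]
    print(f"{name:6s}: success rate {row.success_rate:.0%} over {row.n} episodes")
print("a longer run (20000 steps) separates the policies further; see the docs")
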