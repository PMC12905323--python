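"""Step the scanning environment by hand and read the per-step quantities.

Runs the deterministic sweep baseline on the single-gap benchmark scene and
prints, per step, the shadow fraction p_t, the newly covered target voxels
n_t, the reward, and the cumulative coverage — ending with the terminal
success bonus once 95% of the target volume has been insonified.
"""

from ribscan import IntercostalScanEnv, scripted_sweep_policy
from ribscan.phantom import benchmark_scene

env = IntercostalScanEnv(benchmark_scene(), seed=0)
env.reset(seed=11)
policy = scripted_sweep_policy(env)

print(f"target voxels N = {env.grid.N}")
done = False
while not done:
    _, reward, done, out = env.step(policy())
    print(
        f"step {env.step_count:2d} action={out.action}  p_t={out.p_t:.2f}"
        f"  n_t={out.n_t:3d}  reward={reward:7.3f}"
        f"  coverage={out.coverage_fraction:5.1%}  {out.terminal.value}"
    )
print(
    "\nthe final reward is the terminal bonus k_end (1 + a1/D + a2 P), paid when"
    "\ncumulative coverage reaches 95% of the target volume"
)
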