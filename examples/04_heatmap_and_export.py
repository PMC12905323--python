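"""Map success rates over target positions and export a planned trajectory.

Sweeps a small spherical target over a coarse (x, y) lattice beneath the ribs
(success averaged over z, as in the position-impact analysis), then exports
one planned episode as CSV/JSON with contact points in both generic and
patient scale.
"""

from pathlib import Path

import numpy as np

import ribscan as rs
from ribscan.phantom import benchmark_scene

scene = benchmark_scene()
env = rs.IntercostalScanEnv(scene, seed=0)
policy = rs.scripted_sweep_policy(env)

rates, xs, ys = rs.position_heatmap(
    policy, env, stride_mm=30.0, target_volume_cm3=3.0, seed=1
)
valid = np.isfinite(rates)
print(f"heatmap: {valid.sum()} valid (x, y) positions, stride 30 mm")
print(f"mean success over valid positions: {np.nanmean(rates):.0%}")
print("(positions under a rib or outside the torso are marked missing)")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
result = rs.run_episode(env, policy, seed=11)
csv_path = rs.export_trajectory(result, env.frame, env, out / "trajectory")
print(f"episode success={result.success} in {result.steps} steps")
print(f"trajectory written to {csv_path} (h, theta, phi, psi, adj, contact xyz)")
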