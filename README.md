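# ribscan

Reinforcement-learning planning of **shadow-free intercostal ultrasound
scanning trajectories**.

Imaging organs or tumors that lie beneath the rib cage (most prominently the
liver) is hard because bone blocks ultrasound: the probe must look through
narrow intercostal gaps, and a poorly chosen pose leaves the target in
acoustic shadow. `ribscan` builds a 3D virtual scanning environment from
segmented anatomy (or from procedurally generated rib-cage phantoms), models
the probe as a ray fan blocked by bone, and trains a dueling double deep
Q-network to move the probe over the skin so that the whole target volume is
insonified with little shadow and little attenuation. It is a library first
(see `examples/`), with a thin `ribscan` command-line layer for the standard
workflows.

## The model in brief

* **State** — a 120 mm cube around the target, voxelized at 4 mm into a 30³
  lattice with three binary channels per voxel (target, bone, insonified);
  the three most recent grids form the 9-channel observation.
* **Actions** — discrete moves on a cylinder fitted to the rib cage:
  h ± 4 mm, θ ± 3°, plus probe rotations φ ± 2°, ψ ± 2°, and a `switch`
  action toggling a readjusting mode used to relocate between gaps.
* **Rewards** — per step `r = r_c + α₁ r_a + α₂ r_s` with coverage
  `r_c = n_t/N`, attenuation `r_a = e^{−d_t/R_c}`, and shadow
  `r_s = 1 − p_t`; `switch` costs −1, readjusting steps score 0, a step whose
  shadow fraction exceeds `T_th` scores −0.1 and its coverage is discarded.
  Covering 95% of the target ends the episode with the bonus
  `r_end = k_end (1 + α₁/D + α₂ P)`.
* **Learner** — dueling decomposition `Q = V + (A − mean A)`, double-Q
  targets, prioritized replay with importance weights, ε-greedy exploration;
  implemented as a compact numpy network (explicit forward/backward, Adam,
  Huber, gradient clipping) that is bit-reproducible from one master seed.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

```python
from ribscan import IntercostalScanEnv, scripted_sweep_policy
from ribscan.phantom import benchmark_scene

env = IntercostalScanEnv(benchmark_scene(), seed=0)
env.reset(seed=11)
policy = scripted_sweep_policy(env)
done = False
while not done:
    _, reward, done, out = env.step(policy())
    print(env.step_count, out.action, round(out.p_t, 2), out.n_t,
          round(reward, 3), round(out.coverage_fraction, 3), out.terminal.value)
```

prints (abridged — the deterministic sweep baseline on the single-gap
benchmark scene):

```
3 0 0.0 12 1.235 0.214 none
4 0 0.0 16 1.334 0.5   none
5 0 0.0 16 1.341 0.786 none
6 0 0.0 12 29.924 1.0  success
```

Each row is one examining step: shadow fraction `p_t = 0` (the probe looks
through the open gap), `n_t` newly covered target voxels, the per-step reward
`r_c + r_a + 0.5 r_s`, and cumulative coverage. On the step where coverage
reaches 95% the environment pays the terminal bonus (here 29.92) and the
episode ends in success.

Training and evaluation:

```bash
ribscan train --config my.yaml --seed 1 --out runs/t1   # checkpoints + curve
ribscan eval  --checkpoint runs/t1/checkpoint.npz --episodes 100
ribscan eval  --episodes 100                            # random baseline
ribscan heatmap --stride 8 --out runs/hm                # success vs position
```

Every command writes a manifest (resolved config, master seed, input hashes)
sufficient to re-execute the run.

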