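# Methods

`ribscan` simulates ultrasound (US) scanning of target volumes that lie
beneath the rib cage, and trains a reinforcement-learning agent to plan probe
trajectories that cover those targets while avoiding bone-induced acoustic
shadows and minimizing attenuation. This note records the model, its
assumptions, the tunable parameters, and the design choices made where the
design was genuinely open.

## The scanning model

**Anatomy.** A scene consists of a closed skin surface, a bone occupancy
(rib cage), and 1–3 closed target volumes, all in millimetres. Real scenes
come from segmented CT (watertight STL/PLY meshes, or NIfTI label maps wrapped
as occupancy predicates); synthetic phantoms model the ribs as partial
circular arcs of capsules around a cylindrical torso, which makes the
intercostal gap width an exact, configurable parameter (down to 10 mm) rather
than an emergent property. Synthetic targets are randomly rotated ellipsoids,
rejection-sampled (budget 1000 attempts, then an error) to sit beneath the
ribs with at least 1 mm clearance from bone; their volumes are drawn from the
clinical size classes (small < 4 cm³, medium 4–13.5 cm³, large > 13.5 cm³),
sampled strictly inside the class boundaries so rounding cannot cross them.

**Probe kinematics.** A minimum bounding cylinder (axis pinned to the
longitudinal body axis; radius = minimum enclosing circle of the transverse
projection of the bone points) defines surface coordinates *(h, θ)*. The probe
is mapped to the skin by casting an inward radial ray from outside the body;
the contact frame starts with the centerline along the inward skin normal and
the footprint (long axis) tangent to the cylinder's circumferential direction.
Two rotations complete the pose: *φ* about the outward skin normal, then *ψ*
(tilt) about the rotated long axis. Conventions fixed here (the composition
order is not dictated by the physics and had to be chosen): θ = 0 anterior,
increasing to the patient's left; h from the caudal end of the fitted extent;
φ = +90° turns the footprint cranial. Per-patient frames are affinely resized
to a generic cylinder (radius 150 mm, height 300 mm, an average adult thorax)
for planning; trajectories are mapped back through the inverse affine. The
tilt constraint (≤ 20°) is evaluated in patient space, because angles are not
invariant under the anisotropic resizing; a pose exactly at the limit counts
as valid, with a 1e-9-degree guard against arccos rounding.

**State.** A 120 mm cube centred on the target-union centroid is voxelized at
4 mm (30³ lattice, half-open cells, inclusion by voxel-centre test) with three
binary channels: target, bone, and insonified-by-the-current-plane. The
observation stacks the three most recent grids (oldest first) into a
9×30×30×30 binary array; at reset all three slots hold the initial grid.

**Acoustics.** The transducer is a ray fan: rays parallel to the centerline
from points spaced along the footprint (defaults: footprint 40 mm, spacing
2 mm, imaging depth 120 mm). These three numbers describe the virtual probe,
not a specific commercial transducer; the defaults make the in-plane slab
about ten voxel columns wide and give every column at least two rays
(spacing ≤ half the voxel size is enforced). Rays traverse the lattice by
exact voxel stepping (Amanatides–Woo, vectorized across the fan). Cells before
the first bone cell on a ray are insonified; the bone cell and everything
behind it are shadowed. A cell insonified by any ray is never also counted as
shadowed, and shadowed cells count once per step.

## Rewards

Per examining step: r = r_c + α₁·r_a + α₂·r_s with

* coverage r_c = n_t / N — n_t counts only first-time-covered target voxels;
* attenuation r_a = exp(−d_t / R_c) — d_t is the probe-face-to-target-centroid
  distance, computed in generic scale with R_c the generic radius (the
  underlying notion, "distance between probe and target", admits several
  concrete definitions; this one is smooth and scale-normalized);
* shadow r_s = 1 − p_t, where p_t = n_shadow / N_t and N_t is the total
  scanned slab (insonified + shadowed cells), so p_t ∈ [0, 1] is the shadowed
  fraction of the probe's coverage. When the fan misses the grid entirely,
  p_t = 1 by convention, so uninformative poses fall into the penalty branch.

Dispatch per step: the switch action costs −1 and toggles readjusting mode;
readjusting-mode steps score 0 with no coverage or shadow accounting; an
examining step with p_t ≥ T_th scores −0.1 and its coverage is discarded; an
examining step with p_t < T_th scores r and accrues coverage. When cumulative
coverage reaches 95% of N the episode succeeds and pays
r_end = k_end·(1 + α₁/D + α₂·P), with D and P the means of d_t/R_c and
1 − p_t over the episode's examining steps (readjusting acquisitions are
excluded from the averages; shadowed examining steps are included). Episodes
truncate at 80 steps; tilt beyond 20° terminates with no extra reward and is
logged as a failure. Success does not additionally require p_t < T_th on the
final step. Defaults: α₁ = 1, α₂ = 0.5, T_th = 0.20, k_end = 10 (k_end has no
established value; 10 makes the terminal bonus dominate a typical episode's
step rewards), success fraction 0.95, step sizes 4 mm / 3° / 2° / 2°.

Degenerate inputs: a scene whose targets voxelize to zero cells is a
configuration error at reset; an all-zero distance trace makes D undefined and
raises. Off-surface moves (the projection ray misses the cropped skin) leave
the pose unchanged and score the unchanged state — the probe neither
teleports nor crashes.

## Learning

The action-value network is a dueling architecture,
Q(s,a) = V(s) + (A(s,a) − mean_a′ A(s,a′)), trained with double-Q targets
(online argmax, target-network evaluation), proportional prioritized replay
(exponent 0.6, importance weights annealed 0.4 → 1 and max-normalized,
priorities |TD| + 1e-6), Huber loss, Adam, and global-norm gradient clipping
at 10. The network is written directly in numpy: the 9-channel observation is
average-pooled (factor 3 by default) and flattened into fully-connected ReLU
trunk and head layers. A convolutional trunk would be the natural choice at
full scale; the pooled dense trunk was chosen because it trains orders of
magnitude faster on one CPU while preserving the dueling decomposition
exactly, and every width is a config key. Gradients were verified against
central finite differences in the test suite.

Full-scale defaults follow the study configuration: learning rate 7e-5,
5×10⁶ steps, target copy every 5×10³ steps, ε from 1.0 to 0.05 linearly over
3×10⁶ steps. Values with no established setting are declared package
defaults: γ = 0.99, batch 32, warm-up 1000 transitions, one gradient step per
environment step. Training is single-process; the original distributed
16-node layout (16 × 5×10³ replay buffers) becomes one 5×10⁴ buffer. All
randomness flows from one master seed through named substreams (net-init,
exploration, replay, episodes), making action traces and losses
bit-reproducible; checkpoints store weights, optimizer moments, RNG states,
the replay buffer, and the environment, so a resumed run reproduces an
uninterrupted one exactly.

## Scaled-down study conditions

CPU-sized experiments run on the **benchmark scene**: two ribs with one wide
(28 mm) gap and a 3 cm³ spherical target centred beneath it — the easiest
member of the phantom family, fully deterministic. The scaled training
profile is 2×10⁴ steps, ε decayed over the first 60% of them, buffer equal to
the step budget, target copy every 10³ steps, learning rate 3e-4 (standard
for a network this small), and a reduced network (pool 6, 64-unit trunk,
32-unit heads). Under these conditions a greedy policy reliably beats the
random baseline (which scores 0% success on this scene) but stays far from
ceiling; the deterministic sweep baseline (`scripted_sweep_policy`) bounds
the task from above at 100% on this scene.

## What the synthetic phantoms do and do not show

The capsule-arc ribs control gap width exactly but are not anatomically
curved; the skin is a cylinder, not a body surface; targets are ellipsoids,
not segmented tumors; there is no breathing, deformation, or registration
error. Passing tests therefore demonstrate the correctness of the state,
acoustics, reward, and learning machinery, and qualitative properties (narrow
gaps are harder; shadowed steps are penalized) — not clinical performance on
patient CT. Headline success rates on real anatomy require the external CT
data and full-scale training, both out of scope here.

## Known limitations

* No B-mode image formation, speckle, refraction, or frequency-dependent
  attenuation; attenuation enters only through the distance proxy r_a.
* The mesh reader's point-in-solid test (even–odd ray crossings over all
  faces) is quadratic in mesh size and intended for small segmentation
  meshes.
* `place_targets` and the position heatmap require the capsule rib-cage
  phantom; mesh scenes support fixed targets only.
* Multi-target episodes treat the target union as one coverage ledger
  (one N, one 95% test), matching the single-ledger reward definition.
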