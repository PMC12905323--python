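"""Generate a synthetic rib-cage phantom and inspect its anatomy.

Builds a partial rib cage with a configurable intercostal gap, an enclosing
cylindrical skin, and two medium ellipsoidal targets placed beneath the ribs,
then prints the target volumes and the fitted probe coordinate system.
"""

import numpy as np

import ribscan as rs

scene = rs.generate_phantom(
    rs.PhantomConfig(seed=3, n_targets=2, size_class="medium", intercostal_gap=15.0)
)
print("scene:", scene.frame_id)
for i, t in enumerate(scene.targets):
    print(
        f"  target {i}: volume {t.volume_cm3:.2f} cm^3"
        f" ({rs.classify_size(t.volume_cm3)}), centre {np.round(t.center, 1)} mm"
    )

frame = rs.fit_cylinder(scene.bones.sample_points(400, np.random.default_rng(0)))
print(f"fitted cylinder: R_c = {frame.radius:.1f} mm, height = {frame.height:.1f} mm")
print("the probe moves on this cylinder's surface and is projected onto the skin")
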