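import numpy as np
import pytest

import ribscan as rs
from ribscan.phantom import AnatomyScene, Ellipsoid
from ribscan.simulator import RayCastResult, Terminal

from conftest import scripted_sweep_policy
from oracles import oracle_cast


def _face_pose(contact, centerline, long_axis, adj=False):
    """Hand-built pose for grid-aligned ray-cast tests."""
    return rs.ProbePose(
        h=0.0,
        theta=0.0,
        phi=0.0,
        psi=0.0,
        adj=adj,
        contact_point=np.asarray(contact, float),
        centerline=np.asarray(centerline, float),
        long_axis=np.asarray(long_axis, float),
        skin_normal=-np.asarray(centerline, float),
        tilt_deg=0.0,
    )


def _empty_grid():
    return rs.VoxelGrid(origin=np.zeros(3))


# --- voxelization ------------------------------------------------------------


def test_voxelize_dimensions_and_extent(small_scene):
    grid = rs.voxelize(small_scene)
    assert grid.dims == (30, 30, 30)
    assert grid.edge_mm == pytest.approx(120.0)
    assert grid.resolution == pytest.approx(4.0)
    assert grid.N == grid.target.sum() > 0


def test_voxelize_empty_scene_is_all_zero():
    scene = AnatomyScene(
        skin=rs.CylinderSurface(np.zeros(3), np.array([0, 0, 1.0]), 100.0),
        bones=_NoBones(),
        targets=[],
    )
    grid = rs.voxelize(scene, center=np.zeros(3))
    assert not grid.target.any() and not grid.bone.any() and not grid.insonified.any()


class _NoBones:
    def contains(self, points):
        p = np.atleast_2d(points)
        return np.zeros(len(p), dtype=bool)

    def sample_points(self, n, rng):
        return rng.normal(size=(n, 3))


def test_voxelize_single_aligned_cube_marks_one_voxel():
    """A 4 mm cube exactly on a lattice cell sets exactly one target voxel."""
    cube = Ellipsoid(  # a sphere inscribed would miss corners; use a box stand-in
        center=np.array([2.0, 2.0, 2.0]),
        semi_axes=np.array([2.0, 2.0, 2.0]),
        rotation=np.eye(3),
    )

    class _Box:
        center = np.array([2.0, 2.0, 2.0])
        volume_cm3 = 0.064
        bounds = np.array([[0.0, 0.0, 0.0], [4.0, 4.0, 4.0]])

        def contains(self, points):
            p = np.atleast_2d(points)
            return np.all((p >= 0.0) & (p < 4.0), axis=1)

    scene = AnatomyScene(
        skin=rs.CylinderSurface(np.zeros(3), np.array([0, 0, 1.0]), 100.0),
        bones=_NoBones(),
        targets=[_Box()],
    )
    grid = rs.voxelize(scene, center=np.array([2.0, 2.0, 2.0]))
    assert grid.N == 1
    i = np.argwhere(grid.target)
    assert (i[0] == [14, 14, 14]).all()  # cube centred in the lattice


def test_voxelize_sphere_count_matches_inclusion_oracle(small_scene):
    grid = rs.voxelize(small_scene)
    centers = grid.voxel_centers()
    expect = np.zeros(len(centers), dtype=bool)
    for t in small_scene.targets:
        expect |= t.contains(centers)  # per-voxel-center inclusion, same rule
    assert (expect.reshape(grid.dims) == grid.target).all()
    # sanity: count within 15% of the continuum volume / voxel volume
    vol_voxels = small_scene.total_target_volume_cm3 * 1000.0 / 64.0
    assert abs(grid.N - vol_voxels) / vol_voxels < 0.15


def test_voxelize_warns_when_target_leaves_cube(small_scene):
    far = np.asarray(small_scene.targets[0].center) + 100.0
    with pytest.warns(UserWarning, match="cube"):
        rs.voxelize(small_scene, center=far)


# --- ray casting --------------------------------------------------------------


def test_cast_rays_bone_free_slab():
    """Probe normal to a cube face marks the rectangular slab of columns."""
    grid = _empty_grid()
    pose = _face_pose([0.0, 58.0, 58.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0])
    res = rs.cast_rays(pose, grid, rs.ProbeModel())
    assert res.n_shadow == 0
    zs = {int(z // 4) for z in np.arange(38.0, 78.0 + 1e-9, 2.0)}
    expect = np.zeros(grid.dims, dtype=bool)
    for z in zs:
        expect[:, 14, z] = True
    assert (res.insonified == expect).all()
    assert res.N_t == res.n_insonified == 30 * len(zs)


def test_cast_rays_bone_slab_shadows_everything_behind():
    grid = _empty_grid()
    grid.bone[10, :, :] = True  # one-voxel wall at depth 40 mm
    pose = _face_pose([0.0, 58.0, 58.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0])
    res = rs.cast_rays(pose, grid, rs.ProbeModel())
    assert res.insonified[:10, 14].sum() == res.n_insonified
    assert not res.insonified[10:].any()
    n_cols = res.n_insonified // 10
    assert res.n_shadow == 20 * n_cols  # wall voxel + 19 behind, per column
    assert res.p_t == pytest.approx(20 / 30)


def test_cast_rays_miss_grid_gives_empty_and_pt_one():
    grid = _empty_grid()
    pose = _face_pose([500.0, 500.0, 500.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0])
    res = rs.cast_rays(pose, grid, rs.ProbeModel())
    assert res.N_t == 0 and res.n_shadow == 0
    assert res.p_t == 1.0  # convention: nothing scanned counts as fully shadowed


def test_cast_rays_ray_spacing_validated():
    grid = _empty_grid()
    pose = _face_pose([0.0, 58.0, 58.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0])
    with pytest.raises(ValueError, match="spacing"):
        rs.cast_rays(pose, grid, rs.ProbeModel(ray_spacing=3.0))


def test_cast_rays_matches_line_of_sight_oracle_random_poses(small_scene):
    """Lattice traversal equals the per-ray crossing oracle on random poses."""
    env = rs.IntercostalScanEnv(small_scene, seed=1)
    env.reset(seed=2)
    rng = np.random.default_rng(3)
    for _ in range(12):
        h = rng.uniform(*env.frame.h_range)
        theta = rng.uniform(-180, 180)
        phi, psi = rng.uniform(-30, 30), rng.uniform(-18, 18)
        try:
            pose = rs.build_pose(h, theta, phi, psi, env.frame, env.skin)
        except rs.OffSurfaceError:
            continue
        res = rs.cast_rays(pose, env.grid, env.probe)
        ins_o, n_ins_o, n_shadow_o = oracle_cast(pose, env.grid, env.probe)
        assert (res.insonified == ins_o).all()
        assert res.n_insonified == n_ins_o
        assert res.n_shadow == n_shadow_o


# --- reward components --------------------------------------------------------


@pytest.mark.parametrize(
    "n_t,N,expect", [(0, 100, 0.0), (100, 100, 1.0), (7, 50, 0.14)]
)
def test_reward_coverage_fraction(n_t, N, expect):
    assert rs.reward_coverage(n_t, N) == pytest.approx(expect)


def test_reward_coverage_rejects_empty_target():
    with pytest.raises(ValueError):
        rs.reward_coverage(0, 0)


def test_reward_attenuation_closed_forms():
    assert rs.reward_attenuation(0.0, 150.0) == pytest.approx(1.0)
    assert rs.reward_attenuation(150.0, 150.0) == pytest.approx(np.exp(-1.0))
    ladder = [rs.reward_attenuation(d, 100.0) for d in np.linspace(0, 300, 20)]
    assert all(a > b for a, b in zip(ladder, ladder[1:]))  # strictly decreasing


@pytest.mark.parametrize(
    "n_shadow,N_t,r_s,p_t",
    [(0, 50, 1.0, 0.0), (50, 50, 0.0, 1.0), (25, 100, 0.75, 0.25), (0, 0, 0.0, 1.0)],
)
def test_reward_shadow_fraction(n_shadow, N_t, r_s, p_t):
    got_rs, got_pt = rs.reward_shadow(n_shadow, N_t)
    assert got_rs == pytest.approx(r_s)
    assert got_pt == pytest.approx(p_t)


def test_reward_step_weighted_sum():
    cfg = rs.RewardConfig(alpha1=1.0, alpha2=0.5)
    assert rs.reward_step(0.1, 0.5, 1.0, cfg) == pytest.approx(1.1)
    cfg0 = rs.RewardConfig(alpha1=0.0, alpha2=0.0)
    assert rs.reward_step(0.3, 0.9, 0.9, cfg0) == pytest.approx(0.3)


def test_reward_step_bounds_property():
    cfg = rs.RewardConfig()
    rng = np.random.default_rng(0)
    for _ in range(200):
        r = rs.reward_step(rng.uniform(), rng.uniform(), rng.uniform(), cfg)
        assert 0.0 <= r <= 1.0 + cfg.alpha1 + cfg.alpha2


def test_reward_terminal_closed_form():
    cfg = rs.RewardConfig(k_end=10.0, alpha1=1.0, alpha2=0.5)
    r = rs.reward_terminal([150.0] * 5, [0.0] * 5, cfg, R_c=150.0)
    assert r == pytest.approx(25.0)  # 10 * (1 + 1/1 + 0.5 * 1)
    assert rs.reward_terminal([150.0], [0.0], rs.RewardConfig(k_end=0.0), 150.0) == 0.0


def test_reward_terminal_monotone_in_distance():
    cfg = rs.RewardConfig()
    near = rs.reward_terminal([50.0] * 4, [0.1] * 4, cfg, 150.0)
    far = rs.reward_terminal([100.0] * 4, [0.1] * 4, cfg, 150.0)
    assert near > far


def test_reward_terminal_degenerate_zero_distances():
    with pytest.raises(ValueError):
        rs.reward_terminal([0.0, 0.0], [0.0, 0.0], rs.RewardConfig(), 150.0)


# --- environment stepping -----------------------------------------------------


def test_reset_deterministic_and_history_filled(bench_env):
    s1 = bench_env.reset(seed=9)
    s2 = bench_env.reset(seed=9)
    assert (s1 == s2).all()
    assert s1.shape == (9, 30, 30, 30)
    # the three temporal slots are identical at episode start
    assert (s1[0:3] == s1[3:6]).all() and (s1[3:6] == s1[6:9]).all()
    assert bench_env.coverage_fraction == 0.0


def test_switch_action_toggles_mode_with_unit_penalty(bench_env):
    bench_env.reset(seed=9)
    cov = bench_env.coverage_fraction
    _, r, _, o = bench_env.step(8)
    assert r == -1.0 and o.adj is True
    assert bench_env.coverage_fraction == cov
    _, r, _, o = bench_env.step(8)
    assert r == -1.0 and o.adj is False


def test_readjusting_steps_score_zero_and_skip_accounting(bench_env):
    bench_env.reset(seed=9)
    bench_env.step(8)  # enter readjusting mode
    for a in (0, 2, 4, 6):
        _, r, done, o = bench_env.step(a)
        assert r == 0.0 and o.n_t == 0
        assert bench_env.coverage_fraction == 0.0
    assert len(bench_env.d_trace) == 0  # readjusting acquisitions excluded


def test_permanent_readjusting_episode_reward_is_switch_count():
    """An episode spent in readjusting mode accrues only the switch penalty."""
    scene = rs.generate_phantom(rs.PhantomConfig(seed=7, size_class="small"))
    env = rs.IntercostalScanEnv(scene, seed=0)
    env.reset(seed=1)
    total, done = 0.0, False
    rng = np.random.default_rng(0)
    env.step(8)
    total += -1.0
    n_switch = 1
    while not done:
        a = int(rng.choice([0, 1, 2, 3]))
        _, r, done, o = env.step(a)
        total += r
    assert o.terminal is Terminal.TRUNCATED
    assert total == pytest.approx(-1.0 * n_switch)


def test_shadowed_step_penalized_and_coverage_discarded(small_scene):
    env = rs.IntercostalScanEnv(small_scene, seed=1)
    env.reset(seed=2)
    found = False
    for _ in range(300):
        _, r, done, o = env.step(int(np.random.default_rng(len(env.episode_log)).integers(8)))
        if not o.adj and o.p_t >= env.reward_config.t_th and o.terminal is Terminal.NONE:
            assert r == pytest.approx(-0.1)
            assert o.n_t == 0
            found = True
        if done:
            env.reset(seed=len(env.episode_log))
    assert found, "no shadowed examining step encountered"


def test_truncation_at_80_steps(bench_env):
    bench_env.reset(seed=9)
    done = False
    n = 0
    while not done:
        _, _, done, o = bench_env.step(4)  # spin phi in place; never succeeds
        n += 1
    assert n == 80
    assert o.terminal is Terminal.TRUNCATED


def test_tilt_beyond_20_degrees_terminates(bench_env):
    bench_env.reset(seed=9)
    done, n = False, 0
    while not done:
        _, _, done, o = bench_env.step(6)  # psi +2 per step
        n += 1
        assert n <= 12
    assert o.terminal is Terminal.TILT
    assert bench_env.pose.tilt_deg > 20.0
    assert n == 11  # psi reaches 22 degrees on the 11th increment


def test_action_step_sizes_applied(bench_env):
    bench_env.reset(seed=9)
    h0, th0 = bench_env.pose.h, bench_env.pose.theta
    bench_env.step(0)
    assert bench_env.pose.h == pytest.approx(h0 + 4.0)
    bench_env.step(2)
    assert bench_env.pose.theta == pytest.approx(th0 + 3.0)
    bench_env.step(5)
    assert bench_env.pose.phi == pytest.approx(-2.0)
    bench_env.step(7)
    assert bench_env.pose.psi == pytest.approx(-2.0)


def test_invalid_action_index_raises(bench_env):
    bench_env.reset(seed=9)
    with pytest.raises(ValueError, match="range"):
        bench_env.step(9)


def test_off_surface_action_leaves_pose_unchanged(bench_scene):
    env = rs.IntercostalScanEnv(bench_scene, seed=0)
    env.reset(seed=9)
    # march h beyond the cropped skin band; pose must stop at the boundary
    last_h = None
    for _ in range(80):
        _, _, done, _ = env.step(0)
        if done:
            break
        if last_h == env.pose.h:
            break
        last_h = env.pose.h
    assert last_h is not None and env.pose.h == last_h  # clamped, not teleported


def test_coverage_monotone_and_success_reward_matches_trace_recompute(bench_env):
    """A scripted sweep succeeds; the terminal bonus equals its trace formula."""
    env = bench_env
    env.reset(seed=11)
    policy = scripted_sweep_policy(env)
    state = env._observation()
    done = False
    cov_prev = 0.0
    while not done:
        state, r, done, o = env.step(policy(state))
        assert env.coverage_fraction >= cov_prev - 1e-12
        cov_prev = env.coverage_fraction
    assert o.terminal is Terminal.SUCCESS
    assert env.coverage_fraction >= 0.95
    cfg = env.reward_config
    D = np.mean(env.d_trace / env.generic_radius)
    P = np.mean(1.0 - env.p_trace)
    assert o.reward == pytest.approx(cfg.k_end * (1 + cfg.alpha1 / D + cfg.alpha2 * P), abs=1e-9)


def test_reward_dispatch_is_total(bench_env):
    """Every logged step lands in exactly one dispatch branch."""
    env = bench_env
    env.reset(seed=4)
    rng = np.random.default_rng(5)
    done = False
    while not done:
        _, r, done, o = env.step(int(rng.integers(9)))
        cfg = env.reward_config
        branches = 0
        if o.action == 8:
            branches += 1
            assert r == cfg.switch_penalty
        elif o.adj:
            branches += 1
            assert r == 0.0
        elif o.terminal is Terminal.SUCCESS:
            branches += 1
        elif o.p_t >= cfg.t_th:
            branches += 1
            assert r == pytest.approx(cfg.shadow_penalty)
        else:
            branches += 1
            assert r == pytest.approx(o.r_c + cfg.alpha1 * o.r_a + cfg.alpha2 * o.r_s)
        assert branches == 1


def test_multi_target_union_coverage_ledger(small_scene):
    """With 2-3 targets, channel 0 holds the union and N counts union voxels;
    the coverage ledger and 95% test apply to the union."""
    env = rs.IntercostalScanEnv(
        small_scene, seed=3, placement={"n": 2, "size_class": "small"}
    )
    env.reset(seed=5)
    assert len(env.scene.targets) == 2
    centers = env.grid.voxel_centers()
    union = np.zeros(len(centers), dtype=bool)
    for t in env.scene.targets:
        union |= t.contains(centers)
    assert env.grid.N == union.sum()
    # distinct placement per reset (training randomization)
    c1 = env.scene.targets[0].center.copy()
    env.reset(seed=6)
    assert not np.allclose(c1, env.scene.targets[0].center)


def test_episode_log_jsonl_roundtrip(tmp_path, bench_env):
    import json

    bench_env.reset(seed=9)
    for a in (0, 2, 8, 1):
        bench_env.step(a)
    p = bench_env.write_episode_log(tmp_path / "ep.jsonl")
    lines = [json.loads(ln) for ln in p.read_text().splitlines()]
    assert len(lines) == 4
    assert lines[2]["action"] == "switch" and lines[2]["reward"] == -1.0
    assert {"p_t", "d_t", "pose", "coverage_fraction"} <= set(lines[0])
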