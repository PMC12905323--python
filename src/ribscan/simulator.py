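"""The scanning Markov decision process: voxel state, ray-cast shadows, rewards.

State
-----
A 120 mm cube centred on the target-union centroid is voxelized at 4 mm into a
30x30x30 lattice with three binary channels per voxel: target present, bone
present, and insonified by the current imaging plane.  Bone occlusion or being
outside the imaging plane leaves the third channel at zero.  The observation
handed to the agent stacks the three most recent voxel grids (oldest first)
into a 9-channel binary array, giving the policy short-range temporal context.

Acoustics
---------
Each transducer element emits a ray parallel to the probe centerline from a
point on the footprint; rays pass through soft tissue but are blocked by bone.
Voxels traversed before the first bone voxel on a ray are insonified; the bone
voxel and everything behind it (to the imaging depth) are shadowed.  A lattice
cell reached unblocked by any ray counts as insonified; shadowed cells are
counted once per step and never marked in the grid.

Rewards
-------
Per examining step the reward is ``r_t = r_c + a1 * r_a + a2 * r_s`` with
coverage ``r_c = n_t / N`` (first-time-covered target voxels over total),
attenuation ``r_a = exp(-d_t / R_c)`` (probe-target distance normalized by the
cylinder radius), and shadow ``r_s = 1 - p_t`` where ``p_t`` is the shadowed
fraction of the scanned slab.  The dispatch is:

* ``switch`` action: -1 (toggles readjusting mode, no accounting);
* readjusting mode: 0 (acquisitions excluded from coverage);
* examining with ``p_t >= T_th``: -0.1 and the step's coverage is discarded;
* examining with ``p_t < T_th``: ``r_t`` and coverage accrues;
* cumulative coverage >= 95% of N: terminal success with
  ``r_end = k_end * (1 + a1 / D + a2 * P)`` where D and P average ``d_t/R_c``
  and ``1 - p_t`` over the episode's examining steps.

Episodes truncate at 80 steps; tilting the centerline more than 20 degrees
from the skin normal terminates the episode without extra reward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .geometry import (
    CylindricalFrame,
    OffSurfaceError,
    ProbePose,
    Surface,
    build_pose,
    fit_cylinder,
)
from .phantom import AnatomyScene, place_targets

__all__ = [
    "VoxelGrid",
    "ProbeModel",
    "RewardConfig",
    "StepOutcome",
    "Terminal",
    "ACTIONS",
    "N_ACTIONS",
    "voxelize",
    "cast_rays",
    "reward_coverage",
    "reward_attenuation",
    "reward_shadow",
    "reward_step",
    "reward_terminal",
    "IntercostalScanEnv",
]

ACTIONS = ("h+", "h-", "theta+", "theta-", "phi+", "phi-", "psi+", "psi-", "switch")
N_ACTIONS = len(ACTIONS)
SWITCH = 8


@dataclass
class VoxelGrid:
    """3-channel binary occupancy lattice over a cube around the target."""

    origin: np.ndarray  # corner of voxel (0,0,0), mm
    resolution: float = 4.0  # mm
    dims: tuple[int, int, int] = (30, 30, 30)
    target: np.ndarray = None  # bool, channel 0
    bone: np.ndarray = None  # bool, channel 1
    insonified: np.ndarray = None  # bool, channel 2 (current imaging plane)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        for name in ("target", "bone", "insonified"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.dims, dtype=bool))

    @property
    def N(self) -> int:
        """Total number of target voxels."""
        return int(self.target.sum())

    @property
    def edge_mm(self) -> float:
        return self.resolution * self.dims[0]

    def voxel_centers(self) -> np.ndarray:
        """(nx*ny*nz, 3) voxel-center coordinates, C-order."""
        idx = np.indices(self.dims).reshape(3, -1).T
        return self.origin + (idx + 0.5) * self.resolution

    def channels(self) -> np.ndarray:
        """(3, nx, ny, nz) uint8 stack: target, bone, insonified."""
        return np.stack([self.target, self.bone, self.insonified]).astype(np.uint8)


def voxelize(
    scene: AnatomyScene,
    center: np.ndarray | None = None,
    edge_mm: float = 120.0,
    resolution: float = 4.0,
) -> VoxelGrid:
    """Rasterize targets and bones around ``center`` by voxel-center inclusion.

    Emits a warning (recorded on the grid provenance) if a target extends
    beyond the cube; outside voxels are simply not counted in N.
    """
    if center is None:
        center = scene.targets_centroid
    center = np.asarray(center, float)
    n = int(round(edge_mm / resolution))
    grid = VoxelGrid(origin=center - edge_mm / 2.0, resolution=resolution, dims=(n, n, n))
    centers = grid.voxel_centers()
    grid.target = scene.target_contains(centers).reshape(grid.dims)
    grid.bone = scene.bone_contains(centers).reshape(grid.dims)
    lo, hi = grid.origin, grid.origin + edge_mm
    for t in scene.targets:
        b = np.asarray(t.bounds, float)
        if (b[0] < lo).any() or (b[1] > hi).any():
            import warnings

            warnings.warn(
                f"target extends beyond the {edge_mm:.0f} mm cube; outside voxels ignored",
                stacklevel=2,
            )
            break
    return grid


@dataclass(frozen=True)
class ProbeModel:
    """Virtual linear transducer: ray fan geometry."""

    footprint_length: float = 40.0  # mm along the probe long axis
    ray_spacing: float = 2.0  # mm between adjacent rays
    imaging_depth: float = 120.0  # mm along the centerline (clipped to grid)

    def __post_init__(self):
        if self.footprint_length <= 0:
            raise ValueError("footprint_length must be positive")
        if self.ray_spacing <= 0:
            raise ValueError("ray_spacing must be positive")

    def ray_origins(self, pose: ProbePose) -> np.ndarray:
        n = int(round(self.footprint_length / self.ray_spacing)) + 1
        offsets = np.linspace(
            -self.footprint_length / 2.0, self.footprint_length / 2.0, n
        )
        return pose.contact_point[None, :] + offsets[:, None] * pose.long_axis[None, :]


@dataclass
class RayCastResult:
    insonified: np.ndarray  # bool lattice, channel 2 for this step
    n_insonified: int
    n_shadow: int

    @property
    def N_t(self) -> int:
        """Total scanned slab: insonified plus shadowed cells."""
        return self.n_insonified + self.n_shadow

    @property
    def p_t(self) -> float:
        """Shadowed fraction of the scanned slab; 1 when nothing is scanned."""
        return self.n_shadow / self.N_t if self.N_t > 0 else 1.0


def cast_rays(pose: ProbePose, grid: VoxelGrid, probe: ProbeModel) -> RayCastResult:
    """Exact lattice traversal of the ray fan with bone occlusion.

    Vectorized Amanatides-Woo stepping across all rays in lockstep.  Cells hit
    unblocked by at least one ray are insonified; cells reachable only through
    bone (including the blocking bone cell itself) are shadowed.  A cell that
    is insonified by any ray is never also counted as shadowed.
    """
    if probe.ray_spacing > grid.resolution / 2.0 + 1e-9:
        raise ValueError("ray_spacing must be at most half the voxel resolution")
    d = np.asarray(pose.centerline, float)
    origins = probe.ray_origins(pose)
    nd = np.asarray(grid.dims)
    lo = grid.origin
    hi = grid.origin + nd * grid.resolution

    # clip rays to the grid AABB intersected with [0, imaging_depth]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo[None, :] - origins) / d[None, :]
        t2 = (hi[None, :] - origins) / d[None, :]
    tmin_ax = np.where(np.isfinite(t1), np.minimum(t1, t2), -np.inf)
    tmax_ax = np.where(np.isfinite(t2), np.maximum(t1, t2), np.inf)
    # axes where the ray is parallel and outside the slab never intersect
    par = np.abs(d) < 1e-12
    inside = (origins >= lo[None, :]) & (origins <= hi[None, :])
    bad = par[None, :] & ~inside
    t_enter = np.where(bad.any(axis=1), np.inf, np.maximum(tmin_ax.max(axis=1), 0.0))
    t_exit = np.minimum(tmax_ax.min(axis=1), probe.imaging_depth)

    ins = np.zeros(grid.dims, dtype=bool)
    shadow = np.zeros(grid.dims, dtype=bool)
    active = t_enter < t_exit - 1e-12
    if not active.any():
        return RayCastResult(ins, 0, 0)

    r = int(active.sum())
    o = origins[active]
    te = t_enter[active] + 1e-9  # nudge off exact boundaries
    tx = t_exit[active]
    p0 = o + te[:, None] * d[None, :]
    ivox = np.floor((p0 - lo[None, :]) / grid.resolution).astype(np.int64)
    ivox = np.clip(ivox, 0, nd - 1)
    step = np.where(d > 0, 1, -1).astype(np.int64)
    with np.errstate(divide="ignore"):
        tdelta = grid.resolution / np.abs(d)
    # parametric distance to the next voxel boundary per axis
    next_bound = lo[None, :] + (ivox + (step > 0)) * grid.resolution
    with np.errstate(divide="ignore", invalid="ignore"):
        tmax = (next_bound - o) / d[None, :]
    tmax = np.where(np.isfinite(tmax), tmax, np.inf)

    blocked = np.zeros(r, dtype=bool)
    alive = np.ones(r, dtype=bool)
    bone = grid.bone
    while alive.any():
        iv = np.clip(ivox, 0, nd[None, :] - 1)  # dead rays may sit out of bounds
        ii, jj, kk = iv[:, 0], iv[:, 1], iv[:, 2]
        cur_bone = bone[ii, jj, kk] & alive
        # visit: unblocked rays mark insonified unless the cell is bone,
        # which blocks the ray and is itself shadowed
        free = alive & ~blocked
        hit_bone = free & cur_bone
        mark_ins = free & ~cur_bone
        if mark_ins.any():
            ins[ii[mark_ins], jj[mark_ins], kk[mark_ins]] = True
        behind = (alive & blocked) | hit_bone
        if behind.any():
            shadow[ii[behind], jj[behind], kk[behind]] = True
        blocked |= hit_bone
        # advance each alive ray across its nearest boundary
        axis = np.argmin(tmax, axis=1)
        t_now = tmax[np.arange(r), axis]
        ivox[np.arange(r), axis] += step[axis] * alive
        tmax[np.arange(r), axis] += tdelta[axis] * alive
        alive &= t_now < tx
        alive &= np.all((ivox >= 0) & (ivox < nd[None, :]), axis=1)

    shadow &= ~ins
    return RayCastResult(ins, int(ins.sum()), int(shadow.sum()))


# --- reward components ---------------------------------------------------


def reward_coverage(n_t: int, N: int) -> float:
    """Fraction of the target newly covered this step."""
    if N <= 0:
        raise ValueError("target has no voxels; reconfigure the scene")
    return n_t / N


def reward_attenuation(d_t: float, R_c: float) -> float:
    """exp(-d/R_c): favours imaging from the closest intercostal window."""
    if d_t < 0 or R_c <= 0:
        raise ValueError("need d_t >= 0 and R_c > 0")
    return float(np.exp(-d_t / R_c))


def reward_shadow(n_shadow: int, N_t: int) -> tuple[float, float]:
    """Returns (r_s, p_t) with p_t the shadowed fraction of the scanned slab."""
    p_t = n_shadow / N_t if N_t > 0 else 1.0
    return 1.0 - p_t, p_t


@dataclass(frozen=True)
class RewardConfig:
    """Reward weights, thresholds and episode-control constants."""

    alpha1: float = 1.0  # attenuation weight
    alpha2: float = 0.5  # shadow weight
    t_th: float = 0.20  # max tolerated shadowed fraction per step
    k_end: float = 10.0  # terminal success reward scale
    success_fraction: float = 0.95  # cumulative coverage for success
    switch_penalty: float = -1.0
    shadow_penalty: float = -0.1
    max_steps: int = 80
    tilt_limit_deg: float = 20.0

    def __post_init__(self):
        if not (0.0 < self.t_th <= 1.0):
            raise ValueError("t_th must be in (0, 1]")
        if not (0.0 < self.success_fraction <= 1.0):
            raise ValueError("success_fraction must be in (0, 1]")


def reward_step(r_c: float, r_a: float, r_s: float, config: RewardConfig) -> float:
    """Weighted per-step reward; the coverage coefficient is fixed at 1."""
    return r_c + config.alpha1 * r_a + config.alpha2 * r_s


def reward_terminal(
    d_trace: np.ndarray, p_trace: np.ndarray, config: RewardConfig, R_c: float
) -> float:
    """Terminal success bonus from the episode's examining-step traces.

    ``D`` is the mean normalized probe-target distance and ``P`` the mean
    non-shadow fraction over the T examining steps.
    """
    d = np.asarray(d_trace, float)
    p = np.asarray(p_trace, float)
    if d.size == 0:
        raise ValueError("terminal reward needs at least one examining step")
    D = float(np.mean(d / R_c))
    if D == 0.0:
        raise ValueError("all probe-target distances are zero; degenerate episode")
    P = float(np.mean(1.0 - p))
    return config.k_end * (1.0 + config.alpha1 / D + config.alpha2 * P)


class Terminal(str, Enum):
    NONE = "none"
    SUCCESS = "success"
    TRUNCATED = "truncated"
    TILT = "tilt_violation"


@dataclass
class StepOutcome:
    """Per-step bookkeeping: counts, reward components, dispatch result."""

    action: int
    n_t: int = 0
    N: int = 0
    N_t: int = 0
    n_shadow: int = 0
    p_t: float = 1.0
    d_t: float = np.nan
    r_c: float = 0.0
    r_a: float = 0.0
    r_s: float = 0.0
    reward: float = 0.0
    terminal: Terminal = Terminal.NONE
    adj: bool = False
    coverage_fraction: float = 0.0
    pose: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        rec = {
            "action": ACTIONS[self.action] if self.action >= 0 else "reset",
            "n_t": self.n_t,
            "N_t": self.N_t,
            "n_shadow": self.n_shadow,
            "p_t": self.p_t,
            "d_t": None if np.isnan(self.d_t) else self.d_t,
            "reward": self.reward,
            "terminal": self.terminal.value,
            "adj": self.adj,
            "coverage_fraction": self.coverage_fraction,
        }
        rec.update({"pose": self.pose})
        return rec


@dataclass(frozen=True)
class StepSizes:
    """Discrete action increments."""

    h_mm: float = 4.0
    theta_deg: float = 3.0
    phi_deg: float = 2.0
    psi_deg: float = 2.0


class IntercostalScanEnv:
    """Episodic environment: discrete 9-action space, 9x30x30x30 observation.

    Actions 0..7 are +/- increments of (h, theta, phi, psi); action 8 toggles
    the readjusting mode.  ``reset`` optionally re-places targets (the
    training randomization), voxelizes the scene around the target centroid,
    and drops the probe at a uniformly random valid (h, theta) with
    phi = psi = 0 in examining mode.
    """

    n_actions = N_ACTIONS

    def __init__(
        self,
        scene: AnatomyScene,
        frame: CylindricalFrame | None = None,
        probe: ProbeModel | None = None,
        reward_config: RewardConfig | None = None,
        step_sizes: StepSizes | None = None,
        placement: dict | None = None,
        seed: int = 0,
    ):
        self.base_scene = scene
        self.scene = scene
        self.probe = probe or ProbeModel()
        self.reward_config = reward_config or RewardConfig()
        self.step_sizes = step_sizes or StepSizes()
        # e.g. {"n": 1, "size_class": "small"} to randomize targets per episode
        self.placement = placement
        self.rng = np.random.default_rng(seed)
        if frame is None:
            pts = scene.bones.sample_points(400, np.random.default_rng(12345))
            frame = fit_cylinder(pts)
        self.frame = frame
        self.grid: VoxelGrid | None = None
        self.pose: ProbePose | None = None
        self._history: list[np.ndarray] = []
        self._covered: np.ndarray | None = None
        self._d_trace: list[float] = []
        self._p_trace: list[float] = []
        self.step_count = 0
        self.episode_log: list[StepOutcome] = []

    # --- helpers ---------------------------------------------------------

    @property
    def skin(self) -> Surface:
        return self.scene.skin

    def _observation(self) -> np.ndarray:
        return np.concatenate(self._history, axis=0).astype(np.float32)

    def _generic_distance(self) -> float:
        """Probe-face-to-target-centroid distance in generic scale."""
        c = self.frame.to_generic(self.pose.contact_point)
        t = self.frame.to_generic(self.scene.targets_centroid)
        return float(np.linalg.norm(c - t))

    def _push_grid(self, insonified: np.ndarray) -> None:
        self.grid.insonified = insonified
        self._history.append(self.grid.channels())
        if len(self._history) > 3:
            self._history.pop(0)

    @property
    def coverage_fraction(self) -> float:
        return float(self._covered.sum()) / self.grid.N

    @property
    def generic_radius(self) -> float:
        return self.frame.generic_radius

    # --- episode interface ------------------------------------------------

    def reset(self, seed: int | None = None) -> np.ndarray:
        if seed is not None:
            self.rng = np.random.default_rng(seed)
        if self.placement is not None:
            self.scene = place_targets(
                self.base_scene,
                n=self.placement.get("n", 1),
                size_class=self.placement.get("size_class", "medium"),
                seed=int(self.rng.integers(2**31)),
            )
        self.grid = voxelize(self.scene)
        if self.grid.N == 0:
            raise ValueError("no target voxels inside the state cube")
        self._covered = np.zeros(self.grid.dims, dtype=bool)
        self._d_trace, self._p_trace = [], []
        self.step_count = 0
        self.episode_log = []
        # random valid initial surface coordinates, phi = psi = 0, examining
        h_lo, h_hi = self.frame.h_range
        for _ in range(200):
            h = float(self.rng.uniform(h_lo, h_hi))
            theta = float(self.rng.uniform(-180.0, 180.0))
            try:
                self.pose = build_pose(h, theta, 0.0, 0.0, self.frame, self.skin)
                break
            except OffSurfaceError:
                continue
        else:
            raise RuntimeError("could not find a valid initial probe pose")
        cast = cast_rays(self.pose, self.grid, self.probe)
        self.grid.insonified = cast.insonified
        grid_ch = self.grid.channels()
        self._history = [grid_ch.copy(), grid_ch.copy(), grid_ch.copy()]
        return self._observation()

    def step(self, action: int) -> tuple[np.ndarray, float, bool, StepOutcome]:
        if self.grid is None:
            raise RuntimeError("call reset() before step()")
        if not (0 <= action < N_ACTIONS):
            raise ValueError(f"action index {action} out of range 0..{N_ACTIONS - 1}")
        cfg = self.reward_config
        self.step_count += 1
        outcome = StepOutcome(action=action, N=self.grid.N, adj=self.pose.adj)

        if action == SWITCH:
            self.pose.adj = not self.pose.adj
            outcome.adj = self.pose.adj
            outcome.reward = cfg.switch_penalty
            # pose unchanged: re-use the previous imaging plane for the state
            self._push_grid(self.grid.insonified.copy())
        else:
            sz = self.step_sizes
            dh = {0: sz.h_mm, 1: -sz.h_mm}.get(action, 0.0)
            dth = {2: sz.theta_deg, 3: -sz.theta_deg}.get(action, 0.0)
            dph = {4: sz.phi_deg, 5: -sz.phi_deg}.get(action, 0.0)
            dps = {6: sz.psi_deg, 7: -sz.psi_deg}.get(action, 0.0)
            try:
                new_pose = build_pose(
                    self.pose.h + dh,
                    self.pose.theta + dth,
                    self.pose.phi + dph,
                    self.pose.psi + dps,
                    self.frame,
                    self.skin,
                    adj=self.pose.adj,
                )
                self.pose = new_pose
            except OffSurfaceError:
                pass  # invalid action: pose unchanged, ordinary accounting below
            cast = cast_rays(self.pose, self.grid, self.probe)
            outcome.N_t = cast.N_t
            outcome.n_shadow = cast.n_shadow
            outcome.p_t = cast.p_t
            if self.pose.adj:
                outcome.reward = 0.0  # readjusting: acquisitions excluded
            else:
                d_t = self._generic_distance()
                outcome.d_t = d_t
                self._d_trace.append(d_t)
                self._p_trace.append(cast.p_t)
                r_s, p_t = reward_shadow(cast.n_shadow, cast.N_t)
                if p_t >= cfg.t_th:
                    outcome.reward = cfg.shadow_penalty  # coverage discarded
                else:
                    newly = cast.insonified & self.grid.target & ~self._covered
                    outcome.n_t = int(newly.sum())
                    self._covered |= newly
                    outcome.r_c = reward_coverage(outcome.n_t, self.grid.N)
                    outcome.r_a = reward_attenuation(d_t, self.generic_radius)
                    outcome.r_s = r_s
                    outcome.reward = reward_step(
                        outcome.r_c, outcome.r_a, outcome.r_s, cfg
                    )
                    if self.coverage_fraction >= cfg.success_fraction:
                        outcome.reward = reward_terminal(
                            self._d_trace, self._p_trace, cfg, self.generic_radius
                        )
                        outcome.terminal = Terminal.SUCCESS
            # a pose exactly at the limit is valid; 1e-9 deg guards arccos rounding
            if (
                outcome.terminal is Terminal.NONE
                and self.pose.tilt_deg > cfg.tilt_limit_deg + 1e-9
            ):
                outcome.terminal = Terminal.TILT
            self._push_grid(cast.insonified)

        if outcome.terminal is Terminal.NONE and self.step_count >= cfg.max_steps:
            outcome.terminal = Terminal.TRUNCATED
        outcome.coverage_fraction = self.coverage_fraction
        outcome.pose = {
            "h": self.pose.h,
            "theta": self.pose.theta,
            "phi": self.pose.phi,
            "psi": self.pose.psi,
            "adj": self.pose.adj,
        }
        self.episode_log.append(outcome)
        done = outcome.terminal is not Terminal.NONE
        return self._observation(), outcome.reward, done, outcome

    # --- episode traces ----------------------------------------------------

    @property
    def d_trace(self) -> np.ndarray:
        return np.asarray(self._d_trace, float)

    @property
    def p_trace(self) -> np.ndarray:
        return np.asarray(self._p_trace, float)

    def write_episode_log(self, path: str | Path) -> Path:
        """Episode log as JSON lines, one step record per line."""
        path = Path(path)
        with path.open("w") as fh:
            for o in self.episode_log:
                fh.write(json.dumps(o.to_record()) + "\n")
        return path
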