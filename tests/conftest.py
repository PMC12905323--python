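import numpy as np
import pytest

import ribscan as rs
from ribscan.phantom import benchmark_scene


@pytest.fixture(scope="session")
def small_scene():
    """Deterministic phantom with one small target."""
    return rs.generate_phantom(rs.PhantomConfig(seed=7, size_class="small"))


@pytest.fixture(scope="session")
def bench_scene():
    """Single-gap benchmark scene with a centred spherical target."""
    return benchmark_scene()


@pytest.fixture()
def bench_env(bench_scene):
    return rs.IntercostalScanEnv(bench_scene, seed=0)


@pytest.fixture(scope="session")
def cyl_setup():
    """Analytic cylinder skin + frame for geometry tests."""
    frame = rs.CylindricalFrame(
        axis_point=np.array([0.0, 0.0, -50.0]),
        axis_dir=np.array([0.0, 0.0, 1.0]),
        e_anterior=np.array([1.0, 0.0, 0.0]),
        radius=60.0,
        height=100.0,
    )
    skin = rs.CylinderSurface(
        axis_point=np.array([0.0, 0.0, -50.0]),
        axis_dir=np.array([0.0, 0.0, 1.0]),
        radius=80.0,
        h_min=0.0,
        h_max=100.0,
    )
    return frame, skin


def scripted_sweep_policy(env, sweep_mm: float = 12.0):
    """Deterministic policy: steer (theta, h) to the target, then sweep h."""
    return rs.scripted_sweep_policy(env, sweep_mm)
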