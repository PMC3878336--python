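import numpy as np
import pytest

from attencorr import ConeSpec, NoiseParams, PhantomSpec, RaySet, TwoViewRecording, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_ray_cones():
    """A minimal 3-ray quadrature per view (axial plus two 10-degree tilts),
    small enough for finite-difference and brute-force oracles."""
    t = np.deg2rad(10.0)
    dirs_top = np.array(
        [
            [-1.0, 0.0, 0.0],
            [-np.cos(t), np.sin(t), 0.0],
            [-np.cos(t), 0.0, np.sin(t)],
        ]
    )
    w = np.full(3, 1.0 / 3.0)
    top = RaySet(dirs_top, w)
    bottom = RaySet(dirs_top * np.array([-1.0, 1.0, 1.0]), w)
    return top, bottom


@pytest.fixture
def small_instance(rng, three_ray_cones):
    """Random small two-view problem for gradient and optimizer checks."""
    shape = (5, 5, 5)
    I = 100.0 * rng.random(shape)
    alpha = 0.01 + 0.05 * rng.random(shape)
    beta2 = 0.8
    recs = TwoViewRecording(
        VolumeGrid(100.0 * rng.random(shape)),
        VolumeGrid(100.0 * rng.random(shape)),
    )
    noise = NoiseParams(m=0.05, sigma=10.0)
    return I, alpha, beta2, recs, noise, three_ray_cones
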