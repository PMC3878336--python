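"""Synthetic ground-truth phantoms and two-view measurement simulation.

Two phantoms are provided.  The *textured sphere* is a solid sphere with
constant absorption (0.006 per voxel) whose interior 60 % of the radius
fluoresces at intensity 4094; both fields carry an independent smooth random
texture with standard deviation ~30 % of the field maximum.  Every voxel of
the sphere then carries both intensity and attenuation information — the
well-posed case.  The *3-D Shepp-Logan* phantom consists of overlapping
ellipsoids with homogeneous intensities (rescaled to [0, 65535]) and
per-region attenuation values chosen to avoid any monotone relation with
intensity — the ill-posed case with large fluorophore-free regions.

Measurements are simulated with the confocal forward model (opposed top and
bottom cones), a bleaching factor beta_2 for the second view, and
Poisson-Gaussian noise with variance m^2 I + sigma^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import raytrace
from .volume_io import TwoViewRecording, VolumeGrid, as_volume


@dataclass(frozen=True)
class PhantomSpec:
    kind: str = "textured_sphere"
    shape: tuple[int, int, int] = (80, 80, 80)
    sphere_absorption: float = 0.006
    interior_intensity: float = 4094.0
    interior_fraction: float = 0.6
    radius_fraction: float = 0.4  # sphere radius as a fraction of the grid extent
    texture_rel_std: float = 0.3
    texture_smooth_sigma: float = 4.0  # correlation length of the texture, voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.interior_fraction <= 1.0:
            raise ValueError("interior_fraction must lie in (0, 1]")
        if self.texture_rel_std < 0:
            raise ValueError("texture_rel_std must be non-negative")


@dataclass(frozen=True)
class NoiseParams:
    """Poisson scaling m (intensity levels per photon-equivalent) and Gaussian
    read-out noise sigma (intensity levels); per-voxel variance m^2 I + sigma^2."""

    m: float = 0.05
    sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 0 or self.sigma < 0:
            raise ValueError("noise parameters must be non-negative")


def _smooth_texture(shape, rel_std, smooth_sigma, field_max, rng) -> np.ndarray:
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=smooth_sigma, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return smooth * (rel_std * field_max / sd)


def make_textured_sphere(spec: PhantomSpec) -> tuple[VolumeGrid, VolumeGrid]:
    """Textured-sphere ground truth: returns (I_true, alpha_true)."""
    if spec.kind != "textured_sphere":
        raise ValueError(f"spec.kind must be 'textured_sphere', got {spec.kind!r}")
    shape = tuple(spec.shape)
    rng = np.random.default_rng(spec.seed)
    zz, yy, xx = np.meshgrid(*[np.arange(n) - (n - 1) / 2.0 for n in shape], indexing="ij")
    r = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
    radius = spec.radius_fraction * min(shape)
    sphere = r <= radius
    core = r <= spec.interior_fraction * radius

    alpha = np.where(sphere, spec.sphere_absorption, 0.0)
    I = np.where(core, spec.interior_intensity, 0.0)
    if spec.texture_rel_std > 0:
        tex_a = _smooth_texture(
            shape, spec.texture_rel_std, spec.texture_smooth_sigma, spec.sphere_absorption, rng
        )
        tex_i = _smooth_texture(
            shape, spec.texture_rel_std, spec.texture_smooth_sigma, spec.interior_intensity, rng
        )
        alpha = np.where(sphere, alpha + tex_a, 0.0)
        I = np.where(core, I + tex_i, 0.0)
    return (
        VolumeGrid(np.maximum(I, 0.0)),
        VolumeGrid(np.maximum(alpha, 0.0)),
    )


# 3-D Shepp-Logan ellipsoids: intensity value, semi-axes (a, b, c) in x/y/z of
# the [-1, 1]^3 frame, centre (x0, y0, z0), rotation phi (deg) about z.  The
# geometry is the standard published tabulation; the intensity of each region
# is the value the classic additive phantom attains there (painted in order,
# later ellipsoids overwrite).
_SHEPP_LOGAN_ELLIPSOIDS = [
    # value   a       b      c      x0     y0      z0     phi
    (1.00, 0.6900, 0.920, 0.810, 0.00, 0.000, 0.00, 0.0),
    (0.20, 0.6624, 0.874, 0.780, 0.00, -0.0184, 0.00, 0.0),
    (0.00, 0.1100, 0.310, 0.220, 0.22, 0.000, 0.00, -18.0),
    (0.00, 0.1600, 0.410, 0.280, -0.22, 0.000, 0.00, 18.0),
    (0.30, 0.2100, 0.250, 0.410, 0.00, 0.350, -0.15, 0.0),
    (0.30, 0.0460, 0.046, 0.050, 0.00, 0.100, 0.25, 0.0),
    (0.30, 0.0460, 0.046, 0.050, 0.00, -0.100, 0.25, 0.0),
    (0.30, 0.0460, 0.023, 0.050, -0.08, -0.605, 0.00, 0.0),
    (0.30, 0.0230, 0.023, 0.020, 0.00, -0.606, 0.00, 0.0),
    (0.30, 0.0230, 0.046, 0.020, 0.06, -0.605, 0.00, 0.0),
]

# Per-region attenuation lookup (per voxel-length at the reference 80^3 grid,
# all within [0, 0.01]).  Deliberately decorrelated from intensity: the bright
# shell (I=65535) and tumour 5 (I=19660) share alpha=0.002, tumours 6/7 share
# 0.004, and tumour 9 is attenuation-free despite being bright.
SHEPP_LOGAN_ATTENUATIONS = (0.002, 0.008, 0.006, 0.006, 0.002, 0.004, 0.004, 0.010, 0.000, 0.005)


def make_shepp_logan_3d(spec: PhantomSpec) -> tuple[VolumeGrid, VolumeGrid]:
    """3-D Shepp-Logan ground truth: returns (I_true, alpha_true)."""
    if spec.kind != "shepp_logan":
        raise ValueError(f"spec.kind must be 'shepp_logan', got {spec.kind!r}")
    shape = tuple(spec.shape)
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij"
    )
    z, y, x = grids
    I = np.zeros(shape)
    alpha = np.zeros(shape)
    for (value, a, b, c, x0, y0, z0, phi), att in zip(
        _SHEPP_LOGAN_ELLIPSOIDS, SHEPP_LOGAN_ATTENUATIONS
    ):
        p = np.deg2rad(phi)
        xr = (x - x0) * np.cos(p) + (y - y0) * np.sin(p)
        yr = -(x - x0) * np.sin(p) + (y - y0) * np.cos(p)
        inside = (xr / a) ** 2 + (yr / b) ** 2 + ((z - z0) / c) ** 2 <= 1.0
        I[inside] = value * 65535.0
        alpha[inside] = att
    return VolumeGrid(I), VolumeGrid(alpha)


def make_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, VolumeGrid]:
    if spec.kind == "textured_sphere":
        return make_textured_sphere(spec)
    if spec.kind == "shepp_logan":
        return make_shepp_logan_3d(spec)
    raise ValueError(f"unknown phantom kind {spec.kind!r}")


def apply_psf(vol, sigmas) -> VolumeGrid:
    """Anisotropic Gaussian smoothing standing in for the microscope's point
    spread function; reflective boundaries preserve total interior intensity."""
    vol = as_volume(vol)
    sigmas = np.atleast_1d(np.asarray(sigmas, float))
    if sigmas.size == 1:
        sigmas = np.repeat(sigmas, 3)
    if np.any(sigmas < 0):
        raise ValueError("PSF sigmas must be non-negative")
    if np.all(sigmas == 0):
        return vol.copy()
    out = ndimage.gaussian_filter(vol.values, sigma=tuple(sigmas), mode="reflect")
    return VolumeGrid(out, vol.spacing)


def apply_noise(vol, noise: NoiseParams) -> VolumeGrid:
    """Poisson-Gaussian measurement noise.

    With gain 1/m^2 photon-equivalents per intensity level the output is
    ``m^2 * Poisson(v / m^2) + N(0, sigma^2)``: unbiased, with variance
    ``m^2 v + sigma^2`` — exactly the variance the data weights assume.
    """
    vol = as_volume(vol)
    v = vol.values
    if np.any(v < 0):
        raise ValueError("apply_noise requires a non-negative volume")
    rng = np.random.default_rng(noise.seed)
    if noise.m > 0:
        out = noise.m ** 2 * rng.poisson(v / noise.m ** 2).astype(np.float64)
    else:
        out = v.copy()
    if noise.sigma > 0:
        out += rng.normal(0.0, noise.sigma, size=v.shape)
    return VolumeGrid(out, vol.spacing)


def simulate_two_views(
    I_true,
    alpha_true,
    beta2: float = 0.8,
    cones=None,
    noise: NoiseParams | None = None,
) -> TwoViewRecording:
    """Simulate the two opposite-side recordings of a ground-truth pair.

    Top view: F_1[alpha, I, beta_1=1]; bottom view: F_2[alpha, I, beta_2]
    (beta_2 < 1 models bleaching-induced signal loss between recordings).
    Independent noise streams are derived per view from ``noise.seed``.
    """
    I_true = as_volume(I_true)
    alpha_true = as_volume(alpha_true)
    if I_true.shape != alpha_true.shape:
        raise ValueError("I_true and alpha_true must share a shape")
    if beta2 <= 0:
        raise ValueError("beta2 must be positive")
    if cones is None:
        cones = (raytrace.ConeSpec(view="top"), raytrace.ConeSpec(view="bottom"))
    top = raytrace.simulate_view(I_true, alpha_true, 1.0, cones[0])
    bottom = raytrace.simulate_view(I_true, alpha_true, beta2, cones[1])
    if noise is not None:
        seeds = np.random.SeedSequence(noise.seed).spawn(2)
        top = apply_noise(top, NoiseParams(noise.m, noise.sigma, seed=seeds[0]))
        bottom = apply_noise(bottom, NoiseParams(noise.m, noise.sigma, seed=seeds[1]))
    return TwoViewRecording(top=top, bottom=bottom)


def make_dataset(
    spec: PhantomSpec,
    beta2: float = 0.8,
    noise: NoiseParams | None = NoiseParams(),
    psf_sigmas=(2.0, 1.0, 1.0),
    cones=None,
):
    """Full simulation pipeline: phantom -> PSF smoothing of the ground truth ->
    two-view simulation -> noise.  Returns (I_true, alpha_true, recording).

    The PSF is applied to the ground-truth fields themselves (band-limiting
    them for Nyquist-safe sampling), so reconstruction errors measure the
    method, not the blur.
    """
    I_true, alpha_true = make_phantom(spec)
    if psf_sigmas is not None:
        I_true = apply_psf(I_true, psf_sigmas)
        alpha_true = apply_psf(alpha_true, psf_sigmas)
    recs = simulate_two_views(I_true, alpha_true, beta2=beta2, cones=cones, noise=noise)
    return I_true, alpha_true, recs
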