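"""The confocal forward model.

A recording position x emits photons that are excited and detected through the
same cone of rays converging on the objective lens.  Along each ray the signal
follows Beer-Lambert attenuation, so the measured signal is

    F_i(x) = beta_i * I(x) * C_i(x)**2,
    C_i(x) = sum_r s_i(r) * T_r(x),
    T_r(x) = exp( - integral_0^inf alpha(x + l*r) dl ),

where C_i is the cone transmission of view i (normalized so C_i = 1 for
alpha = 0), T_r the single-ray transmittance, and the square accounts for the
identical excitation and emission paths.  beta_2 models photobleaching-induced
signal loss of the second recording.

Attenuation is assumed zero outside the recorded volume (natural boundary
condition).  The discrete line integral advances one z-slice per step (a shear
sweep with a constant bilinear in-plane shift per ray); its transpose — needed
for the attenuation gradient — is the same sweep run backwards, so forward
model and gradient form an exact adjoint pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._kernels import sweep_accumulate
from .volume_io import VolumeGrid, as_volume


@dataclass(frozen=True)
class ConeSpec:
    """Illumination/detection cone of one view.

    The axis points from the sample toward the lens: ``(-1, 0, 0)`` in
    (z, y, x) order for the top view (lens at z = 0), ``(+1, 0, 0)`` for the
    bottom view.  ``half_angle`` is a free parameter of the optics (not fixed
    by the model); ``ray_spacing`` controls the angular quadrature density.
    """

    view: str = "top"
    half_angle: float = 30.0
    ray_spacing: float = 6.0
    weighting: str = "solid_angle"  # or "uniform"

    def __post_init__(self) -> None:
        if not 0.0 < self.half_angle < 90.0:
            raise ValueError(f"half_angle must be in (0, 90) deg, got {self.half_angle}")
        if self.ray_spacing <= 0:
            raise ValueError(f"ray_spacing must be positive, got {self.ray_spacing}")
        if self.view not in ("top", "bottom"):
            raise ValueError(f"view must be 'top' or 'bottom', got {self.view!r}")

    @property
    def axis(self) -> np.ndarray:
        return np.array([-1.0, 0.0, 0.0]) if self.view == "top" else np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class RaySet:
    """Quadrature over a cone: unit directions (R, 3) in (z, y, x) order and
    positive weights summing to 1."""

    directions: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "directions", np.atleast_2d(np.asarray(self.directions, float)))
        object.__setattr__(self, "weights", np.atleast_1d(np.asarray(self.weights, float)))
        if self.directions.shape != (self.weights.size, 3):
            raise ValueError("directions must be (R, 3) matching R weights")
        if np.any(self.weights <= 0):
            raise ValueError("quadrature weights must be positive")
        if not math.isclose(float(self.weights.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("quadrature weights must sum to 1")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("ray directions must be unit vectors")
        if np.any(np.abs(self.directions[:, 0]) < 1e-9):
            raise ValueError("rays perpendicular to the optical axis are not traceable")

    def __len__(self) -> int:
        return self.weights.size


def sample_cone_directions(cone: ConeSpec) -> RaySet:
    """Polar-grid quadrature of the cone: rings every ``ray_spacing`` degrees
    from the axis out to ``half_angle``, azimuthal spacing ~``ray_spacing`` at
    each ring, ring weights proportional to the solid angle of the annular
    patch each ring represents (or uniform if requested).  The axial ray is
    always included."""
    s = cone.ray_spacing
    thetas = np.arange(0.0, cone.half_angle + 1e-9, s)
    axis_z = cone.axis[0]
    directions: list[np.ndarray] = []
    weights: list[float] = []
    for theta in thetas:
        lo = max(theta - s / 2.0, 0.0)
        hi = min(theta + s / 2.0, cone.half_angle)
        patch = 2.0 * math.pi * (math.cos(math.radians(lo)) - math.cos(math.radians(hi)))
        t = math.radians(theta)
        if theta == 0.0:
            n_az = 1
        else:
            n_az = max(1, int(round(360.0 * math.sin(t) / s)))
        for k in range(n_az):
            phi = 2.0 * math.pi * k / n_az
            d = np.array(
                [
                    axis_z * math.cos(t),
                    math.sin(t) * math.cos(phi),
                    math.sin(t) * math.sin(phi),
                ]
            )
            directions.append(d / np.linalg.norm(d))
            if cone.weighting == "uniform":
                weights.append(1.0)
            else:
                weights.append(max(patch, 1e-300) / n_az)
    w = np.asarray(weights)
    return RaySet(np.vstack(directions), w / w.sum())


def _resolve_rays(cone) -> RaySet:
    if isinstance(cone, RaySet):
        return cone
    return sample_cone_directions(cone)


def _ray_step(direction: np.ndarray) -> tuple[int, float, float, float]:
    """Slice-synchronized step for a ray: (dz, dy, dx) with |dz| = 1 and the
    step length along the ray in voxel units."""
    rz, ry, rx = direction
    dz = -1 if rz < 0 else 1
    dy = ry / abs(rz)
    dx = rx / abs(rz)
    step_len = math.sqrt(1.0 + dy * dy + dx * dx)
    return dz, dy, dx, step_len


def ray_line_integral(alpha: np.ndarray, direction) -> np.ndarray:
    """Line integral of alpha from every voxel along ``direction`` to the
    volume boundary (trapezoid: half weight on the start voxel)."""
    direction = np.asarray(direction, float)
    dz, dy, dx, step = _ray_step(direction)
    acc = sweep_accumulate(alpha, dz, dy, dx)
    return step * (0.5 * alpha + acc)


def ray_line_integral_adjoint(field: np.ndarray, direction) -> np.ndarray:
    """Exact transpose of :func:`ray_line_integral` as a linear map."""
    direction = np.asarray(direction, float)
    dz, dy, dx, step = _ray_step(direction)
    acc = sweep_accumulate(field, -dz, -dy, -dx)
    return step * (0.5 * field + acc)


def ray_transmittance_field(alpha: np.ndarray, direction) -> np.ndarray:
    """exp(-line integral) for one ray direction, for every voxel."""
    return np.exp(-ray_line_integral(alpha, direction))


def transmittance(alpha, x, r) -> float:
    """Reference single-point transmittance: direct trilinear sampling of the
    attenuation field at one-voxel steps along the ray from ``x`` (voxel
    coordinates, (z, y, x) order) until it leaves the volume.

    Diagnostic/oracle path; the production sweep is cross-checked against it.
    """
    alpha = as_volume(alpha).values
    x = np.asarray(x, float)
    r = np.asarray(r, float)
    r = r / np.linalg.norm(r)
    shape = np.asarray(alpha.shape, float)
    # the ray exits the volume as soon as any coordinate leaves the box
    t_exit = math.inf
    for i in range(3):
        if r[i] > 1e-12:
            t_exit = min(t_exit, (shape[i] - x[i]) / r[i])
        elif r[i] < -1e-12:
            t_exit = min(t_exit, (-1.0 - x[i]) / r[i])
    if not math.isfinite(t_exit):
        t_exit = float(shape.max())
    n_steps = int(math.ceil(t_exit)) + 1
    ells = np.arange(n_steps + 1, dtype=float)
    pts = x[None, :] + ells[:, None] * r[None, :]
    samples = ndimage.map_coordinates(alpha, pts.T, order=1, mode="constant", cval=0.0)
    integral = 0.5 * samples[0] + samples[1:].sum()
    return float(np.exp(-integral))


def cone_transmission(alpha, cone) -> VolumeGrid:
    """Weight-normalized cone transmission C(x); equals 1 everywhere for
    alpha = 0 and lies in (0, 1] for finite alpha >= 0."""
    vol = as_volume(alpha)
    rays = _resolve_rays(cone)
    out = np.zeros(vol.shape)
    for d, w in zip(rays.directions, rays.weights):
        out += w * ray_transmittance_field(vol.values, d)
    return VolumeGrid(out, vol.spacing)


def simulate_view(I, alpha, beta: float, cone) -> VolumeGrid:
    """Simulated confocal measurement F = beta * I * C**2."""
    I = as_volume(I)
    alpha = as_volume(alpha)
    if I.shape != alpha.shape:
        raise ValueError(f"I and alpha must share a shape: {I.shape} vs {alpha.shape}")
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    C = cone_transmission(alpha, cone)
    return VolumeGrid(beta * I.values * C.values ** 2, I.spacing)


def backproject_weighted(alpha, cone, field) -> VolumeGrid:
    """Adjoint ray accumulation used by the attenuation gradient.

    For every voxel x, accumulates ``field * T_r`` over all positions whose
    path to the lens passes through x, summed over the cone quadrature:

        out = sum_r w_r * A_r^T (field * T_r[alpha]),

    where A_r is the discrete line-integral operator of ray r.  Because A_r^T
    is the exact transpose of the operator inside T_r, the resulting data
    gradient is the exact derivative of the discrete energy.
    """
    vol = as_volume(alpha)
    fld = as_volume(field)
    rays = _resolve_rays(cone)
    out = np.zeros(vol.shape)
    for d, w in zip(rays.directions, rays.weights):
        T = ray_transmittance_field(vol.values, d)
        out += w * ray_line_integral_adjoint(fld.values * T, d)
    return VolumeGrid(out, vol.spacing)
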