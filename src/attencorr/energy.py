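"""The variational objective and its analytic derivatives.

The reconstruction minimizes, over the attenuation field alpha >= 0, the
attenuation-free intensities I >= 0, and the bleaching factor beta_2 > 0,

    E = sum_i sum_x (I_i - F_i)^2 / (m^2 I_i + sigma^2)        (data term)
      + lambda * sum_x psi(|grad alpha|^2)                     (smoothness)
      + mu * sum_x sqrt(alpha^2 + eps_sp^2)                    (sparsity)

with F_i = beta_i * I * C_i^2 the forward model, psi the identity for
Tikhonov-Miller (TM) smoothing or the smoothed total-variation loss
psi(t) = sqrt(t + eps_tv^2) for TV.  The data weights use the *recorded*
intensities I_i (fixed per run after background subtraction), which makes the
Gaussian approximation of the Poisson photon statistics explicit: the per-voxel
noise variance is m^2 I_i + sigma^2.  For m = 0, sigma = 1 the data term
reduces to an unweighted least-squares model.

All gradients here are exact derivatives of the *discrete* energy (sums over
voxels, forward-difference gradients with their adjoint backward-difference
divergences), so they satisfy finite-difference checks to rounding accuracy —
the property the quasi-Newton optimizer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import raytrace
from .volume_io import TwoViewRecording, VolumeGrid, as_volume


@dataclass(frozen=True)
class RegularizerSpec:
    """Prior configuration: smoothness kind and weight, sparsity weight, and
    the numerical stabilizers of the smoothed absolute values."""

    kind: str = "tm"
    lam: float = 0.0
    mu: float = 0.0
    eps_tv: float = 1e-10
    eps_sp: float = 1e-10

    def __post_init__(self) -> None:
        if self.kind.lower() not in ("tm", "tv"):
            raise ValueError(f"regularizer kind must be 'tm' or 'tv', got {self.kind!r}")
        object.__setattr__(self, "kind", self.kind.lower())
        if self.lam < 0 or self.mu < 0:
            raise ValueError("regularizer weights must be non-negative")
        if self.eps_tv <= 0 or self.eps_sp <= 0:
            raise ValueError("stabilizer constants must be positive")


@dataclass
class EnergyBreakdown:
    """Energy terms (raw, i.e. before weighting) and gradients.

    ``e_total = e_data + lam * e_smooth + mu * e_sparse``.
    """

    e_data: float
    e_smooth: float
    e_sparse: float
    e_total: float
    grad_alpha: Optional[np.ndarray] = None
    grad_I: Optional[np.ndarray] = None
    grad_beta2: Optional[float] = None


def data_weight(rec_view, m: float, sigma: float) -> np.ndarray:
    """Per-voxel data weight 1 / (m^2 I_i + sigma^2) from the recorded view."""
    if m == 0 and sigma == 0:
        raise ValueError("degenerate noise model: m and sigma cannot both be 0")
    I_rec = np.maximum(as_volume(rec_view).values, 0.0)
    return 1.0 / (m * m * I_rec + sigma * sigma)


# ---------------------------------------------------------------------------
# forward-difference gradient and its exact adjoint (Neumann boundaries)

def _fwd_diff(a: np.ndarray, axis: int) -> np.ndarray:
    out = np.zeros_like(a)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    src[axis] = slice(1, None)
    dst[axis] = slice(0, -1)
    out[tuple(dst)] = a[tuple(src)] - a[tuple(dst)]
    return out


def _fwd_diff_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    """Transpose of :func:`_fwd_diff`; equals minus the backward-difference
    divergence with the matching boundary rows."""
    out = np.zeros_like(g)
    n = g.shape[axis]
    idx = lambda s: tuple(s if i == axis else slice(None) for i in range(3))  # noqa: E731
    out[idx(slice(1, None))] = g[idx(slice(0, -1))]
    out[idx(slice(0, n - 1))] -= g[idx(slice(0, n - 1))]
    return out


def _grad_fields(alpha: np.ndarray):
    return tuple(_fwd_diff(alpha, ax) for ax in range(3))


def tv_divergence(alpha, eps_tv: float = 1e-10) -> VolumeGrid:
    """div( grad(alpha) / sqrt(|grad alpha|^2 + eps_tv^2) ) with the
    forward/backward adjoint-pair discretization; minus this field is the
    exact derivative of the discrete TV energy sum."""
    if eps_tv <= 0:
        raise ValueError("eps_tv must be positive")
    vol = as_volume(alpha)
    g = _grad_fields(vol.values)
    norm = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2 + eps_tv ** 2)
    div = np.zeros_like(vol.values)
    for ax in range(3):
        div -= _fwd_diff_adjoint(g[ax] / norm, ax)
    return VolumeGrid(div, vol.spacing)


def _smoothness(alpha: np.ndarray, reg: RegularizerSpec):
    """Raw smoothness energy sum and its exact gradient."""
    g = _grad_fields(alpha)
    g2 = g[0] ** 2 + g[1] ** 2 + g[2] ** 2
    if reg.kind == "tm":
        e = float(g2.sum())
        grad = np.zeros_like(alpha)
        for ax in range(3):
            grad += 2.0 * _fwd_diff_adjoint(g[ax], ax)
    else:
        root = np.sqrt(g2 + reg.eps_tv ** 2)
        e = float(root.sum())
        grad = np.zeros_like(alpha)
        for ax in range(3):
            grad += _fwd_diff_adjoint(g[ax] / root, ax)
    return e, grad


def _sparsity(alpha: np.ndarray, reg: RegularizerSpec):
    root = np.sqrt(alpha ** 2 + reg.eps_sp ** 2)
    return float(root.sum()), alpha / root


# ---------------------------------------------------------------------------
# data term and gradients

def grad_intensity(D1, D2, C1, C2, w1, w2, beta2: float) -> np.ndarray:
    """dE_data/dI(x) = -2 sum_i beta_i D_i C_i^2 w_i."""
    return -2.0 * (D1 * C1 ** 2 * w1 + beta2 * D2 * C2 ** 2 * w2)


def grad_beta(D2, I, C2, w2) -> float:
    """dE_data/dbeta_2 = -2 sum_x D_2 I C_2^2 w_2."""
    return float(-2.0 * np.sum(D2 * I * C2 ** 2 * w2))


def grad_attenuation(
    I,
    alpha,
    beta2: float,
    rays_top,
    rays_bottom,
    C1,
    C2,
    D1,
    D2,
    w1,
    w2,
    reg: RegularizerSpec,
) -> np.ndarray:
    """Full dE/dalpha: adjoint ray accumulation of the per-voxel product
    I * C_i * D_i * w_i for each view (factor 4 beta_i from the squared cone
    transmission), plus the smoothness and sparsity derivatives."""
    grad = np.zeros_like(alpha)
    for beta_i, rays, C, D, w in (
        (1.0, rays_top, C1, D1, w1),
        (beta2, rays_bottom, C2, D2, w2),
    ):
        field = I * C * D * w
        bp = raytrace.backproject_weighted(alpha, rays, field)
        grad += 4.0 * beta_i * bp.values
    if reg.lam > 0:
        grad += reg.lam * _smoothness(alpha, reg)[1]
    if reg.mu > 0:
        grad += reg.mu * _sparsity(alpha, reg)[1]
    return grad


def total_energy(
    state,
    recs: TwoViewRecording,
    reg: RegularizerSpec,
    noise,
    cones,
    compute_gradients: bool = True,
) -> EnergyBreakdown:
    """Evaluate the full objective and (optionally) all analytic gradients.

    ``state`` is ``(I, alpha, beta2)``; ``cones`` is a pair (top, bottom) of
    ConeSpec or RaySet; ``noise`` provides the Poisson scaling ``m`` and
    read-out noise ``sigma`` of the data weights.
    """
    I, alpha, beta2 = state
    I = as_volume(I).values
    alpha = as_volume(alpha).values
    if np.any(alpha < 0) or np.any(I < 0) or beta2 <= 0:
        raise ValueError("constraints violated: need alpha >= 0, I >= 0, beta2 > 0")
    rays_top = raytrace._resolve_rays(cones[0])
    rays_bottom = raytrace._resolve_rays(cones[1])
    w1 = data_weight(recs.top, noise.m, noise.sigma)
    w2 = data_weight(recs.bottom, noise.m, noise.sigma)
    C1 = raytrace.cone_transmission(alpha, rays_top).values
    C2 = raytrace.cone_transmission(alpha, rays_bottom).values
    D1 = recs.top.values - 1.0 * I * C1 ** 2
    D2 = recs.bottom.values - beta2 * I * C2 ** 2
    e_data = float(np.sum(w1 * D1 ** 2) + np.sum(w2 * D2 ** 2))
    e_smooth, g_smooth = _smoothness(alpha, reg)
    e_sparse, g_sparse = _sparsity(alpha, reg)
    e_total = e_data + reg.lam * e_smooth + reg.mu * e_sparse
    if not np.isfinite(e_total):
        raise FloatingPointError("non-finite energy")
    bd = EnergyBreakdown(e_data, e_smooth, e_sparse, e_total)
    if compute_gradients:
        bd.grad_I = grad_intensity(D1, D2, C1, C2, w1, w2, beta2)
        bd.grad_beta2 = grad_beta(D2, I, C2, w2)
        grad = np.zeros_like(alpha)
        for beta_i, rays, C, D, w in (
            (1.0, rays_top, C1, D1, w1),
            (beta2, rays_bottom, C2, D2, w2),
        ):
            field = I * C * D * w
            bp = raytrace.backproject_weighted(alpha, rays, field)
            grad += 4.0 * beta_i * bp.values
        bd.grad_alpha = grad + reg.lam * g_smooth + reg.mu * g_sparse
    return bd
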