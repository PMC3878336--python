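"""Baselines, error metrics, parameter rules of thumb, and the grid-search
evaluation harness.

The one-factor-per-slice model is the classical depth-correction family:
every z-slice of a view is multiplied by a single factor.  Given the true
intensities, the factors minimizing the per-slice squared error have a closed
form, so this baseline is an *oracle upper bound* on everything that family
can achieve — and it still cannot equalize the interior of an attenuated
object, which is the motivation for estimating a full attenuation field.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import RegularizerSpec
from .optimizer import ReconstructionState, SolverConfig, reconstruct
from .phantoms import NoiseParams
from .volume_io import TwoViewRecording, VolumeGrid, as_volume


@dataclass
class SliceCorrection:
    """Per-z-slice correction factors for the two views."""

    c1: np.ndarray
    c2: np.ndarray

    def __post_init__(self) -> None:
        self.c1 = np.asarray(self.c1, float)
        self.c2 = np.asarray(self.c2, float)
        if self.c1.shape != self.c2.shape or self.c1.ndim != 1:
            raise ValueError("c1 and c2 must be 1-D sequences of equal length")


def optimal_slice_factors(recs: TwoViewRecording, I_hat) -> SliceCorrection:
    """Ground-truth-optimal per-slice factors c_i(z) = sum I_hat*I_i / sum I_i^2
    over each slice (0 where a slice carries no signal)."""
    I_hat = as_volume(I_hat).values
    if I_hat.shape != recs.top.shape:
        raise ValueError("I_hat must match the recording shape")
    factors = []
    for view in (recs.top.values, recs.bottom.values):
        num = np.sum(I_hat * view, axis=(1, 2))
        den = np.sum(view ** 2, axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            c = num / den
        c[den == 0] = 0.0
        factors.append(c)
    return SliceCorrection(*factors)


def apply_slice_correction(
    recs: TwoViewRecording, corr: SliceCorrection
) -> tuple[VolumeGrid, VolumeGrid]:
    """Multiply each z-slice of each view by its correction factor."""
    nz = recs.top.shape[0]
    if corr.c1.size != nz:
        raise ValueError(f"correction length {corr.c1.size} does not match nz={nz}")
    top = recs.top.values * corr.c1[:, None, None]
    bottom = recs.bottom.values * corr.c2[:, None, None]
    return (
        VolumeGrid(top, recs.top.spacing),
        VolumeGrid(bottom, recs.bottom.spacing),
    )


def rmse(a, b) -> float:
    """Root mean squared error over all voxels."""
    a = as_volume(a).values
    b = as_volume(b).values
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def suggest_parameters(
    expected_residual: float,
    expected_alpha: float,
    expected_grad: float,
    reg_kind: str = "tm",
) -> tuple[float, float]:
    """Rule-of-thumb prior weights balancing the energy terms.

    With expected data residual r (intensity levels), expected attenuation a
    and attenuation-gradient magnitude g:

        TM: lambda = r^2 / g^2,   TV: lambda = r^2 / g,   mu = r^2 / a.

    Returns the formula values; they are starting points for a grid search,
    not optima.
    """
    if min(expected_residual, expected_alpha, expected_grad) <= 0:
        raise ValueError("all expected magnitudes must be positive")
    r2 = expected_residual ** 2
    if reg_kind.lower() == "tm":
        lam = r2 / expected_grad ** 2
    elif reg_kind.lower() == "tv":
        lam = r2 / expected_grad
    else:
        raise ValueError(f"reg_kind must be 'tm' or 'tv', got {reg_kind!r}")
    return lam, r2 / expected_alpha


def grid_search(
    recs: TwoViewRecording,
    I_true,
    alpha_true,
    lambda_grid,
    mu_grid,
    m_grid,
    reg_kind: str = "tm",
    solver: SolverConfig = SolverConfig(),
    sigma: float = 1.0,
    cones=None,
) -> pd.DataFrame:
    """Exponential grid search over (lambda, mu, m); one reconstruction per
    grid point, reported in the evaluation-table layout
    (m, lambda, mu, E, nIter, beta, rms_I, rms_alpha).  Failures are recorded
    per row without aborting the sweep."""
    rows = []
    for m, lam, mu in itertools.product(m_grid, lambda_grid, mu_grid):
        row = {"m": m, "lambda": lam, "mu": mu}
        try:
            state = reconstruct(
                recs,
                reg=RegularizerSpec(kind=reg_kind, lam=lam, mu=mu),
                noise=NoiseParams(m=m, sigma=sigma),
                cones=cones,
                solver=solver,
            )
            row.update(
                E=state.energy_trace[-1],
                nIter=state.iteration,
                beta=state.beta2,
                rms_I=rmse(state.I, I_true),
                rms_alpha=rmse(state.alpha, alpha_true),
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            row.update(E=np.nan, nIter=0, beta=np.nan, rms_I=np.nan, rms_alpha=np.nan,
                       error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
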