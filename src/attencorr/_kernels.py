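"""Low-level slice-sweep kernels for ray accumulation.

The discrete line integral along a ray is built from a shear sweep: each step
advances exactly one z-slice and applies a constant in-plane bilinear shift
(dy, dx), with zeros outside the volume.  The accumulator

    S(x) = sum_{k >= 1} (W^k v)(x),     (W v)(z, y, x) = bilerp(v[z + dz], y + dy, x + dx)

satisfies the recursion S = W (v + S) and is computed in a single pass over
slices.  Because W is a constant-offset bilinear gather with zero padding, its
transpose is the same gather with negated offsets, so the exact adjoint of the
accumulation is the same sweep run with (-dz, -dy, -dx).  This property is what
makes the analytic attenuation gradient the exact derivative of the discrete
energy.

A numba-compiled kernel is used when numba is importable; the pure-numpy
implementation is the reference and is cross-checked in the tests.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _add_shifted2d(out: np.ndarray, a: np.ndarray, oy: int, ox: int, w: float) -> None:
    """out[y, x] += w * a[y + oy, x + ox] wherever the source index is valid."""
    ny, nx = a.shape
    y0, y1 = max(0, -oy), min(ny, ny - oy)
    x0, x1 = max(0, -ox), min(nx, nx - ox)
    if y1 <= y0 or x1 <= x0:
        return
    out[y0:y1, x0:x1] += w * a[y0 + oy : y1 + oy, x0 + ox : x1 + ox]


def _bilinear_shift2d(a: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Gather a 2-D slice at a constant fractional offset, zero outside."""
    iy = int(np.floor(dy))
    fy = dy - iy
    ix = int(np.floor(dx))
    fx = dx - ix
    out = np.zeros_like(a)
    for oy, wy in ((iy, 1.0 - fy), (iy + 1, fy)):
        if wy == 0.0:
            continue
        for ox, wx in ((ix, 1.0 - fx), (ix + 1, fx)):
            if wx == 0.0:
                continue
            _add_shifted2d(out, a, oy, ox, wy * wx)
    return out


def sweep_accumulate_numpy(vol: np.ndarray, dz: int, dy: float, dx: float) -> np.ndarray:
    """S(x) = sum_{k>=1} bilerp(vol, x + k*(dz, dy, dx)) with zeros outside."""
    nz = vol.shape[0]
    out = np.zeros_like(vol)
    zs = range(1, nz) if dz < 0 else range(nz - 2, -1, -1)
    for z in zs:
        zp = z + dz
        out[z] = _bilinear_shift2d(vol[zp] + out[zp], dy, dx)
    return out


if _HAVE_NUMBA:

    @njit(cache=True)
    def _sweep_accumulate_nb(vol, dz, dy, dx):  # pragma: no cover - numba
        nz, ny, nx = vol.shape
        out = np.zeros_like(vol)
        iy = int(np.floor(dy))
        fy = dy - iy
        ix = int(np.floor(dx))
        fx = dx - ix
        w00 = (1.0 - fy) * (1.0 - fx)
        w01 = (1.0 - fy) * fx
        w10 = fy * (1.0 - fx)
        w11 = fy * fx
        if dz < 0:
            zlo, zhi, zstep = 1, nz, 1
        else:
            zlo, zhi, zstep = nz - 2, -1, -1
        for z in range(zlo, zhi, zstep):
            zp = z + dz
            for y in range(ny):
                ya = y + iy
                yb = ya + 1
                for x in range(nx):
                    xa = x + ix
                    xb = xa + 1
                    acc = 0.0
                    if 0 <= ya < ny:
                        if 0 <= xa < nx:
                            acc += w00 * (vol[zp, ya, xa] + out[zp, ya, xa])
                        if 0 <= xb < nx:
                            acc += w01 * (vol[zp, ya, xb] + out[zp, ya, xb])
                    if 0 <= yb < ny:
                        if 0 <= xa < nx:
                            acc += w10 * (vol[zp, yb, xa] + out[zp, yb, xa])
                        if 0 <= xb < nx:
                            acc += w11 * (vol[zp, yb, xb] + out[zp, yb, xb])
                    out[z, y, x] = acc
        return out


def sweep_accumulate(vol: np.ndarray, dz: int, dy: float, dx: float) -> np.ndarray:
    """Ray accumulation S = sum_{k>=1} W^k vol along step (dz, dy, dx), |dz| = 1.

    Single-threaded and bit-deterministic on both code paths.
    """
    vol = np.ascontiguousarray(vol, dtype=np.float64)
    if _HAVE_NUMBA:
        return _sweep_accumulate_nb(vol, dz, float(dy), float(dx))
    return sweep_accumulate_numpy(vol, dz, dy, dx)
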