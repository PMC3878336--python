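"""3-D volume containers and I/O: TIFF/HDF5 reading and writing, sub-sampling,
background-offset removal, and confidence-weighted fusion of corrected views.

Axis order is fixed to ``(z, y, x)`` with z the depth axis along the optical
axis; the top view's lens sits at ``z = 0``, the bottom view's at ``z = nz-1``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile
from scipy import ndimage


class VolumeFormatError(ValueError):
    """Raised when a file cannot be interpreted as a 3-D volume."""


@dataclass
class VolumeGrid:
    """A scalar field sampled on a regular voxel lattice.

    Parameters
    ----------
    values
        3-D array in ``(z, y, x)`` order.  Intensity volumes (levels) or
        attenuation fields (per voxel-length).
    spacing
        Physical voxel extents in micrometres per axis, ``(dz, dy, dx)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3-D field, got ndim={self.values.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive extents, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.values.copy(), self.spacing)


def as_volume(obj, spacing=(1.0, 1.0, 1.0)) -> VolumeGrid:
    """Coerce an array or VolumeGrid to a VolumeGrid."""
    if isinstance(obj, VolumeGrid):
        return obj
    return VolumeGrid(np.asarray(obj, dtype=np.float64), spacing)


@dataclass
class TwoViewRecording:
    """A pair of co-registered recordings of the same sample from opposite
    sides (registration is a precondition, not performed here)."""

    top: VolumeGrid
    bottom: VolumeGrid
    offsets: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.top.shape != self.bottom.shape:
            raise ValueError(
                f"views must share a voxel grid: {self.top.shape} vs {self.bottom.shape}"
            )


def read_volume(path: str | os.PathLike, spacing=None) -> VolumeGrid:
    """Read a multi-page TIFF stack or an HDF5 volume.

    Voxel spacing is taken from file metadata when present
    (``element_size_um`` attribute for HDF5, ImageJ metadata for TIFF),
    else from the ``spacing`` override, else 1 um isotropic.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".h5", ".hdf5", ".he5"):
            with h5py.File(path, "r") as f:
                name = "volume" if "volume" in f else _first_3d_dataset(f)
                dset = f[name]
                values = np.asarray(dset[()], dtype=np.float64)
                meta = dset.attrs.get("element_size_um")
                if spacing is None and meta is not None:
                    spacing = tuple(float(s) for s in np.asarray(meta).ravel())
        else:
            with tifffile.TiffFile(path) as tf:
                values = np.asarray(tf.asarray(), dtype=np.float64)
                if spacing is None:
                    spacing = _tiff_spacing(tf)
    except VolumeFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise VolumeFormatError(f"cannot read volume from {path!r}: {exc}") from exc
    if values.ndim != 3:
        raise VolumeFormatError(f"{path!r} does not contain a 3-D volume (ndim={values.ndim})")
    return VolumeGrid(values, spacing if spacing is not None else (1.0, 1.0, 1.0))


def _first_3d_dataset(f: h5py.File) -> str:
    names: list[str] = []
    f.visit(names.append)
    for name in names:
        if isinstance(f[name], h5py.Dataset) and f[name].ndim == 3:
            return name
    raise VolumeFormatError(f"no 3-D dataset found in {f.filename!r}")


def _tiff_spacing(tf: tifffile.TiffFile):
    meta = tf.imagej_metadata or {}
    dz = meta.get("spacing")
    page = tf.pages[0]
    res = page.tags.get("XResolution")
    dx = dy = None
    if res is not None and res.value[0] > 0:
        dx = dy = res.value[1] / res.value[0]
    if dz is not None and dx is not None:
        return (float(dz), float(dy), float(dx))
    return None


def write_volume(vol: VolumeGrid, path: str | os.PathLike, dtype=None) -> None:
    """Write a volume as multi-page TIFF or HDF5 (chosen by extension).

    ``dtype`` converts on write; requesting an unsigned integer type for a
    field with negative values is rejected (information would be destroyed).
    """
    path = os.fspath(path)
    values = vol.values
    if dtype is not None:
        dtype = np.dtype(dtype)
        if dtype.kind == "u" and values.min() < 0:
            raise ValueError(
                "volume contains negative values; refusing lossy cast to "
                f"unsigned type {dtype}"
            )
        values = values.astype(dtype)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5", ".he5"):
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("volume", data=values)
            dset.attrs["element_size_um"] = np.asarray(vol.spacing, dtype=np.float64)
    else:
        dz, dy, dx = vol.spacing
        kwargs = {}
        if values.dtype in (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)):
            kwargs = {
                "imagej": True,
                "resolution": (1.0 / dx, 1.0 / dy),
                "metadata": {"spacing": dz, "unit": "um"},
            }
        tifffile.imwrite(path, values, **kwargs)


def subsample(vol: VolumeGrid, target_shape) -> VolumeGrid:
    """Down-sample by weighted averaging; spacing is rescaled accordingly.

    Integer reduction factors use exact block means (this is the noise
    reduction step normally applied before reconstruction); non-integer
    factors use a uniform pre-filter followed by linear resampling.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if len(target_shape) != 3 or any(n < 1 for n in target_shape):
        raise ValueError(f"target_shape must be 3 positive counts, got {target_shape}")
    if any(t > s for t, s in zip(target_shape, vol.shape)):
        raise ValueError(
            f"subsample cannot upsample: target {target_shape} exceeds shape {vol.shape}"
        )
    factors = tuple(s / t for s, t in zip(vol.shape, target_shape))
    new_spacing = tuple(sp * f for sp, f in zip(vol.spacing, factors))
    if all(s % t == 0 for s, t in zip(vol.shape, target_shape)):
        f = tuple(s // t for s, t in zip(vol.shape, target_shape))
        v = vol.values.reshape(
            target_shape[0], f[0], target_shape[1], f[1], target_shape[2], f[2]
        )
        out = v.mean(axis=(1, 3, 5))
        return VolumeGrid(out, new_spacing)
    size = tuple(max(1, int(np.ceil(f))) for f in factors)
    smoothed = ndimage.uniform_filter(vol.values, size=size, mode="nearest")
    coords = np.meshgrid(
        *[(np.arange(t) + 0.5) * f - 0.5 for t, f in zip(target_shape, factors)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(smoothed, coords, order=1, mode="nearest")
    return VolumeGrid(out, new_spacing)


def subtract_background_offset(vol: VolumeGrid) -> tuple[VolumeGrid, float]:
    """Estimate the background offset as the mode of the integer-binned
    intensity histogram (bin width 1, ties to the lowest bin) and subtract
    it, clamping at zero."""
    if vol.values.size == 0:
        raise ValueError("cannot estimate a background offset from an empty volume")
    binned = np.maximum(np.rint(vol.values), 0).astype(np.int64)
    offset = float(np.argmax(np.bincount(binned.ravel())))
    corrected = np.maximum(vol.values - offset, 0.0)
    return VolumeGrid(corrected, vol.spacing), offset


def fuse_views(
    rec_top: VolumeGrid,
    rec_bottom: VolumeGrid,
    conf_top: VolumeGrid,
    conf_bottom: VolumeGrid,
) -> VolumeGrid:
    """Fuse two corrected views by a per-voxel convex combination weighted by
    confidence fields (typically the squared cone transmissions ``C_i**2``,
    the model's per-voxel signal retention).  Where both confidences vanish
    the output is 0.
    """
    grids = (rec_top, rec_bottom, conf_top, conf_bottom)
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError(f"all four grids must share a shape, got {shapes}")
    w1 = np.maximum(conf_top.values, 0.0)
    w2 = np.maximum(conf_bottom.values, 0.0)
    total = w1 + w2
    with np.errstate(invalid="ignore", divide="ignore"):
        fused = (w1 * rec_top.values + w2 * rec_bottom.values) / total
    fused[total == 0] = 0.0
    return VolumeGrid(fused, rec_top.spacing)
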