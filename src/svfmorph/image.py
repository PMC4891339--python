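"""Image and field containers, NIfTI I/O, interpolation, smoothing, pyramids.

All in-memory fields live in *voxel units* on grids that are assumed (and
checked at load time) to have isotropic spacing; conversion to millimetres
happens only when reading from or writing to NIfTI.  Displacements and
velocities therefore compose directly with array indices, which keeps the
integration and ladder-step voxel thresholds free of unit juggling.

Out-of-domain samples evaluate to 0 for every interpolation, matching the
modelling assumption that velocity fields vanish away from the head.
Smoothing uses reflective boundary conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ScalarImage", "Svf", "DeformationField", "ConfidenceMask",
    "read_image", "write_image", "read_vector_field", "write_vector_field",
    "read_mask", "resample", "warp_vector_field", "gaussian_smooth",
    "build_pyramid", "downsample_vector_field", "upsample_vector_field",
]

_ISOTROPY_RTOL = 1e-3


def _check_isotropic(spacing: np.ndarray) -> float:
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    if np.max(np.abs(spacing - spacing[0])) > _ISOTROPY_RTOL * spacing[0]:
        raise ValueError(
            f"anisotropic spacing {spacing} not supported; resample to an "
            "isotropic grid first"
        )
    return float(spacing[0])


@dataclass
class ScalarImage:
    """A 3D scalar intensity grid with geometry.

    Parameters
    ----------
    data
        3D array of finite intensities.
    spacing
        Isotropic voxel edge length in mm.
    affine
        Voxel-to-world 4x4 matrix kept for round-trip I/O fidelity.
    """

    data: np.ndarray
    spacing: float = 1.0
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != np.float32:  # float32 kept for fast paths
            self.data = self.data.astype(np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite voxels")
        if self.affine is None:
            self.affine = np.diag([self.spacing] * 3 + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "ScalarImage":
        """New image on the same geometry."""
        return ScalarImage(data, spacing=self.spacing, affine=self.affine.copy())

    def same_grid(self, other) -> bool:
        return self.shape == tuple(other.shape)


@dataclass
class _VectorField:
    """Shared behaviour of velocity and displacement fields (voxel units)."""

    data: np.ndarray
    spacing: float = 1.0
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != np.float32:
            self.data = self.data.astype(np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(
                f"expected a (nx, ny, nz, 3) grid, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("vector field contains non-finite components")
        if self.affine is None:
            self.affine = np.diag([self.spacing] * 3 + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    def with_data(self, data: np.ndarray):
        return type(self)(data, spacing=self.spacing, affine=self.affine.copy())

    def same_grid(self, other) -> bool:
        return self.shape == tuple(other.shape)

    def max_norm(self) -> float:
        """Largest voxel-unit vector magnitude on the grid."""
        return float(np.sqrt((self.data ** 2).sum(axis=-1)).max())


class Svf(_VectorField):
    """Stationary velocity field v; exp(v) parameterizes a diffeomorphism.

    SVFs form an additive group voxelwise: ``v.with_data(v.data + w.data)``
    is the Lie-algebra sum.
    """


class DeformationField(_VectorField):
    """Displacement field d of a deformation phi(x) = x + d(x), voxel units."""


@dataclass
class ConfidenceMask:
    """Voxelwise weight in [0, 1] for the similarity term of the registration."""

    values: np.ndarray
    spacing: float = 1.0
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.values.ndim}")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("confidence values must lie in [0, 1]")
        if self.affine is None:
            self.affine = np.diag([self.spacing] * 3 + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_grid(self, other) -> bool:
        return self.shape == tuple(other.shape)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_image(path: str | Path) -> ScalarImage:
    """Read a 3D scalar NIfTI-1 volume.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    ValueError
        If the payload is not 3D or contains non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar volume, got {data.shape}")
    spacing = _check_isotropic(img.header.get_zooms()[:3])
    return ScalarImage(data, spacing=spacing, affine=np.asarray(img.affine))


def write_image(image: ScalarImage, path: str | Path) -> None:
    """Write a scalar image as single-precision NIfTI-1."""
    out = nib.Nifti1Image(image.data.astype(np.float32), image.affine)
    out.header.set_zooms((image.spacing,) * 3)
    nib.save(out, str(path))


def read_vector_field(path: str | Path, kind: type = Svf):
    """Read a 3-component NIfTI (4th dimension of size 3) as ``kind``.

    On-disk components are millimetres; they are divided by the isotropic
    voxel spacing on load so that the in-memory field is in voxel units.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 5 and data.shape[3] == 1:  # ITK-style (x,y,z,1,3) layout
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a (nx, ny, nz, 3) field, got {data.shape}")
    spacing = _check_isotropic(img.header.get_zooms()[:3])
    return kind(data / spacing, spacing=spacing, affine=np.asarray(img.affine))


def write_vector_field(field_obj, path: str | Path) -> None:
    """Write a velocity/displacement field as mm-valued 4D NIfTI."""
    mm = (field_obj.data * field_obj.spacing).astype(np.float32)
    out = nib.Nifti1Image(mm, field_obj.affine)
    nib.save(out, str(path))


def read_mask(path: str | Path) -> ConfidenceMask:
    """Read a [0, 1]-valued NIfTI mask; values are clipped to [0, 1]."""
    img = read_image(path)
    return ConfidenceMask(np.clip(img.data, 0.0, 1.0), spacing=img.spacing,
                          affine=img.affine)


# ---------------------------------------------------------------------------
# Interpolation / resampling

_ORDERS = {"linear": 1, "bspline3": 3}


_COORD_CACHE: dict = {}


def _identity_coords(shape: tuple[int, int, int],
                     dtype=np.float64) -> np.ndarray:
    """(3, nx, ny, nz) voxel index grid (cached; treat as read-only)."""
    key = (shape, np.dtype(dtype).char)
    if key not in _COORD_CACHE:
        if len(_COORD_CACHE) > 16:
            _COORD_CACHE.clear()
        _COORD_CACHE[key] = np.mgrid[
            0:shape[0], 0:shape[1], 0:shape[2]].astype(dtype)
    return _COORD_CACHE[key]


def sample_at(volume: np.ndarray, coords: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample ``volume`` at voxel coordinates ``coords`` ((3, ...) array).

    Outside-domain samples return 0.
    """
    return ndimage.map_coordinates(volume, coords, order=order, mode="constant",
                                   cval=0.0, prefilter=(order > 1))


def resample(image: ScalarImage, deformation: DeformationField,
             interpolation: str = "linear") -> ScalarImage:
    """Pull an image back through a deformation: out(x) = image(x + d(x)).

    Parameters
    ----------
    interpolation
        ``"linear"`` or ``"bspline3"`` (cubic B-spline).
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if not image.same_grid(deformation):
        raise ValueError(
            f"geometry mismatch: image {image.shape} vs deformation "
            f"{deformation.shape}")
    coords = (_identity_coords(image.shape, deformation.data.dtype)
              + np.moveaxis(deformation.data, -1, 0))
    return image.with_data(sample_at(image.data, coords, _ORDERS[interpolation]))


def warp_vector_field(vec: np.ndarray, deformation_data: np.ndarray) -> np.ndarray:
    """Sample each component of ``vec`` ((..., 3)) at x + d(x) (linear)."""
    coords = (_identity_coords(vec.shape[:3], deformation_data.dtype)
              + np.moveaxis(deformation_data, -1, 0))
    out = np.empty_like(vec)
    for c in range(3):
        out[..., c] = sample_at(vec[..., c], coords, order=1)
    return out


# ---------------------------------------------------------------------------
# Smoothing and pyramids


def gaussian_smooth(obj, sigma: float):
    """Gaussian-smooth an image, field, mask or ndarray.

    ``sigma`` is in grid units of the object's own grid (so coarser pyramid
    levels use the same nominal value).  ``sigma == 0`` returns the input
    unchanged.  Vector fields are smoothed component-wise over the three
    spatial axes only; boundaries are handled by reflection.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return obj
    if isinstance(obj, np.ndarray):
        if obj.ndim == 4:
            return _smooth_vec(obj, sigma)
        return ndimage.gaussian_filter(obj, sigma, mode="reflect")
    if isinstance(obj, (Svf, DeformationField)):
        return obj.with_data(_smooth_vec(obj.data, sigma))
    if isinstance(obj, ScalarImage):
        return obj.with_data(ndimage.gaussian_filter(obj.data, sigma, mode="reflect"))
    if isinstance(obj, ConfidenceMask):
        sm = ndimage.gaussian_filter(obj.values, sigma, mode="reflect")
        return ConfidenceMask(np.clip(sm, 0.0, 1.0), spacing=obj.spacing,
                              affine=obj.affine.copy())
    raise TypeError(f"cannot smooth object of type {type(obj)}")


def _smooth_vec(data: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(data, (sigma, sigma, sigma, 0), mode="reflect")


_ANTIALIAS_SIGMA = 1.0  # grid units, applied before 2x decimation


def build_pyramid(image: ScalarImage, levels: int) -> list[ScalarImage]:
    """Multi-resolution pyramid, level 0 = full resolution.

    Each coarser level smooths with a fixed antialiasing kernel then keeps
    every second voxel; spacing doubles accordingly.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    out = [image]
    for _ in range(1, levels):
        prev = out[-1]
        sm = ndimage.gaussian_filter(prev.data, _ANTIALIAS_SIGMA, mode="reflect")
        dec = sm[::2, ::2, ::2]
        out.append(ScalarImage(dec, spacing=prev.spacing * 2))
    return out


def downsample_vector_field(v, levels: int):
    """Decimate a voxel-unit field to pyramid level ``levels`` (halving magnitudes)."""
    data = v.data
    spacing = v.spacing
    for _ in range(levels):
        data = _smooth_vec(data, _ANTIALIAS_SIGMA)[::2, ::2, ::2, :] / 2.0
        spacing *= 2
    return type(v)(data, spacing=spacing)


def upsample_vector_field(v, target_shape: tuple[int, int, int], spacing: float | None = None):
    """Resample a voxel-unit field onto a grid twice as fine (doubling magnitudes)."""
    factors = [t / s for t, s in zip(target_shape, v.shape)]
    out = np.empty(tuple(target_shape) + (3,), dtype=np.float64)
    for c in range(3):
        out[..., c] = ndimage.zoom(v.data[..., c], factors, order=1,
                                   mode="nearest", grid_mode=False)
    scale = float(np.mean(factors))
    return type(v)(out * scale, spacing=spacing if spacing is not None
                   else v.spacing / scale)
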