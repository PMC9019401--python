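"""Attenuation volumes: container, synthetic phantoms, gradients, NIfTI I/O.

The central object is :class:`AttenuationVolume`, a non-negative scalar field
delta(x) on a regular grid with physical voxel spacing.  Every acoustic kernel
reads this medium: reflection and transmission are driven by the spatial
gradient of delta, normalised by the volume-wide maximum ``max_delta``.

Conventions
-----------
Voxel indexing is 0-based and physical position is ``origin + index * spacing``
(voxel-center convention).  Axis 2 (the last axis) is the depth axis used by
the default beam geometry.  Default spacing is (0.59, 0.59, 0.6) mm: 0.6 mm
between slices and 0.59 mm between in-plane pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from echoray.errors import ConfigurationError, DomainError, FormatError

#: Default in-plane / slice spacing in mm.
DEFAULT_SPACING = (0.59, 0.59, 0.6)

#: Default full-size grid (as acquired clinically); phantoms for testing use
#: much smaller grids.  The odd 521 first dimension is kept as documented
#: rather than silently rounded to 512.
DEFAULT_GRID_SHAPE = (521, 512, 344)


class AttenuationVolume:
    """A 3D non-negative attenuation field delta(x) on a regular grid.

    Parameters
    ----------
    values
        3D array of attenuation values, all >= 0.
    spacing
        Physical voxel step per axis in mm, all > 0.
    origin
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    def __init__(
        self,
        values: np.ndarray,
        spacing: Sequence[float] = DEFAULT_SPACING,
        origin: Sequence[float] = (0.0, 0.0, 0.0),
    ):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise FormatError(f"values must be a 3D array, got ndim={values.ndim}")
        if values.size == 0:
            raise ConfigurationError("values must be non-empty")
        if np.any(values < 0):
            raise DomainError("attenuation values must be non-negative")
        spacing = np.asarray(spacing, dtype=float)
        if spacing.shape != (3,) or np.any(spacing <= 0):
            raise ConfigurationError(f"spacing must be 3 positive floats, got {spacing}")
        self.values = values
        self.spacing = spacing
        self.origin = np.asarray(origin, dtype=float)
        self.max_delta = float(values.max())
        self._gradient_field: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    # -- coordinate transforms ------------------------------------------------

    def to_index(self, position: Sequence[float]) -> np.ndarray:
        """Physical position (mm) -> fractional voxel index."""
        return (np.asarray(position, dtype=float) - self.origin) / self.spacing

    def contains(self, position: Sequence[float]) -> bool:
        """True if the physical position lies within the voxel-center bounds."""
        idx = self.to_index(position)
        return bool(np.all(idx >= 0) and np.all(idx <= np.array(self.shape) - 1))

    # -- gradient sampling ----------------------------------------------------

    def gradient_field(self) -> np.ndarray:
        """Per-voxel gradient of delta, shape (3, *grid), units per mm.

        Central differences in the interior, one-sided on boundary faces;
        computed once and cached.
        """
        if self._gradient_field is None:
            grads = np.gradient(self.values, *self.spacing, edge_order=1)
            self._gradient_field = np.stack(grads, axis=0)
        return self._gradient_field

    def sample_gradient(self, positions: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated gradient at physical positions (N, 3) -> (N, 3)."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        idx = (positions - self.origin) / self.spacing  # (N, 3) fractional
        lo = idx < -1e-9
        hi = idx > (np.array(self.shape) - 1) + 1e-9
        if np.any(lo | hi):
            bad = positions[np.any(lo | hi, axis=1)][0]
            raise DomainError(f"position {tuple(bad)} mm is outside the volume")
        coords = idx.T  # (3, N) for map_coordinates
        field = self.gradient_field()
        out = np.empty_like(positions)
        for axis in range(3):
            out[:, axis] = map_coordinates(field[axis], coords, order=1, mode="nearest")
        return out


@dataclass(frozen=True)
class Layer:
    """A depth-stratified medium: delta applies for depth >= boundary_mm."""

    boundary_mm: float
    delta: float


@dataclass(frozen=True)
class Inclusion:
    """A spherical or ellipsoidal region of constant delta."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    delta: float
    shape: Literal["sphere", "ellipsoid"] = "ellipsoid"


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic attenuation phantom.

    A phantom starts as a uniform background, is overridden by depth layers
    in order (along axis 2), then by inclusions, then optional additive
    Gaussian texture noise clipped at zero.
    """

    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_delta: float = 1.0
    layers: tuple[Layer, ...] = ()
    inclusions: tuple[Inclusion, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(int(s) <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ConfigurationError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.background_delta < 0:
            raise ConfigurationError("background_delta must be >= 0")
        bounds = [ly.boundary_mm for ly in self.layers]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ConfigurationError(f"layer boundaries must be strictly increasing: {bounds}")
        if any(ly.delta < 0 for ly in self.layers):
            raise ConfigurationError("layer delta values must be >= 0")
        for inc in self.inclusions:
            if inc.delta < 0:
                raise ConfigurationError("inclusion delta must be >= 0")
            if any(r <= 0 for r in inc.radii_mm):
                raise ConfigurationError("inclusion radii must be > 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        """Load a spec from a JSON document mirroring the dataclass fields."""
        doc = json.loads(Path(path).read_text())
        layers = tuple(Layer(**ly) for ly in doc.pop("layers", []))
        inclusions = tuple(
            Inclusion(
                center_mm=tuple(inc["center_mm"]),
                radii_mm=tuple(inc["radii_mm"]),
                delta=inc["delta"],
                shape=inc.get("shape", "ellipsoid"),
            )
            for inc in doc.pop("inclusions", [])
        )
        for key in ("grid_shape", "spacing", "origin"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(layers=layers, inclusions=inclusions, **doc)


def make_phantom(spec: PhantomSpec) -> AttenuationVolume:
    """Build a synthetic attenuation volume from a :class:`PhantomSpec`.

    Deterministic given (spec, seed): the texture noise flows through a
    generator seeded with ``spec.seed``.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    values = np.full(shape, float(spec.background_delta))

    # physical coordinate grids (voxel centers)
    axes = [spec.origin[a] + np.arange(shape[a]) * spec.spacing[a] for a in range(3)]

    for layer in spec.layers:
        mask = axes[2] >= layer.boundary_mm
        values[:, :, mask] = layer.delta

    if spec.inclusions:
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        for inc in spec.inclusions:
            rx, ry, rz = inc.radii_mm
            if inc.shape == "sphere":
                rx = ry = rz = inc.radii_mm[0]
            dist2 = (
                ((xx - inc.center_mm[0]) / rx) ** 2
                + ((yy - inc.center_mm[1]) / ry) ** 2
                + ((zz - inc.center_mm[2]) / rz) ** 2
            )
            values[dist2 <= 1.0] = inc.delta

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=shape)
        np.clip(values, 0.0, None, out=values)

    return AttenuationVolume(values, spacing=spec.spacing, origin=spec.origin)


def estimate_gradient(volume: AttenuationVolume, voxel_index: Sequence[int]) -> np.ndarray:
    """Finite-difference gradient of delta at one voxel, in units per mm.

    Central differences in the interior; one-sided differences on boundary
    faces (zero-padding would fabricate interfaces at the volume edge).
    """
    idx = tuple(int(i) for i in voxel_index)
    shape = volume.shape
    if len(idx) != 3 or any(i < 0 or i >= shape[a] for a, i in enumerate(idx)):
        raise DomainError(f"voxel index {idx} out of bounds for shape {shape}")
    v = volume.values
    grad = np.empty(3)
    for axis in range(3):
        i = idx[axis]
        h = volume.spacing[axis]
        lo = list(idx)
        hi = list(idx)
        if shape[axis] == 1:
            grad[axis] = 0.0
            continue
        if i == 0:
            hi[axis] = 1
            grad[axis] = (v[tuple(hi)] - v[tuple(idx)]) / h
        elif i == shape[axis] - 1:
            lo[axis] = i - 1
            grad[axis] = (v[tuple(idx)] - v[tuple(lo)]) / h
        else:
            lo[axis] = i - 1
            hi[axis] = i + 1
            grad[axis] = (v[tuple(hi)] - v[tuple(lo)]) / (2 * h)
    return grad


def write_volume(volume: AttenuationVolume, path: str | Path) -> None:
    """Write a volume as single-scalar NIfTI with spacing in the header zooms."""
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> AttenuationVolume:
    """Read a scalar 3D NIfTI volume; spacing comes from the header zooms (mm)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got ndim={data.ndim} in {path.name}")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(z <= 0 for z in zooms):
        raise FormatError(f"missing or invalid spacing metadata (zooms={zooms}) in {path.name}")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return AttenuationVolume(data, spacing=zooms, origin=origin)
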