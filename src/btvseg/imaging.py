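"""Geometry-aware volumetric image and mask types.

World coordinates are millimetres in the LPS (left-posterior-superior)
convention used by DICOM-derived tooling; voxel indices are 0-based and a
voxel is represented by its centre (no fractional/partial voxels).  All
volumes are reported in millilitres: ``voxel volume [ml] = prod(spacing
mm) / 1000``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageGeometry",
    "SUVImage",
    "StructureMask",
    "VOISphere",
    "suv_from_activity",
    "resample_mask",
    "rasterize_sphere",
]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class ImageGeometry:
    """Regular 3-D voxel grid embedded in world (mm, LPS) space.

    Parameters
    ----------
    shape
        Voxel counts per axis (3 positive ints).
    spacing
        Voxel edge lengths in mm per axis (3 strictly positive reals).
    origin
        World position (mm) of the centre of voxel (0, 0, 0).
    orientation
        3x3 orthonormal direction-cosine matrix; columns are the world
        directions of the three index axes.  Defaults to identity.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[tuple[float, ...], ...] = field(
        default=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    )

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape!r}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing!r}")
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("orientation must be a 3x3 orthonormal matrix")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "orientation", tuple(tuple(row) for row in R))

    # -- derived quantities -------------------------------------------------

    @property
    def rotation(self) -> np.ndarray:
        return np.asarray(self.orientation, dtype=float)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to world mm."""
        idx = np.asarray(index, dtype=float)
        return idx * np.asarray(self.spacing) @ self.rotation.T + np.asarray(self.origin)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (..., 3) to continuous voxel indices."""
        pts = np.asarray(points, dtype=float) - np.asarray(self.origin)
        return pts @ self.rotation / np.asarray(self.spacing)

    def voxel_centres(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"), axis=-1
        )
        return self.index_to_world(idx)

    def approx_equal(self, other: "ImageGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.rotation, other.rotation, atol=tol)
        )


def _check_geometry(values: np.ndarray, geometry: ImageGeometry) -> None:
    if tuple(values.shape) != tuple(geometry.shape):
        raise ValueError(
            f"array shape {values.shape} does not match geometry shape {geometry.shape}"
        )


@dataclass
class SUVImage:
    """Scalar PET field in body-weight SUV units (dimensionless g/ml)."""

    geometry: ImageGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_geometry(self.values, self.geometry)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")


@dataclass
class StructureMask:
    """Binary voxel mask (GTV, BTV, VOI, ...) on a stated grid."""

    geometry: ImageGeometry
    voxels: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        _check_geometry(self.voxels, self.geometry)

    @property
    def volume_ml(self) -> float:
        return int(self.voxels.sum()) * self.geometry.voxel_volume_ml

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def with_label(self, label: str) -> "StructureMask":
        return StructureMask(self.geometry, self.voxels, label)


@dataclass(frozen=True)
class VOISphere:
    """Spherical volume of interest given by centre (world mm) and volume (ml)."""

    centre: tuple[float, float, float]
    volume_ml: float

    def __post_init__(self) -> None:
        if not self.volume_ml > 0:
            raise ValueError("sphere volume must be positive")
        object.__setattr__(self, "centre", tuple(float(c) for c in self.centre))

    @property
    def radius_mm(self) -> float:
        # V [ml] = 1000 mm^3 -> r = (3 V / 4 pi)^(1/3)
        return float((3.0 * self.volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def suv_from_activity(
    activity_kbq_ml: np.ndarray,
    geometry: ImageGeometry,
    injected_dose_mbq: float,
    body_weight_kg: float,
) -> SUVImage:
    """Convert an activity-concentration map to body-weight SUV.

    SUV = activity [kBq/ml] x body weight [kg] / injected dose [MBq],
    the standard body-weight convention (tissue density 1 g/ml).
    """
    if not injected_dose_mbq > 0:
        raise ValueError("injected dose must be positive")
    if not body_weight_kg > 0:
        raise ValueError("body weight must be positive")
    act = np.asarray(activity_kbq_ml, dtype=float)
    if not np.all(np.isfinite(act)) or np.any(act < 0):
        raise ValueError("activity must be finite and non-negative")
    return SUVImage(geometry, act * body_weight_kg / injected_dose_mbq)


def resample_mask(
    mask: StructureMask, target: ImageGeometry, method: str = "nearest"
) -> StructureMask:
    """Resample a binary mask onto another grid (nearest neighbour only).

    Each target voxel takes the value of the source voxel whose centre is
    nearest (in world mm) to the target voxel centre; target voxels whose
    centres fall outside the source grid extent become False.  Nearest
    neighbour preserves binarity; this is how a thresholded PET VOI is
    back-projected onto the planning-CT grid.
    """
    if method != "nearest":
        raise ValueError(f"unsupported mask resampling method {method!r}")
    if mask.geometry.approx_equal(target):
        return StructureMask(target, mask.voxels.copy(), mask.label)
    centres = target.voxel_centres().reshape(-1, 3)
    src_idx = mask.geometry.world_to_index(centres)
    nearest = np.rint(src_idx).astype(int)
    shape = np.asarray(mask.geometry.shape)
    inside = np.all((nearest >= 0) & (nearest < shape), axis=1)
    out = np.zeros(len(centres), dtype=bool)
    if inside.any():
        sel = nearest[inside]
        out[inside] = mask.voxels[sel[:, 0], sel[:, 1], sel[:, 2]]
    else:
        warnings.warn(
            "source and target grids do not overlap; returning empty mask",
            stacklevel=2,
        )
    return StructureMask(target, out.reshape(target.shape), mask.label)


def rasterize_sphere(sphere: VOISphere, geometry: ImageGeometry) -> StructureMask:
    """Rasterize a sphere: a voxel is True iff its centre lies within radius."""
    centres = geometry.voxel_centres()
    d2 = np.sum((centres - np.asarray(sphere.centre)) ** 2, axis=-1)
    voxels = d2 <= sphere.radius_mm**2
    if not voxels.any():
        warnings.warn("sphere lies entirely outside the grid; mask is empty", stacklevel=2)
    return StructureMask(geometry, voxels, label="VOI_sphere")
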