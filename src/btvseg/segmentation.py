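"""Automated biological-target-volume (BTV) segmentation of FDG-PET lesions.

Two families of algorithms, both producing a single connected lesion VOI
grown from the lesion's SUV_max voxel:

* fixed-percentage thresholds — voxels at or above ``percent x SUV_max``
  of the search region (the study set: 38%, 42%, 47%, 50%);
* PERCIST-TLG background-adaptive threshold — voxels at or above
  ``liver mean SUV + sd_multiplier x liver SD``, the liver statistics
  measured in a fixed-volume (15 ml) hepatic VOI.

The search region must be supplied by the caller (a generous box or mask
around the tumour): an unguided whole-body search would capture brain or
bladder uptake.  Thresholds are relative to the region's own SUV_max, not
a global image maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .imaging import ImageGeometry, StructureMask, SUVImage, VOISphere, rasterize_sphere

__all__ = [
    "ThresholdSpec",
    "SearchRegion",
    "BackgroundStats",
    "LesionNotAboveBackgroundWarning",
    "PERCENT_THRESHOLDS",
    "ALGORITHM_NAMES",
    "lesion_suv_max",
    "percent_threshold_btv",
    "background_stats",
    "percist_tlg_btv",
    "exclude_structures",
    "segment_lesion",
    "run_all_algorithms",
]

#: The study's fixed-percentage threshold set, as fractions of SUV_max.
PERCENT_THRESHOLDS: tuple[float, ...] = (0.38, 0.42, 0.47, 0.50)

#: Canonical algorithm labels used in cohort tables.
ALGORITHM_NAMES: tuple[str, ...] = ("SUV38", "SUV42", "SUV47", "SUV50", "PERCIST")


class LesionNotAboveBackgroundWarning(UserWarning):
    """Lesion SUV_max below the background-adaptive threshold (PET-negative)."""


@dataclass(frozen=True)
class ThresholdSpec:
    """Segmentation recipe.

    ``percent_of_max`` mode uses ``percent`` (fraction of region SUV_max);
    ``percist_tlg`` mode uses ``background_voi`` and ``sd_multiplier`` to
    form the absolute threshold ``liver mean + sd_multiplier x liver SD``.
    """

    mode: Literal["percent_of_max", "percist_tlg"]
    percent: float | None = None
    sd_multiplier: float = 3.0
    background_voi: VOISphere | None = None

    def __post_init__(self) -> None:
        if self.mode == "percent_of_max":
            if self.percent is None or not 0 < self.percent <= 1:
                raise ValueError("percent must lie in (0, 1]")
        elif self.mode == "percist_tlg":
            if self.sd_multiplier < 0:
                raise ValueError("sd_multiplier must be >= 0")
            if self.background_voi is None:
                raise ValueError("percist_tlg mode requires a background VOI")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SearchRegion:
    """Mask restricting where the lesion is sought (e.g. a tumour bounding box)."""

    mask: StructureMask

    def __post_init__(self) -> None:
        if self.mask.is_empty:
            raise ValueError("search region must be nonempty")

    @classmethod
    def from_box(
        cls,
        geometry: ImageGeometry,
        centre_mm: tuple[float, float, float],
        half_extent_mm: tuple[float, float, float],
    ) -> "SearchRegion":
        """Axis-aligned (in index space) box around a world-mm centre."""
        centres = geometry.voxel_centres()
        inside = np.all(
            np.abs(centres - np.asarray(centre_mm)) <= np.asarray(half_extent_mm),
            axis=-1,
        )
        return cls(StructureMask(geometry, inside, label="search_region"))


@dataclass(frozen=True)
class BackgroundStats:
    """Normal-background SUV statistics from the hepatic reference VOI."""

    mean_suv: float
    sd_suv: float
    n_voxels: int

    def threshold(self, sd_multiplier: float) -> float:
        return self.mean_suv + sd_multiplier * self.sd_suv


def _connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be one of 6, 18, 26") from None
    return ndimage.generate_binary_structure(3, rank)


def _check_region(pet: SUVImage, region: SearchRegion) -> None:
    if not region.mask.geometry.approx_equal(pet.geometry):
        raise ValueError("search region must live on the PET grid")
    if region.mask.is_empty:
        raise ValueError("search region is empty")


def lesion_suv_max(pet: SUVImage, region: SearchRegion) -> tuple[float, tuple[int, int, int]]:
    """Maximum SUV inside the region and the index of the attaining voxel.

    Ties are broken toward the lowest lexicographic voxel index, making the
    seed deterministic.
    """
    _check_region(pet, region)
    masked = np.where(region.mask.voxels, pet.values, -np.inf)
    flat = int(np.argmax(masked))  # first occurrence = lexicographic winner
    seed = tuple(int(i) for i in np.unravel_index(flat, pet.values.shape))
    return float(pet.values[seed]), seed  # type: ignore[index]


def _grow_from_seed(
    candidates: np.ndarray, seed: tuple[int, int, int], connectivity: int
) -> np.ndarray:
    labels, _ = ndimage.label(candidates, structure=_connectivity_structure(connectivity))
    lab = labels[seed]
    assert lab != 0, "seed voxel must be in the candidate set"
    return labels == lab


def percent_threshold_btv(
    pet: SUVImage,
    region: SearchRegion,
    spec: ThresholdSpec,
    connectivity: int = 26,
) -> StructureMask:
    """Fixed-percentage-of-SUV_max lesion VOI.

    Candidates are region voxels with SUV >= percent x SUV_max (inclusive,
    so the seed always qualifies); the returned mask is the connected
    component of the candidates containing the SUV_max seed.
    """
    if spec.mode != "percent_of_max":
        raise ValueError("spec.mode must be 'percent_of_max'")
    suv_max, seed = lesion_suv_max(pet, region)
    candidates = region.mask.voxels & (pet.values >= spec.percent * suv_max)
    voxels = _grow_from_seed(candidates, seed, connectivity)
    return StructureMask(pet.geometry, voxels, label=f"BTV_SUV{round(spec.percent * 100)}")


def background_stats(pet: SUVImage, voi: VOISphere) -> BackgroundStats:
    """Mean and sample SD (n-1 denominator) of SUV over the rasterized VOI."""
    mask = rasterize_sphere(voi, pet.geometry)
    n = int(mask.voxels.sum())
    if n < 2:
        raise ValueError("background VOI must cover at least 2 voxels of the grid")
    vals = pet.values[mask.voxels]
    return BackgroundStats(float(vals.mean()), float(vals.std(ddof=1)), n)


def percist_tlg_btv(
    pet: SUVImage,
    region: SearchRegion,
    spec: ThresholdSpec,
    connectivity: int = 26,
) -> StructureMask:
    """PERCIST-TLG lesion VOI with the background-adaptive absolute threshold.

    The lesion boundary is ``liver mean SUV + sd_multiplier x liver SD``
    (default multiplier 3).  A lesion whose SUV_max falls below that
    threshold yields an empty mask and a
    :class:`LesionNotAboveBackgroundWarning` — a PET-negative lesion is a
    result, not a crash.
    """
    if spec.mode != "percist_tlg":
        raise ValueError("spec.mode must be 'percist_tlg'")
    stats = background_stats(pet, spec.background_voi)
    threshold = stats.threshold(spec.sd_multiplier)
    suv_max, seed = lesion_suv_max(pet, region)
    if suv_max < threshold:
        warnings.warn(
            f"lesion not above background (SUV_max {suv_max:.3g} < threshold "
            f"{threshold:.3g}); returning empty mask",
            LesionNotAboveBackgroundWarning,
            stacklevel=2,
        )
        return StructureMask(
            pet.geometry, np.zeros(pet.geometry.shape, dtype=bool), label="BTV_PERCIST"
        )
    candidates = region.mask.voxels & (pet.values >= threshold)
    voxels = _grow_from_seed(candidates, seed, connectivity)
    return StructureMask(pet.geometry, voxels, label="BTV_PERCIST")


def exclude_structures(btv: StructureMask, avoid: StructureMask) -> StructureMask:
    """Mask out adjacent high-physiologic-uptake structures: btv AND NOT avoid."""
    if not btv.geometry.approx_equal(avoid.geometry):
        raise ValueError("btv and avoid masks must share a geometry")
    return StructureMask(btv.geometry, btv.voxels & ~avoid.voxels, label=btv.label)


def segment_lesion(
    pet: SUVImage,
    region: SearchRegion,
    spec: ThresholdSpec,
    connectivity: int = 26,
) -> StructureMask:
    """Dispatch on the threshold mode."""
    if spec.mode == "percent_of_max":
        return percent_threshold_btv(pet, region, spec, connectivity)
    return percist_tlg_btv(pet, region, spec, connectivity)


def run_all_algorithms(
    pet: SUVImage,
    region: SearchRegion,
    liver_voi: VOISphere,
    sd_multiplier: float = 3.0,
    connectivity: int = 26,
) -> dict[str, StructureMask]:
    """Run the full five-algorithm battery: SUV38/42/47/50 and PERCIST."""
    out: dict[str, StructureMask] = {}
    for pct, name in zip(PERCENT_THRESHOLDS, ALGORITHM_NAMES):
        spec = ThresholdSpec(mode="percent_of_max", percent=pct)
        out[name] = percent_threshold_btv(pet, region, spec, connectivity)
    spec = ThresholdSpec(
        mode="percist_tlg", sd_multiplier=sd_multiplier, background_voi=liver_voi
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", LesionNotAboveBackgroundWarning)
        out["PERCIST"] = percist_tlg_btv(pet, region, spec, connectivity)
    return out
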