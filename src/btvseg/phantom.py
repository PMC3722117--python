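"""Synthetic PET/CT phantoms with known ground truth.

Each phantom emulates the statistical structure of a planning FDG-PET/CT
study: one focal lesion (sphere or axis-aligned ellipsoid) with peak SUV
drawn from a distribution spanning ~3-18 (median near 9), soft-tissue
background uptake, a hepatic compartment with Gaussian SUV texture (the
PERCIST background reference), partial-volume blur via an isotropic
Gaussian point-spread function, additive Gaussian noise, and an imperfect
"manually drawn" GTV obtained from the true lesion by a signed-distance
offset (dilation/erosion in mm) plus a low-frequency random boundary warp.

The PET grid is coarse (4 mm), the planning-CT grid fine (2 mm), sharing
one field of view.  All randomness flows from a single seed; a fixed seed
reproduces every output bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import ImageGeometry, StructureMask, SUVImage, VOISphere
from .segmentation import SearchRegion

__all__ = [
    "LesionSpec",
    "LiverSpec",
    "GTVErrorSpec",
    "PhantomSpec",
    "PhantomOutput",
    "generate_phantom",
    "generate_cohort",
    "allocate_sites",
    "default_pet_geometry",
    "default_ct_geometry",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def default_pet_geometry() -> ImageGeometry:
    """4 mm isotropic PET grid, 192 mm field of view."""
    return ImageGeometry(shape=(48, 48, 48), spacing=(4.0, 4.0, 4.0), origin=(2.0, 2.0, 2.0))


def default_ct_geometry() -> ImageGeometry:
    """2 mm isotropic planning-CT grid over the same field of view."""
    return ImageGeometry(shape=(96, 96, 96), spacing=(2.0, 2.0, 2.0), origin=(1.0, 1.0, 1.0))


@dataclass(frozen=True)
class LesionSpec:
    """Axis-aligned ellipsoidal lesion; equal semiaxes give a sphere."""

    centre_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    peak_suv: float

    def support(self, geometry: ImageGeometry) -> np.ndarray:
        centres = geometry.voxel_centres()
        rel = (centres - np.asarray(self.centre_mm)) / np.asarray(self.semiaxes_mm)
        return np.sum(rel**2, axis=-1) <= 1.0


@dataclass(frozen=True)
class LiverSpec:
    """Hepatic compartment: ellipsoidal extent with Gaussian SUV texture."""

    centre_mm: tuple[float, float, float] = (146.0, 96.0, 96.0)
    semiaxes_mm: tuple[float, float, float] = (28.0, 34.0, 30.0)
    mean_suv: float = 2.0
    sd_suv: float = 0.3

    def support(self, geometry: ImageGeometry) -> np.ndarray:
        centres = geometry.voxel_centres()
        rel = (centres - np.asarray(self.centre_mm)) / np.asarray(self.semiaxes_mm)
        return np.sum(rel**2, axis=-1) <= 1.0


@dataclass(frozen=True)
class GTVErrorSpec:
    """Manual-contouring error model for the simulated GTV.

    ``offset_mm`` shifts the true boundary outward (positive = dilation,
    matching the tendency of manual GTVs to exceed true tumour extent) or
    inward (negative = erosion); ``warp_amplitude_mm`` adds a seeded
    low-frequency boundary perturbation of the stated RMS amplitude with
    correlation length ``warp_scale_mm``.
    """

    offset_mm: float = 0.0
    warp_amplitude_mm: float = 0.0
    warp_scale_mm: float = 30.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative description of one synthetic patient."""

    lesions: tuple[LesionSpec, ...]
    geometry_pet: ImageGeometry = field(default_factory=default_pet_geometry)
    geometry_ct: ImageGeometry = field(default_factory=default_ct_geometry)
    background_suv: float = 1.0
    liver: LiverSpec = field(default_factory=LiverSpec)
    psf_fwhm_mm: float = 7.0
    noise_sd_suv: float = 0.2
    gtv_error: GTVErrorSpec = field(default_factory=GTVErrorSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lesions:
            raise ValueError("at least one lesion is required")
        for les in self.lesions:
            if les.peak_suv <= self.background_suv:
                raise ValueError("lesion peak SUV must exceed background SUV")
            if any(a <= 0 for a in les.semiaxes_mm):
                raise ValueError("lesion semiaxes must be positive")
        if self.background_suv < 0 or self.psf_fwhm_mm < 0 or self.noise_sd_suv < 0:
            raise ValueError("background SUV, PSF FWHM and noise SD must be >= 0")


@dataclass
class PhantomOutput:
    """Generated phantom: PET, schematic CT, truth masks, simulated GTV."""

    pet: SUVImage
    ct: np.ndarray  # schematic HU volume on the CT grid
    truth_mask: StructureMask  # pre-blur lesion support, PET grid
    truth_mask_ct: StructureMask  # analytic lesion raster, CT grid
    gtv_mask: StructureMask  # simulated manual contour, CT grid
    liver_voi: VOISphere
    provenance: PhantomSpec

    def search_region(self, margin_mm: float = 15.0) -> SearchRegion:
        """Bounding box around the lesion(s) with a stated margin, PET grid."""
        lo = np.min(
            [np.asarray(l.centre_mm) - np.asarray(l.semiaxes_mm) for l in self.provenance.lesions],
            axis=0,
        )
        hi = np.max(
            [np.asarray(l.centre_mm) + np.asarray(l.semiaxes_mm) for l in self.provenance.lesions],
            axis=0,
        )
        centre = (lo + hi) / 2.0
        half = (hi - lo) / 2.0 + margin_mm
        return SearchRegion.from_box(self.pet.geometry, tuple(centre), tuple(half))


def _world_extent(geometry: ImageGeometry) -> tuple[np.ndarray, np.ndarray]:
    # axis-aligned extent of voxel-centre positions (identity orientation assumed
    # for phantoms, which always use it)
    first = geometry.index_to_world(np.zeros(3))
    last = geometry.index_to_world(np.asarray(geometry.shape) - 1.0)
    return np.minimum(first, last), np.maximum(first, last)


def _paint_ideal(spec: PhantomSpec, geometry: ImageGeometry, rng: np.random.Generator) -> np.ndarray:
    field_ = np.full(geometry.shape, spec.background_suv, dtype=float)
    liver_support = spec.liver.support(geometry)
    liver_vals = rng.normal(spec.liver.mean_suv, spec.liver.sd_suv, size=int(liver_support.sum()))
    field_[liver_support] = np.clip(liver_vals, 0.0, None)
    for les in spec.lesions:
        field_[les.support(geometry)] = les.peak_suv
    return field_


def _simulate_gtv(
    truth_ct: np.ndarray, geometry: ImageGeometry, err: GTVErrorSpec, rng: np.random.Generator
) -> np.ndarray:
    spacing = np.asarray(geometry.spacing)
    d_out = ndimage.distance_transform_edt(~truth_ct, sampling=spacing)
    d_in = ndimage.distance_transform_edt(truth_ct, sampling=spacing)
    signed = d_out - d_in  # positive outside the true lesion
    boundary_shift = float(err.offset_mm)
    if err.warp_amplitude_mm > 0:
        warp = rng.standard_normal(geometry.shape)
        warp = ndimage.gaussian_filter(warp, sigma=err.warp_scale_mm / spacing)
        sd = warp.std()
        if sd > 0:
            warp *= err.warp_amplitude_mm / sd
        return signed <= boundary_shift + warp
    return signed <= boundary_shift


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate one phantom; a fixed spec (incl. seed) is bit-reproducible."""
    rng = np.random.default_rng(spec.seed)

    lo_pet, hi_pet = _world_extent(spec.geometry_pet)
    lo_ct, hi_ct = _world_extent(spec.geometry_ct)
    for les in spec.lesions:
        c, a = np.asarray(les.centre_mm), np.asarray(les.semiaxes_mm)
        if np.any(c - a < np.maximum(lo_pet, lo_ct)) or np.any(
            c + a > np.minimum(hi_pet, hi_ct)
        ):
            raise ValueError(f"lesion at {les.centre_mm} extends outside the grid")

    truth_pet = np.zeros(spec.geometry_pet.shape, dtype=bool)
    for les in spec.lesions:
        truth_pet |= les.support(spec.geometry_pet)
    liver_pet = spec.liver.support(spec.geometry_pet)
    if np.any(truth_pet & liver_pet):
        raise ValueError("lesion and liver compartments overlap")

    ideal = _paint_ideal(spec, spec.geometry_pet, rng)
    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm / _FWHM_TO_SIGMA / np.asarray(spec.geometry_pet.spacing)
        blurred = ndimage.gaussian_filter(ideal, sigma=sigma_vox, mode="nearest")
    else:
        blurred = ideal
    if spec.noise_sd_suv > 0:
        blurred = blurred + rng.normal(0.0, spec.noise_sd_suv, size=blurred.shape)
    pet = SUVImage(spec.geometry_pet, np.clip(blurred, 0.0, None))

    truth_ct = np.zeros(spec.geometry_ct.shape, dtype=bool)
    for les in spec.lesions:
        truth_ct |= les.support(spec.geometry_ct)
    gtv = _simulate_gtv(truth_ct, spec.geometry_ct, spec.gtv_error, rng)
    if not gtv.any():
        raise ValueError("GTV error model eroded the contour away entirely")

    # schematic CT in HU: soft tissue everywhere, denser lesion/liver
    ct = np.full(spec.geometry_ct.shape, 40.0)
    ct[spec.liver.support(spec.geometry_ct)] = 60.0
    ct[truth_ct] = 70.0

    return PhantomOutput(
        pet=pet,
        ct=ct,
        truth_mask=StructureMask(spec.geometry_pet, truth_pet, label="truth"),
        truth_mask_ct=StructureMask(spec.geometry_ct, truth_ct, label="truth"),
        gtv_mask=StructureMask(spec.geometry_ct, gtv, label="GTV"),
        liver_voi=VOISphere(spec.liver.centre_mm, 15.0),
        provenance=spec,
    )


def allocate_sites(n: int, site_mix: tuple[float, float, float]) -> list[str]:
    """Deterministic largest-remainder allocation of n patients to sites."""
    from .cohort import SITES

    props = np.asarray(site_mix, dtype=float)
    if len(props) != len(SITES) or abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
        raise ValueError("site proportions must be non-negative and sum to 1")
    raw = n * props
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    # ties broken by site order (stable sort on descending remainder)
    for i in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    labels: list[str] = []
    for site, c in zip(SITES, counts):
        labels.extend([site] * int(c))
    return labels


_LESION_CENTRE = (64.0, 96.0, 96.0)


def _site_lesion(site: str, rng: np.random.Generator) -> LesionSpec:
    # site presets: oesophageal small/elongated, lung medium sphere,
    # pelvic large; peak SUV log-normal, median ~9.2, clipped to the
    # observed 3.1-18.2 range
    peak = float(np.clip(np.exp(rng.normal(np.log(9.2), 0.35)), 3.1, 18.2))
    if site == "lung":
        r = float(rng.uniform(14.0, 22.0))
        semiaxes = (r, r, r)
    elif site == "oesophageal":
        semiaxes = (
            float(rng.uniform(8.0, 12.0)),
            float(rng.uniform(8.0, 12.0)),
            float(rng.uniform(22.0, 32.0)),
        )
    else:  # pelvic
        semiaxes = tuple(float(rng.uniform(18.0, 28.0)) for _ in range(3))
    return LesionSpec(centre_mm=_LESION_CENTRE, semiaxes_mm=semiaxes, peak_suv=peak)


def generate_cohort(
    n: int,
    site_mix: tuple[float, float, float] = (0.40, 0.25, 0.35),
    seed: int = 0,
    gtv_error: GTVErrorSpec = GTVErrorSpec(offset_mm=3.0, warp_amplitude_mm=1.5),
    **spec_overrides,
) -> list[tuple[PhantomOutput, str]]:
    """Generate a site-mixed phantom cohort (default mix 40/25/35%).

    Manual GTVs are by default oversized (3 mm dilation + 1.5 mm warp),
    mirroring the tendency of manual contours to exceed true tumour
    extent.  ``spec_overrides`` are forwarded to every PhantomSpec.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    sites = allocate_sites(n, site_mix)
    rng = np.random.default_rng(seed)
    out: list[tuple[PhantomOutput, str]] = []
    for i, site in enumerate(sites):
        lesion = _site_lesion(site, rng)
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            lesions=(lesion,),
            gtv_error=gtv_error,
            seed=child_seed,
            **spec_overrides,
        )
        out.append((generate_phantom(spec), site))
    return out
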