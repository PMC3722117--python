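"""Clinical interchange I/O: NIfTI volumes and DICOM RT structure sets.

NIfTI is the pipeline's canonical on-disk format; DICOM RTSTRUCT is
boundary I/O for exchanging segmented VOIs with planning systems.  The
RTSTRUCT dialect written here is deliberately minimal and interoperable:
one ROI per structure, CLOSED_PLANAR contours on axial slices, holes as
separate polygons (no keyhole technique).

Conventions (fixed so round trips are exact):

* world coordinates are LPS mm, DICOM's native patient system; NIfTI
  affines (RAS) are converted on read/write by negating the first two
  world axes;
* contours are extracted at the 0.5 iso-level of the binary field with
  the voxel-centre convention, outer boundaries counter-clockwise;
* polygons are implicitly closed (last vertex differs from the first);
* rasterization uses the even-odd rule on voxel centres.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage.draw import polygon2mask

from .imaging import ImageGeometry, StructureMask, SUVImage

__all__ = [
    "ContourSet",
    "GeometryMismatchError",
    "mask_to_contours",
    "contours_to_mask",
    "write_nifti",
    "read_nifti_suv",
    "read_nifti_mask",
    "write_rtstruct",
    "read_rtstruct",
]

_LPS_FLIP = np.diag([-1.0, -1.0, 1.0])

RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


class GeometryMismatchError(ValueError):
    """An RTSTRUCT's contours do not lie on the expected grid's slice planes."""


@dataclass
class ContourSet:
    """Named set of closed planar polygons (world mm) on axial CT slices.

    Each polygon is an (N, 3) array of ordered vertices with constant z
    (slice plane); closure is implicit (first vertex is not repeated).
    """

    name: str
    polygons: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.polygons = [np.asarray(p, dtype=float).reshape(-1, 3) for p in self.polygons]


# ---------------------------------------------------------------------------
# NIfTI


def _geometry_to_ras_affine(geometry: ImageGeometry) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = _LPS_FLIP @ (geometry.rotation * np.asarray(geometry.spacing))
    affine[:3, 3] = _LPS_FLIP @ np.asarray(geometry.origin)
    return affine


def _geometry_from_ras_affine(affine: np.ndarray, shape: tuple[int, ...]) -> ImageGeometry:
    lin = _LPS_FLIP @ affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    return ImageGeometry(
        shape=tuple(int(n) for n in shape),
        spacing=tuple(spacing),
        origin=tuple(_LPS_FLIP @ affine[:3, 3]),
        orientation=tuple(map(tuple, lin / spacing)),
    )


def write_nifti(path, payload: SUVImage | StructureMask) -> None:
    """Write an SUV image (float32) or mask (uint8 0/1) as .nii/.nii.gz."""
    if isinstance(payload, StructureMask):
        data = payload.voxels.astype(np.uint8)
    else:
        data = payload.values.astype(np.float64)
    img = nib.Nifti1Image(data, _geometry_to_ras_affine(payload.geometry))
    nib.save(img, str(path))


def _load_nifti(path) -> tuple[np.ndarray, ImageGeometry]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return data, _geometry_from_ras_affine(img.affine, data.shape)


def read_nifti_suv(path) -> SUVImage:
    data, geometry = _load_nifti(path)
    return SUVImage(geometry, data.astype(float))


def read_nifti_mask(path, label: str = "") -> StructureMask:
    data, geometry = _load_nifti(path)
    return StructureMask(geometry, data > 0, label=label)


# ---------------------------------------------------------------------------
# mask <-> contours


def _require_axial(geometry: ImageGeometry) -> None:
    if not np.allclose(geometry.rotation, np.eye(3), atol=1e-6):
        raise ValueError("contour extraction requires an axially sliced identity-oriented grid")


def _trace_slice_boundaries(sl: np.ndarray) -> list[np.ndarray]:
    """Closed boundary loops of a binary slice along voxel edges.

    Vertices lie on half-integer index positions (voxel corners): the 0.5
    iso-level of the nearest-neighbour-interpolated binary field.  Each
    directed edge keeps the inside on its left, so outer boundaries come
    out counter-clockwise and holes clockwise.  At checkerboard corners
    the left-turn rule is taken (in-plane foreground treated
    4-connected), keeping every polygon non-self-intersecting.
    """
    # doubled integer coordinates avoid float dict keys: vertex (2i+-1, 2j+-1)
    segments: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(start: tuple[int, int], end: tuple[int, int]) -> None:
        segments.setdefault(start, []).append(end)

    inside = np.pad(sl, 1)
    for i, j in zip(*np.nonzero(inside)):
        x, y = 2 * int(i), 2 * int(j)
        if not inside[i - 1, j]:
            add((x - 1, y + 1), (x - 1, y - 1))
        if not inside[i + 1, j]:
            add((x + 1, y - 1), (x + 1, y + 1))
        if not inside[i, j - 1]:
            add((x - 1, y - 1), (x + 1, y - 1))
        if not inside[i, j + 1]:
            add((x + 1, y + 1), (x - 1, y + 1))

    loops: list[np.ndarray] = []
    while segments:
        start = next(iter(segments))
        loop = [start]
        prev = None
        current = start
        while True:
            nexts = segments[current]
            if len(nexts) == 1 or prev is None:
                nxt = nexts.pop()
            else:
                # checkerboard corner: prefer the left turn w.r.t. travel
                d = (current[0] - prev[0], current[1] - prev[1])
                left = (current[0] - d[1], current[1] + d[0])
                nxt = left if left in nexts else nexts[0]
                nexts.remove(nxt)
            if not nexts:
                del segments[current]
            prev, current = current, nxt
            if current == start:
                break
            loop.append(current)
        # back to original index space (pad offset 1, doubling 2)
        loops.append((np.asarray(loop, dtype=float) - 2.0) / 2.0)
    return loops


def mask_to_contours(mask: StructureMask) -> ContourSet:
    """Boundary polygons of the mask per axial slice.

    Contours follow voxel edges — the 0.5 iso-level of the binary field
    under the voxel-centre (nearest-neighbour) convention — so a single
    1 mm voxel yields a 1x1 mm square polygon and mask -> contours ->
    mask round trips are exact.  Multiple polygons per slice are allowed;
    holes appear as separate clockwise polygons (no keyhole technique).
    An empty mask yields an empty ContourSet.
    """
    _require_axial(mask.geometry)
    polys: list[np.ndarray] = []
    for k in range(mask.geometry.shape[2]):
        sl = mask.voxels[:, :, k]
        if not sl.any():
            continue
        for ij in _trace_slice_boundaries(sl):
            idx = np.column_stack([ij, np.full(len(ij), k, dtype=float)])
            polys.append(mask.geometry.index_to_world(idx))
    return ContourSet(name=mask.label or "structure", polygons=polys)


def contours_to_mask(
    contours: ContourSet, geometry: ImageGeometry, label: str | None = None
) -> StructureMask:
    """Rasterize contours: voxel true iff its centre is inside an odd
    number of that slice's polygons (even-odd rule)."""
    _require_axial(geometry)
    voxels = np.zeros(geometry.shape, dtype=bool)
    ni, nj, nk = geometry.shape
    for poly in contours.polygons:
        idx = geometry.world_to_index(poly)
        k = float(np.mean(idx[:, 2]))
        k_round = int(round(k))
        if abs(k - k_round) > 0.5 or not 0 <= k_round < nk:
            warnings.warn("contour lies off the target grid slices; ignored", stacklevel=2)
            continue
        fill = polygon2mask((ni, nj), idx[:, :2])
        voxels[:, :, k_round] ^= fill  # XOR = even-odd parity across polygons
    return StructureMask(geometry, voxels, label=label if label is not None else contours.name)


# ---------------------------------------------------------------------------
# DICOM RTSTRUCT


def write_rtstruct(path, contour_sets: list[ContourSet] | ContourSet, geometry: ImageGeometry) -> None:
    """Write contour set(s) as a minimal CLOSED_PLANAR RTSTRUCT.

    The referenced geometry is recorded (grid shape, spacing, origin) in
    the StructureSetLabel-adjacent private fields via standard plane
    positions; readers validate contours against their own expected grid.
    """
    if isinstance(contour_sets, ContourSet):
        contour_sets = [contour_sets]
    _require_axial(geometry)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTSTRUCT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.Manufacturer = "btvseg"
    ds.StructureSetLabel = "btvseg"
    now = datetime.datetime.now()
    ds.StructureSetDate = now.strftime("%Y%m%d")
    ds.StructureSetTime = now.strftime("%H%M%S")
    ds.FrameOfReferenceUID = generate_uid()

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    ds.RTROIObservationsSequence = []
    for number, cs in enumerate(contour_sets, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = cs.name
        roi.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for poly in cs.polygons:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = len(poly)
            item.ContourData = [float(v) for v in np.asarray(poly).ravel()]
            rc.ContourSequence.append(item)
        ds.ROIContourSequence.append(rc)

        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.RTROIInterpretedType = ""
        obs.ROIInterpreter = ""
        ds.RTROIObservationsSequence.append(obs)

    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


def read_rtstruct(path, geometry: ImageGeometry | None = None) -> list[ContourSet]:
    """Read an RTSTRUCT back into ContourSets.

    If ``geometry`` is given, each contour's plane must coincide with one
    of its axial slice planes (within 1e-3 mm of a slice position);
    otherwise a :class:`GeometryMismatchError` is raised.
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"cannot parse RTSTRUCT {path}: {exc}") from exc
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise ValueError(f"{path}: not an RTSTRUCT (Modality={getattr(ds, 'Modality', None)!r})")
    names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.get("StructureSetROISequence", [])
    }
    out: list[ContourSet] = []
    for rc in ds.get("ROIContourSequence", []):
        name = names.get(int(rc.ReferencedROINumber), f"ROI{rc.ReferencedROINumber}")
        polys = []
        for item in rc.get("ContourSequence", []):
            pts = np.asarray([float(v) for v in item.ContourData]).reshape(-1, 3)
            if geometry is not None:
                k = geometry.world_to_index(pts)[:, 2]
                if np.ptp(k) > 1e-3 or abs(k[0] - round(k[0])) > 1e-3 or not (
                    0 <= round(k[0]) < geometry.shape[2]
                ):
                    raise GeometryMismatchError(
                        f"contour of ROI {name!r} at z-index {k[0]:.3f} does not lie on a "
                        "slice plane of the expected geometry"
                    )
            polys.append(pts)
        out.append(ContourSet(name=name, polygons=polys))
    return out
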