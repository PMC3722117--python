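import numpy as np
import pytest

from btvseg.imaging import ImageGeometry, StructureMask, SUVImage


@pytest.fixture
def geom8() -> ImageGeometry:
    """Small isotropic 2 mm grid for voxel-level oracles."""
    return ImageGeometry(shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0), origin=(1.0, 1.0, 1.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130712)


def random_mask(geometry: ImageGeometry, rng: np.random.Generator, p: float = 0.3,
                label: str = "") -> StructureMask:
    return StructureMask(geometry, rng.random(geometry.shape) < p, label=label)


def mask_to_voxel_set(mask: StructureMask) -> set[tuple[int, int, int]]:
    """Independent set-based view of a mask for brute-force overlap oracles."""
    return {tuple(int(v) for v in idx) for idx in np.argwhere(mask.voxels)}


def brute_force_nearest_resample(mask: StructureMask, target: ImageGeometry) -> np.ndarray:
    """Literal per-voxel nearest-centre mapping, kept independent of the
    vectorised implementation it checks."""
    out = np.zeros(target.shape, dtype=bool)
    src = mask.geometry
    for i in range(target.shape[0]):
        for j in range(target.shape[1]):
            for k in range(target.shape[2]):
                world = target.index_to_world(np.array([i, j, k], dtype=float))
                cont = src.world_to_index(world)
                nearest = np.rint(cont).astype(int)
                if np.all(nearest >= 0) and np.all(nearest < np.asarray(src.shape)):
                    out[i, j, k] = mask.voxels[tuple(nearest)]
    return out


def uniform_suv(geometry: ImageGeometry, value: float) -> SUVImage:
    return SUVImage(geometry, np.full(geometry.shape, float(value)))
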