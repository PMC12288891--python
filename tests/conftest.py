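import numpy as np
import pytest

from dhmpheno.preprocess import CellPatch, _outer_polygon


def patch_from_arrays(patch: np.ndarray, mask: np.ndarray,
                      frame_id: int = 0, cell_id: int = 0) -> CellPatch:
    """Build a CellPatch from raw arrays, recomputing the outer polygon."""
    if mask.any():
        poly = _outer_polygon(mask, (0, 0))
    else:
        poly = np.zeros((1, 2))
    ys, xs = np.nonzero(mask)
    centroid = (float(ys.mean()), float(xs.mean())) if ys.size else (0.0, 0.0)
    return CellPatch(patch=np.asarray(patch), mask=mask,
                     contour=poly, centroid=centroid, area_px=int(mask.sum()),
                     frame_id=frame_id, cell_id=cell_id)


def digital_disk(radius: int, size: int = 96, phase: float = 2.0,
                 center: tuple[int, int] | None = None):
    """A filled digital disk mask with uniform phase."""
    if center is None:
        center = (size // 2, size // 2)
    rr, cc = np.mgrid[0:size, 0:size]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    patch = np.where(mask, phase, 0.0)
    return patch, mask


@pytest.fixture
def disk_patch():
    patch, mask = digital_disk(10)
    return patch_from_arrays(patch, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
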