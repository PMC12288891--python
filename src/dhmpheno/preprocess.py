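"""Background correction, thresholding segmentation and patch extraction.

The pipeline mirrors standard off-axis DHM post-processing of suspended
cells in flow: the channel background is static within one acquisition, so
it is estimated once as the per-pixel median of the first ``n`` frames and
subtracted from every frame.  Cells are then segmented by binary
thresholding of the corrected phase image (strictly above 0.8 rad by
default) and outer contours of 8-connected foreground components are
extracted.  Every contour enclosing strictly more than 30 px is kept and
stored with the 96 x 96 patch centred on its area centroid; windows that
would cross the frame border are dropped and counted.

Coordinates are 0-based (row, col) with pixel centres at integer positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "PhaseFrame",
    "Contour",
    "CellPatch",
    "DEFAULT_BACKGROUND_N",
    "DEFAULT_THRESHOLD_RAD",
    "DEFAULT_MIN_AREA_PX",
    "PATCH_SIZE",
    "estimate_background",
    "subtract_background",
    "segment",
    "filter_and_extract",
    "extract_cells",
]

DEFAULT_BACKGROUND_N = 50
DEFAULT_THRESHOLD_RAD = 0.8
DEFAULT_MIN_AREA_PX = 30
PATCH_SIZE = 96

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class PhaseFrame:
    """One 2D phase image in radians."""

    pixels: np.ndarray
    frame_id: int = 0
    acquisition_id: str = ""
    corrected: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("PhaseFrame.pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("phase values must be finite")


@dataclass
class Contour:
    """One segmented object: outer border polygon plus its filled region."""

    polygon: np.ndarray        # (N, 2) float (row, col) in frame coordinates
    bbox: tuple[int, int]      # (row0, col0) of the local mask
    mask: np.ndarray           # local boolean filled region (holes ignored)
    area_px: int               # enclosed pixel count
    centroid: tuple[float, float]  # area centroid, frame coordinates


@dataclass
class CellPatch:
    """A 96 x 96 phase patch around one segmented cell."""

    patch: np.ndarray          # (96, 96) float32, radians
    mask: np.ndarray           # (96, 96) bool, aligned to patch
    contour: np.ndarray        # (N, 2) float (row, col) in patch coordinates
    centroid: tuple[float, float]  # frame coordinates
    area_px: int
    frame_id: int = 0
    cell_id: int = 0
    border_flag: bool = False


def estimate_background(frames, n: int = DEFAULT_BACKGROUND_N) -> np.ndarray:
    """Per-pixel median over the first ``n`` frames of an acquisition.

    The background is computed once per acquisition and reused for every
    frame.  If fewer than ``n`` frames are available the median is taken
    over all of them and a warning is emitted.
    """
    stack = np.asarray([f.pixels if isinstance(f, PhaseFrame) else f
                        for f in frames])
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("need at least one 2D frame of uniform shape")
    if n < 1:
        raise ValueError("n must be >= 1")
    if stack.shape[0] < n:
        warnings.warn(
            f"only {stack.shape[0]} frames available for background "
            f"estimation (requested n={n}); using all of them",
            stacklevel=2)
    return np.median(stack[:n], axis=0)


def subtract_background(frame: PhaseFrame | np.ndarray,
                        background: np.ndarray) -> PhaseFrame:
    """Pixelwise background subtraction; no clipping is applied."""
    if not isinstance(frame, PhaseFrame):
        frame = PhaseFrame(pixels=frame)
    background = np.asarray(background)
    if frame.pixels.shape != background.shape:
        raise ValueError(
            f"shape mismatch: frame {frame.pixels.shape} vs "
            f"background {background.shape}")
    out = (frame.pixels.astype(np.float64) - background).astype(np.float32)
    return PhaseFrame(pixels=out, frame_id=frame.frame_id,
                      acquisition_id=frame.acquisition_id, corrected=True)


def _outer_polygon(filled: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Sub-pixel outer border of a filled component via marching squares."""
    padded = np.pad(filled.astype(np.float64), 1)
    polys = measure.find_contours(padded, 0.5)
    poly = max(polys, key=len)
    return poly - 1.0 + np.asarray(offset, dtype=float)


def segment(frame: PhaseFrame,
            threshold: float = DEFAULT_THRESHOLD_RAD) -> list[Contour]:
    """Binary thresholding plus outer-border extraction.

    The foreground mask is ``pixels > threshold`` (strict).  Connected
    components use 8-connectivity; only outer borders are extracted, so
    holes inside a cell are filled and ignored.  Components are returned
    in row-major scan order of their first foreground pixel, which makes
    the ordering deterministic.
    """
    if not frame.corrected:
        raise ValueError("segment expects a background-corrected frame")
    binary = frame.pixels > threshold
    labels, n = ndimage.label(binary, structure=_EIGHT_CONNECTED)
    contours: list[Contour] = []
    if n == 0:
        return contours
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        local = labels[sl] == i
        filled = ndimage.binary_fill_holes(local)
        r0, c0 = sl[0].start, sl[1].start
        area = int(filled.sum())
        ys, xs = np.nonzero(filled)
        centroid = (float(ys.mean()) + r0, float(xs.mean()) + c0)
        poly = _outer_polygon(filled, (r0, c0))
        contours.append(Contour(polygon=poly, bbox=(r0, c0), mask=filled,
                                area_px=area, centroid=centroid))
    return contours


def filter_and_extract(frame: PhaseFrame, contours: list[Contour],
                       min_area: int = DEFAULT_MIN_AREA_PX,
                       patch_size: int = PATCH_SIZE,
                       ) -> tuple[list[CellPatch], int]:
    """Keep contours enclosing strictly more than ``min_area`` px and cut
    the ``patch_size`` window centred on each area centroid.

    The window's top-left corner is ``floor(centroid) - patch_size // 2``;
    cells whose window crosses the frame border are dropped (truncated
    patches would corrupt morphology features) and counted in the returned
    border-rejection tally.

    Returns (patches, border_rejections).
    """
    h, w = frame.pixels.shape
    half = patch_size // 2
    patches: list[CellPatch] = []
    border_rejections = 0
    cell_id = 0
    for cont in contours:
        if cont.area_px <= min_area:  # strict "more than min_area" filter
            continue
        cr, cc = int(np.floor(cont.centroid[0])), int(np.floor(cont.centroid[1]))
        rs, cs = cr - half, cc - half
        re, ce = rs + patch_size, cs + patch_size
        if rs < 0 or cs < 0 or re > h or ce > w:
            border_rejections += 1
            continue
        patch = frame.pixels[rs:re, cs:ce].astype(np.float32)
        mask = np.zeros((patch_size, patch_size), dtype=bool)
        r0, c0 = cont.bbox
        mh, mw = cont.mask.shape
        # intersect the component mask with the window
        gr0, gc0 = max(r0, rs), max(c0, cs)
        gr1, gc1 = min(r0 + mh, re), min(c0 + mw, ce)
        if gr1 > gr0 and gc1 > gc0:
            mask[gr0 - rs:gr1 - rs, gc0 - cs:gc1 - cs] = \
                cont.mask[gr0 - r0:gr1 - r0, gc0 - c0:gc1 - c0]
        patches.append(CellPatch(
            patch=patch, mask=mask,
            contour=cont.polygon - np.array([rs, cs], dtype=float),
            centroid=cont.centroid, area_px=cont.area_px,
            frame_id=frame.frame_id, cell_id=cell_id))
        cell_id += 1
    return patches, border_rejections


@dataclass
class ExtractionResult:
    """Per-acquisition extraction bookkeeping."""

    patches: list[CellPatch] = field(default_factory=list)
    n_frames: int = 0
    contours_detected: int = 0
    survivors: int = 0
    area_rejections: int = 0
    border_rejections: int = 0


def extract_cells(frames: np.ndarray, background_n: int = DEFAULT_BACKGROUND_N,
                  threshold: float = DEFAULT_THRESHOLD_RAD,
                  min_area: int = DEFAULT_MIN_AREA_PX,
                  patch_size: int = PATCH_SIZE,
                  acquisition_id: str = "") -> ExtractionResult:
    """Full preprocessing of one acquisition stack.

    Estimates the static background from the first ``background_n`` frames,
    subtracts it from every frame, segments, filters and extracts patches.
    Cell ids are assigned sequentially across the stack.
    """
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    background = estimate_background(frames, n=background_n)
    result = ExtractionResult(n_frames=frames.shape[0])
    next_id = 0
    for fi in range(frames.shape[0]):
        corrected = subtract_background(
            PhaseFrame(frames[fi], frame_id=fi, acquisition_id=acquisition_id),
            background)
        contours = segment(corrected, threshold=threshold)
        result.contours_detected += len(contours)
        n_small = sum(1 for c in contours if c.area_px <= min_area)
        result.area_rejections += n_small
        patches, rejected = filter_and_extract(
            corrected, contours, min_area=min_area, patch_size=patch_size)
        result.border_rejections += rejected
        for p in patches:
            p.cell_id = next_id
            next_id += 1
        result.patches.extend(patches)
    result.survivors = len(result.patches)
    return result
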