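"""Detection of GFP-labelled neuromasts on the green projection.

Neuromasts appear as compact, bright rosettes on a dark background.  The
detector is a classical blob chain: background subtraction (image median) →
Gaussian smoothing → Otsu threshold → connected components → area and
circularity gates → intensity-weighted centroid.  Each surviving component
becomes a square analysis region ("white square") centred on its centroid,
inside which leukocyte infiltration is later quantified.

A larva is *data-producing* when at least one neuromast square was found;
larvae without detections yield no score and are tracked in the QC
accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure


@dataclass(frozen=True)
class DetectionParams:
    """Knobs of the neuromast blob detector.

    ``roi_side`` is the side of the square analysis region, default 48 px
    (about three rosette diameters at the default rendering scale).  Blob
    area gates are in px² on the thresholded component; circularity is
    4*pi*A/P² and rejects elongated autofluorescence streaks.
    """

    smoothing_sigma: float = 2.0
    threshold_method: str = "otsu"
    min_blob_area: int = 100
    max_blob_area: int = 4000
    min_circularity: float = 0.4
    roi_side: int = 48

    def __post_init__(self) -> None:
        if self.min_blob_area >= self.max_blob_area:
            raise ValueError("min_blob_area must be < max_blob_area")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("min_circularity must lie in [0, 1]")
        if self.roi_side < 1:
            raise ValueError("roi_side must be positive")


@dataclass
class NeuromastROI:
    """A detected neuromast and its square analysis region.

    ``square`` is (top, left, side) in pixel coordinates, possibly extending
    past the frame; use :meth:`clipped_slices` for array indexing.
    """

    centroid: tuple[float, float]  # (y, x)
    square: tuple[int, int, int]  # (top, left, side)
    area_px: int
    detection_score: float

    def clipped_slices(self, shape: tuple[int, int]) -> tuple[slice, slice]:
        top, left, side = self.square
        y0, y1 = max(0, top), min(shape[0], top + side)
        x0, x1 = max(0, left), min(shape[1], left + side)
        if y0 >= y1 or x0 >= x1:
            raise ValueError(f"ROI {self.square} has no area inside frame {shape}")
        return slice(y0, y1), slice(x0, x1)

    def clipped_area(self, shape: tuple[int, int]) -> int:
        ys, xs = self.clipped_slices(shape)
        return (ys.stop - ys.start) * (xs.stop - xs.start)


def _square_for(centroid: tuple[float, float], side: int) -> tuple[int, int, int]:
    cy, cx = centroid
    return int(round(cy - side / 2.0)), int(round(cx - side / 2.0)), side


def detect_neuromasts(
    green_projection: np.ndarray,
    params: DetectionParams | None = None,
) -> list[NeuromastROI]:
    """Detect neuromast blobs on the projected green channel.

    Returns a possibly empty list of ROIs sorted along the image x-axis
    (deterministic output order).  Centroids are intensity-weighted on the
    background-subtracted image.
    """
    if params is None:
        params = DetectionParams()
    img = np.asarray(green_projection, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"projection must be 2D, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("projection contains non-finite values")

    sub = img - np.median(img)
    np.clip(sub, 0.0, None, out=sub)
    smooth = ndimage.gaussian_filter(sub, params.smoothing_sigma)
    if smooth.max() <= 0:
        return []
    if params.threshold_method != "otsu":
        raise ValueError(f"unknown threshold method {params.threshold_method!r}")
    thr = filters.threshold_otsu(smooth)
    mask = smooth > thr
    if not mask.any():
        return []
    # rosettes are rings of cells: fill the dimmer rosette centre so each
    # neuromast is one compact component rather than an annulus
    mask = ndimage.binary_fill_holes(mask)

    labels = measure.label(mask, connectivity=2)
    rois: list[NeuromastROI] = []
    for region in measure.regionprops(labels, intensity_image=sub):
        area = int(region.area)
        if not params.min_blob_area <= area <= params.max_blob_area:
            continue
        perimeter = region.perimeter
        if perimeter > 0:
            circularity = 4.0 * np.pi * area / perimeter**2
            if circularity < params.min_circularity:
                continue
        cy, cx = region.centroid_weighted
        score = float(region.image_intensity.sum())
        rois.append(
            NeuromastROI(
                centroid=(float(cy), float(cx)),
                square=_square_for((cy, cx), params.roi_side),
                area_px=area,
                detection_score=score,
            )
        )
    rois.sort(key=lambda r: (r.centroid[1], r.centroid[0]))
    return rois


def _overlap_area(a: tuple[int, int, int], b: tuple[int, int, int]) -> int:
    ay, ax, aside = a
    by, bx, bside = b
    dy = min(ay + aside, by + bside) - max(ay, by)
    dx = min(ax + aside, bx + bside) - max(ax, bx)
    return max(0, dy) * max(0, dx)


def merge_overlapping_rois(rois: list[NeuromastROI]) -> list[NeuromastROI]:
    """Merge ROIs whose squares overlap by more than half the smaller square.

    Members of an overlap group collapse into one ROI at the
    detection-score-weighted centroid; score and component area accumulate.
    Output count never exceeds input count.
    """
    n = len(rois)
    if n <= 1:
        return list(rois)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            inter = _overlap_area(rois[i].square, rois[j].square)
            smaller = min(rois[i].square[2] ** 2, rois[j].square[2] ** 2)
            if inter > 0.5 * smaller:
                parent[find(i)] = find(j)

    groups: dict[int, list[NeuromastROI]] = {}
    for i, roi in enumerate(rois):
        groups.setdefault(find(i), []).append(roi)

    merged: list[NeuromastROI] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        weights = np.array([max(m.detection_score, 1e-12) for m in members])
        cents = np.array([m.centroid for m in members])
        cy, cx = (weights[:, None] * cents).sum(axis=0) / weights.sum()
        side = max(m.square[2] for m in members)
        merged.append(
            NeuromastROI(
                centroid=(float(cy), float(cx)),
                square=_square_for((cy, cx), side),
                area_px=sum(m.area_px for m in members),
                detection_score=float(sum(m.detection_score for m in members)),
            )
        )
    merged.sort(key=lambda r: (r.centroid[1], r.centroid[0]))
    return merged


def larva_is_data_producing(rois: list[NeuromastROI]) -> bool:
    """A larva yields data iff at least one neuromast square was detected."""
    return len(rois) >= 1
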