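"""Per-larva leukocyte quantification.

Two readouts mirror the assay's two quantification styles:

* **intensity mode** (automated screen): the mean background-subtracted red
  fluorescence inside each detected neuromast square, averaged over all
  squares of the larva.  "Relative" intensity is defined against the
  larva's own background — the median red level outside all squares — so
  the zero point is unstained tissue and the score is invariant to camera
  offset.
* **count mode** (manual-assay analogue): difference-of-Gaussians spot
  detection over the red projection, counting spots inside a band around
  the horizontal myoseptum (default half-width five cell diameters at
  10 px per cell diameter) between the first somite and the tail end.

Orientation QC estimates the body axis from the bright-field silhouette
(principal axis of the largest dark component); larvae tilted beyond a
threshold are flagged unfavourably mounted and excluded from scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, measure

from .neuromast_detection import NeuromastROI


@dataclass(frozen=True)
class BandSpec:
    """The myoseptum counting band.

    ``axis`` runs from the first-somite point to the end of the tail;
    ``half_width`` extends perpendicular on both sides (default 5 cell
    diameters of 10 px, i.e. a 10-cell-diameter-wide band).  Boundary points
    (distance exactly ``half_width``) count as inside.
    """

    axis: tuple[tuple[float, float], tuple[float, float]]  # ((y0,x0),(y1,x1))
    half_width: float = 50.0

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        (y0, x0), (y1, x1) = self.axis
        if math.hypot(y1 - y0, x1 - x0) <= 0:
            raise ValueError("band axis must have positive length")


@dataclass(frozen=True)
class SpotParams:
    """Difference-of-Gaussians spot detector settings."""

    low_sigma: float = 2.0
    high_sigma: float = 6.0
    threshold: float = 150.0  # absolute threshold on the DoG response
    min_distance: int = 3  # peak separation; closer true cells merge


@dataclass
class LarvaMeasurement:
    """One larva's inflammation readout plus QC flags."""

    larva_id: str
    condition_label: str
    mode: str  # intensity | count | both
    roi_scores: list[float] = field(default_factory=list)
    inflammation_score: float | None = None
    band_count: int | None = None
    n_rois: int = 0
    orientation_ok: bool = True
    data_producing: bool = False


def roi_background(red_projection: np.ndarray, rois: list[NeuromastROI]) -> float:
    """Median red level outside all analysis squares (one value per larva)."""
    red = np.asarray(red_projection, dtype=np.float64)
    mask = np.ones(red.shape, dtype=bool)
    for roi in rois:
        ys, xs = roi.clipped_slices(red.shape)
        mask[ys, xs] = False
    if not mask.any():  # squares cover the frame: fall back to global median
        return float(np.median(red))
    return float(np.median(red[mask]))


def roi_red_intensity(
    red_projection: np.ndarray,
    roi: NeuromastROI,
    background: float = 0.0,
) -> float:
    """Mean relative red intensity in one square: mean(px) − background, ≥ 0."""
    red = np.asarray(red_projection, dtype=np.float64)
    ys, xs = roi.clipped_slices(red.shape)  # raises on zero-area ROI
    return max(float(red[ys, xs].mean()) - background, 0.0)


def score_larva_intensity(
    red_projection: np.ndarray,
    rois: list[NeuromastROI],
    larva_id: str = "",
    condition_label: str = "",
    orientation_ok: bool = True,
) -> LarvaMeasurement:
    """Average the per-square relative red intensity over a larva.

    Larvae with zero detected squares are flagged not data-producing and
    receive no score.
    """
    m = LarvaMeasurement(
        larva_id=larva_id,
        condition_label=condition_label,
        mode="intensity",
        n_rois=len(rois),
        orientation_ok=orientation_ok,
    )
    if not rois:
        return m
    bg = roi_background(red_projection, rois)
    m.roi_scores = [roi_red_intensity(red_projection, roi, bg) for roi in rois]
    m.inflammation_score = float(np.mean(m.roi_scores))
    m.data_producing = True
    return m


def detect_leukocyte_spots(
    red_projection: np.ndarray,
    params: SpotParams | None = None,
) -> np.ndarray:
    """Detect leukocyte spot centroids on the red projection.

    Difference-of-Gaussians response thresholded at ``params.threshold``,
    local maxima at least ``min_distance`` px apart, each refined to the
    local centre of mass.  Ground-truth cells closer than the resolution
    limit merge into a single detection.  Returns an (N, 2) array of (y, x).
    """
    if params is None:
        params = SpotParams()
    img = np.asarray(red_projection, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"projection must be 2D, got shape {img.shape}")
    sub = img - np.median(img)
    dog = ndimage.gaussian_filter(sub, params.low_sigma) - ndimage.gaussian_filter(
        sub, params.high_sigma
    )
    peaks = feature.peak_local_max(
        dog, min_distance=params.min_distance, threshold_abs=params.threshold
    )
    if len(peaks) == 0:
        return np.empty((0, 2))
    # refine each peak by the local intensity centroid (sub-pixel)
    refined = np.empty((len(peaks), 2))
    r = 3
    h, w = sub.shape
    for i, (py, px) in enumerate(peaks):
        y0, y1 = max(0, py - r), min(h, py + r + 1)
        x0, x1 = max(0, px - r), min(w, px + r + 1)
        win = np.clip(sub[y0:y1, x0:x1], 0.0, None)
        total = win.sum()
        if total <= 0:
            refined[i] = (py, px)
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        refined[i] = ((yy * win).sum() / total, (xx * win).sum() / total)
    return refined


def count_in_band(spots: np.ndarray, band: BandSpec) -> int:
    """Count spots inside the myoseptum band.

    A spot counts when its perpendicular distance to the axis is at most
    ``half_width`` (boundary inclusive) *and* its projection onto the axis
    falls within the segment.
    """
    spots = np.asarray(spots, dtype=np.float64)
    if spots.size == 0:
        return 0
    (y0, x0), (y1, x1) = band.axis
    p0 = np.array([y0, x0])
    u = np.array([y1 - y0, x1 - x0])
    length = float(np.linalg.norm(u))
    u = u / length
    rel = spots - p0
    t = rel @ u
    perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
    eps = 1e-9
    inside = (perp <= band.half_width + eps) & (t >= -eps) & (t <= length + eps)
    return int(inside.sum())


def score_larva_count(
    red_projection: np.ndarray,
    band: BandSpec,
    larva_id: str = "",
    condition_label: str = "",
    orientation_ok: bool = True,
    spot_params: SpotParams | None = None,
) -> LarvaMeasurement:
    """Manual-analogue readout: leukocyte spots counted in the band."""
    spots = detect_leukocyte_spots(red_projection, spot_params)
    m = LarvaMeasurement(
        larva_id=larva_id,
        condition_label=condition_label,
        mode="count",
        orientation_ok=orientation_ok,
        band_count=count_in_band(spots, band),
    )
    m.data_producing = True  # count mode needs no neuromast detection
    return m


def estimate_body_axis(
    brightfield: np.ndarray,
) -> tuple[float, tuple[tuple[float, float], tuple[float, float]]]:
    """Estimate the larva's long-axis tilt from the bright-field silhouette.

    The body absorbs light, so the silhouette is the largest below-threshold
    component; its principal axis (PCA of pixel coordinates) gives the tilt
    angle in degrees from horizontal, in (-90, 90].  Returns the angle and
    an axis segment spanning the silhouette (used as the default myoseptum
    axis for the counting band).
    """
    bf = np.asarray(brightfield, dtype=np.float64)
    thr = 0.5 * (bf.min() + bf.max())
    mask = bf < thr
    if not mask.any():
        raise ValueError("no body silhouette found in bright-field channel")
    labels = measure.label(mask)
    largest = max(measure.regionprops(labels), key=lambda r: r.area)
    coords = largest.coords.astype(np.float64)
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]  # (dy, dx) of principal axis
    if v[1] < 0:
        v = -v
    angle = math.degrees(math.atan2(v[0], v[1]))
    t = centered @ v
    lo, hi = np.percentile(t, [1.0, 99.0])
    p0 = center + lo * v
    p1 = center + hi * v
    return angle, ((float(p0[0]), float(p0[1])), (float(p1[0]), float(p1[1])))


def orientation_qc(angle_deg: float, max_tilt_deg: float = 15.0) -> bool:
    """A larva is scoreable when its body axis is close to horizontal."""
    return abs(angle_deg) <= max_tilt_deg
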