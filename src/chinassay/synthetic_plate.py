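"""Synthetic larva plates with known ground truth.

The generator emulates what the screening microscope sees in one well of a
384-well plate: a 3-channel z-stack of a single zebrafish larva.  The larva
is reduced to the features the quantification pipeline consumes:

* a trunk/tail silhouette (bright-field) whose long axis is the horizontal
  myoseptum;
* 5-9 regularly spaced posterior lateral-line neuromasts on that axis,
  rendered in the green channel as rosettes (rings of cell-sized Gaussian
  spots);
* fluorescent leukocytes in the red channel.  Under control conditions they
  sit in a ventral/posterior stripe below the myoseptum; under treatment an
  additional Poisson number per neuromast is recruited into the immediate
  neuromast neighbourhood, emulating copper-induced infiltration.

Mounting is imperfect: with probability ``1 - lateral_orientation_prob`` the
larva lies at a steep angle (unfavourable position); deciding whether such a
larva is scoreable is the pipeline's QC job, not the generator's.

Optics are modelled as per-slice Gaussian blur (in-focus PSF plus extra
defocus per z-step away from the focal plane) and additive Gaussian camera
noise on a 16-bit scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import ZStack, save_manifest, write_zstack

CONTROL_LABELS = frozenset({"control", "untreated", "dmso"})

# 384-well plate coordinates: rows A-P, columns 1-24
_PLATE_ROWS = "ABCDEFGHIJKLMNOP"


def well_name(index: int, plate_format: int = 384) -> str:
    n_cols = 24 if plate_format == 384 else 12
    row, col = divmod(index, n_cols)
    if row >= len(_PLATE_ROWS):
        raise ValueError(f"well index {index} exceeds plate format {plate_format}")
    return f"{_PLATE_ROWS[row]}{col + 1:02d}"


@dataclass(frozen=True)
class SceneParams:
    """Tunable parameters of the synthetic scene.

    Geometry is in pixels of the virtual camera (default frame 1024 x 1300,
    echoing a 1,300 x 1,024 px screening camera).  Intensities are 16-bit
    camera units.
    """

    image_shape: tuple[int, int] = (1024, 1300)  # (H, W)
    n_slices: int = 9
    n_neuromasts: int = 7
    neuromast_radius: float = 8.0  # rosette ring radius, px
    neuromast_peak: float = 2000.0  # per rosette cell-spot, camera units
    cell_sigma: float = 3.0  # Gaussian sigma of a single cell, px
    cell_peak_mean: float = 1500.0  # leukocyte peak intensity mean
    cell_peak_sd: float = 200.0
    body_half_height: float = 60.0  # trunk half-height around the myoseptum, px
    recruit_mean: float = 8.0  # expected leukocytes recruited per neuromast
    recruit_radius_factor: float = 2.0  # recruitment zone = factor * neuromast_radius
    baseline_count: float = 10.0  # expected ventral/posterior background leukocytes
    rmax: float = 8.0  # dose-response saturation (leukocytes per neuromast)
    k50: float = 1.0  # dose giving half-maximal recruitment (arbitrary units)
    lateral_orientation_prob: float = 0.75  # chance of scoreable lateral mounting
    favorable_tilt_deg: float = 4.0  # |tilt| bound for well-mounted larvae
    unfavorable_tilt_deg: tuple[float, float] = (25.0, 55.0)
    noise_sd: float = 30.0  # additive Gaussian camera noise, camera units
    psf_sigma: float = 1.0  # in-focus blur, px
    defocus_sigma_per_slice: float = 0.6  # extra blur per z-step off focus, px
    bf_background: float = 1000.0  # bright-field background level
    bf_body: float = 600.0  # bright-field level inside the body silhouette

    def __post_init__(self) -> None:
        if not 0.0 <= self.lateral_orientation_prob <= 1.0:
            raise ValueError("lateral_orientation_prob must lie in [0, 1]")
        if not 5 <= self.n_neuromasts <= 9:
            raise ValueError("n_neuromasts must be in 5..9")
        if self.recruit_mean < 0 or self.baseline_count < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0 or self.psf_sigma < 0 or self.defocus_sigma_per_slice < 0:
            raise ValueError("blur/noise parameters must be non-negative")

    def recruit_at(self, dose: float | None) -> float:
        """Expected recruited leukocytes per neuromast.

        Monotone saturating dose response rmax * d / (d + k50); equals 0 at
        dose 0.  When no dose is given, ``recruit_mean`` is used directly.
        """
        if dose is None:
            return self.recruit_mean
        if dose < 0:
            raise ValueError(f"dose must be non-negative, got {dose}")
        return self.rmax * dose / (dose + self.k50)


@dataclass
class LarvaModel:
    """Ground truth for one synthetic larva."""

    body_axis: tuple[tuple[float, float], tuple[float, float]]  # ((y0,x0),(y1,x1))
    body_half_height: float
    neuromast_centers: list[tuple[float, float]]  # (y, x) on the axis
    neuromast_radius: float
    leukocytes: list[tuple[tuple[float, float], float, float]]  # (pos, peak, sigma)
    orientation_ok: bool
    condition_label: str
    dose: float | None = None
    tilt_deg: float = 0.0

    @property
    def n_leukocytes(self) -> int:
        return len(self.leukocytes)

    def leukocytes_near_neuromasts(self, radius: float | None = None) -> int:
        """Count ground-truth leukocytes within ``radius`` of any neuromast."""
        if radius is None:
            radius = 2.0 * self.neuromast_radius
        if not self.leukocytes or not self.neuromast_centers:
            return 0
        cells = np.array([pos for pos, _, _ in self.leukocytes])
        centers = np.array(self.neuromast_centers)
        d = np.linalg.norm(cells[:, None, :] - centers[None, :, :], axis=2)
        return int((d.min(axis=1) <= radius).sum())


@dataclass(frozen=True)
class PlateLayout:
    """Assignment of larvae to wells over replicate plates.

    Each condition gets ``larvae_per_condition_per_plate`` consecutive wells
    on every replicate plate; each well holds at most one larva.
    """

    conditions: tuple[tuple[str, float | None], ...]  # (label, dose)
    larvae_per_condition_per_plate: int = 24
    replicates: int = 3
    plate_format: int = 384

    def __post_init__(self) -> None:
        labels = [c for c, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        if len(labels) * self.larvae_per_condition_per_plate > self.plate_format:
            raise ValueError("layout does not fit on the plate")

    def wells(self) -> list[tuple[int, str, str, float | None]]:
        """(replicate, well_id, condition, dose) for every occupied well."""
        out = []
        for rep in range(1, self.replicates + 1):
            idx = 0
            for label, dose in self.conditions:
                for _ in range(self.larvae_per_condition_per_plate):
                    out.append((rep, well_name(idx, self.plate_format), label, dose))
                    idx += 1
        return out


def _axis_geometry(params: SceneParams, tilt_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Body axis endpoints (first somite -> tail end) for a given tilt.

    Steeply tilted (unfavourably mounted) larvae are foreshortened so the
    body still fits in the frame, as a rolled larva would in a well image.
    """
    h, w = params.image_shape
    cy, cx = h / 2.0, w / 2.0
    theta = math.radians(tilt_deg)
    half_len = 0.44 * w
    if abs(math.sin(theta)) > 1e-6:
        half_len = min(half_len, 0.46 * h / abs(math.sin(theta)))
    u = np.array([math.sin(theta), math.cos(theta)])  # unit vector, (dy, dx)
    p0 = np.array([cy, cx]) - half_len * u
    p1 = np.array([cy, cx]) + half_len * u
    return p0, p1


def generate_larva(
    params: SceneParams,
    condition: str,
    rng: np.random.Generator,
    dose: float | None = None,
) -> LarvaModel:
    """Draw one larva's ground truth.

    Controls receive only the ventral/posterior baseline population
    (Poisson(baseline_count)); treated larvae additionally receive
    Poisson(recruit) leukocytes per neuromast placed uniformly within
    ``recruit_radius_factor * neuromast_radius`` of each neuromast centre,
    where recruit follows the saturating dose response (or ``recruit_mean``
    when no dose is supplied).  Mounting orientation is
    Bernoulli(lateral_orientation_prob).
    """
    if dose is not None and dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    h, w = params.image_shape

    orientation_ok = bool(rng.random() < params.lateral_orientation_prob)
    if orientation_ok:
        tilt = float(rng.uniform(-params.favorable_tilt_deg, params.favorable_tilt_deg))
    else:
        lo, hi = params.unfavorable_tilt_deg
        tilt = float(rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi))
    p0, p1 = _axis_geometry(params, tilt)
    u = (p1 - p0) / np.linalg.norm(p1 - p0)
    n_hat = np.array([u[1], -u[0]])  # normal; ventral side has larger y
    if n_hat[0] < 0:
        n_hat = -n_hat
    axis_len = float(np.linalg.norm(p1 - p0))

    # neuromasts: regularly spaced along the myoseptum, small jitter along axis
    k = params.n_neuromasts
    ts = (np.arange(k) + 0.5) / k * axis_len
    ts += rng.uniform(-0.01, 0.01, size=k) * axis_len
    ts.sort()
    # enforce minimal spacing (jitter is tiny relative to spacing, but be safe)
    min_gap = 4.0 * params.neuromast_radius
    for i in range(1, k):
        if ts[i] - ts[i - 1] < min_gap:
            ts[i] = ts[i - 1] + min_gap
    ts = np.clip(ts, 0.0, axis_len)
    centers = [(float(y), float(x)) for y, x in (p0 + t * u for t in ts)]

    treated = condition.strip().lower() not in CONTROL_LABELS
    recruit = params.recruit_at(dose) if treated else 0.0
    if dose is not None and dose == 0:
        recruit = 0.0

    leukocytes: list[tuple[tuple[float, float], float, float]] = []

    def _add_cell(pos: np.ndarray) -> None:
        pos = np.clip(pos, [1.0, 1.0], [h - 2.0, w - 2.0])
        peak = float(
            np.clip(rng.normal(params.cell_peak_mean, params.cell_peak_sd), 200.0, 60000.0)
        )
        leukocytes.append(((float(pos[0]), float(pos[1])), peak, params.cell_sigma))

    # ventral/posterior baseline: below the myoseptum, biased to the rear 60%
    n_base = int(rng.poisson(params.baseline_count))
    for _ in range(n_base):
        t = float(rng.uniform(0.4, 1.0)) * axis_len
        d = float(rng.uniform(8.0, params.body_half_height))
        _add_cell(p0 + t * u + d * n_hat)

    # treatment: recruited leukocytes clustered at each neuromast
    r_rec = params.recruit_radius_factor * params.neuromast_radius
    for cy, cx in centers:
        for _ in range(int(rng.poisson(recruit))):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            rad = r_rec * math.sqrt(rng.uniform())
            _add_cell(np.array([cy + rad * math.sin(ang), cx + rad * math.cos(ang)]))

    return LarvaModel(
        body_axis=((float(p0[0]), float(p0[1])), (float(p1[0]), float(p1[1]))),
        body_half_height=params.body_half_height,
        neuromast_centers=centers,
        neuromast_radius=params.neuromast_radius,
        leukocytes=leukocytes,
        orientation_ok=orientation_ok,
        condition_label=condition,
        dose=dose,
        tilt_deg=tilt,
    )


def _stamp_gaussian(
    img: np.ndarray, y: float, x: float, peak: float, sigma: float
) -> None:
    """Add a 2D Gaussian spot into ``img`` in place (window of +-4 sigma)."""
    h, w = img.shape
    r = int(math.ceil(4.0 * sigma))
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1, dtype=np.float32) - y
    xx = np.arange(x0, x1, dtype=np.float32) - x
    g = np.exp(-(yy[:, None] ** 2 + xx[None, :] ** 2) / (2.0 * sigma**2))
    img[y0:y1, x0:x1] += peak * g


def _ideal_channels(larva: LarvaModel, params: SceneParams) -> np.ndarray:
    """Noise-free, unblurred (3, H, W) scene."""
    h, w = params.image_shape
    ideal = np.zeros((3, h, w), dtype=np.float32)

    # bright-field: light background, darker body band around the axis
    p0 = np.array(larva.body_axis[0])
    p1 = np.array(larva.body_axis[1])
    u = (p1 - p0) / np.linalg.norm(p1 - p0)
    axis_len = float(np.linalg.norm(p1 - p0))
    yy, xx = np.mgrid[0:h, 0:w]
    rel_y = yy - p0[0]
    rel_x = xx - p0[1]
    t = rel_y * u[0] + rel_x * u[1]
    perp = np.abs(rel_y * u[1] - rel_x * u[0])
    body = (t >= 0) & (t <= axis_len) & (perp <= larva.body_half_height)
    ideal[0] = params.bf_background
    ideal[0][body] = params.bf_body

    # green: neuromast rosettes = ring of 8 cell-spots at the rosette radius
    for cy, cx in larva.neuromast_centers:
        for j in range(8):
            ang = j * math.pi / 4.0
            _stamp_gaussian(
                ideal[1],
                cy + larva.neuromast_radius * math.sin(ang),
                cx + larva.neuromast_radius * math.cos(ang),
                params.neuromast_peak,
                params.cell_sigma,
            )

    # red: individual leukocytes
    for (cy, cx), peak, sigma in larva.leukocytes:
        _stamp_gaussian(ideal[2], cy, cx, peak, sigma)
    return ideal


def render_zstack(
    larva: LarvaModel,
    params: SceneParams,
    rng: np.random.Generator,
    n_slices: int | None = None,
) -> ZStack:
    """Render a larva into a 3-channel z-stack.

    Slice k is blurred with sigma = psf_sigma + |k - central| *
    defocus_sigma_per_slice and carries independent additive Gaussian camera
    noise; the central (in-focus) slice index is recorded in the stack
    metadata.  Requires an odd number of slices, at least 5.
    """
    if n_slices is None:
        n_slices = params.n_slices
    if n_slices < 5 or n_slices % 2 == 0:
        raise ValueError(f"n_slices must be odd and >= 5, got {n_slices}")
    central = n_slices // 2
    ideal = _ideal_channels(larva, params)
    c, h, w = ideal.shape
    out = np.empty((c, n_slices, h, w), dtype=np.uint16)
    for k in range(n_slices):
        sigma = params.psf_sigma + abs(k - central) * params.defocus_sigma_per_slice
        for ch in range(c):
            plane = ideal[ch]
            if sigma > 0:
                plane = ndimage.gaussian_filter(plane, sigma)
            if params.noise_sd > 0:
                plane = plane + rng.normal(0.0, params.noise_sd, size=plane.shape)
            out[ch, k] = np.clip(np.rint(plane), 0, 65535).astype(np.uint16)
    return ZStack(data=out, central_plane=central)


def well_rng(seed: int, replicate: int, well_index: int) -> np.random.Generator:
    """Per-well RNG from one plate seed.

    Streams are split by (replicate, well) counter so adding wells or
    conditions never perturbs previously generated wells.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(replicate, well_index))
    )


def generate_plate(
    layout: PlateLayout,
    params: SceneParams,
    out_dir: str | Path,
    seed: int,
    write_images: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full plate run: TIFF per occupied well + manifest + truth.

    Writes ``manifest.csv``, ``ground_truth.csv`` (one row per larva) and
    ``ground_truth_cells.json`` (per-cell coordinates) under ``out_dir``.
    Fully reproducible from ``seed``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    manifest_rows = []
    truth_rows = []
    cell_records = {}
    for rep, well, condition, dose in layout.wells():
        well_index = int(well[1:]) - 1 + _PLATE_ROWS.index(well[0]) * (
            24 if layout.plate_format == 384 else 12
        )
        rng = well_rng(seed, rep, well_index)
        larva = generate_larva(params, condition, rng, dose=dose)
        fname = f"plate{rep}_{well}.tif"
        larva_id = f"r{rep}_{well}"
        if write_images:
            stack = render_zstack(larva, params, rng)
            try:
                write_zstack(out_dir / fname, stack)
            except OSError as exc:
                raise OSError(f"failed writing {out_dir / fname}: {exc}") from exc
        manifest_rows.append(
            {
                "well_id": well,
                "file": fname,
                "condition": condition,
                "dose": dose,
                "replicate": rep,
                "seed": seed,
            }
        )
        truth_rows.append(
            {
                "larva_id": larva_id,
                "well_id": well,
                "replicate": rep,
                "condition": condition,
                "dose": dose,
                "n_leukocytes": larva.n_leukocytes,
                "n_near_neuromasts": larva.leukocytes_near_neuromasts(),
                "n_neuromasts": len(larva.neuromast_centers),
                "orientation_ok": larva.orientation_ok,
                "tilt_deg": larva.tilt_deg,
            }
        )
        cell_records[larva_id] = {
            "neuromast_centers": [list(c) for c in larva.neuromast_centers],
            "leukocytes": [
                {"y": pos[0], "x": pos[1], "peak": peak, "sigma": sigma}
                for pos, peak, sigma in larva.leukocytes
            ],
            "body_axis": [list(p) for p in larva.body_axis],
        }

    manifest = pd.DataFrame(
        manifest_rows, columns=["well_id", "file", "condition", "dose", "replicate", "seed"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "larva_id", "well_id", "replicate", "condition", "dose",
            "n_leukocytes", "n_near_neuromasts", "n_neuromasts",
            "orientation_ok", "tilt_deg",
        ],
    )
    save_manifest(out_dir / "manifest.csv", manifest)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    (out_dir / "ground_truth_cells.json").write_text(json.dumps(cell_records, indent=1))
    return manifest, truth


def small_scene(
    image_shape: tuple[int, int] = (220, 360),
    n_slices: int = 5,
    **overrides,
) -> SceneParams:
    """A reduced field of view with full-scale objects.

    Object geometry (cell sigma, rosette radius, band widths) is unchanged in
    pixel units; only the frame, trunk height and slice count shrink, so
    per-neuromast statistics match the full-frame default at a fraction of
    the rendering cost.
    """
    defaults = dict(
        image_shape=image_shape,
        n_slices=n_slices,
        body_half_height=55.0,
    )
    defaults.update(overrides)
    return SceneParams(**defaults)
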