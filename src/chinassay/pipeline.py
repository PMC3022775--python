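"""Well-to-report orchestration: read → focus → project → detect → score.

Failures are isolated per well — a corrupt image is logged and skipped, not
fatal — but a run aborts when more than half the wells are unreadable,
which almost always indicates a wrong configuration rather than a few bad
files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import pandas as pd

from .focus_projection import (
    autofocus_central_plane,
    extended_focus_project,
    plate_focus_policy,
)
from .image_io import PlateManifest, ZStack, read_zstack
from .leukocyte_quantification import (
    BandSpec,
    LarvaMeasurement,
    SpotParams,
    estimate_body_axis,
    orientation_qc,
    score_larva_count,
    score_larva_intensity,
)
from .neuromast_detection import (
    DetectionParams,
    detect_neuromasts,
    larva_is_data_producing,
    merge_overlapping_rois,
)

log = logging.getLogger("chinassay")

MEASUREMENT_COLUMNS = (
    "larva_id", "condition", "mode", "n_rois", "inflammation_score",
    "band_count", "orientation_ok", "data_producing",
)


@dataclass(frozen=True)
class QuantifyConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    spots: SpotParams = field(default_factory=SpotParams)
    band_half_width: float = 50.0
    max_tilt_deg: float = 15.0
    mode: str = "intensity"  # intensity | count | both
    focus_policy: str = "first-well"
    projection_operator: str = "max"


def quantify_stack(
    stack: ZStack,
    config: QuantifyConfig | None = None,
    central_plane: int | None = None,
    larva_id: str = "",
    condition: str = "",
) -> LarvaMeasurement:
    """Quantify a single well's z-stack into one larva measurement.

    When ``central_plane`` is not supplied (no plate-wide focus policy in
    effect), autofocus runs on this stack's green channel.
    """
    if config is None:
        config = QuantifyConfig()
    if central_plane is None:
        central_plane, _ = autofocus_central_plane(stack, "green")
    proj = extended_focus_project(stack, central_plane, config.projection_operator)

    bf_central = stack.channel("brightfield")[central_plane]
    angle, axis = estimate_body_axis(bf_central)
    ok = orientation_qc(angle, config.max_tilt_deg)

    if not ok:
        # unfavourably mounted: no scoring, only QC bookkeeping
        return LarvaMeasurement(
            larva_id=larva_id,
            condition_label=condition,
            mode=config.mode,
            orientation_ok=False,
        )

    if config.mode == "count":
        band = BandSpec(axis=axis, half_width=config.band_half_width)
        return score_larva_count(
            proj.red, band, larva_id, condition, True, config.spots
        )

    rois = merge_overlapping_rois(detect_neuromasts(proj.green, config.detection))
    m = score_larva_intensity(proj.red, rois, larva_id, condition, True)
    if config.mode == "both" and larva_is_data_producing(rois):
        band = BandSpec(axis=axis, half_width=config.band_half_width)
        m.band_count = score_larva_count(
            proj.red, band, larva_id, condition, True, config.spots
        ).band_count
        m.mode = "both"
    return m


def quantify_plate(
    manifest: PlateManifest,
    config: QuantifyConfig | None = None,
) -> pd.DataFrame:
    """Quantify every well of a plate into a per-larva results table."""
    if config is None:
        config = QuantifyConfig()

    def load(file: str) -> ZStack:
        return read_zstack(manifest.resolve(file))

    planes = plate_focus_policy(manifest, load, policy=config.focus_policy)

    rows: list[dict] = []
    failures = 0
    wells = list(manifest)
    for row in wells:
        larva_id = f"r{row.replicate}_{row.well_id}"
        try:
            stack = load(row.file)
            m = quantify_stack(
                stack,
                config,
                central_plane=planes[larva_id],
                larva_id=larva_id,
                condition=row.condition,
            )
        except Exception as exc:
            failures += 1
            log.warning("well %s failed, skipping: %s", larva_id, exc)
            continue
        rows.append(
            {
                "larva_id": m.larva_id,
                "condition": m.condition_label,
                "mode": m.mode,
                "n_rois": m.n_rois,
                "inflammation_score": m.inflammation_score,
                "band_count": m.band_count,
                "orientation_ok": m.orientation_ok,
                "data_producing": m.data_producing,
            }
        )
        if not m.orientation_ok:
            log.info("well %s excluded: unfavourable orientation", larva_id)
        elif not m.data_producing and config.mode != "count":
            log.info("well %s excluded: no neuromast detected", larva_id)
    if wells and failures > 0.5 * len(wells):
        raise RuntimeError(
            f"{failures}/{len(wells)} wells unreadable — aborting; check configuration"
        )
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    log.info(
        "plate quantified: %d wells, %d failures, %d orientation-excluded, %d scored",
        len(wells), failures,
        int((~df["orientation_ok"]).sum()) if len(df) else 0,
        int(df["data_producing"].sum()) if len(df) else 0,
    )
    return df


def simulate_and_quantify(
    params,
    condition: str,
    n: int,
    seed: int,
    dose: float | None = None,
    config: QuantifyConfig | None = None,
    stream: int = 0,
) -> list[LarvaMeasurement]:
    """Simulate ``n`` wells of one condition and quantify them in memory.

    Equivalent to generate_plate → quantify_plate for a single condition but
    without touching disk; the first well sets the plate-wide focal plane
    (first-well policy).  ``stream`` separates independent condition arms or
    replicate plates drawn from the same seed.
    """
    from .synthetic_plate import generate_larva, render_zstack, well_rng

    if config is None:
        config = QuantifyConfig()
    out: list[LarvaMeasurement] = []
    plane: int | None = None
    for i in range(n):
        rng = well_rng(seed, stream, i)
        larva = generate_larva(params, condition, rng, dose=dose)
        stack = render_zstack(larva, params, rng)
        if plane is None:
            plane, _ = autofocus_central_plane(stack, "green")
        out.append(
            quantify_stack(
                stack, config, central_plane=plane,
                larva_id=f"s{stream}_w{i}", condition=condition,
            )
        )
    return out


def measurements_from_frame(df: pd.DataFrame) -> list[LarvaMeasurement]:
    """Rebuild measurement objects from a per-larva results table."""
    out = []
    for row in df.itertuples(index=False):
        score = row.inflammation_score
        band = row.band_count
        out.append(
            LarvaMeasurement(
                larva_id=row.larva_id,
                condition_label=row.condition,
                mode=row.mode,
                inflammation_score=None if pd.isna(score) else float(score),
                band_count=None if pd.isna(band) else int(band),
                n_rois=int(row.n_rois),
                orientation_ok=bool(row.orientation_ok),
                data_producing=bool(row.data_producing),
            )
        )
    return out
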