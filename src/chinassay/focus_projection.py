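"""Central-plane autofocus and extended-focus projection.

The screening microscope acquires a short z-stack per well; quantification
runs on a single 2D image per fluorescence channel built from five optical
sections centred on the in-focus plane (two in each direction).  The
projection operator here is the per-pixel maximum over that window — the
simplest extended-focus operator for sparse bright objects; a per-pixel
best-focus variant is selectable.

Autofocus scores each slice by the variance of its Laplacian response (a
standard sharpness metric) and picks the argmax, breaking ties toward the
stack's middle slice.  The plate-level policy mirrors screening practice:
focus is determined on the first well and applied plate-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .image_io import PlateManifest, ZStack

WINDOW = 5  # optical sections entering the projection


@dataclass
class ProjectionResult:
    """Extended-focus projections of the fluorescence channels."""

    green: np.ndarray
    red: np.ndarray
    central_plane: int
    slices_used: list[int]
    focus_scores: np.ndarray | None = None


def focus_scores(stack: ZStack, channel: str = "green") -> np.ndarray:
    """Per-slice sharpness: variance of the Laplacian response."""
    planes = stack.channel(channel).astype(np.float64)
    return np.array([np.var(ndimage.laplace(p)) for p in planes])


def autofocus_central_plane(
    stack: ZStack, channel: str = "green"
) -> tuple[int, np.ndarray]:
    """Index of the sharpest slice, ties broken toward the middle slice."""
    scores = focus_scores(stack, channel)
    best = scores.max()
    candidates = np.flatnonzero(np.isclose(scores, best, rtol=1e-12, atol=0.0))
    mid = (len(scores) - 1) / 2.0
    chosen = int(min(candidates, key=lambda i: (abs(i - mid), i)))
    return chosen, scores


def projection_window(z: int, central_plane: int, window: int = WINDOW) -> list[int]:
    """Contiguous slice window of min(window, Z) slices containing the plane.

    At stack edges the window is clipped and re-centred so the full
    min(window, Z) real slices are always used.
    """
    if not 0 <= central_plane < z:
        raise ValueError(f"central_plane {central_plane} out of range for Z={z}")
    n = min(window, z)
    start = int(np.clip(central_plane - n // 2, 0, z - n))
    return list(range(start, start + n))


def extended_focus_project(
    stack: ZStack,
    central_plane: int,
    operator: str = "max",
    window: int = WINDOW,
) -> ProjectionResult:
    """Project green and red channels over the focus window.

    ``operator='max'`` (default) takes the per-pixel maximum over the window;
    ``operator='best-focus'`` picks, per pixel, the value from the slice with
    the locally sharpest response.
    """
    slices = projection_window(stack.n_slices, central_plane, window)
    out: dict[str, np.ndarray] = {}
    for name in ("green", "red"):
        sub = stack.channel(name)[slices].astype(np.float64)
        if operator == "max":
            out[name] = sub.max(axis=0)
        elif operator == "best-focus":
            sharp = np.stack([np.abs(ndimage.laplace(ndimage.gaussian_filter(p, 1.0))) for p in sub])
            idx = sharp.argmax(axis=0)
            out[name] = np.take_along_axis(sub, idx[None], axis=0)[0]
        else:
            raise ValueError(f"unknown projection operator {operator!r}")
    return ProjectionResult(
        green=out["green"],
        red=out["red"],
        central_plane=central_plane,
        slices_used=slices,
    )


def plate_focus_policy(
    manifest: PlateManifest,
    load_stack: Callable[[str], ZStack],
    policy: str = "first-well",
    channel: str = "green",
) -> dict[str, int]:
    """Assign a central focal plane to every well of a plate.

    ``first-well`` (default, mirroring the original screening setup) runs
    autofocus on the first well only and applies that plane plate-wide;
    ``per-well`` autofocuses every well independently.  The first well being
    unreadable is fatal under the default policy since the plate-wide plane
    cannot be set.
    """
    rows = list(manifest)
    if not rows:
        raise ValueError("empty manifest: no wells to focus")
    planes: dict[str, int] = {}
    if policy == "first-well":
        first = rows[0]
        try:
            stack = load_stack(first.file)
        except Exception as exc:
            raise RuntimeError(
                f"cannot establish plate focus: first well {first.well_id} unreadable ({exc})"
            ) from exc
        plane, _ = autofocus_central_plane(stack, channel)
        for row in rows:
            planes[_well_key(row)] = plane
    elif policy == "per-well":
        for row in rows:
            stack = load_stack(row.file)
            plane, _ = autofocus_central_plane(stack, channel)
            planes[_well_key(row)] = plane
    else:
        raise ValueError(f"unknown focus policy {policy!r}")
    return planes


def _well_key(row) -> str:
    return f"r{row.replicate}_{row.well_id}"
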