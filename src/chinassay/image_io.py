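"""Image and table I/O for the assay pipeline.

A well's image data is a 3-channel z-stack (bright-field, green/GFP,
red/DsRED2) stored as a multi-page 16-bit TIFF.  Page order on disk is
channel-major: all bright-field pages first, then all green, then all red
(overridable on read).  Coordinates throughout the package are 0-based
``(row, col) = (y, x)`` with the origin at the top-left pixel; geometry is
in pixel units unless a pixel size is recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

CHANNEL_NAMES = ("brightfield", "green", "red")

MANIFEST_COLUMNS = ("well_id", "file", "condition", "dose", "replicate")


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk layout."""


@dataclass
class ZStack:
    """One well's image data: ``data`` has shape (3, Z, H, W).

    ``pixel_size_um`` / ``z_spacing_um`` are ``None`` when unknown — missing
    metadata is explicit, never silently defaulted.  ``central_plane`` is the
    in-focus slice index when it has been determined (at render or autofocus
    time), else ``None``.
    """

    data: np.ndarray
    channel_names: tuple[str, str, str] = CHANNEL_NAMES
    pixel_size_um: float | None = None
    z_spacing_um: float | None = None
    central_plane: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError(
                f"ZStack data must have shape (3, Z, H, W), got {self.data.shape}"
            )
        if len(self.channel_names) != 3:
            raise ValueError("exactly 3 channel names required")

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the (Z, H, W) sub-stack for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ValueError(
                f"unknown channel {name!r}; have {self.channel_names}"
            ) from None
        return self.data[idx]


def write_zstack(path: str | Path, stack: ZStack) -> Path:
    """Write a ZStack as a channel-major multi-page 16-bit TIFF.

    Acquisition metadata (channel order, central plane, pixel sizes) is
    embedded as a JSON image description so round trips are lossless.
    """
    path = Path(path)
    data = np.asarray(stack.data)
    if data.dtype != np.uint16:
        data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    c, z, h, w = data.shape
    meta = {
        "channels": list(stack.channel_names),
        "n_slices": z,
        "central_plane": stack.central_plane,
        "pixel_size_um": stack.pixel_size_um,
        "z_spacing_um": stack.z_spacing_um,
        "page_order": "channel-major",
    }
    tifffile.imwrite(
        path,
        data.reshape(c * z, h, w),
        photometric="minisblack",
        description=json.dumps(meta),
    )
    return path


def read_zstack(
    path: str | Path,
    channel_order: Sequence[str] = CHANNEL_NAMES,
) -> ZStack:
    """Read a multi-page TIFF into a ZStack.

    ``channel_order`` names the channels in on-disk page order; the returned
    stack is always re-ordered to the canonical (brightfield, green, red).
    The page count must be divisible by 3 (three channels per well).
    """
    path = Path(path)
    if sorted(channel_order) != sorted(CHANNEL_NAMES):
        raise ValueError(
            f"channel_order must be a permutation of {CHANNEL_NAMES}, got {tuple(channel_order)}"
        )
    try:
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            desc = tif.pages[0].description
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise OSError(f"could not read TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    if n_pages % 3 != 0:
        raise FormatError(
            f"{path}: page count {n_pages} is not divisible by 3 channels"
        )
    z = n_pages // 3
    arr = pages.reshape(3, z, *pages.shape[1:])
    # re-order on-disk channels to canonical order
    order = [tuple(channel_order).index(name) for name in CHANNEL_NAMES]
    arr = arr[order]

    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    return ZStack(
        data=arr,
        channel_names=CHANNEL_NAMES,
        pixel_size_um=meta.get("pixel_size_um"),
        z_spacing_um=meta.get("z_spacing_um"),
        central_plane=meta.get("central_plane"),
    )


@dataclass
class PlateManifest:
    """Mapping from wells to image files and treatment conditions."""

    table: pd.DataFrame
    base_dir: Path | None = None

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return self.table.itertuples(index=False)

    def resolve(self, file: str) -> Path:
        p = Path(file)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p


def load_manifest(path: str | Path, check_files: bool = True) -> PlateManifest:
    """Load and validate a plate manifest CSV.

    Required columns: well_id, file, condition, dose, replicate (plus an
    optional seed column).  Well ids must be unique per (replicate, well);
    doses must be non-negative numbers (empty allowed → NaN).
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"well_id": str, "condition": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing required columns {missing}")
    key = list(zip(table["replicate"], table["well_id"]))
    if len(set(key)) != len(key):
        dupes = sorted({k for k in key if key.count(k) > 1})
        raise ValueError(f"{path}: duplicate well assignments {dupes[:5]}")
    table["dose"] = pd.to_numeric(table["dose"], errors="raise")
    if (table["dose"].dropna() < 0).any():
        raise ValueError(f"{path}: negative dose in manifest")
    manifest = PlateManifest(table=table, base_dir=path.parent)
    if check_files:
        for row in manifest:
            p = manifest.resolve(row.file)
            if not p.exists():
                raise FileNotFoundError(f"manifest entry {row.well_id}: missing image {p}")
    return manifest


def save_manifest(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path
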