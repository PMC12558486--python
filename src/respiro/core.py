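"""Domain types, file I/O and configuration shared by every pipeline stage.

The pipeline works on bright-field microscopy of respiratory organoids:
each well of a plate is imaged as a grid of fields of view (tiles), each
field as a z-stack of focal planes. Downstream stages fuse, stitch,
segment and measure these images; everything here is the plumbing those
stages share.

Conventions (used everywhere, stated once):

* arrays are row-major, 0-based, indexed ``(row, col)``, origin top-left;
* intensity images are converted to float in ``[0, 1]`` at load by
  dividing by the bit-depth maximum (16-bit assumed unless the file
  header says otherwise);
* binary masks are boolean arrays, serialized as 8-bit PNG with
  foreground 255 / background 0;
* tables are RFC-4180 CSV with a header row and a deterministic row
  order.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("respiro")


def get_logger(name: str = "respiro") -> logging.Logger:
    """Package logger; handlers are configured by the CLI, not on import."""
    return logging.getLogger(name)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ZStackTile:
    """Ordered focal planes for one field of view.

    Parameters
    ----------
    planes : list of 2D float arrays
        Focal planes ordered by acquisition z index, values in [0, 1].
    z_step_um : float
        Physical distance between consecutive planes in micrometres.
    grid_pos : (row, col)
        Position of this field in the well's tile grid.
    well_id : str
    timepoint_h : float
        Acquisition time in hours.
    """

    planes: list[np.ndarray]
    z_step_um: float = 100.0
    grid_pos: tuple[int, int] = (0, 0)
    well_id: str = ""
    timepoint_h: float = 0.0

    def __post_init__(self) -> None:
        if len(self.planes) < 1:
            raise ValueError("a z-stack needs at least one plane")
        shape0 = self.planes[0].shape
        for i, p in enumerate(self.planes):
            if p.ndim != 2:
                raise ValueError(f"plane {i} is not 2D (shape {p.shape})")
            if p.shape != shape0:
                raise ValueError(
                    f"plane shape mismatch: plane 0 is {shape0}, plane {i} is {p.shape}"
                )
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape

    @property
    def n_planes(self) -> int:
        return len(self.planes)


@dataclass
class TileGrid:
    """Complete nx x ny grid of fused 2D tiles for one well.

    ``nx`` counts tiles along x (columns), ``ny`` along y (rows), matching
    the acquisition convention "2 images along the x-axis and 3 along the
    y-axis". ``tiles[row][col]`` is the fused tile at that grid position.
    """

    tiles: list[list[np.ndarray]]
    nx: int = 2
    ny: int = 3
    overlap_frac_x: float = 0.1
    overlap_frac_y: float = 0.1

    def __post_init__(self) -> None:
        if len(self.tiles) != self.ny or any(len(r) != self.nx for r in self.tiles):
            raise ValueError(
                f"grid incomplete: expected {self.ny} rows x {self.nx} cols"
            )
        shape0 = self.tiles[0][0].shape
        for r in self.tiles:
            for t in r:
                if t is None:
                    raise ValueError("missing grid position")
                if t.shape != shape0:
                    raise ValueError("all tiles must share one shape")
        for f in (self.overlap_frac_x, self.overlap_frac_y):
            if not (0 <= f < 0.5):
                raise ValueError("overlap fraction must be in [0, 0.5)")

    @property
    def tile_shape(self) -> tuple[int, int]:
        return self.tiles[0][0].shape


@dataclass
class EFSI:
    """Extended-focus stitched image: one square all-in-focus view of a well."""

    image: np.ndarray
    side_px: int = 2100
    pixel_size_um: float = 2.0
    well_id: str = ""
    timepoint_h: float = 0.0

    def __post_init__(self) -> None:
        h, w = self.image.shape
        if h != w or h != self.side_px:
            raise ValueError(
                f"EFSI must be square of side {self.side_px}, got {self.image.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class BinaryMask:
    """Boolean segmentation mask aligned to some image.

    ``resolution`` tags the scale the mask lives at: ``"efsi"`` (full
    stitched-image grid, where physical measurement happens) or
    ``"network"`` (the downsampled segmentation-input grid).
    """

    mask: np.ndarray
    resolution: str = "efsi"

    def __post_init__(self) -> None:
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class PipelineConfig:
    """All stage parameters in one place; mirrors the YAML config file.

    Every randomized stage consumes ``seed``; two runs with equal config
    and inputs produce byte-identical CSV outputs.
    """

    # efsi stage
    sharpness_window: int = 9
    majority_window: int = 11
    grid_nx: int = 2
    grid_ny: int = 3
    overlap_frac_x: float = 0.1
    overlap_frac_y: float = 0.1
    registration_mode: str = "fixed_overlap"
    crop_side_px: int = 2100
    pixel_size_um: float = 2.0
    z_step_um: float = 100.0
    # preprocess
    low_pct: float = 1.0
    high_pct: float = 99.0
    clahe_clip_limit: float = 1.0
    clahe_tile_size: int = 32
    network_side_px: int = 512
    # segmentation
    backend: str = "threshold"
    prob_threshold: float = 0.5
    smoothing_sigma: float = 1.0
    # objects
    seed_min_distance_px: int = 10
    watershed_sigma: float = 2.0
    min_area_px: float = 300.0
    max_area_px: float | None = None
    min_form_factor: float = 0.1
    max_form_factor: float | None = None
    # tracking / FIS
    max_match_distance_px: float = 50.0
    fis_min_area_px: float = 1500.0
    fis_min_fold: float = 0.8
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        numeric = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)
        }
        for k, v in numeric.items():
            if not np.isfinite(v):
                raise ValueError(f"config field {k} is not finite: {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------

_BIT_DEPTH_MAX = {np.dtype(np.uint8): 255.0, np.dtype(np.uint16): 65535.0}


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Convert an integer intensity image to float64 in [0, 1]."""
    if arr.dtype in _BIT_DEPTH_MAX:
        return arr.astype(np.float64) / _BIT_DEPTH_MAX[arr.dtype]
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64)
    raise ValueError(f"unsupported image dtype {arr.dtype}")


def read_zstack(
    path_set: Sequence[str | Path],
    z_step_um: float = 100.0,
    grid_pos: tuple[int, int] = (0, 0),
    well_id: str = "",
    timepoint_h: float = 0.0,
) -> ZStackTile:
    """Read an ordered set of TIFF files into a :class:`ZStackTile`.

    ``path_set`` is ordered by acquisition z index. Single-plane files are
    the norm; a multi-page TIFF is accepted and split by page. Values are
    scaled to [0, 1] by the bit-depth maximum.
    """
    if len(path_set) == 0:
        raise ValueError("empty path set: a z-stack needs at least one file")
    planes: list[np.ndarray] = []
    for p in path_set:
        arr = tifffile.imread(str(p))
        if arr.ndim == 2:
            pages = [arr]
        elif arr.ndim == 3:
            pages = list(arr)  # multi-page: split by page
        else:
            raise ValueError(f"{p}: not a grayscale image (shape {arr.shape})")
        for page in pages:
            if page.ndim != 2:
                raise ValueError(f"{p}: page is not 2D grayscale")
            planes.append(_to_unit_float(page))
    return ZStackTile(planes, z_step_um, grid_pos, well_id, timepoint_h)


def write_zstack(tile: ZStackTile, paths: Sequence[str | Path]) -> None:
    """Write planes back to 16-bit TIFF files, one per plane (lossless for
    values that originated from 16-bit data)."""
    if len(paths) != tile.n_planes:
        raise ValueError("one output path per plane required")
    for plane, p in zip(tile.planes, paths):
        arr = np.round(np.clip(plane, 0, 1) * 65535.0).astype(np.uint16)
        tifffile.imwrite(str(p), arr)


def write_efsi_tiff(efsi: EFSI, path: str | Path) -> None:
    arr = np.round(np.clip(efsi.image, 0, 1) * 65535.0).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_efsi_tiff(
    path: str | Path, pixel_size_um: float = 2.0, well_id: str = "", timepoint_h: float = 0.0
) -> EFSI:
    arr = _to_unit_float(tifffile.imread(str(path)))
    return EFSI(arr, side_px=arr.shape[0], pixel_size_um=pixel_size_um,
                well_id=well_id, timepoint_h=timepoint_h)


def write_mask_png(mask: BinaryMask, path: str | Path) -> None:
    """Serialize a binary mask as 8-bit PNG, foreground 255 / background 0."""
    iio.imwrite(str(path), (mask.mask.astype(np.uint8) * 255))


def read_mask_png(path: str | Path, resolution: str = "efsi") -> BinaryMask:
    """Read a PNG mask; non-binary values are coerced foreground by ``>0``."""
    arr = iio.imread(str(path))
    if arr.ndim == 3:  # flatten accidental RGB by first channel
        arr = arr[..., 0]
    vals = np.unique(arr)
    if not np.isin(vals, (0, 255)).all():
        logger.warning("%s: non-binary PNG, coercing values >0 to foreground", path)
    return BinaryMask(arr > 0, resolution=resolution)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

_SORT_PRIORITY = ["well_id", "timepoint_h", "track_id", "object_id"]


def write_table(records, path: str | Path) -> None:
    """Write tabular records to CSV with a header row.

    Accepts a DataFrame or a list of dataclass instances / dicts with
    uniform columns. Rows are sorted by (well_id, timepoint_h, object id)
    where those columns exist, so output is deterministic. Floats are
    written with 9 significant digits; missing values become empty cells.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records
        ]
        df = pd.DataFrame(rows)
    sort_cols = [c for c in _SORT_PRIORITY if c in df.columns]
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.9g", lineterminator="\r\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# File layout
# ---------------------------------------------------------------------------


def tile_filename(well: str, timepoint_h: float, row: int, col: int, plane: int) -> str:
    """Canonical raw-tile filename: ``{well}_{timepoint}_r{row}c{col}_z{plane}.tif``."""
    tp = f"{timepoint_h:g}"
    return f"{well}_{tp}_r{row}c{col}_z{plane}.tif"
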