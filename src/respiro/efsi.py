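"""Extended-focus stitched image (EFSI) construction.

Organoids sit at different depths inside an extracellular-matrix droplet,
so no single focal plane captures them all sharply. Each field of view is
acquired as a z-stack (default 10 planes, 100 um apart); this module

1. fuses each stack into one all-in-focus tile by per-pixel selection of
   the sharpest plane (focus stacking),
2. stitches the tile grid of a well into one canvas, and
3. crops the canvas to the square EFSI on which segmentation and
   measurement run.

Sharpness is scored by the local variance of the Laplacian; the winning
plane-index map is smoothed by a majority (mode) filter before value
lookup so isolated noisy pixels do not flip planes. Fusion selects
values, never invents them: every fused pixel equals some plane's value
at that location.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core import EFSI, TileGrid, ZStackTile, get_logger

logger = get_logger(__name__)


# ---------------------------------------------------------------------------
# Focus stacking
# ---------------------------------------------------------------------------


def sharpness_map(plane: np.ndarray, window: int = 9) -> np.ndarray:
    """Local focus score: variance of the Laplacian in a sliding window.

    Returns a non-negative array of the plane's shape. High values mark
    in-focus texture; defocus blur suppresses the Laplacian response.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("sharpness window must be odd and >= 3")
    lap = ndimage.laplace(plane.astype(np.float64))
    mean = ndimage.uniform_filter(lap, window)
    mean_sq = ndimage.uniform_filter(lap * lap, window)
    var = mean_sq - mean * mean
    return np.maximum(var, 0.0)


def _majority_filter(index_map: np.ndarray, n_planes: int, window: int) -> np.ndarray:
    """Mode filter on a small-integer label map.

    Ties resolve to the lowest plane index (argmax over per-index local
    counts scans indices in ascending order).
    """
    counts = np.empty((n_planes,) + index_map.shape, dtype=np.float64)
    for i in range(n_planes):
        counts[i] = ndimage.uniform_filter((index_map == i).astype(np.float64), window)
    return np.argmax(counts, axis=0)


def fuse_zstack(
    tile: ZStackTile, sharpness_window: int = 9, majority_window: int = 11
) -> np.ndarray:
    """Fuse a z-stack into one all-in-focus 2D image.

    Each output pixel is taken from the plane with the maximal local
    sharpness score at that pixel, after majority smoothing of the
    plane-index map. Equal sharpness picks the lowest plane index, which
    makes the result deterministic and (on value-identical planes)
    independent of plane order.
    """
    if sharpness_window < 3 or sharpness_window % 2 == 0:
        raise ValueError("sharpness window must be odd and >= 3")
    h, w = tile.shape
    if sharpness_window > min(h, w):
        raise ValueError("sharpness window larger than the image")
    if tile.n_planes == 1:
        return tile.planes[0].copy()

    scores = np.stack([sharpness_map(p, sharpness_window) for p in tile.planes])
    index_map = np.argmax(scores, axis=0)  # ties -> lowest index
    index_map = _majority_filter(index_map, tile.n_planes, majority_window)
    stack = np.stack(tile.planes)
    rows, cols = np.indices((h, w))
    return stack[index_map, rows, cols]


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------


def _resolve_overlaps_correlate(
    grid: TileGrid, ox_fixed: int, oy_fixed: int, band: int = 40
) -> tuple[int, int]:
    """Refine overlaps by phase correlation between adjacent tiles.

    The shift search is restricted to a band around the nominal overlap;
    a low-confidence peak falls back to the fixed overlap with a warning.
    """
    h, w = grid.tile_shape
    ox, oy = ox_fixed, oy_fixed

    def _peak_shift(a: np.ndarray, b: np.ndarray) -> float | None:
        if a.size == 0 or a.std() < 1e-12 or b.std() < 1e-12:
            return None
        shift, error, _ = phase_cross_correlation(a, b, normalization=None)
        if error > 0.99:  # essentially no correlation structure
            return None
        return float(shift[1] if a.shape[1] >= a.shape[0] else shift[0])

    if grid.nx > 1 and ox_fixed > 0:
        a = grid.tiles[0][0][:, w - ox_fixed - band : w]
        b = grid.tiles[0][1][:, : ox_fixed + band]
        d = _peak_shift(a, b)
        if d is None:
            logger.warning("correlate mode found no x peak; using fixed overlap")
        else:
            cand = ox_fixed - int(round(d))
            if 0 < cand < w // 2:
                ox = cand
    if grid.ny > 1 and oy_fixed > 0:
        a = grid.tiles[0][0][h - oy_fixed - band : h, :]
        b = grid.tiles[1][0][: oy_fixed + band, :]
        d = _peak_shift(a.T, b.T)
        if d is None:
            logger.warning("correlate mode found no y peak; using fixed overlap")
        else:
            cand = oy_fixed - int(round(d))
            if 0 < cand < h // 2:
                oy = cand
    return ox, oy


def _feather_weights(h: int, w: int, row: int, col: int, ny: int, nx: int,
                     ox: int, oy: int) -> np.ndarray:
    """Per-tile blending weight: linear ramps across overlap zones on edges
    that have a neighbour, 1 elsewhere."""
    wx = np.ones(w)
    wy = np.ones(h)
    if ox > 0:
        ramp = np.linspace(1.0 / (ox + 1), 1 - 1.0 / (ox + 1), ox)
        if col > 0:
            wx[:ox] = ramp
        if col < nx - 1:
            wx[w - ox:] = ramp[::-1]
    if oy > 0:
        ramp = np.linspace(1.0 / (oy + 1), 1 - 1.0 / (oy + 1), oy)
        if row > 0:
            wy[:oy] = ramp
        if row < ny - 1:
            wy[h - oy:] = ramp[::-1]
    return np.outer(wy, wx)


def stitch_grid(grid: TileGrid, registration_mode: str = "fixed_overlap") -> np.ndarray:
    """Stitch a complete tile grid into one canvas.

    Overlap zones are blended by linear feathering. Output size is
    ``nx*w - (nx-1)*ox`` by ``ny*h - (ny-1)*oy`` where (ox, oy) are the
    resolved pixel overlaps. In ``fixed_overlap`` mode the overlaps come
    straight from the grid's overlap fractions and the result is
    deterministic; ``correlate`` mode refines them by phase correlation.
    """
    if registration_mode not in ("fixed_overlap", "correlate"):
        raise ValueError(f"unknown registration mode {registration_mode!r}")
    h, w = grid.tile_shape
    if grid.nx == 1 and grid.ny == 1:
        return grid.tiles[0][0].copy()

    ox = int(round(grid.overlap_frac_x * w))
    oy = int(round(grid.overlap_frac_y * h))
    if registration_mode == "correlate":
        ox, oy = _resolve_overlaps_correlate(grid, ox, oy)

    out_w = grid.nx * w - (grid.nx - 1) * ox
    out_h = grid.ny * h - (grid.ny - 1) * oy
    acc = np.zeros((out_h, out_w), dtype=np.float64)
    wacc = np.zeros((out_h, out_w), dtype=np.float64)
    for row in range(grid.ny):
        for col in range(grid.nx):
            y0 = row * (h - oy)
            x0 = col * (w - ox)
            wt = _feather_weights(h, w, row, col, grid.ny, grid.nx, ox, oy)
            acc[y0 : y0 + h, x0 : x0 + w] += grid.tiles[row][col] * wt
            wacc[y0 : y0 + h, x0 : x0 + w] += wt
    return acc / wacc


# ---------------------------------------------------------------------------
# Cropping
# ---------------------------------------------------------------------------


def crop_square(
    image: np.ndarray,
    side_px: int = 2100,
    pixel_size_um: float = 2.0,
    well_id: str = "",
    timepoint_h: float = 0.0,
) -> EFSI:
    """Centered square crop of the stitched canvas -> EFSI."""
    h, w = image.shape
    if h < side_px or w < side_px:
        raise ValueError(
            f"canvas {h}x{w} smaller than requested square side {side_px}; no padding"
        )
    y0 = (h - side_px) // 2
    x0 = (w - side_px) // 2
    crop = image[y0 : y0 + side_px, x0 : x0 + side_px].copy()
    return EFSI(crop, side_px=side_px, pixel_size_um=pixel_size_um,
                well_id=well_id, timepoint_h=timepoint_h)


def build_efsi(
    stacks: list[ZStackTile],
    nx: int = 2,
    ny: int = 3,
    overlap_frac_x: float = 0.1,
    overlap_frac_y: float = 0.1,
    side_px: int = 2100,
    pixel_size_um: float = 2.0,
    sharpness_window: int = 9,
    majority_window: int = 11,
    registration_mode: str = "fixed_overlap",
) -> EFSI:
    """Full stage: fuse every field's z-stack, stitch the grid, crop square.

    ``stacks`` carry their own ``grid_pos``; the grid must be complete.
    """
    tiles: list[list[np.ndarray | None]] = [[None] * nx for _ in range(ny)]
    for st in stacks:
        r, c = st.grid_pos
        tiles[r][c] = fuse_zstack(st, sharpness_window, majority_window)
    grid = TileGrid(tiles, nx=nx, ny=ny,
                    overlap_frac_x=overlap_frac_x, overlap_frac_y=overlap_frac_y)
    canvas = stitch_grid(grid, registration_mode)
    side = min(side_px, min(canvas.shape))
    if side < side_px:
        logger.warning("canvas %s too small for side %d; cropping to %d",
                       canvas.shape, side_px, side)
    return crop_square(canvas, side, pixel_size_um,
                       well_id=stacks[0].well_id, timepoint_h=stacks[0].timepoint_h)
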