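"""EFSI -> segmentation-input preprocessing.

The fixed sequence — percentile normalization, CLAHE, resize — is applied
identically at training and inference time. Masks travel the opposite
way: network-resolution masks are nearest-neighbour upsampled back to
EFSI resolution before any instance processing, because physical areas
are defined on the EFSI grid (area_um2 = area_px * pixel_size_um^2 at
2.0 um/px).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import exposure, transform

from .core import EFSI, BinaryMask


@dataclass
class NetworkInput:
    """Square float image in [0, 1] at the segmentation input resolution."""

    image: np.ndarray
    side_px: int = 512
    source: EFSI | None = None

    def __post_init__(self) -> None:
        h, w = self.image.shape
        if h != w or h != self.side_px:
            raise ValueError(f"network input must be {self.side_px}px square")
        if self.image.min() < -1e-9 or self.image.max() > 1 + 1e-9:
            raise ValueError("network input values must lie in [0, 1]")


def percentile_normalize(
    image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Rescale intensities so the [low, high] percentile range maps to [0, 1].

    Values below the low percentile clip to 0, above the high percentile
    to 1. A constant image (degenerate range) maps to all zeros.
    """
    if low_pct >= high_pct:
        raise ValueError("low percentile must be below high percentile")
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = np.percentile(image, [low_pct, high_pct])
    if hi <= lo:
        return np.zeros_like(image, dtype=np.float64)
    return np.clip((image.astype(np.float64) - lo) / (hi - lo), 0.0, 1.0)


def clahe(image: np.ndarray, clip_limit: float = 1.0, tile_size: int = 32) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` is the normalized clip parameter of the standard
    algorithm; ``tile_size`` is the side of the square contextual tiles
    in pixels. Input and output are in [0, 1]. Constant images pass
    through unchanged.
    """
    h, w = image.shape
    if tile_size > min(h, w) // 2:
        raise ValueError("tile_size too large: need >= 2 tiles per axis")
    if image.min() < -1e-9 or image.max() > 1 + 1e-9:
        raise ValueError("clahe expects input in [0, 1]")
    if np.ptp(image) < 1e-12:
        return image.astype(np.float64).copy()
    out = exposure.equalize_adapthist(
        np.clip(image, 0, 1), kernel_size=tile_size, clip_limit=clip_limit
    )
    return out.astype(np.float64)


def resize_image(image: np.ndarray, target_side: int) -> np.ndarray:
    """Resize a square intensity image with anti-aliased bilinear interpolation."""
    h, w = image.shape
    if h != w:
        raise ValueError(f"source must be square, got {image.shape} (crop first)")
    if h == target_side:
        return image.copy()
    out = transform.resize(
        image, (target_side, target_side), order=1, anti_aliasing=h > target_side,
        preserve_range=True,
    )
    return np.clip(out, image.min(), image.max())


def resize_mask(mask: BinaryMask, target_side: int, resolution: str | None = None) -> BinaryMask:
    """Resize a binary mask with nearest-neighbour interpolation (stays binary)."""
    h, w = mask.shape
    if h != w:
        raise ValueError(f"mask must be square, got {mask.shape}")
    if h == target_side:
        out = mask.mask.copy()
    else:
        out = transform.resize(
            mask.mask.astype(np.uint8), (target_side, target_side),
            order=0, anti_aliasing=False, preserve_range=True,
        ).astype(bool)
    return BinaryMask(out, resolution=resolution or mask.resolution)


def prepare_network_input(
    efsi: EFSI,
    side_px: int = 512,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    clip_limit: float = 1.0,
    tile_size: int = 32,
) -> NetworkInput:
    """The fixed preprocessing sequence: normalize -> CLAHE -> resize."""
    img = percentile_normalize(efsi.image, low_pct, high_pct)
    img = clahe(img, clip_limit, tile_size)
    img = np.clip(resize_image(img, side_px), 0.0, 1.0)
    return NetworkInput(img, side_px=side_px, source=efsi)


def mask_to_efsi_scale(mask: BinaryMask, efsi_side_px: int) -> BinaryMask:
    """Upsample a network-scale mask to the EFSI grid for measurement."""
    return resize_mask(mask, efsi_side_px, resolution="efsi")
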