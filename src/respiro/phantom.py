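"""Synthetic bright-field organoid phantom: the repository's microscope.

Real data for this pipeline is a plate of extracellular-matrix droplets
imaged in transmitted light: organoids appear as bright-lumen,
dark-rimmed blobs of varied shape at different depths, among bubbles and
under uneven illumination. The generator reproduces those features with
known ground truth — per-object identity, footprint, area and growth
factor — so every stage (fusion, stitching, segmentation, watershed,
measurement, tracking, FIS) can be tested against exact truth without
any downloads.

What it renders:

* organoids as discs / ellipses / lobed blobs with a bright lumen and a
  dark rim on a mid-grey background;
* bubbles as high-contrast rings that are *not* part of the truth
  foreground (they are artifacts the pipeline must reject);
* a low-order polynomial illumination field and Gaussian sensor noise;
* per-organoid defocus: in a z-stack each organoid is sharp only near
  its assigned focal plane (Gaussian blur growing with plane distance);
* temporal growth: each organoid's area scales by its growth factor,
  emulating forskolin-induced swelling between 0 h and 24 h.

One shared noise field is used for all planes of a stack and for the
all-in-focus reference, which keeps the fusion and stitching oracles
exact; independent per-plane noise is a realism knob the tests do not
need. Every output is a pure function of the parameters plus the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import EFSI, ZStackTile, TileGrid, get_logger
from .objects import LabelMap

logger = get_logger(__name__)


# ---------------------------------------------------------------------------
# Scene description
# ---------------------------------------------------------------------------


@dataclass
class PhantomOrganoid:
    """One synthetic organoid: a radial shape with growth and focus depth."""

    id: int
    center_rc: tuple[float, float]
    shape: str = "disc"  # disc | ellipse | lobed
    radius_px: float = 25.0
    aspect: float = 1.0  # minor/major for ellipse
    angle_rad: float = 0.0
    n_lobes: int = 0
    lobe_amp: float = 0.0
    growth_factor: float = 1.0
    rim_darkness: float = 0.25  # subtracted from background on the rim
    lumen_brightness: float = 0.72  # absolute lumen level
    rim_width_px: float = 3.0
    focus_plane: int = 0


@dataclass
class PhantomBubble:
    center_rc: tuple[float, float]
    radius_px: float = 15.0
    ring_contrast: float = 0.3
    ring_width_px: float = 3.0


@dataclass
class PhantomScene:
    canvas_side_px: int = 700
    organoids: list[PhantomOrganoid] = field(default_factory=list)
    bubbles: list[PhantomBubble] = field(default_factory=list)
    illumination_coeffs: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    noise_sigma: float = 0.01
    background: float = 0.45
    seed: int = 0
    time_index: int = 0  # bumps the noise stream between timepoints


@dataclass
class PhantomTruth:
    """Exact ground truth for a rendered scene.

    ``id_map`` labels pixels by generator organoid id (for tracking and
    growth recovery); ``label_map`` applies the annotation rule that
    touching objects form a single instance (8-connected components of
    the union), which is how human annotators would draw the masks.
    """

    id_map: np.ndarray
    label_map: np.ndarray
    areas_px: dict[int, int]
    centroids_rc: dict[int, tuple[float, float]]
    growth_factors: dict[int, float]

    @property
    def foreground(self) -> np.ndarray:
        return self.id_map > 0

    @property
    def n_instances(self) -> int:
        return int(self.label_map.max())


# ---------------------------------------------------------------------------
# Footprints
# ---------------------------------------------------------------------------


def _footprint(o: PhantomOrganoid, side: int) -> np.ndarray:
    """Boolean footprint of one organoid on the canvas (clipped at edges)."""
    r0 = o.radius_px
    margin = int(np.ceil(r0 * (1 + o.lobe_amp) / min(o.aspect, 1.0))) + 2
    cr, cc = o.center_rc
    r_lo, r_hi = max(0, int(cr) - margin), min(side, int(cr) + margin + 1)
    c_lo, c_hi = max(0, int(cc) - margin), min(side, int(cc) + margin + 1)
    rows = np.arange(r_lo, r_hi)[:, None] - cr
    cols = np.arange(c_lo, c_hi)[None, :] - cc
    # rotate into the organoid frame
    u = rows * np.cos(o.angle_rad) + cols * np.sin(o.angle_rad)
    v = -rows * np.sin(o.angle_rad) + cols * np.cos(o.angle_rad)
    if o.shape == "ellipse":
        inside = (u / r0) ** 2 + (v / (r0 * o.aspect)) ** 2 <= 1.0
    elif o.shape == "lobed":
        theta = np.arctan2(v, u)
        r_t = r0 * (1.0 + o.lobe_amp * np.cos(o.n_lobes * theta))
        inside = u**2 + v**2 <= r_t**2
    else:
        inside = u**2 + v**2 <= r0**2
    out = np.zeros((side, side), dtype=bool)
    out[r_lo:r_hi, c_lo:c_hi] = inside
    return out


def _organoid_delta(o: PhantomOrganoid, side: int, background: float) -> np.ndarray:
    """Additive intensity contribution of one organoid: bright lumen, dark rim."""
    fp = _footprint(o, side)
    if not fp.any():
        return np.zeros((side, side))
    depth = ndimage.distance_transform_edt(fp)
    rim = fp & (depth <= o.rim_width_px)
    lumen = fp & ~rim
    delta = np.zeros((side, side))
    delta[rim] = -o.rim_darkness
    delta[lumen] = o.lumen_brightness - background
    return delta


def _bubble_delta(b: PhantomBubble, side: int) -> np.ndarray:
    cr, cc = b.center_rc
    margin = int(np.ceil(b.radius_px + b.ring_width_px)) + 2
    r_lo, r_hi = max(0, int(cr) - margin), min(side, int(cr) + margin + 1)
    c_lo, c_hi = max(0, int(cc) - margin), min(side, int(cc) + margin + 1)
    rows = np.arange(r_lo, r_hi)[:, None] - cr
    cols = np.arange(c_lo, c_hi)[None, :] - cc
    rad = np.hypot(rows, cols)
    ring = np.abs(rad - b.radius_px) <= b.ring_width_px / 2
    delta = np.zeros((side, side))
    delta[r_lo:r_hi, c_lo:c_hi][ring] = -b.ring_contrast
    return delta


def _illumination(scene: PhantomScene) -> np.ndarray:
    """Low-order polynomial illumination field, mean ~1."""
    s = scene.canvas_side_px
    y, x = np.mgrid[0:s, 0:s] / (s - 1)
    y, x = y - 0.5, x - 0.5
    a = scene.illumination_coeffs
    f = 1.0 + a[0] * x + a[1] * y + a[2] * x * y + a[3] * (x**2 - 1 / 12) + a[4] * (y**2 - 1 / 12)
    return f


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------


def truth_from_scene(scene: PhantomScene) -> PhantomTruth:
    """Exact label maps and per-id statistics from the scene description.

    Where organoid footprints overlap, the higher id wins in ``id_map``
    (overlaps are kept small at generation time); ``label_map`` merges
    touching footprints into single instances per the annotation rule.
    """
    side = scene.canvas_side_px
    id_map = np.zeros((side, side), dtype=np.int32)
    for o in scene.organoids:
        id_map[_footprint(o, side)] = o.id
    from skimage.measure import label as cc_label

    label_map = cc_label(id_map > 0, connectivity=2).astype(np.int32)
    areas, cents = {}, {}
    for o in scene.organoids:
        sel = id_map == o.id
        n = int(sel.sum())
        areas[o.id] = n
        if n:
            rr, cc = np.nonzero(sel)
            cents[o.id] = (float(rr.mean()), float(cc.mean()))
        else:
            cents[o.id] = o.center_rc
    return PhantomTruth(
        id_map=id_map,
        label_map=label_map,
        areas_px=areas,
        centroids_rc=cents,
        growth_factors={o.id: o.growth_factor for o in scene.organoids},
    )


def generate_scene(
    n_organoids: int = 20,
    size_range_px: tuple[float, float] = (12.0, 35.0),
    shape_mix: tuple[float, float, float] = (0.5, 0.3, 0.2),  # disc, ellipse, lobed
    n_bubbles: int = 2,
    seed: int = 0,
    canvas_side_px: int = 700,
    growth_range: tuple[float, float] = (1.0, 1.0),
    n_touching_pairs: int = 0,
    n_planes: int = 1,
    noise_sigma: float = 0.01,
    illumination_amp: float = 0.08,
    max_tries: int = 2000,
) -> tuple[PhantomScene, PhantomTruth]:
    """Place organoids and bubbles at random; return scene plus exact truth.

    Organoids are placed without touching unless ``n_touching_pairs``
    pairs are forced to touch (their merged footprint counts as one
    instance in the annotation-rule truth). Deterministic under seed.
    """
    if size_range_px[0] <= 0 or size_range_px[1] < size_range_px[0]:
        raise ValueError("invalid size range")
    rng = np.random.default_rng(seed)
    side = canvas_side_px
    organoids: list[PhantomOrganoid] = []
    placed: list[tuple[float, float, float]] = []  # (r, c, radius)

    def _fits(r, c, rad, min_gap=4.0) -> bool:
        if not (rad + 2 <= r <= side - rad - 3 and rad + 2 <= c <= side - rad - 3):
            return False
        return all(np.hypot(r - pr, c - pc) >= rad + prad + min_gap
                   for pr, pc, prad in placed)

    def _sample_shape():
        u = rng.random()
        if u < shape_mix[0]:
            return "disc"
        if u < shape_mix[0] + shape_mix[1]:
            return "ellipse"
        return "lobed"

    def _make(oid, r, c, rad):
        shape = _sample_shape()
        return PhantomOrganoid(
            id=oid,
            center_rc=(r, c),
            shape=shape,
            radius_px=rad,
            aspect=rng.uniform(0.6, 0.9) if shape == "ellipse" else 1.0,
            angle_rad=rng.uniform(0, np.pi),
            n_lobes=int(rng.integers(3, 6)) if shape == "lobed" else 0,
            lobe_amp=rng.uniform(0.08, 0.18) if shape == "lobed" else 0.0,
            growth_factor=float(rng.uniform(*growth_range)),
            rim_darkness=float(rng.uniform(0.18, 0.3)),
            lumen_brightness=float(rng.uniform(0.65, 0.8)),
            rim_width_px=float(rng.uniform(2.5, 4.0)),
            focus_plane=int(rng.integers(0, max(n_planes, 1))),
        )

    oid = 1
    n_single = n_organoids - 2 * n_touching_pairs
    if n_single < 0:
        raise ValueError("n_touching_pairs too large for n_organoids")
    tries = 0
    while len(placed) < n_single:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_organoids} organoids on a {side}px canvas; "
                "reduce n_organoids or sizes"
            )
        tries += 1
        rad = rng.uniform(*size_range_px)
        r, c = rng.uniform(0, side), rng.uniform(0, side)
        if _fits(r, c, rad):
            organoids.append(_make(oid, r, c, rad))
            placed.append((r, c, rad))
            oid += 1
    for _ in range(n_touching_pairs):
        while True:
            if tries > max_tries:
                raise RuntimeError("could not place touching pair; reduce n or sizes")
            tries += 1
            rad1 = rng.uniform(*size_range_px)
            rad2 = rng.uniform(*size_range_px)
            r, c = rng.uniform(0, side), rng.uniform(0, side)
            ang = rng.uniform(0, 2 * np.pi)
            d = rad1 + rad2 - 2.0  # slight overlap so footprints touch
            r2, c2 = r + d * np.cos(ang), c + d * np.sin(ang)
            # the pair must clear every other organoid, and its union the canvas
            if _fits(r, c, rad1, min_gap=4.0):
                ok = all(
                    np.hypot(r2 - pr, c2 - pc) >= rad2 + prad + 4.0
                    for pr, pc, prad in placed
                )
                if ok and rad2 + 2 <= r2 <= side - rad2 - 3 and rad2 + 2 <= c2 <= side - rad2 - 3:
                    o1 = _make(oid, r, c, rad1)
                    o1.shape = "disc"
                    oid += 1
                    o2 = _make(oid, r2, c2, rad2)
                    o2.shape = "disc"
                    oid += 1
                    organoids.extend([o1, o2])
                    placed.append((r, c, rad1))
                    placed.append((r2, c2, rad2))
                    break
    bubbles = []
    for _ in range(n_bubbles):
        for _ in range(max_tries):
            rad = rng.uniform(8, 18)
            r, c = rng.uniform(rad + 2, side - rad - 2), rng.uniform(rad + 2, side - rad - 2)
            if all(np.hypot(r - pr, c - pc) >= rad + prad + 6.0 for pr, pc, prad in placed):
                bubbles.append(PhantomBubble((r, c), rad, float(rng.uniform(0.2, 0.35))))
                placed.append((r, c, rad))
                break
    coeffs = tuple(rng.uniform(-illumination_amp, illumination_amp, 5))
    scene = PhantomScene(
        canvas_side_px=side,
        organoids=organoids,
        bubbles=bubbles,
        illumination_coeffs=coeffs,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return scene, truth_from_scene(scene)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _composite(scene: PhantomScene, blur_sigmas: dict[int, float] | None = None) -> np.ndarray:
    """Clean composite: background + organoid and bubble deltas, optionally
    defocus-blurred per organoid, times the illumination field."""
    side = scene.canvas_side_px
    img = np.full((side, side), scene.background)
    for o in scene.organoids:
        delta = _organoid_delta(o, side, scene.background)
        sig = (blur_sigmas or {}).get(o.id, 0.0)
        if sig > 0.05:
            delta = ndimage.gaussian_filter(delta, sig)
        img += delta
    for b in scene.bubbles:
        img += _bubble_delta(b, side)
    img *= _illumination(scene)
    return img


def _noise_field(scene: PhantomScene) -> np.ndarray:
    rng = np.random.default_rng((scene.seed, scene.time_index, 9173))
    side = scene.canvas_side_px
    return rng.normal(0.0, scene.noise_sigma, (side, side)) if scene.noise_sigma > 0 else np.zeros((side, side))


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0, 1) * 65535.0) / 65535.0


def render_brightfield(scene: PhantomScene) -> np.ndarray:
    """All-in-focus bright-field rendering, 16-bit quantized, values in [0,1]."""
    return _quantize(_composite(scene) + _noise_field(scene))


def cut_tiles(
    image: np.ndarray, nx: int, ny: int, overlap_frac: float
) -> tuple[TileGrid, int, int]:
    """Cut a square canvas into an nx x ny tile grid with exact integer
    overlaps chosen so the stitched size equals the canvas side.

    Returns (grid, ox, oy) where ox/oy are the overlap widths in pixels.
    """
    s = image.shape[0]

    def _solve(n: int) -> tuple[int, int]:
        if n == 1:
            return s, 0
        w = int(np.ceil(s / (n - (n - 1) * overlap_frac)))
        while (n * w - s) % (n - 1):
            w += 1
        o = (n * w - s) // (n - 1)
        return w, o

    w, ox = _solve(nx)
    h, oy = _solve(ny)
    tiles = [
        [image[r * (h - oy) : r * (h - oy) + h, c * (w - ox) : c * (w - ox) + w].copy()
         for c in range(nx)]
        for r in range(ny)
    ]
    return TileGrid(tiles, nx=nx, ny=ny,
                    overlap_frac_x=ox / w, overlap_frac_y=oy / h), ox, oy


def render_zstack_tiles(
    scene: PhantomScene,
    n_planes: int = 10,
    z_step_um: float = 100.0,
    nx: int = 2,
    ny: int = 3,
    overlap_frac: float = 0.1,
    blur_per_plane_px: float = 1.2,
    well_id: str = "",
    timepoint_h: float = 0.0,
) -> tuple[list[ZStackTile], EFSI]:
    """Render the scene as per-field z-stacks plus the all-in-focus reference.

    Each organoid is sharp only near its assigned focal plane; defocus is
    Gaussian blur with sigma = blur_per_plane_px * |plane - focus_plane|.
    Tiles are cut with exact known overlap, so fusing and stitching them
    should reconstruct the reference EFSI.
    """
    noise = _noise_field(scene)
    ref = _quantize(_composite(scene) + noise)
    plane_images = []
    for k in range(n_planes):
        sig = {o.id: blur_per_plane_px * abs(k - o.focus_plane) for o in scene.organoids}
        plane_images.append(_quantize(_composite(scene, sig) + noise))
    stacks = []
    for r in range(ny):
        for c in range(nx):
            planes = []
            for k in range(n_planes):
                grid, _, _ = cut_tiles(plane_images[k], nx, ny, overlap_frac)
                planes.append(grid.tiles[r][c])
            stacks.append(ZStackTile(planes, z_step_um, (r, c), well_id, timepoint_h))
    ref_efsi = EFSI(ref, side_px=scene.canvas_side_px, pixel_size_um=2.0,
                    well_id=well_id, timepoint_h=timepoint_h)
    return stacks, ref_efsi


# ---------------------------------------------------------------------------
# Time evolution and annotators
# ---------------------------------------------------------------------------


def advance_time(scene: PhantomScene, t_fraction: float) -> PhantomScene:
    """Scene at a later timepoint: each organoid's area scales by
    growth_factor**t_fraction (linear size by the square root); centres
    and ids are preserved. Organoids grown past the canvas edge are
    clipped, with a warning, and the truth reflects the clipping."""
    if not (0 <= t_fraction <= 1):
        raise ValueError("t_fraction must be in [0, 1]")
    new_orgs = []
    side = scene.canvas_side_px
    for o in scene.organoids:
        scale = o.growth_factor ** (t_fraction / 2.0)
        new_rad = o.radius_px * scale
        r, c = o.center_rc
        if r - new_rad < 0 or c - new_rad < 0 or r + new_rad > side or c + new_rad > side:
            logger.warning("organoid %d grown past the canvas edge; clipped", o.id)
        new_orgs.append(dataclasses.replace(o, radius_px=new_rad))
    return dataclasses.replace(
        scene, organoids=new_orgs, time_index=scene.time_index + 1
    )


def simulate_annotators(
    truth_mask: np.ndarray,
    boundary_jitter_px: float = 2.0,
    miss_rate: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two noisy human-like annotations of a truth mask.

    Each annotator independently dilates or erodes every object boundary
    by up to ``boundary_jitter_px`` and misses whole objects at
    ``miss_rate``. Returns two boolean masks.
    """
    from skimage.measure import label as cc_label

    comps = cc_label(truth_mask, connectivity=2)
    n = comps.max()
    out = []
    for a in range(2):
        rng = np.random.default_rng((seed, a))
        mask = np.zeros_like(truth_mask, dtype=bool)
        for i in range(1, n + 1):
            if rng.random() < miss_rate:
                continue
            obj = comps == i
            delta = rng.uniform(-boundary_jitter_px, boundary_jitter_px)
            if abs(delta) < 1e-9:
                mask |= obj
                continue
            signed = ndimage.distance_transform_edt(~obj) - ndimage.distance_transform_edt(obj)
            mask |= signed <= delta
        out.append(mask)
    return out[0], out[1]
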