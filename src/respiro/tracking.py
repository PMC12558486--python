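"""Organoid tracking across time points and forskolin-induced-swelling
(FIS) quantification.

Tracking is position-based and runs in *reverse chronological order*:
matching starts from the last frame and works backward. Organoids grow
over time, so a large late-stage organoid can cover the position of its
small initial state; matching backwards lets the later footprint claim
exactly one antecedent instead of the early object being absorbed by a
wrong, larger neighbour.

FIS quantification normalizes each tracked organoid's area to its 0 h
baseline (fold change, 0 h == 1), applies the assay's selection filter
(baseline area >= 1500 px and fold change >= 0.8 by default) and
summarizes per group as n / median / Q1 / Q3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import get_logger
from .objects import LabelMap

logger = get_logger(__name__)


@dataclass
class SwellingRecord:
    """Per-track swelling between two time points."""

    track_id: int
    well_id: str
    area_t0_px: float
    area_t1_px: float
    fold_change: float


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------


def _centroids_areas(lm: LabelMap):
    labels = lm.labels
    n = lm.n_objects
    if n == 0:
        return np.zeros((0, 2)), np.zeros(0)
    idx = np.arange(1, n + 1)
    from scipy import ndimage

    cents = np.array(ndimage.center_of_mass(np.ones_like(labels), labels, idx))
    areas = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    return cents, areas


def _match_pair_greedy(
    later: LabelMap, earlier: LabelMap, max_dist: float
) -> dict[int, int]:
    """Match each later-frame object to at most one earlier-frame object.

    Greedy nearest-centroid in increasing-distance order; a pair whose
    distance exceeds ``max_dist`` still matches if the earlier centroid
    falls inside the later object's footprint (containment override —
    the grown organoid covers its initial position). Ties at equal
    distance resolve to the lower earlier object id. Injective per pair.
    """
    c_late, _ = _centroids_areas(later)
    c_early, _ = _centroids_areas(earlier)
    nl, ne = len(c_late), len(c_early)
    if nl == 0 or ne == 0:
        return {}
    d = np.linalg.norm(c_late[:, None] - c_early[None], axis=2)
    allowed = d <= max_dist
    for j in range(ne):
        r, c = int(round(c_early[j, 0])), int(round(c_early[j, 1]))
        if 0 <= r < later.labels.shape[0] and 0 <= c < later.labels.shape[1]:
            lab = later.labels[r, c]
            if lab > 0:
                allowed[lab - 1, j] = True
    order = np.argsort(d, axis=None, kind="stable")
    matched_late: set[int] = set()
    matched_early: set[int] = set()
    out: dict[int, int] = {}
    for flat in order:
        i, j = divmod(int(flat), ne)
        if not allowed[i, j] or i in matched_late or j in matched_early:
            continue
        out[i + 1] = j + 1
        matched_late.add(i)
        matched_early.add(j)
    return out


def _match_pair_hungarian(
    later: LabelMap, earlier: LabelMap, max_dist: float
) -> dict[int, int]:
    """Optimal-assignment variant of the pairwise matcher."""
    c_late, _ = _centroids_areas(later)
    c_early, _ = _centroids_areas(earlier)
    if len(c_late) == 0 or len(c_early) == 0:
        return {}
    d = np.linalg.norm(c_late[:, None] - c_early[None], axis=2)
    big = d.max() + max_dist + 1.0
    cost = np.where(d <= max_dist, d, big)
    rows, cols = linear_sum_assignment(cost)
    return {int(i) + 1: int(j) + 1 for i, j in zip(rows, cols) if d[i, j] <= max_dist}


def track_reverse(
    frames: list[tuple[float, LabelMap]],
    max_match_distance_px: float = 50.0,
    well_id: str = "",
    method: str = "greedy",
) -> pd.DataFrame:
    """Link organoid instances across time points, newest frame first.

    ``frames`` is time-ordered ``[(timepoint_h, LabelMap), ...]``. Each
    object in frame t is matched to one unmatched object in frame t-1;
    unmatched later objects terminate tracks, unmatched earlier objects
    are emitted as single-frame tracks. Returns a TrackTable DataFrame
    with columns (track_id, well_id, timepoint_h, object_id,
    centroid_row, centroid_col, area_px, area_um2).
    """
    if len(frames) < 2:
        raise ValueError("tracking needs at least 2 frames")
    shape0 = frames[0][1].labels.shape
    if any(lm.labels.shape != shape0 for _, lm in frames):
        raise ValueError("all frames must share one shape")
    matcher = _match_pair_greedy if method == "greedy" else _match_pair_hungarian

    times = [t for t, _ in frames]
    maps = [lm for _, lm in frames]
    n_frames = len(frames)

    # track id assignment seeded from the LAST frame, then walk backward
    track_of: list[dict[int, int]] = [{} for _ in range(n_frames)]
    next_track = 1
    for obj in range(1, maps[-1].n_objects + 1):
        track_of[-1][obj] = next_track
        next_track += 1
    for f in range(n_frames - 1, 0, -1):
        pairs = matcher(maps[f], maps[f - 1], max_match_distance_px)
        for late_obj, early_obj in pairs.items():
            track_of[f - 1][early_obj] = track_of[f][late_obj]
        for obj in range(1, maps[f - 1].n_objects + 1):
            if obj not in track_of[f - 1]:
                track_of[f - 1][obj] = next_track
                next_track += 1

    rows = []
    for f in range(n_frames):
        cents, areas = _centroids_areas(maps[f])
        px = maps[f].pixel_size_um
        for obj in range(1, maps[f].n_objects + 1):
            rows.append(
                dict(
                    track_id=track_of[f][obj],
                    well_id=well_id,
                    timepoint_h=times[f],
                    object_id=obj,
                    centroid_row=cents[obj - 1, 0],
                    centroid_col=cents[obj - 1, 1],
                    area_px=float(areas[obj - 1]),
                    area_um2=float(areas[obj - 1]) * px**2,
                )
            )
    df = pd.DataFrame(rows, columns=[
        "track_id", "well_id", "timepoint_h", "object_id",
        "centroid_row", "centroid_col", "area_px", "area_um2",
    ])
    return df.sort_values(["timepoint_h", "track_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# FIS quantification
# ---------------------------------------------------------------------------


def compute_fold_changes(tt: pd.DataFrame, t0_h: float, t1_h: float) -> list[SwellingRecord]:
    """Per-track area fold change area(t1)/area(t0), 0 h normalized to 1.

    Only tracks matched at both time points yield a record; zero baseline
    area is skipped with a warning.
    """
    for t in (t0_h, t1_h):
        if not (tt["timepoint_h"] == t).any():
            raise ValueError(f"timepoint {t} h not present in track table")
    a0 = tt[tt["timepoint_h"] == t0_h].set_index("track_id")
    a1 = tt[tt["timepoint_h"] == t1_h].set_index("track_id")
    records = []
    for track_id in sorted(set(a0.index) & set(a1.index)):
        area0 = float(a0.loc[track_id, "area_px"])
        area1 = float(a1.loc[track_id, "area_px"])
        if area0 <= 0:
            logger.warning("track %d has zero baseline area; skipped", track_id)
            continue
        records.append(
            SwellingRecord(
                track_id=int(track_id),
                well_id=str(a0.loc[track_id, "well_id"]),
                area_t0_px=area0,
                area_t1_px=area1,
                fold_change=area1 / area0,
            )
        )
    return records


def fis_filter(
    records: list[SwellingRecord],
    min_area_px: float = 1500.0,
    min_fold: float = 0.8,
) -> list[SwellingRecord]:
    """Assay selection filter: baseline area >= min_area_px AND fold change
    >= min_fold (both boundary-inclusive)."""
    return [
        r for r in records
        if r.area_t0_px >= min_area_px and r.fold_change >= min_fold
    ]


def summarize_fis(
    records: list[SwellingRecord], group_labels: dict[int, str] | None = None
) -> pd.DataFrame:
    """Per-group descriptive summary of fold changes and baseline areas.

    ``group_labels`` maps track_id -> group name; tracks without a label
    (or all tracks if None) fall into group "all". Quartiles use linear
    interpolation (the median-unbiased convention of numpy's default).
    """
    if not records:
        raise ValueError("no swelling records to summarize")
    groups: dict[str, list[SwellingRecord]] = {}
    for r in records:
        g = (group_labels or {}).get(r.track_id, "all")
        groups.setdefault(g, []).append(r)
    rows = []
    for g in sorted(groups):
        recs = groups[g]
        folds = np.array([r.fold_change for r in recs])
        areas = np.array([r.area_t0_px for r in recs])
        rows.append(
            dict(
                group=g,
                n=len(recs),
                fold_median=float(np.median(folds)),
                fold_q1=float(np.percentile(folds, 25)),
                fold_q3=float(np.percentile(folds, 75)),
                area_median_px=float(np.median(areas)),
                area_q1_px=float(np.percentile(areas, 25)),
                area_q3_px=float(np.percentile(areas, 75)),
            )
        )
    return pd.DataFrame(rows)
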