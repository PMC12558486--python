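"""Reverse-chronological tracking, fold changes and the swelling filter."""

import numpy as np
import pandas as pd
import pytest

from respiro.objects import LabelMap
from respiro.tracking import (
    SwellingRecord,
    compute_fold_changes,
    fis_filter,
    summarize_fis,
    track_reverse,
)
from tests.conftest import disc_mask


def _lm(*discs, side=200):
    lab = np.zeros((side, side), dtype=np.int32)
    for i, (r, c, rad) in enumerate(discs, start=1):
        lab[disc_mask(side, (r, c), rad)] = i
    return LabelMap(lab)


class TestTrackReverse:
    def test_static_objects_keep_identity(self):
        frames = [(float(t), _lm((50, 50, 10), (150, 150, 12))) for t in range(4)]
        df = track_reverse(frames)
        assert df.track_id.nunique() == 2
        for _, grp in df.groupby("track_id"):
            assert len(grp) == 4
            assert grp.area_px.nunique() == 1

    def test_growing_object_single_track(self):
        frames = [(float(t), _lm((100, 100, r))) for t, r in enumerate((10, 13, 16, 20))]
        df = track_reverse(frames)
        assert df.track_id.nunique() == 1
        areas = df.sort_values("timepoint_h").area_px.to_numpy()
        assert (np.diff(areas) > 0).all()

    def test_late_appearing_object_still_tracked(self):
        """An object present only from t=1 on (e.g. drifting into focus)
        gets a full track because identities are seeded from the LAST frame."""
        frames = [
            (0.0, _lm((60, 60, 10))),
            (1.0, _lm((60, 60, 11), (150, 150, 8))),
            (2.0, _lm((60, 60, 12), (150, 150, 9))),
        ]
        df = track_reverse(frames)
        assert df.track_id.nunique() == 2
        lens = sorted(df.groupby("track_id").size().tolist())
        assert lens == [2, 3]

    def test_reverse_beats_naive_forward_on_appearing_object(self):
        """Discriminating case for the reverse-chronology design: a naive
        forward matcher seeded at t=0 can never assign the object that
        first appears at t=1, while reverse tracking covers it fully."""
        frames = [
            (0.0, _lm((60, 60, 10))),
            (1.0, _lm((60, 60, 10), (150, 150, 12))),
            (2.0, _lm((60, 60, 10), (150, 150, 15))),
        ]

        def naive_forward(frs):
            # seed tracks at t=0, nearest-centroid forward, no track births
            from scipy import ndimage as ndi

            prev = {i + 1: ndi.center_of_mass(frs[0][1].labels == i + 1)
                    for i in range(frs[0][1].n_objects)}
            for _, lm in frs[1:]:
                cur = {i + 1: ndi.center_of_mass(lm.labels == i + 1)
                       for i in range(lm.n_objects)}
                matched = {}
                for tid, (pr, pc) in prev.items():
                    best = min(cur, key=lambda k: (cur[k][0] - pr) ** 2
                               + (cur[k][1] - pc) ** 2)
                    matched[tid] = cur.pop(best)
                prev = matched  # leftover objects dropped — no new tracks
            return len(prev)

        assert naive_forward(frames) == 1  # forward loses the second organoid
        df = track_reverse(frames)
        assert df[df.timepoint_h == 2.0].track_id.nunique() == 2
        assert df.track_id.nunique() == 2

    def test_growth_swallows_origin_containment_override(self):
        """A small early organoid whose centroid lies inside the much larger
        late footprint is matched even when centroid distance exceeds the
        gate, because the grown object covers its initial position."""
        frames = [(0.0, _lm((100, 70, 8))), (1.0, _lm((100, 100, 45)))]
        df = track_reverse(frames, max_match_distance_px=10.0)
        assert df.track_id.nunique() == 1 and len(df) == 2

    def test_moving_object_followed_within_gate(self):
        frames = [(0.0, _lm((60, 60, 10))), (1.0, _lm((66, 64, 10))),
                  (2.0, _lm((72, 68, 10)))]
        df = track_reverse(frames)
        assert df.track_id.nunique() == 1 and len(df) == 3

    def test_distant_object_not_matched_beyond_gate(self):
        frames = [(0.0, _lm((30, 30, 8))), (1.0, _lm((170, 170, 8)))]
        df = track_reverse(frames, max_match_distance_px=50.0)
        assert df.track_id.nunique() == 2  # two single-frame tracks

    def test_hungarian_matches_greedy_on_unambiguous_scene(self):
        frames = [(0.0, _lm((50, 50, 10), (150, 150, 10))),
                  (1.0, _lm((52, 52, 11), (148, 148, 11)))]
        cols = ["track_id", "timepoint_h", "object_id"]
        g = track_reverse(frames, method="greedy")
        h = track_reverse(frames, method="hungarian")
        pd.testing.assert_frame_equal(g[cols], h[cols])

    def test_crossing_ambiguity_hungarian_globally_optimal(self):
        """Two objects converging: the Hungarian matcher must pick the
        assignment with minimal total displacement (8+6 px, not 24+22)."""
        frames = [(0.0, _lm((50, 100, 8), (80, 100, 8))),
                  (1.0, _lm((58, 100, 8), (74, 100, 8)))]
        df = track_reverse(frames, method="hungarian")
        disp = 0.0
        for _, grp in df.groupby("track_id"):
            grp = grp.sort_values("timepoint_h")
            disp += np.hypot(
                np.diff(grp.centroid_row.to_numpy()),
                np.diff(grp.centroid_col.to_numpy()),
            ).sum()
        assert disp < 20

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            track_reverse([(0.0, _lm((50, 50, 10)))])

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            track_reverse([(0.0, _lm((50, 50, 10), side=100)),
                           (1.0, _lm((50, 50, 10), side=120))])

    def test_empty_final_frame_early_objects_become_tracks(self):
        frames = [(0.0, _lm((50, 50, 10))),
                  (1.0, LabelMap(np.zeros((200, 200), dtype=np.int32)))]
        df = track_reverse(frames)
        assert df.track_id.nunique() == 1 and len(df) == 1
        assert df.timepoint_h.tolist() == [0.0]

    def test_area_um2_uses_pixel_size(self):
        lab = disc_mask(100, (50, 50), 10).astype(np.int32)
        frames = [(0.0, LabelMap(lab, pixel_size_um=2.0)),
                  (1.0, LabelMap(lab, pixel_size_um=2.0))]
        df = track_reverse(frames)
        np.testing.assert_allclose(df.area_um2, df.area_px * 4.0)


class TestFoldChange:
    def _tracks(self):
        rows = []
        for tid, areas in [(1, [1000, 1500, 2000]), (2, [500, 400, 250])]:
            for tp, a in zip([0.0, 0.5, 1.0], areas):
                rows.append(dict(track_id=tid, timepoint_h=tp, area_px=float(a),
                                 well_id="W1", object_id=tid))
        return pd.DataFrame(rows)

    def test_fold_change_is_final_over_baseline(self):
        recs = compute_fold_changes(self._tracks(), 0.0, 1.0)
        by_id = {r.track_id: r for r in recs}
        assert by_id[1].fold_change == 2.0
        assert by_id[2].fold_change == 0.5
        assert by_id[1].area_t0_px == 1000 and by_id[1].area_t1_px == 2000

    def test_track_missing_baseline_yields_no_record(self):
        df = self._tracks()
        df = df[~((df.track_id == 2) & (df.timepoint_h == 0.0))]
        recs = compute_fold_changes(df, 0.0, 1.0)
        assert [r.track_id for r in recs] == [1]

    def test_zero_baseline_skipped_with_warning(self, caplog):
        df = self._tracks()
        df.loc[(df.track_id == 1) & (df.timepoint_h == 0.0), "area_px"] = 0.0
        recs = compute_fold_changes(df, 0.0, 1.0)
        assert [r.track_id for r in recs] == [2]

    def test_absent_timepoint_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            compute_fold_changes(self._tracks(), 0.0, 24.0)


class TestFisFilter:
    # (baseline area px, fold change) -> keep iff area >= 1500 AND fold >= 0.8
    TOY = [(2000, 1.5), (1000, 1.5), (2000, 0.5), (1600, 0.8), (1500, 0.79)]

    def _recs(self, pairs):
        return [
            SwellingRecord(track_id=i, well_id="W", area_t0_px=a,
                           area_t1_px=a * f, fold_change=f)
            for i, (a, f) in enumerate(pairs)
        ]

    def test_toy_table_two_survivors(self):
        kept = fis_filter(self._recs(self.TOY), min_area_px=1500, min_fold=0.8)
        pairs = sorted((r.area_t0_px, r.fold_change) for r in kept)
        assert pairs == [(1600, 0.8), (2000, 1.5)]

    def test_boundary_values_inclusive(self):
        recs = self._recs([(1500, 0.8)])
        assert fis_filter(recs, 1500, 0.8) == recs

    def test_nan_fold_change_always_dropped(self):
        recs = self._recs([(9000, float("nan"))])
        assert fis_filter(recs, 0, 0) == []


class TestSummarize:
    def _recs(self, folds, start_id=0):
        return [
            SwellingRecord(track_id=start_id + i, well_id="W", area_t0_px=2000.0,
                           area_t1_px=2000.0 * f, fold_change=f)
            for i, f in enumerate(folds)
        ]

    def test_median_and_quartiles_match_numpy_linear(self):
        folds = [1.0, 1.2, 1.4, 1.6, 2.0]
        df = summarize_fis(self._recs(folds))
        assert len(df) == 1
        row = df.iloc[0]
        assert row["n"] == 5
        assert row.fold_median == np.median(folds)
        assert row.fold_q1 == np.percentile(folds, 25)
        assert row.fold_q3 == np.percentile(folds, 75)

    def test_groups_summarized_separately(self):
        healthy = self._recs([1.7, 1.8, 1.9], start_id=0)
        cf = self._recs([1.3, 1.4, 1.5], start_id=10)
        labels = {r.track_id: "healthy" for r in healthy}
        labels.update({r.track_id: "cf" for r in cf})
        df = summarize_fis(healthy + cf, labels).set_index("group")
        assert df.loc["healthy", "fold_median"] == 1.8
        assert df.loc["cf", "fold_median"] == 1.4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_fis([])
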