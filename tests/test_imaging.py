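"""Rendering, segmentation and tracking, including the full round trip."""

import numpy as np
import pandas as pd
import pytest

from histodyn import (ImagingParams, LabeledObject, calibrated_control,
                      mitotic_chromatin_totals, read_ilastik_csv, read_tiff,
                      render_image_stack, segment_frame, segment_stack,
                      simulate_embryo, track_objects, write_tiff)


def _one_nucleus_table(total=1000.0, x=20.0, y=20.0, z=7.0, volume=300.0):
    return pd.DataFrame([dict(nucleus_id=0, parent_id=-1, cycle=10, frame=0,
                              t=0.0, x=x, y=y, z=z, volume=volume,
                              phase="interphase", total_ch=total,
                              mean_ch=total / volume)])


FIXTURE_PARAMS = ImagingParams(pixel_size=0.5, z_step=0.5,
                               shape_zyx=(28, 144, 216), sigma_scale=0.35)


@pytest.fixture(scope="module")
def roundtrip_run():
    """Noise-free NC10-11 movie rendered with a margin, segmented, tracked."""
    cfg = calibrated_control(seed=0, noise_cv=0.0, background=0.0,
                             start_nucleus_count=6, embryo_length=90.0,
                             embryo_width=55.0)
    cfg = cfg.replace(cycle_schedule={nc: cfg.cycle_schedule[nc]
                                      for nc in (10, 11)})
    table, truth = simulate_embryo(cfg)
    shifted = table.copy()
    shifted["x"] += 8.0
    shifted["y"] += 8.0
    shifted["z"] += 1.0
    stack = render_image_stack(shifted, "H3", FIXTURE_PARAMS)
    frames = segment_stack(stack, FIXTURE_PARAMS, min_size=5)
    tracked = track_objects(frames, max_disp=8.0, channel="H3")
    return table, truth, stack, frames, tracked


class TestRender:
    def test_blob_integral_matches_total(self):
        params = ImagingParams(pixel_size=0.5, z_step=0.5,
                               shape_zyx=(30, 80, 80))
        stack = render_image_stack(_one_nucleus_table(z=7.5), "ch", params)
        assert stack.sum() == pytest.approx(1000.0, rel=0.02)

    def test_empty_table_gives_background_stack(self):
        params = ImagingParams(shape_zyx=(4, 16, 16), background=3.0)
        stack = render_image_stack(pd.DataFrame(
            columns=["frame", "x", "y", "z", "volume", "total_ch"]), "ch",
            params)
        assert np.allclose(stack, 3.0)

    def test_two_nuclei_give_two_local_maxima_at_centroids(self):
        t = pd.concat([
            _one_nucleus_table(x=15.0), _one_nucleus_table(x=45.0)
        ], ignore_index=True)
        params = ImagingParams(pixel_size=0.5, z_step=0.5,
                               shape_zyx=(28, 80, 120))
        stack = render_image_stack(t, "ch", params)
        frame = stack[0]
        # argmax scan within each half of the field
        half = frame[:, :, :60]
        z1, y1, x1 = np.unravel_index(np.argmax(half), half.shape)
        half2 = frame[:, :, 60:]
        z2, y2, x2 = np.unravel_index(np.argmax(half2), half2.shape)
        assert abs((x1 + 0.5) * 0.5 - 15.0) <= 0.5
        assert abs((x2 + 60 + 0.5) * 0.5 - 45.0) <= 0.5

    def test_out_of_field_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="histodyn.render"):
            render_image_stack(_one_nucleus_table(x=500.0), "ch",
                               ImagingParams(shape_zyx=(5, 32, 32)))
        assert any("clipped" in r.message for r in caplog.records)

    def test_tiff_round_trip(self, tmp_path):
        params = ImagingParams(pixel_size=0.5, z_step=0.5,
                               shape_zyx=(6, 32, 32))
        stack = render_image_stack(_one_nucleus_table(x=8.0, y=8.0, z=1.5,
                                                      volume=50.0),
                                   "ch", params)
        path = tmp_path / "stack.tiff"
        write_tiff(path, stack)
        assert np.allclose(read_tiff(path), stack)


class TestSegment:
    def test_two_separated_blobs_two_objects(self):
        t = pd.concat([_one_nucleus_table(x=10.0), _one_nucleus_table(x=30.0)],
                      ignore_index=True)
        params = ImagingParams(pixel_size=0.5, z_step=0.5,
                               shape_zyx=(28, 80, 80))
        objs = segment_frame(render_image_stack(t, "ch", params)[0], params)
        assert len(objs) == 2

    def test_all_zero_frame_no_objects(self):
        assert segment_frame(np.zeros((5, 16, 16))) == []

    def test_total_equals_mean_times_size(self):
        t = _one_nucleus_table()
        params = ImagingParams(pixel_size=0.5, z_step=0.5,
                               shape_zyx=(28, 80, 80))
        (obj,) = segment_frame(render_image_stack(t, "ch", params)[0], params)
        assert obj.total_intensity == pytest.approx(
            obj.mean_intensity * obj.size_in_pixels, rel=1e-9)

    def test_fixed_threshold_requires_value(self):
        with pytest.raises(ValueError, match="threshold"):
            segment_frame(np.ones((4, 8, 8)), threshold_method="fixed")

    def test_intensity_recovery_on_rendered_frames(self, roundtrip_run):
        table, _, _, frames, _ = roundtrip_run
        ratios = []
        for f in range(len(frames)):
            est = sorted(o.total_intensity for o in frames[f])
            tru = sorted(table[table.frame == f]["total_H3"])
            assert len(est) == len(tru)
            ratios += [a / b for a, b in zip(est, tru)]
        within = np.mean(np.abs(np.array(ratios) - 1.0) < 0.05)
        assert within >= 0.95


class TestTrack:
    @staticmethod
    def _obj(frame, label, x, y=0.0, z=0.0):
        return LabeledObject(frame=frame, label=label, x=x, y=y, z=z,
                             size_in_pixels=50, volume=10.0,
                             total_intensity=100.0, mean_intensity=2.0)

    def test_single_moving_object_single_track(self):
        frames = [[self._obj(f, 1, x=1.0 * f)] for f in range(10)]
        out = track_objects(frames, max_disp=5.0)
        assert out["nucleus_id"].nunique() == 1
        assert len(out) == 10

    def test_split_creates_two_daughters_with_parent(self):
        frames = [[self._obj(0, 1, x=10.0)],
                  [self._obj(1, 1, x=8.0), self._obj(1, 2, x=12.0)],
                  [self._obj(2, 1, x=8.0), self._obj(2, 2, x=12.0)]]
        out = track_objects(frames, max_disp=5.0, start_cycle=10)
        parent_track = out[out.frame == 0]["nucleus_id"].iloc[0]
        daughters = out[out.frame == 1]
        assert (daughters["parent_id"] == parent_track).all()
        assert daughters["nucleus_id"].nunique() == 2
        assert (daughters["cycle"] == 11).all()
        # daughters persist as the same tracks in frame 2
        assert set(out[out.frame == 2]["nucleus_id"]) == set(
            daughters["nucleus_id"])

    def test_far_object_starts_new_track(self):
        frames = [[self._obj(0, 1, x=0.0)], [self._obj(1, 1, x=50.0)]]
        out = track_objects(frames, max_disp=5.0)
        assert out["nucleus_id"].nunique() == 2
        assert (out["parent_id"] == -1).all()

    def test_deterministic(self, roundtrip_run):
        _, _, _, frames, tracked = roundtrip_run
        again = track_objects(frames, max_disp=8.0, channel="H3")
        pd.testing.assert_frame_equal(tracked, again)

    def test_rejects_nonpositive_max_disp(self):
        with pytest.raises(ValueError):
            track_objects([], max_disp=0.0)


class TestRoundTrip:
    def test_track_recovery(self, roundtrip_run):
        table, _, _, _, tracked = roundtrip_run
        assert tracked["nucleus_id"].nunique() == table["nucleus_id"].nunique()
        n_div_true = (table.groupby("nucleus_id")["parent_id"].first() >= 0).sum()
        n_div_tracked = (tracked.groupby("nucleus_id")["parent_id"].first()
                         >= 0).sum()
        assert n_div_tracked == n_div_true

    def test_chromatin_trend_reproduced_within_5pct(self, roundtrip_run):
        table, _, _, _, tracked = roundtrip_run
        # tracked tables carry no phase annotation; classify by the volume
        # drop at mitosis (chromatin mass much smaller than the nucleus)
        tr = tracked.copy()
        thresh = tr.groupby("cycle")["volume"].transform("median") * 0.45
        tr["phase"] = np.where(tr["volume"] < thresh, "mitosis", "interphase")
        true_cs = mitotic_chromatin_totals(table, "H3")
        est_cs = mitotic_chromatin_totals(tr, "H3")
        assert est_cs.normalized_mean(11) == pytest.approx(
            true_cs.normalized_mean(11), rel=0.05)


class TestIlastikReader:
    def test_default_mapping_round_trip(self, tmp_path):
        raw = pd.DataFrame({
            "frame": [0, 0, 1],
            "trackId": [1, 2, 1],
            "parentTrackId": [-1, -1, -1],
            "Center_of_the_object_0": [10.0, 40.0, 11.0],
            "Center_of_the_object_1": [12.0, 42.0, 13.0],
            "Center_of_the_object_2": [5.0, 5.0, 5.0],
            "Size_in_pixels_0": [200, 220, 210],
            "Total_Intensity_0": [5000.0, 5200.0, 5100.0],
            "Mean_Intensity_0": [25.0, 23.6, 24.3],
        })
        path = tmp_path / "export.csv"
        raw.to_csv(path, index=False)
        params = ImagingParams(pixel_size=0.5, z_step=1.0)
        table = read_ilastik_csv(path, channel="H3", params=params)
        assert set(table["nucleus_id"]) == {1, 2}
        assert table["x"].iloc[0] == pytest.approx(5.0)  # 10 px * 0.5 um
        assert table["volume"].iloc[0] == pytest.approx(200 * 0.25)
        assert table["total_H3"].iloc[0] == 5000.0
        assert table["t"].iloc[2] == pytest.approx(45.0)

    def test_missing_columns_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"frame": [0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="column"):
            read_ilastik_csv(path)

    def test_custom_column_map(self, tmp_path):
        raw = pd.DataFrame({"T": [0], "id": [7], "cx": [2.0], "cy": [3.0],
                            "npx": [100], "tot": [900.0], "mean": [9.0]})
        path = tmp_path / "custom.csv"
        raw.to_csv(path, index=False)
        table = read_ilastik_csv(path, column_map={
            "frame": "T", "nucleus_id": "id", "x": "cx", "y": "cy",
            "size_in_pixels": "npx", "total_intensity": "tot",
            "mean_intensity": "mean"})
        assert table["nucleus_id"].iloc[0] == 7
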