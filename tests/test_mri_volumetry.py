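"""3-D segmentation, counting, volumetry, diameter rules and tracking."""

import numpy as np
import pytest

from conftest import dice, flood_fill_count
from tuberphen.mri_volumetry import (
    GrowthTable,
    SeedSet,
    TuberLabelMap,
    TuberRecord,
    Volume3D,
    equivalent_diameter_mm,
    filter_tubers,
    label_and_count,
    load_labelmap,
    load_volume,
    measure_tubers,
    region_grow_levelset,
    save_labelmap,
    save_volume,
    summarize_conditions,
    track_tubers,
)
from tuberphen.synthetic_fixtures import (
    TuberSpec,
    default_mri_scene,
    make_mri_scene,
)


class TestIO:
    def test_labelmap_roundtrip_tiff_and_nifti(self, tmp_path):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 5, size=(32, 32, 32)).astype(np.int32)
        lm = TuberLabelMap(labels)
        for name in ("lm.tif", "lm.nii"):
            save_labelmap(lm, tmp_path / name)
            back = load_labelmap(tmp_path / name)
            assert np.array_equal(back.labels, labels)

    def test_nifti_header_voxel_size_read(self, tmp_path):
        arr = np.zeros((4, 5, 6), dtype=np.float32)
        save_volume(arr, tmp_path / "v.nii", voxel_size=(1.1, 1.0, 1.0))
        vol = load_volume(tmp_path / "v.nii")
        assert vol.voxel_size == pytest.approx((1.1, 1.0, 1.0))
        assert vol.shape == (4, 5, 6)

    def test_explicit_voxel_size_wins_over_header(self, tmp_path, caplog):
        arr = np.zeros((4, 4, 4), dtype=np.float32)
        save_volume(arr, tmp_path / "v.nii", voxel_size=(1.1, 1.0, 1.0))
        vol = load_volume(tmp_path / "v.nii", voxel_size=(2.0, 2.0, 2.0))
        assert vol.voxel_size == (2.0, 2.0, 2.0)

    def test_tiff_without_voxel_size_errors(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "v.tif", np.zeros((4, 4, 4), np.float32),
                         photometric="minisblack")
        with pytest.raises(ValueError, match="voxel size"):
            load_volume(tmp_path / "v.tif")


def _ellipsoid_volume(shape, center, radius, inside=200.0, outside=50.0,
                      noise=5.0, seed=0):
    zz, yy, xx = np.indices(shape)
    mask = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius ** 2
    rng = np.random.default_rng(seed)
    intens = np.where(mask, inside, outside) + rng.normal(0, noise, shape)
    return Volume3D(intens, voxel_size=(1.0, 1.0, 1.0)), mask


class TestRegionGrowing:
    def test_bright_ellipsoid_recovered(self):
        vol, truth = _ellipsoid_volume((40, 40, 40), (20, 20, 20), 10)
        seeds = np.zeros(vol.shape, dtype=np.int32)
        seeds[20, 17:24, 17:24] = 1
        grown = region_grow_levelset(vol, SeedSet(seeds), k=2.5)
        assert dice(grown.labels == 1, truth) >= 0.95

    def test_two_disjoint_spheres_stay_disjoint(self):
        vol, _ = _ellipsoid_volume((40, 40, 40), (12, 12, 12), 6)
        intens = vol.intensities.copy()
        zz, yy, xx = np.indices(vol.shape)
        second = ((zz - 28) ** 2 + (yy - 28) ** 2 + (xx - 28) ** 2) <= 36
        intens[second] = 200.0
        vol2 = Volume3D(intens, voxel_size=(1, 1, 1))
        seeds = np.zeros(vol.shape, dtype=np.int32)
        seeds[12, 11:14, 11:14] = 1
        seeds[28, 27:30, 27:30] = 2
        grown = region_grow_levelset(vol2, SeedSet(seeds), k=2.5)
        assert not np.any((grown.labels == 1) & second)
        assert set(np.unique(grown.labels)) == {0, 1, 2}

    def test_seed_on_background_keeps_seed_with_warning(self):
        vol, _ = _ellipsoid_volume((20, 20, 20), (10, 10, 10), 5, noise=0.0)
        seeds = np.zeros(vol.shape, dtype=np.int32)
        seeds[2, 2, 2] = 1  # constant background: sigma 0, band is degenerate
        intens = vol.intensities.copy()
        intens[2, 2, 2] = 250.0  # seed voxel unlike anything else
        with pytest.warns(UserWarning, match="seed 1"):
            grown = region_grow_levelset(
                Volume3D(intens, voxel_size=(1, 1, 1)), SeedSet(seeds), k=0.5,
                smooth=False)
        assert grown.labels[2, 2, 2] == 1
        assert (grown.labels == 1).sum() == 1

    def test_fixture_scene_dice(self, mri_sessions):
        sess = mri_sessions[-1]
        grown = region_grow_levelset(sess.volume, sess.seeds, k=2.5)
        for lab in sess.truth.label_ids:
            assert dice(grown.labels == lab, sess.truth.labels == lab) >= 0.95


class TestLabelAndCount:
    def test_two_separated_blobs(self):
        arr = np.zeros((10, 10, 10), dtype=bool)
        arr[1, 1, 1:6] = True
        arr[8, 8, 0:5] = True
        n, sizes = label_and_count(arr)
        assert n == 2 and sorted(sizes.values()) == [5, 5]

    def test_corner_touching_blobs_connectivity(self):
        arr = np.zeros((4, 4, 4), dtype=bool)
        arr[0, 0, 0] = True
        arr[1, 1, 1] = True  # touches only at a corner
        n26, _ = label_and_count(arr, connectivity=26)
        n6, _ = label_and_count(arr, connectivity=6)
        assert n26 == 1 and n6 == 2

    def test_empty_array(self):
        n, sizes = label_and_count(np.zeros((5, 5, 5), dtype=bool))
        assert n == 0 and sizes == {}

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_agrees_with_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(123)
        for _ in range(100):
            arr = rng.random((20, 20, 20)) < 0.2
            n, sizes = label_and_count(arr, connectivity=connectivity)
            n_oracle, sizes_oracle = flood_fill_count(arr, connectivity)
            assert n == n_oracle
            assert sorted(sizes.values()) == sizes_oracle

    def test_volume_conservation(self, mri_sessions):
        lm = mri_sessions[0].truth
        _, sizes = label_and_count(lm)
        assert sum(sizes.values()) == int((lm.labels > 0).sum())


class TestMeasurement:
    def test_thousand_voxels_at_default_voxel(self):
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        labels.flat[:1000] = 0
        labels[:10, :10, :10] = 1  # 1000 voxels
        rec, = measure_tubers(TuberLabelMap(labels))
        assert rec.volume_cm3 == pytest.approx(1.1, rel=1e-9)

    def test_single_voxel_closed_form(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[2, 2, 2] = 1
        rec, = measure_tubers(TuberLabelMap(labels))
        assert rec.volume_cm3 == pytest.approx(0.0011)
        assert rec.equivalent_diameter == pytest.approx(
            (6 * 1.1 / np.pi) ** (1 / 3))
        assert "sub_detectable" in rec.flags

    @pytest.mark.parametrize("r_mm", [5.0, 10.0, 15.0])
    def test_digitized_sphere_volume_within_5pct(self, r_mm):
        vs = (1.1, 1.0, 1.0)
        shape = (40, 40, 40)
        center = (20 * 1.1, 20.0, 20.0)
        zz = np.arange(shape[0]) * vs[0]
        yy = np.arange(shape[1]) * vs[1]
        xx = np.arange(shape[2]) * vs[2]
        inside = ((zz[:, None, None] - center[0]) ** 2
                  + (yy[None, :, None] - center[1]) ** 2
                  + (xx[None, None, :] - center[2]) ** 2) <= r_mm ** 2
        rec, = measure_tubers(TuberLabelMap(inside.astype(np.int32)), vs)
        analytic = 4.0 / 3.0 * np.pi * r_mm ** 3 / 1000.0
        assert rec.volume_cm3 == pytest.approx(analytic, rel=0.05)
        assert rec.equivalent_diameter == pytest.approx(2 * r_mm, rel=0.02)

    def test_voxel_calibration_linearity(self):
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels[2:5, 2:5, 2:5] = 1
        v1, = measure_tubers(TuberLabelMap(labels), (1.1, 1.0, 1.0))
        v2, = measure_tubers(TuberLabelMap(labels), (2.2, 1.0, 1.0))
        assert v2.volume_cm3 == pytest.approx(2 * v1.volume_cm3)


def _rec(tid, dase, diam, center=(0.0, 0.0, 0.0)):
    vol_mm3 = np.pi / 6.0 * diam ** 3
    return TuberRecord(tuber_id=tid, dase=dase,
                       voxel_count=max(int(vol_mm3 / 1.1), 1),
                       volume_cm3=vol_mm3 / 1000.0,
                       equivalent_diameter=diam, centroid_mm=center)


class TestDiameterRules:
    def test_final_under_15_excluded_from_all_sessions(self):
        records = {1: [_rec(1, 32, 8), _rec(1, 73, 14)]}
        retained, log = filter_tubers(records)
        assert retained == {}
        assert log[0]["reason"] == "below_yield_diameter"

    def test_small_early_sessions_retained_when_final_qualifies(self):
        records = {1: [_rec(1, 32, 4), _rec(1, 46, 9), _rec(1, 73, 16)]}
        retained, log = filter_tubers(records)
        assert len(retained[1]) == 3 and log == []

    def test_exactly_15_retained_boundary_is_strict(self):
        records = {1: [_rec(1, 73, 15.0)]}
        retained, _ = filter_tubers(records)
        assert 1 in retained

    def test_sub_detectable_flagged(self):
        records = {1: [_rec(1, 32, 2.5), _rec(1, 73, 20)]}
        retained, _ = filter_tubers(records)
        assert "sub_detectable" in retained[1][0].flags
        assert "sub_detectable" not in retained[1][1].flags

    def test_missing_final_record_errors(self):
        records = {1: [_rec(1, 73, 20)], 2: [_rec(2, 32, 10)]}
        with pytest.raises(ValueError, match="final session"):
            filter_tubers(records)


class TestTracking:
    def test_fixture_scene_identity(self, mri_sessions):
        sessions = []
        for sess in mri_sessions:
            sessions.append(measure_tubers(
                sess.truth, sess.volume.voxel_size, dase=sess.dase))
        table = track_tubers(sessions)
        # ground-truth identity: each track must carry one truth label only
        for recs in table.tracks.values():
            assert len({r.tuber_id for r in recs}) == 1

    def test_late_appearing_tuber_starts_short_track(self):
        s1 = [_rec(1, 32, 20, (10, 10, 10))]
        s2 = [_rec(1, 46, 22, (10, 10, 10)), _rec(2, 46, 5, (40, 40, 40))]
        s3 = [_rec(1, 73, 24, (10, 10, 10)), _rec(2, 73, 16, (40, 40, 40))]
        table = track_tubers([s1, s2, s3])
        lengths = sorted(len(v) for v in table.tracks.values())
        assert lengths == [2, 3]

    def test_ranking_sorted_by_final_volume(self):
        s1 = [_rec(i, 32, d, (float(20 * i), 0, 0))
              for i, d in [(1, 10), (2, 25), (3, 18)]]
        s2 = [_rec(i, 73, d, (float(20 * i), 0, 0))
              for i, d in [(1, 21), (2, 42.5), (3, 32)]]
        table = track_tubers([s1, s2])
        finals = [table.tracks[t][-1].volume_cm3 for t in table.ranking]
        assert finals == sorted(finals, reverse=True)
        assert table.rank_name(table.ranking[0]) == "Tuber-01"

    def test_competing_match_resolved_by_distance(self):
        s1 = [_rec(1, 32, 20, (10.0, 10.0, 10.0))]
        s2 = [_rec(1, 46, 20, (12.0, 10.0, 10.0)),
              _rec(2, 46, 8, (18.0, 10.0, 10.0))]
        table = track_tubers([s1, s2])
        assert len(table.tracks) == 2
        two_long = [t for t, v in table.tracks.items() if len(v) == 2]
        assert len(two_long) == 1
        assert table.tracks[two_long[0]][1].centroid_mm[0] == 12.0

    def test_needs_two_sessions(self):
        with pytest.raises(ValueError):
            track_tubers([[_rec(1, 32, 20)]])


class TestConditionSummary:
    @staticmethod
    def _table(plant, cond, scale, seed):
        rng = np.random.default_rng(seed)
        tracks = {}
        for tid in range(1, 4):
            tracks[tid] = [
                _rec(tid, dase, 16 + tid + float(rng.normal(0, 0.2)))
                for dase in (32, 46, 73)
            ]
            for i, r in enumerate(tracks[tid]):
                tracks[tid][i] = TuberRecord(
                    tuber_id=r.tuber_id, dase=r.dase,
                    voxel_count=r.voxel_count,
                    volume_cm3=r.volume_cm3 * scale,
                    equivalent_diameter=r.equivalent_diameter,
                    centroid_mm=r.centroid_mm)
        return GrowthTable(plant, cond, tracks, [3, 2, 1])

    def test_shifted_condition_gets_distinct_letter_early(self):
        tables = [self._table(f"c{i}", "Control", 1.0, i) for i in range(4)]
        tables += [self._table(f"m{i}", "MWD", 1.5, 10 + i) for i in range(4)]
        df = summarize_conditions(tables)
        first = df[df.dase == 32]
        letters = dict(zip(first.condition, first.volume_letters))
        assert letters["Control"] != letters["MWD"]

    def test_identical_conditions_share_letters(self):
        tables = [self._table(f"c{i}", "Control", 1.0, i) for i in range(3)]
        tables += [self._table(f"m{i}", "MWD", 1.0, i) for i in range(3)]
        df = summarize_conditions(tables)
        for _, row in df.groupby("dase"):
            assert len(set(row.volume_letters)) == 1

    def test_single_plant_suppresses_letters(self):
        tables = [self._table("c0", "Control", 1.0, 0),
                  self._table("m0", "MWD", 1.5, 1)]
        df = summarize_conditions(tables)
        assert df.volume_letters.isna().all()


class TestDiameterFormula:
    def test_equivalent_diameter_inverts_sphere_volume(self):
        for d in (3.0, 15.0, 40.0):
            v = np.pi / 6.0 * d ** 3
            assert equivalent_diameter_mm(v) == pytest.approx(d)
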