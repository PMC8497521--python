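"""Bead aggregates: centre, detection, filtering, normalization, models."""

import math

import numpy as np
import pandas as pd
import pytest

from plasmidquant import bead as bd
from plasmidquant.imagecore import BinaryMask


def _mask(arr):
    return BinaryMask(foreground=np.asarray(arr, dtype=bool), channel="x")


def _table(**cols):
    defaults = {"bead_id": 0, "channel": "green", "n_voxels": 100,
                "volume_um3": 100.0, "centroid_z_um": 0.0,
                "centroid_y_um": 0.0, "centroid_x_um": 0.0,
                "distance_um": 10.0}
    n = max(len(v) for v in cols.values() if hasattr(v, "__len__"))
    data = {}
    for key in defaults:
        val = cols.get(key, defaults[key])
        data[key] = val if hasattr(val, "__len__") and not \
            isinstance(val, str) else [val] * n
    return pd.DataFrame(data)


class TestBeadCenter:
    def test_centered_sphere_center_recovered(self):
        arr = np.zeros((21, 21, 21))
        zz, yy, xx = np.mgrid[:21, :21, :21]
        arr[(zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 36] = 1
        c = bd.bead_center(_mask(arr), _mask(np.zeros_like(arr)),
                           voxel_size=(2.0, 1.0, 1.0))
        assert c.z_um == pytest.approx(20.0, abs=1.0)
        assert c.y_um == pytest.approx(10.0, abs=0.5)
        assert c.x_um == pytest.approx(10.0, abs=0.5)

    def test_median_robust_to_outlier_where_mean_is_not(self):
        arr = np.zeros((21, 21, 21))
        zz, yy, xx = np.mgrid[:21, :21, :21]
        sphere = (zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 36
        arr[sphere] = 1
        base = bd.bead_center(_mask(arr), _mask(np.zeros_like(arr)),
                              (1, 1, 1))
        arr_out = arr.copy()
        arr_out[0, 0, 0] = 1  # distant stray voxel
        with_out = bd.bead_center(_mask(arr_out), _mask(np.zeros_like(arr)),
                                  (1, 1, 1))
        assert with_out.z_um == base.z_um  # median unmoved
        idx = np.nonzero(arr_out)
        assert np.mean(idx[0]) < 10.0  # the mean does move

    def test_matches_sorting_oracle(self, rng):
        arr = rng.random((10, 12, 14)) < 0.2
        if not arr.any():
            arr[0, 0, 0] = True
        c = bd.bead_center(_mask(arr), _mask(np.zeros_like(arr)),
                           (1.5, 0.5, 0.5))
        idx = np.nonzero(arr)
        expected = [float(np.sort(ax)[len(ax) // 2]) if len(ax) % 2
                    else float(np.mean(np.sort(ax)[len(ax) // 2 - 1:
                                                   len(ax) // 2 + 1]))
                    for ax in idx]
        assert c.z_um == pytest.approx(expected[0] * 1.5)
        assert c.y_um == pytest.approx(expected[1] * 0.5)
        assert c.x_um == pytest.approx(expected[2] * 0.5)

    def test_empty_union_raises(self):
        z = np.zeros((3, 3, 3))
        with pytest.raises(ValueError, match="no foreground"):
            bd.bead_center(_mask(z), _mask(z), (1, 1, 1))


class TestDetectAggregates:
    def test_unit_voxel_block_volume(self):
        arr = np.zeros((6, 6, 6))
        arr[1:3, 1:3, 1:3] = 1
        center = bd.BeadCenter(0, 0, 0, 1)
        t = bd.detect_aggregates(_mask(arr), _mask(np.zeros_like(arr)),
                                 (1, 1, 1), center)
        assert len(t) == 1
        assert t["volume_um3"].iloc[0] == pytest.approx(8.0)

    def test_anisotropic_voxel_volume_scaling(self):
        arr = np.zeros((6, 6, 6))
        arr[1:3, 1:3, 1:3] = 1
        center = bd.BeadCenter(0, 0, 0, 1)
        t = bd.detect_aggregates(_mask(arr), _mask(np.zeros_like(arr)),
                                 (1.0, 0.25, 0.25), center)
        assert t["volume_um3"].iloc[0] == pytest.approx(8 * 0.0625)

    def test_channels_labelled_independently(self):
        a = np.zeros((5, 5, 5))
        a[0, 0, 0] = 1
        b = np.zeros((5, 5, 5))
        b[0, 0, 1] = 1  # adjacent to a's voxel, but in the other channel
        center = bd.BeadCenter(0, 0, 0, 1)
        t = bd.detect_aggregates(_mask(a), _mask(b), (1, 1, 1), center)
        assert len(t) == 2
        assert set(t["channel"]) == {"green", "red"}
        # adding voxels to one channel never changes the other's table
        b2 = b.copy()
        b2[3, 3, 3] = 1
        t2 = bd.detect_aggregates(_mask(a), _mask(b2), (1, 1, 1), center)
        pd.testing.assert_frame_equal(
            t[t["channel"] == "green"].reset_index(drop=True),
            t2[t2["channel"] == "green"].reset_index(drop=True))

    def test_empty_masks_empty_table(self):
        z = np.zeros((4, 4, 4))
        t = bd.detect_aggregates(_mask(z), _mask(z), (1, 1, 1),
                                 bd.BeadCenter(0, 0, 0, 0))
        assert t.empty

    def test_generator_truth_volumes_recovered(self, segmented_bead):
        truth, img, table, free, carrier = segmented_bead
        center = bd.bead_center(free, carrier, img.voxel_size)
        det = bd.detect_aggregates(free, carrier, img.voxel_size, center)
        vox_vol = np.prod(img.voxel_size)
        matched = 0
        for _, row in table.iterrows():
            sub = det[det["channel"] == row["channel"]]
            d = np.linalg.norm(
                sub[["centroid_z_um", "centroid_y_um",
                     "centroid_x_um"]].to_numpy()
                - row[["centroid_z_um", "centroid_y_um",
                       "centroid_x_um"]].to_numpy(dtype=float), axis=1)
            if len(d) and d.min() <= 2.0:
                hit = sub.iloc[int(np.argmin(d))]
                bound = (row["surface_voxels"] + 1) * vox_vol
                assert abs(hit["volume_um3"]
                           - row["volume_rendered_um3"]) <= bound
                matched += 1
        assert matched >= 0.9 * len(table)


class TestFilterAggregates:
    def test_volume_boundary_is_inclusive_at_50(self):
        t = _table(volume_um3=[49.9, 50.0, 50.1],
                   distance_um=[10.0, 10.0, 10.0])
        out = bd.filter_aggregates(t, min_volume=50.0, bead_radius_um=100.0)
        assert list(out["retained"]) == [False, True, True]
        assert "volume" in out["removal_reason"].iloc[0]

    def test_aggregate_outside_bead_removed(self):
        t = _table(volume_um3=[100.0, 100.0, 100.0, 100.0],
                   distance_um=[10.0, 50.0, 90.0, 130.0])
        out = bd.filter_aggregates(t, min_volume=50.0, bead_radius_um=100.0)
        assert list(out["retained"]) == [True, True, True, False]
        assert "outside" in out["removal_reason"].iloc[3]

    def test_empty_table_passthrough(self):
        out = bd.filter_aggregates(_table(volume_um3=[]).iloc[:0])
        assert out.empty
        assert "retained" in out.columns


class TestNormalizeDistances:
    def test_simple_arithmetic(self):
        t = bd.filter_aggregates(
            _table(volume_um3=[100.0] * 3,
                   distance_um=[100.0, 200.0, 400.0]),
            bead_radius_um=500.0)
        out = bd.normalize_distances(t)
        assert list(out["normalized_distance"]) == [0.25, 0.5, 1.0]

    def test_equidistant_aggregates_all_one(self):
        t = bd.filter_aggregates(
            _table(volume_um3=[100.0] * 3, distance_um=[50.0] * 3),
            bead_radius_um=100.0)
        out = bd.normalize_distances(t)
        assert (out["normalized_distance"] == 1.0).all()

    def test_per_bead_independence_matches_groupwise_max(self, rng):
        n = 40
        t = _table(volume_um3=[100.0] * n,
                   distance_um=list(rng.uniform(1, 300, n)))
        t["bead_id"] = rng.choice(["b1", "b2", "b3"], size=n)
        t = bd.filter_aggregates(t, bead_radius_um=1000.0)
        out = bd.normalize_distances(t)
        for bead, sub in out.groupby("bead_id"):
            dmax = sub["distance_um"].max()  # brute-force per-bead max
            assert np.allclose(sub["normalized_distance"],
                               sub["distance_um"] / dmax)
            assert sub["normalized_distance"].max() == 1.0

    def test_scale_invariance_under_voxel_rescaling(self):
        d = [10.0, 20.0, 40.0]
        t1 = bd.normalize_distances(bd.filter_aggregates(
            _table(volume_um3=[100.0] * 3, distance_um=d),
            bead_radius_um=100.0))
        t2 = bd.normalize_distances(bd.filter_aggregates(
            _table(volume_um3=[100.0] * 3,
                   distance_um=[3 * x for x in d]),
            bead_radius_um=300.0))
        assert np.allclose(t1["normalized_distance"],
                           t2["normalized_distance"])

    def test_single_aggregate_flagged(self):
        t = bd.filter_aggregates(_table(volume_um3=[60.0],
                                        distance_um=[30.0]),
                                 bead_radius_um=100.0)
        out = bd.normalize_distances(t)
        assert out["normalized_distance"].iloc[0] == 1.0
        assert out["normalization_flag"].iloc[0] == "single aggregate"


class TestLossRatio:
    def test_simple_count_ratio(self):
        t = _table(volume_um3=[100.0] * 25,
                   channel=["green"] * 5 + ["red"] * 20)
        t["retained"] = True
        out = bd.loss_ratio(t)
        pooled = out[out["bead_id"] == "pooled"].iloc[0]
        assert pooled["ratio"] == pytest.approx(0.25)

    def test_zero_green_gives_zero(self):
        t = _table(volume_um3=[100.0] * 4, channel=["red"] * 4)
        t["retained"] = True
        out = bd.loss_ratio(t)
        assert out[out["bead_id"] == "pooled"]["ratio"].iloc[0] == 0.0

    def test_zero_red_flagged_infinite(self):
        t = _table(volume_um3=[100.0] * 3, channel=["green"] * 3)
        t["retained"] = True
        out = bd.loss_ratio(t)
        pooled = out[out["bead_id"] == "pooled"].iloc[0]
        assert pooled["ratio"] == math.inf
        assert pooled["flag"] == "no carrier"

    def test_generator_free_fraction_recovered(self, segmented_bead):
        truth, img, table, free, carrier = segmented_bead
        center = bd.bead_center(free, carrier, img.voxel_size)
        det = bd.normalize_distances(bd.filter_aggregates(
            bd.detect_aggregates(free, carrier, img.voxel_size, center),
            min_volume=50.0))
        pooled = bd.loss_ratio(det)
        r = pooled[pooled["bead_id"] == "pooled"]["ratio"].iloc[0]
        # binomial CI around free_fraction/(1-free_fraction) at n ~ 30
        expect = truth.free_fraction / (1 - truth.free_fraction)
        assert 0.3 * expect < r < 3.0 * expect


class TestSizeModels:
    def test_exact_loglinear_data_recovered(self):
        d = np.linspace(0, 1, 20)
        t = _table(volume_um3=list(10 ** (2 + 0.8 * d)),
                   distance_um=list(100 * d + 1))
        t["retained"] = True
        t["normalized_distance"] = d
        reg = bd.size_distance_regression(t)
        assert reg["slope"] == pytest.approx(0.8, abs=1e-10)
        assert reg["intercept"] == pytest.approx(2.0, abs=1e-10)

    def test_constant_volumes_zero_slope(self):
        d = np.linspace(0, 1, 10)
        t = _table(volume_um3=[100.0] * 10, distance_um=list(d * 50 + 1))
        t["retained"] = True
        t["normalized_distance"] = d
        reg = bd.size_distance_regression(t)
        assert reg["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_distance_variance_raises(self):
        t = _table(volume_um3=[100.0] * 5, distance_um=[10.0] * 5)
        t["retained"] = True
        t["normalized_distance"] = 1.0
        with pytest.raises(ValueError, match="variance"):
            bd.size_distance_regression(t)

    def test_lmm_balanced_fixture_equals_difference_of_status_means(self):
        """With equal aggregates per bead per status the status estimate is
        the plain difference of status means (verifiable by hand)."""
        rows = []
        rng = np.random.default_rng(5)
        for bead in range(4):
            shift = rng.normal(0, 0.3)
            for status, mu in (("green", 2.4), ("red", 2.1)):
                for _ in range(6):
                    rows.append({"bead_id": bead, "channel": status,
                                 "volume_um3": 10 ** (mu + shift
                                                      + rng.normal(0, 0.1)),
                                 "distance_um": 10.0})
        t = pd.DataFrame(rows)
        t["retained"] = True
        res = bd.size_by_status_lmm(t)
        y = np.log10(t["volume_um3"])
        hand = y[t["channel"] == "green"].mean() \
            - y[t["channel"] == "red"].mean()
        assert res["status_effect"] == pytest.approx(hand, abs=1e-8)

    def test_lmm_single_bead_falls_back_to_ols(self):
        t = _table(volume_um3=[100.0, 120.0, 60.0, 70.0],
                   channel=["green", "green", "red", "red"])
        t["retained"] = True
        with pytest.warns(UserWarning, match="single bead"):
            res = bd.size_by_status_lmm(t)
        assert res["method"] == "ols_fallback"

    def test_filter_then_normalize_order_is_fixed(self):
        """The pipeline normalizes by the max *retained* distance: a far
        small aggregate removed by the filter must not stretch the scale."""
        t = _table(volume_um3=[100.0, 100.0, 10.0],
                   distance_um=[50.0, 100.0, 200.0])
        out = bd.normalize_distances(
            bd.filter_aggregates(t, min_volume=50.0, bead_radius_um=300.0))
        kept = out[out["retained"]]
        assert kept["normalized_distance"].max() == 1.0
        assert kept["normalized_distance"].iloc[0] == pytest.approx(0.5)
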