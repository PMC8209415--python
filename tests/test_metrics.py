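import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrgridqa import metrics


def corr_frame(x, y, x1, y1):
    return pd.DataFrame({"x": x, "y": y, "x1": x1, "y1": y1})


class TestDistances:
    def test_plane_distortion_values(self):
        assert metrics.plane_distortion(0, 0, 0, 0) == 0.0
        assert metrics.plane_distortion(0, 0, 3, 4) == 5.0
        assert metrics.plane_distortion(1, 2, 4, 6) == metrics.plane_distortion(4, 6, 1, 2)

    def test_3d_distortion_values(self):
        assert metrics.distortion_3d(0, 0, 0, 1, 2, 2) == 3.0
        # planar reduction
        assert metrics.distortion_3d(1, 1, 5, 4, 5, 5) == metrics.plane_distortion(1, 1, 4, 5)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=6))
    def test_3d_at_least_plane(self, v):
        x, y, z, x1, y1, z1 = v
        assert metrics.distortion_3d(x, y, z, x1, y1, z1) >= metrics.plane_distortion(
            x, y, x1, y1
        ) - 1e-12


class TestRadialSummary:
    def test_hand_enumerated_cumulative_rows(self):
        # nodes at 30/70/120 mm from centre with distortions 1/2/3
        corr = corr_frame([30, 70, 120], [0, 0, 0], [31, 72, 123], [0, 0, 0])
        t = metrics.radial_summary(corr, radii=[50, 100, 150])
        assert list(t["n"]) == [1, 2, 3]
        assert list(t["mean_mm"]) == [1.0, 1.5, 2.0]

    def test_constant_distortion(self):
        corr = corr_frame([10, 60, 110], [0, 0, 0], [10, 60, 110], [1.5, 1.5, 1.5])
        t = metrics.radial_summary(corr, radii=[150])
        assert t["mean_mm"].item() == 1.5
        assert t["sd_mm"].item() == 0.0

    def test_whole_disc_row_equals_global_stats(self, rng):
        n = 200
        corr = corr_frame(
            rng.uniform(-170, 170, n),
            rng.uniform(-125, 170, n),
            rng.uniform(-170, 170, n),
            rng.uniform(-125, 170, n),
        )
        t = metrics.radial_summary(corr, radii=[50, 100, 150, 400])
        d = metrics.attach_plane_distortion(corr)["plane_d_mm"]
        assert t["mean_mm"].iloc[-1] == d.mean()
        assert t["sd_mm"].iloc[-1] == d.std(ddof=1)

    def test_empty_disc_warns_and_omits(self):
        corr = corr_frame([100.0], [0.0], [101.0], [0.0])
        with pytest.warns(UserWarning, match="row omitted"):
            t = metrics.radial_summary(corr, radii=[10, 150])
        assert list(t["radius_mm"]) == [150.0]

    def test_monotone_for_radially_increasing_field(self, rng):
        r = rng.uniform(5, 170, 300)
        th = rng.uniform(0, 2 * np.pi, 300)
        x, y = r * np.cos(th), r * np.sin(th)
        d = 3.0 * (r / 170.0) ** 3
        corr = corr_frame(x, y, x + d, y)
        t = metrics.radial_summary(corr, radii=[50, 100, 150, 200])
        assert (np.diff(t["mean_mm"]) >= 0).all()


class TestFractionBelow:
    def test_counts(self):
        corr = corr_frame([0, 0, 0, 0], [0] * 4, [1, 1, 3, 5], [0] * 4)
        assert metrics.fraction_below(corr, 2.0) == 0.5
        assert metrics.fraction_below(corr, 10.0) == 1.0
        assert metrics.fraction_below(corr, 0.5) == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 6), min_size=1, max_size=40), st.floats(0.1, 5))
    def test_complement_sums_to_one(self, ds, thr):
        corr = corr_frame([0] * len(ds), [0] * len(ds), ds, [0] * len(ds))
        below = metrics.fraction_below(corr, thr)
        d = metrics.attach_plane_distortion(corr)["plane_d_mm"]
        at_or_above = float((d >= thr).mean())
        assert below + at_or_above == 1.0


class TestHistogram:
    def test_conservation_and_binning(self):
        corr = corr_frame([0] * 4, [0] * 4, [0.6, 0.6, 1.2, 0.1], [0] * 4)
        h = metrics.histogram(corr, bin_mm=0.5)
        assert h["count"].sum() == 4
        assert h.loc[(h.bin_lo_mm == 0.5), "count"].item() == 2
        assert h.loc[(h.bin_lo_mm == 0.0), "count"].item() == 1

    def test_uniform_fills_bins_evenly(self, rng):
        d = rng.uniform(0, 2.5, 20000)
        corr = corr_frame(np.zeros_like(d), np.zeros_like(d), d, np.zeros_like(d))
        h = metrics.histogram(corr, bin_mm=0.5)
        assert len(h) == 5
        assert np.allclose(h["count"], 4000, rtol=0.1)


class TestMarkPoints:
    def test_clockwise_from_plus_y(self):
        m = metrics.mark_points().set_index("point_id")
        assert m.loc["r50_a0", ["x", "y"]].to_list() == pytest.approx([0.0, 50.0])
        assert m.loc["r50_a90", ["x", "y"]].to_list() == pytest.approx([50.0, 0.0])
        assert m.loc["r100_a180", ["x", "y"]].to_list() == pytest.approx([0.0, -100.0])
        assert m.loc["r150_a270", ["x", "y"]].to_list() == pytest.approx([-150.0, 0.0])

    def test_default_set_has_eleven_points(self):
        m = metrics.mark_points()
        assert len(m) == 11
        assert "r150_a180" not in set(m["point_id"])


class TestLayerSelection:
    def test_exactly_30_selects_all(self):
        assert list(metrics.select_layers(30, 30)) == list(range(30))

    def test_90_slices_rule(self):
        sel = metrics.select_layers(90, 30)
        assert sel[0] == 0
        assert list(sel[1:]) == [(g + 1) * 3 - 1 for g in range(1, 30)]

    def test_too_few_slices_raises(self):
        with pytest.raises(ValueError):
            metrics.select_layers(20, 30)


def make_profiles(n_layers=30, dz=3.0, drift=0.0):
    marks = metrics.mark_points()
    rows = []
    for s in range(n_layers):
        for _, m in marks.iterrows():
            rows.append(
                {
                    "point_id": m.point_id,
                    "radius_mm": m.radius_mm,
                    "angle_deg": m.angle_deg,
                    "node_id": 0,
                    "slice_index": s,
                    "z": s * dz,
                    "x": m.x + drift * s,
                    "y": m.y,
                }
            )
    return pd.DataFrame(rows)


class TestMark3D:
    def test_identical_layers_give_slice_spacing(self):
        t = metrics.mark_point_3d_summary(make_profiles(dz=3.0))
        assert np.allclose(t["mean_mm"], 3.0)
        assert np.allclose(t["sd_mm"], 0.0)

    def test_planar_mode_zero_for_no_drift(self):
        t = metrics.mark_point_3d_summary(make_profiles(dz=3.0), z_mode="planar")
        assert np.allclose(t["mean_mm"], 0.0)

    def test_constant_drift(self):
        t = metrics.mark_point_3d_summary(make_profiles(dz=0.0, drift=0.5), z_mode="planar")
        assert np.allclose(t["mean_mm"], 0.5)

    def test_average_rows_pool_angles(self):
        t = metrics.mark_point_3d_summary(make_profiles())
        avg = t[t.label == "average"]
        assert list(avg["radius_mm"]) == [50.0, 100.0, 150.0]
        assert list(avg["n_pairs"]) == [4 * 29, 4 * 29, 3 * 29]


class TestExportField:
    def test_zero_field_and_consistency(self, rng):
        x = rng.uniform(-100, 100, 50)
        y = rng.uniform(-100, 100, 50)
        corr = corr_frame(x, y, x, y)
        v = metrics.export_field(corr)
        assert (v[["dx", "dy", "d"]].to_numpy() == 0).all()
        corr2 = corr_frame(x, y, x + 1.0, y - 2.0)
        v2 = metrics.export_field(corr2)
        assert len(v2) == 50
        assert np.allclose(v2["d"], np.hypot(v2["dx"], v2["dy"]))
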