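import numpy as np
import pytest

from mrgridqa.distortion import radial_model, zero_model
from mrgridqa.phantom import build_phantom
from mrgridqa.protocols import PRESETS, protocol_preset
from mrgridqa.simulate import (
    CT_INTENSITY,
    MR_INTENSITY,
    material_codes,
    render_mr,
    render_reference,
    slice_positions,
    true_displacements,
)


class TestProtocols:
    @pytest.mark.parametrize(
        "name, fov, matrix, bw, thick",
        [
            ("unity", 537.6, 1008, 1033.0, 1.6),
            ("ge_hde", 480.0, 512, 195.31, 5.0),
            ("ge_750", 500.0, 512, 195.31, 3.0),
        ],
    )
    def test_presets(self, name, fov, matrix, bw, thick):
        p = protocol_preset(name)
        assert (p.fov_mm, p.matrix, p.pixel_bandwidth_hz_per_px) == (fov, matrix, bw)
        assert p.slice_thickness_mm == thick

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            protocol_preset("philips")

    def test_pixel_sizes(self):
        assert protocol_preset("ge_hde").pixel_size_mm == pytest.approx(0.9375)
        assert protocol_preset("unity").pixel_size_mm == pytest.approx(0.5333333333)


class TestGeometry:
    def test_slice_positions_centred_foot_to_head(self, proto750):
        zs = slice_positions(proto750, 5)
        assert np.allclose(zs, [-6, -3, 0, 3, 6])

    def test_odd_matrix_voxel_on_isocenter(self, spec):
        proto = protocol_preset("ge_750", matrix=501)
        vol = render_reference(spec, proto, n_slices=1)
        xs, ys = vol.pixel_coords_mm()
        assert 0.0 in xs and 0.0 in ys

    def test_even_matrix_isocenter_between_voxels(self, ref750):
        xs, _ = ref750.pixel_coords_mm()
        assert 0.0 not in xs
        assert np.min(np.abs(xs)) == pytest.approx(ref750.pixel_size_mm / 2)

    def test_phantom_exceeding_fov_raises(self, spec):
        small = protocol_preset("ge_750", fov_mm=300.0)
        with pytest.raises(ValueError, match="exceeds FOV"):
            render_reference(spec, small, n_slices=1)


class TestMaterials:
    def test_marker_water_and_air(self, spec):
        codes = material_codes(
            spec, np.array([0.0, 5.0, 300.0]), np.array([0.0, 5.0, 0.0])
        )
        assert codes[0] == 2  # diamond centre: resin
        assert codes[1] == 1  # cell interior: water
        assert codes[2] == 0  # outside face circle: air

    def test_cut_side_is_air(self, spec):
        assert material_codes(spec, np.array([0.0]), np.array([-180.0]))[0] == 0


class TestRenderReference:
    def test_deterministic(self, spec, proto750, ref750):
        again = render_reference(spec, proto750, n_slices=1)
        assert np.array_equal(again.data, ref750.data)

    def test_contrast(self, ref750):
        xs, ys = ref750.pixel_coords_mm()
        cc = np.argmin(np.abs(xs)), np.argmin(np.abs(ys))
        # diamond centre voxel is solid resin (bright on CT role)
        assert ref750.data[0, cc[1], cc[0]] == CT_INTENSITY["resin"]
        # a cell centre is water (dark on CT role)
        col = np.argmin(np.abs(xs - 45.0))
        row = np.argmin(np.abs(ys - 45.0))
        assert ref750.data[0, row, col] == CT_INTENSITY["water"]


class TestRenderMR:
    def test_null_warp_inverts_contrast_only(self, spec, proto750, ref750):
        mr = render_mr(spec, proto750, zero_model(), n_slices=1)
        # identical geometry, swapped water/resin contrast: pixels that are
        # pure material in the reference are the matching pure material in
        # the MR render (anti-aliased boundary pixels are intermediate)
        ref_sl, mr_sl = ref750.data[0], mr.data[0]
        pure_wall = ref_sl == CT_INTENSITY["resin"]
        pure_water = ref_sl == CT_INTENSITY["water"]
        assert pure_wall.any() and pure_water.any()
        assert (mr_sl[pure_wall] == MR_INTENSITY["resin"]).all()
        assert (mr_sl[pure_water] == MR_INTENSITY["water"]).all()
        # and the interior contrast is inverted overall
        inside = (ref_sl > 0) & (mr_sl > 0)
        corr = np.corrcoef(ref_sl[inside], mr_sl[inside])[0, 1]
        assert corr < -0.7

    def test_pure_translation_shifts_content(self, spec, proto750, ref750):
        from skimage.registration import phase_cross_correlation

        shift_mm = (1.5, -0.9)  # (dx, dy)
        # a constant displacement cannot vanish at the isocenter, so the
        # translation is emulated by shifting the sampling grid instead
        mr = render_mr(
            spec, proto750, zero_model(), n_slices=1,
            origin_shift=(shift_mm[0], shift_mm[1]),
        )
        ref_mr = render_mr(spec, proto750, zero_model(), n_slices=1)
        (drow, dcol), _, _ = phase_cross_correlation(
            ref_mr.data[0], mr.data[0], upsample_factor=50
        )
        px = proto750.pixel_size_mm
        assert dcol * px == pytest.approx(shift_mm[0], abs=0.1 * px)
        assert drow * px == pytest.approx(shift_mm[1], abs=0.1 * px)

    def test_seed_contract(self, spec, proto750):
        m1 = radial_model(1.0, seed=7)
        m2 = radial_model(1.0, seed=8)
        a = render_mr(spec, proto750, m1, snr=15, n_slices=1)
        b = render_mr(spec, proto750, m1, snr=15, n_slices=1)
        c = render_mr(spec, proto750, m2, snr=15, n_slices=1)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_large_field_warns(self, spec, proto750):
        with pytest.warns(RuntimeWarning, match="half the cell pitch"):
            render_mr(spec, proto750, radial_model(8.0), n_slices=1)


class TestTrueDisplacements:
    def test_zero_model_all_zero(self, proto750, lattice):
        t = true_displacements(zero_model(), proto750, lattice, [0.0, 10.0])
        assert (t[["dx", "dy", "dz", "d_plane"]].to_numpy() == 0).all()
        assert len(t) == 2 * lattice.n_nodes

    def test_isocenter_row_zero(self, proto750, lattice, model3):
        t = true_displacements(model3, proto750, lattice, [0.0])
        row = t[(t.x == 0) & (t.y == 0)]
        assert np.allclose(row[["dx", "dy", "dz"]], 0.0)

    def test_oracle_bounds_recovered_distortion(
        self, proto750, lattice, model3, ref750_detected, mr750_3mm_detected
    ):
        t = true_displacements(model3, proto750, lattice, [0.0])
        rec = np.hypot(
            mr750_3mm_detected.x_det - ref750_detected.x_det,
            mr750_3mm_detected.y_det - ref750_detected.y_det,
        )
        # detector tolerance: a recovered value never exceeds the field's
        # true maximum by more than the detection error budget
        assert np.nanmax(rec) <= t.d_plane.max() + 0.3
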