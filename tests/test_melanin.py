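"""F_RPE fusion and melanin quantification: counting, areas, volumes."""

import numpy as np
import pytest
from PIL import Image

from melanoct import (
    FRPEVolume,
    MelaninThicknessMap,
    compute_frpe,
    enface_projection,
    lesion_area,
    ped_volume,
    render_colormap,
    thickness_map,
    transverse_scale,
)
from melanoct.contrast import AngioVolume, AttenuationVolume
from melanoct.polarimetry import DOPUVolume


def _inputs(shape=(2, 4, 8), dopu=0.7, mu_norm=0.6, flow=False):
    ones = np.ones(shape)
    d = DOPUVolume(dopu=dopu * ones, valid_mask=np.ones(shape, bool))
    a = AttenuationVolume(mu_mm1=mu_norm * 10 * ones, mu_norm=mu_norm * ones,
                          mu_ref_mm1=10.0, tail_cutoff_px=0,
                          valid_mask=np.ones(shape, bool))
    dec = np.ones(shape) if flow else np.zeros(shape)
    an = AngioVolume(decorrelation=dec, binary_flow=dec >= 0.3, threshold=0.3)
    return d, a, an


class TestFRPE:
    def test_uniform_dopu_one_zeroes_index(self):
        f = compute_frpe(*_inputs(dopu=1.0))
        assert np.all(f.frpe == 0.0)

    def test_flow_voxels_excluded(self):
        f = compute_frpe(*_inputs(flow=True))
        assert np.all(f.frpe == 0.0)

    def test_printed_operating_point(self):
        """mu_norm 0.6, DOPU 0.7, no flow: F = 0.18, above the 0.15 cut."""
        f = compute_frpe(*_inputs(dopu=0.7, mu_norm=0.6))
        assert np.allclose(f.frpe, 0.18)
        assert np.all(f.frpe >= f.pixel_threshold)

    def test_invalid_inputs_zeroed(self):
        d, a, an = _inputs()
        d.valid_mask[0] = False
        f = compute_frpe(d, a, an)
        assert np.all(f.frpe[0] == 0.0)
        assert np.all(f.frpe[1] > 0.0)

    def test_dimension_mismatch_rejected(self):
        d, a, an = _inputs()
        d2 = DOPUVolume(dopu=np.ones((2, 4, 9)), valid_mask=np.ones((2, 4, 9), bool))
        with pytest.raises(ValueError, match="dimensions"):
            compute_frpe(d2, a, an)

    def test_provenance_recorded(self):
        d, a, an = _inputs()
        d.source = "synthesized"
        f = compute_frpe(d, a, an)
        assert f.inputs_provenance["dopu_source"] == "synthesized"


class TestThicknessMap:
    def test_counts_times_pitch(self):
        frpe = np.zeros((2, 3, 40))
        frpe[0, 0, 2:20] = 0.2            # 18 suprathreshold voxels
        frpe[1, 2, [5, 9, 30]] = 0.99     # non-contiguous counting
        fv = FRPEVolume(frpe=frpe, pixel_threshold=0.15, axial_pitch_um=4.0)
        m = thickness_map(fv, aline_pitch_mm=0.05, bscan_pitch_mm=0.1)
        assert m.thickness_um[0, 0] == 72.0
        assert m.thickness_um[1, 2] == 12.0
        assert m.thickness_um[0, 1] == 0.0

    def test_zero_volume_and_invariants(self):
        fv = FRPEVolume(frpe=np.zeros((3, 4, 16)), axial_pitch_um=4.0)
        m = thickness_map(fv, 0.05, 0.1)
        assert np.all(m.thickness_um == 0.0)
        m2 = thickness_map(fv, 0.05, 0.1)
        assert np.array_equal(m.thickness_um, m2.thickness_um)  # deterministic
        rng = np.random.default_rng(0)
        fv3 = FRPEVolume(frpe=rng.uniform(0, 0.4, (3, 4, 16)), axial_pitch_um=4.0)
        m3 = thickness_map(fv3, 0.05, 0.1)
        assert np.all(m3.thickness_um % 4.0 == 0)               # pitch-quantized
        assert m3.thickness_um.max() <= 16 * 4.0


def _tmap(th, aline=6.0 / 512, bscan=6.0 / 256):
    return MelaninThicknessMap(thickness_um=np.asarray(th, float),
                               axial_pitch_um=4.0, aline_pitch_mm=aline,
                               bscan_pitch_mm=bscan)


class TestLesionArea:
    def test_empty_mask(self):
        res = lesion_area(_tmap(np.zeros((16, 16))))
        assert res.area_mm2 == 0.0

    def test_hundred_pixels_fullscale_pitches(self):
        """100 pixels at the full 6 mm / 512 x 6 mm / 256 raster."""
        th = np.zeros((32, 32))
        th.flat[:100] = 80.0
        res = lesion_area(_tmap(th))
        assert res.area_mm2 == pytest.approx(100 * (6.0 / 512) * (6.0 / 256))
        assert res.area_mm2 == pytest.approx(0.0274658203125)

    def test_linear_in_pixel_count(self):
        for n in (1, 7, 50):
            th = np.zeros((16, 32))
            th.flat[:n] = 99.0
            res = lesion_area(_tmap(th, aline=0.01, bscan=0.02))
            assert res.area_mm2 == pytest.approx(n * 0.0002)

    def test_disc_area_close_to_analytic(self):
        pitch = 6.0 / 256
        n = 256
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        r2 = ((yy + 0.5) * pitch - 3.0) ** 2 + ((xx + 0.5) * pitch - 3.0) ** 2
        th = np.where(r2 <= 0.25, 100.0, 0.0)
        res = lesion_area(_tmap(th, aline=pitch, bscan=pitch))
        assert abs(res.area_mm2 / (np.pi * 0.25) - 1.0) < 0.05

    def test_roi_polygon_restricts_and_validates(self):
        th = np.full((20, 20), 100.0)
        square = np.array([[2, 2], [2, 12], [12, 12], [12, 2]], float)
        res = lesion_area(_tmap(th, aline=0.1, bscan=0.1), roi_polygon=square)
        assert 0 < res.area_mm2 < lesion_area(_tmap(th, 0.1, 0.1)).area_mm2
        outside = np.array([[50, 50], [50, 60], [60, 60]], float)
        with pytest.raises(ValueError, match="outside"):
            lesion_area(_tmap(th), roi_polygon=outside)


class TestPEDVolume:
    def test_uniform_box(self):
        """100 um elevation over 1 mm of A-lines in one B-scan."""
        n_alines = 43                       # 43 * 23.4 um ~ 1.0062 mm
        pitch_mm = 0.0234
        inner = np.full((1, n_alines), 100.0)
        bruch = inner + 100.0 / 4.0         # 25 px = 100 um at 4 um pitch
        pv = ped_volume(inner, bruch, 4.0, pitch_mm, 0.0234)
        expect = 0.1 * (n_alines * pitch_mm) * 0.0234
        assert pv.volume_mm3 == pytest.approx(expect)

    def test_zero_elevation(self):
        m = np.full((4, 8), 50.0)
        pv = ped_volume(m, m, 4.0, 0.05, 0.1)
        assert pv.volume_mm3 == 0.0
        assert np.all(pv.per_bscan_area_mm2 == 0.0)

    def test_crossing_surfaces_rejected_with_location(self):
        inner = np.full((2, 4), 30.0)
        bruch = np.full((2, 4), 40.0)
        inner[1, 2] = 45.0
        with pytest.raises(ValueError, match=r"bscan=1, aline=2"):
            ped_volume(inner, bruch, 4.0, 0.05, 0.1)

    def test_spherical_cap_closed_form(self, clean_phantom_ped=None):
        from melanoct import PhantomConfig, generate_phantom
        h_um, a_mm = 150.0, 1.5
        cfg = PhantomConfig(seed=2, ped={"radius_mm": a_mm, "height_um": h_um},
                            snr_db=None, scramble_p=0.0, flow_fraction=0.0,
                            n_repeats=1)
        tomo, truth = generate_phantom(cfg)
        pv = ped_volume(truth.ped_inner_boundary_px, truth.bruch_depth_px,
                        tomo.axial_pitch_um, tomo.aline_pitch_um / 1000,
                        tomo.bscan_pitch_um / 1000)
        h = h_um / 1000.0
        cap = np.pi * h * (3 * a_mm**2 + h**2) / 6.0
        assert abs(pv.volume_mm3 / cap - 1.0) < 0.03


class TestTransverseScale:
    def test_reference_eye_unity(self):
        assert transverse_scale(24.46) == pytest.approx(1.0)

    def test_short_eye(self):
        assert transverse_scale(22.4) == pytest.approx((22.4 - 1.82) / (24.46 - 1.82))
        assert transverse_scale(22.4) == pytest.approx(0.909, abs=5e-4)

    def test_out_of_range_rejected(self):
        for al in (10.0, 40.0):
            with pytest.raises(ValueError):
                transverse_scale(al)

    def test_area_scales_quadratically(self):
        th = np.zeros((16, 16))
        th.flat[:10] = 99.0
        s = transverse_scale(22.4)
        base = lesion_area(_tmap(th, 0.01, 0.02))
        scaled = lesion_area(_tmap(th, 0.01, 0.02), scale=s)
        assert scaled.area_mm2 == pytest.approx(base.area_mm2 * s**2)


class TestEnfaceProjection:
    def test_constant_volume_mean(self):
        vol = np.full((3, 4, 10), 2.5)
        assert np.all(enface_projection(vol, "mean") == 2.5)

    def test_sum_nonnegative_and_range(self):
        rng = np.random.default_rng(1)
        vol = rng.uniform(0, 1, (3, 4, 10))
        assert np.all(enface_projection(vol, "sum", (2, 7)) >= 0)
        with pytest.raises(ValueError, match="range"):
            enface_projection(vol, "mean", (5, 5))

    def test_max_dominates_mean(self):
        rng = np.random.default_rng(2)
        vol = rng.standard_normal((3, 4, 10))
        assert np.all(enface_projection(vol, "max") >= enface_projection(vol, "mean"))


class TestColormap:
    def test_endpoint_colors_and_roundtrip(self, tmp_path):
        import matplotlib
        th = np.zeros((8, 8))
        th[0, 0] = 120.0
        rgb, meta = render_colormap(_tmap(th), palette="inferno", range_um=(0, 120))
        cmap = matplotlib.colormaps["inferno"]
        lo = np.array(cmap(0.0)[:3]) * 255
        hi = np.array(cmap(1.0)[:3]) * 255
        assert np.allclose(rgb[1, 1], lo.round())
        assert np.allclose(rgb[0, 0], hi.round())
        assert meta["range_um"] == [0.0, 120.0]
        p = tmp_path / "map.png"
        Image.fromarray(rgb).save(p)
        back = np.asarray(Image.open(p))
        assert np.array_equal(back, rgb)
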