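"""Paraxial ray-tracing: matrices, imaging, magnification, clipping."""

import math

import numpy as np
import pytest

from pmrf import optics
from pmrf.optics import (
    AS_BUILT_GAPS,
    ParaxialRay,
    _disk_overlap,
    _image_distance,
    _magnification_at_image,
    as_built_model,
    build_detection_model,
    collection_efficiency,
    effective_focal_length,
    fit_gap_to_measurements,
    fit_s1_to_magnification,
    magnification_vs_scan,
    make_fold,
    make_thin_lens,
    make_translation,
    propagate_ray,
    select_theta,
    trace_field,
    transfer_matrix,
)


class TestEffectiveFocalLength:
    @pytest.mark.parametrize("f_tube, m, n, expected", [
        (200, 40, 1.33, 6.65),    # 40x water-immersion detection objective
        (200, 20, 1.0, 10.0),     # 20x air remote objective
        (100, 10, 1.0, 10.0),     # reduces to f_tube / M in air
    ])
    def test_values(self, f_tube, m, n, expected):
        assert effective_focal_length(f_tube, m, n) == pytest.approx(
            expected, rel=1e-12)

    @pytest.mark.parametrize("args", [(0, 40, 1.33), (200, -1, 1.0),
                                      (200, 40, 0)])
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            effective_focal_length(*args)


class TestElements:
    def test_translation_matrix_form(self):
        el = make_translation(10.0, 1.33)
        assert np.allclose(el.matrix, [[1, 0], [10 / 1.33, 1]])
        assert np.linalg.det(el.matrix) == pytest.approx(1, abs=1e-15)

    def test_zero_translation_is_identity(self):
        assert np.allclose(make_translation(0.0).matrix, np.eye(2))

    def test_translation_reduced_angle_invariance(self):
        # y' = y + d*alpha; the reduced angle is unchanged, and d/n keeps
        # the same geometric displacement in denser media
        r1 = propagate_ray(ParaxialRay(0.1, 0.0), [make_translation(10, 1.0)])
        r2 = propagate_ray(ParaxialRay(0.1, 0.0),
                           [make_translation(13.3, 1.33)])
        for r in (r1, r2):
            assert r.reduced_angle == pytest.approx(0.1)
            assert r.height == pytest.approx(1.0)

    def test_lens_matrix_form_and_determinant(self):
        el = make_thin_lens(10.0, 1.0)
        assert np.allclose(el.matrix, [[1, -0.1], [0, 1]])
        assert np.linalg.det(el.matrix) == pytest.approx(1, abs=1e-15)

    def test_parallel_ray_crosses_axis_at_focus(self):
        out = propagate_ray(ParaxialRay(0.0, 5.0),
                            [make_thin_lens(10), make_translation(10)])
        assert out.height == pytest.approx(0.0, abs=1e-12)

    def test_huge_focal_length_approaches_identity(self):
        assert np.allclose(make_thin_lens(1e12).matrix, np.eye(2),
                           atol=1e-11)

    def test_invalid_elements(self):
        with pytest.raises(ValueError):
            make_translation(5.0, n=0)
        with pytest.raises(ValueError):
            make_thin_lens(0.0)

    def test_fold_is_ray_identity(self):
        ray = ParaxialRay(0.05, 1.7)
        out = propagate_ray(ray, [make_fold(45.0)])
        assert out == ray


class TestPropagation:
    def test_empty_element_list_returns_input(self):
        ray = ParaxialRay(0.02, -0.3)
        assert propagate_ray(ray, []) == ray

    def test_composed_matrix_unimodular(self, rng):
        els = []
        for _ in range(12):
            if rng.random() < 0.5:
                els.append(make_translation(rng.uniform(1, 100),
                                            rng.choice([1.0, 1.33])))
            else:
                els.append(make_thin_lens(rng.uniform(5, 300)))
        assert np.linalg.det(transfer_matrix(els)) == pytest.approx(
            1.0, abs=1e-12)

    def test_single_lens_imaging(self):
        # object 15 mm before an f=10 lens: thin-lens equation gives the
        # image 30 mm behind it at magnification -2
        els = [make_translation(15), make_thin_lens(10)]
        assert _image_distance(els) == pytest.approx(30, rel=1e-12)
        assert _magnification_at_image(els) == pytest.approx(-2, rel=1e-12)

    def test_thin_lens_equation_oracle(self, rng):
        # brute-force oracle: 1/s' = 1/f - 1/(-s) with m = -s'/s
        for _ in range(100):
            f = rng.uniform(5, 200)
            s = rng.uniform(1.05 * f, 5 * f)  # real image region
            els = [make_translation(s), make_thin_lens(f)]
            s_img = 1.0 / (1.0 / f - 1.0 / s)
            m = -s_img / s
            assert _image_distance(els) == pytest.approx(s_img, rel=1e-9)
            assert _magnification_at_image(els) == pytest.approx(m, rel=1e-9)


class TestDetectionModel:
    def test_f_obj_from_formula(self):
        model = build_detection_model(all_4f=True)
        assert model.f_obj == pytest.approx(6.65, rel=1e-12)

    def test_delta_l_value(self):
        # delta_L = f_obj2 * theta(rad) = 10 mm * 8 deg = 1.396 mm
        model = build_detection_model(all_4f=True)
        assert model.delta_l == pytest.approx(10 * math.radians(8), rel=1e-12)
        assert model.delta_l == pytest.approx(1.396, abs=5e-4)

    def test_delta_l_linear_in_theta(self):
        thetas = np.linspace(1, 15, 8)
        dls = [build_detection_model({"theta_deg": t}).delta_l
               for t in thetas]
        slopes = np.diff(dls) / np.diff(np.radians(thetas))
        assert np.allclose(slopes, 10.0, rtol=1e-12)

    def test_all_4f_gaps_are_focal_sums(self):
        m = build_detection_model(all_4f=True)
        assert m.d1 == pytest.approx(m.f_obj + m.f_l4)
        assert m.gap_l4_l5 == pytest.approx(m.f_l4 + m.f_l5)
        assert m.gap_l5_pbs + m.gap_pbs_obj2 == pytest.approx(
            m.f_l5 + m.f_obj2)
        assert m.mirror_gap == pytest.approx(2 * m.f_obj2)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config"):
            build_detection_model({"nonsense": 1.0})


class TestTraceField:
    def test_exact_4f_magnification(self):
        # exact-4f relay: analytically M = M_obj * f_obj2 / f_L5 = 4/3,
        # the near-perfect-imaging value (n_water/n_air = 1.33)
        model = build_detection_model(all_4f=True)
        res = trace_field(model, field_half_width=50.0)
        assert res.lateral_magnification == pytest.approx(4.0 / 3.0,
                                                          abs=1e-9)
        assert res.lateral_magnification == pytest.approx(1.33, abs=5e-3)

    def test_pupil_matched_relay_reaches_water_air_ratio(self):
        # choosing f_L5 = M_obj f_obj2 / n_water makes the remote
        # magnification exactly n_water/n_air
        model = build_detection_model({"f_l5": 40 * 10 / 1.33}, all_4f=True)
        res = trace_field(model)
        assert res.lateral_magnification == pytest.approx(1.33, abs=1e-9)

    def test_on_axis_chief_ray_stays_on_axis(self):
        model = build_detection_model(all_4f=True)
        res = trace_field(model, field_half_width=50.0)
        chief = [pts for pts, lab in zip(res.polylines,
                                         res.field_point_labels)
                 if lab == "axis"]
        # middle ray of the axial field point passes through pupil center
        heights = [abs(y) for _, y in chief[1]]
        assert max(heights) < 1e-12

    def test_symmetric_field_points(self):
        model = build_detection_model(all_4f=True)
        res = trace_field(model, field_half_width=40.0)
        plus = [p for p, l in zip(res.polylines, res.field_point_labels)
                if l == "field +"]
        minus = [p for p, l in zip(res.polylines, res.field_point_labels)
                 if l == "field -"]
        for pp, pm in zip(plus, minus[::-1]):
            for (z1, y1), (z2, y2) in zip(pp, pm):
                assert y1 == pytest.approx(-y2, abs=1e-12)


class TestMagnificationVsScan:
    def test_offset_zero_matches_trace(self):
        model = build_detection_model(all_4f=True)
        curve = magnification_vs_scan(model, [0.0])
        assert curve[0][1] == pytest.approx(4.0 / 3.0, abs=1e-9)

    def test_monotone_near_zero_for_as_built(self):
        model = as_built_model()
        curve = magnification_vs_scan(model, np.linspace(-10, 10, 9))
        mags = np.abs([m for _, m in curve])
        diffs = np.diff(mags)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_smooth_over_scan_range(self):
        model = as_built_model()
        curve = magnification_vs_scan(model, np.linspace(-40, 40, 17))
        mags = np.array([m for _, m in curve])
        # no discontinuities: second differences stay tiny vs the values
        assert np.max(np.abs(np.diff(mags, 2))) < 0.01 * np.abs(mags).mean()

    def test_paraxial_scale_invariance(self):
        base = dict(AS_BUILT_GAPS)
        model = build_detection_model(base)
        k = 2.0
        scaled_cfg = {key: k * v for key, v in base.items()}
        scaled_cfg.update({
            "f_tube_design": k * 200, "f_l4": k * 200, "f_l5": k * 300,
            "f_obj2": k * 10, "f_l6": k * 300})
        scaled = build_detection_model(scaled_cfg)
        offs = np.array([-20.0, 0.0, 20.0])
        c1 = magnification_vs_scan(model, offs)
        c2 = magnification_vs_scan(scaled, k * offs)
        for (_, m1), (_, m2) in zip(c1, c2):
            assert m1 == pytest.approx(m2, rel=1e-9)

    def test_out_of_range_offset_refused(self):
        with pytest.raises(ValueError, match="outside modeled range"):
            magnification_vs_scan(as_built_model(), [90.0])


class TestCollectionEfficiency:
    def test_in_focus_on_axis_is_unity(self):
        assert collection_efficiency(as_built_model(), 0.0, 0.0) == 1.0

    def test_mirror_symmetry_in_field_offset(self, rng):
        model = as_built_model()
        for _ in range(10):
            d = rng.uniform(-50, 50)
            x = rng.uniform(0, 3000)
            assert collection_efficiency(model, d, x) == pytest.approx(
                collection_efficiency(model, d, -x), abs=1e-15)

    def test_nonincreasing_in_defocus_magnitude(self):
        model = as_built_model()
        for x in (0.0, 1000.0, 4000.0):
            effs = [collection_efficiency(model, d, x)
                    for d in np.linspace(0, 2000, 30)]
            assert np.all(np.diff(effs) <= 1e-12)

    def test_monte_carlo_clipping_oracle(self, rng):
        model = as_built_model()
        r_ap = model.f_obj2 * model.na_obj2
        n = 10_000
        for _ in range(20):
            d = rng.uniform(0, 3000)
            x = rng.uniform(0, 5000)
            eff = collection_efficiency(model, d, x)
            # uniform rays over the footprint disk, clipped by the aperture
            r_beam = r_ap * (model.f_obj2 + d * 1e-3) / model.f_obj2
            phi = rng.uniform(0, 2 * math.pi, n)
            rad = r_beam * np.sqrt(rng.uniform(0, 1, n))
            px = x * 1e-3 + rad * np.cos(phi)
            py = rad * np.sin(phi)
            mc = np.mean(px ** 2 + py ** 2 <= r_ap ** 2)
            assert eff == pytest.approx(mc, abs=0.011)

    def test_negative_aperture_rejected(self):
        with pytest.raises(ValueError):
            collection_efficiency(as_built_model(), 0, 0,
                                  aperture_radius=-1.0)

    def test_disk_overlap_degenerate_cases(self):
        assert _disk_overlap(5.0, 1.0, 1.0) == 0.0
        assert _disk_overlap(0.0, 1.0, 3.0) == pytest.approx(math.pi)


class TestCalibrationHelpers:
    def test_select_theta_finds_grid_minimum(self):
        model = as_built_model()
        theta = select_theta(model, theta_min=1.0, theta_max=20.0, step=0.1)
        # the returned angle minimizes the footprint objective on the grid
        def footprint(t):
            br = model.pupil_radius * model.f_obj2 / model.f_l5
            return (br + model.f_obj2 * math.radians(t) / 2
                    + 0.1 / math.radians(t))
        grid = np.arange(1.0, 20.05, 0.1)
        assert footprint(theta) == pytest.approx(
            min(footprint(t) for t in grid))

    def test_d1_calibration_recovers_gap(self):
        truth = build_detection_model(dict(AS_BUILT_GAPS, d1=110.0))
        measured = magnification_vs_scan(truth, [-30, -15, 0, 15, 30])
        start = as_built_model()  # d1 = 100
        fitted = fit_gap_to_measurements(start, "d1", measured,
                                         bounds=(60.0, 160.0))
        assert fitted == pytest.approx(110.0, abs=0.5)

    def test_s1_calibration_recovers_object_distance(self):
        truth = build_detection_model(dict(AS_BUILT_GAPS, s1=6.70))
        target_mag = _magnification_at_image(truth.elements())
        fitted = fit_s1_to_magnification(truth, target_mag,
                                         bounds=(6.6, 6.8))
        assert fitted == pytest.approx(6.70, abs=1e-4)
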