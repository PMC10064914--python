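"""Binarization, skeletonization and the quadrant density metrics."""

import math

import numpy as np
import pytest

from octaqa import (
    EnFaceAngiogram,
    ImageCalibration,
    SceneConfig,
    binarize_vessels,
    build_etdrs_grid,
    generate_angiogram,
    quadrant_metrics,
    skeleton_length_mm,
    skeletonize_vessels,
)
from octaqa.etdrs_grid import PIXEL_SIZE_3MM_245, QUADRANTS
from octaqa.vessel_metrics import VesselMaps, quadrant_metrics_from_binary


def _img(pixels, calib=None, **kw):
    pixels = np.asarray(pixels, dtype=float)
    if calib is None:
        h, w = pixels.shape
        calib = ImageCalibration(w, h, PIXEL_SIZE_3MM_245, ((w - 1) / 2, (h - 1) / 2), "OD")
    return EnFaceAngiogram(pixels=pixels, calib=calib, **kw)


class TestBinarize:
    def test_all_zero_image_gives_empty_map(self):
        img = _img(np.zeros((64, 64)))
        assert not binarize_vessels(img, method="global_otsu").any()
        assert not binarize_vessels(img, method="local_mean").any()

    def test_two_level_strips_recovered_exactly_by_otsu(self):
        px = np.zeros((64, 64))
        px[10:20, :] = 200.0
        px[40:45, :] = 200.0
        binary = binarize_vessels(_img(px), method="global_otsu", min_component_px=1)
        assert np.array_equal(binary, px > 0)

    def test_speckle_components_below_floor_removed(self):
        px = np.zeros((64, 64))
        px[5, 5] = px[5, 6] = 200.0  # 2-px speck
        px[30:40, 30] = 200.0  # 10-px line survives
        binary = binarize_vessels(_img(px), method="global_otsu", min_component_px=5)
        assert binary.sum() == 10

    def test_dice_against_ground_truth_on_synthetic_scene(self):
        img, scene = generate_angiogram(SceneConfig(), seed=0)
        binary = binarize_vessels(img)
        truth = scene.vessel_raster
        dice = 2 * (binary & truth).sum() / (binary.sum() + truth.sum())
        assert dice >= 0.9

    def test_low_signal_flag(self):
        assert _img(np.zeros((8, 8)), signal_strength=7).low_signal
        assert not _img(np.zeros((8, 8)), signal_strength=8).low_signal


class TestSkeletonize:
    def test_wide_bar_thins_to_line(self):
        binary = np.zeros((20, 30), dtype=bool)
        binary[8:13, 5:25] = True
        skel = skeletonize_vessels(binary)
        assert skel[10, 10:20].all()
        assert (skel.sum(axis=0)[10:20] == 1).all()

    def test_empty_map_stays_empty(self):
        assert not skeletonize_vessels(np.zeros((10, 10), dtype=bool)).any()

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(3)
        binary = rng.random((60, 60)) > 0.6
        skel = skeletonize_vessels(binary)
        assert np.array_equal(skeletonize_vessels(skel), skel)

    def test_skeleton_subset_of_binary_enforced(self):
        with pytest.raises(ValueError):
            VesselMaps(
                binary_map=np.zeros((4, 4), dtype=bool),
                skeleton_map=np.ones((4, 4), dtype=bool),
            )


def _brute_force_length(skel, calib):
    """Independent oracle: enumerate every unordered 8-adjacent pixel pair."""
    ps = calib.pixel_size_mm
    pts = list(zip(*np.nonzero(skel)))
    total, isolated = 0.0, 0
    for i, (r1, c1) in enumerate(pts):
        has_neighbor = False
        for r2, c2 in pts:
            if (r1, c1) == (r2, c2):
                continue
            dr, dc = abs(r1 - r2), abs(c1 - c2)
            if dr <= 1 and dc <= 1:
                has_neighbor = True
        for r2, c2 in pts[i + 1 :]:
            dr, dc = abs(r1 - r2), abs(c1 - c2)
            if dr <= 1 and dc <= 1:
                total += ps * math.sqrt(2) if dr == 1 and dc == 1 else ps
        if not has_neighbor:
            isolated += 1
    return total + isolated * ps


class TestSkeletonLength:
    def test_axial_run_is_step_count_times_pixel(self, calib245):
        skel = np.zeros((245, 245), dtype=bool)
        skel[100, 50:61] = True  # 11 pixels, 10 steps
        mask = np.ones_like(skel)
        assert skeleton_length_mm(skel, mask, calib245) == pytest.approx(10 * PIXEL_SIZE_3MM_245)

    def test_diagonal_run_weighted_sqrt2(self, calib245):
        skel = np.zeros((245, 245), dtype=bool)
        for k in range(11):
            skel[50 + k, 50 + k] = True
        mask = np.ones_like(skel)
        expected = 10 * math.sqrt(2) * PIXEL_SIZE_3MM_245
        assert skeleton_length_mm(skel, mask, calib245) == pytest.approx(expected)

    def test_plus_sign_matches_hand_count(self, calib245):
        skel = np.zeros((245, 245), dtype=bool)
        skel[100, 95:106] = True
        skel[95:106, 100] = True
        mask = np.ones_like(skel)
        # two 11-px lines sharing the center: 20 axial steps, plus the four
        # diagonal adjacencies between arm pixels around the junction
        expected = (20 + 4 * math.sqrt(2)) * PIXEL_SIZE_3MM_245
        assert skeleton_length_mm(skel, mask, calib245) == pytest.approx(expected)
        assert skeleton_length_mm(skel, mask, calib245) == pytest.approx(
            _brute_force_length(skel, calib245)
        )

    def test_isolated_pixels_contribute_one_pixel_each(self, calib245):
        skel = np.zeros((245, 245), dtype=bool)
        skel[10, 10] = skel[50, 50] = True
        mask = np.ones_like(skel)
        assert skeleton_length_mm(skel, mask, calib245) == pytest.approx(2 * PIXEL_SIZE_3MM_245)

    def test_random_small_skeletons_match_pair_enumeration_oracle(self, calib245, rng):
        mask = np.ones((245, 245), dtype=bool)
        for _ in range(30):
            skel = np.zeros((245, 245), dtype=bool)
            n = rng.integers(1, 21)
            rr = rng.integers(100, 112, size=n)
            cc = rng.integers(100, 112, size=n)
            skel[rr, cc] = True
            got = skeleton_length_mm(skel, mask, calib245)
            assert got == pytest.approx(_brute_force_length(skel, calib245))

    def test_shape_mismatch_rejected(self, calib245):
        with pytest.raises(ValueError, match="shape"):
            skeleton_length_mm(
                np.zeros((10, 10), dtype=bool), np.zeros((9, 9), dtype=bool), calib245
            )


class TestQuadrantMetrics:
    def test_all_true_binary_gives_pd_one(self, grid245):
        binary = np.ones((245, 245), dtype=bool)
        qm = quadrant_metrics_from_binary(binary, grid245)
        assert all(qm.pd[q] == 1.0 for q in QUADRANTS)

    def test_all_false_binary_gives_zeros(self, grid245):
        binary = np.zeros((245, 245), dtype=bool)
        qm = quadrant_metrics_from_binary(binary, grid245)
        assert all(qm.pd[q] == 0.0 and qm.vld[q] == 0.0 for q in QUADRANTS)

    def test_single_vessel_in_superior_quadrant_only(self, grid245, calib245):
        binary = np.zeros((245, 245), dtype=bool)
        binary[50, 110:135] = True  # horizontal line through the superior wedge
        skel = binary.copy()
        qm = quadrant_metrics_from_binary(binary, grid245, skeleton=skel)
        length = skeleton_length_mm(skel, grid245.masks["superior"], calib245)
        assert length > 0
        assert qm.vld["superior"] == pytest.approx(length / grid245.area_mm2("superior"))
        for q in ("inferior", "nasal", "temporal"):
            assert qm.vld[q] == 0.0 and qm.pd[q] == 0.0

    def test_pd_monotone_under_added_vessel_pixels(self, grid245, rng):
        binary = rng.random((245, 245)) > 0.8
        qm1 = quadrant_metrics_from_binary(binary, grid245)
        extra = binary | (rng.random((245, 245)) > 0.9)
        qm2 = quadrant_metrics_from_binary(extra, grid245)
        assert all(qm2.pd[q] >= qm1.pd[q] for q in QUADRANTS)

    def test_laterality_involution_propagates(self, scene128):
        img, _ = scene128
        grid = build_etdrs_grid(img.calib)
        qm = quadrant_metrics(img, grid)

        calib = img.calib
        flipped_calib = ImageCalibration(
            calib.width_px, calib.height_px, calib.pixel_size_mm,
            (calib.width_px - 1 - calib.fovea_center[0], calib.fovea_center[1]),
            "OS" if calib.laterality == "OD" else "OD",
        )
        flipped = EnFaceAngiogram(np.fliplr(img.pixels), flipped_calib, img.signal_strength)
        qm_f = quadrant_metrics(flipped, build_etdrs_grid(flipped_calib))
        for q in QUADRANTS:
            assert qm_f.pd[q] == pytest.approx(qm.pd[q], abs=1e-12)
            # thinning is not exactly mirror-equivariant; lengths agree closely
            assert qm_f.vld[q] == pytest.approx(qm.vld[q], rel=0.1)

    def test_scale_consistency_of_analytic_scene(self):
        # same mm-space scene rasterized at two resolutions
        segments = [((-1.2, 0.4), (1.3, 0.6)), ((0.3, -1.3), (0.5, 1.2)),
                    ((-1.0, -1.0), (1.0, 0.2))]

        def metrics_at(n):
            calib = ImageCalibration(n, n, 3.0 / n, ((n - 1) / 2, (n - 1) / 2), "OD")
            ps = calib.pixel_size_mm
            yy, xx = np.mgrid[0:n, 0:n]
            x_mm = (xx - calib.fovea_center[0]) * ps
            y_mm = (yy - calib.fovea_center[1]) * ps
            binary = np.zeros((n, n), dtype=bool)
            for (x0, y0), (x1, y1) in segments:
                dx, dy = x1 - x0, y1 - y0
                t = np.clip(((x_mm - x0) * dx + (y_mm - y0) * dy) / (dx**2 + dy**2), 0, 1)
                d = np.hypot(x_mm - (x0 + t * dx), y_mm - (y0 + t * dy))
                binary |= d <= 0.025
            return quadrant_metrics_from_binary(binary, build_etdrs_grid(calib))

        qm1, qm2 = metrics_at(245), metrics_at(490)
        for q in QUADRANTS:
            assert qm2.pd[q] == pytest.approx(qm1.pd[q], rel=0.03)
            # the 8-connected step sum carries an angle-dependent bias of up
            # to ~8% for oblique lines, which does not vanish with resolution
            assert qm2.vld[q] == pytest.approx(qm1.vld[q], rel=0.08)

    def test_plausible_healthy_ranges_of_generator(self):
        img, scene = generate_angiogram(SceneConfig(), seed=4)
        tm = scene.true_quadrant_metrics
        for q in QUADRANTS:
            assert 0.25 <= tm.pd[q] <= 0.45
            assert 13.0 <= tm.vld[q] <= 22.0

    def test_empty_mask_rejected(self, calib245):
        from octaqa.etdrs_grid import ETDRSGrid

        masks = {q: np.zeros((245, 245), dtype=bool) for q in QUADRANTS}
        bad = ETDRSGrid(masks=masks, calib=calib245)
        with pytest.raises(ValueError, match="empty mask"):
            quadrant_metrics_from_binary(np.ones((245, 245), dtype=bool), bad)
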