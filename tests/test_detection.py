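"""Scale-space extremum selection, pruning and the detection pipeline."""

import math

import numpy as np
import pytest

from cytoblob.detection import (
    Blob,
    DetectionConfig,
    circle_intersection_area,
    detect,
    disc_overlap_fraction,
    find_scale_space_extrema,
    prune_overlaps,
)
from cytoblob.scale_space import ScaleSpace, SigmaSchedule, build_scale_space

from conftest import gaussian_spot_image

SQRT2 = math.sqrt(2.0)


def brute_force_extrema(volume: ScaleSpace, config: DetectionConfig):
    """Independent triple-loop 26-neighbor scan (the extremum oracle).

    Mirrors the detector's comparison rule: a voxel qualifies when no
    neighbor exceeds it (weak local maximum) and it passes the thresholds.
    """
    resp = volume.responses
    ns, h, w = resp.shape
    vmax = resp.max()
    thr = 1e-9  # numerical noise floor
    if vmax > thr:
        thr = max(thr, config.threshold_rel * vmax)
    if config.threshold_abs is not None:
        thr = max(thr, config.threshold_abs)
    found = set()
    for k in range(1, ns - 1):
        for y in range(1, h - 1):
            for x in range(1, w - 1):
                v = resp[k, y, x]
                if v < thr:
                    continue
                is_max = True
                for dk in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if dk == dy == dx == 0:
                                continue
                            if v < resp[k + dk, y + dy, x + dx]:
                                is_max = False
                    if not is_max:
                        break
                if is_max:
                    found.add((k, y, x))
    return found


def make_blob(x, y, radius, response=1.0):
    return Blob(x=x, y=y, sigma=radius / SQRT2, response=response)


class TestExtrema:
    def test_matches_brute_force_scan_on_random_volumes(self, rng):
        sched = SigmaSchedule.linear(1.0, 5.0, 5)
        config = DetectionConfig(threshold_rel=1e-6)
        for _ in range(10):
            vol = ScaleSpace(rng.normal(size=(5, 16, 16)), sched)
            blobs = find_scale_space_extrema(vol, config)
            got = {
                (sched.sigmas.index(b.sigma), int(b.y), int(b.x)) for b in blobs
            }
            assert got == brute_force_extrema(vol, config)

    def test_constant_image_yields_no_blobs(self):
        sched = SigmaSchedule.linear(1.0, 3.0, 3)
        vol = build_scale_space(np.full((20, 20), 0.6), sched)
        assert find_scale_space_extrema(vol, DetectionConfig()) == []

    def test_single_spot_recovered_with_correct_scale(self):
        img = gaussian_spot_image(size=80, center=(40, 40), sigma=4.0)
        sched = SigmaSchedule.linear(1.0, 8.0, 8)
        blobs = detect(img, sched, DetectionConfig())
        assert len(blobs) == 1
        (b,) = blobs
        assert math.hypot(b.x - 40, b.y - 40) <= 1.0
        assert abs(b.sigma - 4.0) <= 1.0  # one schedule step

    def test_translation_covariance(self):
        img = gaussian_spot_image(size=90, center=(40, 38), sigma=4.0)
        shifted = gaussian_spot_image(size=90, center=(45, 45), sigma=4.0)
        sched = SigmaSchedule.linear(2.0, 7.0, 6)
        (b0,) = detect(img, sched)
        (b1,) = detect(shifted, sched)
        assert (b1.x - b0.x, b1.y - b0.y) == (7.0, 5.0)

    def test_raising_threshold_never_adds_blobs(self, rng):
        sched = SigmaSchedule.linear(1.0, 5.0, 5)
        vol = ScaleSpace(rng.normal(size=(5, 24, 24)), sched)
        lo = find_scale_space_extrema(vol, DetectionConfig(threshold_rel=0.05))
        hi = find_scale_space_extrema(vol, DetectionConfig(threshold_rel=0.3))
        lo_set = {(b.x, b.y, b.sigma) for b in lo}
        hi_set = {(b.x, b.y, b.sigma) for b in hi}
        assert hi_set <= lo_set

    def test_blobs_ordered_by_descending_response(self, rng):
        sched = SigmaSchedule.linear(1.0, 5.0, 5)
        vol = ScaleSpace(rng.normal(size=(5, 32, 32)), sched)
        blobs = find_scale_space_extrema(vol, DetectionConfig(threshold_rel=1e-6))
        responses = [b.response for b in blobs]
        assert responses == sorted(responses, reverse=True)


class TestCircleOverlap:
    def test_against_grid_integration(self):
        # oracle: count pixels inside both discs on a fine grid
        r1, r2, d = 5.0, 3.0, 4.0
        step = 0.01
        xs = np.arange(-r1, d + r2, step)
        ys = np.arange(-max(r1, r2), max(r1, r2), step)
        xx, yy = np.meshgrid(xs, ys)
        inside = (xx**2 + yy**2 <= r1**2) & ((xx - d) ** 2 + yy**2 <= r2**2)
        numeric = inside.sum() * step * step
        assert circle_intersection_area(r1, r2, d) == pytest.approx(
            numeric, rel=1e-3
        )

    def test_disjoint_and_contained_cases(self):
        assert circle_intersection_area(2.0, 3.0, 6.0) == 0.0
        assert circle_intersection_area(2.0, 5.0, 1.0) == pytest.approx(
            math.pi * 4.0
        )


class TestPruneOverlaps:
    def test_concentric_duplicates_collapse_to_one(self):
        b = make_blob(10, 10, 5.0, response=2.0)
        dup = make_blob(10, 10, 5.0, response=1.0)
        assert prune_overlaps([b, dup], overlap_max=0.5) == [b]

    def test_disjoint_discs_both_kept(self):
        b1 = make_blob(10, 10, 3.0, response=2.0)
        b2 = make_blob(30, 10, 3.0, response=1.0)
        assert prune_overlaps([b1, b2], overlap_max=0.0) == [b1, b2]

    def test_collinear_equal_response_tie_break(self):
        # radius-5 discs at x = 0, 6, 12: (0,6) overlap ~28% of a disc,
        # (0,12) tangent (zero overlap); with overlap_max=0.05 the lowest
        # tie-order blob (x=0) wins, x=6 is dropped, x=12 survives
        blobs = [make_blob(x, 0.0, 5.0, response=1.0) for x in (0.0, 6.0, 12.0)]
        frac = disc_overlap_fraction(blobs[0], blobs[1])
        assert frac == pytest.approx(
            circle_intersection_area(5, 5, 6) / (math.pi * 25), rel=1e-12
        )
        kept = prune_overlaps(blobs, overlap_max=0.05)
        assert [b.x for b in kept] == [0.0, 12.0]


class TestDetectPipeline:
    def test_blank_field_gives_no_blobs(self):
        assert detect(np.full((64, 64), 0.8)) == []

    def test_synthetic_field_fully_recovered(self, standard_scene):
        rgb, truth = standard_scene
        blobs = detect(rgb)
        assert len(blobs) == len(truth)
        for cell in truth:
            nearest = min(
                math.hypot(b.x - cell.x, b.y - cell.y) for b in blobs
            )
            assert nearest <= 2.0

    def test_scale_covariance_under_upsampling(self):
        img = gaussian_spot_image(size=64, center=(30, 28), sigma=3.0)
        sched = SigmaSchedule.logarithmic(2.0, 6.0, 6)
        (b,) = detect(img, sched)
        up = img.repeat(2, axis=0).repeat(2, axis=1)
        (b2,) = detect(up, sched.scaled(2.0))
        assert abs(b2.x - 2 * b.x) <= 2.0 and abs(b2.y - 2 * b.y) <= 2.0
        # sigma doubles up to one schedule step
        i = sched.nearest_index(b.sigma)
        i2 = sched.scaled(2.0).nearest_index(b2.sigma)
        assert abs(i2 - i) <= 1

    def test_determinism_byte_for_byte(self, standard_scene):
        rgb, _ = standard_scene
        first = repr(detect(rgb))
        second = repr(detect(rgb))
        assert first == second

    def test_radius_law(self, standard_scene):
        rgb, _ = standard_scene
        for b in detect(rgb):
            assert b.radius == pytest.approx(SQRT2 * b.sigma, abs=1e-12)

    def test_agrees_with_reference_log_detector(self, standard_scene):
        # independent cross-check against scikit-image's LoG blob detector
        from skimage.feature import blob_log

        from cytoblob.scale_space import to_grayscale

        rgb, truth = standard_scene
        gray = to_grayscale(rgb)
        ref = blob_log(
            1.0 - gray, min_sigma=2.0, max_sigma=9.0, num_sigma=10,
            threshold=0.05,
        )
        ours = detect(rgb, SigmaSchedule.linear(2.0, 9.0, 10))
        matched = 0
        for b in ours:
            if any(math.hypot(b.x - c, b.y - r) <= 2.0 for r, c, _ in ref):
                matched += 1
        assert matched >= 0.9 * len(ours)
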