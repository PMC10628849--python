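"""Box matching and the localization-noise diagnostics."""

import numpy as np
import pytest

from boxnoise import (Box, ImageRecord, MatchPair, NoiseModel, ValidationError,
                      binned_sigma, boundary_correlation, boundary_errors,
                      box_iou, fit_sigma_slope, gamma, match_boxes,
                      noise_report, sigma, size_class, synthesize)
from boxnoise.matching import BoundaryError


def err(delta, scale, boundary="left", extent=640.0):
    return BoundaryError(boundary, delta, scale, extent)


class TestSizeClass:
    @pytest.mark.parametrize("ratio,expected", [
        (0.05, "small"), (0.1, "small"), (0.11, "middle"),
        (0.2, "middle"), (0.3, "middle"), (0.31, "large"),
        (0.5, "large"), (1.0, "large"),
    ])
    def test_thresholds(self, ratio, expected):
        assert size_class(ratio * 640, 640) == expected

    def test_oversized_rejected(self):
        with pytest.raises(ValidationError):
            size_class(700, 640)


class TestBoundaryErrors:
    def test_hand_example(self):
        clean = Box(10, 10, 110, 210, "x")
        noisy = Box(5, 10, 120, 210, "x")
        left, top, right, bottom = boundary_errors(clean, noisy, 640, 640)
        assert left.delta == 5 and left.scale == 100
        assert left.relative == pytest.approx(0.05)
        assert right.delta == -10
        assert right.relative == pytest.approx(-0.10)
        assert top.delta == 0 and bottom.delta == 0
        assert top.scale == 200  # clean height for top/bottom

    def test_identical_boxes_zero(self):
        b = Box(10, 10, 110, 210, "x")
        assert all(e.delta == 0 and e.relative == 0
                   for e in boundary_errors(b, b, 640, 640))

    def test_relative_is_delta_over_scale(self):
        e = err(15, 100)
        assert e.relative == pytest.approx(0.15)


class TestMatchBoxes:
    def test_identity_match(self, toy_record):
        pairs = match_boxes(toy_record, toy_record)
        assert len(pairs) == 2
        assert all(p.iou == pytest.approx(1.0) for p in pairs)

    def test_picks_highest_iou_candidate(self):
        clean = ImageRecord("i", 100, 100, [Box(0, 0, 10, 10, "x")])
        good = Box(0, 0, 10, 6, "x")    # IoU 0.6
        poor = Box(0, 0, 10, 3, "x")    # IoU 0.3
        noisy = ImageRecord("i", 100, 100, [poor, good])
        pairs = match_boxes(clean, noisy)
        assert len(pairs) == 1 and pairs[0].noisy is good
        assert pairs[0].iou == pytest.approx(0.6)

    def test_label_must_agree(self):
        clean = ImageRecord("i", 100, 100, [Box(0, 0, 10, 10, "x")])
        noisy = ImageRecord("i", 100, 100, [Box(0, 0, 10, 9, "y")])
        assert match_boxes(clean, noisy) == []

    def test_dimension_mismatch_rejected(self):
        a = ImageRecord("i", 100, 100, [])
        b = ImageRecord("i", 200, 100, [])
        with pytest.raises(ValidationError):
            match_boxes(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_bruteforce_enumeration(self, seed):
        """Max-IoU selection equals exhaustive same-label pair enumeration."""
        rng = np.random.default_rng(seed)
        def boxes(n):
            out = []
            for _ in range(n):
                x, y = rng.uniform(0, 80, 2)
                w, h = rng.uniform(5, 40, 2)
                out.append(Box(x, y, min(x + w, 120), min(y + h, 120),
                               label=rng.choice(["a", "b"])))
            return out
        clean = ImageRecord("i", 120, 120, boxes(int(rng.integers(1, 10))))
        noisy = ImageRecord("i", 120, 120, boxes(int(rng.integers(1, 10))))
        got = {id(p.clean): p.noisy for p in match_boxes(clean, noisy)}
        for cbox in clean.boxes:
            candidates = [(box_iou(cbox, n), i, n) for i, n in enumerate(noisy.boxes)
                          if n.label == cbox.label and box_iou(cbox, n) > 0]
            if not candidates:
                assert id(cbox) not in got
            else:
                best = max(candidates, key=lambda t: (t[0], -t[1]))[2]
                assert got[id(cbox)] is best


class TestGammaSigma:
    def test_zero_noise(self):
        errors = [err(0, 100), err(0, 50)]
        assert gamma(errors) == 0.0 and sigma(errors) == 0.0

    def test_single_error(self):
        assert gamma([err(15, 100)]) == pytest.approx(0.15)
        assert sigma([err(-7, 100)]) == pytest.approx(7.0)

    def test_two_errors_by_hand(self):
        errors = [err(3, 10), err(4, 10)]
        assert gamma(errors) == pytest.approx(np.sqrt(0.125))
        assert sigma(errors) == pytest.approx(np.sqrt(12.5))

    def test_empty_collection_rejected(self):
        with pytest.raises(ValidationError):
            gamma([])
        with pytest.raises(ValidationError):
            sigma([])


class TestBinnedSigma:
    def test_single_bin_by_hand(self):
        errors = [err(10 if i % 2 else -10, 100) for i in range(20)]
        points = binned_sigma(errors)
        assert points == [(pytest.approx(100.0), pytest.approx(10.0))]

    def test_two_bins_ordered(self):
        errors = ([err(5, 40) for _ in range(10)]
                  + [err(8, 100) for _ in range(10)])
        points = binned_sigma(errors)
        assert [p[0] for p in points] == [40, 100]
        assert [p[1] for p in points] == [5, 8]

    def test_sparse_bins_dropped(self):
        errors = [err(5, 40) for _ in range(10)] + [err(9, 100)]
        assert len(binned_sigma(errors)) == 1

    def test_rescaling_to_reference_image(self):
        # size 100 in a 1280 image appears at 50 on the 640 axis
        errors = [err(4, 100, extent=1280.0) for _ in range(10)]
        (mean_size, local_sigma), = binned_sigma(errors)
        assert mean_size == pytest.approx(50.0)
        assert local_sigma == pytest.approx(2.0)


class TestSigmaSlope:
    def test_exact_line_through_origin(self):
        points = [(s, 0.15 * s) for s in (50, 100, 200, 400)]
        assert fit_sigma_slope(points) == pytest.approx(0.15)

    def test_zero_sigmas(self):
        assert fit_sigma_slope([(100, 0.0), (200, 0.0)]) == 0.0

    def test_closed_form_by_hand(self):
        points = [(100, 10), (200, 20), (400, 44)]
        assert fit_sigma_slope(points) == pytest.approx(22600 / 210000)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_sigma_slope([(100, 10)])


def make_pair(rels, image_id="i"):
    """MatchPair with prescribed relative errors (unit scales)."""
    clean = Box(10, 10, 11, 11, "x")
    errors = tuple(
        BoundaryError(b, r, 1.0, 640.0)
        for b, r in zip(("left", "top", "right", "bottom"), rels)
    )
    return MatchPair(image_id, clean, Box(9, 9, 12, 12, "x"), 0.5, errors)


class TestBoundaryCorrelation:
    def test_duplicated_series_fully_correlated(self):
        pairs = [make_pair([r, r, 0.1 * i, -0.2 * i])
                 for i, r in enumerate((0.1, -0.3, 0.2, 0.05))]
        corr = boundary_correlation(pairs)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_hand_computed_values(self):
        data = np.array([[0.1, 0.0, -0.1, 0.2],
                         [-0.2, 0.1, 0.0, 0.1],
                         [0.3, -0.1, 0.1, -0.3]])
        pairs = [make_pair(row) for row in data]
        corr = boundary_correlation(pairs)
        expected = np.corrcoef(data.T)
        assert np.allclose(corr.values, expected)

    def test_constant_series_flagged_not_nan_everywhere(self):
        pairs = [make_pair([0.0, 0.1 * i, -0.1 * i, 0.2 * i])
                 for i in range(1, 5)]
        corr = boundary_correlation(pairs)
        assert not corr.defined[0, 1] and not corr.defined[1, 0]
        assert corr.defined[1, 2]
        assert corr[0, 0] == 1.0

    def test_independent_noise_weakly_correlated(self, edge_safe_clean):
        noisy = synthesize(edge_safe_clean, NoiseModel(gamma=0.15, seed=9))
        report = noise_report(edge_safe_clean, noisy)
        off = report.correlation.values - np.eye(4)
        assert np.nanmax(np.abs(off)) < 0.05

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            boundary_correlation([make_pair([0.1, 0.2, 0.3, 0.4])])


class TestNoiseReport:
    def test_identical_sets(self, edge_safe_clean):
        report = noise_report(edge_safe_clean, edge_safe_clean)
        assert report.gamma_overall == 0.0
        assert report.n_unmatched_clean == 0
        off_diagonal = report.correlation.defined & ~np.eye(4, dtype=bool)
        assert not off_diagonal.any()

    def test_unmatched_clean_counted_and_excluded(self):
        from boxnoise import AnnotationSet
        clean = AnnotationSet({"i": ImageRecord("i", 100, 100, [
            Box(0, 0, 10, 10, "x"), Box(50, 50, 60, 60, "y")])})
        noisy = AnnotationSet({"i": ImageRecord("i", 100, 100, [
            Box(0, 0, 10, 9, "x")])})
        report = noise_report(clean, noisy)
        assert report.n_unmatched_clean == 1
        assert report.n_pairs == 1

    def test_disjoint_image_ids_rejected(self):
        from boxnoise import AnnotationSet
        a = AnnotationSet({"i": ImageRecord("i", 10, 10, [])})
        b = AnnotationSet({"j": ImageRecord("j", 10, 10, [])})
        with pytest.raises(ValidationError):
            noise_report(a, b)

    @pytest.mark.parametrize("g", [0.1, 0.15, 0.2])
    def test_parameter_recovery(self, g, edge_safe_clean):
        """gamma of a synthesized set re-estimates the synthesis parameter
        within 3 standard errors of the RMS estimator."""
        noisy = synthesize(edge_safe_clean, NoiseModel(gamma=g, seed=21))
        report = noise_report(edge_safe_clean, noisy)
        tol = 3 * g / np.sqrt(2 * report.n_errors)
        assert abs(report.gamma_overall - g) < tol

    def test_mean_relative_error_near_zero(self, edge_safe_clean):
        noisy = synthesize(edge_safe_clean, NoiseModel(gamma=0.15, seed=22))
        report = noise_report(edge_safe_clean, noisy)
        n = report.n_pairs
        for mean in report.mean_relative_per_boundary.values():
            assert abs(mean) < 4 * 0.15 / np.sqrt(n)

    def test_sigma_slope_recovers_gamma(self, edge_safe_clean):
        noisy = synthesize(edge_safe_clean, NoiseModel(gamma=0.15, seed=23))
        report = noise_report(edge_safe_clean, noisy)
        assert report.sigma_slope == pytest.approx(0.15, rel=0.10)

    def test_size_class_stats_and_histograms_present(self, edge_safe_clean):
        noisy = synthesize(edge_safe_clean, NoiseModel(gamma=0.15, seed=24))
        report = noise_report(edge_safe_clean, noisy)
        assert set(report.size_class_stats) == {"small", "middle", "large"}
        for h in report.histograms.values():
            assert sum(h["counts"]) > 0
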