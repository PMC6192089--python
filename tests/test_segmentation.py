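"""Graph-search segmentation: gradient maps, shortest path vs brute force,
sequential B-scan detection, manual-correction re-search, disruptions."""

import numpy as np
import pytest

from octlayers import (
    AnnotationSet,
    Disruption,
    GraphParams,
    InterfaceSet,
    apply_disruptions,
    directional_gradient,
    find_min_weight_path,
    refine_with_manual,
    segment_bscan,
    segment_volume,
)
from octlayers.errors import (
    BoundsError,
    SegmentationFailureError,
    ValidationError,
)
from octlayers.segmentation import (
    BRIGHT_TO_DARK,
    DARK_TO_BRIGHT,
    path_weight,
)


def brute_force_min_path(weights, band=None, w_min=1e-5):
    """Independent oracle: enumerate every connected path, return the
    minimum-weight one with lexicographically smallest row sequence."""
    g = np.asarray(weights, dtype=np.float64)
    n_rows, n_cols = g.shape
    if band is None:
        lo = np.zeros(n_cols, dtype=int)
        hi = np.full(n_cols, n_rows, dtype=int)
    else:
        lo = np.broadcast_to(np.asarray(band[0], dtype=int), (n_cols,))
        hi = np.broadcast_to(np.asarray(band[1], dtype=int), (n_cols,))
    results = []

    def extend(path):
        x = len(path)
        if x == n_cols:
            results.append(path)
            return
        for z in range(path[-1] - 1, path[-1] + 2):
            if lo[x] <= z < hi[x]:
                extend(path + (z,))

    for z0 in range(lo[0], hi[0]):
        extend((z0,))
    # minimizing total weight == maximizing the summed gradient gain, and
    # the gain involves no per-edge constant, so ties compare exactly
    best_gain, best_path = -np.inf, None
    for path in results:
        vals = g[np.array(path), np.arange(n_cols)]
        gain = float(np.sum(vals[:-1] + vals[1:]))
        if gain > best_gain or (gain == best_gain and path < best_path):
            best_gain, best_path = gain, path
    return np.array(best_path), path_weight(g, np.array(best_path), w_min)


def step_image(n_rows, n_cols, z0, low=0.2, high=0.8):
    img = np.full((n_rows, n_cols), low)
    img[z0:] = high
    return img


class TestDirectionalGradient:
    def test_constant_image_is_all_zero(self):
        g = directional_gradient(np.full((10, 5), 0.3), DARK_TO_BRIGHT)
        assert np.all(g == 0.0)

    def test_step_edge_peaks_at_first_bright_row(self):
        g = directional_gradient(step_image(12, 4, z0=7), DARK_TO_BRIGHT)
        assert np.all(g[7] == 1.0)
        g_other = g.copy()
        g_other[7] = 0.0
        assert np.all(g_other == 0.0)

    def test_wrong_polarity_sees_nothing(self):
        g = directional_gradient(step_image(12, 4, z0=7), BRIGHT_TO_DARK)
        assert np.all(g == 0.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            directional_gradient(np.ones((1, 5)), DARK_TO_BRIGHT)


class TestFindMinWeightPath:
    def test_uniform_weights_take_topmost_band_row(self):
        g = np.full((9, 6), 0.4)
        p = find_min_weight_path(g, band=(2, 7))
        assert np.all(p.depths == 2)

    def test_step_edge_path_lies_on_edge_row(self):
        g = directional_gradient(step_image(15, 8, z0=9), DARK_TO_BRIGHT)
        p = find_min_weight_path(g)
        assert np.all(p.depths == 9)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.random((6, 8))
        p = find_min_weight_path(g)
        rows, w = brute_force_min_path(g)
        assert np.array_equal(p.depths, rows)
        assert path_weight(g, p.depths.astype(int)) == w

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_with_bands(self, seed):
        rng = np.random.default_rng(1000 + seed)
        g = rng.random((7, 6))
        lo = rng.integers(0, 3, size=6)
        hi = lo + rng.integers(2, 4, size=6)
        p = find_min_weight_path(g, band=(lo, hi))
        rows, w = brute_force_min_path(g, band=(lo, hi))
        assert np.array_equal(p.depths, rows)

    def test_empty_band_rejected(self):
        with pytest.raises(BoundsError):
            find_min_weight_path(np.ones((5, 4)), band=(3, 3))

    def test_band_outside_image_rejected(self):
        with pytest.raises(BoundsError):
            find_min_weight_path(np.ones((5, 4)), band=(0, 9))

    def test_path_connectivity(self):
        rng = np.random.default_rng(3)
        p = find_min_weight_path(rng.random((20, 30)))
        assert np.all(np.abs(np.diff(p.depths)) <= 1)


class TestSegmentBscan:
    def test_noise_free_phantom_within_one_pixel(self, clean_phantom):
        _, volume, truth, _ = clean_phantom
        result = segment_volume(volume)
        assert np.abs(result.depths - truth.depths).max() <= 1.0

    def test_noisy_phantom_mae_within_one_pixel(self, noisy_phantom):
        _, volume, truth, _ = noisy_phantom
        result = segment_volume(volume)
        mae = np.abs(result.depths - truth.depths).mean(axis=(1, 2))
        assert mae.max() <= 1.0

    def test_interface_ordering_with_gap(self, noisy_phantom):
        _, volume, _, _ = noisy_phantom
        params = GraphParams()
        result = segment_volume(volume, params)
        gaps = np.diff(result.depths, axis=0)
        assert gaps.min() >= params.min_gap_px

    def test_constant_image_fails_loudly(self):
        with pytest.raises(SegmentationFailureError):
            segment_bscan(np.full((60, 40), 0.5))

    def test_randomized_specs_recovered(self, small_geometry):
        from conftest import random_phantom_spec
        from octlayers.synth import generate_phantom

        rng = np.random.default_rng(42)
        for i in range(3):
            spec = random_phantom_spec(rng, small_geometry)
            volume, truth, _ = generate_phantom(spec, seed=i)
            result = segment_volume(volume)
            assert np.abs(result.depths - truth.depths).max() <= 1.0


class TestRefineWithManual:
    def test_drawn_on_edge_returns_drawn(self):
        img = step_image(30, 12, z0=14)
        drawn = np.full(12, 14.0)
        p = refine_with_manual(img, drawn, half_band_px=5)
        assert np.array_equal(p.depths, drawn)

    def test_offset_drawn_line_returns_to_edge(self, clean_phantom):
        _, volume, truth, _ = clean_phantom
        img = volume.bscan(1)
        true_line = truth.depths[5, 1]  # interface 6, strongest outer edge
        drawn = np.clip(true_line + 3.0, 0, img.shape[0] - 1)
        p = refine_with_manual(img, drawn, half_band_px=5)
        assert np.abs(p.depths - true_line).max() <= 1.0

    def test_band_confinement_on_flat_region(self):
        img = np.full((30, 10), 0.5)
        img[25:] = 0.9  # some contrast far below, outside the band
        drawn = np.full(10, 10.0)
        p = refine_with_manual(img, drawn, half_band_px=1)
        assert np.all(np.abs(p.depths - 10.0) <= 1.0)

    def test_restriction_never_beats_unconstrained(self):
        rng = np.random.default_rng(5)
        img = rng.random((25, 15))
        g = directional_gradient(img, DARK_TO_BRIGHT)
        free = find_min_weight_path(g)
        drawn = np.full(15, 12.0)
        banded = refine_with_manual(img, drawn, half_band_px=3, smooth_sigma=(0, 0))
        w_free = path_weight(g, free.depths.astype(int))
        w_band = path_weight(g, banded.depths.astype(int))
        assert w_band >= w_free - 1e-12

    def test_drawn_line_outside_image_rejected(self):
        with pytest.raises(BoundsError):
            refine_with_manual(np.ones((10, 4)), np.full(4, 20.0))


class TestApplyDisruptions:
    @pytest.fixture()
    def interfaces(self):
        depths = np.tile(np.arange(10, 90, 10, dtype=float)[:, None, None], (1, 2, 16))
        return InterfaceSet(depths, np.ones((8, 2, 16), dtype=bool))

    def test_empty_annotations_identity(self, interfaces):
        out = apply_disruptions(interfaces, AnnotationSet())
        assert np.array_equal(out.valid, interfaces.valid)
        assert np.array_equal(out.depths, interfaces.depths)

    def test_full_bscan_annotation_clears_trace(self, interfaces):
        ann = AnnotationSet(disruptions=[Disruption(4, 1, 0, 16)])
        out = apply_disruptions(interfaces, ann)
        assert not out.valid[3, 1].any()
        assert out.valid[3, 0].all()
        assert np.array_equal(out.depths, interfaces.depths)

    def test_overlapping_annotations_union(self, interfaces):
        ann = AnnotationSet(
            disruptions=[Disruption(2, 0, 0, 10), Disruption(2, 0, 5, 14)]
        )
        out = apply_disruptions(interfaces, ann)
        expected = np.ones(16, dtype=bool)
        expected[0:14] = False
        assert np.array_equal(out.valid[1, 0], expected)

    def test_out_of_range_annotation_rejected(self, interfaces):
        with pytest.raises(BoundsError):
            apply_disruptions(
                interfaces, AnnotationSet(disruptions=[Disruption(9, 0, 0, 4)])
            )
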