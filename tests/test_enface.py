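"""Enface maps, the ETDRS central subfield, and per-eye metrics."""

import numpy as np
import pytest

from octlayers import (
    AnnotationSet,
    Disruption,
    InterfaceSet,
    LAYERS,
    OCTVolume,
    ScanGeometry,
    apply_disruptions,
    central_subfield_mask,
    compute_layer_metrics,
    disruption_percent,
    find_fovea,
    layer_metrics,
    reflectance_map,
    thickness_map,
    total_thickness_map,
)
from octlayers.enface import EnfaceMap
from octlayers.errors import BoundsError, InsufficientDataError


def flat_interfaces(depths_list, n_bscans=4, n_ascans=20):
    depths = np.tile(
        np.asarray(depths_list, dtype=float)[:, None, None], (1, n_bscans, n_ascans)
    )
    return InterfaceSet(depths, np.ones((8, n_bscans, n_ascans), dtype=bool))


@pytest.fixture()
def geometry():
    return ScanGeometry(n_bscans=4, n_ascans=20, n_depth=60)


class TestThicknessMap:
    def test_ten_pixels_is_39_microns(self, geometry):
        iset = flat_interfaces([10, 20, 25, 30, 35, 45, 50, 55])
        m = thickness_map(iset, "NFL", geometry)
        assert np.allclose(m.values, 39.0)

    def test_coincident_interfaces_zero(self, geometry):
        iset = flat_interfaces([10, 20, 20, 30, 35, 45, 50, 55])
        m = thickness_map(iset, "GCLIPL", geometry)
        assert np.allclose(m.values, 0.0)

    def test_invalid_bounding_interface_unassigns_pixel(self, geometry):
        iset = flat_interfaces([10, 20, 25, 30, 35, 45, 50, 55])
        iset.valid[0, 2, 7] = False  # interface 1 invalid at (b=2, x=7)
        m = thickness_map(iset, "NFL", geometry)
        assert not m.assigned[2, 7]
        assert np.isnan(m.values[2, 7])
        assert m.assigned.sum() == 4 * 20 - 1

    def test_conservation_of_layer_sums(self, clean_phantom):
        spec, volume, truth, _ = clean_phantom
        geom = volume.geometry
        total = total_thickness_map(truth, geom)
        acc = np.zeros_like(total.values)
        for layer in LAYERS:
            acc += thickness_map(truth, layer, geom).values
        assert np.allclose(acc, total.values, atol=1e-9)


class TestReflectanceMap:
    def test_noise_free_phantom_matches_spec_levels(self, clean_phantom):
        spec, volume, truth, _ = clean_phantom
        for i, layer in enumerate(LAYERS):
            m = reflectance_map(volume, truth, layer)
            assert m.assigned.all()
            assert np.allclose(m.values, spec.layer_level[i]), layer

    def test_zero_thickness_column_unassigned(self, geometry):
        iset = flat_interfaces([10, 20, 20, 30, 35, 45, 50, 55])
        volume = OCTVolume(np.full(geometry.shape, 0.5), geometry)
        m = reflectance_map(volume, iset, "GCLIPL")
        assert not m.assigned.any()

    def test_noisy_phantom_subfield_mean_close(self, noisy_phantom):
        spec, volume, truth, _ = noisy_phantom
        mask = central_subfield_mask(volume.geometry)
        m = reflectance_map(volume, truth, "ONL")
        got = m.values[mask.mask & m.assigned].mean()
        assert abs(got - 0.37) < 0.01


class TestCentralSubfieldMask:
    def test_default_geometry_spans_17_bscan_rows(self):
        mask = central_subfield_mask(ScanGeometry())
        rows = np.unique(np.nonzero(mask.mask)[0])
        assert rows.size == 17

    def test_physical_area_close_to_circle(self):
        g = ScanGeometry()
        mask = central_subfield_mask(g)
        area_mm2 = mask.n_pixels * g.bscan_spacing_um * g.ascan_spacing_um / 1e6
        # within one boundary-pixel ring of pi * 0.5^2
        ring = 2 * np.pi * 0.5 * max(g.bscan_spacing_um, g.ascan_spacing_um) / 1e3
        assert abs(area_mm2 - np.pi * 0.25) < ring

    def test_degenerate_single_pixel_grid(self):
        g = ScanGeometry(n_bscans=1, n_ascans=1, n_depth=10)
        mask = central_subfield_mask(g, center=(0, 0))
        assert mask.mask.shape == (1, 1) and mask.mask[0, 0]

    def test_center_outside_grid_rejected(self):
        with pytest.raises(BoundsError):
            central_subfield_mask(ScanGeometry(), center=(100, 0))


class TestLayerMetrics:
    def test_uniform_total_thickness_gives_cst(self, subfield_geometry):
        n_b, n_x = subfield_geometry.n_bscans, subfield_geometry.n_ascans
        total = EnfaceMap(np.full((n_b, n_x), 283.0), np.ones((n_b, n_x), bool))
        mask = central_subfield_mask(subfield_geometry)
        lm = layer_metrics({}, {}, total, mask)
        assert lm.CST == pytest.approx(283.0)

    def test_reflectance_ratio_of_uniform_maps(self, subfield_geometry):
        n_b, n_x = subfield_geometry.n_bscans, subfield_geometry.n_ascans
        ones = np.ones((n_b, n_x), bool)
        rmaps = {
            "ONL": EnfaceMap(np.full((n_b, n_x), 0.4), ones, unit="relative intensity"),
            "RPE": EnfaceMap(np.full((n_b, n_x), 0.5), ones, unit="relative intensity"),
        }
        total = EnfaceMap(np.full((n_b, n_x), 300.0), ones)
        mask = central_subfield_mask(subfield_geometry)
        lm = layer_metrics({}, rmaps, total, mask)
        assert lm.ONL_R == pytest.approx(0.8)
        assert lm.RPE_R == pytest.approx(1.0)

    def test_empty_mask_coverage_reports_missing_not_zero(self, subfield_geometry):
        n_b, n_x = subfield_geometry.n_bscans, subfield_geometry.n_ascans
        tmap = EnfaceMap(np.full((n_b, n_x), np.nan), np.zeros((n_b, n_x), bool))
        total = EnfaceMap(np.full((n_b, n_x), 300.0), np.ones((n_b, n_x), bool))
        mask = central_subfield_mask(subfield_geometry)
        lm = layer_metrics({"NFL": tmap}, {}, total, mask)
        assert lm.NFL_T is None
        assert lm.CST == pytest.approx(300.0)

    def test_noise_free_phantom_metrics_match_spec(self, clean_phantom):
        spec, volume, truth, _ = clean_phantom
        lm, dm = compute_layer_metrics(volume, truth)
        # reflectance ratios exact; thickness within axial quantization
        for i, layer in enumerate(LAYERS):
            assert getattr(lm, f"{layer}_R") == pytest.approx(spec.layer_level[i])
        assert lm.ONL_T == pytest.approx(spec.layer_thickness_um[4], abs=3.9)
        assert dm.as_dict() == {"NFL_d": 0.0, "INL_d": 0.0, "ONL_d": 0.0, "RPE_d": 0.0}


class TestDisruptionPercent:
    def make_mask(self, geometry):
        return central_subfield_mask(geometry)

    def test_no_disruptions_all_zero(self, subfield_geometry):
        n_b, n_x = subfield_geometry.n_bscans, subfield_geometry.n_ascans
        iset = flat_interfaces([10, 15, 20, 25, 30, 40, 45, 50], n_b, n_x)
        dm = disruption_percent(iset, self.make_mask(subfield_geometry))
        assert all(v == 0.0 for v in dm.as_dict().values())

    def test_half_mask_invalid_is_50_percent(self, subfield_geometry):
        n_b, n_x = subfield_geometry.n_bscans, subfield_geometry.n_ascans
        iset = flat_interfaces([10, 15, 20, 25, 30, 40, 45, 50], n_b, n_x)
        mask = self.make_mask(subfield_geometry)
        sel = np.argwhere(mask.mask)
        half = sel[: len(sel) // 2]
        iset.valid[2][half[:, 0], half[:, 1]] = False  # interface 3
        dm = disruption_percent(iset, mask)
        assert dm.INL_d == pytest.approx(100.0 * (len(sel) // 2) / len(sel))
        assert dm.NFL_d == 0.0

    def test_union_not_sum(self, subfield_geometry):
        n_b, n_x = subfield_geometry.n_bscans, subfield_geometry.n_ascans
        iset = flat_interfaces([10, 15, 20, 25, 30, 40, 45, 50], n_b, n_x)
        mask = self.make_mask(subfield_geometry)
        iset.valid[4][mask.mask] = False  # interface 5
        iset.valid[5][mask.mask] = False  # interface 6
        dm = disruption_percent(iset, mask)
        assert dm.ONL_d == 100.0

    def test_monotone_under_added_annotations(self, subfield_geometry):
        n_b, n_x = subfield_geometry.n_bscans, subfield_geometry.n_ascans
        iset = flat_interfaces([10, 15, 20, 25, 30, 40, 45, 50], n_b, n_x)
        mask = self.make_mask(subfield_geometry)
        previous = disruption_percent(iset, mask).as_dict()
        ann = AnnotationSet()
        rng = np.random.default_rng(0)
        for _ in range(6):
            k = int(rng.integers(1, 9))
            b = int(rng.integers(0, n_b))
            x0 = int(rng.integers(0, n_x - 5))
            ann.disruptions.append(Disruption(k, b, x0, x0 + 5))
            iset = apply_disruptions(iset, ann)
            current = disruption_percent(iset, mask).as_dict()
            assert all(current[m] >= previous[m] for m in current)
            assert all(0.0 <= current[m] <= 100.0 for m in current)
            previous = current


class TestMetricExclusion:
    def test_corrupting_disrupted_regions_changes_no_metric(self, small_geometry):
        from octlayers.synth import DisruptionZone, PhantomSpec, generate_phantom

        zone = DisruptionZone(4, b_start=0, b_end=2, x_start=80, x_end=120)
        spec = PhantomSpec(
            geometry=small_geometry,
            inner_surface_um=120.0,
            noise_sigma=0.0,
            disruption_zones=[zone],
        )
        volume, truth, annotations = generate_phantom(spec, seed=3)
        iset = apply_disruptions(truth, annotations)
        baseline_lm, baseline_dm = compute_layer_metrics(volume, iset)

        corrupted = volume.intensities.copy()
        # destroy the INL and OPL rows (the layers bounding the disrupted
        # interface) inside the zone's columns
        z_lo = int(np.floor(truth.depths[2, 0:2, 80:120].min()))
        z_hi = int(np.ceil(truth.depths[4, 0:2, 80:120].max()))
        corrupted[0:2, z_lo:z_hi, 80:120] = 0.0
        vol2 = OCTVolume(corrupted, small_geometry)
        iset2 = iset.copy()
        iset2.depths[3, 0:2, 80:120] += 5.0  # and its depth estimates
        lm2, dm2 = compute_layer_metrics(vol2, iset2)

        # metrics touching the disrupted interface are computed from
        # assigned pixels only, so corruption inside the zone is invisible
        for name, v in baseline_lm.as_dict().items():
            if name in ("INL_T", "OPL_T", "INL_R", "OPL_R"):
                got = getattr(lm2, name)
                assert got == pytest.approx(v), name
        assert dm2.as_dict() == baseline_dm.as_dict()


class TestFindFovea:
    def test_default_phantom_pit_found_at_center(self, clean_phantom):
        _, volume, truth, _ = clean_phantom
        geom = volume.geometry
        b, x = find_fovea(total_thickness_map(truth, geom))
        assert abs(b - (geom.n_bscans - 1) / 2) <= 1
        assert abs(x - (geom.n_ascans - 1) / 2) <= 1

    def test_offset_pit_recovered(self, small_geometry):
        from octlayers.synth import PhantomSpec, generate_phantom

        spec = PhantomSpec(
            geometry=small_geometry,
            inner_surface_um=120.0,
            noise_sigma=0.0,
            pit_center=(1.0, 60.0),
        )
        volume, truth, _ = generate_phantom(spec, seed=4)
        b, x = find_fovea(total_thickness_map(truth, volume.geometry))
        assert abs(b - 1.0) <= 1 and abs(x - 60.0) <= 1

    def test_uniform_map_returns_grid_center(self):
        m = EnfaceMap(np.full((9, 11), 250.0), np.ones((9, 11), bool))
        assert find_fovea(m) == (4, 5)

    def test_all_unassigned_rejected(self):
        m = EnfaceMap(np.full((4, 4), np.nan), np.zeros((4, 4), bool))
        with pytest.raises(InsufficientDataError):
            find_fovea(m)
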