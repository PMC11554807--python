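"""Synthetic generator: acquisition layout, field determinism, cargo
conservation, tissue rings and planted spheroids."""

import numpy as np
import pytest

import traffiq as tq
from traffiq.synthetic import PlacementError


class TestAcquisitionLayout:
    def test_default_potency_grid_has_24_sites_at_330um_pitch(self):
        sites = tq.make_acquisition_layout(5, 330.0, omit_centre=True)
        assert len(sites) == 24
        dists = [
            np.hypot(ax - bx, ay - by)
            for i, (ax, ay) in enumerate(sites)
            for bx, by in sites[i + 1 :]
        ]
        assert min(dists) == pytest.approx(330.0)

    def test_single_site_grid_with_centre_omitted_is_empty(self):
        assert tq.make_acquisition_layout(1, 330.0, omit_centre=True) == []

    def test_full_3x3_grid_enumerated(self):
        sites = tq.make_acquisition_layout(3, 100.0, omit_centre=False)
        assert len(sites) == 9
        expected = [(c * 100.0, r * 100.0) for r in range(3) for c in range(3)]
        assert sites == expected
        dists = [
            np.hypot(ax - bx, ay - by)
            for i, (ax, ay) in enumerate(sites)
            for bx, by in sites[i + 1 :]
        ]
        assert all(d >= 100.0 for d in dists)

    @pytest.mark.parametrize("grid_n", [2, 4, 6])
    def test_omit_centre_refused_for_even_grids(self, grid_n):
        with pytest.raises(ValueError, match="centre"):
            tq.make_acquisition_layout(grid_n, 330.0, omit_centre=True)

    @pytest.mark.parametrize("grid_n,omit,expected", [(5, True, 24), (5, False, 25), (3, True, 8)])
    def test_site_count_formula(self, grid_n, omit, expected):
        assert len(tq.make_acquisition_layout(grid_n, 50.0, omit)) == expected


class TestGenerateField:
    def test_empty_field_is_background_plus_noise(self):
        spec = tq.FieldSpec(cargo_inside_fraction=0.5, n_cells=0, noise_sd=0.0, seed=1)
        field, truth = tq.generate_field(spec)
        assert truth.n_cells == 0
        for chan in field.channels.values():
            np.testing.assert_allclose(chan, spec.background_level)

    def test_all_cargo_inside_leaves_zero_outside_fu(self):
        spec = tq.FieldSpec(cargo_inside_fraction=1.0, n_cells=4, noise_sd=0.0, seed=2)
        _field, truth = tq.generate_field(spec)
        assert np.all(truth.outside_fu == 0)
        assert np.all(truth.inside_fu == spec.cargo_total_fu)

    def test_same_seed_is_bit_identical(self):
        spec = tq.FieldSpec(cargo_inside_fraction=0.6, n_cells=5, seed=42)
        f1, t1 = tq.generate_field(spec)
        f2, t2 = tq.generate_field(spec)
        for role in f1.channels:
            np.testing.assert_array_equal(f1.channels[role], f2.channels[role])
        np.testing.assert_array_equal(t1.body_labels, t2.body_labels)
        np.testing.assert_array_equal(t1.inside_fu, t2.inside_fu)

    @pytest.mark.parametrize("frac", [0.0, 0.25, 0.5, 0.9])
    def test_cargo_conservation_pre_noise(self, frac):
        spec = tq.FieldSpec(cargo_inside_fraction=frac, n_cells=4, noise_sd=0.0, seed=5)
        _field, truth = tq.generate_field(spec)
        np.testing.assert_allclose(
            truth.inside_fu + truth.outside_fu, spec.cargo_total_fu
        )
        np.testing.assert_allclose(truth.inside_fu, frac * spec.cargo_total_fu)

    def test_planted_masks_disjoint_across_cells(self):
        spec = tq.FieldSpec(cargo_inside_fraction=0.5, n_cells=6, noise_sd=0.0, seed=9)
        _field, truth = tq.generate_field(spec)
        # label images encode disjointness: each pixel belongs to <= 1 cell
        for i in range(truth.n_cells):
            body = truth.body_mask(i)
            assert (truth.body_labels[body] == i + 1).all()
            assert truth.nucleus_mask(i).sum() > 0
            assert truth.tgn_mask(i).sum() > 0
            assert not (truth.tgn_mask(i) & ~body).any()

    def test_monotone_true_ratio_in_inside_fraction(self):
        ratios = []
        for frac in (0.2, 0.4, 0.6, 0.8):
            spec = tq.FieldSpec(cargo_inside_fraction=frac, n_cells=3, noise_sd=0.0, seed=7)
            _f, truth = tq.generate_field(spec)
            ratios.append(float(np.mean(truth.inside_fu / truth.outside_fu)))
        assert ratios == sorted(ratios)
        assert len(set(ratios)) == len(ratios)

    def test_overfull_field_raises_with_achievable_count(self):
        spec = tq.FieldSpec(
            cargo_inside_fraction=0.5, n_cells=200, field_width_px=128,
            field_height_px=128, noise_sd=0.0, seed=1,
        )
        with pytest.raises(PlacementError, match="achievable"):
            tq.generate_field(spec)

    def test_geometry_invariants_enforced(self):
        with pytest.raises(ValueError, match="nucleus_radius_um"):
            tq.FieldSpec(cargo_inside_fraction=0.5, nucleus_radius_um=9.0, cell_radius_um=8.0)
        with pytest.raises(ValueError, match="TGN"):
            tq.FieldSpec(cargo_inside_fraction=0.5, tgn_radius_um=6.0)
        with pytest.raises(ValueError):
            tq.FieldSpec(cargo_inside_fraction=1.5)


class TestGeneratePlate:
    def test_default_layout_has_16_ko_and_8_wt_control_wells(self):
        layout = tq.default_potency_layout()
        assert len(layout.wells_with_role("KO_untreated")) == 16
        assert len(layout.wells_with_role("WT_untreated")) == 8
        assert layout.grid_n == 5 and layout.site_spacing_um == 330.0

    def test_missing_moi_in_dose_table_raises(self):
        layout = tq.default_potency_layout(mois=[1e4])
        ko = tq.FieldSpec(cargo_inside_fraction=0.84)
        wt = tq.FieldSpec(cargo_inside_fraction=0.70)
        with pytest.raises(ValueError, match="dose_response"):
            tq.generate_plate(layout, ko, wt, {1e3: (0.8, 5.0)}, seed=0)

    def test_same_seed_gives_identical_plate(self):
        layout = tq.default_potency_layout(mois=[1e5], wells_per_moi=1)
        ko = tq.FieldSpec(cargo_inside_fraction=0.84, n_cells=3)
        wt = tq.FieldSpec(cargo_inside_fraction=0.70, n_cells=3)
        dose = {1e5: (0.8, 3.0)}
        p1 = tq.generate_plate(layout, ko, wt, dose, seed=11)
        p2 = tq.generate_plate(layout, ko, wt, dose, seed=11)
        assert p1.fields.keys() == p2.fields.keys()
        for key in p1.fields:
            f1, f2 = p1.fields[key][0], p2.fields[key][0]
            for role in f1.channels:
                np.testing.assert_array_equal(f1.channels[role], f2.channels[role])

    def test_roles_map_to_expected_inside_fraction(self):
        layout = tq.default_potency_layout(mois=[1e5], wells_per_moi=1)
        ko = tq.FieldSpec(cargo_inside_fraction=0.9, n_cells=2, noise_sd=0.0)
        wt = tq.FieldSpec(cargo_inside_fraction=0.3, n_cells=2, noise_sd=0.0)
        plate = tq.generate_plate(layout, ko, wt, {1e5: (0.5, 2.0)}, seed=4)
        frac_by_role = {"KO_untreated": 0.9, "WT_untreated": 0.3, "treated": 0.5}
        roles = {w.well_id: w.role for w in layout.wells}
        for (well_id, _site), (_f, truth) in plate.fields.items():
            if truth.n_cells == 0:
                continue
            total = truth.inside_fu + truth.outside_fu
            np.testing.assert_allclose(
                truth.inside_fu / total, frac_by_role[roles[well_id]]
            )


class TestTissueField:
    def test_unit_enrichment_leaves_cargo_uniform(self):
        img, _truth = tq.generate_tissue_field(
            n_cells=4, enrichment=1.0, noise_sd=0.0, seed=1
        )
        np.testing.assert_allclose(img.channels["cargo"], img.channels["cargo"].flat[0])

    def test_ground_truth_records_requested_spheroid_areas(self):
        _img, truth = tq.generate_tissue_field(
            n_cells=0, enrichment=1.0, spheroid_areas_um2=[10.0, 30.0],
            noise_sd=0.0, seed=2,
        )
        assert truth.spheroid_areas_um2 == [10.0, 30.0]

    def test_planted_spheroid_areas_recovered_by_labelling(self):
        """Independent oracle: label the noiseless calbindin channel and
        measure areas; each must match the request within one pixel ring."""
        from skimage import measure as skmeasure

        areas = [25.0, 60.0, 120.0]
        img, _truth = tq.generate_tissue_field(
            n_cells=0, enrichment=1.0, spheroid_areas_um2=areas, noise_sd=0.0, seed=3
        )
        px = img.pixel_size_um
        mask = img.channels["calbindin"] > img.channels["calbindin"].min() + 1
        lab = skmeasure.label(mask)
        measured = sorted(
            r.area * px**2 for r in skmeasure.regionprops(lab)
        )
        assert len(measured) == len(areas)
        for got, want in zip(measured, sorted(areas)):
            r_px = np.sqrt(want / np.pi) / px
            ring_tol = (2 * np.pi * r_px + 4) * px**2  # one-pixel perimeter ring
            assert abs(got - want) <= ring_tol

    def test_oversized_spheroid_raises(self):
        with pytest.raises(PlacementError):
            tq.generate_tissue_field(
                n_cells=0, enrichment=1.0, spheroid_areas_um2=[1e6],
                noise_sd=0.0, seed=1, field_width_px=128, field_height_px=128,
            )

    def test_ring_sits_at_planted_enrichment(self):
        E = 3.0
        img, truth = tq.generate_tissue_field(n_cells=3, enrichment=E, noise_sd=0.0, seed=5)
        cargo = img.channels["cargo"]
        bg = cargo.flat[0]
        ring = cargo > bg
        assert ring.any()
        np.testing.assert_allclose(cargo[ring], E * 20.0)
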