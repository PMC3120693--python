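"""Imaging pipeline tests: filtering, segmentation, measurement, outlier
rules, background subtraction and RNA spot counting."""

import math

import numpy as np
import pandas as pd
import pytest

from stochexpr.errors import ParameterError
from stochexpr.imaging import (BackgroundModel, CellRecord, ImagingParams,
                               count_rna, despeckle, fit_background,
                               measure_cell, measure_cells, preprocess_stack,
                               remove_outliers, segment_cells,
                               segment_cells_rna, subtract_background)
from stochexpr.synthetic import (GeneratorConfig, SyntheticScene,
                                 match_to_ground_truth, render_spot_image,
                                 render_stack)


def record(label=1, area=10, intensity=100.0, **kw):
    return CellRecord(label=label, area=area, solidity=1.0, eccentricity=0.9,
                      chosen_slice=1, total_intensity=intensity, **kw)


class TestPreprocess:
    def test_constant_stack_unchanged_and_summed(self):
        stack = np.full((4, 8, 8), 3.0)
        filtered, i_sum = preprocess_stack(stack)
        np.testing.assert_array_equal(filtered, stack)
        np.testing.assert_array_equal(i_sum, np.full((8, 8), 12.0))

    def test_hot_pixel_removed(self):
        stack = np.full((1, 8, 8), 5.0)
        stack[0, 3, 3] = 1e6
        filtered, _ = preprocess_stack(stack)
        assert filtered.max() == 5.0

    def test_identical_slices_sum_linearly(self):
        rng = np.random.default_rng(0)
        one = rng.uniform(0, 10, (6, 6))
        filtered, i_sum = preprocess_stack(np.stack([one] * 3))
        np.testing.assert_allclose(i_sum, 3 * filtered[0])

    def test_empty_stack_rejected(self):
        with pytest.raises(ParameterError):
            preprocess_stack(np.zeros((0, 4, 4)))


class TestSegmentation:
    def test_well_separated_rods_fully_recovered(self, protein_scene):
        _, i_sum = preprocess_stack(protein_scene.stack)
        labels = segment_cells(i_sum)
        matches = match_to_ground_truth(labels, protein_scene)
        assert labels.max() == len(protein_scene.cells)
        assert (matches.label > 0).all()

    def test_touching_pair_split_by_extended_maxima(self):
        cfg = GeneratorConfig(n_cells=2)
        cells = pd.DataFrame([
            dict(cell_id=0, cx=100, cy=100, theta=0.0, length=18, width=6,
                 is_clustered=False, center_slice=2),
            dict(cell_id=1, cx=115, cy=109, theta=0.9, length=18, width=6,
                 is_clustered=True, center_slice=2),
        ])
        cells["protein_count"] = [3000, 3500]
        cells["rna_count"] = 0
        scene = render_stack(SyntheticScene(cells=cells, config=cfg), seed=3)
        _, i_sum = preprocess_stack(scene.stack)
        labels = segment_cells(i_sum)
        matches = match_to_ground_truth(labels, scene)
        assert labels.max() == 2
        assert (matches.label > 0).all()

    def test_border_touching_object_removed(self):
        cfg = GeneratorConfig(n_cells=2)
        cells = pd.DataFrame([
            dict(cell_id=0, cx=128, cy=128, theta=0.3, length=18, width=6,
                 is_clustered=False, center_slice=2),
            dict(cell_id=1, cx=252, cy=60, theta=0.0, length=18, width=6,
                 is_clustered=False, center_slice=2),
        ])
        cells["protein_count"] = [3000, 3000]
        cells["rna_count"] = 0
        scene = render_stack(SyntheticScene(cells=cells, config=cfg), seed=4)
        _, i_sum = preprocess_stack(scene.stack)
        labels = segment_cells(i_sum)
        matches = match_to_ground_truth(labels, scene)
        assert labels.max() == 1
        assert matches.label[0] > 0 and matches.label[1] == 0

    def test_constant_image_rejected(self):
        with pytest.raises(ParameterError):
            segment_cells(np.ones((16, 16)))


class TestMeasureCell:
    def make(self, totals):
        # one 2x2 cell; slice k has constant value totals[k]/4
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[1:3, 1:3] = 1
        stack = np.stack([np.full((4, 4), t / 4.0) for t in totals])
        return stack, labels

    def test_argmax_slice_selected(self):
        stack, labels = self.make([1.0, 5.0, 3.0])
        rec = measure_cell(stack, labels, 1)
        assert rec.chosen_slice == 1
        assert rec.total_intensity == pytest.approx(5.0)
        assert not rec.flag_discarded_slice

    def test_peak_on_first_slice_flagged(self):
        stack, labels = self.make([9.0, 1.0, 1.0])
        rec = measure_cell(stack, labels, 1)
        assert rec.chosen_slice == 0
        assert rec.flag_discarded_slice

    def test_all_tied_prefers_lowest_interior(self):
        stack, labels = self.make([2.0, 2.0, 2.0, 2.0])
        rec = measure_cell(stack, labels, 1)
        assert rec.chosen_slice == 1
        assert not rec.flag_discarded_slice

    def test_missing_label_rejected(self):
        stack, labels = self.make([1.0, 2.0, 3.0])
        with pytest.raises(ParameterError):
            measure_cell(stack, labels, 7)


class TestRemoveOutliers:
    def test_top_intensity_rule_floor(self):
        # floor(0.025*40)=1 flagged; floor(0.025*39)=0 flagged
        recs40 = [record(label=i, intensity=float(i)) for i in range(1, 41)]
        out = remove_outliers(recs40)
        flagged = [r for r in out if r.flag_outlier_intensity]
        assert len(flagged) == 1 and flagged[0].total_intensity == 40.0
        out39 = remove_outliers(recs40[:39])
        assert sum(r.flag_outlier_intensity for r in out39) == 0

    def test_area_rule_median_bounds(self):
        recs = [record(label=i, area=a)
                for i, a in enumerate([8, 10, 12, 100], start=1)]
        out = remove_outliers(recs)
        assert [r.flag_outlier_area for r in out] == [False, False, False,
                                                      True]

    def test_inputs_not_mutated_and_idempotent_area_rule(self):
        recs = [record(label=i, area=a, intensity=float(a))
                for i, a in enumerate([10, 11, 12, 13, 100], start=1)]
        out = remove_outliers(recs)
        assert all(not r.flagged for r in recs)
        survivors = [r for r in out if not r.flagged]
        again = remove_outliers([record(label=r.label, area=r.area,
                                        intensity=r.total_intensity)
                                 for r in survivors])
        assert sum(r.flag_outlier_area for r in again) == 0

    def test_all_flagged_rejected(self):
        rec = record()
        rec.flag_border = True
        with pytest.raises(ParameterError):
            remove_outliers([rec])


class TestBackground:
    def test_exact_line_recovered(self):
        areas = np.array([5.0, 10.0, 20.0, 40.0])
        model = fit_background(areas, 2.0 * areas + 5.0)
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(5.0)

    def test_noisy_line_within_sampling_error(self):
        rng = np.random.default_rng(3)
        areas = rng.uniform(50, 150, 200)
        y = 12.0 * areas + 400.0 + rng.normal(0, 30.0, 200)
        model = fit_background(areas, y)
        # 3 SE of the OLS slope with sigma=30 over this design
        assert model.slope == pytest.approx(12.0, abs=0.25)
        assert model.intercept == pytest.approx(400.0, abs=30.0)

    def test_intercept_shift_property(self):
        areas = np.array([5.0, 10.0, 20.0])
        y = 3.0 * areas + 1.0
        m1 = fit_background(areas, y)
        m2 = fit_background(areas, y + 10.0)
        assert m2.slope == pytest.approx(m1.slope)
        assert m2.intercept == pytest.approx(m1.intercept + 10.0)

    def test_degenerate_areas_rejected(self):
        with pytest.raises(ParameterError):
            fit_background([5.0, 5.0], [1.0, 2.0])

    def test_subtraction_and_negative_retention(self):
        model = BackgroundModel(slope=2.0, intercept=5.0)
        recs = [record(label=1, area=10, intensity=100.0),
                record(label=2, area=50, intensity=20.0)]
        out = subtract_background(recs, model)
        assert out[0].corrected_intensity == pytest.approx(75.0)
        assert out[1].corrected_intensity == pytest.approx(20.0 - 105.0)

    def test_zero_model_is_identity(self):
        out = subtract_background([record(intensity=42.0)],
                                  BackgroundModel(0.0, 0.0))
        assert out[0].corrected_intensity == 42.0


class TestProteinRoundTrip:
    def test_corrected_intensity_tracks_protein_count(self, protein_scene,
                                                      control_scene):
        filt, i_sum = preprocess_stack(protein_scene.stack)
        labels = segment_cells(i_sum)
        records = measure_cells(filt, labels)
        cf, ci = preprocess_stack(control_scene.stack)
        ctrl = measure_cells(cf, segment_cells(ci))
        model = fit_background([r.area for r in ctrl],
                               [r.total_intensity for r in ctrl])
        records = subtract_background(records, model)
        matches = match_to_ground_truth(labels, protein_scene)
        by_label = {r.label: r.corrected_intensity for r in records}
        pairs = np.array([
            (protein_scene.cells.protein_count[m.cell_id], by_label[m.label])
            for m in matches.itertuples() if m.label in by_label])
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert r >= 0.95


class TestCountRNA:
    def test_round_trip_counts_1_to_8(self, spot_scene):
        labels = segment_cells_rna(spot_scene.spot_image)
        _, per_cell = count_rna(spot_scene.spot_image, labels)
        matches = match_to_ground_truth(labels, spot_scene)
        errs = [abs(int(spot_scene.cells.rna_count[m.cell_id])
                    - per_cell.get(m.label, 0))
                for m in matches.itertuples() if m.label > 0]
        assert len(errs) >= 20
        assert np.mean(errs) <= 1.0

    def test_unit_intensity_estimate_near_truth(self, spot_scene):
        labels = segment_cells_rna(spot_scene.spot_image)
        spots, _ = count_rna(spot_scene.spot_image, labels)
        unit = spots[0].unit_intensity
        assert unit == pytest.approx(
            spot_scene.config.rna_unit_intensity, rel=0.1)

    def test_explicit_spot_multiples(self):
        # one cell, one 3-RNA spot plus a far 1-RNA spot; unit supplied
        cfg = GeneratorConfig(n_cells=1, photon_noise=False,
                              read_noise_sd=0.0, hot_pixel_rate=0.0)
        cells = pd.DataFrame([dict(cell_id=0, cx=128, cy=128, theta=0.0,
                                   length=22, width=6, is_clustered=False,
                                   center_slice=2, protein_count=0,
                                   rna_count=4)])
        spots = pd.DataFrame([dict(cell_id=0, offset=-0.6, rna=3),
                              dict(cell_id=0, offset=0.6, rna=1)])
        scene = render_spot_image(SyntheticScene(cells=cells, config=cfg),
                                  seed=2, spots=spots)
        labels = segment_cells_rna(scene.spot_image)
        records, per_cell = count_rna(scene.spot_image, labels,
                                      unit_intensity=cfg.rna_unit_intensity)
        assert sorted(r.rna_count for r in records) == [1, 3]
        assert per_cell[1] == 4

    def test_no_spots_gives_zero_counts(self):
        cfg = GeneratorConfig(n_cells=3)
        cells = pd.DataFrame([
            dict(cell_id=i, cx=60 + 60 * i, cy=128, theta=0.4 * i,
                 length=18, width=6, is_clustered=False, center_slice=2,
                 protein_count=0, rna_count=0)
            for i in range(3)])
        scene = render_spot_image(SyntheticScene(cells=cells, config=cfg),
                                  seed=5)
        labels = segment_cells_rna(scene.spot_image)
        _, per_cell = count_rna(scene.spot_image, labels)
        assert set(per_cell.values()) == {0}

    def test_exclusion_list_respected(self, spot_scene):
        labels = segment_cells_rna(spot_scene.spot_image)
        drop = int(np.unique(labels[labels > 0])[0])
        labels2 = segment_cells_rna(spot_scene.spot_image, exclusions=[drop])
        assert drop not in np.unique(labels2)

    def test_despeckle_targets_isolated_spikes(self):
        img = np.full((16, 16), 100.0)
        img[5, 5] = 30000.0
        out = despeckle(img)
        assert out[5, 5] == 100.0
        # a smooth 3-px-wide peak survives
        img2 = np.full((16, 16), 100.0)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                img2[8 + dy, 8 + dx] += 200.0
        assert despeckle(img2)[8, 8] == img2[8, 8]
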