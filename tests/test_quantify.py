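"""Morphometry rules: Ki67 ratio, periodicity, count boxes, TLS."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mamspat import quantify as qt
from mamspat import segment as sg
from mamspat import synthetic as syn
from mamspat.core import mm2_of
from mamspat.pipeline import _fill_box, _place_classified_boxes


def _mask_set(pos_px, neg_px, shape=(100, 100)):
    pos = np.zeros(shape, np.int32)
    neg = np.zeros(shape, np.int32)
    pos.ravel()[:pos_px] = 1
    neg.ravel()[pos_px : pos_px + neg_px] = 2
    epi = np.ones(shape, bool)
    return sg.MaskSet(epithelium=epi, ki67_pos=pos, ki67_neg=neg)


class TestKi67Ratio:
    def test_constructed_pixel_counts(self):
        r = qt.ki67_epithelial_ratio(_mask_set(1200, 4800))
        assert r.ratio == pytest.approx(0.25)

    def test_zero_positive_pixels(self):
        r = qt.ki67_epithelial_ratio(_mask_set(0, 500))
        assert r.ratio == 0.0 and r.defined

    def test_equal_areas(self):
        r = qt.ki67_epithelial_ratio(_mask_set(700, 700))
        assert r.ratio == 1.0

    def test_zero_negative_flagged_undefined(self):
        r = qt.ki67_epithelial_ratio(_mask_set(10, 0))
        assert not r.defined and r.ratio is None


class TestPeriodicity:
    def _trace(self, positions):
        return syn.DuctTrace(np.array([[0.0, 0.0], [1e4, 0.0]]),
                             np.asarray(positions, float))

    def test_perfect_periodicity_single_run(self):
        runs = qt.detect_periodic_runs(self._trace([0, 50, 100, 150]))
        assert len(runs) == 1
        assert np.allclose(runs[0].gaps_um, 50.0)

    def test_three_macrophages_no_run(self):
        assert qt.detect_periodic_runs(self._trace([0, 50, 100])) == []

    def test_tight_pair_merged_then_run_detected(self):
        runs = qt.detect_periodic_runs(
            self._trace([0, 50, 54, 100, 150]), cv_tol=0.30, cluster_gap_um=8.0
        )
        assert len(runs) == 1
        assert np.allclose(runs[0].positions_um, [0, 52, 100, 150])

    def test_irregular_spacing_rejected(self):
        runs = qt.detect_periodic_runs(self._trace([0, 10, 100, 110, 300]))
        assert runs == []

    def test_arc_length_not_chord(self):
        """On a semicircular duct the gap is r*theta, not the chord."""
        r, theta = 100.0, np.pi / 6
        angles = np.linspace(0, np.pi, 500)
        poly = np.stack([r * np.cos(angles), r * np.sin(angles)], axis=1)
        positions = np.array([0, 1, 2, 3, 4]) * r * theta
        trace = syn.DuctTrace(poly, positions)
        runs = qt.detect_periodic_runs(trace)
        gaps = qt.inter_macrophage_distances(runs)
        assert np.allclose(gaps, r * theta, rtol=1e-3)
        chord = 2 * r * np.sin(theta / 2)
        assert gaps.mean() > chord

    def test_planted_spacing_recovered(self):
        gaps = []
        for seed in range(4):
            gt = syn.generate_field(syn.slide_scale_config(seed=seed), "young")
            for trace in gt.ducts:
                gaps.extend(
                    qt.inter_macrophage_distances(qt.detect_periodic_runs(trace))
                )
        gaps = np.asarray(gaps)
        assert len(gaps) >= 100
        assert abs(gaps.mean() / 60.0 - 1.0) < 0.02


class TestCountBoxes:
    def test_full_parenchyma_places_all(self):
        mask = np.ones((400, 400), bool)
        boxes = qt.place_count_boxes(mask, 8, pixel_size_um=2.0, seed=0)
        assert len(boxes) == 8

    def test_empty_parenchyma_errors(self):
        with pytest.raises(ValueError):
            qt.place_count_boxes(np.zeros((400, 400), bool), 8, 2.0)

    def test_placement_uniform_over_valid_region(self):
        """Box centres are uniform across the field when everything is valid."""
        mask = np.ones((400, 400), bool)
        xs = []
        for seed in range(300):
            (box,) = qt.place_count_boxes(mask, 1, pixel_size_um=2.0, seed=seed)
            xs.append(box.x0_px)
        # origins uniform on [0, width - box_width]
        lim = 400 - qt.BOX_WIDTH_UM / 2.0
        counts, _ = np.histogram(xs, bins=5, range=(0, lim))
        p = sps.chisquare(counts).pvalue
        assert p > 0.01

    def test_classification_examples(self):
        parenchyma = np.zeros((600, 600), bool)
        parenchyma[100:500, 100:500] = True
        central_box = qt.CountBox(290, 290, pixel_size_um=10.0,
                                  width_um=200, height_um=200)
        edge_box = qt.CountBox(485, 290, pixel_size_um=10.0,
                               width_um=200, height_um=200)
        outside_box = qt.CountBox(10, 10, pixel_size_um=10.0,
                                  width_um=200, height_um=200)
        assert qt.classify_box_location(central_box, parenchyma) == "central"
        assert qt.classify_box_location(edge_box, parenchyma) == "peripheral"
        assert qt.classify_box_location(outside_box, parenchyma) == "n/a"

    def test_classification_flips_once_along_radius(self):
        parenchyma = np.zeros((800, 800), bool)
        yy, xx = np.mgrid[0:800, 0:800]
        parenchyma[(xx - 400) ** 2 + (yy - 400) ** 2 < 350**2] = True
        classes = []
        for x0 in range(360, 760, 20):
            box = qt.CountBox(x0, 390, pixel_size_um=10.0,
                              width_um=200, height_um=200)
            classes.append(qt.classify_box_location(box, parenchyma))
        labels = [c for c in classes if c != "n/a"]
        flips = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
        assert labels[0] == "central"
        assert flips == 1

    def test_counting_rule_examples(self):
        box = qt.CountBox(0.0, 0.0, pixel_size_um=1.0, width_um=100,
                          height_um=50)
        area = np.pi * 25.0
        cells = pd.DataFrame(
            [
                dict(cell_class="in60", x_px=50.0, y_px=2.6, area_px=area),
                dict(cell_class="bottom_tie", x_px=50.0, y_px=50.0, area_px=area),
                dict(cell_class="top_tie", x_px=50.0, y_px=0.0, area_px=area),
                dict(cell_class="right_tie", x_px=100.0, y_px=25.0, area_px=area),
                dict(cell_class="left_tie", x_px=0.0, y_px=25.0, area_px=area),
            ]
        )
        counts = qt.count_cells_in_box(box, cells)
        assert counts.get("in60", 0) == 1
        assert counts.get("top_tie", 0) == 1
        assert counts.get("right_tie", 0) == 1
        assert "bottom_tie" not in counts
        assert "left_tie" not in counts

    def test_tiling_counts_each_cell_once(self, rng):
        """Summing over an exhaustive tiling of boxes counts every interior
        cell exactly once under the >50 % / top-right rule."""
        cells = pd.DataFrame(
            dict(
                cell_class="c",
                x_px=rng.uniform(60, 340, 200),
                y_px=rng.uniform(60, 340, 200),
                area_px=np.pi * 4.0**2,
            )
        )
        total = 0
        for y0 in range(0, 400, 100):
            for x0 in range(0, 400, 100):
                box = qt.CountBox(float(x0), float(y0), pixel_size_um=1.0,
                                  width_um=100, height_um=100)
                total += qt.count_cells_in_box(box, cells).get("c", 0)
        assert total == 200

    def test_macrophage_size_filter_boundary(self):
        areas = np.array([0.49, 0.5, 0.6, 1.2]) * 40.0
        kept = qt.filter_macrophage_objects(areas, 40.0)
        assert kept.tolist() == [20.0, 24.0, 48.0]
        with pytest.warns(UserWarning):
            out = qt.filter_macrophage_objects(areas, None)
        assert np.array_equal(out, areas)


class TestImmuneDensities:
    def test_arithmetic(self):
        box = qt.CountBox(0, 0, pixel_size_um=1.0)
        box.counts = {"macrophage_stromal": 12, "t_cell_epithelial": 6,
                      "t_cell_stromal": 3}
        box.intralobular_stroma_mm2 = 0.046
        box.total_stroma_mm2 = 0.05
        box.luminal_count = 300
        recs = {r.name: r for r in qt.immune_densities(box)}
        assert recs["stromal_mac_per_mm2"].value == pytest.approx(260.87, abs=0.01)
        assert recs["t_epi_per100"].value == pytest.approx(2.0)
        assert recs["t_stromal_per_mm2"].value == pytest.approx(60.0)

    def test_zero_area_flagged(self):
        box = qt.CountBox(0, 0, pixel_size_um=1.0)
        recs = {r.name: r for r in qt.immune_densities(box)}
        assert not recs["stromal_mac_per_mm2"].defined
        assert not recs["t_epi_per100"].defined

    def test_central_peripheral_ratio_recovered(self):
        """Planted 2:1 central:peripheral stromal macrophage density is
        recovered from classified count boxes."""
        central, peripheral = [], []
        seed = 0
        while len(central) + len(peripheral) < 56:
            cfg = syn.slide_scale_config(seed=100 + seed, n_tls=0)
            gt = syn.generate_field(cfg, "young")
            parenchyma = gt.epithelium_mask | gt.stroma_mask
            boxes = _place_classified_boxes(gt, parenchyma, 4, seed=seed)
            for box in boxes:
                _fill_box(box, gt)
                recs = {r.name: r for r in qt.immune_densities(box)}
                rec = recs["stromal_mac_per_mm2"]
                if rec.defined:
                    (central if box.location_class == "central"
                     else peripheral).append(rec.value)
            seed += 1
        ratio = np.mean(central) / np.mean(peripheral)
        assert ratio == pytest.approx(2.0, rel=0.15)


class TestTLS:
    def _planted(self, rng, centre=(500.0, 500.0), n_b=60, n_t=80, mixed=False):
        b = rng.normal(centre, 18.0, size=(n_b, 2))
        if mixed:
            t = rng.normal(centre, 18.0, size=(n_t, 2))
        else:
            ang = rng.uniform(0, 2 * np.pi, n_t)
            rad = rng.uniform(45, 70, n_t)
            t = np.stack([centre[0] + rad * np.cos(ang),
                          centre[1] + rad * np.sin(ang)], axis=1)
        return b, t

    def test_planted_tls_detected(self, rng):
        b, t = self._planted(rng)
        recs, density = qt.detect_tls(b, t, tissue_area_mm2=2.0)
        assert len(recs) == 1 and recs[0].qualifies
        assert density == pytest.approx(0.5)

    def test_mixed_aggregate_rejected(self, rng):
        b, t = self._planted(rng, mixed=True)
        recs, density = qt.detect_tls(b, t, tissue_area_mm2=2.0)
        assert density == 0.0
        assert all(not r.qualifies for r in recs)

    def test_no_b_cells(self):
        recs, density = qt.detect_tls(np.empty((0, 2)), np.empty((0, 2)), 1.0)
        assert recs == [] and density == 0.0

    def test_zero_tissue_area_errors(self, rng):
        b, t = self._planted(rng)
        with pytest.raises(ValueError):
            qt.detect_tls(b, t, tissue_area_mm2=0.0)

    def test_slide_scale_planted_structures_found(self, slide_gt):
        gt = slide_gt
        b = gt.cells_of("b_cell")[["x_px", "y_px"]].to_numpy()
        t = gt.cells_of("t_cell_stromal")[["x_px", "y_px"]].to_numpy()
        area = mm2_of(gt.epithelium_mask | gt.stroma_mask,
                      gt.config.pixel_size_um)
        recs, density = qt.detect_tls(
            b, t, area, pixel_size_um=gt.config.pixel_size_um
        )
        assert sum(r.qualifies for r in recs) == gt.config.n_tls
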