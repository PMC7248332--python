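"""Per-neuron quantification: calls, intensities, areas, combination tables."""

import numpy as np
import pytest

from drgquant import imsim, quant
from drgquant.imsim import SimulationConfig, disk_mask, psf_render, render_section
from drgquant.popsim import NeuronRecord
from drgquant.quant import (
    QuantConfig,
    call_positive,
    circular_vs_mask_intensity,
    classify_size,
    coexpression_table,
    corrected_intensity,
    estimate_background,
    marker_percentage_table,
    measure_mean_intensity,
    measure_soma_area,
)
from drgquant.spots import detect_peaks


class TestCallPositive:
    @pytest.mark.parametrize("count,expected", [(0, False), (2, False), (3, True), (17, True)])
    def test_three_or_more_puncta_rule(self, count, expected):
        assert call_positive(count) is expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            call_positive(-1)


class TestMeanIntensity:
    def test_uniform_image(self):
        assert measure_mean_intensity(np.full((40, 40), 7.0), (20, 20)) == 7.0

    def test_disk_covering_roi(self):
        img = np.zeros((60, 60))
        img[disk_mask((60, 60), (30, 30), 20)] = 10.0
        assert measure_mean_intensity(img, (30, 30)) == 10.0

    def test_clipped_circle_raises(self):
        with pytest.raises(ValueError, match="exits the image"):
            measure_mean_intensity(np.zeros((15, 15)), (3, 3))

    def test_physical_radius_is_6_3_um(self):
        assert QuantConfig().roi_radius_um == pytest.approx(6.3)


class TestBackground:
    def test_region_mean_averaging(self):
        img = np.zeros((60, 90))
        img[disk_mask(img.shape, (30, 15), 10)] = 2.0
        img[disk_mask(img.shape, (30, 45), 10)] = 4.0
        img[disk_mask(img.shape, (30, 75), 10)] = 6.0
        bg = estimate_background(img, [(30, 15), (30, 45), (30, 75)])
        assert bg == pytest.approx(4.0)

    def test_uniform_background_corrects_to_zero(self):
        img = np.full((80, 80), 3.5)
        bg = estimate_background(img, [(20, 20), (20, 60), (60, 20)])
        neuron = measure_mean_intensity(img, (40, 40))
        assert corrected_intensity(neuron, bg) == pytest.approx(0.0)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError, match="3 to 5"):
            estimate_background(np.zeros((50, 50)), [(20, 20), (30, 30)])

    def test_region_containing_puncta_rejected(self, sim_cfg_clean):
        counts = np.zeros((80, 80), dtype=int)
        counts[20, 20] = 1
        img = psf_render(counts, sim_cfg_clean)
        found = detect_peaks(img, 6.0, 1.5)
        with pytest.raises(ValueError, match=r"regions \[0\]"):
            estimate_background(
                img, [(20, 20), (20, 60), (60, 60)], spots=found
            )

    def test_constant_offset_invariance(self, rng):
        """Adding c to every pixel leaves corrected intensities unchanged."""
        img = rng.normal(5.0, 1.0, size=(100, 100))
        centers = [(25, 25), (25, 75), (75, 25), (75, 75)]
        base = corrected_intensity(
            measure_mean_intensity(img, (50, 50)), estimate_background(img, centers)
        )
        shifted = corrected_intensity(
            measure_mean_intensity(img + 11.3, (50, 50)),
            estimate_background(img + 11.3, centers),
        )
        assert abs(base - shifted) < 1e-9


class TestClassifySize:
    @pytest.mark.parametrize(
        "area,expected",
        [(500.0, "small"), (649.9, "small"), (650.0, "medium"), (700.0, "medium"),
         (900.0, "medium"), (900.1, "large"), (901.0, "large")],
    )
    def test_boundaries(self, area, expected):
        assert classify_size(area) == expected

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            classify_size(0.0)


def _make_neuron(i, marker, expr, probes):
    return NeuronRecord(
        id=i,
        marker=marker,
        soma_area=500.0,
        truth_expr={p: p in expr for p in probes},
        called_expr={p: p in expr for p in probes},
        true_puncta={p: 0 for p in probes},
    )


class TestCoexpressionTable:
    def test_single_probe_fractions(self):
        probes = ("ASIC3",)
        pop = [_make_neuron(i, "NF200", {"ASIC3"} if i < 4 else set(), probes) for i in range(10)]
        tab = coexpression_table(pop, probes).set_index("combination")
        assert tab.loc["ASIC3", "fraction"] == pytest.approx(0.4)
        assert tab.loc["none", "fraction"] == pytest.approx(0.6)

    def test_one_neuron_per_combination(self):
        import itertools

        probes = ("ASIC1a", "ASIC2b", "ASIC3")
        combos = [set(c) for k in range(4) for c in itertools.combinations(probes, k)]
        pop = [_make_neuron(i, "NF200", c, probes) for i, c in enumerate(combos)]
        tab = coexpression_table(pop, probes)
        assert len(tab) == 8
        assert (tab["count"] == 1).all()

    def test_partition_property(self, rng):
        probes = ("ASIC1a", "ASIC2b", "ASIC3")
        pop = [
            _make_neuron(i, "CGRP", {p for p in probes if rng.random() < 0.5}, probes)
            for i in range(137)
        ]
        tab = coexpression_table(pop, probes)
        assert tab["count"].sum() == 137
        assert abs(tab["fraction"].sum() - 1.0) < 1e-12

    def test_missing_call_raises(self):
        probes = ("ASIC1a", "ASIC3")
        bad = _make_neuron(0, "IB4", set(), probes)
        del bad.called_expr["ASIC3"]
        with pytest.raises(ValueError, match="ASIC3"):
            coexpression_table([bad], probes)


class TestMarkerPercentages:
    def test_seven_of_ten_is_70_percent(self):
        probes = ("ASIC3",)
        pop = [_make_neuron(i, "NF200", {"ASIC3"} if i < 7 else set(), probes) for i in range(10)]
        assert marker_percentage_table(pop, "ASIC3") == {"NF200": 70.0}

    def test_no_positives_give_zero_not_nan(self):
        probes = ("ASIC3",)
        pop = [_make_neuron(i, "IB4", set(), probes) for i in range(5)]
        assert marker_percentage_table(pop, "ASIC3") == {"IB4": 0.0}

    def test_absent_class_not_reported_as_zero(self):
        probes = ("ASIC3",)
        pop = [_make_neuron(0, "NF200", {"ASIC3"}, probes)]
        table = marker_percentage_table(pop, "ASIC3")
        assert "CGRP" not in table

    def test_percentages_bounded(self, rng):
        probes = ("ASIC3",)
        pop = [
            _make_neuron(i, rng.choice(["NF200", "CGRP", "IB4"]),
                         {"ASIC3"} if rng.random() < 0.5 else set(), probes)
            for i in range(60)
        ]
        assert all(0.0 <= v <= 100.0 for v in marker_percentage_table(pop, "ASIC3").values())


class TestSomaArea:
    def test_pixel_count_times_pixel_area(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :10] = True  # 100 px
        assert measure_soma_area(mask, 0.63) == pytest.approx(39.69)

    def test_rendered_disk_recovers_requested_area(self):
        area = 700.0
        r_px = np.sqrt(area / np.pi) / 0.2
        mask = disk_mask((200, 200), (100, 100), r_px)
        measured = measure_soma_area(mask, 0.2)
        one_pixel_row = 2 * np.pi * np.sqrt(area / np.pi) * 0.2
        assert abs(measured - area) <= one_pixel_row

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            measure_soma_area(np.zeros((5, 5), dtype=bool), 0.63)


class TestCircularVsMask:
    def test_homogeneous_somata_give_perfect_correlation(self):
        img = np.zeros((300, 300))
        labels = np.zeros((300, 300), dtype=int)
        for i, (c, v) in enumerate(zip([(60, 60), (60, 220), (220, 60), (220, 220)], [2, 5, 9, 14])):
            m = disk_mask(img.shape, c, 30)
            labels[m] = i + 1
            img[m] = v
        table, r = circular_vs_mask_intensity(img, labels, radius_px=10)
        assert table["included"].all()
        assert r == pytest.approx(1.0)

    def test_too_few_usable_neurons_raises(self):
        img = np.zeros((100, 100))
        labels = np.zeros((100, 100), dtype=int)
        labels[disk_mask(labels.shape, (30, 30), 20)] = 1
        labels[disk_mask(labels.shape, (70, 70), 20)] = 2
        img[labels > 0] = 1.0
        with pytest.raises(ValueError, match="need >= 3"):
            circular_vs_mask_intensity(img, labels, radius_px=10)

    def test_small_soma_flagged_and_excluded(self):
        img = np.zeros((200, 200))
        labels = np.zeros((200, 200), dtype=int)
        centers = [(40, 40), (40, 150), (150, 40), (150, 150)]
        radii = [25, 25, 25, 5]  # last soma cannot contain the circle
        for i, (c, r0) in enumerate(zip(centers, radii)):
            m = disk_mask(img.shape, c, r0)
            labels[m] = i + 1
            img[m] = float(i + 1)
        table, _ = circular_vs_mask_intensity(img, labels, radius_px=10)
        assert not table.loc[table["label"] == 4, "included"].item()

    def test_synthetic_population_high_linear_correlation(self, rng):
        """Puncta-bearing somata: circular-ROI vs whole-mask mean intensity
        correlate strongly (r > 0.9) across >= 100 neurons."""
        cfg = SimulationConfig(seed=17)
        probes = ("ASIC3",)
        neurons = [
            NeuronRecord(
                id=i,
                marker="CGRP",
                soma_area=300.0,
                truth_expr={"ASIC3": True},
                true_puncta={"ASIC3": int(rng.integers(0, 400))},
                intensity_scale={"ASIC3": 1.0},
            )
            for i in range(100)
        ]
        _, probe_img, labels = render_section(
            neurons, cfg, probe="ASIC3", field_size_um=420.0, rng=rng
        )
        table, r = circular_vs_mask_intensity(
            probe_img, labels, radius_px=int(6.3 / cfg.px_um)
        )
        assert len(table) == 100
        assert r > 0.9
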