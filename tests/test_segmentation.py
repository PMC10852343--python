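import logging

import numpy as np
import pytest

from drgquant import (ImageIOError, ImageStack, LabelMap, SegmentationParams,
                      exclude_overlap, grow_mask, measure_mpi,
                      neuron_instances, nonneuronal_mhcii_mask,
                      nuclei_instances, shrink_mask, tissue_mask)
from helpers import grow_oracle, random_blob_labels, shrink_oracle, truth_to_label


def stack_from(arrays: dict, pixel_area=0.42):
    return ImageStack(channels={k: np.asarray(v) for k, v in arrays.items()},
                      pixel_area_um2=pixel_area, bit_depth=None)


def disc_mask(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestTissueMask:
    def test_blank_image_gives_empty_mask(self):
        stack = stack_from({"PGP9.5": np.zeros((64, 64))})
        out = tissue_mask(stack, SegmentationParams())
        assert out.binary().sum() == 0

    def test_recovers_planted_tissue_area(self, noiseless_scene):
        _, stack, truth, cfg = noiseless_scene
        out = tissue_mask(stack, cfg.segmentation)
        area = out.binary().sum()
        assert abs(area - truth.tissue_area_px) / truth.tissue_area_px < 0.02

    def test_depends_only_on_neuron_marker(self, noiseless_scene):
        _, stack, _, cfg = noiseless_scene
        altered = stack.copy()
        altered.channels["MHCII"] = np.zeros_like(altered.channels["MHCII"])
        a = tissue_mask(stack, cfg.segmentation)
        b = tissue_mask(altered, cfg.segmentation)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_missing_channel_error(self):
        stack = stack_from({"MHCII": np.zeros((8, 8))})
        with pytest.raises(ImageIOError, match="PGP9.5"):
            tissue_mask(stack, SegmentationParams())


class TestNeuronInstances:
    def test_blank_image_gives_no_instances(self):
        stack = stack_from({"PGP9.5": np.zeros((64, 64))})
        out = neuron_instances(stack, SegmentationParams())
        assert out.n_instances == 0

    def test_noiseless_scene_recovered_exactly(self, noiseless_scene):
        _, stack, truth, cfg = noiseless_scene
        out = neuron_instances(stack, cfg.segmentation)
        tn = truth.neurons()
        assert out.n_instances == len(tn)
        areas = out.areas()
        for _, row in tn.iterrows():
            label = truth_to_label(row, out.labels)
            assert label > 0
            assert areas[label] == row.area_px

    def test_fiber_ribbon_excluded(self):
        img = np.zeros((120, 240))
        img[50:53, 10:210] = 10_000.0          # 3 px wide, 200 px long ribbon
        img[80:100, 100:120] = 10_000.0        # a soma-sized blob
        stack = stack_from({"PGP9.5": img})
        params = SegmentationParams(neuron_marker_threshold=5_000.0,
                                    neuron_min_area_px=50,
                                    neuron_max_area_px=10_000)
        out = neuron_instances(stack, params)
        assert out.n_instances == 1
        assert out.areas()[1] == 400  # only the blob survives


class TestShrinkGrow:
    def test_k0_is_identity(self, rng):
        labels = LabelMap(random_blob_labels(rng), class_name="neuron")
        for op in (shrink_mask, grow_mask):
            out = op(labels, 0)
            np.testing.assert_array_equal(out.labels, labels.labels)
            assert out.labels is not labels.labels

    def test_square_erosion_matches_distance_oracle(self):
        arr = np.zeros((40, 40), np.int32)
        arr[10:30, 10:30] = 1  # 20x20 filled square
        out = shrink_mask(LabelMap(arr), 4)
        np.testing.assert_array_equal(out.labels, shrink_oracle(arr, 4))

    def test_erosion_to_extinction_is_dropped_and_logged(self, caplog):
        arr = disc_mask((20, 20), (10, 10), 3).astype(np.int32)
        with caplog.at_level(logging.INFO, logger="drgquant.segmentation"):
            out = shrink_mask(LabelMap(arr), 4)
        assert out.n_instances == 0
        assert any("extinction" in rec.message for rec in caplog.records)

    def test_disc_dilation_matches_distance_oracle(self):
        arr = disc_mask((40, 40), (20, 20), 5).astype(np.int32)
        out = grow_mask(LabelMap(arr), 7)
        np.testing.assert_array_equal(out.labels, grow_oracle(arr, 7))

    def test_grow_then_shrink_contains_original(self, rng):
        arr = disc_mask((60, 60), (30, 30), 10).astype(np.int32)
        closed = shrink_mask(grow_mask(LabelMap(arr), 6), 6)
        assert ((arr > 0) & ~(closed.labels > 0)).sum() == 0

    def test_overlapping_growth_assigned_to_nearest_seed(self):
        arr = np.zeros((30, 60), np.int32)
        arr[disc_mask(arr.shape, (15, 15), 4)] = 1
        arr[disc_mask(arr.shape, (15, 40), 4)] = 2
        out = grow_mask(LabelMap(arr), 10)
        np.testing.assert_array_equal(out.labels, grow_oracle(arr, 10))
        # pixels strictly nearer seed 1 carry label 1 even inside seed 2's reach
        assert out.labels[15, 26] == 1 and out.labels[15, 29] == 2


class TestNonNeuronalMask:
    def test_no_immune_cells_empty(self):
        stack = stack_from({"MHCII": np.full((64, 64), 4_000.0)})
        out = nonneuronal_mhcii_mask(stack, SegmentationParams())
        assert out.n_instances == 0

    def test_captures_exactly_the_bright_cells(self, noiseless_scene):
        _, stack, truth, cfg = noiseless_scene
        out = nonneuronal_mhcii_mask(stack, cfg.segmentation)
        immune = truth.objects[truth.objects["class"] == "immune"]
        assert out.n_instances == len(immune)
        for _, row in immune.iterrows():
            assert truth_to_label(row, out.labels) > 0

    def test_threshold_monotonicity(self, noiseless_scene):
        spec, stack, truth, cfg = noiseless_scene
        import dataclasses
        lowered = dataclasses.replace(
            cfg.segmentation, nonneuronal_mhcii_min=spec.neuron_mhcii_base / 2,
            immune_min_diam_um=2.0, immune_max_diam_um=70.0)
        high = nonneuronal_mhcii_mask(stack, cfg.segmentation)
        low = nonneuronal_mhcii_mask(stack, lowered)
        assert low.binary().sum() > high.binary().sum()
        assert (high.binary() & ~low.binary()).sum() == 0


class TestExcludeOverlap:
    def test_empty_exclusion_is_identity(self):
        arr = disc_mask((30, 30), (15, 15), 6).astype(np.int32)
        out = exclude_overlap(LabelMap(arr, class_name="neuron"),
                              LabelMap(np.zeros_like(arr)))
        np.testing.assert_array_equal(out.labels, arr)

    def test_full_coverage_flags_unmeasurable(self):
        arr = disc_mask((30, 30), (15, 15), 6).astype(np.int32)
        out = exclude_overlap(LabelMap(arr), LabelMap(arr.copy()))
        assert out.binary().sum() == 0
        stack = stack_from({"MHCII": np.full((30, 30), 100.0)})
        (rec,) = measure_mpi(stack, out, "MHCII", expected_ids=[1])
        assert not rec.measurable

    def test_half_coverage_halves_area(self):
        arr = np.zeros((20, 20), np.int32)
        arr[5:15, 5:15] = 1
        excl = np.zeros_like(arr)
        excl[5:15, 10:15] = 1
        out = exclude_overlap(LabelMap(arr), LabelMap(excl))
        assert out.binary().sum() == 50

    def test_never_increases_pixels(self, rng):
        labels = LabelMap(random_blob_labels(rng))
        excl = LabelMap(random_blob_labels(rng, threshold=0.5))
        out = exclude_overlap(labels, excl)
        assert out.binary().sum() <= labels.binary().sum()
        assert ((out.labels > 0) & ~(labels.labels > 0)).sum() == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ImageIOError, match="shape"):
            exclude_overlap(LabelMap(np.zeros((4, 4), np.int32)),
                            LabelMap(np.zeros((5, 5), np.int32)))


class TestNucleiInstances:
    def test_blank_dapi_gives_no_nuclei(self):
        stack = stack_from({"DAPI": np.zeros((64, 64))})
        neurons = LabelMap(np.zeros((64, 64), np.int32))
        neuronal, nonneuronal = nuclei_instances(stack, neurons,
                                                 SegmentationParams())
        assert neuronal.n_instances == 0 and nonneuronal.n_instances == 0

    def test_one_neuronal_nucleus_per_neuron(self, noiseless_scene):
        _, stack, truth, cfg = noiseless_scene
        neurons = neuron_instances(stack, cfg.segmentation)
        neuronal, _ = nuclei_instances(stack, neurons, cfg.segmentation)
        expected = int(truth.neurons().has_nucleus.sum())
        assert neuronal.n_instances == expected

    def test_satellite_nucleus_adjacent_is_nonneuronal(self):
        # a nucleus beside (not inside) a soma: centroid outside the neuron
        h = w = 60
        neuron = disc_mask((h, w), (30, 20), 10)
        dapi = np.zeros((h, w))
        dapi[disc_mask((h, w), (30, 38), 5)] = 8_000.0
        stack = stack_from({"DAPI": dapi})
        params = SegmentationParams(dapi_threshold=4_000.0)
        neuronal, nonneuronal = nuclei_instances(
            stack, LabelMap(neuron.astype(np.int32)), params)
        assert neuronal.n_instances == 0
        assert nonneuronal.n_instances == 1
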