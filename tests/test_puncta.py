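import dataclasses

import numpy as np
import pytest

from drgquant import (ImageStack, LabelMap, PunctaParams, detect_puncta,
                      local_background, polarization_score)
from drgquant.puncta import NeuronTooSmallError
from helpers import puncta_pixels_oracle


def stack_from(arrays, pixel_area=0.42):
    return ImageStack(channels={k: np.asarray(v, float) for k, v in arrays.items()},
                      pixel_area_um2=pixel_area, bit_depth=None)


def square_neuron(side=20, value=1000.0, shape=(40, 40), origin=(10, 10)):
    arr = np.zeros(shape)
    labels = np.zeros(shape, np.int32)
    r, c = origin
    arr[r:r + side, c:c + side] = value
    labels[r:r + side, c:c + side] = 1
    return arr, LabelMap(labels, class_name="neuron")


class TestLocalBackground:
    def test_uniform_neuron(self):
        arr, labels = square_neuron(value=1000.0)
        bg = local_background(stack_from({"MHCII": arr}), labels, 1,
                              PunctaParams())
        assert bg == 1000.0

    def test_median_robust_to_puncta(self):
        # 90% of pixels at 1000, 10% puncta at 2500: median stays 1000 while
        # a mean estimator would report 1150 and inflate the threshold
        arr, labels = square_neuron(value=1000.0)
        arr[10:14, 10:20] = 2500.0  # 40 of 400 px
        stack = stack_from({"MHCII": arr})
        assert local_background(stack, labels, 1, PunctaParams()) == 1000.0
        assert arr[labels.labels == 1].mean() == pytest.approx(1150.0)

    def test_annulus_variant_sees_outside_ring(self):
        arr, labels = square_neuron(value=1000.0)
        arr[labels.labels == 0] = 200.0
        params = PunctaParams(background_estimator="annulus_median")
        bg = local_background(stack_from({"MHCII": arr}), labels, 1, params)
        assert bg == 200.0

    def test_too_small_instance_rejected(self):
        arr = np.zeros((10, 10))
        labels = np.zeros((10, 10), np.int32)
        labels[4:6, 4:6] = 1
        with pytest.raises(NeuronTooSmallError):
            local_background(stack_from({"MHCII": arr}), LabelMap(labels), 1,
                             PunctaParams())


class TestDetectPuncta:
    def test_uniform_signal_no_puncta(self):
        arr, labels = square_neuron(value=1000.0)
        (ps,) = detect_puncta(stack_from({"MHCII": arr}), labels, PunctaParams())
        assert ps.count == 0 and ps.percent_area == 0.0

    def test_five_planted_puncta_counted_and_percent_area(self):
        # neuron 400 px with five 4-px puncta at background + 1200 → 5 puncta,
        # percent area 100·20/400 = 5.0
        arr, labels = square_neuron(value=1000.0)
        for i in range(5):
            r = 12 + 3 * i
            arr[r:r + 2, 12:14] = 2200.0
        (ps,) = detect_puncta(stack_from({"MHCII": arr}), labels, PunctaParams())
        assert ps.count == 5
        assert ps.percent_area == pytest.approx(5.0)

    def test_single_pixel_punctum_rejected(self):
        # the ≥1.5-px rule means integer areas must reach 2
        arr, labels = square_neuron(value=1000.0)
        arr[15, 15] = 2500.0
        (ps,) = detect_puncta(stack_from({"MHCII": arr}), labels, PunctaParams())
        assert ps.count == 0

    def test_monotone_in_delta_and_min_area(self, rng):
        # raising the intensity offset can only remove supra-threshold
        # pixels (monotone puncta area); on well-separated spots the count
        # is monotone too (at a lower offset nearby spots may merge, so the
        # count guarantee needs separation)
        arr, labels = square_neuron(value=1000.0)
        arr[labels.labels == 1] += rng.gamma(2.0, 400.0, size=400)
        stack = stack_from({"MHCII": arr})
        base = PunctaParams()
        areas_delta = [detect_puncta(stack, labels,
                                     dataclasses.replace(base, delta_afu=d)
                                     )[0].puncta_area_px
                       for d in (200.0, 500.0, 800.0, 1200.0)]
        assert areas_delta == sorted(areas_delta, reverse=True)
        counts_area = [detect_puncta(stack, labels,
                                     dataclasses.replace(base, min_area_px=a)
                                     )[0].count
                       for a in (1.0, 1.5, 3.0, 5.0)]
        assert counts_area == sorted(counts_area, reverse=True)

        spots, spot_labels = square_neuron(value=1000.0)
        for i, boost in enumerate((900.0, 1400.0, 2000.0)):
            r = 12 + 3 * i
            spots[r:r + 2, 12:14] = 1000.0 + boost
        spot_stack = stack_from({"MHCII": spots})
        counts_delta = [detect_puncta(spot_stack, spot_labels,
                                      dataclasses.replace(base, delta_afu=d)
                                      )[0].count
                        for d in (800.0, 1200.0, 1800.0, 2500.0)]
        assert counts_delta == [3, 2, 1, 0]

    def test_total_area_denominator(self):
        arr, labels = square_neuron(value=1000.0)
        arr[12:14, 12:14] = 2500.0
        stack = stack_from({"MHCII": arr})
        (ps,) = detect_puncta(stack, labels, PunctaParams(),
                              total_areas={1: 800})
        assert ps.percent_area == pytest.approx(100.0 * 4 / 800)

    def test_too_small_neuron_flagged_not_scored(self):
        arr = np.zeros((10, 10))
        labels = np.zeros((10, 10), np.int32)
        labels[4:7, 4:7] = 1
        (ps,) = detect_puncta(stack_from({"MHCII": arr}), LabelMap(labels),
                              PunctaParams())
        assert not ps.scored

    def test_percent_area_bounded(self, rng):
        params = PunctaParams(delta_afu=50.0)
        for _ in range(20):
            arr, labels = square_neuron(value=100.0)
            arr += rng.uniform(0, 300, size=arr.shape)
            (ps,) = detect_puncta(stack_from({"MHCII": arr}), labels, params)
            assert 0.0 <= ps.percent_area <= 100.0

    def test_matches_pixelwise_oracle(self, rng):
        params = PunctaParams()
        for _ in range(10):
            arr, labels = square_neuron(value=1000.0, side=24, shape=(30, 30),
                                        origin=(3, 3))
            arr += rng.normal(0, 120, size=arr.shape)
            arr = np.clip(arr, 0, None)
            n_spots = rng.integers(0, 6)
            for _ in range(n_spots):
                r, c = rng.integers(5, 24, size=2)
                arr[r:r + 2, c:c + 2] += 1500.0
            stack = stack_from({"MHCII": arr})
            (ps,) = detect_puncta(stack, labels, params)
            got = {frozenset(zip(comp.pixels[0].tolist(), comp.pixels[1].tolist()))
                   for comp in ps.components}
            expected = puncta_pixels_oracle(arr, labels.labels == 1,
                                            params.delta_afu, params.min_area_px)
            assert got == expected


class TestPolarizationScore:
    def test_uniform_signal_zero(self):
        arr, labels = square_neuron(value=1000.0)
        score = polarization_score(stack_from({"MHCII": arr}), labels, 1,
                                   PunctaParams())
        assert score == 0.0

    def test_planted_cap_fraction_recovered(self):
        # 500-px cell with a 50-px contiguous cap at 2.0× background → 10.0%
        arr = np.zeros((40, 40))
        labels = np.zeros((40, 40), np.int32)
        arr[5:25, 5:30] = 1000.0
        labels[5:25, 5:30] = 1
        arr[5:7, 5:30] = 2000.0  # 2 rows × 25 cols = 50 px cap
        score = polarization_score(stack_from({"MHCII": arr}), LabelMap(labels),
                                   1, PunctaParams())
        assert score == pytest.approx(10.0)

    def test_cap_below_fold_threshold_scores_zero(self):
        arr = np.zeros((40, 40))
        labels = np.zeros((40, 40), np.int32)
        arr[5:25, 5:30] = 1000.0
        labels[5:25, 5:30] = 1
        arr[5:7, 5:30] = 1600.0  # 1.6-fold < 1.7-fold gate
        score = polarization_score(stack_from({"MHCII": arr}), LabelMap(labels),
                                   1, PunctaParams())
        assert score == 0.0

    def test_zero_background_with_signal_warns(self):
        arr = np.zeros((40, 40))
        labels = np.zeros((40, 40), np.int32)
        labels[5:25, 5:30] = 1
        arr[5:7, 5:10] = 500.0  # signal on a zero-background cell
        with pytest.warns(UserWarning, match="fold change undefined"):
            score = polarization_score(stack_from({"MHCII": arr}),
                                       LabelMap(labels), 1, PunctaParams())
        assert 0.0 < score <= 100.0

    def test_score_bounded_on_random_inputs(self, rng):
        params = PunctaParams()
        for _ in range(20):
            arr, labels = square_neuron(value=500.0)
            arr += rng.uniform(0, 2000, size=arr.shape)
            score = polarization_score(stack_from({"MHCII": arr}), labels, 1,
                                       params)
            assert 0.0 <= score <= 100.0
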