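import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from skimage.draw import disk

from salamivision import (
    DEFAULT_AREA_CLASS_EDGES,
    FatParticle,
    PipelineConfig,
    area_class_histogram,
    generate_phantom,
    measure_particle,
    measure_slice,
    roundness,
    summarize_sample,
    visible_fat_content,
)


def particle(area, label=1):
    # perimeter value is irrelevant for area-based operations
    return FatParticle(label=label, area_cm2=area, perimeter_cm=1.0,
                       roundness=1.0, centroid=(0.0, 0.0))


def disk_labels(radius, pad=10):
    lab = np.zeros((2 * radius + 2 * pad,) * 2, np.int32)
    rr, cc = disk((radius + pad, radius + pad), radius)
    lab[rr, cc] = 1
    return lab


class TestRoundness:
    def test_ideal_circle_is_exactly_one(self):
        assert roundness(math.pi, 2 * math.pi) == 1.0

    def test_unit_square_closed_form(self):
        assert roundness(1.0, 4.0) == pytest.approx(4 / math.pi)

    def test_two_to_one_ellipse_against_arclength_oracle(self):
        a, b = 2.0, 1.0
        perim, _ = quad(lambda t: math.sqrt(a ** 2 * math.sin(t) ** 2 + b ** 2 * math.cos(t) ** 2),
                        0, 2 * math.pi)
        rf = roundness(math.pi * a * b, perim)
        assert rf == pytest.approx(1.189, abs=2e-3)
        assert rf > 1  # elongation raises roundness

    @pytest.mark.parametrize("area, perim", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_nonpositive_inputs_rejected(self, area, perim):
        with pytest.raises(ValueError):
            roundness(area, perim)

    @given(area=st.floats(1e-3, 1e3), perim=st.floats(1e-3, 1e3), k=st.floats(1e-2, 1e2))
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, area, perim, k):
        # scaling a shape by k multiplies area by k^2 and perimeter by k
        assert roundness(k ** 2 * area, k * perim) == pytest.approx(roundness(area, perim), rel=1e-9)


class TestMeasureParticle:
    def test_digitized_disk_area_and_roundness(self):
        p = measure_particle(disk_labels(60), 1, 0.01)
        assert p.area_cm2 == pytest.approx(math.pi * 0.6 ** 2, rel=0.01)
        assert p.roundness == pytest.approx(1.0, rel=0.05)

    def test_digitized_disk_roundness_converges_monotonically(self):
        errors = [abs(measure_particle(disk_labels(r), 1, 0.01).roundness - 1.0)
                  for r in (10, 30, 100)]
        assert errors[0] > errors[1] > errors[2]

    def test_single_pixel_particle_is_finite(self):
        lab = np.zeros((16, 16), np.int32)
        lab[8, 8] = 1
        p = measure_particle(lab, 1, 0.01)
        assert p.area_cm2 == pytest.approx(0.01 ** 2)
        assert math.isfinite(p.perimeter_cm) and p.perimeter_cm > 0
        assert math.isfinite(p.roundness) and p.roundness > 0

    def test_square_region_closed_form(self):
        lab = np.zeros((120, 120), np.int32)
        lab[10:110, 10:110] = 1
        p = measure_particle(lab, 1, 0.01)
        assert p.area_cm2 == pytest.approx(1.0)
        assert p.roundness == pytest.approx(4 / math.pi, rel=0.05)

    def test_absent_label_raises(self):
        with pytest.raises(KeyError):
            measure_particle(disk_labels(10), 7, 0.01)

    def test_border_particle_flagged(self):
        lab = np.zeros((64, 64), np.int32)
        lab[30:34, 30:34] = 1  # interior
        lab[10:14, 0:4] = 2  # at slice edge
        slice_mask = np.zeros((64, 64), bool)
        slice_mask[5:60, 0:60] = True
        assert not measure_particle(lab, 1, 0.01, slice_mask).touches_border
        assert measure_particle(lab, 2, 0.01, slice_mask).touches_border


class TestVisibleFatContent:
    def test_direct_ratio(self):
        assert visible_fat_content([particle(1), particle(2), particle(3)], 100.0) == pytest.approx(6.0)

    def test_empty_particle_list_is_zero(self):
        assert visible_fat_content([], 50.0) == 0.0

    def test_nonpositive_slice_area_rejected(self):
        with pytest.raises(ValueError):
            visible_fat_content([particle(1)], 0.0)

    def test_invariant_to_calibration(self, small_spec):
        # VFC is a ratio of areas: rescaling cm_per_pixel must not move it
        image, _ = generate_phantom(small_spec(seed=2))
        m1, _, _ = measure_slice(image, PipelineConfig())
        rescaled = type(image)(image.pixels, image.cm_per_pixel * 3.7, image.source_id)
        m2, _, _ = measure_slice(rescaled, PipelineConfig())
        assert m1.vfc_pct == pytest.approx(m2.vfc_pct, rel=1e-9)
        assert m1.n == m2.n


class TestAreaClassHistogram:
    def test_anchor_classes(self):
        areas = [0.05, 0.05, 0.3, 6.0]
        h = area_class_histogram([particle(a) for a in areas], DEFAULT_AREA_CLASS_EDGES)
        assert h.counts[0] == 2  # [0, 0.1)
        assert h.counts[1] == 1  # [0.1, 0.5) holds 0.3
        assert h.counts[-1] == 1  # [5, inf)
        assert h.counts.sum() == 4
        assert h.frequencies.sum() == pytest.approx(1.0)

    def test_edge_value_goes_to_upper_class(self):
        h = area_class_histogram([particle(0.1)], DEFAULT_AREA_CLASS_EDGES)
        assert h.counts[1] == 1 and h.counts[0] == 0

    def test_empty_list_flagged_undefined(self):
        h = area_class_histogram([], DEFAULT_AREA_CLASS_EDGES)
        assert h.counts.sum() == 0
        assert h.frequencies is None

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, derandomize=True)
    def test_conservation_against_bruteforce_binning(self, seed):
        rng = np.random.default_rng(seed)
        areas = rng.lognormal(math.log(0.1), 1.2, size=1000)
        h = area_class_histogram([particle(a) for a in areas], DEFAULT_AREA_CLASS_EDGES)
        assert h.counts.sum() == 1000
        edges = list(DEFAULT_AREA_CLASS_EDGES) + [math.inf]
        brute = [sum(1 for a in areas if lo <= a < hi) for lo, hi in zip(edges, edges[1:])]
        assert h.counts.tolist() == brute


class TestMeasureSlice:
    def test_fat_free_phantom(self, small_spec):
        image, _ = generate_phantom(small_spec(n_particles=0, coverage=None, seed=1))
        m, _, _ = measure_slice(image, PipelineConfig())
        assert m.n == 0
        assert m.vfc_pct == 0.0
        assert math.isnan(m.af_mean_cm2)

    def test_deterministic_repeat(self, small_spec):
        image, _ = generate_phantom(small_spec(seed=4))
        m1, _, _ = measure_slice(image, PipelineConfig())
        m2, _, _ = measure_slice(image, PipelineConfig())
        assert m1.n == m2.n
        assert m1.vfc_pct == m2.vfc_pct
        assert [p.area_cm2 for p in m1.particles] == [p.area_cm2 for p in m2.particles]
        np.testing.assert_array_equal(m1.histogram.counts, m2.histogram.counts)

    def test_maxima_match_bruteforce_scan(self, small_spec):
        image, _ = generate_phantom(small_spec(seed=6))
        m, _, _ = measure_slice(image, PipelineConfig())
        areas = [p.area_cm2 for p in m.particles]
        rfs = [p.roundness for p in m.particles]
        assert m.af_max_cm2 == max(areas)
        assert m.rf_max == max(rfs)
        assert m.af_mean_cm2 == pytest.approx(sum(areas) / len(areas))
        assert m.rf_mean == pytest.approx(sum(rfs) / len(rfs))
        assert m.n_per_area == pytest.approx(m.n / m.area_slice_cm2)


class TestSummarizeSample:
    def _measurement(self, vfc):
        from salamivision.morphometry import AreaClassHistogram, SliceMeasurement

        h = AreaClassHistogram(DEFAULT_AREA_CLASS_EDGES, np.zeros(10, np.int64), None)
        return SliceMeasurement(source_id="X_1", n=0, area_slice_cm2=50.0, particles=(),
                                n_per_area=0.0, vfc_pct=vfc, af_mean_cm2=0.0, af_max_cm2=0.0,
                                rf_mean=0.0, rf_max=0.0, histogram=h)

    def test_hand_computed_mean_sd(self):
        s = summarize_sample([self._measurement(v) for v in (10, 12, 14)], "S")
        assert s.means["vfc_pct"] == pytest.approx(12.0)
        assert s.sds["vfc_pct"] == pytest.approx(2.0)
        assert s.n_replicates == 3

    def test_single_replicate_sd_zero_with_warning(self):
        with pytest.warns(UserWarning):
            s = summarize_sample([self._measurement(11)], "S")
        assert s.means["vfc_pct"] == 11.0
        assert s.sds["vfc_pct"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_sample([], "S")
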