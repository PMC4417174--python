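import numpy as np
import pandas as pd
import pytest

from etsdyn.exceptions import ValidationError
from etsdyn.footprint import (Electropherogram, PeakTable, flag_changes,
                              hypersensitivity_check, integrate_peaks,
                              normalize_to_control, protection,
                              subtract_baseline)


def gaussian_trace(centers, amps, sigma=2.0, n=400, offset=0.0):
    scan = np.arange(float(n))
    sig = np.full(n, offset)
    for c, a in zip(np.atleast_1d(centers), np.atleast_1d(amps)):
        sig += a * np.exp(-0.5 * ((scan - c) / sigma) ** 2)
    return Electropherogram(scan, sig)


def window_map(rows):
    return pd.DataFrame(rows, columns=["base_index", "window_start",
                                       "window_end", "is_control"])


def table(areas: dict, control=None, normalized=False):
    df = pd.DataFrame({"base_index": list(areas), "area": list(areas.values())})
    t = PeakTable(df, control_index=control)
    return normalize_to_control(t) if normalized else t


class TestIntegratePeaks:
    def test_gaussian_area_analytic(self):
        A, sigma = 100.0, 2.0
        trace = gaussian_trace(50.0, A, sigma)
        im = window_map([(1, 30.0, 70.0, False)])
        t = integrate_peaks(trace, im)
        assert t.area(1) == pytest.approx(A * sigma * np.sqrt(2 * np.pi), rel=0.01)

    def test_zero_signal_gives_zero_areas(self):
        trace = Electropherogram(np.arange(100.0), np.zeros(100))
        im = window_map([(1, 10.0, 30.0, False), (2, 40.0, 60.0, False)])
        t = integrate_peaks(trace, im)
        assert t.area(1) == 0.0 and t.area(2) == 0.0

    def test_window_split_conserves_area(self):
        trace = gaussian_trace(50.0, 100.0)
        whole = integrate_peaks(trace, window_map([(1, 30.0, 70.0, False)]))
        halves = integrate_peaks(trace, window_map([
            (1, 30.0, 50.0, False), (2, 50.0, 70.0, False)]))
        assert halves.area(1) + halves.area(2) == pytest.approx(
            whole.area(1), rel=1e-9)

    def test_overlapping_windows_rejected(self):
        trace = gaussian_trace(50.0, 100.0)
        with pytest.raises(ValidationError, match="overlap"):
            integrate_peaks(trace, window_map([
                (1, 30.0, 55.0, False), (2, 50.0, 70.0, False)]))

    def test_window_outside_trace_rejected(self):
        trace = gaussian_trace(50.0, 100.0, n=100)
        with pytest.raises(ValidationError):
            integrate_peaks(trace, window_map([(1, 90.0, 120.0, False)]))


class TestNormalizeToControl:
    def test_control_maps_to_one(self):
        t = table({1: 50.0, 2: 25.0}, control=1, normalized=True)
        assert t.normalized_area(1) == 1.0
        assert t.normalized_area(2) == 0.5

    def test_uniform_rescaling_cancels(self):
        t1 = table({1: 50.0, 2: 25.0}, control=1, normalized=True)
        t3 = table({1: 150.0, 2: 75.0}, control=1, normalized=True)
        assert t3.normalized_area(2) == t1.normalized_area(2)

    def test_zero_control_rejected(self):
        with pytest.raises(ValidationError, match="control"):
            table({1: 0.0, 2: 25.0}, control=1, normalized=True)


class TestProtection:
    def test_identical_tables_zero_protection(self):
        t = table({1: 40.0, 2: 40.0, 9: 60.0}, control=9, normalized=True)
        rep = protection(t, t, core_indices=[1, 2])
        assert rep.protection_percent == 0.0
        assert rep.delta_flags == []

    def test_ninety_percent_protection(self):
        unbound = table({1: 40.0, 2: 40.0, 9: 60.0}, control=9, normalized=True)
        bound = table({1: 4.0, 2: 4.0, 9: 60.0}, control=9, normalized=True)
        rep = protection(bound, unbound, core_indices=[1, 2])
        assert rep.protection_percent == pytest.approx(90.0)

    def test_hypersensitive_core_reports_negative(self):
        unbound = table({1: 40.0, 9: 60.0}, control=9, normalized=True)
        bound = table({1: 80.0, 9: 60.0}, control=9, normalized=True)
        rep = protection(bound, unbound, core_indices=[1])
        assert rep.protection_percent == pytest.approx(-100.0)

    def test_reporting_granularity(self):
        unbound = table({1: 3.0, 9: 2.0}, control=9, normalized=True)
        bound = table({1: 1.0, 9: 2.0}, control=9, normalized=True)
        rep = protection(bound, unbound, core_indices=[1])
        assert rep.protection_percent == round(100 * (1 - 1 / 3), 1)
        assert rep.core_fraction_unbound_rounded == 1.5

    def test_zero_unbound_core_rejected(self):
        unbound = table({1: 0.0, 9: 60.0}, control=9, normalized=True)
        bound = table({1: 4.0, 9: 60.0}, control=9, normalized=True)
        with pytest.raises(ValidationError):
            protection(bound, unbound, core_indices=[1])


class TestFlagChanges:
    def test_identical_tables_no_flags(self):
        t = table({1: 10.0, 2: 20.0, 9: 30.0}, control=9, normalized=True)
        assert flag_changes(t, t) == []

    def test_threshold_arithmetic(self):
        unbound = table({1: 0.5, 2: 0.5, 9: 1.0}, control=9, normalized=True)
        bound = table({1: 0.65, 2: 0.55, 9: 1.0}, control=9, normalized=True)
        # 30% change flagged, 10% not
        assert flag_changes(bound, unbound) == [1]

    def test_zero_threshold_flags_every_change(self):
        unbound = table({1: 0.5, 2: 0.5, 9: 1.0}, control=9, normalized=True)
        bound = table({1: 0.55, 2: 0.500001, 9: 1.0}, control=9, normalized=True)
        assert flag_changes(bound, unbound, threshold=0.0) == [1, 2]

    def test_zero_unbound_nonzero_bound_flagged(self):
        unbound = table({1: 0.0, 2: 0.5, 9: 1.0}, control=9, normalized=True)
        bound = table({1: 0.3, 2: 0.5, 9: 1.0}, control=9, normalized=True)
        assert flag_changes(bound, unbound) == [1]


class TestHypersensitivity:
    def test_threefold_ratio_is_site_specific(self):
        unbound = table({5: 0.4, 6: 0.4, 9: 1.0}, control=9, normalized=True)
        bound = table({5: 1.2, 6: 0.4, 9: 1.0}, control=9, normalized=True)
        assert hypersensitivity_check(bound, unbound, window=[5, 6]) is True

    def test_no_enhancement_not_site_specific(self):
        unbound = table({5: 0.4, 6: 0.4, 9: 1.0}, control=9, normalized=True)
        bound = table({5: 0.4, 6: 0.3, 9: 1.0}, control=9, normalized=True)
        assert hypersensitivity_check(bound, unbound, window=[5, 6]) is False

    def test_ratio_exactly_at_factor_not_flagged(self):
        unbound = table({5: 0.4, 9: 1.0}, control=9, normalized=True)
        bound = table({5: 0.8, 9: 1.0}, control=9, normalized=True)
        assert hypersensitivity_check(bound, unbound, window=[5], factor=2.0) is False

    def test_empty_window_rejected(self):
        t = table({5: 0.4, 9: 1.0}, control=9, normalized=True)
        with pytest.raises(ValidationError):
            hypersensitivity_check(t, t, window=[])


class TestPipelineInvariances:
    """integrate -> normalise -> protection is unchanged by uniform
    intensity scaling and by a common baseline offset (after removal)."""

    def _protection(self, scale=1.0, offset=0.0, baseline_window=None):
        centers = {1: 50.0, 2: 70.0, 9: 200.0}
        unbound_amps = {1: 100.0, 2: 100.0, 9: 120.0}
        bound_amps = {1: 10.0, 2: 10.0, 9: 120.0}
        im = window_map([(i, c - 8.0, c + 8.0, i == 9) for i, c in centers.items()])

        def build(amps):
            tr = gaussian_trace(list(centers.values()),
                                [amps[i] for i in centers], offset=offset)
            return Electropherogram(tr.scan, tr.signal * scale)

        pb = normalize_to_control(integrate_peaks(build(bound_amps), im,
                                                  baseline_window=baseline_window))
        pu = normalize_to_control(integrate_peaks(build(unbound_amps), im,
                                                  baseline_window=baseline_window))
        return protection(pb, pu, core_indices=[1, 2]).protection_percent

    def test_known_suppression_recovered(self):
        assert self._protection() == pytest.approx(90.0, abs=90.0 * 0.02)

    def test_uniform_scaling_invariance(self):
        assert self._protection(scale=3.0) == pytest.approx(self._protection())

    def test_baseline_offset_removed(self):
        with_offset = self._protection(offset=25.0, baseline_window=101)
        assert with_offset == pytest.approx(self._protection(), abs=0.3)

    def test_subtract_baseline_removes_constant(self):
        tr = gaussian_trace(50.0, 100.0, offset=25.0)
        flat = subtract_baseline(tr, window=101)
        ref = gaussian_trace(50.0, 100.0)
        assert flat.signal == pytest.approx(ref.signal, abs=1e-6)
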