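"""Duration and phase metrics against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nfkbdyn.exceptions import SpecificationError
from nfkbdyn.metrics import (ActivityCurve, duration, persistence_time,
                             phase_metrics, threshold_value)


def brute_force_duration(curve, threshold, dt=1e-4):
    """Counting above-threshold samples on a dense grid (independent oracle)."""
    grid = np.arange(curve.times[0], curve.times[-1], dt)
    values = np.interp(grid, curve.times, curve.values)
    return float(np.sum(values > threshold) * dt)


class TestDuration:
    def test_flat_curve_has_zero_duration(self):
        curve = ActivityCurve(np.linspace(0, 10, 11), np.full(11, 3.0), 3.0)
        res = duration(curve)
        assert res.duration == 0.0
        assert res.crossing_intervals == ()

    def test_triangle_crossings_by_interpolation(self):
        """Triangle 0->100 over [0,1], back to 0 over [1,2], basal 0:
        threshold 5, crossings at 0.05 and 1.95, duration 1.90 h."""
        curve = ActivityCurve(np.array([0.0, 1.0, 2.0]),
                              np.array([0.0, 100.0, 0.0]), 0.0)
        res = duration(curve)
        assert res.threshold == pytest.approx(5.0)
        (a, b), = res.crossing_intervals
        assert a == pytest.approx(0.05, abs=1e-12)
        assert b == pytest.approx(1.95, abs=1e-12)
        assert res.duration == pytest.approx(1.90, abs=1e-12)

    def test_below_basal_peak_is_not_an_error(self):
        curve = ActivityCurve(np.linspace(0, 9, 10),
                              np.linspace(5.0, 1.0, 10), 5.0)
        assert duration(curve).duration == 0.0

    def test_open_interval_reaches_last_sample(self):
        t = np.linspace(0, 10, 101)
        v = np.where(t > 4, 50.0, 1.0)
        curve = ActivityCurve(t, v, 1.0)
        res = duration(curve)
        assert res.crossing_intervals[-1][1] == pytest.approx(10.0)
        assert persistence_time(curve) == pytest.approx(10.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_piecewise_linear_curves(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 30)
        times = np.sort(rng.uniform(0, 10, n))
        times = np.unique(np.round(times, 5))
        if times.size < 3:
            times = np.array([0.0, 5.0, 10.0])
        values = rng.uniform(0, 10, times.size)
        curve = ActivityCurve(times, values, basal=float(values.min()))
        res = duration(curve)
        # unfiltered interval sum vs dense-grid counting: within a grid step
        # per crossing pair
        from nfkbdyn.metrics import above_threshold_intervals
        unfiltered = above_threshold_intervals(curve, res.threshold,
                                               min_excursion=0.0)
        total = sum(b - a for a, b in unfiltered)
        brute = brute_force_duration(curve, res.threshold)
        assert abs(total - brute) <= 2e-4 * (len(unfiltered) + 1)
        # the reported duration only drops grazing contacts
        assert total - 0.011 * len(unfiltered) <= res.duration <= total + 1e-12


class TestPhaseMetrics:
    def test_constant_curve_has_zero_aucs(self):
        t = np.linspace(0, 10, 101)
        curve = ActivityCurve(t, np.full_like(t, 4.0), 4.0)
        pm = phase_metrics(curve)
        assert pm.early_auc == 0.0 and pm.late_auc == 0.0

    def test_linear_ramp_late_auc_is_closed_form(self):
        """values = basal + t: late AUC over [6, 8] is the integral of t,
        i.e. 14 nM*h; trapezoid is exact for linear curves."""
        t = np.linspace(0, 10, 2001)
        curve = ActivityCurve(t, 2.0 + t, 2.0)
        pm = phase_metrics(curve)
        assert pm.late_auc == pytest.approx(14.0, rel=5e-3)
        assert pm.early_auc == pytest.approx(2.0, rel=5e-3)

    def test_auc_against_fine_quadrature_for_smooth_curve(self):
        t = np.linspace(0, 10, 401)
        values = 3.0 + 20 * np.exp(-0.5 * (t - 1.5) ** 2)
        curve = ActivityCurve(t, values, 3.0)
        pm = phase_metrics(curve)
        from scipy.integrate import quad
        exact_late = quad(lambda x: 20 * np.exp(-0.5 * (x - 1.5) ** 2),
                          6, 8)[0]
        exact_early = quad(lambda x: 20 * np.exp(-0.5 * (x - 1.5) ** 2),
                           0, 2)[0]
        assert pm.late_auc == pytest.approx(exact_late, rel=5e-3, abs=1e-6)
        assert pm.early_auc == pytest.approx(exact_early, rel=5e-3)

    def test_biphasic_segmentation(self):
        t = np.linspace(0, 16, 1601)
        v = 1.0 + 100 * np.exp(-((t - 0.5) / 0.3) ** 2) \
            + 30 * np.exp(-((t - 7.0) / 2.0) ** 2)
        curve = ActivityCurve(t, v, 1.0)
        pm = phase_metrics(curve)
        assert 0.5 < pm.first_peak_duration < 2.0
        assert 2.0 < pm.second_phase_onset < 5.5
        assert not pm.second_phase_open  # second bump closes before 16 h

    def test_short_curve_rejected(self):
        t = np.linspace(0, 5, 51)
        with pytest.raises(SpecificationError, match="at least"):
            phase_metrics(ActivityCurve(t, np.ones_like(t), 1.0))


def test_threshold_is_basal_plus_five_percent_of_excess():
    t = np.linspace(0, 10, 101)
    curve = ActivityCurve(t, 2.0 + 40 * np.exp(-t), 2.0)
    assert threshold_value(curve) == pytest.approx(2.0 + 0.05 * 40.0,
                                                   rel=1e-3)
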