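"""IKK2 input profiles: shapes, threshold-rule durations, pulse trains."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nfkbdyn.exceptions import SpecificationError
from nfkbdyn.ikk import (DEFAULT_BASAL, PulseTrainSpec,
                         TheoreticalPulseSpec, compose_pulse_train,
                         make_il1b_profile, make_theoretical_profile,
                         make_tnfc_profile, make_tnfp_profile,
                         trapezoid_profile)
from nfkbdyn.metrics import ActivityCurve, duration


def profile_duration(profile, t_end=None, n=200001):
    grid = np.linspace(-0.5, t_end or profile.support_end + 1.0, n)
    curve = ActivityCurve(grid, profile.evaluate(grid), basal=profile.basal)
    return duration(curve).duration


class TestTheoreticalPulse:
    @pytest.mark.parametrize("peak,dur", [(60.0, 8.0), (15.0, 2.0),
                                          (120.0, 4.0)])
    def test_peak_and_threshold_duration_match_request(self, peak, dur):
        profile = make_theoretical_profile(
            TheoreticalPulseSpec(peak_amplitude=peak, duration=dur))
        assert profile.peak == pytest.approx(peak, rel=1e-6)
        assert profile_duration(profile) == pytest.approx(dur, rel=0.02)

    def test_flat_pulse_has_zero_duration(self):
        profile = make_theoretical_profile(
            TheoreticalPulseSpec(peak_amplitude=DEFAULT_BASAL, duration=2.0))
        assert profile_duration(profile, t_end=5.0) == 0.0

    def test_duration_shorter_than_edges_rejected(self):
        with pytest.raises(SpecificationError, match="shorter than"):
            TheoreticalPulseSpec(peak_amplitude=60.0, duration=0.3,
                                 rise_time=0.25, fall_time=0.25)

    def test_trapezoid_area_matches_quadrature(self):
        """Linear rise r, plateau p, fall f: area above basal is
        A (p + (r + f) / 2)."""
        amp, r, p, f = 40.0, 0.5, 2.0, 1.0
        profile = trapezoid_profile(DEFAULT_BASAL + amp, r, p, f)
        analytic = amp * (p + (r + f) / 2.0)
        assert profile.area_above_basal() == pytest.approx(analytic, rel=1e-5)

    def test_duration_monotone_in_request_and_amplitude_invariant(self):
        durations = [1.0, 2.0, 4.0, 8.0]
        measured = [profile_duration(make_theoretical_profile(
            TheoreticalPulseSpec(60.0, d))) for d in durations]
        assert all(b > a for a, b in zip(measured, measured[1:]))
        for amp in (15.0, 120.0):
            alt = profile_duration(make_theoretical_profile(
                TheoreticalPulseSpec(amp, 4.0)))
            ref = measured[2]
            assert abs(alt - ref) / ref < 0.02


class TestRegimeProfiles:
    def test_tnfp_is_brief(self):
        profile = make_tnfp_profile()
        assert profile_duration(profile, t_end=4.0) <= 1.0
        peak_time = np.linspace(0, 1, 2001)[
            np.argmax(profile.evaluate(np.linspace(0, 1, 2001)))]
        assert peak_time <= 0.25
        corrected_peak = profile.peak - profile.basal
        assert profile.evaluate(1.0) - profile.basal <= 0.05 * corrected_peak

    def test_tnfc_is_sustained(self):
        profile = make_tnfc_profile()
        thr = profile.basal + 0.05 * (profile.peak - profile.basal)
        assert profile.evaluate(8.0) > thr
        # plateau at >= 20% of the basal-corrected peak
        assert (profile.evaluate(8.0) - profile.basal) >= \
            0.2 * (profile.peak - profile.basal)

    @pytest.mark.parametrize("maker", [make_tnfp_profile, make_tnfc_profile,
                                       make_il1b_profile])
    def test_basal_before_stimulation(self, maker):
        profile = maker()
        assert profile.evaluate(-1.0) == pytest.approx(profile.basal)
        grid = np.linspace(-2, profile.support_end + 2, 50001)
        values = profile.evaluate(grid)
        assert np.all(values >= 0)
        assert np.all(np.isfinite(values))
        # deterministic: repeated evaluation is identical
        assert np.array_equal(values, profile.evaluate(grid))


class TestPulseTrains:
    def test_single_pulse_identity(self):
        base = make_tnfp_profile()
        train = compose_pulse_train(PulseTrainSpec(1, 3.0, base))
        grid = np.linspace(-1, 10, 5001)
        assert np.array_equal(train.evaluate(grid), base.evaluate(grid))

    def test_triple_pulse_peaks_follow_onsets(self):
        base = make_tnfp_profile()
        train = compose_pulse_train(PulseTrainSpec(3, 2.0, base))
        assert train.onsets == (0.0, 2.0, 4.0)
        for onset in train.onsets:
            window = np.linspace(onset, onset + 0.5, 2001)
            values = train.evaluate(window)
            peak_t = window[np.argmax(values)]
            assert peak_t - onset <= 0.25

    def test_disjoint_pulses_have_additive_area(self):
        base = make_theoretical_profile(TheoreticalPulseSpec(60.0, 1.0))
        train = compose_pulse_train(PulseTrainSpec(2, 20.0, base))
        assert train.area_above_basal() == pytest.approx(
            2.0 * base.area_above_basal(), rel=1e-3)

    def test_overlapping_pulses_never_exceed_single_peak(self):
        base = make_tnfp_profile()
        train = compose_pulse_train(PulseTrainSpec(3, 0.1, base))
        assert train.peak <= base.peak + 1e-9

    def test_negative_separation_rejected(self):
        with pytest.raises(SpecificationError):
            PulseTrainSpec(2, -1.0, make_tnfp_profile())


@settings(max_examples=30, deadline=None, derandomize=True)
@given(peak=st.floats(5.0, 200.0), dur=st.floats(1.0, 12.0))
def test_threshold_duration_property(peak, dur):
    """Requested and measured 5%-threshold durations agree within 2% for any
    admissible amplitude/duration combination."""
    profile = make_theoretical_profile(TheoreticalPulseSpec(peak, dur))
    assert profile_duration(profile, n=100001) == pytest.approx(dur, rel=0.02)
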